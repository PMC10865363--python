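"""Coordination-sphere geometry of one binuclear zinc-sulfamide complex.

Builds the monosubstituted-sulfamide stand-in (the 4W9Y-like model), mines
it for the motif and prints the full geometric site report: first and
second coordination shells of each zinc, inter-zinc distance, candidate
hydrogen bonds of the ligand, and the ligand hydration count.
"""

from bizinc import mine, site_report, synthetic_complex
from bizinc.geometry import report_table

st = synthetic_complex("4W9Y")
(match,) = mine([st]).matches[st.id]
report = site_report(st, match)

print(f"structure: {st.id}   nuclearity: {report.nuclearity}")
for (i, j), d in report.inter_metal_distances.items():
    print(f"inter-zinc distance: {d:.1f} A")
print()
print(report_table(st, report).to_string(index=False))
print("\nFirst shell = dative contacts <= 2.5 A; second shell = (2.5, 3.2] A;")
print("hydrogen-bond candidates are ligand N/O vs environment N/O in [2.2, 3.5] A.")
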