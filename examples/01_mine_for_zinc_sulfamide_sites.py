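"""Mine a set of structures for zinc-bound sulfamide motifs.

Runs the four-stage funnel (element prefilter, sulfamide substructure,
6-angstrom zinc proximity, nuclearity) over the five synthetic stand-in
complexes plus three decoys, and prints the funnel counts and per-match
classification. Only the three sulfamide complexes should survive as
binuclear sites; the phosphonate/phosphinate ligands are rejected by the
substructure pattern, the decoys by the stage their defect touches.
"""

from bizinc import all_synthetic_complexes, build_decoy, mine
from bizinc.mining import report_table

structures = list(all_synthetic_complexes().values())
structures += [build_decoy(kind)[0] for kind in
               ("mononuclear", "sulfonamide_not_sulfamide", "no_metal")]

report = mine(structures)
stages = ["scanned", "element pass", "pattern pass", "zinc within 6 A", "binuclear"]
for stage, count in zip(stages, report.funnel()):
    print(f"{stage:>16s}: {count}")
print()
print(report_table(report).to_string(index=False))
print("\nEach row is one matched sulfamide motif; min_dist is the shortest")
print("motif-to-zinc distance and nuclearity classifies the zinc center.")
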