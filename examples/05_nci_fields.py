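"""Promolecular NCI analysis of the bimetallic site.

Computes promolecular density, reduced density gradient and sign(lambda2)rho
over the zinc neighborhood of two stand-in complexes, classifies the low-s
low-rho region, and contrasts the ligand-zinc strong-attractive tally
between the bridging-amine binding mode and a second-shell bisubstituted
sulfamide. Cube files for external viewers are written to ./nci_out.
"""

from bizinc import synthetic_complex
from bizinc.nci import NCIParams, classify_interactions, compute_field, export_cubes

params = NCIParams(grid_spacing=0.35)  # coarse grid for a quick demo


def summarize(entry):
    st = synthetic_complex(entry)
    fields = compute_field(st, params)
    summary = classify_interactions(fields, params, st)
    pp = summary.per_pair
    mask = (
        (pp.atom_a.str.startswith("LIG") & pp.atom_b.str.startswith("ZN"))
        | (pp.atom_b.str.startswith("LIG") & pp.atom_a.str.startswith("ZN"))
    )
    lig_zn = int(pp[mask]["strong_attractive"].sum()) if not pp.empty else 0
    print(f"{entry}: {summary.n_analyzed} analysis points | "
          f"strong-attractive {summary.fraction_strong_attractive:.2f}, "
          f"vdW {summary.fraction_vdw:.2f}, repulsive {summary.fraction_repulsive:.2f} | "
          f"ligand-Zn strong points: {lig_zn}")
    return st, fields


st, fields = summarize("4W9Y")   # bridging amine: direct Zn engagement
summarize("6SKH")                # bisubstituted: second shell only
paths = export_cubes(fields, st, "nci_out", stem="4w9y")
print("\nwrote:", *[str(p) for p in paths])
print("Strong-attractive points between ligand and zinc mark direct metal")
print("coordination; their absence in the bisubstituted complex reflects the")
print("sulfamide's retreat to the second shell.")
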