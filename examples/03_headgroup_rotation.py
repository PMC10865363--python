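"""Measure the sulfamide-vs-phosphinate headgroup rotation.

Superposes the monosubstituted-sulfamide stand-in onto the phosphonate
stand-in using backbone atoms near the zincs, then expresses both
tetrahedral headgroups in a local frame (origin at S/P, z along the bond to
the linking substituent) and reports the circular-mean rotation of the
triangular base. The stand-ins are built with a designed 22 degree
reorientation, matching the difference between the two binding modes.
"""

from bizinc import synthetic_complex
from bizinc.superpose import backbone_pairing, frame_from_component, headgroup_rotation, superpose

a = synthetic_complex("4W9Y")  # sulfamide
b = synthetic_complex("2PVW")  # phosphonate

pairing = backbone_pairing(a, b, within=8.0)
sup = superpose(a.positions, b.positions, pairing)
fa = frame_from_component(a, next(iter(a.ligand_components())), "S1", "N2")
fb = frame_from_component(b, next(iter(b.ligand_components())), "P1", "C1")
angle, details = headgroup_rotation(a, fa, b, fb, sup, return_details=True)

print(f"superposition: {len(pairing.pairs)} backbone pairs, rmsd {sup.rmsd:.2e} A")
print(f"headgroup rotation: {angle:.1f} degrees")
print(f"per-base-atom azimuth offsets: {[round(o, 2) for o in details['offsets']]}")
print("\nThe rotation is reported modulo the three-fold symmetry of the")
print("tetrahedral base, so values lie in [0, 60] degrees.")
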