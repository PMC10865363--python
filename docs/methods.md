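# Methods

This note documents the models, conventions and numerical choices behind
`bizinc`, in the spirit of a methods appendix: what each stage computes,
which parameters matter, and what the synthetic data does and does not
emulate.

## Structure model

Structures are read with gemmi (PDB and mmCIF) and flattened to a single
conformer model: first coordinate model only, and for alternate locations
the highest-occupancy conformer, ties broken by alt-loc letter. This gives
a deterministic single-conformer model at the cost of discarding minor
conformers — acceptable here because every downstream quantity is a
heavy-atom distance or a field over one conformation. Deposited crystal
structures carry no hydrogens, so **all** distance criteria in the package
are heavy-atom criteria; nothing infers protonation from geometry. Where a
protonation state matters scientifically (the sulfamide NH⁻ vs NH₂
ambiguity, histidine tautomers in cluster models) it is carried as
metadata, never as a geometric edit.

Covalent bonds inside a chemical component are perceived by the standard
distance heuristic: bonded iff d ≤ r_cov(A) + r_cov(B) + 0.45 Å, with
covalent radii from gemmi. The 0.45 Å tolerance spans X-ray coordinate
error without bridging 1,3-neighbors at typical geometries. Metals are
excluded from covalent perception by construction: metal–ligand contacts
are dative/second-shell phenomena and are handled by the coordination
module, not the bond graph.

## Mining funnel

The funnel stages are deliberately ordered from cheap to specific and each
gates the next, so reported counts are monotone:

1. *Element prefilter*: every required element (default S, O, N, Zn) occurs
   in the structure.
2. *Substructure*: the sulfamide pattern S(O)(O)(N)N is matched into the
   element-labeled bond graph of each non-water ligand component (VF2
   monomorphism: pattern edges must exist; bond orders are ignored because
   deposited ligand dictionaries are unreliable for them). The sulfur slot
   additionally requires exactly four heavy-atom neighbors, which excludes
   higher-coordinate sulfur. O1/O2 and N1/N2 swaps describe the same
   chemical motif, so matches are deduplicated by their per-element atom
   sets. The matcher is cross-checked in the test suite against exhaustive
   enumeration on every graph of ≤ 12 atoms.
3. *Metal proximity*: a zinc within 6.0 Å (closed cutoff) of **any** of the
   five matched atoms. Measuring from any motif atom rather than a single
   named atom is the more permissive reading and is recorded in the report.
4. *Nuclearity*: binuclear iff at least two nearby zincs lie within 4.5 Å
   of each other. Crystallographic dizinc centers with a bridging ligand
   span roughly 3.0–3.7 Å; 4.5 Å adds headroom without merging adjacent
   mononuclear sites. Both cutoffs are closed (≤) so boundary behavior is
   deterministic, and both are parameters.

## Coordination geometry

First shell ≤ 2.5 Å, second shell (2.5, 3.2] Å. These bands bracket
typical ~2.0 Å N/O→Zn dative bonds and the > 2.8 Å second-sphere contacts
seen in these complexes, while tolerating coordinate error; both are
configurable. Hydrogen-bond candidates are ligand-N/O × environment-N/O
pairs within [2.2, 3.5] Å, metals excluded; without hydrogens no angle
term or donor/acceptor assignment is defensible, so roles are reported as
candidates only. Waters are identified strictly by component name (HOH and
synonyms); the catalytic water/hydroxide is geometrically a water for
counting purposes since crystallography cannot distinguish the two.
Reported tables round to 1 decimal (the precision of published distance
figures); full precision is kept internally.

Metals get stable labels (`zn1`, `zn2`) from a residue-contact fingerprint
(sorted first-shell protein residues) rather than from asserted catalytic
roles; the fingerprint→label mapping is recorded in the site report, so
cross-complex comparisons match metals by environment, not by file order.

## Superposition and headgroup rotation

Superposition is a Kabsch least-squares fit (proper rotations only —
reflections are rejected to preserve chirality), by default over backbone
N/CA/C atoms of residues within 8 Å of any zinc, matched across structures
by chain/residue/atom identity. RMSD is the root-mean-square residual after
the fit.

The headgroup rotation statistic operationalizes "the tetrahedral base is
rotated": after superposition, each headgroup is expressed in a local frame
with origin at the central atom (S or P) and z along the bond to the
linking substituent; the three base substituents get azimuths about z, and
the rotation is the circular mean of the three azimuth offsets, minimized
over the three cyclic base pairings. Because the base is three-fold
symmetric, a physical rotation t is measurable only as
min(t mod 120°, 120° − t mod 120°); reported values therefore lie in
[0°, 60°]. The chosen pairing and per-atom offsets can be returned for
inspection. On the built-in stand-in pair the statistic returns 22.0°
exactly, by construction of the models.

RMSF over coordinate ensembles follows the trajectory-analysis convention:
each frame is least-squares fitted onto the running mean structure
(iterated to convergence) before per-atom fluctuations are taken; the
superposition can be disabled for closed-form checks (for i.i.d. Gaussian
displacement of σ per coordinate, RMSF = σ√3).

## Cluster models

A recipe lists whole residues, capped fragments (kept atoms plus a named
cut bond) and water selection. Caps are single carbon atoms placed 1.53 Å
along the cut-bond vector from the kept atom — with hydrogen-free inputs,
a heavy-atom methyl stand-in keeps inventories exact and reproducible;
hydrogen addition is a post-processing hook for quantum-chemistry
pipelines. The water network is one pass of "water O within 3.5 Å of any
cluster heavy atom". Every atom carries a provenance tag (residue, cap,
ligand, metal, water) and the inventory is reported as a breakdown rather
than asserted against any published total: published cluster atom counts
are ambiguous about whether caps, hydrogens and the water network are
included, so reconciliation is a reporting problem, not an assertion.
Electronic energies are strictly inputs (kcal/mol, kJ/mol or hartree, one
unit per table); the package only performs E_int = E(AB) − E(A) − E(B) and
relative-energy ranking (minimum pinned to 0, ties in input order).

## NCI fields

The promolecular density is a sum of spherically averaged free-atom
densities, each a fitted sum of exponentials c·exp(−r/ζ) in atomic units
(one term for H/He, two for Li–Ne, three for Na–Ar); gradient and Hessian
are analytic from the same exponentials, and the tests require agreement
with central differences to 1e-5 relative. Elements beyond the fitted
table — including zinc — fall back to the nearest parameterized atomic
number with a logged warning; the promolecular approximation is already
qualitative, and this choice keeps the field defined over the metal site
while flagging the caveat.

The analysis region is the metals plus atoms within 3.5 Å of any metal
(with a further 2 Å ring contributing density only, to suppress edge
artifacts), gridded at a configurable spacing (0.15 Å default for
production fields; demos and tests use 0.35 Å) with 2 Å padding. Points
with ρ > 0.3 a.u. are masked (covalent/core exclusion); within the
remaining region, points with s ≤ 0.5 are classified: strong-attractive
when sign(λ₂)ρ ≤ −0.02 a.u., van der Waals when |sign(λ₂)ρ| ≤ 0.01,
repulsive when sign(λ₂)ρ ≥ +0.02 — the standard promolecular-NCI coloring
thresholds, all exposed as parameters since published analyses give only a
color legend. Whether the 0.3 density value acts as a hard mask or only a
visualization isovalue is ambiguous in common usage; here it masks the
analysis region, and the parameter can be raised to recover the laxer
reading. All density math is in atomic units; interfaces take Å (cube
files convert to Bohr on write).

## Synthetic data

Two generators make the pipeline testable offline.

*Parametric sites* (`bizinc.synthetic`): two Zn ions at a chosen
separation, imidazole/carboxylate mimics at 2.05 Å dative distances, a
tetrahedral sulfamide/phosphinate headgroup whose bridging atom sits at
chosen distances from the zincs, shell waters at 2.8 Å from the ligand
plus distant bulk waters, optional rigid rotation of the headgroup base,
and seeded Gaussian coordinate noise applied **after** the ground truth is
recorded. Ground truth (match count, nuclearity, shell assignments,
hydrogen-bond pairs, designed rotation, shell-water count) reflects the
design geometry. Defaults encode the study conditions of the
monosubstituted complex: Zn–Zn 3.3 Å, bridging N at 2.2/2.1 Å.
Coordinating groups are minimal chemical mimics, not full residues: the
fixtures are meant to be tiny and unambiguous, not force-field realistic.
They contain no protein fold, no solvent structure, no disorder and no
coordinate error beyond the injected isotropic noise — so passing tests
demonstrate correctness of the measurement pipeline, not robustness to
every pathology of real crystallographic data.

*Stand-in complexes* (`bizinc.synthetic_complexes`): idealized synthetic
models of the five studied inhibitor complexes, built by rigid-body
fitting an ideal tetrahedral headgroup template so that the published
heavy-atom distances of each complex hold exactly (seeded multi-start
least squares; residuals < 1e-6 Å), on a backbone scaffold shared across
complexes so superposition is well defined. The sulfamide and phosphonate
stand-ins are constructed with a designed 22° base rotation. These models
encode published distances as inputs; recomputing them validates the
measurement code end to end, and it is stated plainly that this does not
re-derive the crystallography. The snapshot-dependent census of a full
structure-bank mining run (hundreds of thousands scanned) is out of scope;
the funnel itself is fully implemented and exercised on these sets.

## Numerical conventions

- Closed cutoffs everywhere a threshold classifies (≤, ≥), so boundary
  cases are deterministic.
- Deduplication and orderings (matches, shells, hydrogen bonds, cluster
  atoms) are canonical: sorted by distance then index, or by provenance
  group then file order — identical inputs give bit-identical outputs.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the workflow records every parameter,
  default or overridden, in its provenance block.
- Degenerate inputs raise typed errors (collinear superposition pairings,
  empty components, infeasible site geometries, ρ ≤ 0 in the reduced
  gradient, mixed energy units) rather than returning silent defaults.

## Problem sizes

Test and demonstration runs use: stand-in complexes of ~60 atoms, NCI
grids at 0.35 Å spacing (~10⁴–10⁵ points), 100-replicate recovery
batteries, and 1000-frame Gaussian ensembles. These sizes were chosen so
the full suite and the reproduction script each complete in well under a
minute of compute per stage while leaving every statistic far from its
tolerance boundaries; production analyses can raise grid resolution and
replicate counts freely through the exposed parameters.

## Known limitations

- The promolecular zinc density is a nearest-element stand-in; absolute
  NCI magnitudes around the metals are qualitative (the classification
  contrast between binding modes is the supported readout).
- Hydrogen-bond detection is distance-only; no angular or chemical
  plausibility filtering.
- The headgroup rotation is undefined for non-tetrahedral headgroups and
  folds to [0°, 60°] by symmetry.
- Cluster extraction does not add hydrogens or check valence; it prepares
  geometry and bookkeeping for external quantum-chemistry codes.
- The stand-in complexes reproduce published distances, not full deposited
  coordinates; analyses of the real entries require the user to supply the
  coordinate files locally.
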