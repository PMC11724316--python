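# Methods

## Model and assumptions

`ionshell` treats an ion-binding site as a purely geometric object: a metal
centre, the O/N atoms inside an element-specific first-shell distance
window, and the angular arrangement of those ligands. The underlying
chemical model is the one established for chelated Mg²⁺ in nucleic acids:
a rigid hexacoordinated octahedron with Mg…O ≈ 2.07 ± 0.04 Å and
Mg…N ≈ 2.19 ± 0.08 Å, cis/trans angles near 90°/177°, and an empty
2.3–3.4 Å exclusion band around the metal. K⁺ is treated as a softer
6–9-coordinate ion with a 2.6–3.2 Å window and no exclusion zone. All
parameters live in `GeometryParams` (distances in Å, angles in degrees,
B-factors in Å², density in σ) and can be overridden per run from a
`key = value` file or CLI flags; the defaults are the CSD-derived constants
above. Na⁺ and Zn²⁺ are accepted with plausible windows (2.2–2.7 and
1.9–2.4 Å) so that contaminant ions do not crash a run, but the taxonomy
and diagnosis rules are only defined for Mg²⁺ and K⁺.

Hydrogens are ignored throughout (the target structures rarely contain
them); protonation is encoded statically in the role templates — e.g.
(G)N1 and (U)N3 are never coordination acceptors, and N7-alkylated purines
are deliberately absent from the modified-residue alias table. Only blank
or `A` alternate locations are kept, and atoms with occupancy < 0.5 are
excluded from ligand candidacy while remaining in the table: partial
occupancy and alternate conformers are treated as ambiguity signals, not as
geometry. Author (`auth_*`) numbering is the reporting identity. Symmetry
mates are not expanded; all scans operate on the deposited model as read.

## Distortion score

The octahedral-regularity score is the mean absolute deviation of the 15
ligand–ion–ligand angle slots (12 cis at 90°, 3 trans at 180°) from
ideality, with the ligand-to-vertex assignment chosen by exact minimization.
Two implementation facts matter:

* Minimizing over the 6! vertex assignments is equivalent to minimizing
  over the 15 ways of partitioning six ligands into three trans pairs,
  because a vertex assignment only enters the score through which pairs it
  declares opposite. The implementation enumerates the 15 pairings; the
  test suite keeps a brute-force 6!-permutation oracle and checks equality
  on randomized shells.
* The published category thresholds (< 5° correct, 5–10° slightly
  distorted, > 10° highly distorted) are applied to the *mean* deviation,
  which makes them meaningful per angle; the summed deviation over the same
  15 slots is also reported for anyone who reads the thresholds as a sum.
  Non-hexacoordinated shells get no score and the `not_octahedral`
  category.

Cis vs trans for a ligand pair is cut at 135°, the midpoint between the
modal 90° and 177° values; the boundary is inclusive on the cis side.

## Labels and diagnosis

A label is only emitted for hexacoordinated shells: category counts in
canonical order (Oph > Or > Ob > Nb > Ocoo > Obb > Ocno > OHprot > Ow >
NHis) with multiplicity digits, plus the isomer prefix. The prefix rules
are driven by the pairwise cis/trans map: two non-water ligands take
`cis-`/`trans-` from their mutual angle regardless of category mix; three
take `fac-` iff all three pairs are cis, else `mer-`; with four non-water
ligands the *waters'* mutual arrangement is encoded as `Cis-`/`Trans-`;
0, 1, 5 and 6 non-water ligands carry no prefix.

Diagnosis flags are deliberately conservative. `likely_K_as_Mg` requires a
K-style environment (≥ 6 O/N in 2.6–3.2 Å) *and* a depleted Mg window
(< 4 contacts); `likely_Mg_as_K` requires ≥ 5 O/N inside 1.9–2.3 Å;
`likely_water` requires an empty Mg window with at most two exclusion-zone
contacts — reassigning an ion to water is a destructive call and the
threshold errs towards silence. A site is `well_defined` iff it is
hexacoordinated, at most slightly distorted, and (when a per-ion density
sidecar is supplied) its peak is ≥ 4.0 σ; density absent means the density
criterion is skipped, since most users will not have map statistics at
hand.

## Scans and pair taxonomy

The clamp scan enumerates all inter-residue O_ph pairs under 3.4 Å after
discarding any pair with a B-factor above 60 Å²; OP1–OP2 pairs within one
phosphate (≈ 2.5 Å apart by covalent geometry) are excluded, otherwise they
would dominate the output. A pair is `direct_bidentate` when one Mg²⁺ is
inner-shell to both oxygens and `water_mediated` when a Mg²⁺ binds one
oxygen directly and exactly one of its first-shell waters lies in the
2.6–3.2 Å hydrogen-bond window of the other; requiring exactly one bridging
water matches the intermediate motifs the rule is meant to catch.
Carboxylate clamps (Ocoo…Ocoo) are available behind a flag. The
trans-candidate window is 3.9–4.4 Å — the ≈ 4.13 Å trans separation widened
by roughly three standard deviations; because ordinary inter-phosphate
distances overlap this band, hits are always labelled candidates and only
an ion inner-shell to both oxygens confirms them.

Metal pairs share a ligand when the atom is inner-shell to both metals
under each metal's own window; a shared phosphate group is a residue
contributing an O_ph to each ion, possibly through different OP atoms. The
distance bins (≤ 2.6 / 2.6–3.2 / 3.2–4.2 / 4.2–5.5 Å for MgD/C/B/A)
interpolate the exemplar separations of the four classes (≈ 2.4, ≈ 2.8,
≈ 3.8, ≈ 4.5–5.3 Å); they are configuration, not physics, and the defaults
are documented here precisely because the class definitions give centroids
rather than boundaries. Geometrically the bins correspond to face-sharing
(2d/√3 ≈ 2.39 Å), edge-sharing (√2·d ≈ 2.93 Å) and corner-sharing
(≤ 2d ≈ 4.14 Å) octahedra. MgD pairs are always additionally flagged as
requiring independent confirmation. Chains are connected components of the
classified pair graph (networkx; a union–find oracle checks component
counts in the tests).

## Synthetic fixtures

The generator emulates the study conditions directly: every planted motif
is built to its target geometry exactly — octahedra at 2.07/2.19 Å,
phosphate groups with P–OP 1.48 Å, OP–P–OP ≈ 119°, P–OP…Mg = 148° with the
ion in the OP1–P–OP2 plane, carbonyl binding at C=O…Mg = 144° in the base
plane, clamps at a configurable O_ph…O_ph distance (default 2.9 Å), K⁺
shells as 7 oxygens at 2.8 Å, and ion pairs as face-/edge-/corner-sharing
hydration polyhedra at the class-defining separations — before seeded
Gaussian jitter (numpy PCG64) is applied to **all** coordinates. Guanine is
a regular hexagon (side 1.39 Å) fused to a regular pentagon with exocyclic
O6 at 1.23 Å: planar and idealized, sufficient for plane fits and
lone-pair directions. Fragments are chemically plausible but minimal;
residue topology (numbering, parent atoms) is only mocked where a scan
needs it, sterics between fragments are not checked beyond what the
planted geometry requires, and an idealized A-form-like backbone fragment
(twist 32.7°, rise 2.81 Å) serves as the no-hit negative control for all
scans.

Consequently, passing tests demonstrate that the rules recover exactly
planted geometry and degrade gracefully under coordinate noise; they do not
demonstrate robustness to the correlated errors, partial occupancies and
density-limited modelling of real depositions. At 0.05 Å per-coordinate
jitter the label recovery rate measured over 2000 seeded replicates is
≈ 95.6%: the dominant failure mode is a 2.07 Å ligand drifting across the
hard 1.9/2.3 Å window edge, which is the classifier behaving as specified,
not a scan failure (scan recall at the same noise stays ≥ 95%). Each
(spec, seed) pair fixes the output bytes; ground truth is emitted alongside
every fixture and the generator self-checks its planted pair counts at
zero jitter.

## Numerical choices

Radius queries go through a cKDTree and are exact (ties at the radius are
included; results are distance-sorted with the atom index as a
deterministic tie-break). Angles are computed with clamped arccosines;
plane fits use SVD over the ring atoms (exact three-point planes for
OP1–P–OP2). Inclusive window conventions: ligand windows are closed, the
Mg exclusion zone is half-open (2.3, 3.4], the clamp rule is a strict
`< 3.4 Å` with `B ≤ 60` inclusive, and the 135° cis cut is inclusive.
Degenerate inputs degrade rather than fail: unknown residues categorize as
`other` with one logged warning, missing phosphate or ring siblings mark
the descriptor unavailable, an ion with no ligands yields an empty shell
that downstream code flags.

## Problem sizes

The test suite and the acceptance script run entirely on generated
fixtures: single-site structures of 5–40 atoms, oracle-equivalence sweeps
of 100 seeded instances per algorithm, and a 2000-replicate jitter
robustness estimate — chosen as the smallest ensembles that make the
deterministic checks exact and the stochastic rate estimate stable to a
fraction of a percent.

## Known limitations

* No density or map handling: density evidence enters only as an optional
  per-ion sigma sidecar.
* No symmetry expansion, assembly building or re-refinement; the tool
  flags, it never moves atoms.
* The Nb/ protonation templates are static; unusual tautomers or charged
  bases are not recognized.
* Pair-class bin edges between the exemplar separations are conventions;
  reclassification near a boundary is a parameter choice away.
* Counts reported for full depositions depend on the deposition's own
  solvent completeness — the scans see modelled atoms only.
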