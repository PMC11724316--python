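# ionshell

Stereochemical validation and classification of Mg²⁺ (and paired K⁺) binding
sites in nucleic-acid and protein 3D structures.

High-resolution ribosome and RNA structures routinely mis-model their ion
shells: K⁺ deposited as Mg²⁺, incomplete hydration octahedra, ions that are
really waters. `ionshell` implements a compact set of stereochemical rules
that diagnose these problems from coordinates alone, and classifies every
correctly modelled site with the MgRNA-extended nomenclature. It is a
library plus CLI for structural biologists curating metal assignments in
mmCIF/PDB models, with a deterministic synthetic-fixture generator so the
whole pipeline is testable without downloading any deposition.

## The rules it implements

A well-modelled Mg²⁺ is hexacoordinated by O/N ligands at
*d*(Mg…O) ≈ 2.07 ± 0.04 Å / *d*(Mg…N) ≈ 2.19 ± 0.08 Å (acceptance window
1.9–2.3 Å), with cis/trans coordination angles ≈ 90°/177°, which places cis
and trans first-shell oxygen pairs at ≈ 2.93 Å and ≈ 4.13 Å. No O/N atom
should occur in the 2.3–3.4 Å *exclusion zone*; contacts at ≈ 2.8 Å with 7–8
ligands indicate K⁺ (window 2.6–3.2 Å), not Mg²⁺. Octahedral regularity is
scored as the mean absolute deviation of the 15 ligand–Mg–ligand angles from
ideality (minimized over all vertex assignments) and binned
< 5° / 5–10° / > 10° into correct / slightly distorted / highly distorted.

Sites are named by their ligand-category multiset — `Oph` (OP1/OP2), `Or`
(ribose O2′/O3′/O4′/O5′), `Ob` (base O2/O4/O6), `Nb` (non-protonated base
N1/N3/N7), `Ow` (water), plus the protein categories `Obb`, `Ocoo`, `Ocno`,
`OHprot`, `NHis` — with isomer prefixes: `cis-`/`trans-` for two non-water
ligands, `fac-`/`mer-` for three, capitalized `Cis-`/`Trans-` for the two
remaining waters when four non-water ligands are bound (e.g.
`Trans-4Oph.2Ow`).

Structure-wide scans localize the chelated motifs without looking at ions:
bidentate *clamps* as O_ph…O_ph pairs < 3.4 Å (both B-factors ≤ 60 Å²),
trans candidates near 4.1 Å, head-to-tail stacked purines as N7…N7 < 3.4 Å,
and rare O2′(n)…OP(n+1) ≈ 3.0 Å ribose-coordination motifs. Metal–metal
micro-clusters are binned by separation into MgA (> 4.2 Å, phosphate
bridged), MgB (3.2–4.2 Å), MgC (2.6–3.2 Å) and MgD (< 2.6 Å, always flagged
for confirmation), with a 1–3 suffix counting shared phosphate groups or
bridging ligands; mixed Mg…K pairs at 3.5–4.4 Å sharing 2–3 ligands are
MgK_μc2/3. Pair graphs assemble into ion chains.

## Worked example

Generate a planted bidentate-clamp fixture and diagnose it:

```
$ ionshell fixture --motif cis_clamp --out demo
demo/cis_clamp_seed0.cif
demo/cis_clamp_seed0.groundtruth.json
$ ionshell clamps demo/cis_clamp_seed0.cif
[
 {
  "atom_a": "A/G1/OP2",
  "atom_b": "A/G2/OP2",
  "distance": 2.9,
  "op_combo": "OP2-OP2",
  "sequence_separation": 1,
  "stabilizer": "direct_bidentate",
  "ion_id": "M/MG1/MG"
 }
]
```

The scan found one O_ph…O_ph pair at 2.90 Å — the conserved clamp distance,
matching the cis water–water separation — and identified it as a direct
bidentate Mg²⁺ clamp: ion `M/MG1/MG` is inner-shell to both phosphate
oxygens. `ionshell diagnose` on the same file labels that ion
`cis-2Oph.4Ow` with zero consistency flags. The `diagnose`, `pairs` and
`classify` subcommands write the same information as versioned JSON and TSV
tables (`ions.tsv`, `clamps.tsv`, `pairs.tsv`, `summary.tsv`).

As a library:

```python
from ionshell import FixtureSpec, make_fixture, build_all_shells, label_site

table, truth = make_fixture(FixtureSpec(motif="mgC_pair"))
shells = build_all_shells(table)
print([label_site(s).text for s in shells.values()])  # ['Oph.5Ow', 'Oph.5Ow']
```

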