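"""Structure-wide stereochemical scans for Mg2+-binding motifs.

Implements the distance rules that localize the major chelated-Mg2+ motifs
without looking at ions at all (the geometry of the phosphate/nucleobase
scaffold is diagnostic by itself):

* bidentate clamps — O_ph...O_ph pairs under 3.4 A (conserved at ~2.9 A,
  matching the cis water-water separation), after discarding pairs with any
  B-factor above 60 A^2;
* trans-candidates — O_ph pairs near the ~4.1 A trans separation
  (ambiguous, always reported as candidates only);
* head-to-tail stacked purines — N7...N7 under 3.4 A (ordinary stacked
  purines sit >3.8 A apart);
* O2'(n)...OP(n+1) proximity motifs (~3.0 A) marking rare inner-shell
  ribose coordination.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.spatial import cKDTree
import numpy as np

from .geometry import CoordinationShell, GeometryParams, build_all_shells
from .structure import AtomRecord, StructureTable


@dataclass(frozen=True)
class ClampPair:
    """A short anionic-oxygen pair with its stabilizing ion, if any."""

    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    op_combo: str                   # OP1-OP1 | OP2-OP2 | OP1-OP2 | carboxyl
    sequence_separation: int | None  # |delta residue| within a chain, None across chains
    stabilizer: str                 # direct_bidentate | water_mediated | none_found
    ion_id: str = ""


@dataclass(frozen=True)
class TransCandidate:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    ion_id: str = ""
    candidate: bool = True  # trans distances overlap other motifs; never definitive


@dataclass(frozen=True)
class PurineSeat:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    ion_id: str = ""


@dataclass(frozen=True)
class O2pMotif:
    o2_atom: AtomRecord
    op_atom: AtomRecord
    distance: float
    ion_id: str = ""


def _pairs_within(atoms: list[AtomRecord], dmax: float) -> list[tuple[AtomRecord, AtomRecord, float]]:
    if len(atoms) < 2:
        return []
    coords = np.vstack([a.xyz for a in atoms])
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(dmax)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        out.append((atoms[i], atoms[j], d))
    return out


def _seq_sep(a: AtomRecord, b: AtomRecord) -> int | None:
    if a.chain_id != b.chain_id:
        return None
    return abs(a.residue_number - b.residue_number)


def _mg_shells(shells: dict[str, CoordinationShell]) -> list[CoordinationShell]:
    return [s for s in shells.values() if s.ion.element.upper() == "MG"]


def scan_clamps(
    table: StructureTable,
    params: GeometryParams | None = None,
    shells: dict[str, CoordinationShell] | None = None,
    include_carboxyl: bool = False,
) -> list[ClampPair]:
    """All O_ph...O_ph (optionally O_coo...O_coo) pairs under ``clamp_dmax``.

    Pairs within one phosphate group (same residue) are excluded — the
    intra-group OP1-OP2 distance (~2.5 A) would flood the scan — as are
    pairs where either oxygen has B-factor above ``clamp_bmax``.  Each pair
    is annotated ``direct_bidentate`` when one Mg2+ is inner-shell to both
    oxygens, ``water_mediated`` when a Mg2+ binds one oxygen directly and
    reaches the other through exactly one of its first-shell waters, and
    ``none_found`` otherwise (a candidate site awaiting an ion).
    """
    params = params or GeometryParams()
    if shells is None:
        shells = build_all_shells(table, params)
    mg_shells = _mg_shells(shells)
    lo_out, hi_out = params.outer_shell_window

    def annotate(a: AtomRecord, b: AtomRecord) -> tuple[str, str]:
        for sh in mg_shells:
            inner = sh.ligand_ids()
            if a.atom_id in inner and b.atom_id in inner:
                return "direct_bidentate", sh.ion.atom_id
        for sh in mg_shells:
            inner = sh.ligand_ids()
            for bound, free in ((a, b), (b, a)):
                if bound.atom_id in inner and free.atom_id not in inner:
                    waters = [w for w, _ in sh.ligands if w.category == "Ow"]
                    n_bridge = sum(
                        1
                        for w in waters
                        if lo_out <= float(np.linalg.norm(w.xyz - free.xyz)) <= hi_out
                    )
                    if n_bridge == 1:
                        return "water_mediated", sh.ion.atom_id
        return "none_found", ""

    groups: list[tuple[list[AtomRecord], str]] = [(table.by_category("Oph"), "phosphate")]
    if include_carboxyl:
        groups.append((table.by_category("Ocoo"), "carboxyl"))

    out: list[ClampPair] = []
    for atoms, kind in groups:
        for a, b, d in _pairs_within(atoms, params.clamp_dmax - 1e-12):
            if a.residue_key == b.residue_key:
                continue
            if a.b_factor > params.clamp_bmax or b.b_factor > params.clamp_bmax:
                continue
            if kind == "carboxyl":
                combo = "carboxyl"
            else:
                combo = "-".join(sorted((a.name, b.name)))
            stab, ion_id = annotate(a, b)
            out.append(
                ClampPair(a, b, d, combo, _seq_sep(a, b), stab, ion_id)
            )
    return out


def scan_trans_candidates(
    table: StructureTable,
    params: GeometryParams | None = None,
    shells: dict[str, CoordinationShell] | None = None,
) -> list[TransCandidate]:
    """O_ph pairs near the trans O...O separation (3.9-4.4 A by default).

    This distance overlaps ordinary inter-phosphate separations, so every
    hit is explicitly a candidate; the ion annotation (a Mg2+ inner-shell to
    both oxygens) is what confirms a trans-2Oph site.
    """
    params = params or GeometryParams()
    if shells is None:
        shells = build_all_shells(table, params)
    lo, hi = params.trans_candidate_window
    out: list[TransCandidate] = []
    for a, b, d in _pairs_within(table.by_category("Oph"), hi + 1e-12):
        if d < lo or a.residue_key == b.residue_key:
            continue
        ion_id = ""
        for sh in _mg_shells(shells):
            inner = sh.ligand_ids()
            if a.atom_id in inner and b.atom_id in inner:
                ion_id = sh.ion.atom_id
                break
        out.append(TransCandidate(a, b, d, ion_id))
    return out


def scan_purine_seats(
    table: StructureTable,
    params: GeometryParams | None = None,
    shells: dict[str, CoordinationShell] | None = None,
) -> list[PurineSeat]:
    """Head-to-tail stacked purine N7 pairs (N7...N7 < 3.4 A).

    Consecutive stacked purines keep their N7 atoms >3.8 A apart; only the
    head-to-tail arrangement brings them under 3.4 A, where they chelate a
    metal in cis-2Nb.4Ow fashion.
    """
    params = params or GeometryParams()
    if shells is None:
        shells = build_all_shells(table, params)
    n7 = [a for a in table.by_category("Nb") if a.name == "N7"]
    out: list[PurineSeat] = []
    for a, b, d in _pairs_within(n7, params.clamp_dmax - 1e-12):
        if a.residue_key == b.residue_key:
            continue
        ion_id = ""
        for sh in shells.values():
            inner = sh.ligand_ids()
            if a.atom_id in inner and b.atom_id in inner:
                ion_id = sh.ion.atom_id
                break
        out.append(PurineSeat(a, b, d, ion_id))
    return out


def scan_o2p_motifs(
    table: StructureTable,
    params: GeometryParams | None = None,
    shells: dict[str, CoordinationShell] | None = None,
) -> list[O2pMotif]:
    """O2'(n)...OP1/OP2(n+1) contacts under 3.4 A (rare ribose-Mg motifs).

    The short contact marks the backbone turn that lets an O2' enter a Mg2+
    first shell (sites of the Cis-3Oph.Or.2Ow / fac-2Oph.Or.3Ow type arise
    downstream when the coordinated ion is labelled).
    """
    params = params or GeometryParams()
    if shells is None:
        shells = build_all_shells(table, params)
    out: list[O2pMotif] = []
    for o2 in table.atoms:
        if o2.name != "O2'" or o2.category != "Or":
            continue
        nxt_key = (o2.chain_id, o2.residue_number + 1, "")
        for op_name in ("OP1", "OP2"):
            op = table.residue_atom(nxt_key, op_name)
            if op is None:
                continue
            d = float(np.linalg.norm(op.xyz - o2.xyz))
            if d > params.clamp_dmax:
                continue
            ion_id = ""
            for sh in _mg_shells(shells):
                if o2.atom_id in sh.ligand_ids():
                    ion_id = sh.ion.atom_id
                    break
            out.append(O2pMotif(o2, op, d, ion_id))
    return out
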