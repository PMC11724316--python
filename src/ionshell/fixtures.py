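"""Deterministic synthetic structures with planted, labelled ion motifs.

Every motif the analysis modules detect can be generated here as a small,
chemically plausible coordinate fragment: ideal or perturbed Mg(H2O)6
octahedra, phosphate groups forming bidentate clamps, head-to-tail purine
N7 seats, K+-like shells (7 ligands at ~2.8 A), Mg...Mg / Mg...K pairs at
class-defining separations, and an idealized A-form backbone fragment as a
no-hit negative control.  Geometry targets are met exactly before seeded
Gaussian jitter is applied, and each fixture ships with its
:class:`GroundTruth` (expected labels, scan hits and pair class).

Fragments are built from internal-coordinate templates: P-OP bonds of
1.48 A with an OP-P-OP angle of ~119 deg, a planar guanine constructed from
a regular hexagon (side 1.39 A) fused to a regular pentagon (shared C4-C5
edge), C=O bonds of 1.23 A.  Ions are placed first; octahedron vertices are
filled with waters.  Full nucleotides are only mocked up where a scan needs
residue topology (O2' motifs, purine seats).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structure import AtomRecord, StructureTable, assign_roles

MG_O = 2.07    # target Mg...O first-shell distance, Angstrom
MG_N = 2.19    # target Mg...N first-shell distance
K_O = 2.8      # typical K...O first-shell distance
P_OP = 1.48    # P-OP bond length
OP_P_OP = 119.0
C_O = 1.23     # carbonyl bond length
RING_SIDE = 1.39
P_OP_ION = 148.0  # target P-OP...ion angle for monodentate phosphate binding

MOTIFS = (
    "ideal_6Ow",
    "Oph5Ow",
    "Ob5Ow",
    "Nb5Ow",
    "cis_clamp",
    "trans_2Oph",
    "fac_3Oph",
    "mer_3Oph",
    "Cis_4Oph",
    "Trans_4Oph",
    "Cis_3Oph_Or",
    "fac_2Oph_Or",
    "purine_seat",
    "o2p_motif",
    "outer_shell",
    "incomplete_shell",
    "K_site",
    "mgA_pair",
    "mgB_pair",
    "mgC_pair",
    "mgD_pair",
    "mgK_pair",
    "helix_negative",
)


class FixtureError(ValueError):
    """Inconsistent fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure; (spec, seed) fixes the output bytes."""

    motif: str
    jitter_sd: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise FixtureError(f"unknown motif {self.motif!r}; choose from {MOTIFS}")
        if self.jitter_sd < 0:
            raise FixtureError("jitter_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the analysis pipeline should recover from a fixture."""

    labels: dict[str, str] = field(default_factory=dict)  # ion atom_id -> label text
    clamp_count: int = 0
    trans_candidate_count: int = 0
    purine_seat_count: int = 0
    o2p_count: int = 0
    pair_class: str | None = None
    expected_flags: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "clamp_count": self.clamp_count,
                "trans_candidate_count": self.trans_candidate_count,
                "purine_seat_count": self.purine_seat_count,
                "o2p_count": self.o2p_count,
                "pair_class": self.pair_class,
                "expected_flags": self.expected_flags,
            },
            indent=1,
            ensure_ascii=False,
        )


# ---------------------------------------------------------------------------
# vector utilities

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])

#: ideal octahedron vertex directions
OCTA = (EX, -EX, EY, -EY, EZ, -EZ)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to u (deterministic choice)."""
    ref = EZ if abs(np.dot(u, EZ)) < 0.9 else EX
    return _unit(np.cross(np.cross(u, ref), u))


def _frame_transform(
    src: tuple[np.ndarray, np.ndarray], dst: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Rotation mapping orthonormal frame (src1, src2, src1 x src2) onto dst."""
    s1, s2 = _unit(src[0]), _unit(src[1])
    s2 = _unit(s2 - np.dot(s2, s1) * s1)
    d1, d2 = _unit(dst[0]), _unit(dst[1])
    d2 = _unit(d2 - np.dot(d2, d1) * d1)
    s = np.column_stack([s1, s2, np.cross(s1, s2)])
    d = np.column_stack([d1, d2, np.cross(d1, d2)])
    return d @ s.T


# ---------------------------------------------------------------------------
# guanine template (planar, z = 0)


def _guanine_template() -> dict[str, np.ndarray]:
    atoms: dict[str, np.ndarray] = {}
    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for k, nm in enumerate(hex_names):
        th = math.radians(90.0 + 60.0 * k)
        atoms[nm] = RING_SIDE * np.array([math.cos(th), math.sin(th), 0.0])
    a, b = atoms["C4"], atoms["C5"]
    mid = (a + b) / 2.0
    out_dir = _unit(np.array([mid[0], mid[1], 0.0]))
    apo = RING_SIDE / (2.0 * math.tan(math.radians(36.0)))
    c5c = mid + apo * out_dir  # pentagon center
    phi_a = math.atan2(a[1] - c5c[1], a[0] - c5c[0])
    phi_b = math.atan2(b[1] - c5c[1], b[0] - c5c[0])
    delta = (phi_b - phi_a + math.pi) % (2 * math.pi) - math.pi
    sgn = 1.0 if delta > 0 else -1.0
    r5 = RING_SIDE / (2.0 * math.sin(math.radians(36.0)))
    for step, nm in ((1, "N9"), (2, "C8"), (3, "N7")):
        phi = phi_a - sgn * step * math.radians(72.0)
        atoms[nm] = c5c + r5 * np.array([math.cos(phi), math.sin(phi), 0.0])
    atoms["O6"] = atoms["C6"] + C_O * _unit(atoms["C6"])
    return atoms


_GUA = _guanine_template()


# ---------------------------------------------------------------------------
# builder


class _Builder:
    """Accumulates AtomRecords with simple chain/residue bookkeeping."""

    def __init__(self) -> None:
        self.records: list[AtomRecord] = []
        self._water_n = 0
        self._metal_n = 0

    def atom(
        self,
        name: str,
        element: str,
        resname: str,
        chain: str,
        resnum: int,
        xyz: np.ndarray,
        b: float = 20.0,
        occ: float = 1.0,
    ) -> AtomRecord:
        rec = AtomRecord(
            atom_id=f"{chain}/{resname}{resnum}/{name}",
            element=element,
            name=name,
            residue_name=resname,
            chain_id=chain,
            residue_number=resnum,
            icode="",
            xyz=np.asarray(xyz, dtype=float),
            b_factor=b,
            occupancy=occ,
        )
        self.records.append(rec)
        return rec

    def water(self, xyz: np.ndarray, b: float = 20.0) -> AtomRecord:
        self._water_n += 1
        return self.atom("O", "O", "HOH", "S", self._water_n, xyz, b=b)

    def metal(self, element: str, xyz: np.ndarray, b: float = 15.0) -> AtomRecord:
        self._metal_n += 1
        return self.atom(
            element.upper(), element.upper(), element.upper(), "M", self._metal_n, xyz, b=b
        )

    def phosphate(
        self,
        ion_pos: np.ndarray,
        vertex_u: np.ndarray,
        resnum: int,
        coord_name: str = "OP1",
        chain: str = "A",
        d: float = MG_O,
        b: float = 20.0,
        b_coord: float | None = None,
    ) -> AtomRecord:
        """Phosphate group coordinating an ion through one OP atom.

        The coordinated OP sits at ``ion + d * vertex_u``; P is placed so the
        P-OP...ion angle is 148 deg with the ion in the OP1-P-OP2 plane; the
        sibling OP points away from the ion.  Returns the coordinated OP.
        """
        u = _unit(vertex_u)
        op = ion_pos + d * u
        w = _perp(u)
        alpha = math.radians(P_OP_ION)
        p = op + P_OP * (math.cos(alpha) * (-u) + math.sin(alpha) * w)
        q = _unit(op - p)
        s = _unit(w - np.dot(w, q) * q)
        beta = math.radians(OP_P_OP)
        cand1 = p + P_OP * (math.cos(beta) * q + math.sin(beta) * s)
        cand2 = p + P_OP * (math.cos(beta) * q - math.sin(beta) * s)
        sib = cand1 if np.linalg.norm(cand1 - ion_pos) >= np.linalg.norm(cand2 - ion_pos) else cand2
        sib_name = "OP2" if coord_name == "OP1" else "OP1"
        self.atom("P", "P", "G", chain, resnum, p, b=b)
        rec = self.atom(coord_name, "O", "G", chain, resnum, op, b=b_coord if b_coord is not None else b)
        self.atom(sib_name, "O", "G", chain, resnum, sib, b=b)
        return rec

    def guanine(self, rot: np.ndarray, trans: np.ndarray, resnum: int, chain: str = "B") -> None:
        for nm, pos in _GUA.items():
            elem = nm[0]
            self.atom(nm, elem, "G", chain, resnum, rot @ pos + trans)

    def table(self, spec: FixtureSpec) -> StructureTable:
        if spec.jitter_sd > 0:
            rng = np.random.default_rng(spec.seed)
            noise = rng.normal(0.0, spec.jitter_sd, (len(self.records), 3))
            for rec, dx in zip(self.records, noise):
                rec.xyz = rec.xyz + dx
        tbl = StructureTable(self.records, provenance=f"fixture:{spec.motif} seed={spec.seed}")
        assign_roles(tbl)
        return tbl


def _base_placement_ob(vertex_u: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform putting the guanine O6 at d*vertex_u with the ion at
    the origin, C6=O6...ion = 144 deg, and the ion in the base plane."""
    o, c = _GUA["O6"], _GUA["C6"]
    chat = _unit(c - o)
    w = _unit(np.cross(EZ, chat))  # in-plane perpendicular
    alpha = math.radians(144.0)
    # of the two in-plane sides, keep the ion farther from the other ring O/N
    on_atoms = [v for nm, v in _GUA.items() if nm[0] in "ON" and nm != "O6"]

    def _min_sep(sign: float) -> float:
        ion = o + d * (math.cos(alpha) * chat + sign * math.sin(alpha) * w)
        return min(float(np.linalg.norm(ion - v)) for v in on_atoms)

    sign = 1.0 if _min_sep(1.0) >= _min_sep(-1.0) else -1.0
    ion_t = o + d * (math.cos(alpha) * chat + sign * math.sin(alpha) * w)
    rot = _frame_transform((o - ion_t, EZ), (vertex_u, _perp(vertex_u)))
    trans = -rot @ ion_t
    return rot, trans


def _base_placement_nb(
    vertex_u: np.ndarray, d: float, normal: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform putting N7 at d*vertex_u, lone pair toward the origin."""
    n7 = _GUA["N7"]
    u1 = _unit(_GUA["C5"] - n7)
    u2 = _unit(_GUA["C8"] - n7)
    lp = -_unit(u1 + u2)
    ion_t = n7 + d * lp
    tgt_normal = normal if normal is not None else _perp(vertex_u)
    rot = _frame_transform((n7 - ion_t, EZ), (vertex_u, tgt_normal))
    trans = -rot @ ion_t
    return rot, trans


def _octahedral_ion(
    b: _Builder,
    assignment: list[tuple[np.ndarray, str]],
    ion_pos: np.ndarray | None = None,
    element: str = "MG",
    d_o: float = MG_O,
    params: dict | None = None,
) -> AtomRecord:
    """Metal plus ligands at the given octahedron vertices.

    ``assignment`` holds (vertex direction, kind) with kind one of Ow, Oph,
    Op2 (phosphate via OP2), Or, Ob, Nb.
    """
    params = params or {}
    pos = ion_pos if ion_pos is not None else np.zeros(3)
    ion = b.metal(element, pos)
    resnum = 1
    for u, kind in assignment:
        if kind == "Ow":
            b.water(pos + d_o * _unit(u))
        elif kind in ("Oph", "Op2"):
            b.phosphate(
                pos,
                u,
                resnum,
                coord_name="OP1" if kind == "Oph" else "OP2",
                d=d_o,
                b_coord=params.get(f"b_factor_{resnum}"),
            )
            resnum += 1
        elif kind == "Or":
            b.atom("O2'", "O", "G", "A", resnum, pos + d_o * _unit(u))
            resnum += 1
        elif kind == "Ob":
            rot, trans = _base_placement_ob(_unit(u), d_o)
            b.guanine(rot, rot @ np.zeros(3) + trans + pos * 0, resnum)
            # shift whole base so the ion sits at `pos`
            for rec in b.records[-len(_GUA):]:
                rec.xyz = rec.xyz + pos
            resnum += 1
        elif kind == "Nb":
            rot, trans = _base_placement_nb(_unit(u), MG_N)
            b.guanine(rot, trans, resnum)
            for rec in b.records[-len(_GUA):]:
                rec.xyz = rec.xyz + pos
            resnum += 1
        else:
            raise FixtureError(f"unknown ligand kind {kind}")
    return ion


# vertex layouts per isomer (non-water vertices first)
_LAYOUTS = {
    "cis2": ([EX, EY], [-EX, -EY, EZ, -EZ]),
    "trans2": ([EX, -EX], [EY, -EY, EZ, -EZ]),
    "fac3": ([EX, EY, EZ], [-EX, -EY, -EZ]),
    "mer3": ([EX, -EX, EY], [-EY, EZ, -EZ]),
    "Cis4": ([EX, -EX, -EY, -EZ], [EY, EZ]),
    "Trans4": ([EX, -EX, EY, -EY], [EZ, -EZ]),
    "one": ([EX], [-EX, EY, -EY, EZ, -EZ]),
    "none": ([], list(OCTA)),
}


def make_fixture(spec: FixtureSpec) -> tuple[StructureTable, GroundTruth]:
    """Build the synthetic structure and its ground truth for one motif."""
    b = _Builder()
    gt = GroundTruth()
    p = spec.params
    m = spec.motif

    if m == "ideal_6Ow":
        d = float(p.get("ligand_distance", MG_O))
        ion = _octahedral_ion(b, [(u, "Ow") for u in OCTA], d_o=d)
        gt.labels[ion.atom_id] = "6Ow"
    elif m == "Oph5Ow":
        nw, wa = _LAYOUTS["one"]
        ion = _octahedral_ion(b, [(u, "Oph") for u in nw] + [(u, "Ow") for u in wa])
        gt.labels[ion.atom_id] = "Oph.5Ow"
        gt.clamp_count = 0
    elif m == "Ob5Ow":
        ion = b.metal("MG", np.zeros(3))
        rot, trans = _base_placement_ob(EX, MG_O)
        b.guanine(rot, trans, 1)
        for u in OCTA[1:]:
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "Ob.5Ow"
    elif m == "Nb5Ow":
        ion = b.metal("MG", np.zeros(3))
        rot, trans = _base_placement_nb(EX, MG_N)
        b.guanine(rot, trans, 1)
        for u in OCTA[1:]:
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "Nb.5Ow"
    elif m == "cis_clamp":
        dist = float(p.get("oo_distance", 2.9))
        if dist >= 3.4:
            raise FixtureError(f"cis_clamp needs d(Oph...Oph) < 3.4 A, got {dist}")
        theta = 2.0 * math.asin(dist / (2.0 * MG_O))
        mhat, nhat = _unit(EX + EY), _unit(EY - EX)
        u1 = math.cos(theta / 2) * mhat - math.sin(theta / 2) * nhat
        u2 = math.cos(theta / 2) * mhat + math.sin(theta / 2) * nhat
        ion = b.metal("MG", np.zeros(3))
        b.phosphate(np.zeros(3), u1, 1, coord_name=p.get("op_name_1", "OP2"),
                    b_coord=p.get("b_factor_1"))
        b.phosphate(np.zeros(3), u2, 2, coord_name=p.get("op_name_2", "OP2"),
                    b_coord=p.get("b_factor_2"))
        for u in (-u1, -u2, EZ, -EZ):
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "cis-2Oph.4Ow"
        bmax = 60.0
        b1 = p.get("b_factor_1", 20.0) or 20.0
        b2 = p.get("b_factor_2", 20.0) or 20.0
        gt.clamp_count = 1 if (b1 <= bmax and b2 <= bmax) else 0
    elif m == "trans_2Oph":
        nw, wa = _LAYOUTS["trans2"]
        ion = _octahedral_ion(b, [(u, "Oph") for u in nw] + [(u, "Ow") for u in wa])
        gt.labels[ion.atom_id] = "trans-2Oph.4Ow"
        gt.trans_candidate_count = 1  # Oph...Oph = 2 * 2.07 = 4.14 A
    elif m in ("fac_3Oph", "mer_3Oph"):
        nw, wa = _LAYOUTS["fac3" if m == "fac_3Oph" else "mer3"]
        ion = _octahedral_ion(b, [(u, "Oph") for u in nw] + [(u, "Ow") for u in wa])
        gt.labels[ion.atom_id] = ("fac-" if m == "fac_3Oph" else "mer-") + "3Oph.3Ow"
        gt.clamp_count = 3 if m == "fac_3Oph" else 2  # cis Oph pairs at 2.93 A
        gt.trans_candidate_count = 0 if m == "fac_3Oph" else 1
    elif m in ("Cis_4Oph", "Trans_4Oph"):
        nw, wa = _LAYOUTS["Cis4" if m == "Cis_4Oph" else "Trans4"]
        ion = _octahedral_ion(b, [(u, "Oph") for u in nw] + [(u, "Ow") for u in wa])
        gt.labels[ion.atom_id] = ("Cis-" if m == "Cis_4Oph" else "Trans-") + "4Oph.2Ow"
        # cis Oph pairs sit at sqrt(2) * 2.07 = 2.93 A < 3.4
        gt.clamp_count = 5 if m == "Cis_4Oph" else 4
        gt.trans_candidate_count = 1 if m == "Cis_4Oph" else 2
    elif m == "Cis_3Oph_Or":
        ion = b.metal("MG", np.zeros(3))
        for i, u in enumerate((EX, -EX, -EY), start=1):
            b.phosphate(np.zeros(3), u, i)
        b.atom("O2'", "O", "A", "A", 4, MG_O * -EZ)
        for u in (EY, EZ):
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "Cis-3Oph.Or.2Ow"
        gt.clamp_count = 2  # the two cis Oph pairs at 2.93 A
        gt.trans_candidate_count = 1  # the trans pair at 4.14 A
    elif m == "fac_2Oph_Or":
        ion = b.metal("MG", np.zeros(3))
        b.phosphate(np.zeros(3), EX, 1)
        b.phosphate(np.zeros(3), EY, 2)
        b.atom("O2'", "O", "A", "A", 3, MG_O * EZ)
        for u in (-EX, -EY, -EZ):
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "fac-2Oph.Or.3Ow"
        gt.clamp_count = 1
    elif m == "purine_seat":
        ion = b.metal("MG", np.zeros(3))
        rot1, tr1 = _base_placement_nb(EX, MG_N, normal=EZ)
        b.guanine(rot1, tr1, 1, chain="B")
        rot2, tr2 = _base_placement_nb(EY, MG_N, normal=EX)
        b.guanine(rot2, tr2, 5, chain="B")
        for u in (-EX, -EY, EZ, -EZ):
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "cis-2Nb.4Ow"
        gt.purine_seat_count = 1  # N7...N7 = sqrt(2) * 2.19 = 3.10 A < 3.4
    elif m == "o2p_motif":
        d_o2p = float(p.get("o2p_distance", 3.0))
        if d_o2p > 3.4:
            raise FixtureError(f"o2p_motif needs d(O2'...OP) <= 3.4 A, got {d_o2p}")
        ion = b.metal("MG", np.zeros(3))
        o2 = b.atom("O2'", "O", "G", "A", 10, MG_O * EX)
        op_name = p.get("op_name", "OP1")
        op = o2.xyz + d_o2p * EX
        pp = op + P_OP * _unit(EX + EZ)
        q = _unit(op - pp)
        beta = math.radians(OP_P_OP)
        sib = pp + P_OP * (math.cos(beta) * q + math.sin(beta) * _unit(EX - EZ))
        b.atom("P", "P", "G", "A", 11, pp)
        b.atom(op_name, "O", "G", "A", 11, op)
        b.atom("OP2" if op_name == "OP1" else "OP1", "O", "G", "A", 11, sib)
        for u in OCTA[1:]:
            b.water(MG_O * u)
        gt.labels[ion.atom_id] = "Or.5Ow"
        gt.o2p_count = 1
    elif m == "outer_shell":
        ion = _octahedral_ion(b, [(u, "Ow") for u in OCTA])
        w_pos = MG_O * EX  # first-shell water carrying the outer-shell contacts
        d_hb = float(p.get("hb_distance", 2.9))
        o6, n7 = _GUA["O6"], _GUA["N7"]
        half = float(np.linalg.norm(n7 - o6)) / 2.0
        if d_hb <= half:
            raise FixtureError("hb_distance shorter than half the O6...N7 spread")
        a = math.sqrt(d_hb * d_hb - half * half)
        o6_t = w_pos + np.array([a, half, 0.0])
        n7_t = w_pos + np.array([a, -half, 0.0])
        centroid = np.mean(list(_GUA.values()), axis=0)
        rot = _frame_transform((n7 - o6, EZ), (n7_t - o6_t, EZ))
        trans = o6_t - rot @ o6
        if (rot @ centroid + trans)[0] < o6_t[0]:
            # mirror so the ring body extends away from the hydration shell
            rot = _frame_transform((n7 - o6, EZ), (n7_t - o6_t, -EZ))
            trans = o6_t - rot @ o6
        b.guanine(rot, trans, 1)
        gt.labels[ion.atom_id] = "6Ow"
    elif m == "incomplete_shell":
        n = int(p.get("n_ligands", 4))
        ion = _octahedral_ion(b, [(u, "Ow") for u in OCTA[:n]])
        gt.expected_flags[ion.atom_id] = ["incomplete_shell", "not_octahedral"]
    elif m == "K_site":
        element = p.get("element", "K")
        d = float(p.get("ligand_distance", K_O))
        ion = b.metal(element, np.zeros(3))
        for u in (EZ, -EZ):
            b.water(d * u)
        for k in range(5):
            th = math.radians(72.0 * k)
            b.water(d * np.array([math.cos(th), math.sin(th), 0.0]))
        if element.upper() == "MG":
            gt.expected_flags[ion.atom_id] = ["likely_K_as_Mg"]
    elif m == "mgA_pair":
        sep = float(p.get("separation", 4.8))
        pm = math.sqrt(max((MG_O + P_OP) ** 2 - (sep / 2.0) ** 2, 0.0))
        if pm <= 0:
            raise FixtureError("mgA_pair separation too large for bridging phosphates")
        mg1, mg2 = np.zeros(3), np.array([sep, 0.0, 0.0])
        pos_p = [np.array([sep / 2.0, pm, 0.0]), np.array([sep / 2.0, -pm, 0.0])]
        ion1, ion2 = b.metal("MG", mg1), b.metal("MG", mg2)
        for i, pp in enumerate(pos_p, start=1):
            b.atom("P", "P", "G", "A", i, pp)
            b.atom("OP1", "O", "G", "A", i, mg1 + MG_O * _unit(pp - mg1))
            b.atom("OP2", "O", "G", "A", i, mg2 + MG_O * _unit(pp - mg2))
        for mg in (mg1, mg2):
            d1 = _unit(pos_p[0] - mg)
            d2 = _unit(pos_p[1] - mg)
            e1 = d1
            e2 = _unit(d2 - np.dot(d2, e1) * e1)
            e3 = np.cross(e1, e2)
            for u in (-e1, -e2, e3, -e3):
                b.water(mg + MG_O * u)
        gt.labels[ion1.atom_id] = "cis-2Oph.4Ow"
        gt.labels[ion2.atom_id] = "cis-2Oph.4Ow"
        # each ion chelates the two bridging phosphates in cis -> two clamps
        gt.clamp_count = 2
        gt.pair_class = "MgA_μc2"
    elif m == "mgB_pair":
        sep = float(p.get("separation", 3.8))
        mg1, mg2 = np.zeros(3), np.array([sep, 0.0, 0.0])
        y = math.sqrt(MG_O**2 - (sep / 2.0) ** 2)
        bridge = np.array([sep / 2.0, y, 0.0])
        ion1, ion2 = b.metal("MG", mg1), b.metal("MG", mg2)
        b.water(bridge)
        for mg in (mg1, mg2):
            e1 = _unit(bridge - mg)
            e2 = _unit(np.cross(EZ, e1))
            for u in (-e1, e2, -e2, EZ, -EZ):
                b.water(mg + MG_O * u)
        gt.labels[ion1.atom_id] = "6Ow"
        gt.labels[ion2.atom_id] = "6Ow"
        gt.pair_class = "MgB_μc1"
    elif m == "mgC_pair":
        sep = float(p.get("separation", 2.8))
        mg1, mg2 = np.zeros(3), np.array([sep, 0.0, 0.0])
        rho = math.sqrt(MG_O**2 - (sep / 2.0) ** 2)
        ion1, ion2 = b.metal("MG", mg1), b.metal("MG", mg2)
        bridges = []
        for psi_deg, kind in ((90.0, "Oph"), (210.0, "Ow"), (330.0, "Ow")):
            psi = math.radians(psi_deg)
            pos = np.array([sep / 2.0, rho * math.cos(psi), rho * math.sin(psi)])
            bridges.append(pos)
            if kind == "Ow":
                b.water(pos)
            else:
                pp = pos + P_OP * EZ
                b.atom("P", "P", "G", "A", 1, pp)
                b.atom("OP1", "O", "G", "A", 1, pos)
                q = _unit(pos - pp)
                beta = math.radians(OP_P_OP)
                b.atom("OP2", "O", "G", "A", 1,
                       pp + P_OP * (math.cos(beta) * q + math.sin(beta) * EX))
        for mg in (mg1, mg2):
            for pos in bridges:
                b.water(mg - MG_O * _unit(pos - mg))
        gt.labels[ion1.atom_id] = "Oph.5Ow"
        gt.labels[ion2.atom_id] = "Oph.5Ow"
        gt.pair_class = "MgC_μc3"
    elif m == "mgD_pair":
        d = MG_O
        mg1 = np.zeros(3)
        mg2 = (2.0 * d / 3.0) * np.array([1.0, 1.0, 1.0])  # |mg2| = 2d/sqrt(3) = 2.39
        ion1, ion2 = b.metal("MG", mg1), b.metal("MG", mg2)
        nhat = _unit(np.array([1.0, 1.0, 1.0]))
        for u in (EX, EY, EZ):  # shared face
            b.water(d * u)
        for u in (-EX, -EY, -EZ):
            pos = d * u
            b.water(pos)  # Mg1 own
            refl = pos - 2.0 * (np.dot(pos, nhat) - d / math.sqrt(3.0)) * nhat
            b.water(refl)  # Mg2 own (mirror through the shared face)
        gt.labels[ion1.atom_id] = "6Ow"
        gt.labels[ion2.atom_id] = "6Ow"
        gt.pair_class = "MgD_μc3"
    elif m == "mgK_pair":
        sep = float(p.get("separation", 4.0))
        d_kw = 2.9  # K...bridging-water distance, inside the K window
        mg, kk = np.zeros(3), np.array([sep, 0.0, 0.0])
        x = (sep**2 + MG_O**2 - d_kw**2) / (2.0 * sep)
        y = math.sqrt(MG_O**2 - x * x)
        w1 = np.array([x, y, 0.0])
        w2 = np.array([x, -y, 0.0])
        ion1, ion2 = b.metal("MG", mg), b.metal("K", kk)
        b.water(w1)
        b.water(w2)
        e1 = _unit(w1)
        e2 = _unit(w2 - np.dot(w2, e1) * e1)
        e3 = np.cross(e1, e2)
        for u in (-e1, -e2, e3, -e3):
            b.water(mg + MG_O * u)
        for k in range(5):
            th = math.radians(72.0 * k)
            dirv = _unit(math.cos(math.radians(45.0)) * EX
                         + math.sin(math.radians(45.0))
                         * (math.cos(th) * EY + math.sin(th) * EZ))
            b.water(kk + K_O * dirv)
        gt.labels[ion1.atom_id] = "6Ow"
        gt.pair_class = "MgK_μc2"
    elif m == "helix_negative":
        n_res = int(p.get("n_res", 8))
        twist, rise = math.radians(32.7), 2.81
        r_p, r_o2, r_n7 = 8.9, 9.2, 4.5
        for i in range(n_res):
            th = i * twist
            z = i * rise
            radial = np.array([math.cos(th), math.sin(th), 0.0])
            pp = r_p * radial + z * EZ
            b.atom("P", "P", "A", "A", i + 1, pp)
            b.atom("OP1", "O", "A", "A", i + 1, pp + 0.74 * radial + 1.28 * EZ)
            b.atom("OP2", "O", "A", "A", i + 1, pp + 0.74 * radial - 1.28 * EZ)
            th2 = th + math.radians(5.0)
            b.atom("O2'", "O", "A", "A", i + 1,
                   r_o2 * np.array([math.cos(th2), math.sin(th2), 0.0]) + (z + 2.0) * EZ)
            th3 = th + math.radians(100.0)
            b.atom("N7", "N", "A", "A", i + 1,
                   r_n7 * np.array([math.cos(th3), math.sin(th3), 0.0]) + (z + 1.0) * EZ)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise FixtureError(f"unhandled motif {m}")

    table = b.table(spec)
    if spec.jitter_sd == 0:
        _validate_clamp_consistency(table, gt, m)
    return table, gt


def _count_pairs(atoms: list[AtomRecord], lo: float, hi: float, bmax: float | None = None) -> int:
    n = 0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            if atoms[i].residue_key == atoms[j].residue_key:
                continue
            if bmax is not None and (atoms[i].b_factor > bmax or atoms[j].b_factor > bmax):
                continue
            d = float(np.linalg.norm(atoms[i].xyz - atoms[j].xyz))
            if lo <= d < hi:
                n += 1
    return n


def _validate_clamp_consistency(table: StructureTable, gt: GroundTruth, motif: str) -> None:
    """Construction self-check: planted pair geometry matches the ground truth."""
    oph = table.by_category("Oph")
    checks = (
        ("short Oph...Oph", _count_pairs(oph, 0.0, 3.4, bmax=60.0), gt.clamp_count),
        ("trans-candidate Oph...Oph", _count_pairs(oph, 3.9, 4.4 + 1e-9), gt.trans_candidate_count),
        (
            "short N7...N7",
            _count_pairs([a for a in table.by_category("Nb") if a.name == "N7"], 0.0, 3.4),
            gt.purine_seat_count,
        ),
    )
    for what, got, expected in checks:
        if got != expected:
            raise FixtureError(
                f"{motif}: construction yields {got} {what} pairs, ground truth says {expected}"
            )


# ---------------------------------------------------------------------------
# writing


def write_structure(table: StructureTable, path: str | Path, format: str = "mmcif") -> Path:
    """Write the table as a standard-conforming mmCIF or PDB file."""
    if not len(table):
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    st = gemmi.Structure()
    st.name = "ionshell-fixture"
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    # group records by chain / residue first: gemmi containers may reallocate
    # on insertion, so each object is fully built before being added
    chain_order: list[str] = []
    by_chain: dict[str, dict[tuple[int, str, str], list[AtomRecord]]] = {}
    for rec in table:
        if rec.chain_id not in by_chain:
            by_chain[rec.chain_id] = {}
            chain_order.append(rec.chain_id)
        rkey = (rec.residue_number, rec.icode, rec.residue_name)
        by_chain[rec.chain_id].setdefault(rkey, []).append(rec)
    for chain_id in chain_order:
        ch = gemmi.Chain(chain_id)
        for (resnum, icode, resname), recs in by_chain[chain_id].items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            for rec in recs:
                atom = gemmi.Atom()
                atom.name = rec.name
                atom.element = gemmi.Element(rec.element)
                atom.pos = gemmi.Position(*rec.xyz)
                atom.b_iso = rec.b_factor
                atom.occ = rec.occupancy
                if rec.altloc:
                    atom.altloc = rec.altloc
                res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    fmt = format.lower()
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r} (expected mmcif or pdb)")
    return path
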