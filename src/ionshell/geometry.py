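"""First coordination shells and octahedral-geometry descriptors.

A Mg2+ site is accepted as inner-shell when O/N ligands sit in the
1.9-2.3 Angstrom window; the (2.3, 3.4] band around Mg2+ is an *exclusion
zone* in which no O/N atom should occur for a correctly modelled site.
K+ uses the 2.6-3.2 Angstrom window with 6-9 ligands and no exclusion zone.
Octahedral regularity is scored as the deviation of the 15 ligand-ion-ligand
angles (12 cis at 90 deg, 3 trans at 180 deg) from ideality, minimized over
all assignments of ligands to octahedron vertices, and binned into
correct (<5 deg) / slightly distorted (5-10 deg) / highly distorted (>10 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structure import LIGAND_CATEGORIES, AtomRecord, StructureTable


@dataclass(frozen=True)
class GeometryParams:
    """All tunable stereochemical parameters (Angstrom / degrees / A^2 / sigma)."""

    mg_o_mean: float = 2.07          # mean Mg...O first-shell distance
    mg_o_sd: float = 0.04
    mg_n_mean: float = 2.19          # mean Mg...N first-shell distance
    mg_n_sd: float = 0.08
    mg_accept_window: tuple[float, float] = (1.9, 2.3)
    mg_exclusion_zone: tuple[float, float] = (2.3, 3.4)   # half-open (lo, hi]
    k_window: tuple[float, float] = (2.6, 3.2)
    k_coord_range: tuple[int, int] = (6, 9)
    na_window: tuple[float, float] = (2.2, 2.7)
    zn_window: tuple[float, float] = (1.9, 2.4)
    cis_angle: float = 90.0
    cis_angle_sd: float = 3.0
    trans_angle: float = 177.0
    trans_angle_sd: float = 4.0
    cis_oo: float = 2.93
    cis_oo_sd: float = 0.09
    trans_oo: float = 4.13
    trans_oo_sd: float = 0.07
    outer_shell_window: tuple[float, float] = (2.6, 3.2)
    clamp_dmax: float = 3.4
    clamp_bmax: float = 60.0
    trans_candidate_window: tuple[float, float] = (3.9, 4.4)
    distortion_correct_max: float = 5.0
    distortion_slight_max: float = 10.0
    density_min: float = 4.0
    occupancy_min: float = 0.5
    cis_trans_cut: float = 135.0      # ligand pair angle <= cut -> cis
    pair_dmax: float = 5.5            # metal-metal pair search radius

    def window_for(self, element: str) -> tuple[float, float]:
        return {
            "MG": self.mg_accept_window,
            "K": self.k_window,
            "NA": self.na_window,
            "ZN": self.zn_window,
        }.get(element.upper(), self.mg_accept_window)

    def with_overrides(self, overrides: dict[str, object]) -> "GeometryParams":
        """Validated copy; unknown keys raise, tuples accept 'lo,hi' strings."""
        known = {f.name: f.type for f in fields(self)}
        clean: dict[str, object] = {}
        for key, val in overrides.items():
            if key not in known:
                raise KeyError(f"unknown geometry parameter: {key}")
            current = getattr(self, key)
            if isinstance(current, tuple):
                if isinstance(val, str):
                    parts = [float(v) for v in val.split(",")]
                else:
                    parts = [float(v) for v in val]  # type: ignore[union-attr]
                if len(parts) != len(current):
                    raise ValueError(f"{key}: expected {len(current)} values")
                if isinstance(current[0], int):
                    clean[key] = tuple(int(p) for p in parts)
                else:
                    clean[key] = tuple(parts)
            else:
                clean[key] = type(current)(val)  # type: ignore[call-arg]
        return replace(self, **clean)


def load_params(path: str | Path) -> GeometryParams:
    """Read ``key = value`` overrides (distances in Angstrom, angles in degrees)."""
    overrides: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        overrides[key.strip()] = val.strip()
    return GeometryParams().with_overrides(overrides)


# ---------------------------------------------------------------------------
# vector helpers


def angle_deg(a: np.ndarray, center: np.ndarray, b: np.ndarray) -> float:
    """Angle a-center-b in degrees."""
    va, vb = a - center, b - center
    cosang = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through >= 3 points: (centroid, unit normal) via SVD."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def point_plane_distance(point: np.ndarray, centroid: np.ndarray, normal: np.ndarray) -> float:
    return abs(float(np.dot(point - centroid, normal)))


# ---------------------------------------------------------------------------
# shells


@dataclass
class CoordinationShell:
    """A metal ion with its first-shell ligands and derived geometry."""

    ion: AtomRecord
    ligands: list[tuple[AtomRecord, float]]
    exclusion_hits: list[tuple[AtomRecord, float]]
    angles: dict[tuple[int, int], float] = field(default_factory=dict)
    distortion: float = float("nan")        # mean |deviation| over 15 angle slots
    distortion_sum: float = float("nan")    # summed deviation over the same slots
    distortion_category: str = "not_octahedral"
    pairwise_cis_trans: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)

    def ligand_atoms(self) -> list[AtomRecord]:
        return [a for a, _ in self.ligands]

    def ligand_ids(self) -> set[str]:
        return {a.atom_id for a, _ in self.ligands}

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a, _ in self.ligands:
            counts[a.category] = counts.get(a.category, 0) + 1
        return counts


def _trans_pairings(n: int = 6):
    """All 15 partitions of range(6) into 3 unordered pairs."""
    items = list(range(n))

    def rec(rest: list[int]):
        if not rest:
            yield []
            return
        first = rest[0]
        for j in range(1, len(rest)):
            pair = (first, rest[j])
            remaining = rest[1:j] + rest[j + 1:]
            for tail in rec(remaining):
                yield [pair] + tail

    yield from rec(items)


_PAIRINGS = list(_trans_pairings(6))


def octahedral_distortion(
    shell: CoordinationShell, params: GeometryParams | None = None
) -> tuple[float, str]:
    """Score the shell against a regular octahedron.

    Ligands are assigned to ideal vertices by exact minimization over all
    vertex assignments (equivalently, over the 15 ways of choosing the three
    trans pairs); the score is the mean absolute deviation of the 12 cis
    angles from 90 deg and the 3 trans angles from 180 deg.  Returns
    ``(degrees, category)`` and stores both the mean and the summed value on
    the shell.  Non-hexacoordinated shells are ``not_octahedral``.
    """
    params = params or GeometryParams()
    n = shell.coordination_number
    if n != 6:
        shell.distortion = float("nan")
        shell.distortion_sum = float("nan")
        shell.distortion_category = "not_octahedral"
        return float("nan"), "not_octahedral"
    ang = shell.angles
    best = math.inf
    for pairing in _PAIRINGS:
        trans_set = {tuple(sorted(p)) for p in pairing}
        total = 0.0
        for key, a in ang.items():
            if key in trans_set:
                total += abs(a - 180.0)
            else:
                total += abs(a - 90.0)
        if total < best:
            best = total
    mean = best / 15.0
    shell.distortion = mean
    shell.distortion_sum = best
    if mean < params.distortion_correct_max:
        cat = "correct"
    elif mean <= params.distortion_slight_max:
        cat = "slightly_distorted"
    else:
        cat = "highly_distorted"
    shell.distortion_category = cat
    return mean, cat


def cis_trans(
    shell: CoordinationShell,
    ligand_a: int | AtomRecord,
    ligand_b: int | AtomRecord,
    params: GeometryParams | None = None,
) -> str:
    """'cis' or 'trans' for a ligand pair (angle cut at 135 deg, inclusive cis)."""
    params = params or GeometryParams()
    ia = ligand_a if isinstance(ligand_a, int) else _ligand_index(shell, ligand_a)
    ib = ligand_b if isinstance(ligand_b, int) else _ligand_index(shell, ligand_b)
    key = (min(ia, ib), max(ia, ib))
    a = shell.angles[key]
    return "cis" if a <= params.cis_trans_cut else "trans"


def _ligand_index(shell: CoordinationShell, atom: AtomRecord) -> int:
    for i, (a, _) in enumerate(shell.ligands):
        if a.atom_id == atom.atom_id:
            return i
    raise KeyError(f"{atom.atom_id} is not a ligand of {shell.ion.atom_id}")


def build_shell(
    table: StructureTable, ion: AtomRecord, params: GeometryParams | None = None
) -> CoordinationShell:
    """First coordination shell of a metal.

    Ligands are categorized O/N atoms (Oph/Or/Ob/Nb/Ow/Obb/Ocoo/Ocno/
    OHprot/NHis) inside the element-appropriate distance window with
    occupancy >= 0.5; C, P, metals and hydrogens are never ligands.  For Mg,
    O/N atoms in the (2.3, 3.4] exclusion zone are collected separately.
    """
    params = params or GeometryParams()
    if ion.category != "metal":
        raise ValueError(f"{ion.atom_id} is not a metal (category {ion.category})")
    lo, hi = params.window_for(ion.element)
    is_mg = ion.element.upper() == "MG"
    search_r = max(hi, params.mg_exclusion_zone[1]) if is_mg else hi
    ligands: list[tuple[AtomRecord, float]] = []
    exclusion: list[tuple[AtomRecord, float]] = []
    for atom, dist in table.neighbors(ion.xyz, search_r + 1e-9):
        if atom.index == ion.index:
            continue
        if atom.element not in ("O", "N"):
            continue
        if (
            lo <= dist <= hi
            and atom.category in LIGAND_CATEGORIES
            and atom.occupancy >= params.occupancy_min
        ):
            ligands.append((atom, dist))
        elif is_mg and params.mg_exclusion_zone[0] < dist <= params.mg_exclusion_zone[1]:
            exclusion.append((atom, dist))
    shell = CoordinationShell(ion=ion, ligands=ligands, exclusion_hits=exclusion)
    for i, j in combinations(range(len(ligands)), 2):
        a = angle_deg(ligands[i][0].xyz, ion.xyz, ligands[j][0].xyz)
        shell.angles[(i, j)] = a
        shell.pairwise_cis_trans[(i, j)] = "cis" if a <= params.cis_trans_cut else "trans"
    octahedral_distortion(shell, params)
    return shell


def build_all_shells(
    table: StructureTable, params: GeometryParams | None = None
) -> dict[str, CoordinationShell]:
    params = params or GeometryParams()
    return {m.atom_id: build_shell(table, m, params) for m in table.metals()}


# ---------------------------------------------------------------------------
# per-ligand descriptors


@dataclass(frozen=True)
class PhosphateDescriptor:
    """Geometry of a phosphate-bound ion relative to its OP1-P-OP2 group."""

    p_op_ion_angle: float     # degrees at the coordinated OP atom
    plane_distance: float     # unsigned ion distance to the OP1-P-OP2 plane


def phosphate_geometry(
    table: StructureTable, shell: CoordinationShell
) -> dict[str, PhosphateDescriptor | None]:
    """P-OP...ion angle and ion-to-(OP1,P,OP2)-plane distance per Oph ligand.

    Well-modelled phosphate-bound Mg2+ shows P-OP...Mg around 148 +/- 10 deg
    with the ion close to the OP1-P-OP2 plane (deviation ~0.7 +/- 0.3 A).
    ``None`` marks ligands whose parent P/OP siblings are missing.
    """
    out: dict[str, PhosphateDescriptor | None] = {}
    for atom, _ in shell.ligands:
        if atom.category != "Oph":
            continue
        key = atom.residue_key
        p = table.residue_atom(key, "P")
        op1 = table.residue_atom(key, "OP1")
        op2 = table.residue_atom(key, "OP2")
        if p is None or op1 is None or op2 is None:
            out[atom.atom_id] = None
            continue
        ang = angle_deg(p.xyz, atom.xyz, shell.ion.xyz)
        normal = np.cross(op1.xyz - p.xyz, op2.xyz - p.xyz)
        nn = np.linalg.norm(normal)
        if nn < 1e-9:
            out[atom.atom_id] = None
            continue
        dist = abs(float(np.dot(shell.ion.xyz - p.xyz, normal / nn)))
        out[atom.atom_id] = PhosphateDescriptor(ang, dist)
    return out


# ring-atom templates for base-plane fits (parent residue names)
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINES = frozenset({"A", "G", "DA", "DG"})
PYRIMIDINES = frozenset({"C", "U", "DC", "DT"})
CARBONYL_CARBON = {"O2": "C2", "O4": "C4", "O6": "C6"}
N_RING_NEIGHBORS = {"N1": ("C2", "C6"), "N3": ("C2", "C4"), "N7": ("C5", "C8")}


@dataclass(frozen=True)
class BaseDescriptor:
    """Geometry of a nucleobase-bound ion relative to the base plane."""

    alignment_angle: float | None  # C=O...ion angle (Ob) or lone-pair misalignment (Nb)
    plane_distance: float          # unsigned ion distance to the base plane


def base_geometry(
    table: StructureTable,
    shell: CoordinationShell,
    aliases: dict[str, str] | None = None,
) -> dict[str, BaseDescriptor | None]:
    """Base-plane distance and carbonyl/lone-pair alignment per Ob/Nb ligand.

    For a carbonyl oxygen the angle is C=O...ion (around 144 deg with the ion
    in the base plane for well-modelled sites); for a ring nitrogen it is the
    in-plane misalignment between the lone-pair bisector and the ion
    direction (0 deg = perfectly aligned).  Incomplete rings yield ``None``.
    """
    if aliases is None:
        from .structure import load_residue_aliases

        aliases = load_residue_aliases()
    out: dict[str, BaseDescriptor | None] = {}
    for atom, _ in shell.ligands:
        if atom.category not in ("Ob", "Nb"):
            continue
        parent = aliases.get(atom.residue_name.upper(), atom.residue_name.upper())
        if parent in PURINES:
            ring_names = PURINE_RING
        elif parent in PYRIMIDINES:
            ring_names = PYRIMIDINE_RING
        else:
            out[atom.atom_id] = None
            continue
        ring = [table.residue_atom(atom.residue_key, nm) for nm in ring_names]
        if any(r is None for r in ring):
            out[atom.atom_id] = None
            continue
        pts = np.vstack([r.xyz for r in ring])  # type: ignore[union-attr]
        centroid, normal = fit_plane(pts)
        plane_d = point_plane_distance(shell.ion.xyz, centroid, normal)
        align: float | None = None
        if atom.category == "Ob":
            cname = CARBONYL_CARBON.get(atom.name)
            carb = table.residue_atom(atom.residue_key, cname) if cname else None
            if carb is not None:
                align = angle_deg(carb.xyz, atom.xyz, shell.ion.xyz)
        else:
            nbrs = N_RING_NEIGHBORS.get(atom.name)
            if nbrs:
                a1 = table.residue_atom(atom.residue_key, nbrs[0])
                a2 = table.residue_atom(atom.residue_key, nbrs[1])
                if a1 is not None and a2 is not None:
                    u1 = a1.xyz - atom.xyz
                    u2 = a2.xyz - atom.xyz
                    lp = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
                    lp /= np.linalg.norm(lp)
                    v = shell.ion.xyz - atom.xyz
                    v /= np.linalg.norm(v)
                    align = math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(lp, v))))))
        out[atom.atom_id] = BaseDescriptor(align, plane_d)
    return out


# ---------------------------------------------------------------------------
# outer shell


def outer_shell_contacts(
    table: StructureTable,
    shell: CoordinationShell,
    params: GeometryParams | None = None,
) -> list[tuple[AtomRecord, AtomRecord, float]]:
    """Water-mediated contacts of the shell: (first-shell water, acceptor, d).

    For each inner-shell water, all non-water O/N atoms in the hydrogen-bond
    window (2.6-3.2 A by default) are counted once per (water, acceptor)
    pair; atoms already inner-shell to the same ion are excluded.
    """
    params = params or GeometryParams()
    lo, hi = params.outer_shell_window
    inner = shell.ligand_ids()
    seen: set[tuple[str, str]] = set()
    out: list[tuple[AtomRecord, AtomRecord, float]] = []
    for water, _ in shell.ligands:
        if water.category != "Ow":
            continue
        for atom, dist in table.neighbors(water.xyz, hi + 1e-9):
            if dist < lo or atom.index == water.index:
                continue
            if atom.element not in ("O", "N") or atom.is_water:
                continue
            if atom.atom_id in inner:
                continue
            key = (water.atom_id, atom.atom_id)
            if key in seen:
                continue
            seen.add(key)
            out.append((water, atom, dist))
    out.sort(key=lambda t: (t[0].index, t[2]))
    return out
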