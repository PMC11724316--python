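"""Typed atom tables for ion-site analysis.

Parses mmCIF/PDB coordinate files into a flat, spatially indexed table of
:class:`AtomRecord` objects and assigns every atom a chemical-role category
(phosphate oxygen, ribose oxygen, nucleobase O/N, water, metal, ...).  The
role vocabulary follows the MgRNA-style nomenclature extended to protein
ligands:

====== =============================================================
Oph    anionic phosphate oxygens OP1/OP2
Or     ribose / bridging oxygens O2', O3', O4', O5'
Ob     nucleobase carbonyl oxygens O2/O4/O6
Nb     non-protonated nucleobase ring nitrogens (per-base template)
Ow     water oxygen
Obb    amino-acid backbone carbonyl oxygen
Ocoo   Asp/Glu carboxylate oxygen
Ocno   Asn/Gln side-chain carbonyl oxygen
OHprot Ser/Thr/Tyr hydroxyl oxygen
NHis   non-protonated His ND1/NE2
metal  MG/K/NA/ZN ions
other  everything else (unknown residues degrade here, never fail)
====== =============================================================

File I/O is delegated to :mod:`gemmi`; the spatial index is a scipy
cKDTree over all atom coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: role categories that may appear in a coordination shell
LIGAND_CATEGORIES = frozenset(
    {"Oph", "Or", "Ob", "Nb", "Ow", "Obb", "Ocoo", "Ocno", "OHprot", "NHis"}
)

#: elements recognized as analyzable metals (configurable via assign_roles)
DEFAULT_METAL_ELEMENTS = frozenset({"MG", "K", "NA", "ZN"})

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(Exception):
    """Raised for unparseable or empty input structures."""


@dataclass
class AtomRecord:
    """One atom with coordinates, identity and (after role assignment) a category."""

    atom_id: str
    element: str
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    icode: str
    xyz: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    category: str = "other"
    index: int = -1  # position in the owning table

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.atom_id}: coordinates must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.atom_id}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_number, icode) — identity of the parent residue."""
        return (self.chain_id, self.residue_number, self.icode)

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUES

    @property
    def is_metal(self) -> bool:
        return self.category == "metal"

    def __repr__(self) -> str:  # compact, used in reports
        return f"<{self.atom_id}>"


class StructureTable:
    """Ordered atom collection with an exact radius-query index.

    The index is rebuilt lazily and always returns precisely the brute-force
    set of atoms within a radius of a probe point.
    """

    def __init__(self, atoms: Iterable[AtomRecord], provenance: str = "") -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        self.provenance = provenance
        seen: dict[str, int] = {}
        for i, a in enumerate(self.atoms):
            a.index = i
            if a.atom_id in seen:
                seen[a.atom_id] += 1
                a.atom_id = f"{a.atom_id}#{seen[a.atom_id]}"
            else:
                seen[a.atom_id] = 0
        self._coords: np.ndarray | None = None
        self._tree: cKDTree | None = None
        self._residues: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            self._residues.setdefault(a.residue_key, []).append(a)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            if self.atoms:
                self._coords = np.vstack([a.xyz for a in self.atoms])
            else:
                self._coords = np.empty((0, 3))
        return self._coords

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    def neighbors(
        self, point: np.ndarray, radius: float
    ) -> list[tuple[AtomRecord, float]]:
        """All atoms within ``radius`` of ``point``, sorted by distance."""
        if radius <= 0:
            return []
        if not self.atoms:
            return []
        idx = self.tree.query_ball_point(np.asarray(point, dtype=float), radius)
        out = [
            (self.atoms[i], float(np.linalg.norm(self.atoms[i].xyz - point)))
            for i in idx
        ]
        out.sort(key=lambda t: (t[1], t[0].index))
        return out

    def residue_atoms(self, key: tuple[str, int, str]) -> list[AtomRecord]:
        return self._residues.get(key, [])

    def residue_atom(self, key: tuple[str, int, str], name: str) -> AtomRecord | None:
        for a in self._residues.get(key, []):
            if a.name == name:
                return a
        return None

    def metals(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.category == "metal"]

    def by_category(self, category: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.category == category]


# ---------------------------------------------------------------------------
# role templates


def load_role_templates() -> dict[tuple[str, str], str]:
    """Parse the shipped residue/atom -> category table (text, versioned)."""
    templates: dict[tuple[str, str], str] = {}
    text = resources.files("ionshell.data").joinpath("roles.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, cat = line.split("\t")
        templates[(res, atom)] = cat
    return templates


def load_residue_aliases() -> dict[str, str]:
    """Modified-residue -> parent-residue alias map (e.g. PSU -> U)."""
    aliases: dict[str, str] = {}
    text = resources.files("ionshell.data").joinpath("aliases.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, parent = line.split("\t")
        aliases[alias] = parent
    return aliases


def assign_roles(
    table: StructureTable,
    templates: dict[tuple[str, str], str] | None = None,
    aliases: dict[str, str] | None = None,
    metal_elements: frozenset[str] = DEFAULT_METAL_ELEMENTS,
) -> StructureTable:
    """Assign every atom exactly one role category, in place.

    Unknown residues are never an error: their O/N atoms degrade to
    ``other`` with one logged warning per residue name.
    """
    if templates is None:
        templates = load_role_templates()
    if aliases is None:
        aliases = load_residue_aliases()
    warned: set[str] = set()
    known_residues = {res for res, _ in templates}
    for a in table.atoms:
        rn = a.residue_name.upper()
        elem = a.element.upper()
        if rn in WATER_RESIDUES:
            a.category = "Ow" if elem == "O" else "other"
            continue
        if elem in metal_elements:
            a.category = "metal"
            continue
        rn = aliases.get(rn, rn)
        cat = templates.get((rn, a.name))
        if cat is not None:
            a.category = cat
        else:
            a.category = "other"
            if rn not in known_residues and elem in ("O", "N") and rn not in warned:
                warned.add(rn)
                logger.warning(
                    "unknown residue %s: O/N atoms categorized as 'other'", rn
                )
    return table


# ---------------------------------------------------------------------------
# file reading


def _atom_id(chain: str, resname: str, resnum: int, icode: str, name: str) -> str:
    ic = icode.strip()
    return f"{chain}/{resname}{resnum}{ic}/{name}"


def read_structure(
    path: str | Path,
    format: str = "auto",
    keep_altloc: str = "A",
    assign: bool = True,
) -> StructureTable:
    """Read an mmCIF or PDB file into a :class:`StructureTable`.

    Only blank or ``keep_altloc`` alternate locations are retained (the
    analysis treats a single conformer; alternates are an ambiguity signal).
    Hydrogens are retained in the table but never act as ligands.  Author
    (``auth_*``) chain/residue numbering is used as the reporting identity.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
    }.get(format.lower())
    if fmt is None:
        raise ValueError(f"unknown format {format!r} (expected mmcif, pdb or auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path.name}: file contains no model")
    model = st[0]
    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            resnum = residue.seqid.num
            icode = residue.seqid.icode.strip()
            for atom in residue:
                if atom.altloc not in ("", "\0") and atom.altloc != keep_altloc:
                    continue
                records.append(
                    AtomRecord(
                        atom_id=_atom_id(chain.name, residue.name, resnum, icode, atom.name),
                        element=atom.element.name.upper(),
                        name=atom.name,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_number=resnum,
                        icode=icode,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        b_factor=atom.b_iso,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        altloc="" if atom.altloc == "\0" else atom.altloc,
                    )
                )
    if not records:
        raise StructureError(f"{path.name}: model contains no atoms")
    table = StructureTable(records, provenance=f"{path.name} ({format})")
    if assign:
        assign_roles(table)
    return table
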