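"""Shared helpers: hand-built atom tables and fixture merging."""

from __future__ import annotations

import numpy as np
import pytest

from ionshell.structure import AtomRecord, StructureTable


def make_atom(
    name: str,
    element: str,
    xyz,
    category: str,
    resname: str = "G",
    chain: str = "A",
    resnum: int = 1,
    b: float = 20.0,
    occ: float = 1.0,
) -> AtomRecord:
    return AtomRecord(
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
        category=category,
    )


def make_table(records) -> StructureTable:
    return StructureTable(records, provenance="test")


def merge_tables(tables, offsets) -> StructureTable:
    """Translate each table by its offset and merge into one (residues renumbered)."""
    records = []
    for i, (tbl, off) in enumerate(zip(tables, offsets)):
        off = np.asarray(off, dtype=float)
        for a in tbl:
            records.append(
                AtomRecord(
                    atom_id=f"{i}:{a.atom_id}",
                    element=a.element,
                    name=a.name,
                    residue_name=a.residue_name,
                    chain_id=a.chain_id,
                    residue_number=a.residue_number + 1000 * i,
                    icode=a.icode,
                    xyz=a.xyz + off,
                    b_factor=a.b_factor,
                    occupancy=a.occupancy,
                    category=a.category,
                )
            )
    return StructureTable(records, provenance="merged")


@pytest.fixture
def octa_waters():
    """Six water oxygens at ideal octahedron vertices around the origin."""

    def _build(d: float = 2.07, element: str = "MG"):
        from ionshell.fixtures import OCTA

        recs = [make_atom(element, element, (0, 0, 0), "metal", resname=element, chain="M")]
        for i, u in enumerate(OCTA, start=1):
            recs.append(
                make_atom("O", "O", d * np.asarray(u), "Ow", resname="HOH", chain="S", resnum=i)
            )
        return make_table(recs)

    return _build
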