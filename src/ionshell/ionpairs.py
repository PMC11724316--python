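"""Metal-metal micro-cluster detection, taxonomy and chain assembly.

Two metals form a micro-cluster when they share one to three bridging
first-shell ligands (waters, O/N atoms) or phosphate groups.  Mg...Mg pairs
are binned by inter-metal distance: MgA (>4.2 A, bridged by at least one
phosphate group), MgB (3.2-4.2 A), MgC (2.6-3.2 A) and MgD (under 2.6 A,
always flagged for independent confirmation); the 1-3 suffix counts shared
phosphate groups (MgA) or shared ligands (MgB-D).  Mixed Mg...K pairs at
3.5-4.4 A sharing two or three ligands are MgK_uc2/3.  Pair graphs are
assembled into connected components ("ion chains") with networkx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import CoordinationShell, GeometryParams
from .structure import AtomRecord, StructureTable

MU = "μ"  # micro sign used in class labels (MgA_uc -> MgA_μc)


@dataclass
class IonPair:
    """Two metals with their separation and shared-ligand inventory."""

    ion_a: AtomRecord
    ion_b: AtomRecord
    distance: float
    shared_waters: int
    shared_nonwater: int
    shared_phosphate_groups: int
    shared_ligand_ids: tuple[str, ...]
    class_label: str = "unclassified"
    reason: str = ""
    caution: bool = False  # set for MgD pairs (need independent confirmation)

    @property
    def shared_total(self) -> int:
        return self.shared_waters + self.shared_nonwater


# distance bin edges (Angstrom); the source taxonomy gives exemplar
# distances (~2.4, ~2.8, ~3.8, ~4.5-5.3), these defaults interpolate them
MGD_MAX = 2.6
MGC_MAX = 3.2
MGB_MAX = 4.2
MGA_MAX = 5.5
MGK_WINDOW = (3.5, 4.4)


def find_pairs(
    table: StructureTable,
    shells: dict[str, CoordinationShell],
    dmax: float = MGA_MAX,
    params: GeometryParams | None = None,
) -> list[IonPair]:
    """All metal pairs within ``dmax`` sharing a bridging ligand or phosphate group.

    Sharing is evaluated on inner-shell membership under each metal's own
    acceptance window (a water bridging a Mg2+ at 2.07 A and a K+ at 2.9 A
    counts as shared).
    """
    params = params or GeometryParams()
    metals = [s.ion for s in shells.values()]
    out: list[IonPair] = []
    for i in range(len(metals)):
        for j in range(i + 1, len(metals)):
            a, b = metals[i], metals[j]
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d > dmax:
                continue
            sa, sb = shells[a.atom_id], shells[b.atom_id]
            ids_a, ids_b = sa.ligand_ids(), sb.ligand_ids()
            shared = ids_a & ids_b
            atoms_a = {at.atom_id: at for at, _ in sa.ligands}
            shared_w = sum(1 for sid in shared if atoms_a[sid].category == "Ow")
            shared_nw = len(shared) - shared_w
            # phosphate groups contributing an Oph to *each* ion (possibly
            # through different OP atoms of the same group)
            res_a = {at.residue_key for at, _ in sa.ligands if at.category == "Oph"}
            res_b = {at.residue_key for at, _ in sb.ligands if at.category == "Oph"}
            spg = len(res_a & res_b)
            if not shared and spg == 0:
                continue
            out.append(
                IonPair(
                    ion_a=a,
                    ion_b=b,
                    distance=d,
                    shared_waters=shared_w,
                    shared_nonwater=shared_nw,
                    shared_phosphate_groups=spg,
                    shared_ligand_ids=tuple(sorted(shared)),
                )
            )
    out.sort(key=lambda p: p.distance)
    return out


def classify_pair(pair: IonPair) -> str:
    """Assign the micro-cluster class label; stores it on the pair.

    Classification is symmetric in the two ions.  Every both-Mg pair with a
    shared ligand receives exactly one class or ``unclassified`` with a
    machine-readable reason.
    """
    ea, eb = pair.ion_a.element.upper(), pair.ion_b.element.upper()
    d = pair.distance
    label = "unclassified"
    reason = ""
    if ea == "MG" and eb == "MG":
        if d <= MGD_MAX:
            if pair.shared_total >= 1:
                label = f"MgD_{MU}c{min(pair.shared_total, 3)}"
                pair.caution = True
            else:
                reason = "no shared ligand"
        elif d < MGC_MAX:
            if pair.shared_total >= 1:
                label = f"MgC_{MU}c{min(pair.shared_total, 3)}"
            else:
                reason = "no shared ligand"
        elif d < MGB_MAX:
            if pair.shared_total >= 1:
                label = f"MgB_{MU}c{min(pair.shared_total, 3)}"
            else:
                reason = "no shared ligand"
        elif d <= MGA_MAX:
            if pair.shared_phosphate_groups >= 1:
                label = f"MgA_{MU}c{min(pair.shared_phosphate_groups, 3)}"
            else:
                reason = "MgA distance range but no bridging phosphate group"
        else:
            reason = f"distance {d:.2f} beyond {MGA_MAX} A"
    elif {ea, eb} == {"MG", "K"}:
        if MGK_WINDOW[0] <= d <= MGK_WINDOW[1] and pair.shared_total in (2, 3):
            label = f"MgK_{MU}c{pair.shared_total}"
        else:
            reason = (
                f"Mg-K pair outside window {MGK_WINDOW} or sharing "
                f"{pair.shared_total} ligands (need 2-3)"
            )
    else:
        reason = f"unsupported element pair {ea}-{eb}"
    pair.class_label = label
    pair.reason = reason
    return label


def classify_pairs(pairs: list[IonPair]) -> list[IonPair]:
    for p in pairs:
        classify_pair(p)
    return pairs


@dataclass
class IonChain:
    """A connected component of the classified pair graph."""

    ions: list[str]
    edges: list[tuple[str, str, str]]  # (ion_a, ion_b, class_label)
    contacted_residues: list[str] = field(default_factory=list)


def assemble_chains(
    pairs: list[IonPair],
    shells: dict[str, CoordinationShell] | None = None,
) -> list[IonChain]:
    """Connected components of the pair graph, largest first."""
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.ion_a.atom_id, p.ion_b.atom_id, label=p.class_label)
    chains: list[IonChain] = []
    for comp in nx.connected_components(g):
        ions = sorted(comp)
        edges = [
            (min(u, v), max(u, v), data["label"])
            for u, v, data in g.edges(ions, data=True)
        ]
        edges.sort()
        contacted: set[str] = set()
        if shells:
            for ion_id in ions:
                sh = shells.get(ion_id)
                if sh is None:
                    continue
                for at, _ in sh.ligands:
                    if not at.is_water:
                        ck = at.residue_key
                        contacted.add(f"{ck[0]}/{at.residue_name}{ck[1]}{ck[2]}")
        chains.append(IonChain(ions=ions, edges=edges, contacted_residues=sorted(contacted)))
    chains.sort(key=lambda c: (-len(c.ions), c.ions))
    return chains
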