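"""Site nomenclature labels and per-ion misassignment diagnoses.

A hexacoordinated ion is named by the multiset of its ligand categories in
canonical order, e.g. ``cis-2Oph.4Ow`` for two phosphate oxygens in cis plus
four waters.  Isomer prefixes: with exactly two non-water ligands the pair
is ``cis-``/``trans-``; with three, ``fac-`` (all mutually cis) or ``mer-``;
with four, the *waters'* mutual arrangement is encoded with capitalized
``Cis-``/``Trans-``.  Sites with 0, 1, 5 or 6 non-water ligands carry no
prefix.

Diagnoses flag the recurrent deposition problems around Mg2+: incomplete
shells, exclusion-zone contacts, K+ modelled as Mg2+ (and vice versa),
probable waters, and weak density peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .geometry import CoordinationShell, GeometryParams
from .structure import AtomRecord, StructureTable

#: canonical ordering of ligand categories inside a label
CATEGORY_ORDER = ["Oph", "Or", "Ob", "Nb", "Ocoo", "Obb", "Ocno", "OHprot", "Ow", "NHis"]
_ORDER_INDEX = {c: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class SiteLabel:
    """Canonical nomenclature for one hexacoordinated site."""

    counts: tuple[tuple[str, int], ...]  # (category, multiplicity), canonical order
    prefix: str                          # "", cis-, trans-, fac-, mer-, Cis-, Trans-
    text: str                            # e.g. "cis-2Oph.4Ow"

    @property
    def coordination_number(self) -> int:
        return sum(n for _, n in self.counts)


def _label_text(counts: tuple[tuple[str, int], ...], prefix: str) -> str:
    parts = [f"{n if n > 1 else ''}{cat}" for cat, n in counts]
    return prefix + ".".join(parts)


def label_site(
    shell: CoordinationShell, params: GeometryParams | None = None
) -> SiteLabel | None:
    """Label a hexacoordinated shell; returns None otherwise (diagnose instead)."""
    params = params or GeometryParams()
    if shell.coordination_number != 6:
        return None
    raw = shell.category_counts()
    counts = tuple(
        (cat, raw[cat]) for cat in sorted(raw, key=lambda c: _ORDER_INDEX.get(c, 99))
    )
    nonwater = [i for i, (a, _) in enumerate(shell.ligands) if a.category != "Ow"]
    waters = [i for i, (a, _) in enumerate(shell.ligands) if a.category == "Ow"]

    def rel(i: int, j: int) -> str:
        return shell.pairwise_cis_trans[(min(i, j), max(i, j))]

    prefix = ""
    if len(nonwater) == 2:
        prefix = rel(*nonwater) + "-"
    elif len(nonwater) == 3:
        pairs = [(nonwater[0], nonwater[1]), (nonwater[0], nonwater[2]), (nonwater[1], nonwater[2])]
        prefix = "fac-" if all(rel(i, j) == "cis" for i, j in pairs) else "mer-"
    elif len(nonwater) == 4 and len(waters) == 2:
        prefix = rel(*waters).capitalize() + "-"
    return SiteLabel(counts=counts, prefix=prefix, text=_label_text(counts, prefix))


@dataclass
class Diagnosis:
    """Consistency assessment of one metal site."""

    ion_id: str
    flags: set[str] = field(default_factory=set)
    evidence: dict[str, object] = field(default_factory=dict)
    well_defined: bool = False


def _count_on_in_window(
    table: StructureTable, ion: AtomRecord, lo: float, hi: float, half_open: bool = False
) -> int:
    n = 0
    for atom, dist in table.neighbors(ion.xyz, hi + 1e-9):
        if atom.index == ion.index or atom.element not in ("O", "N"):
            continue
        if (lo < dist if half_open else lo <= dist) and dist <= hi:
            n += 1
    return n


def diagnose_ion(
    table: StructureTable,
    shell: CoordinationShell,
    density: float | None = None,
    params: GeometryParams | None = None,
) -> Diagnosis:
    """Flag identification issues for one metal.

    ``likely_K_as_Mg``: a Mg-labelled ion surrounded K-style (>= 6 O/N in
    2.6-3.2 A, < 4 in 1.9-2.3 A).  ``likely_Mg_as_K``: a K-labelled ion with
    >= 5 O/N in the Mg window.  ``likely_water``: a Mg with no in-window
    contact and at most two in the exclusion zone.  ``well_defined`` requires
    six ligands, at most slight octahedral distortion, and (when a density
    sidecar is given) a peak >= 4.0 sigma.
    """
    params = params or GeometryParams()
    ion = shell.ion
    d = Diagnosis(ion_id=ion.atom_id)
    elem = ion.element.upper()
    cn = shell.coordination_number

    mg_lo, mg_hi = params.mg_accept_window
    k_lo, k_hi = params.k_window
    n_mg_window = _count_on_in_window(table, ion, mg_lo, mg_hi)
    n_k_window = _count_on_in_window(table, ion, k_lo, k_hi)

    if elem == "MG":
        if cn < 6:
            d.flags.add("incomplete_shell")
            d.evidence["coordination_number"] = cn
        if shell.exclusion_hits:
            d.flags.add("exclusion_zone_contact")
            d.evidence["exclusion_zone"] = [
                (a.atom_id, round(dist, 2)) for a, dist in shell.exclusion_hits
            ]
        if n_k_window >= 6 and n_mg_window < 4:
            d.flags.add("likely_K_as_Mg")
            d.evidence["k_window_contacts"] = n_k_window
        ez_lo, ez_hi = params.mg_exclusion_zone
        n_ez = _count_on_in_window(table, ion, ez_lo, ez_hi, half_open=True)
        if n_mg_window == 0 and n_ez <= 2:
            d.flags.add("likely_water")
            d.evidence["exclusion_zone_contacts"] = n_ez
    elif elem == "K":
        if n_mg_window >= 5:
            d.flags.add("likely_Mg_as_K")
            d.evidence["mg_window_contacts"] = n_mg_window
    if cn != 6:
        d.flags.add("not_octahedral")
    if density is not None and density < params.density_min:
        d.flags.add("low_density")
        d.evidence["density"] = density
    if ion.occupancy < params.occupancy_min:
        d.flags.add("low_occupancy")
        d.evidence["occupancy"] = ion.occupancy
    d.well_defined = (
        cn == 6
        and shell.distortion_category in ("correct", "slightly_distorted")
        and (density is None or density >= params.density_min)
    )
    return d


def summarize_sites(
    records: list[tuple[SiteLabel | None, Diagnosis]],
) -> pd.DataFrame:
    """Frequency table of site labels split by well-definedness."""
    rows: dict[str, dict[str, int]] = {}
    for label, diag in records:
        text = label.text if label is not None else "(not hexacoordinated)"
        row = rows.setdefault(text, {"well_defined": 0, "other": 0})
        row["well_defined" if diag.well_defined else "other"] += 1
    df = pd.DataFrame(
        [
            {"label": k, "well_defined": v["well_defined"], "other": v["other"],
             "total": v["well_defined"] + v["other"]}
            for k, v in rows.items()
        ]
    )
    if df.empty:
        return pd.DataFrame(columns=["label", "well_defined", "other", "total"])
    return df.sort_values(["total", "label"], ascending=[False, True]).reset_index(drop=True)
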