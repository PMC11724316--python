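"""Consolidated per-structure ion diagnosis report.

Runs the whole pipeline — parse, role assignment, shells, labels and
diagnoses, motif scans, ion-pair taxonomy, chain assembly, summaries — and
serializes the result as versioned JSON plus flat TSV tables (ions.tsv,
clamps.tsv, pairs.tsv, summary.tsv).  Deterministic for a fixed input and
configuration; provenance (tool version, parameters, input name) is kept in
a separate block so reports can be compared byte-for-byte on content.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__ as _pkg_version
from .classify import Diagnosis, SiteLabel, diagnose_ion, label_site, summarize_sites
from .geometry import (
    GeometryParams,
    build_all_shells,
    outer_shell_contacts,
    phosphate_geometry,
)
from .ionpairs import IonChain, IonPair, assemble_chains, classify_pairs, find_pairs
from .motifs import (
    ClampPair,
    O2pMotif,
    PurineSeat,
    TransCandidate,
    scan_clamps,
    scan_o2p_motifs,
    scan_purine_seats,
    scan_trans_candidates,
)
from .structure import StructureTable, read_structure

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class RunConfig:
    """Everything a diagnosis run depends on."""

    input_path: str | Path
    format: str = "auto"
    params: GeometryParams = field(default_factory=GeometryParams)
    density_sidecar: str | Path | None = None
    include_carboxyl_clamps: bool = False


@dataclass
class IonReport:
    ion_id: str
    element: str
    coordination_number: int
    label: SiteLabel | None
    diagnosis: Diagnosis
    distortion: float
    distortion_sum: float
    distortion_category: str
    ligand_distances: list[tuple[str, float]]
    outer_shell_count: int


@dataclass
class StructureReport:
    provenance: dict
    ions: list[IonReport]
    clamps: list[ClampPair]
    trans_candidates: list[TransCandidate]
    purine_seats: list[PurineSeat]
    o2p_motifs: list[O2pMotif]
    pairs: list[IonPair]
    chains: list[IonChain]
    summary: pd.DataFrame

    def to_dict(self) -> dict:
        """JSON-ready dict; provenance separated from content."""

        def _num(x: float) -> float | None:
            return None if (isinstance(x, float) and math.isnan(x)) else round(x, 4)

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "ions": [
                {
                    "ion_id": r.ion_id,
                    "element": r.element,
                    "coordination_number": r.coordination_number,
                    "label": r.label.text if r.label else None,
                    "flags": sorted(r.diagnosis.flags),
                    "well_defined": r.diagnosis.well_defined,
                    "distortion": _num(r.distortion),
                    "distortion_sum": _num(r.distortion_sum),
                    "distortion_category": r.distortion_category,
                    "ligands": [[a, round(d, 3)] for a, d in r.ligand_distances],
                    "outer_shell_contacts": r.outer_shell_count,
                }
                for r in self.ions
            ],
            "clamps": [
                {
                    "atom_a": c.atom_a.atom_id,
                    "atom_b": c.atom_b.atom_id,
                    "distance": round(c.distance, 3),
                    "op_combo": c.op_combo,
                    "sequence_separation": c.sequence_separation,
                    "stabilizer": c.stabilizer,
                    "ion_id": c.ion_id,
                }
                for c in self.clamps
            ],
            "trans_candidates": [
                {
                    "atom_a": t.atom_a.atom_id,
                    "atom_b": t.atom_b.atom_id,
                    "distance": round(t.distance, 3),
                    "ion_id": t.ion_id,
                    "candidate": t.candidate,
                }
                for t in self.trans_candidates
            ],
            "purine_seats": [
                {
                    "atom_a": s.atom_a.atom_id,
                    "atom_b": s.atom_b.atom_id,
                    "distance": round(s.distance, 3),
                    "ion_id": s.ion_id,
                }
                for s in self.purine_seats
            ],
            "o2p_motifs": [
                {
                    "o2_atom": s.o2_atom.atom_id,
                    "op_atom": s.op_atom.atom_id,
                    "distance": round(s.distance, 3),
                    "ion_id": s.ion_id,
                }
                for s in self.o2p_motifs
            ],
            "pairs": [
                {
                    "ion_a": p.ion_a.atom_id,
                    "ion_b": p.ion_b.atom_id,
                    "distance": round(p.distance, 3),
                    "shared_waters": p.shared_waters,
                    "shared_nonwater": p.shared_nonwater,
                    "shared_phosphate_groups": p.shared_phosphate_groups,
                    "class": p.class_label,
                    "reason": p.reason,
                    "caution": p.caution,
                }
                for p in self.pairs
            ],
            "chains": [
                {
                    "ions": c.ions,
                    "edges": [list(e) for e in c.edges],
                    "contacted_residues": c.contacted_residues,
                }
                for c in self.chains
            ],
            "summary": {
                "labels": self.summary.to_dict(orient="records"),
                "flag_counts": self._flag_counts(),
                "op_combo_counts": self._op_combo_counts(),
            },
        }

    def _flag_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.ions:
            for f in r.diagnosis.flags:
                counts[f] = counts.get(f, 0) + 1
        return dict(sorted(counts.items()))

    def _op_combo_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.clamps:
            counts[c.op_combo] = counts.get(c.op_combo, 0) + 1
        return dict(sorted(counts.items()))

    def to_json(self, exclude_provenance: bool = False) -> str:
        d = self.to_dict()
        if exclude_provenance:
            d.pop("provenance")
        return json.dumps(d, indent=1, ensure_ascii=False, sort_keys=False)

    def write(self, out_dir: str | Path, formats: tuple[str, ...] = ("json", "tsv")) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "json" in formats:
            (out / "report.json").write_text(self.to_json() + "\n")
        if "tsv" in formats:
            d = self.to_dict()
            pd.DataFrame(d["ions"]).drop(columns=["ligands"], errors="ignore").to_csv(
                out / "ions.tsv", sep="\t", index=False
            )
            pd.DataFrame(d["clamps"]).to_csv(out / "clamps.tsv", sep="\t", index=False)
            pd.DataFrame(d["pairs"]).to_csv(out / "pairs.tsv", sep="\t", index=False)
            self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    def flagged_selection(self) -> str:
        """Viewer-agnostic selection text listing flagged ion ids."""
        return "\n".join(r.ion_id for r in self.ions if r.diagnosis.flags)


def load_density_sidecar(path: str | Path) -> dict[str, float]:
    """Per-ion density peaks: TSV with columns ion_id, sigma ('#' comments)."""
    out: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        ion_id, sigma = line.split("\t")[:2]
        out[ion_id] = float(sigma)
    return out


def diagnose_table(
    table: StructureTable,
    params: GeometryParams | None = None,
    density: dict[str, float] | None = None,
    include_carboxyl_clamps: bool = False,
    provenance: dict | None = None,
) -> StructureReport:
    """Full diagnosis pipeline over an already-parsed table."""
    params = params or GeometryParams()
    density = density or {}
    shells = build_all_shells(table, params)
    ions: list[IonReport] = []
    records: list[tuple[SiteLabel | None, Diagnosis]] = []
    for ion_id in sorted(shells, key=lambda i: shells[i].ion.index):
        sh = shells[ion_id]
        lbl = label_site(sh, params)
        diag = diagnose_ion(table, sh, density.get(ion_id), params)
        outer = outer_shell_contacts(table, sh, params)
        ions.append(
            IonReport(
                ion_id=ion_id,
                element=sh.ion.element,
                coordination_number=sh.coordination_number,
                label=lbl,
                diagnosis=diag,
                distortion=sh.distortion,
                distortion_sum=sh.distortion_sum,
                distortion_category=sh.distortion_category,
                ligand_distances=[(a.atom_id, d) for a, d in sh.ligands],
                outer_shell_count=len(outer),
            )
        )
        records.append((lbl, diag))
    clamps = scan_clamps(table, params, shells, include_carboxyl=include_carboxyl_clamps)
    trans = scan_trans_candidates(table, params, shells)
    seats = scan_purine_seats(table, params, shells)
    o2p = scan_o2p_motifs(table, params, shells)
    pairs = classify_pairs(find_pairs(table, shells, params.pair_dmax, params))
    chains = assemble_chains(pairs, shells)
    summary = summarize_sites(records)
    prov = dict(provenance or {})
    prov.setdefault("tool", f"ionshell {_pkg_version}")
    prov.setdefault("source", table.provenance)
    prov.setdefault("params", dataclasses.asdict(params))
    return StructureReport(
        provenance=prov,
        ions=ions,
        clamps=clamps,
        trans_candidates=trans,
        purine_seats=seats,
        o2p_motifs=o2p,
        pairs=pairs,
        chains=chains,
        summary=summary,
    )


def run_diagnosis(config: RunConfig) -> StructureReport:
    """Read a structure file and produce its consolidated report."""
    table = read_structure(config.input_path, config.format)
    density = (
        load_density_sidecar(config.density_sidecar) if config.density_sidecar else None
    )
    return diagnose_table(
        table,
        config.params,
        density,
        include_carboxyl_clamps=config.include_carboxyl_clamps,
        provenance={"input": str(config.input_path)},
    )
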