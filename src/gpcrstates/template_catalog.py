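"""Structure annotation catalog and representative template selection.

Each annotated structure row carries the quality measures used to pick a
single representative structure per receptor and activation state:
resolution, fraction of generic positions modelled for receptor and
G protein, sequence identity to the human receptor, the degree-active
percentage (an externally supplied measure of how open the intracellular
coupling interface is), ligand modality and G-protein presence.

Default thresholds follow the main selection protocol (receptor
completeness >= 83%, G-protein completeness >= 43%, sequence identity
> 90%, resolution <= 3.6 A, degree active <= 20% for inactive and >= 90%
for active candidates, agonist-bound G-protein complexes required for the
active state).  An alternative published variant of the completeness and
resolution cut-offs (>= 86%, <= 4.0 A) exists; both are expressible through
:class:`SelectionCriteria`, and the package does not reconcile them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationRow",
    "SelectionCriteria",
    "TemplateCatalog",
    "load_annotation",
    "select_representatives",
    "count_selection",
    "tm6_opening_proxy",
]

STATES = ("inactive", "intermediate", "active")
CLASSES = ("A", "B1", "C", "F")
INACTIVE_MODALITIES = frozenset({"inverse agonist", "antagonist"})
ACTIVE_MODALITIES = frozenset({"agonist"})

REQUIRED_COLUMNS = [
    "structure_id", "receptor", "gpcr_class", "state_annotation",
    "resolution", "receptor_completeness", "seq_identity_human",
    "degree_active", "ligand_modality", "has_gprotein_complex",
]
OPTIONAL_COLUMNS = ["gprotein_completeness", "release_date", "parent_id"]


@dataclass(frozen=True)
class AnnotationRow:
    structure_id: str
    receptor: str
    gpcr_class: str
    state_annotation: str
    resolution: float
    receptor_completeness: float
    seq_identity_human: float
    degree_active: float
    ligand_modality: str
    has_gprotein_complex: bool
    gprotein_completeness: float | None = None
    release_date: str = ""
    #: parent PDB deposition; differs from structure_id for artificial
    #: per-monomer entries split out of a heterodimer structure
    parent_id: str = ""

    def __post_init__(self):
        if self.gpcr_class not in CLASSES:
            raise ValueError(f"unknown GPCR class {self.gpcr_class!r}")
        if self.state_annotation not in STATES:
            raise ValueError(f"unknown state {self.state_annotation!r}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name in ("receptor_completeness", "seq_identity_human",
                     "degree_active"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.gprotein_completeness is not None and not (
                0 <= self.gprotein_completeness <= 100):
            raise ValueError("gprotein_completeness outside [0, 100]")
        if not self.parent_id:
            object.__setattr__(self, "parent_id", self.structure_id)


@dataclass(frozen=True)
class SelectionCriteria:
    """Filter thresholds for representative templates.

    Boundary conventions: completeness and degree-active cuts are
    inclusive (>= / <=), resolution is inclusive (<=), sequence identity
    is strictly greater than the threshold.
    """

    min_receptor_completeness: float = 83.0
    min_gprotein_completeness: float = 43.0
    min_seq_identity: float = 90.0
    max_resolution: float = 3.6
    max_degree_active_inactive: float = 20.0
    min_degree_active_active: float = 90.0
    require_gprotein_for_active: bool = True
    inactive_modalities: frozenset = INACTIVE_MODALITIES
    active_modalities: frozenset = ACTIVE_MODALITIES

    def passes_common(self, row: AnnotationRow) -> bool:
        return (row.receptor_completeness >= self.min_receptor_completeness
                and row.seq_identity_human > self.min_seq_identity
                and row.resolution <= self.max_resolution)

    def passes_inactive(self, row: AnnotationRow) -> bool:
        return (self.passes_common(row)
                and row.state_annotation == "inactive"
                and row.degree_active <= self.max_degree_active_inactive
                and row.ligand_modality in self.inactive_modalities)

    def passes_active(self, row: AnnotationRow) -> bool:
        if not (self.passes_common(row)
                and row.state_annotation == "active"
                and row.degree_active >= self.min_degree_active_active
                and row.ligand_modality in self.active_modalities):
            return False
        if self.require_gprotein_for_active:
            if not row.has_gprotein_complex:
                return False
            if (row.gprotein_completeness is None
                    or row.gprotein_completeness < self.min_gprotein_completeness):
                return False
        return True

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["inactive_modalities"] = sorted(d["inactive_modalities"])
        d["active_modalities"] = sorted(d["active_modalities"])
        return d


@dataclass
class TemplateCatalog:
    rows: list
    representatives: dict = field(default_factory=dict)
    criteria: SelectionCriteria | None = None

    def representative_rows(self) -> dict:
        by_id = {r.structure_id: r for r in self.rows}
        return {k: by_id[v] for k, v in self.representatives.items()}

    def receptors_with_both_states(self) -> list:
        recs = {}
        for (receptor, state) in self.representatives:
            recs.setdefault(receptor, set()).add(state)
        return sorted(r for r, states in recs.items()
                      if {"inactive", "active"} <= states)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return bool(int(v))
    return str(v).strip().lower() in {"true", "yes", "1"}


def load_annotation(path) -> list:
    """Read an annotation catalog TSV/CSV into typed rows."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#",
                     dtype={"structure_id": str, "receptor": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation catalog missing required column(s): "
                         f"{missing}")
    rows = []
    for rec in df.to_dict("records"):
        gp = rec.get("gprotein_completeness")
        if gp is None or (isinstance(gp, float) and math.isnan(gp)):
            gp = None
        else:
            gp = float(gp)
        rows.append(AnnotationRow(
            structure_id=str(rec["structure_id"]),
            receptor=str(rec["receptor"]),
            gpcr_class=str(rec["gpcr_class"]),
            state_annotation=str(rec["state_annotation"]),
            resolution=float(rec["resolution"]),
            receptor_completeness=float(rec["receptor_completeness"]),
            seq_identity_human=float(rec["seq_identity_human"]),
            degree_active=float(rec["degree_active"]),
            ligand_modality=str(rec["ligand_modality"]),
            has_gprotein_complex=_parse_bool(rec["has_gprotein_complex"]),
            gprotein_completeness=gp,
            release_date=str(rec.get("release_date", "") or ""),
            parent_id=str(rec.get("parent_id", "") or "")
            if not (isinstance(rec.get("parent_id"), float)
                    and math.isnan(rec.get("parent_id"))) else "",
        ))
    return rows


def write_annotation(path, rows) -> None:
    recs = []
    for r in rows:
        d = {k: getattr(r, k) for k in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
        if d["gprotein_completeness"] is None:
            d["gprotein_completeness"] = ""
        recs.append(d)
    pd.DataFrame(recs, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS).to_csv(
        path, sep="\t", index=False)


def select_representatives(rows,
                           criteria: SelectionCriteria | None = None
                           ) -> TemplateCatalog:
    """Pick one representative per (receptor, state) among passing rows.

    Tie-break between passing candidates: best (lowest) resolution, then
    highest receptor completeness, then lexicographic structure id.
    """
    if not rows:
        raise ValueError("annotation catalog is empty")
    criteria = criteria or SelectionCriteria()
    candidates: dict = {}
    for row in rows:
        for state, ok in (("inactive", criteria.passes_inactive(row)),
                          ("active", criteria.passes_active(row))):
            if ok:
                candidates.setdefault((row.receptor, state), []).append(row)
    representatives = {}
    for key, cand in candidates.items():
        best = min(cand, key=lambda r: (r.resolution,
                                        -r.receptor_completeness,
                                        r.structure_id))
        representatives[key] = best.structure_id
    return TemplateCatalog(rows=list(rows), representatives=representatives,
                           criteria=criteria)


def count_selection(catalog: TemplateCatalog,
                    resolution_bins=(2.0, 2.5, 3.0, 3.5, 4.0)) -> dict:
    """Integer bookkeeping of the selection.

    Representative entries are per (receptor, state); artificial
    per-monomer entries split from one heterodimer deposition share a
    parent id, so entry counts and distinct-structure counts can differ.
    Both are reported rather than reconciled.
    """
    rep_rows = catalog.representative_rows()
    inact = {k: v for k, v in rep_rows.items() if k[1] == "inactive"}
    act = {k: v for k, v in rep_rows.items() if k[1] == "active"}
    inact_parents = {r.parent_id for r in inact.values()}
    act_parents = {r.parent_id for r in act.values()}
    all_parents = inact_parents | act_parents

    per_class = {}
    for cls in CLASSES:
        members = {r.receptor for r in catalog.rows if r.gpcr_class == cls}
        ni = sum(1 for r in inact.values() if r.gpcr_class == cls)
        na = sum(1 for r in act.values() if r.gpcr_class == cls)
        per_class[cls] = {"receptors_in_catalog": len(members),
                          "n_inactive": ni, "n_active": na}

    res_by_parent = {}
    for r in rep_rows.values():
        res_by_parent[r.parent_id] = r.resolution
    edges = list(resolution_bins)
    hist = {f"<={edges[0]:.1f}": 0}
    for lo, hi in zip(edges, edges[1:]):
        hist[f"{lo:.1f}-{hi:.1f}"] = 0
    hist[f">{edges[-1]:.1f}"] = 0
    for res in res_by_parent.values():
        if res <= edges[0]:
            hist[f"<={edges[0]:.1f}"] += 1
        elif res > edges[-1]:
            hist[f">{edges[-1]:.1f}"] += 1
        else:
            for lo, hi in zip(edges, edges[1:]):
                if lo < res <= hi:
                    hist[f"{lo:.1f}-{hi:.1f}"] += 1
                    break

    return {
        "n_inactive": len(inact),
        "n_active_entries": len(act),
        "n_active": len(act_parents),
        "n_inactive_structures": len(inact_parents),
        "n_pairs": len(catalog.receptors_with_both_states()),
        "n_template_entries": len(rep_rows),
        "n_template_structures": len(all_parents),
        "n_templates_le_3A": sum(1 for res in res_by_parent.values()
                                 if res <= 3.0),
        "per_class": per_class,
        "resolution_histogram": hist,
    }


def tm6_opening_proxy(structure) -> float | None:
    """Calpha distance (A) between positions 2x46 and 6x37.

    A crude, non-canonical proxy for the intracellular TM6 opening; the
    catalog's degree-active column comes from an external method and is
    never recomputed from this number.
    """
    from .structure_model import GenericPosition
    by_gen = structure.by_generic()
    a = by_gen.get(GenericPosition(2, 46))
    b = by_gen.get(GenericPosition(6, 37))
    if a is None or b is None or a.ca is None or b.ca is None:
        return None
    return float(np.linalg.norm(a.ca - b.ca))
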