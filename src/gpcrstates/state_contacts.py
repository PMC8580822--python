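"""State-specific contact frequencies, conservation filtering and
determinant classification.

For every generic residue pair observed in a class's representative
ensembles, the contact frequency in the inactive and the active set is the
percentage of templates forming the contact among templates in which both
positions are resolved (so unmodelled loops do not deflate frequencies;
an all-templates denominator is available as an option).  Pairs whose
inactive-active frequency difference reaches the class threshold are
state-specific: "inactivating" when more frequent in the inactive state,
"activating" otherwise.  A sequence-conservation cut-off then requires the
amino-acid pairs observed to form the contact to be present in at least a
minimum fraction of the class's receptors.  Positions are finally
classified as inactivators (only inactivating contacts), activators (only
activating) or switches (both).

All threshold comparisons are done on exact rational counts; the reported
percentage is a rounded view only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import pandas as pd

from .structure_model import GenericPosition

__all__ = [
    "PairFrequencyRecord",
    "ClassThresholds",
    "DeterminantMap",
    "SegmentNetwork",
    "compute_pair_frequencies",
    "filter_state_specific",
    "conservation_filter",
    "classify_positions",
    "cross_class_overlap",
    "aggregate_segment_network",
]

#: class frequency-difference thresholds (percentage points), adjusted to
#: the structural coverage of each class, and the conservation minimum
DEFAULT_CLASS_THRESHOLDS = {"A": 40.0, "B1": 67.0, "C": 75.0, "F": 100.0}
DEFAULT_CONSERVATION_MIN = 0.30

ROLE_INACTIVATOR = "inactivator"
ROLE_ACTIVATOR = "activator"
ROLE_SWITCH = "switch"


@dataclass(frozen=True)
class ClassThresholds:
    by_class: tuple = tuple(sorted(DEFAULT_CLASS_THRESHOLDS.items()))
    conservation_min: float = DEFAULT_CONSERVATION_MIN

    def threshold(self, gpcr_class: str) -> float:
        d = dict(self.by_class)
        if gpcr_class not in d:
            raise KeyError(f"no frequency-difference threshold configured "
                           f"for class {gpcr_class!r}")
        t = d[gpcr_class]
        if not 0 < t <= 100:
            raise ValueError(f"threshold {t} outside (0, 100]")
        return t

    @classmethod
    def from_dict(cls, mapping: dict, conservation_min: float = DEFAULT_CONSERVATION_MIN):
        return cls(tuple(sorted(mapping.items())), conservation_min)


@dataclass
class PairFrequencyRecord:
    gpcr_class: str
    pair: tuple                      # (GenericPosition, GenericPosition)
    k_inactive: int                  # templates forming the contact
    n_inactive_obs: int              # templates with both positions resolved
    k_active: int
    n_active_obs: int
    observed_aa_pairs: frozenset = frozenset()
    label: str | None = None         # "inactivating" / "activating"
    conservation_fraction: float | None = None

    @property
    def freq_inactive_exact(self) -> Fraction:
        if self.n_inactive_obs == 0:
            return Fraction(0)
        return Fraction(100 * self.k_inactive, self.n_inactive_obs)

    @property
    def freq_active_exact(self) -> Fraction:
        if self.n_active_obs == 0:
            return Fraction(0)
        return Fraction(100 * self.k_active, self.n_active_obs)

    @property
    def diff_exact(self) -> Fraction:
        return self.freq_inactive_exact - self.freq_active_exact

    @property
    def freq_inactive(self) -> float:
        return float(self.freq_inactive_exact)

    @property
    def freq_active(self) -> float:
        return float(self.freq_active_exact)

    @property
    def diff(self) -> float:
        return float(self.diff_exact)


def compute_pair_frequencies(contact_sets_inactive, contact_sets_active,
                             gpcr_class: str,
                             denominator: str = "resolved") -> list:
    """Per-pair inactive/active contact frequencies for one class.

    ``denominator`` is ``"resolved"`` (templates where both positions are
    resolved; default) or ``"all"`` (every template of the state).  Pairs
    formed in neither state are omitted by construction.
    """
    if not contact_sets_inactive or not contact_sets_active:
        raise ValueError("need at least one template per state to define "
                         "contact frequencies")
    if denominator not in ("resolved", "all"):
        raise ValueError(f"unknown denominator mode {denominator!r}")

    pairs = set()
    aa_pairs: dict = {}
    for cs in list(contact_sets_inactive) + list(contact_sets_active):
        for c in cs.contacts:
            pairs.add(c.pair)
            aa_pairs.setdefault(c.pair, set()).add(c.aa_pair)

    records = []
    for pair in sorted(pairs):
        counts = {}
        for state, sets in (("inactive", contact_sets_inactive),
                            ("active", contact_sets_active)):
            k = n = 0
            for cs in sets:
                resolved = (pair[0] in cs.positions_resolved
                            and pair[1] in cs.positions_resolved)
                if denominator == "all" or resolved:
                    n += 1
                if pair in cs.pair_dict():
                    k += 1
            counts[state] = (k, n)
        records.append(PairFrequencyRecord(
            gpcr_class=gpcr_class, pair=pair,
            k_inactive=counts["inactive"][0],
            n_inactive_obs=counts["inactive"][1],
            k_active=counts["active"][0],
            n_active_obs=counts["active"][1],
            observed_aa_pairs=frozenset(aa_pairs[pair])))
    return records


def filter_state_specific(records, thresholds: ClassThresholds | None = None):
    """Keep pairs with |frequency difference| >= the class threshold and
    label them; sorted by |difference| descending, then canonical pair."""
    thresholds = thresholds or ClassThresholds()
    classes = {r.gpcr_class for r in records}
    if len(classes) > 1:
        raise ValueError(f"records span multiple classes: {sorted(classes)}")
    out = []
    for r in records:
        t = Fraction(str(thresholds.threshold(r.gpcr_class)))
        d = r.diff_exact
        if abs(d) >= t:
            label = "inactivating" if d > 0 else "activating"
            out.append(replace(r, label=label))
    out.sort(key=lambda r: (-abs(r.diff_exact), r.pair))
    return out


def _match_fraction(record, alignment: pd.DataFrame) -> Fraction:
    pa, pb = str(record.pair[0]), str(record.pair[1])
    n = len(alignment.index)
    if n == 0:
        raise ValueError("class alignment is empty")
    matches = 0
    cols = alignment.columns
    for _, row in alignment.iterrows():
        aa_a = row[pa] if pa in cols else "-"
        aa_b = row[pb] if pb in cols else "-"
        if (aa_a, aa_b) in record.observed_aa_pairs:
            matches += 1
    return Fraction(matches, n)


def conservation_filter(records, alignment: pd.DataFrame,
                        min_fraction: float = DEFAULT_CONSERVATION_MIN):
    """Keep records whose observed amino-acid pair is present in at least
    ``min_fraction`` of the class's receptors (boundary inclusive).

    ``alignment`` is receptors x generic-position columns holding
    one-letter codes ('-' or missing column counts as non-matching).
    """
    if alignment is None or alignment.empty:
        raise ValueError("class alignment is empty")
    cut = Fraction(str(min_fraction))
    out = []
    for r in records:
        frac = _match_fraction(r, alignment)
        if frac >= cut:
            out.append(replace(r, conservation_fraction=float(frac)))
    return out


@dataclass
class DeterminantPosition:
    position: GenericPosition
    role: str
    contacts: list
    consensus_aa: str = "X"
    consensus_conservation: float | None = None

    @property
    def segment(self) -> str:
        return self.position.segment


@dataclass
class DeterminantMap:
    gpcr_class: str
    positions: list

    def by_position(self) -> dict:
        return {p.position: p for p in self.positions}

    def roles(self) -> dict:
        return {p.position: p.role for p in self.positions}

    def count_by_role(self) -> dict:
        out = {ROLE_INACTIVATOR: 0, ROLE_ACTIVATOR: 0, ROLE_SWITCH: 0}
        for p in self.positions:
            out[p.role] += 1
        return out


def classify_positions(state_specific_records,
                       alignment: pd.DataFrame | None = None) -> DeterminantMap:
    """Partition determinant positions into inactivators, activators and
    switches from their already filtered state-specific contacts."""
    classes = {r.gpcr_class for r in state_specific_records}
    gpcr_class = classes.pop() if len(classes) == 1 else ""
    by_pos: dict = {}
    for r in state_specific_records:
        if r.label is None:
            raise ValueError("records must be labelled by filter_state_specific")
        for pos in r.pair:
            by_pos.setdefault(pos, []).append(r)
    positions = []
    for pos in sorted(by_pos):
        labels = {r.label for r in by_pos[pos]}
        if labels == {"inactivating"}:
            role = ROLE_INACTIVATOR
        elif labels == {"activating"}:
            role = ROLE_ACTIVATOR
        else:
            role = ROLE_SWITCH
        consensus, cons_frac = "X", None
        if alignment is not None and str(pos) in alignment.columns:
            col = alignment[str(pos)]
            col = col[col != "-"]
            if len(col):
                counts = col.value_counts()
                consensus = sorted(counts[counts == counts.max()].index)[0]
                cons_frac = float(counts.max() / len(alignment.index))
        positions.append(DeterminantPosition(
            position=pos, role=role, contacts=sorted(
                by_pos[pos], key=lambda r: (-abs(r.diff_exact), r.pair)),
            consensus_aa=consensus, consensus_conservation=cons_frac))
    return DeterminantMap(gpcr_class=gpcr_class, positions=positions)


def cross_class_overlap(maps) -> dict:
    """Venn-style sharing of determinant positions across class maps."""
    if len(maps) < 2:
        raise ValueError("need at least two class maps")
    membership: dict = {}
    roles: dict = {}
    for m in maps:
        for p in m.positions:
            membership.setdefault(p.position, set()).add(m.gpcr_class)
            roles.setdefault(p.position, {})[m.gpcr_class] = p.role
    shared_by = {k: 0 for k in range(1, len(maps) + 1)}
    for classes in membership.values():
        shared_by[len(classes)] += 1
    role_sharing = {ROLE_INACTIVATOR: 0, ROLE_ACTIVATOR: 0, ROLE_SWITCH: 0}
    for pos, by_class in roles.items():
        if len(by_class) < 2:
            continue
        role_values = set(by_class.values())
        if len(role_values) == 1:
            role_sharing[role_values.pop()] += 1
    return {
        "n_positions": len(membership),
        "shared_by": shared_by,
        "same_role_shared": role_sharing,
        "positions_by_share": {
            k: sorted(str(p) for p, c in membership.items() if len(c) == k)
            for k in shared_by
        },
    }


@dataclass
class SegmentNetwork:
    gpcr_class: str
    #: (segment_a, segment_b) -> {"n_inactivating": int, "n_activating": int}
    edges: dict
    segment_switch: dict
    inactivating_fraction: float
    inactivating_fraction_intersegment: float


def aggregate_segment_network(state_specific_records) -> SegmentNetwork:
    """Aggregate labelled pairs into a segment-level contact network."""
    classes = {r.gpcr_class for r in state_specific_records}
    gpcr_class = classes.pop() if len(classes) == 1 else ""
    edges: dict = {}
    seg_labels: dict = {}
    n_inact = n_act = n_inact_inter = n_act_inter = 0
    for r in state_specific_records:
        seg_a, seg_b = r.pair[0].segment, r.pair[1].segment
        key = tuple(sorted((seg_a, seg_b)))
        e = edges.setdefault(key, {"n_inactivating": 0, "n_activating": 0})
        slot = "n_inactivating" if r.label == "inactivating" else "n_activating"
        e[slot] += 1
        if r.label == "inactivating":
            n_inact += 1
            n_inact_inter += seg_a != seg_b
        else:
            n_act += 1
            n_act_inter += seg_a != seg_b
        for seg in key:
            seg_labels.setdefault(seg, set()).add(r.label)
    total = n_inact + n_act
    total_inter = n_inact_inter + n_act_inter
    return SegmentNetwork(
        gpcr_class=gpcr_class,
        edges=edges,
        segment_switch={seg: labels == {"inactivating", "activating"}
                        for seg, labels in sorted(seg_labels.items())},
        inactivating_fraction=(100.0 * n_inact / total) if total else 0.0,
        inactivating_fraction_intersegment=(
            100.0 * n_inact_inter / total_inter) if total_inter else 0.0,
    )


def intersegment_edge_count(network: SegmentNetwork, segment: str) -> int:
    """Number of state-specific contacts a segment makes to other segments."""
    n = 0
    for (a, b), e in network.edges.items():
        if a == b:
            continue
        if segment in (a, b):
            n += e["n_inactivating"] + e["n_activating"]
    return n


def records_to_frame(records) -> pd.DataFrame:
    rows = [{
        "gpcr_class": r.gpcr_class,
        "pos_a": str(r.pair[0]), "pos_b": str(r.pair[1]),
        "freq_inactive": round(r.freq_inactive, 1),
        "freq_active": round(r.freq_active, 1),
        "diff": round(r.diff, 1),
        "n_inactive_obs": r.n_inactive_obs, "n_active_obs": r.n_active_obs,
        "label": r.label or "",
        "conservation_fraction": (round(r.conservation_fraction, 3)
                                  if r.conservation_fraction is not None else ""),
        "observed_aa_pairs": ";".join(
            f"{a}{b}" for a, b in sorted(r.observed_aa_pairs)),
    } for r in records]
    return pd.DataFrame(rows)


def determinants_to_frame(det_map: DeterminantMap) -> pd.DataFrame:
    rows = [{
        "gpcr_class": det_map.gpcr_class,
        "position": str(p.position),
        "segment": p.segment,
        "role": p.role,
        "consensus_aa": p.consensus_aa,
        "consensus_conservation": (round(p.consensus_conservation, 3)
                                   if p.consensus_conservation is not None
                                   else ""),
        "n_contacts": len(p.contacts),
    } for p in det_map.positions]
    return pd.DataFrame(rows)
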