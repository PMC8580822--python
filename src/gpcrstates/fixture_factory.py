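"""Synthetic inputs for every pipeline stage.

This module generates the five kinds of study inputs as idealized,
fully-controlled stand-ins for experimental data:

* ideal seven-helix bundles (1.5 A rise, 100 deg twist per residue,
  backbone + Cbeta, full idealized side chains where a typed contact is
  required) with generic numbering and optional imposed inter-state
  rigid motions per helix region (ground truth recorded);
* template contact ensembles with programmed per-pair inactive/active
  contact frequencies and per-position resolution dropout, realized by
  deterministic counting so recovered frequencies are exact;
* class sequence alignments with programmed per-position amino-acid
  composition;
* an annotation catalog emulating a published structure-annotation table
  (synthetic: identifiers and quality values are constructed, with rows
  straddling every selection-filter boundary);
* a two-group mutant signalling table emulating a published mutant
  potency/efficacy table (synthetic: replicate values are constructed
  around programmed group means and rank configurations).

Everything is deterministic under the supplied seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from .contact_engine import Contact, ContactSet
from .structure_model import (
    AnnotatedStructure, AtomRecord, GenericPosition, LigandGroup,
    ResidueRecord, one_to_three,
)
from .template_catalog import AnnotationRow
from .mutation_stats import MutantRecord

__all__ = [
    "BundleSpec",
    "MotionSpec",
    "EnsembleSpec",
    "make_ideal_bundle",
    "apply_motion",
    "motion_with_measured_translation",
    "add_coordinate_noise",
    "make_contact_ensemble",
    "make_alignment",
    "make_annotation_catalog",
    "make_mutant_table",
    "make_contact_pair",
    "random_structure",
    "ligand_near_position",
    "decoy_galpha",
    "write_structure_cif",
    "write_mutant_table",
    "bundle_mapping",
]

RISE = 1.5          # A per residue along the helix axis
TWIST = 100.0       # deg per residue
CA_RADIUS = 2.3     # A, Calpha distance from the helix axis

# idealized side-chain templates: atom -> (element, along, perp1, perp2)
# offsets (A) in the local frame (d = outward from helix axis, p, q).
# Crude but deterministic geometry; bonded neighbours sit 1.3-1.6 A apart.
SIDE_CHAINS = {
    "A": [("CB", "C", 1.53, 0.0, 0.0)],
    "G": [],
    "S": [("CB", "C", 1.5, 0.0, 0.0), ("OG", "O", 2.7, 0.5, 0.0)],
    "T": [("CB", "C", 1.5, 0.0, 0.0), ("OG1", "O", 2.7, 0.5, 0.0),
          ("CG2", "C", 2.5, -0.9, 0.6)],
    "C": [("CB", "C", 1.5, 0.0, 0.0), ("SG", "S", 3.0, 0.4, 0.0)],
    "V": [("CB", "C", 1.5, 0.0, 0.0), ("CG1", "C", 2.6, 0.8, 0.3),
          ("CG2", "C", 2.6, -0.9, 0.3)],
    "L": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.8, 0.3, 0.0),
          ("CD1", "C", 3.6, 1.2, 0.3), ("CD2", "C", 3.6, -1.0, 0.4)],
    "I": [("CB", "C", 1.5, 0.0, 0.0), ("CG1", "C", 2.7, 0.6, 0.0),
          ("CG2", "C", 2.4, -1.0, 0.5), ("CD1", "C", 4.0, 0.6, 0.2)],
    "M": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.8, 0.4, 0.0),
          ("SD", "S", 4.2, 0.0, 0.3), ("CE", "C", 5.5, 0.5, 0.0)],
    "P": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.3, 1.0, 0.4),
          ("CD", "C", 1.6, 1.9, 0.2)],
    "D": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.9, 0.3, 0.0),
          ("OD1", "O", 3.6, 1.3, 0.0), ("OD2", "O", 3.6, -0.8, 0.3)],
    "N": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.9, 0.3, 0.0),
          ("OD1", "O", 3.6, 1.3, 0.0), ("ND2", "N", 3.6, -0.8, 0.3)],
    "E": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.8, 0.4, 0.0),
          ("CD", "C", 4.1, 0.0, 0.0), ("OE1", "O", 4.8, 1.1, 0.0),
          ("OE2", "O", 4.8, -1.0, 0.2)],
    "Q": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.8, 0.4, 0.0),
          ("CD", "C", 4.1, 0.0, 0.0), ("OE1", "O", 4.8, 1.1, 0.0),
          ("NE2", "N", 4.8, -1.0, 0.2)],
    "K": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.8, 0.4, 0.0),
          ("CD", "C", 4.1, 0.0, 0.3), ("CE", "C", 5.4, 0.4, 0.0),
          ("NZ", "N", 6.6, 0.0, 0.0)],
    "R": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.8, 0.4, 0.0),
          ("CD", "C", 4.1, 0.0, 0.3), ("NE", "N", 5.4, 0.3, 0.0),
          ("CZ", "C", 6.7, 0.0, 0.0), ("NH1", "N", 7.4, 1.1, 0.0),
          ("NH2", "N", 7.4, -1.1, 0.0)],
    "H": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.9, 0.0, 0.0),
          ("ND1", "N", 3.6, 1.2, 0.0), ("CD2", "C", 3.7, -1.1, 0.0),
          ("CE1", "C", 4.9, 0.9, 0.0), ("NE2", "N", 5.0, -0.5, 0.0)],
    "F": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.9, 0.0, 0.0),
          ("CD1", "C", 3.6, 1.2, 0.0), ("CD2", "C", 3.6, -1.2, 0.0),
          ("CE1", "C", 5.0, 1.2, 0.0), ("CE2", "C", 5.0, -1.2, 0.0),
          ("CZ", "C", 5.7, 0.0, 0.0)],
    "Y": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.9, 0.0, 0.0),
          ("CD1", "C", 3.6, 1.2, 0.0), ("CD2", "C", 3.6, -1.2, 0.0),
          ("CE1", "C", 5.0, 1.2, 0.0), ("CE2", "C", 5.0, -1.2, 0.0),
          ("CZ", "C", 5.7, 0.0, 0.0), ("OH", "O", 7.1, 0.0, 0.0)],
    "W": [("CB", "C", 1.5, 0.0, 0.0), ("CG", "C", 2.9, 0.0, 0.0),
          ("CD1", "C", 3.5, 1.2, 0.0), ("NE1", "N", 4.8, 1.4, 0.0),
          ("CD2", "C", 4.0, -0.8, 0.0), ("CE2", "C", 5.1, 0.4, 0.0),
          ("CE3", "C", 4.3, -2.1, 0.0), ("CZ2", "C", 6.4, 0.1, 0.0),
          ("CZ3", "C", 5.6, -2.4, 0.0), ("CH2", "C", 6.6, -1.3, 0.0)],
}


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _perp_basis(u):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ u) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = _unit(np.cross(u, ref))
    q = np.cross(u, p)
    return p, q


def _build_residue(aa: str, chain: str, seqnum: int, ca: np.ndarray,
                   d: np.ndarray, axis: np.ndarray,
                   prev_ca=None, next_ca=None, full_sidechain=True) -> ResidueRecord:
    """Residue with approximate backbone and an idealized side chain
    pointing along the outward direction d."""
    d = _unit(d)
    p = _unit(np.cross(axis, d))
    q = np.cross(d, p)
    atoms = []
    if prev_ca is None and next_ca is None:
        un = q
    else:
        ref = prev_ca if prev_ca is not None else 2 * ca - next_ca
        un = _unit(ref - ca)
    atoms.append(AtomRecord("N", "N", tuple(ca + 1.46 * un)))
    atoms.append(AtomRecord("CA", "C", tuple(ca)))
    nxt = next_ca if next_ca is not None else (2 * ca - prev_ca
                                               if prev_ca is not None
                                               else ca + 3.8 * q)
    uc = _unit(nxt - ca)
    c_pos = ca + 1.52 * uc
    atoms.append(AtomRecord("C", "C", tuple(c_pos)))
    atoms.append(AtomRecord("O", "O", tuple(c_pos + 1.23 * d)))
    template = SIDE_CHAINS.get(aa, SIDE_CHAINS["A"])
    if not full_sidechain and aa not in ("G",):
        template = template[:1]
    for name, element, a_, p_, q_ in template:
        atoms.append(AtomRecord(name, element,
                                tuple(ca + a_ * d + p_ * p + q_ * q)))
    return ResidueRecord(chain=chain, seqnum=seqnum, aa=aa, atoms=atoms)


@dataclass(frozen=True)
class BundleSpec:
    n_helices: int = 7
    residues_per_helix: int = 25
    bundle_radius: float = 11.0
    include_h8: bool = False
    #: generic-position string -> one-letter aa substitution (built with a
    #: full idealized side chain)
    substitutions: tuple = ()
    default_aa: str = "A"
    chain: str = "A"
    structure_id: str = "BNDL"
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_helices <= 7:
            raise ValueError("n_helices must be in 1..7")
        if self.residues_per_helix < 9:
            raise ValueError("helices need at least 9 residues")
        if self.bundle_radius < 2 * CA_RADIUS + 1.0:
            raise ValueError("bundle radius too small: helices overlap")

    @property
    def substitution_map(self) -> dict:
        return {GenericPosition.parse(k): v for k, v in self.substitutions}


def make_ideal_bundle(spec: BundleSpec | None = None) -> AnnotatedStructure:
    """Idealized transmembrane bundle with generic numbers attached.

    Helix k (1-based) sits on a ring at angle 2 pi (k-1) / n; odd helices
    run extracellular (+z) to intracellular, even helices the opposite, so
    the chain alternates direction as in the native fold.  The central
    residue of each helix carries generic offset 50 and lies at z = 0
    (the membrane mid-plane).
    """
    spec = spec or BundleSpec()
    n = spec.residues_per_helix
    centre_idx = (n - 1) // 2
    subs = spec.substitution_map
    residues = []
    helix_meta = {}
    helices = list(range(1, spec.n_helices + 1))
    for k in helices:
        theta = 2 * math.pi * (k - 1) / max(spec.n_helices, 1)
        base = np.array([spec.bundle_radius * math.cos(theta),
                         spec.bundle_radius * math.sin(theta), 0.0])
        u = np.array([0.0, 0.0, -1.0 if k % 2 == 1 else 1.0])
        p, q = _perp_basis(u)
        cas, ds = [], []
        for i in range(n):
            z = (i - centre_idx) * RISE
            ang = math.radians(TWIST * i)
            radial = math.cos(ang) * p + math.sin(ang) * q
            cas.append(base + u * z + CA_RADIUS * radial)
            ds.append(radial)
        for i in range(n):
            offset = 50 + (i - centre_idx)
            gen = GenericPosition(k, offset)
            aa = subs.get(gen, spec.default_aa)
            res = _build_residue(
                aa, spec.chain, 100 * k + i, cas[i], ds[i], u,
                prev_ca=cas[i - 1] if i > 0 else None,
                next_ca=cas[i + 1] if i < n - 1 else None,
                full_sidechain=gen in subs)
            res = replace(res, generic=gen, segment=gen.segment)
            residues.append(res)
        helix_meta[f"TM{k}"] = {"base": base.tolist(), "axis": u.tolist(),
                                "centre_idx": centre_idx}
    if spec.include_h8:
        # short intracellular helix running outward along +x below TM7
        base = np.array([spec.bundle_radius + 4.0, 0.0,
                         -(centre_idx * RISE + 4.0)])
        u = np.array([1.0, 0.0, 0.0])
        p, q = _perp_basis(u)
        cas = []
        for i in range(8):
            ang = math.radians(TWIST * i)
            radial = math.cos(ang) * p + math.sin(ang) * q
            cas.append(base + u * (i * RISE) + CA_RADIUS * radial)
        for i in range(8):
            gen = GenericPosition(8, 47 + i)
            res = _build_residue(spec.default_aa, spec.chain, 800 + i,
                                 cas[i], _unit(cas[i] - base - u * (i * RISE)),
                                 u,
                                 prev_ca=cas[i - 1] if i > 0 else None,
                                 next_ca=cas[i + 1] if i < 7 else None,
                                 full_sidechain=False)
            residues.append(replace(res, generic=gen, segment=gen.segment))
        helix_meta["H8"] = {"base": base.tolist(), "axis": u.tolist(),
                            "centre_idx": 0}
    return AnnotatedStructure(
        structure_id=spec.structure_id, residues=residues,
        metadata={"bundle_spec": spec, "helices": helix_meta})


@dataclass(frozen=True)
class MotionSpec:
    """Imposed inter-state motion per helix region.

    ``moves`` maps a TM label to region entries
    ``{"ec_end"|"mid"|"ic_end": {"translation": (x, y, z),
    "rotation_deg": angle}}``.  The terminal ``end_window`` residues of a
    helix move rigidly with their end's values (rotation about the helix
    axis, oriented extracellularly so signs match the measurement
    convention, applied first; then translation); residues between zones
    are linearly interpolated.  The end zone is longer than the
    measurement window so local axis fits stay inside rigid material, and
    the mid value is held throughout the +-6.5 A mid-membrane plateau so
    the superposition core stays clean.
    """

    moves: tuple = ()
    end_window: int = 8
    mid_hold: float = 6.5

    @classmethod
    def single(cls, tm: str, region: str, translation=(0, 0, 0),
               rotation_deg: float = 0.0) -> "MotionSpec":
        return cls(moves=((tm, region, tuple(translation),
                           float(rotation_deg)),))

    @classmethod
    def build(cls, spec_dict: dict) -> "MotionSpec":
        moves = []
        for tm, regions in spec_dict.items():
            for region, m in regions.items():
                moves.append((tm, region, tuple(m.get("translation", (0, 0, 0))),
                              float(m.get("rotation_deg", 0.0))))
        return cls(moves=tuple(moves))

    def per_helix(self) -> dict:
        out: dict = {}
        for tm, region, trans, rot in self.moves:
            out.setdefault(tm, {})[region] = (np.asarray(trans, float),
                                              float(rot))
        return out


def _rotate_about_axis(x, point, axis, angle_deg):
    axis = _unit(axis)
    ang = math.radians(angle_deg)
    v = x - point
    return (point + v * math.cos(ang)
            + np.cross(axis, v) * math.sin(ang)
            + axis * (axis @ v) * (1 - math.cos(ang)))


def apply_motion(s: AnnotatedStructure, motion: MotionSpec) -> AnnotatedStructure:
    """Active-state copy of a bundle with the programmed motions applied.

    Ground truth is recorded in ``metadata["ground_truth_motion"]``.
    """
    meta = s.metadata.get("helices")
    if meta is None:
        raise ValueError("structure lacks bundle helix metadata")
    per_helix = motion.per_helix()
    for tm in per_helix:
        if tm not in meta:
            raise ValueError(f"helix {tm!r} not present in bundle")

    new_residues = []
    for r in s.residues:
        tm = r.segment
        if tm not in per_helix or r.generic is None:
            new_residues.append(r)
            continue
        hm = meta[tm]
        base = np.asarray(hm["base"])
        axis = np.asarray(hm["axis"])
        if axis[2] < 0:                      # rotate about the EC-oriented axis
            axis = -axis
        regions = per_helix[tm]
        span = [x for x in s.residues if x.segment == tm]
        span.sort(key=lambda x: x.generic.offset)
        n = len(span)
        idx = next(i for i, x in enumerate(span) if x.generic == r.generic)
        z_signed = (idx - hm["centre_idx"]) * RISE      # along chain direction
        # which terminus is which: z along the membrane normal
        ca_first, ca_last = span[0].ca, span[-1].ca
        first_is_ec = ca_first[2] > ca_last[2]
        w = motion.end_window

        def region_of_index(i):
            if i < w:
                return "ec_end" if first_is_ec else "ic_end"
            if i >= n - w:
                return "ic_end" if first_is_ec else "ec_end"
            return None

        def value_for(region):
            if region in regions:
                return regions[region]
            return (np.zeros(3), 0.0)

        end_region = region_of_index(idx)
        if end_region is not None:
            trans, rot = value_for(end_region)
        elif abs(z_signed) <= motion.mid_hold:
            trans, rot = value_for("mid")
        else:
            # ramp between the mid plateau and the nearer end window
            if z_signed > 0:
                side_region = region_of_index(n - 1)
                z_edge = ((n - w) - hm["centre_idx"]) * RISE
            else:
                side_region = region_of_index(0)
                z_edge = (hm["centre_idx"] - (w - 1)) * RISE
            frac = ((abs(z_signed) - motion.mid_hold)
                    / max(abs(z_edge) - motion.mid_hold, 1e-9))
            frac = min(max(frac, 0.0), 1.0)
            trans_mid, rot_mid = value_for("mid")
            trans_end, rot_end = value_for(side_region)
            trans = (1 - frac) * trans_mid + frac * trans_end
            rot = (1 - frac) * rot_mid + frac * rot_end
        moved = []
        for a in r.atoms:
            x = _rotate_about_axis(a.pos, base, axis, rot) + trans
            moved.append(replace(a, xyz=tuple(x)))
        new_residues.append(replace(r, atoms=moved))
    out = replace(s, residues=new_residues, metadata=dict(s.metadata))
    out.metadata["ground_truth_motion"] = {
        tm: {region: {"translation_A": float(np.linalg.norm(v[0])),
                      "rotation_deg": v[1]}
             for region, v in regions.items()}
        for tm, regions in per_helix.items()}
    return out


def motion_with_measured_translation(s: AnnotatedStructure, tm: str,
                                     region: str, translation_A: float,
                                     rotation_deg: float = 0.0,
                                     direction=(1.0, 0.0, 0.0),
                                     measure_window: int = 4) -> MotionSpec:
    """Motion whose measured region translation equals ``translation_A``.

    A rotation about the helix axis also displaces the region's Calpha
    centroid; the returned translation vector compensates for that shift
    so the downstream centroid-displacement measurement recovers exactly
    the requested magnitude together with the requested rotation.
    """
    hm = s.metadata["helices"][tm]
    base = np.asarray(hm["base"])
    axis = np.asarray(hm["axis"])
    if axis[2] < 0:
        axis = -axis
    span = [r for r in s.residues if r.segment == tm]
    span.sort(key=lambda r: r.generic.offset)
    if region == "mid":
        window = sorted(span, key=lambda r: abs(r.ca[2]))[:5]
    else:
        first_is_ec = span[0].ca[2] > span[-1].ca[2]
        take_first = (region == "ec_end") == first_is_ec
        window = span[:measure_window] if take_first else span[-measure_window:]
    c = np.mean([r.ca for r in window], axis=0)
    delta = _rotate_about_axis(c, base, axis, rotation_deg) - c
    u = _unit(direction)
    t = translation_A * u - delta
    return MotionSpec.single(tm, region, tuple(t), rotation_deg)


def add_coordinate_noise(s: AnnotatedStructure, sigma: float,
                         seed: int = 0) -> AnnotatedStructure:
    rng = np.random.default_rng(seed)
    new_residues = []
    for r in s.residues:
        atoms = [replace(a, xyz=tuple(a.pos + rng.normal(0, sigma, 3)))
                 for a in r.atoms]
        new_residues.append(replace(r, atoms=atoms))
    return replace(s, residues=new_residues, metadata=dict(s.metadata))


# ---------------------------------------------------------------------------
# contact ensembles with programmed frequencies


@dataclass(frozen=True)
class EnsembleSpec:
    gpcr_class: str
    n_inactive: int
    n_active: int
    #: ((pos_a, pos_b), freq_inactive_pct, freq_active_pct, (aa_a, aa_b))
    pairs: tuple
    #: (pos, state, template_index) entries removed from positions_resolved
    dropout: tuple = ()
    extra_positions: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_inactive < 1 or self.n_active < 1:
            raise ValueError("need at least one template per state")


def _resolved_indices(pos_a, pos_b, state, n, dropout):
    dropped = {idx for (p, s, idx) in dropout
               if s == state and p in (pos_a, pos_b)}
    return [i for i in range(n) if i not in dropped]


def make_contact_ensemble(spec: EnsembleSpec):
    """Inactive/active ContactSet lists with exactly programmed
    frequencies.

    A pair programmed at f% in a state is present in exactly
    ``f/100 * n_resolved`` templates (the first ones among those with both
    endpoints resolved); a non-integer product is a spec error.
    """
    positions = set()
    for (pa, pb), *_ in spec.pairs:
        positions.add(pa)
        positions.add(pb)
    positions |= set(spec.extra_positions)
    positions = {GenericPosition.parse(p) if isinstance(p, str) else p
                 for p in positions}
    pos_str = {str(p): p for p in positions}
    dropout = tuple((str(p), s, i) for (p, s, i) in spec.dropout)

    # per template: which positions are resolved
    def resolved_for(state, idx):
        gone = {p for (p, s, i) in dropout if s == state and i == idx}
        return {pos for key, pos in pos_str.items() if key not in gone}

    assignments = {("inactive", i): [] for i in range(spec.n_inactive)}
    assignments.update({("active", i): [] for i in range(spec.n_active)})
    for (pa, pb), f_inact, f_act, aa_pair in spec.pairs:
        a, b = pos_str[str(pa)], pos_str[str(pb)]
        if not a < b:
            a, b = b, a
        for state, f, n in (("inactive", f_inact, spec.n_inactive),
                            ("active", f_act, spec.n_active)):
            idxs = _resolved_indices(str(a), str(b), state, n, dropout)
            k_exact = f * len(idxs) / 100.0
            k = round(k_exact)
            if abs(k_exact - k) > 1e-9:
                raise ValueError(
                    f"frequency {f}% not realizable over {len(idxs)} "
                    f"resolved {state} templates for pair {a}-{b}")
            for i in idxs[:k]:
                assignments[(state, i)].append(
                    Contact(pos_a=a, pos_b=b, types=frozenset({"vdw"}),
                            min_distance=3.5, atom_pair=("CB", "CB"),
                            aa_a=aa_pair[0], aa_b=aa_pair[1]))
    sets = {"inactive": [], "active": []}
    for state, n in (("inactive", spec.n_inactive), ("active", spec.n_active)):
        for i in range(n):
            sets[state].append(ContactSet(
                structure_id=f"{spec.gpcr_class}-{state[:5]}-{i:02d}",
                contacts=sorted(assignments[(state, i)], key=lambda c: c.pair),
                positions_resolved=resolved_for(state, i)))
    return sets["inactive"], sets["active"]


def make_alignment(receptors, composition: dict) -> pd.DataFrame:
    """Class alignment with programmed per-position composition.

    ``composition`` maps a generic-position string to either a single
    amino acid (fully conserved) or a list of (aa, count) pairs whose
    counts sum to at most len(receptors); remaining receptors get '-'.
    Assignment is deterministic in receptor order.
    """
    data = {}
    for pos, comp in composition.items():
        if isinstance(comp, str):
            col = [comp] * len(receptors)
        else:
            col = []
            for aa, count in comp:
                col.extend([aa] * count)
            if len(col) > len(receptors):
                raise ValueError(f"composition at {pos} exceeds receptor count")
            col.extend(["-"] * (len(receptors) - len(col)))
        data[str(pos)] = col
    return pd.DataFrame(data, index=list(receptors))


# ---------------------------------------------------------------------------
# annotation catalog emulator


def _rows_for_group(gpcr_class, receptors, state, resolutions, start_idx,
                    parent_overrides=None, completeness=96.0):
    modality = "antagonist" if state == "inactive" else "agonist"
    degree = 5.0 if state == "inactive" else 97.0
    rows = []
    parent_overrides = parent_overrides or {}
    for j, (receptor, res) in enumerate(zip(receptors, resolutions)):
        sid = f"{gpcr_class}{state[0].upper()}{start_idx + j:03d}"
        rows.append(AnnotationRow(
            structure_id=sid, receptor=receptor, gpcr_class=gpcr_class,
            state_annotation=state, resolution=round(res, 2),
            receptor_completeness=completeness,
            seq_identity_human=99.0, degree_active=degree,
            ligand_modality=modality,
            has_gprotein_complex=state == "active",
            gprotein_completeness=85.0 if state == "active" else None,
            parent_id=parent_overrides.get(receptor, "")))
    return rows


def _resolutions(n_good, n_fair, lo=1.9, hi_good=3.0, lo_fair=3.05, hi=3.55):
    good = list(np.round(np.linspace(lo, hi_good, max(n_good, 1)), 2))[:n_good]
    fair = list(np.round(np.linspace(lo_fair, hi, max(n_fair, 1)), 2))[:n_fair]
    return good + fair


def make_annotation_catalog(seed: int = 0, n_total: int = 510):
    """Synthetic structure-annotation catalog.

    Identifiers and quality values are constructed (synthetic stand-in for
    a curated annotation table), arranged so the default selection
    criteria yield the per-class representative template counts
    A 33/14, B1 3/10, C 4/2 and F 2/2 (inactive/active), 13 receptors
    with both states, and 45 of the distinct template structures at
    resolution <= 3.0 A.  One heterodimer parent deposition contributes
    two artificial per-monomer active entries.  Filler rows straddle every
    selection boundary.  Row order is shuffled deterministically by seed.
    """
    rows = []

    # --- class A: 38 receptors, 9 with both states
    pairs_a = [f"A_R{i:02d}" for i in range(1, 10)]
    inact_only_a = [f"A_I{i:02d}" for i in range(1, 25)]      # 24 receptors
    act_only_a = [f"A_G{i:02d}" for i in range(1, 6)]         # 5 receptors
    inact_a = pairs_a + inact_only_a                           # 33
    act_a = pairs_a + act_only_a                               # 14
    rows += _rows_for_group("A", inact_a, "inactive",
                            _resolutions(22, 11), 0)
    rows += _rows_for_group("A", act_a, "active",
                            _resolutions(10, 4), 100)

    # --- class B1: 3 inactive, 10 active, 2 receptors with both
    pairs_b = ["B1_GLP1", "B1_CRF1"]
    inact_b = pairs_b + ["B1_PTH1"]
    act_b = pairs_b + [f"B1_A{i:02d}" for i in range(1, 9)]
    rows += _rows_for_group("B1", inact_b, "inactive", _resolutions(2, 1), 0)
    rows += _rows_for_group("B1", act_b, "active", _resolutions(5, 5), 100)

    # --- class C: GABA_B heterodimer handled as per-monomer entries that
    # share one parent deposition for the active state
    inact_c = ["C_GB2", "C_MGLU5", "C_MGLU2", "C_MGLU3"]
    act_c = ["C_GB1", "C_GB2"]
    rows += _rows_for_group("C", inact_c, "inactive", _resolutions(3, 1), 0)
    rows += _rows_for_group("C", act_c, "active", [2.9, 2.9], 100,
                            parent_overrides={"C_GB1": "C_HDIMER_ACT",
                                              "C_GB2": "C_HDIMER_ACT"})
    # the GABA_B1 monomer of the inactive heterodimer misses the
    # completeness cut, so only GABA_B2 has an inactive representative
    rows.append(AnnotationRow(
        structure_id="CI900", receptor="C_GB1", gpcr_class="C",
        state_annotation="inactive", resolution=3.0,
        receptor_completeness=80.0, seq_identity_human=99.0,
        degree_active=5.0, ligand_modality="antagonist",
        has_gprotein_complex=False, parent_id="C_HDIMER_INACT"))

    # --- class F: SMO both states, FZD4 inactive, FZD7 active
    rows += _rows_for_group("F", ["F_SMO", "F_FZD4"], "inactive",
                            _resolutions(1, 1), 0)
    rows += _rows_for_group("F", ["F_SMO", "F_FZD7"], "active",
                            _resolutions(1, 1), 100)

    n_designed = len(rows)

    # --- boundary rows: exactly at, just inside and just outside every
    # criterion boundary; at-boundary passing rows belong to receptors with
    # a better representative so the designed selection is unchanged
    def boundary(sid, receptor, cls, state, **kw):
        base = dict(structure_id=sid, receptor=receptor, gpcr_class=cls,
                    state_annotation=state, resolution=2.5,
                    receptor_completeness=96.0, seq_identity_human=99.0,
                    degree_active=5.0 if state == "inactive" else 97.0,
                    ligand_modality=("antagonist" if state == "inactive"
                                     else "agonist"),
                    has_gprotein_complex=state == "active",
                    gprotein_completeness=85.0 if state == "active" else None)
        base.update(kw)
        return AnnotationRow(**base)

    fillers = [
        boundary("AB001", "A_R01", "A", "inactive", resolution=3.6),
        boundary("AB002", "A_R01", "A", "inactive", resolution=3.61),
        boundary("AB003", "A_R01", "A", "inactive", resolution=3.59),
        boundary("AB004", "A_R02", "A", "inactive",
                 receptor_completeness=83.0, resolution=3.5),
        boundary("AB005", "A_R02", "A", "inactive",
                 receptor_completeness=82.9),
        boundary("AB006", "A_R02", "A", "inactive",
                 receptor_completeness=83.1, resolution=3.5),
        boundary("AB007", "A_R03", "A", "inactive", seq_identity_human=90.0),
        boundary("AB008", "A_R03", "A", "inactive", seq_identity_human=90.1,
                 resolution=3.5),
        boundary("AB009", "A_R03", "A", "inactive", seq_identity_human=89.9),
        boundary("AB010", "A_R04", "A", "inactive", degree_active=20.0,
                 resolution=3.5),
        boundary("AB011", "A_R04", "A", "inactive", degree_active=20.1),
        boundary("AB012", "A_R05", "A", "active", degree_active=90.0,
                 resolution=3.5),
        boundary("AB013", "A_R05", "A", "active", degree_active=89.9),
        boundary("AB014", "A_R06", "A", "active",
                 gprotein_completeness=43.0, resolution=3.5),
        boundary("AB015", "A_R06", "A", "active",
                 gprotein_completeness=42.9),
        boundary("AB016", "A_R07", "A", "active", has_gprotein_complex=False,
                 gprotein_completeness=None),
        boundary("AB017", "A_R07", "A", "inactive",
                 ligand_modality="agonist"),
        boundary("AB018", "A_R08", "A", "active", ligand_modality="apo"),
        boundary("AB019", "A_R08", "A", "intermediate", degree_active=55.0,
                 ligand_modality="agonist"),
        # tie-break exercise: passing duplicate at worse resolution
        boundary("AB020", "A_R09", "A", "inactive", resolution=3.1),
    ]
    rows += fillers

    # --- bulk fillers to the catalog size, all failing one criterion
    per_class_total = {"A": 406, "B1": 60, "C": 30, "F": 14}
    fail_cycle = [
        {"resolution": 4.2},
        {"receptor_completeness": 60.0},
        {"seq_identity_human": 80.0},
        {"state_annotation": "intermediate", "degree_active": 50.0,
         "ligand_modality": "agonist"},
        {"ligand_modality": "apo", "state_annotation": "inactive",
         "degree_active": 10.0},
    ]
    for cls, total in per_class_total.items():
        have = sum(1 for r in rows if r.gpcr_class == cls)
        for i in range(total - have):
            kw = dict(fail_cycle[i % len(fail_cycle)])
            state = kw.pop("state_annotation", "inactive")
            fillers_kw = dict(
                structure_id=f"{cls}X{i:03d}",
                receptor=f"{cls}_F{i % 40:02d}",
                gpcr_class=cls, state_annotation=state,
                resolution=kw.pop("resolution", 2.8),
                receptor_completeness=kw.pop("receptor_completeness", 95.0),
                seq_identity_human=kw.pop("seq_identity_human", 99.0),
                degree_active=kw.pop("degree_active", 10.0),
                ligand_modality=kw.pop("ligand_modality", "antagonist"),
                has_gprotein_complex=False)
            rows.append(AnnotationRow(**fillers_kw))
    assert len(rows) == n_total, (len(rows), n_total)
    order = np.random.default_rng(seed).permutation(len(rows))
    return [rows[i] for i in order]


# ---------------------------------------------------------------------------
# mutant signalling table emulator

# programmed per-mutant potency shifts (dlogEC50 from wild type) and
# efficacy shifts (dEmax).  Group means and rank configurations are the
# study conditions; replicate triplets are symmetric around each value.
_MUTANTS_STATE = ["D2x50A", "N3x35A", "L3x43A", "F6x44A", "N7x49A", "Y7x53A"]
_MUTANTS_NONSTATE = ["V2x48A", "T3x24A", "S4x57A", "A5x53A", "I6x31A",
                     "V7x40A"]
_SHIFTS = {
    "Gs": {
        "state_changing": {"dlog": [0.25, 0.45, 0.62, 0.88, 1.90, 2.32],
                           "demax": [-9.5, -8.1, -3.2, -0.3, 0.8, 3.5]},
        "nonstate_changing": {"dlog": [-0.05, 0.08, 0.08, 0.12, 0.12, 0.97],
                              "demax": [-6.0, -4.4, -2.0, -1.1, 2.1, 5.2]},
        "wt_log_ec50": -7.94, "wt_emax": 100.0,
    },
    "G15": {
        "state_changing": {"dlog": [0.55, 1.00, 1.15, 1.30, 1.50, 2.00],
                           "demax": [-12.0, -9.0, -5.0, -1.0, -0.2, 2.4]},
        "nonstate_changing": {"dlog": [0.02, 0.02, 0.10, 0.18, 0.28, 0.90],
                              "demax": [-7.5, -3.3, -2.2, 1.0, 4.0, 6.1]},
        "wt_log_ec50": -6.62, "wt_emax": 100.0,
    },
}


def make_mutant_table(seed: int = 0, n_replicates: int = 3):
    """Synthetic mutant potency/efficacy table (stand-in for a published
    per-mutant data table): six predicted state-changing and six
    nonstate-changing alanine mutants plus wild type, for two G proteins,
    in replicate.  Group mean potency shifts are 1.07 vs 0.22 (Gs) and
    1.25 vs 0.25 (G15) by construction.
    """
    offsets = np.linspace(-0.05, 0.05, n_replicates)
    offsets -= offsets.mean()
    records = []
    for gprot, cfg in _SHIFTS.items():
        for rep, off in enumerate(offsets, start=1):
            records.append(MutantRecord(
                mutant="WT", group="wt", g_protein=gprot,
                log_ec50=cfg["wt_log_ec50"] + off,
                emax=cfg["wt_emax"] + 10 * off, replicate=rep))
        for group, names in (("state_changing", _MUTANTS_STATE),
                             ("nonstate_changing", _MUTANTS_NONSTATE)):
            shifts = cfg[group]
            for name, dlog, demax in zip(names, shifts["dlog"],
                                         shifts["demax"]):
                for rep, off in enumerate(offsets, start=1):
                    records.append(MutantRecord(
                        mutant=name, group=group, g_protein=gprot,
                        log_ec50=cfg["wt_log_ec50"] + dlog + off,
                        emax=cfg["wt_emax"] + demax + 10 * off,
                        replicate=rep))
    order = np.random.default_rng(seed).permutation(len(records))
    return [records[i] for i in order]


def write_mutant_table(path, records) -> None:
    pd.DataFrame([{
        "mutant": r.mutant, "group": r.group, "g_protein": r.g_protein,
        "log_ec50": round(r.log_ec50, 4), "emax": round(r.emax, 3),
        "replicate": r.replicate} for r in records]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# small geometric fixtures


def make_contact_pair(aa_a: str, aa_b: str, min_sidechain_distance: float,
                      adjacent: bool = False,
                      generics=("3x49", "3x50")) -> AnnotatedStructure:
    """Two residues with side chains facing each other, the closest
    side-chain heavy atoms separated by exactly the requested distance."""
    d = np.array([1.0, 0.0, 0.0])
    axis = np.array([0.0, 0.0, 1.0])
    res_a = _build_residue(aa_a, "A", 10, np.zeros(3), d, axis)
    seq_b = 11 if adjacent else 50

    def min_dist(sep):
        res_b = _build_residue(aa_b, "A", seq_b, np.array([sep, 0.0, 0.0]),
                               -d, axis)
        xa = res_a.coords(sidechain_only=True)
        xb = res_b.coords(sidechain_only=True)
        from scipy.spatial.distance import cdist
        return float(cdist(xa, xb).min())

    lo, hi = 3.0, 60.0
    while min_dist(lo) > min_sidechain_distance:
        lo -= 0.5
        if lo <= 0.1:
            break
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < min_sidechain_distance:
            lo = mid
        else:
            hi = mid
    sep = 0.5 * (lo + hi)
    res_b = _build_residue(aa_b, "A", seq_b, np.array([sep, 0.0, 0.0]),
                           -d, axis)
    ga, gb = (GenericPosition.parse(g) for g in generics)
    res_a = replace(res_a, generic=ga, segment=ga.segment)
    res_b = replace(res_b, generic=gb, segment=gb.segment)
    return AnnotatedStructure(structure_id="PAIR", residues=[res_a, res_b])


_AA_POOL = "ADEFHIKLMNQRSTVWY"


def random_structure(seed: int = 0, n_residues: int = 40,
                     box: float = 28.0) -> AnnotatedStructure:
    """Random cluster of residues with idealized side chains; exercises
    every contact criterion and the adjacency rules in the oracle tests."""
    rng = np.random.default_rng(seed)
    residues = []
    seqnum = 1
    codes = [1, 2, 3, 4, 5, 6, 7, 12, 45]
    used = set()
    for i in range(n_residues):
        aa = _AA_POOL[rng.integers(len(_AA_POOL))]
        ca = rng.uniform(0, box, 3)
        d = _unit(rng.normal(size=3))
        axis = _unit(np.cross(d, rng.normal(size=3)))
        res = _build_residue(aa, "A", seqnum, ca, d, axis)
        code = codes[rng.integers(len(codes))]
        offset = int(rng.integers(20, 70))
        while (code, offset) in used:
            offset = int(rng.integers(20, 70))
        used.add((code, offset))
        gen = GenericPosition(code, offset)
        residues.append(replace(res, generic=gen, segment=gen.segment))
        # mostly consecutive numbering so the adjacent-residue rule fires
        seqnum += int(rng.integers(1, 3))
    return AnnotatedStructure(structure_id=f"RND{seed}", residues=residues)


def ligand_near_position(s: AnnotatedStructure, generic: str,
                         distance: float = 3.4, n_atoms: int = 8,
                         name: str = "LIG") -> AnnotatedStructure:
    """Copy of the structure with a compact decoy ligand placed against
    the side chain of one position (outward from the bundle centre)."""
    pos = GenericPosition.parse(generic)
    res = s.by_generic().get(pos)
    if res is None:
        raise KeyError(f"position {generic} not in structure")
    centre = np.mean([r.ca for r in s.residues if r.ca is not None], axis=0)
    anchor_atom = res.atoms[-1]
    d = _unit(anchor_atom.pos - centre)
    base = anchor_atom.pos + distance * d
    atoms = [AtomRecord("C1", "C", tuple(base))]
    for i in range(1, n_atoms):
        ang = 2 * math.pi * i / (n_atoms - 1)
        p, q = _perp_basis(d)
        atoms.append(AtomRecord(
            f"C{i + 1}", "C",
            tuple(base + 1.4 * d + 1.2 * (math.cos(ang) * p
                                          + math.sin(ang) * q))))
    lig = LigandGroup(name=name, chain="L", seqnum=1, atoms=atoms)
    return replace(s, ligands=list(s.ligands) + [lig],
                   metadata=dict(s.metadata))


def decoy_galpha(s: AnnotatedStructure, generics, distance: float = 3.4,
                 chain: str = "G") -> AnnotatedStructure:
    """Decoy Galpha fragment: one alanine residue placed against each of
    the listed receptor positions, packaged as a separate structure."""
    centre = np.mean([r.ca for r in s.residues if r.ca is not None], axis=0)
    residues = []
    for i, g in enumerate(generics):
        res = s.by_generic().get(GenericPosition.parse(g))
        if res is None:
            raise KeyError(f"position {g} not in structure")
        anchor = res.atoms[-1]
        d = _unit(anchor.pos - centre)
        ca = anchor.pos + (distance + 1.53) * d
        residues.append(_build_residue("A", chain, i + 1, ca, -d,
                                       _unit(np.cross(d, [0, 0, 1.0])
                                             if abs(d[2]) < 0.9
                                             else np.cross(d, [1.0, 0, 0]))))
    return AnnotatedStructure(structure_id=f"{s.structure_id}-GA",
                              residues=residues)


# ---------------------------------------------------------------------------
# mmCIF round trip


def write_structure_cif(s: AnnotatedStructure, path) -> None:
    """Write residues (and ligand side table) to mmCIF via gemmi."""
    st = gemmi.Structure()
    st.name = s.structure_id
    model = gemmi.Model("1")
    chains: dict = {}

    def chain_for(name):
        if name not in chains:
            chains[name] = gemmi.Chain(name)
        return chains[name]

    for r in s.residues:
        res = gemmi.Residue()
        res.name = r.name3
        res.seqid = gemmi.SeqId(r.seqnum, " ")
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.pos)
            atom.occ = a.occupancy
            atom.altloc = a.altloc or "\0"
            res.add_atom(atom)
        chain_for(r.chain).add_residue(res)
    for lig in s.ligands:
        res = gemmi.Residue()
        res.name = lig.name
        res.seqid = gemmi.SeqId(lig.seqnum, " ")
        res.het_flag = "H"
        for a in lig.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.pos)
            atom.occ = a.occupancy
            res.add_atom(atom)
        chain_for(lig.chain).add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


def bundle_mapping(s: AnnotatedStructure) -> dict:
    """(chain, seqnum) -> GenericPosition mapping of an annotated fixture."""
    return {(r.chain, r.seqnum): r.generic for r in s.residues
            if r.generic is not None}
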