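"""Rigid-body quantitation of transmembrane helix movements on activation.

An inactive/active structure pair of one receptor is superposed on the
least mobile part of the fold: the Calpha atoms of shared TM generic
positions within +-6 A of the membrane mid-plane (Kabsch least squares).
Each helix is then measured at three regions -- extracellular end, membrane
mid and intracellular end -- as the displacement of the region's Calpha
centroid (translation, A) and as the mean azimuthal shift of the region's
residues about the local helix axis after removing axis tilt (rotation,
degrees; positive = counterclockwise viewed from the extracellular side).

The membrane frame is either supplied externally or estimated from the
bundle: the normal is the first principal axis of all TM Calpha, oriented
extracellularly, with the centroid as centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_model import AnnotatedStructure, TM_SEGMENTS, segment_span

__all__ = [
    "MembraneFrame",
    "RegionSpec",
    "SuperposedPair",
    "HelixMovementReport",
    "kabsch",
    "superpose_pair",
    "estimate_membrane_frame",
    "region_translation",
    "region_rotation",
    "measure_pair",
    "class_consensus_movements",
]

REGIONS = ("ec_end", "mid", "ic_end")
NOT_MEASURABLE = None


@dataclass(frozen=True)
class MembraneFrame:
    center: tuple
    normal: tuple          # unit vector pointing extracellularly

    def __post_init__(self):
        n = np.asarray(self.normal, float)
        if not math.isclose(float(np.linalg.norm(n)), 1.0, abs_tol=1e-6):
            raise ValueError("membrane normal must be a unit vector")

    @property
    def c(self) -> np.ndarray:
        return np.asarray(self.center, float)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, float)

    def height(self, xyz: np.ndarray) -> np.ndarray:
        """Signed distance from the mid-plane (positive = extracellular)."""
        return (np.atleast_2d(xyz) - self.c) @ self.n


@dataclass(frozen=True)
class RegionSpec:
    end_window: int = 4
    mid_window: int = 5
    #: residues used for the local helix-axis fit
    axis_window: int = 7

    def __post_init__(self):
        if min(self.end_window, self.mid_window) < 3:
            raise ValueError("region windows must contain >= 3 residues")

    def window(self, region: str) -> int:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return self.mid_window if region == "mid" else self.end_window


def kabsch(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid transform R, t with R @ moving + t ~= fixed."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum(
        ((moving - cm) @ R.T + cf - fixed) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class SuperposedPair:
    receptor: str
    inactive: AnnotatedStructure
    active: AnnotatedStructure          # transformed onto the inactive frame
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    core_positions: list
    frame: MembraneFrame

    def shared_tm_positions(self, tm: str) -> list:
        gen_i = {r.generic for r in segment_span(self.inactive, tm)}
        gen_a = {r.generic for r in segment_span(self.active, tm)}
        shared = gen_i & gen_a
        return sorted(shared, key=lambda g: g.offset)


def estimate_membrane_frame(s: AnnotatedStructure,
                            mode: str = "bundle_axis",
                            external: MembraneFrame | None = None
                            ) -> MembraneFrame:
    """Membrane mid-plane frame: external annotation or the bundle axis.

    In bundle-axis mode the normal is the first principal axis of all TM
    Calpha atoms; it is oriented extracellularly using the helix topology
    (odd helices run extracellular to intracellular, so their low generic
    offsets sit on the extracellular side; even helices the opposite), and
    the centre is the TM Calpha centroid.
    """
    if mode == "external":
        if external is None:
            raise ValueError("external mode requires a supplied frame")
        return external
    if mode != "bundle_axis":
        raise ValueError(f"unknown membrane frame mode {mode!r}")

    tm_cas, ec_guess = [], []
    n_segments = 0
    for tm in TM_SEGMENTS:
        span = segment_span(s, tm)
        cas = [(r.generic.offset, r.ca) for r in span if r.ca is not None]
        if len(cas) < 3:
            continue
        n_segments += 1
        tm_cas.extend(ca for _, ca in cas)
        cas.sort(key=lambda t: t[0])
        code = span[0].generic.segment_code
        # extracellular terminus: low offsets on odd helices, high on even
        ec_guess.append(cas[0][1] if code % 2 == 1 else cas[-1][1])
    if n_segments < 4:
        raise ValueError(f"membrane frame needs >= 4 TM segments with "
                         f"Calpha; found {n_segments}")
    X = np.asarray(tm_cas)
    center = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - center)
    normal = Vt[0] / np.linalg.norm(Vt[0])
    ec_centroid = np.mean(ec_guess, axis=0)
    if (ec_centroid - center) @ normal < 0:
        normal = -normal
    return MembraneFrame(center=tuple(center), normal=tuple(normal))


def superpose_pair(inactive: AnnotatedStructure, active: AnnotatedStructure,
                   frame: MembraneFrame | None = None,
                   slab_half_width: float = 6.0,
                   receptor: str = "") -> SuperposedPair:
    """Kabsch-fit the active structure onto the inactive one using shared
    mid-membrane TM Calpha atoms (|height| <= ``slab_half_width``)."""
    frame = frame or estimate_membrane_frame(inactive)
    by_i, by_a = inactive.by_generic(), active.by_generic()
    shared = [g for g in by_i if g in by_a
              and g.segment in TM_SEGMENTS
              and by_i[g].ca is not None and by_a[g].ca is not None]
    if len(shared) < 20:
        raise ValueError(f"only {len(shared)} shared TM generic positions "
                         "with Calpha; need >= 20 for superposition")
    core = [g for g in shared
            if abs(float(frame.height(by_i[g].ca)[0])) <= slab_half_width]
    if len(core) < 3:
        raise ValueError("fewer than 3 shared mid-membrane positions")
    core = sorted(core)
    Xi = np.stack([by_i[g].ca for g in core])
    Xa = np.stack([by_a[g].ca for g in core])
    R, t, rmsd = kabsch(Xa, Xi)
    # robust core: drop slab positions that move with a rearranging helix
    # (residual outliers), so the reference frame tracks the static fold
    for _ in range(2):
        resid = np.linalg.norm(Xa @ R.T + t - Xi, axis=1)
        cut = max(2.0 * float(np.median(resid)), 0.5)
        keep = resid <= cut
        if keep.all() or keep.sum() < max(3, len(core) // 2):
            break
        core = [g for g, k in zip(core, keep) if k]
        Xi, Xa = Xi[keep], Xa[keep]
        R, t, rmsd = kabsch(Xa, Xi)
    return SuperposedPair(
        receptor=receptor or inactive.receptor or active.receptor,
        inactive=inactive, active=active.transformed(R, t),
        rotation=R, translation=t, rmsd=rmsd,
        core_positions=core, frame=frame)


def _region_positions(pair: SuperposedPair, tm: str, region: str,
                      spec: RegionSpec):
    """Shared positions of one region, ordered by generic offset."""
    shared = pair.shared_tm_positions(tm)
    w = spec.window(region)
    if len(shared) < w:
        return None
    by_i = pair.inactive.by_generic()
    heights = {g: float(pair.frame.height(by_i[g].ca)[0]) for g in shared}
    if region == "mid":
        return sorted(sorted(shared, key=lambda g: abs(heights[g]))[:w],
                      key=lambda g: g.offset)
    first_is_ec = heights[shared[0]] > heights[shared[-1]]
    if (region == "ec_end") == first_is_ec:
        return shared[:w]
    return shared[-w:]


def region_translation(pair: SuperposedPair, tm: str, region: str,
                       spec: RegionSpec | None = None) -> float | None:
    """Distance (A) between region Calpha centroids after superposition;
    ``None`` when the region has too few shared residues."""
    spec = spec or RegionSpec()
    positions = _region_positions(pair, tm, region, spec)
    if positions is None or len(positions) < 3:
        return NOT_MEASURABLE
    by_i, by_a = pair.inactive.by_generic(), pair.active.by_generic()
    ci = np.mean([by_i[g].ca for g in positions], axis=0)
    ca = np.mean([by_a[g].ca for g in positions], axis=0)
    return float(np.linalg.norm(ca - ci))


def _principal_axis(X: np.ndarray) -> np.ndarray:
    c = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - c)
    return Vt[0] / np.linalg.norm(Vt[0])


def _helix_axis(X: np.ndarray) -> np.ndarray:
    """Local helix axis from consecutive Calpha positions.

    Second differences of points on an ideal helix lie exactly in the
    plane perpendicular to the axis, so the axis is the null direction of
    their scatter; this is unbiased for short windows where a principal
    component of the points themselves tilts.  Oriented from the first to
    the last residue.
    """
    d2 = X[2:] - 2 * X[1:-1] + X[:-2]
    if len(d2) < 2:
        return _principal_axis(X)
    _, _, Vt = np.linalg.svd(d2)
    axis = Vt[-1] / np.linalg.norm(Vt[-1])
    if axis @ (X[-1] - X[0]) < 0:
        axis = -axis
    return axis


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def region_rotation(pair: SuperposedPair, tm: str, region: str,
                    spec: RegionSpec | None = None,
                    min_radial_spread: float = 1.0) -> float | None:
    """Mean signed azimuthal displacement (deg) of region Calpha about the
    local helix axis, after aligning the active axis onto the inactive one.

    Positive angles are counterclockwise when viewed from the
    extracellular side.  ``None`` when the axis fit is degenerate or the
    region is too short.
    """
    spec = spec or RegionSpec()
    positions = _region_positions(pair, tm, region, spec)
    shared = pair.shared_tm_positions(tm)
    if positions is None or len(shared) < max(5, spec.axis_window):
        return NOT_MEASURABLE
    # axis window: axis_window shared residues centred on the region
    idx = [shared.index(g) for g in positions]
    centre = int(round(np.mean(idx)))
    half = spec.axis_window // 2
    lo = max(0, min(centre - half, len(shared) - spec.axis_window))
    window = shared[lo:lo + spec.axis_window]

    by_i, by_a = pair.inactive.by_generic(), pair.active.by_generic()
    Xi = np.stack([by_i[g].ca for g in window])
    Xa = np.stack([by_a[g].ca for g in window])
    axis_i = _helix_axis(Xi)
    # orient the axis extracellularly so the sign convention is stable
    if axis_i @ pair.frame.n < 0:
        axis_i = -axis_i
    # the active-state axis is the inactive axis carried through the rigid
    # fit of the window (more stable than two independent axis fits)
    R_win, _, _ = kabsch(Xi, Xa)
    axis_a = R_win @ axis_i

    R_tilt = _minimal_rotation(axis_a, axis_i)
    # orthonormal basis of the plane perpendicular to the inactive axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ axis_i) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis_i, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_i, e1)

    # all heavy atoms of the region residues, projected onto the plane
    # perpendicular to the axis after removing axis tilt; the mean angular
    # displacement is the rigid-fit rotation of those projections
    atoms_i, atoms_a = [], []
    for g in positions:
        ri, ra = by_i[g], by_a[g]
        names = {a.name for a in ri.atoms} & {a.name for a in ra.atoms}
        for name in sorted(names):
            atoms_i.append(ri.atom(name).pos)
            atoms_a.append(ra.atom(name).pos)
    Ai = np.asarray(atoms_i)
    Aa = np.asarray(atoms_a)
    ci, ca = Ai.mean(axis=0), Aa.mean(axis=0)
    Pi = np.stack([(Ai - ci) @ e1, (Ai - ci) @ e2], axis=1)
    Pa_3d = (Aa - ca) @ R_tilt.T
    Pa = np.stack([Pa_3d @ e1, Pa_3d @ e2], axis=1)
    radii = np.linalg.norm(Pi, axis=1)
    if radii.max() < min_radial_spread:
        return NOT_MEASURABLE
    cross = float(np.sum(Pi[:, 0] * Pa[:, 1] - Pi[:, 1] * Pa[:, 0]))
    dot = float(np.sum(Pi[:, 0] * Pa[:, 0] + Pi[:, 1] * Pa[:, 1]))
    if abs(cross) < 1e-15 and abs(dot) < 1e-15:
        return NOT_MEASURABLE
    # e2 = axis x e1 makes positive angles counterclockwise viewed from
    # the extracellular side
    return math.degrees(math.atan2(cross, dot))


@dataclass
class HelixMovementReport:
    receptor: str
    gpcr_class: str
    rmsd: float
    #: (tm, region) -> {"translation": float|None, "rotation": float|None,
    #:                  "n_residues": int}
    measurements: dict = field(default_factory=dict)

    def translation(self, tm: str, region: str):
        return self.measurements.get((tm, region), {}).get("translation")

    def rotation(self, tm: str, region: str):
        return self.measurements.get((tm, region), {}).get("rotation")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tm, region), m in sorted(self.measurements.items()):
            rows.append({
                "receptor": self.receptor, "gpcr_class": self.gpcr_class,
                "tm": tm, "region": region,
                "translation_A": ("" if m["translation"] is None
                                  else round(m["translation"], 2)),
                "rotation_deg": ("" if m["rotation"] is None
                                 else round(m["rotation"], 1)),
                "n_residues": m["n_residues"],
                "measurable": m["translation"] is not None,
            })
        return pd.DataFrame(rows)


def measure_pair(pair: SuperposedPair, gpcr_class: str = "",
                 spec: RegionSpec | None = None) -> HelixMovementReport:
    """Translation and rotation of every TM x region for one receptor pair."""
    spec = spec or RegionSpec()
    report = HelixMovementReport(receptor=pair.receptor,
                                 gpcr_class=gpcr_class, rmsd=pair.rmsd)
    for tm in TM_SEGMENTS:
        for region in REGIONS:
            positions = _region_positions(pair, tm, region, spec)
            report.measurements[(tm, region)] = {
                "translation": region_translation(pair, tm, region, spec),
                "rotation": region_rotation(pair, tm, region, spec),
                "n_residues": 0 if positions is None else len(positions),
            }
    return report


def class_consensus_movements(reports, threshold: float = 1.0) -> dict:
    """Per class x TM x region: receptors moving strictly beyond the
    threshold and a consensus flag (majority of measured pairs move)."""
    if not reports:
        raise ValueError("no movement reports supplied")
    out: dict = {}
    for rep in reports:
        cls = rep.gpcr_class or "?"
        for (tm, region), m in rep.measurements.items():
            cell = out.setdefault(cls, {}).setdefault((tm, region), {
                "n_measured": 0, "n_moving": 0})
            if m["translation"] is None:
                continue
            cell["n_measured"] += 1
            if m["translation"] > threshold:
                cell["n_moving"] += 1
    for cls in out.values():
        for cell in cls.values():
            cell["consensus"] = (cell["n_measured"] > 0
                                 and cell["n_moving"] * 2 > cell["n_measured"])
    return out
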