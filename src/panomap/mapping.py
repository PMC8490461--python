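"""Panoramic activation mapping and conduction analysis.

Local activation times (LATs) from optical fibers (oLAT_50%, oLAT_SG) and
electrodes (eLAT_SG) are assembled into per-beat activation maps on the
sensor layout.  Conduction velocity is estimated with a trajectory "vector
algorithm": LATs are interpolated along the on-surface shortest path from an
origin, plotted against cumulative geodesic distance and fitted by a line --
the reciprocal slope is the conduction velocity theta (mm/s) and r^2 measures
the uniformity of conduction.  Scanning trajectories over directions yields
the fastest direction, its perpendicular, and the anisotropy ratio.
Opto-electrical concordance compares each electrode's eLAT_SG with the mean
oLAT of its surrounding optical "petal" fibers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .errors import MappingError
from .geometry import EllipsoidSpec, SensorLayout, SurfaceMesh, geodesic_path, surface_distances
from .optical import ShapeClass

LAT_VARIANTS = ("olat_50", "olat_sg", "elat_sg")


@dataclass
class ActivationMap:
    beat_id: int
    lat_by_site: dict[int, float]  # site_id -> LAT ms
    variant: str  # one of LAT_VARIANTS
    excluded_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in LAT_VARIANTS:
            raise MappingError(f"unknown LAT variant {self.variant!r}")
        for sid, lat in self.lat_by_site.items():
            if not np.isfinite(lat):
                raise MappingError(f"site {sid}: non-finite LAT")

    @property
    def total_activation_time(self) -> float:
        v = list(self.lat_by_site.values())
        return float(max(v) - min(v)) if v else 0.0

    def shifted(self, delta_ms: float) -> "ActivationMap":
        return ActivationMap(
            beat_id=self.beat_id,
            lat_by_site={k: v + delta_ms for k, v in self.lat_by_site.items()},
            variant=self.variant,
            excluded_sites=list(self.excluded_sites),
        )


@dataclass
class ConductionEstimate:
    theta: float  # mm/s
    r_squared: float
    trajectory: np.ndarray  # points along the fitted path
    n_points: int

    @property
    def theta_m_per_s(self) -> float:
        """theta in m/s (equivalently mm/ms)."""
        return self.theta / 1000.0


@dataclass
class AnisotropyResult:
    theta_max: float  # mm/s
    direction_max: np.ndarray  # unit surface tangent at the origin
    theta_perpendicular: float  # mm/s
    anisotropy_ratio: float
    per_direction: list[tuple[float, float, float]] = field(default_factory=list)  # (angle, theta, r2)


@dataclass
class ConcordanceReport:
    differences: dict[int, float]  # electrode_id -> mean(petal oLAT) - eLAT_SG, ms
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    by_shape: dict[str, list[float]] = field(default_factory=dict)
    excluded_electrodes: list[int] = field(default_factory=list)


def anisotropy_ratio(theta_max: float, theta_perpendicular: float) -> float:
    """Ratio of fastest over perpendicular conduction velocity."""
    if theta_perpendicular <= 0:
        raise MappingError("perpendicular velocity must be positive")
    return theta_max / theta_perpendicular


def build_activation_map(
    metrics_by_site: dict[int, object],
    layout: SensorLayout,
    beat_id: int,
    lat_variant: str,
) -> ActivationMap:
    """Collect one beat's LATs (variant-tagged) into an activation map."""
    if lat_variant not in LAT_VARIANTS:
        raise MappingError(f"unknown LAT variant {lat_variant!r}")
    known = set(layout.by_id)
    lat_by_site: dict[int, float] = {}
    excluded: list[int] = []
    for sid, m in metrics_by_site.items():
        if sid not in known:
            raise MappingError(f"metrics for unknown site {sid}")
        if getattr(m, "excluded", False):
            excluded.append(sid)
            continue
        lat = getattr(m, lat_variant, None)
        if lat is None or not np.isfinite(lat):
            excluded.append(sid)
            continue
        lat_by_site[sid] = float(lat)
    if not lat_by_site:
        raise MappingError("no valid sites for this beat")
    return ActivationMap(beat_id=beat_id, lat_by_site=lat_by_site, variant=lat_variant,
                         excluded_sites=sorted(excluded))


def interpolate_lat(
    amap: ActivationMap,
    layout: SensorLayout,
    query: np.ndarray,
    k: int = 4,
    power: float = 2.0,
    max_pitch_factor: float = 2.0,
) -> float:
    """Inverse-geodesic-distance-weighted LAT at an arbitrary surface point."""
    sids = [s for s in amap.lat_by_site]
    if len(sids) < 3:
        raise MappingError("need at least 3 mapped sites to interpolate")
    pos = np.array([layout.by_id[s].position for s in sids])
    lats = np.array([amap.lat_by_site[s] for s in sids])
    q = np.asarray(query, dtype=float)
    chord = np.linalg.norm(pos - q, axis=1)
    near = np.argsort(chord)[: max(k, 1)]
    if chord[near[0]] < 1e-9:
        return float(lats[near[0]])
    d = surface_distances(layout.ellipsoid, np.broadcast_to(q, (len(near), 3)), pos[near],
                          n_seg=8, iters=80)
    if d.min() > max_pitch_factor * layout.nominal_pitch:
        raise MappingError("query point too far from any mapped site")
    w = 1.0 / np.maximum(d, 1e-12) ** power
    return float(np.sum(w * lats[near]) / np.sum(w))


def _fit_lat_vs_distance(dists: np.ndarray, lats: np.ndarray) -> tuple[float, float]:
    """Line fit of LAT (ms) vs distance (mm); returns (theta mm/s, r^2)."""
    if len(dists) < 3:
        raise MappingError("trajectory must sample at least 3 points")
    fit = linregress(dists, lats)
    if fit.slope <= 0:
        raise MappingError("non-positive LAT-vs-distance slope (retrograde or flat conduction)")
    theta = 1000.0 / fit.slope  # ms/mm -> mm/s
    return theta, float(fit.rvalue**2)


def _sample_path_lats(
    amap: ActivationMap,
    layout: SensorLayout,
    points: np.ndarray,
    cum: np.ndarray,
    spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated LATs at ~spacing-separated points along a path."""
    keep = [0]
    for i in range(1, len(points)):
        if cum[i] - cum[keep[-1]] >= spacing or i == len(points) - 1:
            keep.append(i)
    dd, ll = [], []
    for i in keep:
        try:
            ll.append(interpolate_lat(amap, layout, points[i]))
            dd.append(cum[i])
        except MappingError:
            continue
    return np.array(dd), np.array(ll)


def estimate_cv(
    amap: ActivationMap,
    layout: SensorLayout,
    mesh: SurfaceMesh,
    origin_site: int,
    target_site: int,
    sample_spacing: float | None = None,
) -> ConductionEstimate:
    """Conduction velocity along the shortest path between two sites."""
    p0 = layout.by_id[origin_site].position
    p1 = layout.by_id[target_site].position
    points, cum = geodesic_path(mesh, p0, p1)
    spacing = sample_spacing if sample_spacing is not None else 0.5 * layout.nominal_pitch
    dd, ll = _sample_path_lats(amap, layout, points, cum, spacing)
    theta, r2 = _fit_lat_vs_distance(dd, ll)
    return ConductionEstimate(theta=theta, r_squared=r2, trajectory=points, n_points=len(dd))


def _tangent_basis(ellipsoid: EllipsoidSpec, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(circumferential, meridional) unit tangents at a surface point."""
    n = ellipsoid.normal(p)
    up = np.array([0.0, 0.0, 1.0])
    e_circ = np.cross(up, n)
    nc = np.linalg.norm(e_circ)
    if nc < 1e-9:  # at a pole: pick any horizontal direction
        e_circ = np.array([1.0, 0.0, 0.0])
        e_circ -= np.dot(e_circ, n) * n
        e_circ /= np.linalg.norm(e_circ)
    else:
        e_circ /= nc
    e_merid = np.cross(n, e_circ)
    return e_circ, e_merid


def walk_surface_ray(
    ellipsoid: EllipsoidSpec,
    origin: np.ndarray,
    direction: np.ndarray,
    length: float,
    step: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """March a geodesic-like ray along the surface by project-and-transport.

    Stops at the truncation rim.  Returns points and cumulative arc lengths.
    """
    p = np.asarray(origin, dtype=float).copy()
    d = np.asarray(direction, dtype=float).copy()
    n = ellipsoid.normal(p)
    d = d - np.dot(d, n) * n
    nd = np.linalg.norm(d)
    if nd == 0:
        raise MappingError("direction is normal to the surface")
    d /= nd
    pts = [p.copy()]
    cum = [0.0]
    zc = ellipsoid.z_cut
    traveled = 0.0
    while traveled < length:
        q = p + step * d
        if q[2] > zc:
            break
        q = ellipsoid.project(q, clamp=False)
        seg = np.linalg.norm(q - p)
        if seg == 0:
            break
        # parallel-transport the direction onto the new tangent plane
        d = q - p
        n = ellipsoid.normal(q)
        d = d - np.dot(d, n) * n
        nd = np.linalg.norm(d)
        if nd == 0:
            break
        d /= nd
        p = q
        traveled += seg
        pts.append(p.copy())
        cum.append(traveled)
    return np.array(pts), np.array(cum)


def estimate_anisotropy(
    amap: ActivationMap,
    layout: SensorLayout,
    mesh: SurfaceMesh,
    origin_site: int,
    n_directions: int = 36,
    trajectory_mm: float = 3.0,
    min_r2: float = 0.9,
    sample_spacing: float | None = None,
) -> AnisotropyResult:
    """Fastest conduction direction, its perpendicular, and their ratio.

    Equally spaced surface directions from the origin are scanned with the
    trajectory CV fit; the fastest direction with r^2 >= min_r2 wins and the
    perpendicular velocity is measured along the 90-degree-rotated trajectory.
    """
    if n_directions < 8:
        raise MappingError("need at least 8 scan directions")
    ell = layout.ellipsoid
    origin = layout.by_id[origin_site].position
    if origin_site not in amap.lat_by_site:
        raise MappingError("origin site is not part of the activation map")
    e1, e2 = _tangent_basis(ell, origin)
    spacing = sample_spacing if sample_spacing is not None else 0.5 * layout.nominal_pitch

    angles = np.linspace(0, 2 * np.pi, n_directions, endpoint=False)
    results: list[tuple[float, float, float]] = []

    def cv_along(angle: float) -> tuple[float, float] | None:
        d = np.cos(angle) * e1 + np.sin(angle) * e2
        pts, cum = walk_surface_ray(ell, origin, d, trajectory_mm, step=spacing / 2)
        if len(pts) < 3 or cum[-1] < 3 * spacing:
            return None
        dd, ll = _sample_path_lats(amap, layout, pts, cum, spacing)
        if len(dd) < 3:
            return None
        try:
            return _fit_lat_vs_distance(dd, ll)
        except MappingError:
            return None

    for ang in angles:
        r = cv_along(float(ang))
        if r is not None:
            results.append((float(ang), r[0], r[1]))

    ok = [r for r in results if r[2] >= min_r2]
    if not ok:
        raise MappingError("no scan direction produced an acceptable linear fit")
    best = max(ok, key=lambda r: r[1])
    perp = cv_along(best[0] + np.pi / 2)
    if perp is None:
        perp = cv_along(best[0] - np.pi / 2)
    if perp is None:
        raise MappingError("perpendicular trajectory could not be fitted")
    direction = np.cos(best[0]) * e1 + np.sin(best[0]) * e2
    return AnisotropyResult(
        theta_max=best[1],
        direction_max=direction,
        theta_perpendicular=perp[0],
        anisotropy_ratio=anisotropy_ratio(best[1], perp[0]),
        per_direction=results,
    )


def concordance(
    optical_map: ActivationMap,
    electrical_map: ActivationMap,
    layout: SensorLayout,
    min_petals: int = 4,
    bin_width_ms: float = 0.5,
    shape_by_site: dict[int, ShapeClass] | None = None,
) -> ConcordanceReport:
    """Per-electrode (mean petal oLAT) - eLAT_SG differences.

    Electrodes with fewer than ``min_petals`` valid optical petals (or no
    electrical LAT) are excluded.  The sign convention is optical minus
    electrical: positive differences mean the optical LAT trails.
    """
    if optical_map.beat_id != electrical_map.beat_id:
        raise MappingError("optical and electrical maps refer to different beats")
    diffs: dict[int, float] = {}
    excluded: list[int] = []
    by_shape: dict[str, list[float]] = {}
    for e_id, petals in layout.petal_map.items():
        elat = electrical_map.lat_by_site.get(e_id)
        if elat is None:
            excluded.append(e_id)
            continue
        olats = [optical_map.lat_by_site[p] for p in petals if p in optical_map.lat_by_site]
        if len(olats) < min_petals:
            excluded.append(e_id)
            continue
        diff = float(np.mean(olats) - elat)
        diffs[e_id] = diff
        if shape_by_site:
            shapes = [shape_by_site.get(p, ShapeClass.UNCLASSIFIED) for p in petals
                      if p in optical_map.lat_by_site]
            names = [s.value for s in shapes]
            dominant = max(set(names), key=names.count)
            by_shape.setdefault(dominant, []).append(diff)
    if not diffs:
        raise MappingError("no electrode has enough valid petals for concordance")
    vals = np.array(list(diffs.values()))
    lo = np.floor(vals.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(vals.max() / bin_width_ms) * bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms, bin_width_ms) if hi > lo else np.array([lo, lo + bin_width_ms])
    counts, edges = np.histogram(vals, bins=edges)
    return ConcordanceReport(
        differences=diffs,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        bin_edges=edges,
        counts=counts,
        by_shape=by_shape,
        excluded_electrodes=sorted(excluded),
    )
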