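"""Geometry of the mapping surface.

The recording cup embraces the ventricles as a tri-axial ellipsoid with the
upper part (the base of the heart) cut away.  This module builds that surface,
meshes it, packs evenly pitched sensor sites onto it (electrodes as "stigma"
sites each surrounded by up to six optical "petal" fibers), computes on-surface
shortest paths, and provides the Mercator and central (azimuthal) projections
used to unroll activation maps.

Conventions: right-handed coordinates, z up toward the heart base, lengths in
millimeters.  The apex of the heart is the lowest pole (0, 0, -c).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .errors import GeometryError, PackingError, ProjectionError

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class Modality(str, Enum):
    OPTICAL = "optical"
    ELECTRICAL = "electrical"


@dataclass(frozen=True)
class EllipsoidSpec:
    """Tri-axial ellipsoid, truncated by a horizontal plane.

    Parameters
    ----------
    semi_axis_a, semi_axis_b : float
        Equatorial semi-axes (mm).
    semi_axis_c : float
        Vertical semi-axis (mm); the apex sits at z = -c.
    truncation_fraction : float
        Fraction of the total vertical extent (2c) removed from the top.
        0 keeps the closed ellipsoid; 0.25 reproduces the reference cup.
    """

    semi_axis_a: float
    semi_axis_b: float
    semi_axis_c: float
    truncation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axis_a, self.semi_axis_b, self.semi_axis_c) <= 0:
            raise GeometryError("all semi-axes must be positive")
        if not (0.0 <= self.truncation_fraction < 1.0):
            raise GeometryError("truncation_fraction must lie in [0, 1)")

    @property
    def axes(self) -> np.ndarray:
        return np.array([self.semi_axis_a, self.semi_axis_b, self.semi_axis_c])

    @property
    def z_cut(self) -> float:
        """Height of the truncation plane: top ``truncation_fraction`` of 2c removed."""
        c = self.semi_axis_c
        return c - 2.0 * c * self.truncation_fraction

    @property
    def apex(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.semi_axis_c])

    def implicit(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        u = p / self.axes
        return np.sum(u * u, axis=-1) - 1.0

    def on_surface(self, points: np.ndarray, rtol: float = 1e-6) -> np.ndarray:
        return np.abs(self.implicit(points)) <= rtol * 3.0

    def project(self, points: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Radially (in scaled coordinates) project points onto the surface.

        With ``clamp`` the result is additionally pulled down to the
        truncation plane so it always lies on the retained part of the cup.
        """
        p = np.asarray(points, dtype=float)
        u = p / self.axes
        norm = np.linalg.norm(u, axis=-1, keepdims=True)
        norm = np.where(norm == 0, 1.0, norm)
        q = (u / norm) * self.axes
        if clamp and self.truncation_fraction > 0:
            q = self.clamp_to_cut(q)
        return q

    def clamp_to_cut(self, points: np.ndarray) -> np.ndarray:
        """Move points above the truncation plane onto the rim ring."""
        q = np.array(points, dtype=float)
        a, b, c = self.axes
        zc = self.z_cut
        flat = q.reshape(-1, 3)
        above = flat[:, 2] > zc
        if np.any(above):
            rho = np.sqrt(max(1.0 - (zc / c) ** 2, 0.0))
            sub = flat[above]
            r = np.sqrt((sub[:, 0] / a) ** 2 + (sub[:, 1] / b) ** 2)
            r = np.where(r == 0, 1.0, r)
            sub[:, 0] *= rho / r
            sub[:, 1] *= rho / r
            sub[:, 2] = zc
            flat[above] = sub
        return flat.reshape(q.shape)

    def normal(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        g = 2.0 * p / (self.axes**2)
        n = np.linalg.norm(g, axis=-1, keepdims=True)
        return g / np.where(n == 0, 1.0, n)

    def surface_area(self, n_grid: int = 400) -> float:
        """Numeric area of the retained (below-cut) surface."""
        a, b, c = self.axes
        th_min, th_max = -np.pi / 2, float(np.arcsin(np.clip(self.z_cut / c, -1, 1)))
        th = np.linspace(th_min, th_max, n_grid)
        ph = np.linspace(0, 2 * np.pi, n_grid)
        T, P = np.meshgrid(th, ph, indexing="ij")
        # |S_theta x S_phi| for S = (a cosT cosP, b cosT sinP, c sinT)
        st, ct, sp, cp = np.sin(T), np.cos(T), np.sin(P), np.cos(P)
        ex = b * c * ct * ct * cp
        ey = a * c * ct * ct * sp
        ez = a * b * ct * st
        el = np.sqrt(ex**2 + ey**2 + ez**2)
        return float(np.trapezoid(np.trapezoid(el, ph, axis=1), th))


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation, ample for ring sizing.
    h = ((a - b) / (a + b)) ** 2 if a + b > 0 else 0.0
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


@dataclass
class SurfaceMesh:
    """Triangulated (possibly truncated) ellipsoid surface."""

    vertices: np.ndarray
    faces: np.ndarray
    ellipsoid: EllipsoidSpec | None = None
    _edges: np.ndarray | None = field(default=None, repr=False)
    _tree: cKDTree | None = field(default=None, repr=False)

    @property
    def edges(self) -> np.ndarray:
        if self._edges is None:
            f = self.faces
            e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e.sort(axis=1)
            self._edges = np.unique(e, axis=0)
        return self._edges

    @property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def adjacency(self, two_hop: bool = False):
        """Sparse symmetric edge-length graph (optionally with 2-hop chords)."""
        n = len(self.vertices)
        e = self.edges
        if two_hop:
            nb: dict[int, set[int]] = {i: set() for i in range(n)}
            for i, j in e:
                nb[int(i)].add(int(j))
                nb[int(j)].add(int(i))
            pairs = set(map(tuple, e.tolist()))
            for i in range(n):
                for j in nb[i]:
                    for k in nb[j]:
                        if k > i and k not in nb[i]:
                            pairs.add((i, k))
            e = np.array(sorted(pairs), dtype=int)
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        m = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return m.tocsr()

    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges) + len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.adjacency(), directed=False)
        return ncomp == 1


def build_mesh(ellipsoid: EllipsoidSpec, target_edge_length: float) -> SurfaceMesh:
    """Triangulate the truncated ellipsoid with roughly uniform edge length.

    Rings of vertices follow lines of constant latitude, spaced by meridian
    arc length; each ring carries ~perimeter/target vertices; adjacent rings
    are stitched with a two-pointer zipper.  The result is watertight below
    the truncation plane (Euler characteristic 1 for a truncated cup, 2 for
    the closed surface).
    """
    a, b, c = ellipsoid.axes
    if target_edge_length <= 0 or target_edge_length >= min(a, b, c):
        raise GeometryError("target_edge_length must be positive and smaller than the smallest semi-axis")

    closed = ellipsoid.truncation_fraction == 0.0
    th_max = np.pi / 2 if closed else float(np.arcsin(np.clip(ellipsoid.z_cut / c, -1, 1)))
    s_eq = 0.5 * (a + b)

    # meridian arc length (representative meridian with semi-axes (s_eq, c))
    th_grid = np.linspace(-np.pi / 2, th_max, 4096)
    ds = np.sqrt((s_eq * np.sin(th_grid)) ** 2 + (c * np.cos(th_grid)) ** 2)
    arc = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(th_grid))])
    total_arc = arc[-1]
    n_rings = max(3, int(round(total_arc / target_edge_length)))
    ring_th = np.interp(np.linspace(0, total_arc, n_rings + 1), arc, th_grid)
    inner_th = ring_th[1:-1] if closed else ring_th[1:]

    vertices_list: list[np.ndarray] = [np.array([[0.0, 0.0, -c]])]  # apex pole
    rings: list[np.ndarray] = []
    ring_phis: list[np.ndarray] = []
    offset = 1
    for k, th in enumerate(inner_th):
        per = _ellipse_perimeter(a * np.cos(th), b * np.cos(th))
        n_k = max(6, int(round(per / target_edge_length)))
        phi = 2 * np.pi * np.arange(n_k) / n_k + (0.5 * GOLDEN_ANGLE * k) % (2 * np.pi / n_k)
        ring = np.column_stack(
            [a * np.cos(th) * np.cos(phi), b * np.cos(th) * np.sin(phi), np.full(n_k, c * np.sin(th))]
        )
        rings.append(np.arange(offset, offset + n_k))
        ring_phis.append(phi)
        vertices_list.append(ring)
        offset += n_k

    vertices = np.vstack(vertices_list)
    faces: list[tuple[int, int, int]] = []

    # apex fan
    r0 = rings[0]
    for i in range(len(r0)):
        faces.append((0, int(r0[i]), int(r0[(i + 1) % len(r0)])))

    # zipper between consecutive rings (two-pointer merge by azimuth)
    for k in range(len(rings) - 1):
        i1, i2 = rings[k], rings[k + 1]
        p1, p2 = ring_phis[k], ring_phis[k + 1]
        n1, n2 = len(i1), len(i2)
        base = p1[0]
        # ring2 azimuths mapped into [base, base + 2pi), rolled to ascending order
        b2 = np.mod(p2 - base, 2 * np.pi) + base
        order2 = np.argsort(b2, kind="stable")
        a1 = np.concatenate([p1, [p1[0] + 2 * np.pi]])
        a2 = np.concatenate([b2[order2], [b2[order2][0] + 2 * np.pi]])
        i, j = 0, 0
        while i < n1 or j < n2:
            if j >= n2:
                adv1 = True
            elif i >= n1:
                adv1 = False
            else:
                adv1 = a1[i + 1] <= a2[j + 1]
            if adv1:
                faces.append((int(i1[i % n1]), int(i1[(i + 1) % n1]), int(i2[order2[j % n2]])))
                i += 1
            else:
                faces.append((int(i1[i % n1]), int(i2[order2[(j + 1) % n2]]), int(i2[order2[j % n2]])))
                j += 1

    if closed:
        top = np.array([0.0, 0.0, c])
        top_idx = len(vertices)
        vertices = np.vstack([vertices, top[None, :]])
        rl = rings[-1]
        for i in range(len(rl)):
            faces.append((top_idx, int(rl[(i + 1) % len(rl)]), int(rl[i])))

    mesh = SurfaceMesh(vertices=vertices, faces=np.array(faces, dtype=int), ellipsoid=ellipsoid)
    areas = mesh.face_areas()
    if np.any(areas <= 0):
        keep = areas > 0
        mesh = SurfaceMesh(vertices=vertices, faces=mesh.faces[keep], ellipsoid=ellipsoid)
    return mesh


# ---------------------------------------------------------------------------
# on-surface shortest paths
# ---------------------------------------------------------------------------


def _relax_on_surface(
    path: np.ndarray,
    ellipsoid: EllipsoidSpec,
    iters: int = 400,
    lam: float = 0.8,
    tol: float = 1e-10,
) -> np.ndarray:
    """Elastic-band relaxation of a polyline constrained to the surface.

    Interior points are repeatedly pulled toward the midpoint of their
    neighbors and re-projected; the polyline converges toward the geodesic.
    Accepts (n, 3) or batched (m, n, 3) polylines; endpoints stay fixed.
    """
    p = np.array(path, dtype=float)
    batched = p.ndim == 3
    if not batched:
        p = p[None, :, :]
    scale = float(np.max(ellipsoid.axes))
    for _ in range(iters):
        mid = 0.5 * (p[:, :-2] + p[:, 2:])
        new = ellipsoid.project(p[:, 1:-1] + lam * (mid - p[:, 1:-1]))
        move = np.max(np.abs(new - p[:, 1:-1])) if new.size else 0.0
        p[:, 1:-1] = new
        if move < tol * scale:
            break
    return p if batched else p[0]


def _polyline_lengths(p: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(p, axis=-2), axis=-1)
    return seg.sum(axis=-1)


def surface_distance(ellipsoid: EllipsoidSpec, src: np.ndarray, dst: np.ndarray,
                     n_seg: int = 16, iters: int = 300) -> float:
    """Geodesic distance between two surface points (chord-seeded relaxation)."""
    return float(surface_distances(ellipsoid, np.asarray(src)[None, :], np.asarray(dst)[None, :],
                                   n_seg=n_seg, iters=iters)[0])


def surface_distances(ellipsoid: EllipsoidSpec, src: np.ndarray, dst: np.ndarray,
                      n_seg: int = 16, iters: int = 300) -> np.ndarray:
    """Vectorized geodesic distances for paired point arrays (m, 3) x (m, 3)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    t = np.linspace(0.0, 1.0, n_seg + 1)
    path = src[:, None, :] * (1 - t)[None, :, None] + dst[:, None, :] * t[None, :, None]
    path[:, 1:-1] = ellipsoid.project(path[:, 1:-1])
    path = _relax_on_surface(path, ellipsoid, iters=iters)
    return _polyline_lengths(path)


def geodesic_path(
    mesh: SurfaceMesh,
    src: np.ndarray,
    dst: np.ndarray,
    refine: bool = True,
    tol_factor: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shortest on-surface path between two points near the mesh.

    Returns the path points (starting and ending at the mesh vertices nearest
    ``src``/``dst``) and strictly increasing cumulative distances (mm).  The
    Dijkstra vertex path is optionally straightened by on-surface relaxation.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    med = float(np.median(mesh.edge_lengths))
    d_src, i_src = mesh.tree.query(src)
    d_dst, i_dst = mesh.tree.query(dst)
    if d_src > tol_factor * med or d_dst > tol_factor * med:
        raise GeometryError("query point lies too far from the surface mesh")
    if i_src == i_dst:
        return mesh.vertices[[i_src]], np.array([0.0])

    graph = mesh.adjacency()
    dist, pred = dijkstra(graph, indices=i_src, return_predecessors=True)
    if not np.isfinite(dist[i_dst]):
        raise GeometryError("mesh is disconnected between the query points")
    chain = [int(i_dst)]
    while chain[-1] != i_src:
        chain.append(int(pred[chain[-1]]))
    chain.reverse()
    pts = mesh.vertices[chain]

    if refine and mesh.ellipsoid is not None and len(pts) > 2:
        # resample so segments are ~half an edge, then relax toward the geodesic
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        n_new = max(len(pts), int(np.ceil(cum[-1] / (0.5 * med))) + 1)
        s = np.linspace(0, cum[-1], n_new)
        pts = np.column_stack([np.interp(s, cum, pts[:, k]) for k in range(3)])
        pts[1:-1] = mesh.ellipsoid.project(pts[1:-1])
        pts = _relax_on_surface(pts, mesh.ellipsoid)

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    pts = pts[keep]
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return pts, cum


# ---------------------------------------------------------------------------
# sensor layout
# ---------------------------------------------------------------------------


@dataclass
class SensorSite:
    site_id: int
    position: np.ndarray
    surface_normal: np.ndarray
    modality: Modality


@dataclass
class SensorLayout:
    """Packed sensor sites with stigma(electrode)-petal(optical) structure."""

    ellipsoid: EllipsoidSpec
    sites: list[SensorSite]
    nominal_pitch: float
    petal_map: dict[int, list[int]]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise GeometryError("site_ids must be unique")

    def positions(self, modality: Modality | None = None) -> np.ndarray:
        return np.array([s.position for s in self.sites if modality is None or s.modality == modality])

    def site_ids(self, modality: Modality | None = None) -> list[int]:
        return [s.site_id for s in self.sites if modality is None or s.modality == modality]

    @property
    def by_id(self) -> dict[int, SensorSite]:
        return {s.site_id: s for s in self.sites}

    def nearest_neighbor_distances(self, k_candidates: int = 5) -> np.ndarray:
        """Per-site geodesic distance to its nearest neighbor."""
        pos = self.positions()
        tree = cKDTree(pos)
        k = min(k_candidates + 1, len(pos))
        _, idx = tree.query(pos, k=k)
        best = np.full(len(pos), np.inf)
        for col in range(1, k):
            d = surface_distances(self.ellipsoid, pos, pos[idx[:, col]], n_seg=8, iters=120)
            best = np.minimum(best, d)
        return best


def _spiral_init(ellipsoid: EllipsoidSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted generalized-Fibonacci sampling of the truncated surface."""
    a, b, c = ellipsoid.axes
    th_max = float(np.arcsin(np.clip(ellipsoid.z_cut / c, -1, 1)))
    th = np.linspace(-np.pi / 2, th_max, 2048)
    per = np.array([_ellipse_perimeter(a * np.cos(t), b * np.cos(t)) for t in th])
    ds = np.sqrt((0.5 * (a + b) * np.sin(th)) ** 2 + (c * np.cos(th)) ** 2)
    dens = per * ds
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(th))])
    cdf /= cdf[-1]
    q = (np.arange(n) + 0.5) / n
    th_i = np.interp(q, cdf, th)
    phi0 = rng.uniform(0, 2 * np.pi)
    phi_i = phi0 + GOLDEN_ANGLE * np.arange(n)
    pts = np.column_stack(
        [a * np.cos(th_i) * np.cos(phi_i), b * np.cos(th_i) * np.sin(phi_i), c * np.sin(th_i)]
    )
    return pts


def _pack_points(
    ellipsoid: EllipsoidSpec,
    n: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    rel_tol: float = 1e-4,
    n_dense: int = 25000,
) -> np.ndarray:
    """Spread n points evenly over the truncated surface.

    Lloyd (centroidal-Voronoi) iteration against a dense area-weighted surface
    sample equalizes the cells, then a short local-repulsion polish lifts the
    minimum spacing; iteration stops once the minimum pairwise distance stops
    improving (relative change < ``rel_tol``) or the budget is exhausted.
    """
    if n == 1:
        return _spiral_init(ellipsoid, 1, rng)
    area = ellipsoid.surface_area()
    ideal = np.sqrt(2.0 * area / (np.sqrt(3.0) * n))  # hex-lattice spacing at this density
    dense = _spiral_init(ellipsoid, max(n_dense, 60 * n), rng)
    pts = _spiral_init(ellipsoid, n, rng)

    n_lloyd = min(150, max_iter)
    prev_min = 0.0
    for _ in range(n_lloyd):
        tree = cKDTree(pts)
        _, lab = tree.query(dense)
        cent = np.zeros((n, 3))
        cnt = np.zeros(n)
        np.add.at(cent, lab, dense)
        np.add.at(cnt, lab, 1)
        occupied = cnt > 0
        cent[occupied] /= cnt[occupied, None]
        new = pts.copy()
        new[occupied] = cent[occupied]
        pts = ellipsoid.project(new)
        min_nn = float(cKDTree(pts).query(pts, k=2)[0][:, 1].min())
        if prev_min > 0 and abs(min_nn - prev_min) / prev_min < rel_tol:
            break
        prev_min = min_nn

    # repulsion polish toward max-min spacing
    r0 = 1.2 * ideal
    k = min(8, n)
    best = pts.copy()
    best_min = float(cKDTree(pts).query(pts, k=2)[0][:, 1].min())
    stall = 0
    for _ in range(max_iter):
        tree = cKDTree(pts)
        d, idx = tree.query(pts, k=k)
        disp = np.zeros_like(pts)
        for col in range(1, k):
            vec = pts - pts[idx[:, col]]
            dist = d[:, col]
            m = dist < r0
            if not np.any(m):
                continue
            w = (r0 - dist[m]) / r0
            disp[m] += vec[m] / dist[m, None] * w[:, None]
        if not np.any(disp):
            break
        pts = ellipsoid.project(pts + 0.08 * r0 * disp)
        min_nn = float(cKDTree(pts).query(pts, k=2)[0][:, 1].min())
        if min_nn > best_min * (1 + rel_tol):
            best_min = min_nn
            best = pts.copy()
            stall = 0
        else:
            stall += 1
        if stall >= 30:
            break
    return best


def _farthest_point_sample(points: np.ndarray, n_pick: int) -> np.ndarray:
    """Greedy max-min (chord metric) subset; deterministic start at lowest z."""
    start = int(np.lexsort((np.arange(len(points)), points[:, 2]))[0])
    chosen = [start]
    d = np.linalg.norm(points - points[start], axis=1)
    for _ in range(n_pick - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen, dtype=int)


def generate_layout(
    ellipsoid: EllipsoidSpec,
    pitch: float,
    n_electrodes: int,
    n_optical: int,
    seed: int,
    max_iter: int = 500,
    max_petals: int = 6,
) -> SensorLayout:
    """Pack an evenly pitched sensor layout onto the truncated ellipsoid.

    Sites are initialized by an area-weighted spiral and relaxed by local
    repulsion at fixed count; electrodes ("stigmata") are then chosen by
    farthest-point sampling so they cover the surface evenly, and each is
    assigned up to six surrounding optical "petals".
    """
    if pitch <= 0:
        raise PackingError("pitch must be positive")
    n = n_electrodes + n_optical
    if n < 1:
        raise PackingError("at least one site required")
    area = ellipsoid.surface_area()
    cell = np.sqrt(3.0) / 2.0 * pitch**2  # hexagonal packing cell
    if n * cell > 1.05 * area:
        raise PackingError(
            f"cannot pack {n} sites at pitch {pitch} mm: requires ~{n * cell:.1f} mm^2, "
            f"surface offers {area:.1f} mm^2"
        )
    rng = np.random.default_rng(seed)
    pts = _pack_points(ellipsoid, n, rng, max_iter=max_iter)

    elec_idx = _farthest_point_sample(pts, n_electrodes) if n_electrodes else np.array([], dtype=int)
    is_elec = np.zeros(n, dtype=bool)
    is_elec[elec_idx] = True

    normals = ellipsoid.normal(pts)
    sites = [
        SensorSite(
            site_id=i,
            position=pts[i],
            surface_normal=normals[i],
            modality=Modality.ELECTRICAL if is_elec[i] else Modality.OPTICAL,
        )
        for i in range(n)
    ]

    # stigma-petal assignment: up to 6 nearest optical sites within an
    # adjacency radius (~1.9x the realized mean spacing)
    petal_map: dict[int, list[int]] = {}
    opt_idx = np.where(~is_elec)[0]
    if len(opt_idx) and len(elec_idx):
        tree = cKDTree(pts)
        mean_nn = float(np.mean(tree.query(pts, k=2)[0][:, 1])) if n > 1 else pitch
        radius = 1.9 * mean_nn
        opt_tree = cKDTree(pts[opt_idx])
        for e in elec_idx:
            d, j = opt_tree.query(pts[e], k=min(max_petals, len(opt_idx)))
            d = np.atleast_1d(d)
            j = np.atleast_1d(j)
            keep = j[d <= radius]
            petal_map[int(e)] = [int(opt_idx[jj]) for jj in keep]
    else:
        for e in elec_idx:
            petal_map[int(e)] = []

    return SensorLayout(ellipsoid=ellipsoid, sites=sites, nominal_pitch=pitch, petal_map=petal_map)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def mercator_projection(points: np.ndarray, ellipsoid: EllipsoidSpec) -> np.ndarray:
    """Unroll surface points to (longitude_deg, mercator_y).

    Longitude is atan2(y, x) in degrees, range (-180, 180]; the vertical
    coordinate is ln|tan(pi/4 + phi/2)| of the normalized latitude
    phi = asin(z / c), so equal heights share the vertical coordinate.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(np.hypot(p[:, 0], p[:, 1]) == 0):
        raise ProjectionError("longitude undefined for a point on the vertical axis")
    lon = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    lon = np.where(lon <= -180.0, lon + 360.0, lon)
    phi = np.arcsin(np.clip(p[:, 2] / ellipsoid.semi_axis_c, -1.0, 1.0))
    phi = np.clip(phi, -np.pi / 2 + 1e-9, np.pi / 2 - 1e-9)
    y = np.log(np.abs(np.tan(np.pi / 4 + phi / 2)))
    return np.column_stack([lon, y])


def central_projection(points: np.ndarray, ellipsoid: EllipsoidSpec) -> np.ndarray:
    """Azimuthal projection about the apex (lowest pole).

    The projected radius is the geodesic arc distance from the apex and the
    angle is the longitude; the apex itself maps to the origin.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(p[:, 2] > ellipsoid.z_cut + 1e-9 * ellipsoid.semi_axis_c):
        raise ProjectionError("point lies beyond the truncation plane")
    apex = ellipsoid.apex
    out = np.zeros((len(p), 2))
    at_apex = np.linalg.norm(p - apex, axis=1) < 1e-12 * ellipsoid.semi_axis_c
    rest = ~at_apex
    if np.any(rest):
        src = np.broadcast_to(apex, p[rest].shape)
        r = surface_distances(ellipsoid, src, p[rest], n_seg=24, iters=500)
        lon = np.arctan2(p[rest, 1], p[rest, 0])
        out[rest, 0] = r * np.cos(lon)
        out[rest, 1] = r * np.sin(lon)
    return out
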