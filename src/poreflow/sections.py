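"""Planar cross-sections of the channel surface and their metrics.

At a centerline point ``p`` with tangent ``t_p`` the channel surface is cut
by the orthogonal plane through ``p``; the intersection points form the raw
section.  A proximity graph over the points (edge when closer than a
threshold) is filtered by visibility: rays from ``p`` sweep the plane and
collect, per ray, the component of the closest in-tolerance point, yielding
the contour actually visible from the centerline.  Per-section metrics are
the closest/farthest contour distances, a least-squares ellipse fit and its
eccentricity e = sqrt(1 - b^2/a^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .channel_surface import ChannelSurface
from .errors import ValidationError
from .structure_io import SurfaceMesh

DEDUP_TOL = 1e-6


@dataclass
class Section:
    """One planar cut: raw points (2D in-plane + 3D), proximity graph labels
    and the visible subset."""

    anchor: np.ndarray            # p (3,)
    normal: np.ndarray            # t_p (3,) unit
    basis: np.ndarray             # (2, 3) in-plane orthonormal vectors
    points2d: np.ndarray          # (k, 2)
    points3d: np.ndarray          # (k, 3)
    empty: bool = False
    component: np.ndarray | None = None   # proximity-graph component labels
    threshold: float | None = None
    visible: np.ndarray | None = None     # indices into points2d


@dataclass
class SectionMetrics:
    d_min: float
    d_max: float
    a: float | None            # ellipse semi-major
    b: float | None            # ellipse semi-minor
    center: np.ndarray | None
    orientation: float | None
    eccentricity: float | None
    n_visible: int
    n_components: int


def plane_basis(normal: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal in-plane basis for a unit normal: the seed
    axis is the Cartesian axis least aligned with the normal."""
    t = np.asarray(normal, float)
    t = t / np.linalg.norm(t)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(t)))] = 1.0
    e1 = np.cross(t, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return np.vstack([e1, e2])


def cut_section(cs: ChannelSurface | SurfaceMesh, p: np.ndarray,
                t_p: np.ndarray, dedup_tol: float = DEDUP_TOL) -> Section:
    """Intersect the (channel) surface triangles with the plane through
    ``p`` orthogonal to ``t_p``.

    Returns all triangle/plane segment endpoints, deduplicated, in a
    deterministic in-plane basis.  A plane missing the surface yields an
    empty (flagged) section, not an error.
    """
    p = np.asarray(p, float).reshape(3)
    t = np.asarray(t_p, float).reshape(3)
    norm = np.linalg.norm(t)
    if abs(norm - 1.0) > 1e-6:
        raise ValidationError("t_p must be a unit vector")
    t = t / norm
    if isinstance(cs, ChannelSurface):
        tris = cs.mesh.vertices[cs.triangles]
    else:
        tris = cs.vertices[cs.triangles]

    basis = plane_basis(t)
    d = np.einsum("ijk,k->ij", tris - p, t)      # signed dists (m, 3)
    segs = _triangle_plane_segments(tris, d)
    if len(segs) == 0:
        return Section(p, t, basis, np.empty((0, 2)), np.empty((0, 3)), empty=True)
    pts = segs.reshape(-1, 3)
    # dedupe on a tolerance lattice
    key = np.round(pts / dedup_tol).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    pts = pts[np.sort(idx)]
    pts2 = (pts - p) @ basis.T
    return Section(p, t, basis, pts2, pts)


def _triangle_plane_segments(tris: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Segment endpoints of each triangle crossing the plane (k, 2, 3)."""
    out = []
    eps = 1e-9
    # triangles touching or crossing the plane; fully coplanar ones are
    # degenerate for a transversal cut and skipped
    touching = (d.min(axis=1) <= eps) & (d.max(axis=1) >= -eps)
    coplanar = (np.abs(d) <= eps).all(axis=1)
    crossing = touching & ~coplanar
    for tri, dd in zip(tris[crossing], d[crossing]):
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            di, dj = dd[i], dd[j]
            if (di > eps and dj < -eps) or (di < -eps and dj > eps):
                lam = di / (di - dj)
                pts.append(tri[i] + lam * (tri[j] - tri[i]))
            elif abs(di) <= eps:
                pts.append(tri[i])
        if len(pts) >= 2 and np.linalg.norm(pts[1] - pts[0]) > eps:
            out.append(np.array(pts[:2]))
    return np.array(out).reshape(-1, 2, 3) if out else np.empty((0, 2, 3))


def default_threshold(points2d: np.ndarray) -> float:
    """3x the median nearest-neighbor distance: scale-free and robust to
    mesh resolution."""
    if len(points2d) < 2:
        return 1.0
    tree = cKDTree(points2d)
    d, _ = tree.query(points2d, k=2)
    med = float(np.median(d[:, 1]))
    return 3.0 * max(med, 1e-9)


def section_graph(section: Section, threshold: float | None = None) -> np.ndarray:
    """Proximity graph over the section points: edge when the in-plane
    distance is below ``threshold``.  Stores and returns component labels."""
    if threshold is None:
        threshold = default_threshold(section.points2d)
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    k = len(section.points2d)
    if k == 0:
        section.component = np.empty(0, int)
        section.threshold = threshold
        return section.component
    tree = cKDTree(section.points2d)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    mat = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(k, k)
    )
    _, labels = connected_components(mat, directed=False)
    section.component = labels
    section.threshold = threshold
    return labels


def visible_contour(section: Section, n_rays: int = 360) -> np.ndarray:
    """Visibility filter: for each of ``n_rays`` uniform in-plane rays from
    the anchor, the closest point lying within the proximity threshold of
    the ray contributes its proximity-graph component; the union of the
    collected components is the visible contour.  Stores and returns
    indices into the section points.

    Closeness to a ray is the perpendicular in-plane distance (capped by
    the same threshold as the proximity graph), so the result is stable in
    ``n_rays`` once the rays are denser than the contour sampling.
    """
    if n_rays < 8:
        raise ValidationError("n_rays must be >= 8")
    if section.component is None:
        section_graph(section)
    k = len(section.points2d)
    if k == 0:
        section.visible = np.empty(0, int)
        return section.visible
    pts = section.points2d
    rho = np.linalg.norm(pts, axis=1)
    tol = float(section.threshold)
    ang = 2 * np.pi * np.arange(n_rays) / n_rays
    u = np.column_stack([np.cos(ang), np.sin(ang)])      # (r, 2)
    proj = pts @ u.T                                      # (k, r) along-ray
    perp2 = rho[:, None] ** 2 - proj**2
    close = (proj > 0) & (perp2 <= tol**2)
    masked = np.where(close, rho[:, None], np.inf)
    hits = np.argmin(masked, axis=0)                      # per-ray nearest
    ok = np.isfinite(masked[hits, np.arange(n_rays)])
    selected = np.unique(section.component[hits[ok]])
    visible = np.flatnonzero(np.isin(section.component, selected))
    section.visible = visible
    return visible


def fit_ellipse(points2d: np.ndarray):
    """Least-squares ellipse fit (conic with ellipse constraint).

    Returns (center(2,), a, b, orientation) with a >= b, or None if the fit
    fails or the points are degenerate.
    """
    from skimage.measure import EllipseModel

    data = np.asarray(points2d, float)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(data)
        if not model:
            return None
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # older scikit-image
        model = EllipseModel()
        if not model.estimate(data):
            return None
        xc, yc, a, b, theta = model.params
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        return None
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    return np.array([xc, yc]), float(a), float(b), float(theta % np.pi)


def section_metrics(section: Section, n_rays: int = 360) -> SectionMetrics:
    """Closest/farthest visible-contour distances plus the best-fit ellipse
    and its eccentricity (ellipse omitted below 5 visible points)."""
    if section.visible is None:
        visible_contour(section, n_rays=n_rays)
    vis = section.visible
    if len(vis) == 0:
        raise ValidationError("empty visible set: no metrics")
    pts = section.points2d[vis]
    rho = np.linalg.norm(pts, axis=1)
    d_min = float(rho.min())
    d_max = float(rho.max())
    n_comp = len(np.unique(section.component[vis]))
    a = b = ecc = orient = None
    center = None
    if len(vis) >= 5:
        fit = fit_ellipse(pts)
        if fit is not None:
            center, a, b, orient = fit
            ecc = float(np.sqrt(max(0.0, 1.0 - (b / a) ** 2)))
    return SectionMetrics(d_min, d_max, a, b, center, orient, ecc,
                          n_visible=len(vis), n_components=n_comp)
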