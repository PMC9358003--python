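"""Centerline between the pruned path's endpoints, with Frenet frames,
curvature, torsion, local radius and z-binned radius profiles.

The centerline is the minimum-cost path on the skeleton graph with edge
cost ``edge_length / mean(clearance)^2`` — inverse-squared clearance pulls
the path toward maximal inscribed spheres — smoothed by a moving average
and resampled at uniform arclength.  Curvature and torsion come from
Savitzky-Golay derivative stencils on the arclength-parametrized points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .channel_surface import ChannelSurface
from .errors import ConnectivityError, ValidationError
from .skeleton import SkeletonGraph

#: Curvature below which the normal/binormal are undefined and the frame is
#: flagged (torsion reported as 0 there).
KAPPA_TOL = 1e-9

#: Exponent of the clearance penalty in the path cost.
CLEARANCE_EXPONENT = 2.0


@dataclass
class Centerline:
    """Uniform-arclength sampled curve with Frenet data."""

    points: np.ndarray        # (m, 3)
    arclength: np.ndarray     # (m,)
    tangents: np.ndarray      # (m, 3) unit
    normals: np.ndarray       # (m, 3) unit where defined
    binormals: np.ndarray     # (m, 3)
    curvature: np.ndarray     # (m,) >= 0
    torsion: np.ndarray       # (m,)
    frame_defined: np.ndarray  # (m,) bool; False where curvature ~ 0
    radius: np.ndarray | None = None
    source_nodes: np.ndarray | None = None   # skeleton node ids of the raw path
    step: float = 0.5

    def __len__(self) -> int:
        return len(self.points)

    def reversed(self) -> "Centerline":
        r = None if self.radius is None else self.radius[::-1].copy()
        total = self.arclength[-1]
        return Centerline(
            self.points[::-1].copy(), (total - self.arclength)[::-1].copy(),
            -self.tangents[::-1].copy(), self.normals[::-1].copy(),
            -self.binormals[::-1].copy(), self.curvature[::-1].copy(),
            self.torsion[::-1].copy(), self.frame_defined[::-1].copy(),
            radius=r, source_nodes=None if self.source_nodes is None
            else self.source_nodes[::-1].copy(), step=self.step,
        )


def compute_centerline(g: SkeletonGraph, source: int, target: int,
                       step: float = 0.5, smooth_window: int = 5) -> Centerline:
    """Clearance-weighted shortest path from ``source`` to ``target``,
    smoothed (moving average, window ``smooth_window``) and resampled at
    uniform arclength ``step``."""
    if step <= 0:
        raise ValidationError("step must be > 0")
    if source == target:
        raise ConnectivityError("source and target coincide")
    n = g.n_nodes
    if not (0 <= source < n and 0 <= target < n):
        raise ConnectivityError("source/target not in skeleton")
    lengths = g.edge_lengths()
    clear = np.maximum(g.clearance, 1e-3)
    pair_clear = 0.5 * (clear[g.edges[:, 0]] + clear[g.edges[:, 1]])
    cost = lengths / pair_clear**CLEARANCE_EXPONENT
    mat = csr_matrix(
        (np.concatenate([cost, cost]),
         (np.concatenate([g.edges[:, 0], g.edges[:, 1]]),
          np.concatenate([g.edges[:, 1], g.edges[:, 0]]))),
        shape=(n, n),
    )
    dist, pred = dijkstra(mat, indices=source, return_predecessors=True)
    if not np.isfinite(dist[target]):
        raise ConnectivityError("source and target are not connected")
    path = [target]
    while path[-1] != source:
        path.append(int(pred[path[-1]]))
    path.reverse()
    path = np.array(path, int)

    pts = _moving_average(g.positions[path], smooth_window)
    pts, arc = _resample(pts, step)
    tangents, normals, binormals, kappa, tau, defined = frenet_from_points(pts, step)
    return Centerline(pts, arc, tangents, normals, binormals, kappa, tau,
                      defined, source_nodes=path, step=step)


def _moving_average(pts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a window that shrinks at the ends (the
    endpoints stay close to the raw entrance/exit nodes)."""
    if window <= 1 or len(pts) <= 2:
        return pts
    half = window // 2
    out = np.empty_like(pts)
    for i in range(len(pts)):
        a = max(0, i - half)
        b = min(len(pts), i + half + 1)
        out[i] = pts[a:b].mean(axis=0)
    return out


def _resample(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    pts = pts[keep]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 1e-9:
        raise ConnectivityError("degenerate (zero-length) centerline")
    m = max(int(round(total / step)), 4)
    snew = np.linspace(0.0, total, m + 1)
    out = np.column_stack([np.interp(snew, s, pts[:, k]) for k in range(3)])
    return out, snew


def frenet_from_points(pts: np.ndarray, step: float
                       ) -> tuple[np.ndarray, ...]:
    """Frenet frames, curvature and torsion of a uniform-arclength polyline.

    Derivatives use Savitzky-Golay stencils (local quartic fit, window
    adapted to the point count); curvature kappa = |c' x c''| / |c'|^3,
    torsion tau = (c' x c'') . c''' / |c' x c''|^2.
    """
    m = len(pts)
    if m < 5:
        raise ValidationError("frenet needs >= 5 points")
    window = min(m if m % 2 == 1 else m - 1, 11)
    poly = min(4, window - 1)
    d1 = savgol_filter(pts, window, poly, deriv=1, delta=step, axis=0, mode="interp")
    d2 = savgol_filter(pts, window, poly, deriv=2, delta=step, axis=0, mode="interp")
    d3 = savgol_filter(pts, window, poly, deriv=3, delta=step, axis=0, mode="interp")

    speed = np.linalg.norm(d1, axis=1)
    speed = np.maximum(speed, 1e-12)
    tangents = d1 / speed[:, None]
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)
    kappa = cross_norm / speed**3
    defined = kappa >= KAPPA_TOL
    tau = np.zeros(m)
    ok = cross_norm > 1e-12
    tau[ok] = np.einsum("ij,ij->i", cross[ok], d3[ok]) / cross_norm[ok] ** 2
    tau[~defined] = 0.0

    normals = np.zeros_like(pts)
    binormals = np.zeros_like(pts)
    raw_n = d2 - np.einsum("ij,ij->i", d2, tangents)[:, None] * tangents
    nn = np.linalg.norm(raw_n, axis=1)
    good = defined & (nn > 1e-12)
    normals[good] = raw_n[good] / nn[good, None]
    binormals[good] = np.cross(tangents[good], normals[good])
    return tangents, normals, binormals, kappa, tau, defined


def local_radius(c: Centerline, cs: ChannelSurface,
                 brute_force: bool = False) -> np.ndarray:
    """Per centerline point: distance to the nearest channel-surface vertex.

    Stored on the centerline (``c.radius``) and returned.
    """
    verts = cs.vertices()
    if len(verts) == 0:
        raise ValidationError("empty channel surface")
    if brute_force:
        d = np.linalg.norm(c.points[:, None, :] - verts[None], axis=2).min(axis=1)
    else:
        tree = cKDTree(verts)
        d, _ = tree.query(c.points)
    c.radius = np.asarray(d, float)
    return c.radius


def radius_profile(frames: list[tuple[np.ndarray, np.ndarray]],
                   bin_width: float = 1.0):
    """Bin per-frame (z, radius) samples along z.

    Returns a DataFrame with columns ``z_bin`` (bin center), ``mean_radius``,
    ``sd`` (sample SD; 0 where a bin holds a single sample), ``n``.  Empty
    bins are omitted.
    """
    import pandas as pd

    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    zs, rs = [], []
    for z, r in frames:
        z = np.asarray(z, float).reshape(-1)
        r = np.asarray(r, float).reshape(-1)
        if len(z) != len(r):
            raise ValidationError("z and radius sample lengths differ")
        zs.append(z)
        rs.append(r)
    if not zs or sum(len(z) for z in zs) == 0:
        raise ValidationError("no radius samples")
    z = np.concatenate(zs)
    r = np.concatenate(rs)
    idx = np.floor(z / bin_width).astype(int)
    df = pd.DataFrame({"bin": idx, "r": r})
    out = df.groupby("bin")["r"].agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    out["z_bin"] = (out["bin"] + 0.5) * bin_width
    out = out.rename(columns={"mean": "mean_radius", "std": "sd", "count": "n"})
    return out[["z_bin", "mean_radius", "sd", "n"]].sort_values("z_bin").reset_index(drop=True)
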