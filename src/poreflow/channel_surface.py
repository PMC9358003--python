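"""Molecular surface construction and channel-surface extraction.

The internal surface is the union-of-balls implicit surface
``min_i (|x - c_i| - r_i) = 0`` triangulated by marching cubes: for a bare
cylindrical lumen of wall-ball radius ``r`` at axis radius ``R`` it yields
lumen radius ``R - r``, consistent with how a rolling-probe surface traces
a tight tube.  An externally computed molecular-surface mesh (OFF/PLY) may
be supplied instead and is used identically downstream.

The channel surface is the subset of mesh triangles whose barycenter lies
inside some channel tetrahedron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .alpha_complex import Tetrahedralization
from .cavity_flow import CavityComponent
from .errors import NoOverlapError, ResolutionError, ValidationError
from .structure_io import AtomSet, SurfaceMesh

#: Containment tolerance for the barycentric point-in-tetrahedron test.
CONTAIN_TOL = 1e-9


@dataclass
class ChannelSurface:
    """Triangles of a :class:`SurfaceMesh` assigned to the channel."""

    mesh: SurfaceMesh
    triangle_ids: np.ndarray      # indices into mesh.triangles
    barycenters: np.ndarray       # (k, 3)
    nearest_atom: np.ndarray      # (k,) atom ids (argmin of distance-to-surface)

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.triangles[self.triangle_ids]

    def vertex_ids(self) -> np.ndarray:
        return np.unique(self.triangles)

    def vertices(self) -> np.ndarray:
        return self.mesh.vertices[self.vertex_ids()]

    def submesh(self) -> SurfaceMesh:
        """Channel triangles as a standalone mesh (reindexed vertices)."""
        vid = self.vertex_ids()
        remap = np.full(self.mesh.n_vertices, -1, dtype=int)
        remap[vid] = np.arange(len(vid))
        return SurfaceMesh(self.mesh.vertices[vid], remap[self.triangles])


def build_surface(atoms: AtomSet, probe: float = 1.4,
                  grid_spacing: float = 0.5) -> SurfaceMesh:
    """Marching-cubes triangulation of the union-of-balls surface.

    The signed field ``f(x) = min_i(|x - c_i| - r_i)`` is sampled on a
    regular grid and the zero level set extracted; vertices are not snapped
    to the analytic surface, so accuracy is controlled solely by
    ``grid_spacing``.
    """
    if len(atoms) == 0:
        raise ValidationError("empty AtomSet")
    if grid_spacing <= 0:
        raise ValidationError("grid_spacing must be > 0")
    if grid_spacing > float(atoms.radii.min()):
        raise ResolutionError(
            f"grid spacing {grid_spacing} exceeds smallest atom radius "
            f"{atoms.radii.min():.3f}: surface unresolvable"
        )
    h = float(grid_spacing)
    margin = float(atoms.radii.max()) + 4 * h
    lo = atoms.centers.min(axis=0) - margin
    hi = atoms.centers.max(axis=0) + margin
    shape = np.ceil((hi - lo) / h).astype(int) + 1

    big = 4 * h  # positive filler far from all atoms; sign is all that matters
    field = np.full(shape, big)
    box_r = atoms.radii + 3 * h
    idx_lo = np.maximum(np.floor((atoms.centers - box_r[:, None] - lo) / h).astype(int), 0)
    idx_hi = np.minimum(np.ceil((atoms.centers + box_r[:, None] - lo) / h).astype(int) + 1,
                        shape)
    for c, r, a, b in zip(atoms.centers, atoms.radii, idx_lo, idx_hi):
        gx = lo[0] + h * np.arange(a[0], b[0])
        gy = lo[1] + h * np.arange(a[1], b[1])
        gz = lo[2] + h * np.arange(a[2], b[2])
        d = np.sqrt(
            (gx[:, None, None] - c[0]) ** 2
            + (gy[None, :, None] - c[1]) ** 2
            + (gz[None, None, :] - c[2]) ** 2
        ) - r
        sub = field[a[0]:b[0], a[1]:b[1], a[2]:b[2]]
        np.minimum(sub, d, out=sub)

    verts, faces, normals, _ = marching_cubes(field, level=0.0, spacing=(h, h, h))
    mesh = SurfaceMesh(verts + lo, faces, vertex_normals=normals)
    # drop degenerate triangles (marching cubes can emit zero-area slivers)
    good = mesh.triangle_areas() > 1e-12
    mesh.triangles = mesh.triangles[good]
    return mesh


def points_in_tets(points: np.ndarray, t: Tetrahedralization,
                   tet_ids: np.ndarray, brute_force: bool = False) -> np.ndarray:
    """For each point, True iff it lies inside some listed tetrahedron.

    Candidate tetrahedra come from a k-d tree over tetrahedron centroids
    (query radius = largest centroid-to-vertex distance); ``brute_force``
    tests every point against every tetrahedron instead (oracle path).
    """
    points = np.asarray(points, float).reshape(-1, 3)
    tet_ids = np.asarray(tet_ids, int)
    verts = t.points[t.tets[tet_ids]]          # (m, 4, 3)
    centroids = verts.mean(axis=1)
    inside = np.zeros(len(points), dtype=bool)
    if len(tet_ids) == 0 or len(points) == 0:
        return inside

    if brute_force:
        cand_lists = [np.arange(len(points))] * len(tet_ids)
    else:
        reach = np.linalg.norm(verts - centroids[:, None], axis=2).max(axis=1)
        tree = cKDTree(points)
        cand_lists = tree.query_ball_point(centroids, r=reach + 1e-9)

    # barycentric containment, vectorized over the candidate points of each tet
    a = verts[:, 0]
    m = np.stack([verts[:, 1] - a, verts[:, 2] - a, verts[:, 3] - a], axis=2)  # (m,3,3)
    minv = np.linalg.inv(m)
    for k, cands in enumerate(cand_lists):
        if len(cands) == 0:
            continue
        cands = np.asarray(cands, int)
        cands = cands[~inside[cands]]
        if len(cands) == 0:
            continue
        lam = (points[cands] - a[k]) @ minv[k].T
        ok = (lam >= -CONTAIN_TOL).all(axis=1) & (lam.sum(axis=1) <= 1 + CONTAIN_TOL)
        inside[cands[ok]] = True
    return inside


def nearest_atoms(points: np.ndarray, centers: np.ndarray,
                  radii: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per point: atom minimizing the distance to the ball surface
    ``|p - c_i| - r_i`` (exact, k-d tree accelerated)."""
    points = np.asarray(points, float).reshape(-1, 3)
    tree = cKDTree(centers)
    d1, i1 = tree.query(points)
    rmax = float(radii.max())
    best_id = i1.copy()
    best_d = d1 - radii[i1]
    # any strictly better atom j satisfies |p - c_j| <= d1 + rmax
    cand_lists = tree.query_ball_point(points, r=d1 + rmax + 1e-9)
    for i, cands in enumerate(cand_lists):
        cands = np.asarray(cands, int)
        d = np.linalg.norm(centers[cands] - points[i], axis=1) - radii[cands]
        k = int(np.argmin(d))
        if d[k] < best_d[i]:
            best_d[i] = d[k]
            best_id[i] = cands[k]
    return best_id, best_d


def extract_channel_surface(mesh: SurfaceMesh, channel: CavityComponent,
                            t: Tetrahedralization, atoms: AtomSet | None = None,
                            brute_force: bool = False) -> ChannelSurface:
    """Mesh triangles whose barycenter lies inside a channel tetrahedron.

    Raises :class:`NoOverlapError` when no triangle qualifies (mesh and
    channel from inconsistent inputs).
    """
    bary = mesh.barycenters()
    inside = points_in_tets(bary, t, channel.tet_ids, brute_force=brute_force)
    ids = np.flatnonzero(inside)
    if len(ids) == 0:
        raise NoOverlapError("no mesh triangle barycenter falls inside the channel")
    if atoms is not None:
        centers, radii = atoms.centers, atoms.radii
    else:
        centers, radii = t.points, np.sqrt(t.weights) - t.probe
    near, _ = nearest_atoms(bary[ids], centers, radii)
    return ChannelSurface(mesh=mesh, triangle_ids=ids, barycenters=bary[ids],
                          nearest_atom=near)


def annotate_lumen(cs: ChannelSurface, atoms: AtomSet):
    """Map each channel triangle to its nearest atom's labels and summarize
    the residues lining the lumen.

    Returns ``(per_triangle, summary)`` DataFrames; unlabeled atoms appear
    as ``UNK``.
    """
    import pandas as pd

    n = len(cs.triangle_ids)
    if atoms.labels is None:
        per = pd.DataFrame({
            "triangle_id": cs.triangle_ids,
            "atom_id": cs.nearest_atom,
            "atom_name": ["UNK"] * n,
            "res_name": ["UNK"] * n,
            "res_id": [-1] * n,
            "chain": ["UNK"] * n,
        })
    else:
        lab = atoms.labels.iloc[cs.nearest_atom].reset_index(drop=True)
        per = pd.DataFrame({
            "triangle_id": cs.triangle_ids,
            "atom_id": cs.nearest_atom,
            "atom_name": lab["atom_name"].values,
            "res_name": lab["res_name"].values,
            "res_id": lab["res_id"].values,
            "chain": lab["chain"].values,
        })
    summary = (
        per.groupby(["res_name", "res_id", "chain"], dropna=False)
        .size()
        .reset_index(name="n_triangles")
        .sort_values("n_triangles", ascending=False)
        .reset_index(drop=True)
    )
    return per, summary
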