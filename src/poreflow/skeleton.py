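"""Channel skeleton and core-path pruning.

The skeleton is the Delaunay-dual graph of the channel tetrahedra: one node
per tetrahedron at its orthocenter (clamped to the tetrahedron, barycenter
fallback), edges between face-adjacent channel tetrahedra, per-node
clearance = distance to the nearest probe-inflated atom surface.  An
externally computed skeleton can be imported from CSV and fed to the same
pruning machinery.

Pruning elects the core path: among the shortest paths (edge-count metric)
connecting every pair of skeleton nodes, the one maximizing the score

    s(path) = length(path)^2 / max(tortuousness(path), eps)

where ``length`` is the number of edges and ``tortuousness`` is the mean
distance of the path's nodes from the straight line through its endpoints.
Straight long paths score high; short or curved paths score low.
"""

from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alpha_complex import Tetrahedralization
from .cavity_flow import CavityComponent
from .channel_surface import nearest_atoms
from .errors import DegeneratePathError, EndpointError, ValidationError

logger = logging.getLogger("poreflow")

#: Floor for the tortuousness denominator: keeps rectilinear paths finite
#: while preserving their dominance.  Set two orders of magnitude above the
#: degeneracy-jitter scale (1e-6 A) so that paths straight up to jitter
#: noise are treated as exactly straight and the length term decides.
TORTUOUSNESS_EPS = 1e-4

#: Above this node count, pruning scores one deterministic BFS shortest path
#: per pair instead of minimizing tortuousness over the whole shortest-path
#: DAG (the two coincide on trees, where shortest paths are unique).
EXACT_DAG_MAX_NODES = 200


@dataclass
class SkeletonGraph:
    """Undirected spatial graph: node positions (n, 3), per-node clearance
    radii, and an (e, 2) edge array."""

    positions: np.ndarray
    clearance: np.ndarray
    edges: np.ndarray
    tet_ids: np.ndarray | None = None   # originating tetrahedron per node

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.clearance = np.asarray(self.clearance, float).reshape(-1)
        self.edges = np.asarray(self.edges, int).reshape(-1, 2)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValidationError("self-loop in skeleton edges")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return [sorted(nbrs) for nbrs in adj]

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(
            self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]], axis=1
        )


@dataclass
class SkeletonPath:
    """Ordered node path with its pruning score."""

    node_ids: np.ndarray
    length: int                 # edge count
    tortuousness: float
    score: float


def build_skeleton(channel: CavityComponent, t: Tetrahedralization) -> SkeletonGraph:
    """Delaunay-dual skeleton of the channel component.

    Nodes sit at tetrahedron orthocenters when those fall inside their
    tetrahedron, else at barycenters; only the largest connected component
    is kept (discards are logged).
    """
    from .channel_surface import points_in_tets

    ids = np.asarray(channel.tet_ids, int)
    verts = t.points[t.tets[ids]]
    bary = verts.mean(axis=1)
    pos = bary.copy()
    # Orthocenters are the power-diagram vertices, i.e. the medial points of
    # the cavity; use them whenever they fall inside the channel region
    # (their own tetrahedron or any other member), else the barycenter.
    ok = points_in_tets(t.orthocenters[ids], t, ids)
    pos[ok] = t.orthocenters[ids[ok]]

    index_of = {int(tid): i for i, tid in enumerate(ids)}
    edges = []
    for i, tid in enumerate(ids):
        for nbr in t.neighbors[tid]:
            j = index_of.get(int(nbr))
            if j is not None and j > i:
                edges.append((i, j))
    edges = np.array(edges, int).reshape(-1, 2)

    _, clearance = nearest_atoms(pos, t.points, np.sqrt(t.weights))
    g = SkeletonGraph(pos, clearance, edges, tet_ids=ids)
    return _largest_component(g)


def _largest_component(g: SkeletonGraph) -> SkeletonGraph:
    labels = np.full(g.n_nodes, -1, int)
    adj = g.adjacency()
    comp = 0
    for seed in range(g.n_nodes):
        if labels[seed] != -1:
            continue
        queue = deque([seed])
        labels[seed] = comp
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if labels[v] == -1:
                    labels[v] = comp
                    queue.append(v)
        comp += 1
    if comp <= 1:
        return g
    sizes = np.bincount(labels)
    keep = int(np.argmax(sizes))
    logger.info("skeleton: keeping largest component (%d of %d nodes)",
                sizes[keep], g.n_nodes)
    mask = labels == keep
    remap = np.cumsum(mask) - 1
    edges = g.edges[mask[g.edges[:, 0]] & mask[g.edges[:, 1]]]
    return SkeletonGraph(
        g.positions[mask], g.clearance[mask], remap[edges],
        tet_ids=None if g.tet_ids is None else g.tet_ids[mask],
    )


def path_tortuousness(positions: np.ndarray) -> float:
    """Mean distance of ALL path nodes (endpoints included) from the
    infinite straight line through the first and last node."""
    p = np.asarray(positions, float).reshape(-1, 3)
    if len(p) < 2:
        raise EndpointError("tortuousness needs >= 2 nodes")
    d = p[-1] - p[0]
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise EndpointError("coincident path endpoints")
    u = d / norm
    q = p - p[0]
    perp = q - np.outer(q @ u, u)
    return float(np.mean(np.linalg.norm(perp, axis=1)))


def path_score(length: int, tortuousness: float,
               eps: float = TORTUOUSNESS_EPS) -> float:
    """Core-path score: edge count squared over floored tortuousness."""
    if length <= 0:
        return 0.0
    return float(length) ** 2 / max(float(tortuousness), eps)


def score_path(g: SkeletonGraph, node_ids) -> SkeletonPath:
    node_ids = np.asarray(node_ids, int)
    length = len(node_ids) - 1
    if length <= 0:
        return SkeletonPath(node_ids, 0, 0.0, 0.0)
    tort = path_tortuousness(g.positions[node_ids])
    return SkeletonPath(node_ids, length, tort, path_score(length, tort))


def prune_skeleton(g: SkeletonGraph) -> SkeletonPath:
    """Max-score shortest path over all node pairs.

    For every pair the shortest path (edge-count metric) with minimum
    tortuousness is scored; ties between pairs break toward the longer
    path, then the lexicographically smallest endpoint pair.

    Single-edge paths are excluded from the election (their tortuousness is
    identically zero by construction, which would let any trivial path
    outscore every real one) unless the graph admits nothing longer.
    """
    n = g.n_nodes
    if n < 2:
        raise DegeneratePathError("skeleton has a single node")
    adj = g.adjacency()
    if n <= EXACT_DAG_MAX_NODES:
        return _prune_exact(g, adj)
    return _prune_bfs_tree(g, adj)


def _bfs_all(adj: list[list[int]], n: int) -> np.ndarray:
    dist = np.full((n, n), -1, dtype=np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[s, v] < 0:
                    dist[s, v] = dist[s, u] + 1
                    queue.append(v)
    if np.any(dist < 0):
        raise ValidationError("skeleton graph not connected")
    return dist


def _prune_exact(g: SkeletonGraph, adj: list[list[int]]) -> SkeletonPath:
    """Exact per-pair minimization of tortuousness over the shortest-path
    DAG, then global score maximization."""
    n = g.n_nodes
    pos = g.positions
    dist = _bfs_all(adj, n)
    best: tuple[float, int, tuple[int, int]] | None = None
    best_key = None
    min_len = 2 if int(dist.max()) >= 2 else 1
    for s in range(n):
        ds = dist[s]
        for t in range(s + 1, n):
            L = int(dist[s][t])
            if L < min_len:
                continue
            dt = dist[t]
            # nodes on some s-t shortest path, grouped by BFS layer
            on = np.flatnonzero(ds + dt == L)
            line_dist = _dist_to_line(pos[on], pos[s], pos[t])
            w = {int(u): float(d) for u, d in zip(on, line_dist)}
            # DP over layers
            dp = {s: w[s]}
            choice: dict[int, int] = {}
            order = sorted((int(u) for u in on), key=lambda u: int(ds[u]))
            for u in order:
                if u == s:
                    continue
                lvl = int(ds[u])
                cands = [v for v in adj[u] if v in w and ds[v] == lvl - 1 and v in dp]
                prev = min(cands, key=lambda v: (dp[v], v))
                dp[u] = w[u] + dp[prev]
                choice[u] = prev
            tort = dp[t] / (L + 1)
            score = path_score(L, tort)
            key = (score, L, (-s, -t))
            if best_key is None or key > best_key:
                best_key = key
                path = [t]
                while path[-1] != s:
                    path.append(choice[path[-1]])
                best = (tort, L, tuple(reversed(path)))
    tort, L, path = best
    return SkeletonPath(np.array(path, int), L, tort, path_score(L, tort))


def _dist_to_line(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        return np.linalg.norm(p - a, axis=1)
    u = d / norm
    q = p - a
    return np.linalg.norm(q - np.outer(q @ u, u), axis=1)


def _prune_bfs_tree(g: SkeletonGraph, adj: list[list[int]]) -> SkeletonPath:
    """One canonical shortest path per pair (exact on trees), scored with a
    vectorized ancestor sweep per source.

    The canonical path minimizes (edge count, Euclidean length)
    lexicographically — encoded as a single Dijkstra weight ``M + length``
    with ``M`` larger than any possible total length — which keeps the path
    tight against the straight chord in tube-like skeletons.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra

    n = g.n_nodes
    pos = g.positions
    best_key = None
    best_pair = None
    # diameter 1 iff the graph is complete; only then are 1-edge paths eligible
    min_len = 1 if len(g.edges) == n * (n - 1) // 2 else 2
    lengths = g.edge_lengths()
    big = float(n) * float(lengths.max() if len(lengths) else 1.0) + 1.0
    w = big + lengths
    rows = np.concatenate([g.edges[:, 0], g.edges[:, 1]])
    cols = np.concatenate([g.edges[:, 1], g.edges[:, 0]])
    mat = csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))
    mat.sort_indices()
    dists, parents = dijkstra(mat, return_predecessors=True)
    if not np.all(np.isfinite(dists)):
        raise ValidationError("skeleton graph not connected")
    hops = np.floor(dists / big).astype(int)
    for s in range(n):
        parent = parents[s]
        parent[s] = s
        depth_all = hops[s]
        # each unordered pair once (tree paths are symmetric): targets t >= s
        targets = np.arange(s, n)
        depth = depth_all[targets]
        dmax = int(depth.max()) if len(depth) else 0
        # ancestor stack: anc[k] = k-th ancestor of each target (clamped at s)
        anc = np.empty((dmax + 1, len(targets)), int)
        anc[0] = targets
        for k in range(1, dmax + 1):
            anc[k] = parent[anc[k - 1]]
        pts = pos[anc]                       # (dmax+1, m, 3)
        d = pos[targets] - pos[s]
        norm = np.linalg.norm(d, axis=1)
        norm[norm < 1e-12] = 1.0
        u = d / norm[:, None]
        q = pts - pos[s]
        proj = np.einsum("knd,nd->kn", q, u)
        perp = q - proj[..., None] * u[None]
        dl = np.linalg.norm(perp, axis=2)    # (dmax+1, m)
        valid = np.arange(dmax + 1)[:, None] <= depth[None, :]
        tort = (dl * valid).sum(axis=0) / (depth + 1)
        with np.errstate(divide="ignore"):
            scores = depth.astype(float) ** 2 / np.maximum(tort, TORTUOUSNESS_EPS)
        for j in np.flatnonzero(depth >= min_len):
            key = (scores[j], int(depth[j]), (-s, -int(targets[j])))
            if best_key is None or key > best_key:
                best_key = key
                best_pair = (s, int(targets[j]), parent.copy())
    s, t, parent = best_pair
    path = [t]
    while path[-1] != s:
        path.append(int(parent[path[-1]]))
    path.reverse()
    return score_path(g, path)


# ---------------------------------------------------------------------------
# CSV import/export (external skeletons feed the same pruning machinery)
# ---------------------------------------------------------------------------

def write_skeleton_csv(g: SkeletonGraph, node_path: str | Path,
                       edge_path: str | Path) -> None:
    with open(node_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "x", "y", "z", "clearance"])
        for i, (p, c) in enumerate(zip(g.positions, g.clearance)):
            wr.writerow([i, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", f"{c:.6f}"])
    with open(edge_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id_a", "id_b"])
        for a, b in g.edges:
            wr.writerow([a, b])


def read_skeleton_csv(node_path: str | Path, edge_path: str | Path) -> SkeletonGraph:
    nodes = []
    clear = []
    with open(node_path, newline="") as fh:
        for row in csv.DictReader(fh):
            nodes.append([float(row["x"]), float(row["y"]), float(row["z"])])
            clear.append(float(row.get("clearance", 1.0)))
    edges = []
    with open(edge_path, newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append([int(row["id_a"]), int(row["id_b"])])
    return _largest_component(
        SkeletonGraph(np.array(nodes), np.array(clear), np.array(edges, int))
    )
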