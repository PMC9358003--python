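"""Discrete flow over complement tetrahedra and cavity classification.

Complement (non-interior) tetrahedra are ordered by the discrete flow: a
tetrahedron flows across a face when its orthocenter lies strictly beyond
that face's plane.  Tetrahedra with a flow path to infinity (through a
convex-hull face whose plane the orthocenter crosses outward) are bulk
solvent; the remaining complement tetrahedra collect into face-connected
cavity components around flow sinks.  Mouths are edge-connected clusters of
the faces where a component meets bulk solvent or the hull, and classify the
component: 0 mouths = void, 1 = pocket, >= 2 = channel.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .alpha_complex import INFINITY, Tetrahedralization
from .errors import NoChannelError

PLANE_TOL = 1e-12

CLASS_BY_MOUTHS = {0: "void", 1: "pocket"}


@dataclass
class CavityComponent:
    """A face-connected set of complement tetrahedra forming one cavity."""

    tet_ids: np.ndarray          # member tetrahedra (sorted)
    mouth_count: int
    mouth_faces: list[np.ndarray]  # per mouth: (m, 3) vertex-id triangles
    volume: float

    @property
    def cls(self) -> str:
        return CLASS_BY_MOUTHS.get(self.mouth_count, "channel")


def _face_planes(t: Tetrahedralization) -> tuple[np.ndarray, np.ndarray]:
    """Per (tet, face-opposite-vertex-k): signed side of the opposite vertex
    and of the orthocenter relative to the face plane.  Shapes (T, 4)."""
    pts = t.points
    tets = t.tets
    own = np.empty((len(tets), 4))
    cen = np.empty((len(tets), 4))
    for k in range(4):
        idx = [j for j in range(4) if j != k]
        a = pts[tets[:, idx[0]]]
        b = pts[tets[:, idx[1]]]
        c = pts[tets[:, idx[2]]]
        normal = np.cross(b - a, c - a)
        own[:, k] = np.einsum("ij,ij->i", pts[tets[:, k]] - a, normal)
        cen[:, k] = np.einsum("ij,ij->i", t.orthocenters - a, normal)
    return own, cen


def flow_relation(t: Tetrahedralization) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-flow edges among complement tetrahedra.

    Returns ``(flows, to_infinity)``: ``flows`` is a (T, 4) bool array where
    ``flows[i, k]`` means tetrahedron ``i`` flows across the face opposite
    vertex ``k`` (its orthocenter lies strictly on the other side of that
    face plane); ``to_infinity[i]`` means some such face is a hull face, so
    ``i`` drains directly to infinity.  Flow is only meaningful between
    complement tetrahedra; entries for interior tetrahedra are False.
    Hull faces always admit the virtual in-edge from infinity regardless of
    flow direction.
    """
    if t.interior is None:
        raise ValueError("interior flags not computed")
    own, cen = _face_planes(t)
    scale = np.maximum(np.abs(own), 1.0)
    # strictly beyond: orthocenter side opposite to the tet's own vertex side
    flows = (own * cen) < -PLANE_TOL * scale
    flows[t.interior] = False
    to_infinity = np.any(flows & (t.neighbors == INFINITY), axis=1)
    return flows, to_infinity


def _bulk_mask(t: Tetrahedralization, flows: np.ndarray, to_infinity: np.ndarray) -> np.ndarray:
    """Complement tetrahedra with a flow path to infinity (bulk solvent).

    Reverse BFS from the directly-draining set along flow edges restricted
    to complement tetrahedra.
    """
    complement = ~t.interior
    bulk = to_infinity & complement
    # reverse adjacency: for each edge i -> j, j gains predecessor i
    queue = deque(np.flatnonzero(bulk))
    # incoming[i] lists tets that flow INTO i
    incoming: list[list[int]] = [[] for _ in range(t.n_tets)]
    src, face = np.nonzero(flows)
    dst = t.neighbors[src, face]
    ok = (dst != INFINITY)
    ok &= complement[src]
    for i, j in zip(src[ok], dst[ok]):
        if complement[j]:
            incoming[j].append(i)
    while queue:
        j = queue.popleft()
        for i in incoming[j]:
            if not bulk[i]:
                bulk[i] = True
                queue.append(i)
    return bulk


def find_cavities(t: Tetrahedralization) -> list[CavityComponent]:
    """Segment complement tetrahedra into cavity components.

    Every complement tetrahedron is either bulk solvent (drains to infinity
    under the discrete flow) or belongs to exactly one face-connected cavity
    component; components are returned sorted by decreasing volume.
    """
    flows, to_infinity = flow_relation(t)
    complement = ~t.interior
    if not np.any(complement):
        return []
    bulk = _bulk_mask(t, flows, to_infinity)
    cavity = complement & ~bulk
    if not np.any(cavity):
        return []

    # face-connected components over cavity tets
    labels = np.full(t.n_tets, -1, dtype=int)
    comp = 0
    for seed in np.flatnonzero(cavity):
        if labels[seed] != -1:
            continue
        queue = deque([seed])
        labels[seed] = comp
        while queue:
            i = queue.popleft()
            for j in t.neighbors[i]:
                if j != INFINITY and cavity[j] and labels[j] == -1:
                    labels[j] = comp
                    queue.append(j)
        comp += 1

    volumes = t.volumes
    components: list[CavityComponent] = []
    for c in range(comp):
        ids = np.flatnonzero(labels == c)
        mouth_faces = _mouth_clusters(t, ids, bulk)
        components.append(
            CavityComponent(
                tet_ids=ids,
                mouth_count=len(mouth_faces),
                mouth_faces=mouth_faces,
                volume=float(volumes[ids].sum()),
            )
        )
    components.sort(key=lambda c: (-c.volume, int(c.tet_ids[0])))
    return components


def _mouth_clusters(
    t: Tetrahedralization, ids: np.ndarray, bulk: np.ndarray
) -> list[np.ndarray]:
    """Edge-connected clusters of the faces where a component meets bulk
    solvent or the convex hull."""
    member = np.zeros(t.n_tets, dtype=bool)
    member[ids] = True
    faces: list[tuple[int, int, int]] = []
    for i in ids:
        for k in range(4):
            j = t.neighbors[i, k]
            if j == INFINITY or (bulk[j] and not member[j]):
                tri = tuple(int(v) for v in np.delete(t.tets[i], k))
                faces.append(tri)
    if not faces:
        return []
    # union-find over faces sharing an (undirected) edge
    parent = list(range(len(faces)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge_map: dict[tuple[int, int], int] = {}
    for fi, tri in enumerate(faces):
        for a, b in ((0, 1), (1, 2), (0, 2)):
            e = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            if e in edge_map:
                ra, rb = find(edge_map[e]), find(fi)
                if ra != rb:
                    parent[rb] = ra
            else:
                edge_map[e] = fi
    roots: dict[int, list[int]] = {}
    for fi in range(len(faces)):
        roots.setdefault(find(fi), []).append(fi)
    return [np.array([faces[fi] for fi in group], dtype=int) for group in roots.values()]


def count_mouths(component: CavityComponent, t: Tetrahedralization) -> int:
    """Recount mouths of a component from scratch (recomputes the flow)."""
    flows, to_infinity = flow_relation(t)
    bulk = _bulk_mask(t, flows, to_infinity)
    return len(_mouth_clusters(t, component.tet_ids, bulk))


def select_channel(
    components: list[CavityComponent], require_mouths: bool = True
) -> CavityComponent:
    """Largest-volume component, preferring those with >= 2 mouths.

    If ``require_mouths`` and no component has two mouths, falls back to the
    overall largest with a warning.  Ties break on the smallest lowest
    tetrahedron id for reproducibility.
    """
    import logging

    if not components:
        raise NoChannelError("no cavity components")
    key = lambda c: (-c.volume, int(c.tet_ids[0]))
    if require_mouths:
        channels = [c for c in components if c.mouth_count >= 2]
        if channels:
            return min(channels, key=key)
        logging.getLogger("poreflow").warning(
            "no component with >= 2 mouths; falling back to largest volume"
        )
    return min(components, key=key)
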