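"""Shared fixtures: the expensive cylinder-pore pipeline products are built
once per session and reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from poreflow import (
    FixtureSpec,
    build_skeleton,
    build_surface,
    compute_centerline,
    extract_channel_surface,
    find_cavities,
    local_radius,
    make_fixture,
    prune_skeleton,
    select_channel,
    weighted_delaunay,
)

PROBE = 1.4
GRID = 0.5


@pytest.fixture(scope="session")
def cylinder():
    """Atoms + ground truth of the reference open pore."""
    atoms, truth = make_fixture(FixtureSpec("cylinder_pore"))
    return atoms, truth


@pytest.fixture(scope="session")
def cylinder_tetra(cylinder):
    atoms, _ = cylinder
    return weighted_delaunay(atoms, probe=PROBE)


@pytest.fixture(scope="session")
def cylinder_channel(cylinder_tetra):
    return select_channel(find_cavities(cylinder_tetra))


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder):
    atoms, _ = cylinder
    return build_surface(atoms, probe=PROBE, grid_spacing=GRID)


@pytest.fixture(scope="session")
def cylinder_channel_surface(cylinder, cylinder_mesh, cylinder_channel, cylinder_tetra):
    atoms, _ = cylinder
    return extract_channel_surface(cylinder_mesh, cylinder_channel,
                                   cylinder_tetra, atoms=atoms)


@pytest.fixture(scope="session")
def cylinder_skeleton(cylinder_channel, cylinder_tetra):
    return build_skeleton(cylinder_channel, cylinder_tetra)


@pytest.fixture(scope="session")
def cylinder_centerline(cylinder_skeleton, cylinder_channel_surface):
    path = prune_skeleton(cylinder_skeleton)
    cl = compute_centerline(cylinder_skeleton, int(path.node_ids[0]),
                            int(path.node_ids[-1]), step=0.5)
    local_radius(cl, cylinder_channel_surface)
    return cl


def random_atoms(n: int, seed: int, box: float = 10.0):
    """Uniform random weighted balls in a cube, radii in [1, 2] A."""
    from poreflow import AtomSet

    rng = np.random.default_rng(seed)
    return AtomSet(rng.uniform(0, box, (n, 3)), rng.uniform(1.0, 2.0, n))
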