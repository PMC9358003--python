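"""Analytic toy "molecules" with known channel geometry.

Each fixture is a wall of overlapping balls around an analytically known
cavity, with ground truth (expected class, mouth count, axis polyline, lumen
radius) emitted alongside, so every pipeline stage can be checked against
closed-form geometry.  Wall balls are spaced at most 1.5x their radius apart
so that probe-inflated walls are watertight.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import FixtureSpecError
from .structure_io import AtomSet

KINDS = (
    "cylinder_pore",
    "torus_channel",
    "pocket",
    "sealed_void",
    "helical_tube",
    "pentalobe_tube",
)

#: Wall-ball center spacing as a multiple of the ball radius.  The in-layer
#: grid step is 1.2 r so that even diagonal neighbors across staggered rings
#: stay within 1.5 r, keeping probe-inflated walls hole-free.
SPACING_FACTOR = 1.2


@dataclass
class FixtureSpec:
    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise FixtureSpecError(f"unknown fixture kind {self.kind!r}")


def make_fixture(spec: FixtureSpec) -> tuple[AtomSet, dict[str, Any]]:
    """Build the atoms and ground-truth descriptor for a fixture."""
    builder = _BUILDERS[spec.kind]
    return builder(**spec.params)


def make_trajectory(
    spec: FixtureSpec, n_frames: int, jitter: float, seed: int = 0
) -> tuple[list[AtomSet], dict[str, Any]]:
    """Frame 0 is the clean fixture; each later frame adds i.i.d. uniform
    jitter in [-jitter, jitter] to every center.  Deterministic in ``seed``."""
    if n_frames < 1:
        raise FixtureSpecError("n_frames must be >= 1")
    if jitter < 0:
        raise FixtureSpecError("jitter must be >= 0")
    atoms, truth = make_fixture(spec)
    rng = np.random.default_rng(seed)
    frames = [atoms]
    for _ in range(1, n_frames):
        delta = rng.uniform(-jitter, jitter, size=atoms.centers.shape)
        frames.append(AtomSet(atoms.centers + delta, atoms.radii.copy(), atoms.labels))
    return frames, truth


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _ring(center: np.ndarray, radius: float, n: int, phase: float = 0.0,
          e1: np.ndarray | None = None, e2: np.ndarray | None = None) -> np.ndarray:
    if e1 is None:
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
    ang = phase + 2 * np.pi * np.arange(n) / n
    return center + radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)


def _check_lumen(axis_radius: float, ball_radius: float, probe: float = 1.4) -> None:
    if axis_radius <= ball_radius + probe:
        raise FixtureSpecError(
            f"lumen sealed: axis radius {axis_radius} <= ball radius {ball_radius} "
            f"+ probe {probe}"
        )


def _tube_rings(axis_points: np.ndarray, tangents: np.ndarray, ring_radius: float,
                spacing: float, radial_fn=None, n_layers: int = 2) -> np.ndarray:
    """Rings of centers of radius ``ring_radius`` perpendicular to ``tangents``
    at each axis point; alternate rings are phase-staggered to close gaps.

    The wall is ``n_layers`` concentric layers thick (growing outward, so the
    lumen radius stays analytic): a single layer of balls in convex position
    has no volumetric interior in the triangulation and would not seal.
    """
    n_ring = max(8, int(np.ceil(2 * np.pi * ring_radius / spacing)))
    centers = []
    ref = np.array([0.0, 0.0, 1.0])
    for i, (p, t) in enumerate(zip(axis_points, tangents)):
        t = t / np.linalg.norm(t)
        a = ref if abs(t @ ref) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(t, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        for layer in range(n_layers):
            phase = (np.pi / n_ring) * ((i + layer) % 2)
            ang = phase + 2 * np.pi * np.arange(n_ring) / n_ring
            r = ring_radius if radial_fn is None else radial_fn(ang)
            r = r + layer * spacing
            centers.append(p + (r * np.cos(ang))[:, None] * e1
                           + (r * np.sin(ang))[:, None] * e2)
    return np.vstack(centers)


def cylinder_pore(axis_radius: float = 6.0, ball_radius: float = 1.5,
                  length: float = 30.0, probe: float = 1.4) -> tuple[AtomSet, dict]:
    """Open cylindrical pore along z: wall-ball centers at ``axis_radius``,
    analytic lumen radius ``axis_radius - ball_radius``."""
    _check_lumen(axis_radius, ball_radius, probe)
    spacing = SPACING_FACTOR * ball_radius
    n_z = max(2, int(np.ceil(length / spacing)) + 1)
    zs = np.linspace(-length / 2, length / 2, n_z)
    axis = np.column_stack([np.zeros(n_z), np.zeros(n_z), zs])
    tangents = np.tile([0.0, 0.0, 1.0], (n_z, 1))
    centers = _tube_rings(axis, tangents, axis_radius, spacing)
    radii = np.full(len(centers), ball_radius)
    atoms = _labeled(centers, radii)
    truth = {
        "class": "channel",
        "mouths": 2,
        "axis": axis,
        "axis_direction": np.array([0.0, 0.0, 1.0]),
        "lumen_radius": axis_radius - ball_radius,
        "length": length,
    }
    return atoms, truth


def pentalobe_tube(base_radius: float = 6.0, lobe_amplitude: float = 1.2,
                   n_lobes: int = 5, ball_radius: float = 1.5,
                   length: float = 20.0, probe: float = 1.4) -> tuple[AtomSet, dict]:
    """Cylindrical pore with ``n_lobes`` radial bulges (five-fold by default,
    mimicking a pentameric channel footprint)."""
    _check_lumen(base_radius - lobe_amplitude, ball_radius, probe)
    spacing = SPACING_FACTOR * ball_radius
    n_z = max(2, int(np.ceil(length / spacing)) + 1)
    zs = np.linspace(-length / 2, length / 2, n_z)
    axis = np.column_stack([np.zeros(n_z), np.zeros(n_z), zs])
    tangents = np.tile([0.0, 0.0, 1.0], (n_z, 1))
    radial = lambda ang: base_radius + lobe_amplitude * np.cos(n_lobes * ang)
    # denser rings so the lobed wall stays watertight at the bulge maxima
    centers = _tube_rings(axis, tangents, base_radius + lobe_amplitude, spacing, radial_fn=radial)
    radii = np.full(len(centers), ball_radius)
    truth = {
        "class": "channel",
        "mouths": 2,
        "axis": axis,
        "axis_direction": np.array([0.0, 0.0, 1.0]),
        "lumen_radius": base_radius - ball_radius,
        "n_lobes": n_lobes,
        "lobe_amplitude": lobe_amplitude,
        "length": length,
    }
    return _labeled(centers, radii), truth


def torus_channel(major_radius: float = 8.0, tube_radius: float = 2.5,
                  ball_radius: float = 1.5, probe: float = 1.4) -> tuple[AtomSet, dict]:
    """Solid torus of overlapping balls; the donut hole is a through channel
    of radius ``major_radius - tube_radius - ball_radius``."""
    hole = major_radius - tube_radius - ball_radius
    if hole <= probe:
        raise FixtureSpecError(f"torus hole radius {hole} <= probe {probe}")
    spacing = SPACING_FACTOR * ball_radius
    centers = []
    n_minor = max(6, int(np.ceil(2 * np.pi * tube_radius / spacing)))
    for k in range(n_minor):
        phi = 2 * np.pi * k / n_minor
        r_ring = major_radius + tube_radius * np.cos(phi)
        z = tube_radius * np.sin(phi)
        n_major = max(8, int(np.ceil(2 * np.pi * r_ring / spacing)))
        centers.append(
            _ring(np.array([0.0, 0.0, z]), r_ring, n_major, phase=(np.pi / n_major) * (k % 2))
        )
    centers = np.vstack(centers)
    radii = np.full(len(centers), ball_radius)
    truth = {"class": "channel", "mouths": 2, "hole_radius": hole,
             "axis_direction": np.array([0.0, 0.0, 1.0])}
    return _labeled(centers, radii), truth


def pocket(axis_radius: float = 6.0, ball_radius: float = 1.5,
           depth: float = 14.0, probe: float = 1.4) -> tuple[AtomSet, dict]:
    """Blind cylindrical hole: a pore open at +z and sealed at -z by a cap of
    overlapping balls -> a single-mouth pocket."""
    _check_lumen(axis_radius, ball_radius, probe)
    spacing = SPACING_FACTOR * ball_radius
    n_z = max(2, int(np.ceil(depth / spacing)) + 1)
    zs = np.linspace(-depth / 2, depth / 2, n_z)
    axis = np.column_stack([np.zeros(n_z), np.zeros(n_z), zs])
    tangents = np.tile([0.0, 0.0, 1.0], (n_z, 1))
    centers = [_tube_rings(axis, tangents, axis_radius, spacing)]
    # sealing cap: concentric disks on two layers below the bottom
    for dz, phase in ((0.0, 0.0), (spacing, 0.5)):
        z = -depth / 2 - dz
        centers.append(np.array([[0.0, 0.0, z]]))
        r = spacing
        while r < axis_radius + ball_radius:
            n = max(6, int(np.ceil(2 * np.pi * r / spacing)))
            centers.append(_ring(np.array([0.0, 0.0, z]), r, n, phase=phase * 2 * np.pi / n))
            r += spacing
    centers = np.vstack(centers)
    radii = np.full(len(centers), ball_radius)
    truth = {"class": "pocket", "mouths": 1, "lumen_radius": axis_radius - ball_radius,
             "depth": depth}
    return _labeled(centers, radii), truth


def sealed_void(shell_radius: float = 6.0, ball_radius: float = 1.5,
                probe: float = 1.4) -> tuple[AtomSet, dict]:
    """Closed spherical shell of overlapping balls enclosing an empty void."""
    if shell_radius <= ball_radius + probe:
        raise FixtureSpecError("void interior unresolvable: shell too tight")
    spacing = SPACING_FACTOR * ball_radius
    layers = []
    for layer in range(2):  # double shell: single layers have no volumetric wall
        r = shell_radius + layer * spacing
        n = int(np.ceil(4 * np.pi * r**2 / spacing**2 * 4.0 / np.sqrt(3)))
        layers.append(r * _fibonacci_sphere(n))
    centers = np.vstack(layers)
    radii = np.full(len(centers), ball_radius)
    truth = {"class": "void", "mouths": 0, "void_radius": shell_radius - ball_radius}
    return _labeled(centers, radii), truth


def helical_tube(a: float = 5.0, b: float = 2.0, turns: float = 2.0,
                 tube_radius: float = 4.0, ball_radius: float = 1.5,
                 probe: float = 1.4) -> tuple[AtomSet, dict]:
    """Tube of balls around the circular helix (a cos t, a sin t, b t).

    Closed-form axis curvature a/(a^2+b^2) and torsion b/(a^2+b^2).
    """
    _check_lumen(tube_radius, ball_radius, probe)
    spacing = SPACING_FACTOR * ball_radius
    arc_per_t = np.hypot(a, b)
    t_max = 2 * np.pi * turns
    n_axis = max(2, int(np.ceil(t_max * arc_per_t / spacing)) + 1)
    ts = np.linspace(0.0, t_max, n_axis)
    axis = np.column_stack([a * np.cos(ts), a * np.sin(ts), b * ts])
    tangents = np.column_stack([-a * np.sin(ts), a * np.cos(ts), np.full_like(ts, b)])
    centers = _tube_rings(axis, tangents, tube_radius, spacing)
    radii = np.full(len(centers), ball_radius)
    denom = a * a + b * b
    # ground-truth axis sampled densely (0.25 A arc) for curve analysis
    n_dense = max(2, int(np.ceil(t_max * arc_per_t / 0.25)) + 1)
    td = np.linspace(0.0, t_max, n_dense)
    axis_dense = np.column_stack([a * np.cos(td), a * np.sin(td), b * td])
    truth = {
        "class": "channel",
        "mouths": 2,
        "axis": axis_dense,
        "lumen_radius": tube_radius - ball_radius,
        "curvature": a / denom,
        "torsion": b / denom,
        "a": a,
        "b": b,
    }
    return _labeled(centers, radii), truth


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _labeled(centers: np.ndarray, radii: np.ndarray) -> AtomSet:
    import pandas as pd

    n = len(centers)
    labels = pd.DataFrame({
        "atom_name": ["X"] * n,
        "res_name": ["FIX"] * n,
        "res_id": np.arange(n),
        "chain": ["A"] * n,
    })
    return AtomSet(centers, radii, labels)


_BUILDERS = {
    "cylinder_pore": cylinder_pore,
    "torus_channel": torus_channel,
    "pocket": pocket,
    "sealed_void": sealed_void,
    "helical_tube": helical_tube,
    "pentalobe_tube": pentalobe_tube,
}
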