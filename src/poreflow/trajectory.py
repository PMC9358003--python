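"""Full-pipeline orchestration over MD frame series, with warm starts.

Frame 0 runs the complete procedure (triangulation, discrete flow, surface,
skeleton, pruning, centerline, sections).  Subsequent frames skip the
pruning step: the previous frame's centerline endpoints are snapped to the
nearest skeleton nodes within a capture radius.  When no node is captured,
or the new centerline deviates from the previous one by more than a
discrepancy threshold (symmetric mean closest-point distance), the frame is
reinitialized with a fresh pruning pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .alpha_complex import weighted_delaunay
from .cavity_flow import find_cavities, select_channel
from .centerline import Centerline, compute_centerline, local_radius
from .channel_surface import build_surface, extract_channel_surface
from .errors import PoreflowError
from .skeleton import build_skeleton, prune_skeleton
from .structure_io import AtomSet, SECTION_COLUMNS, SurfaceMesh

logger = logging.getLogger("poreflow")


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline (Angstrom units)."""

    probe: float = 1.4                 # solvent probe radius
    grid_spacing: float = 0.5          # marching-cubes grid step
    step: float = 0.5                  # centerline resampling step
    bin_width: float = 1.0             # z-bin width for radius profiles
    capture_radius: float = 5.0        # warm-start endpoint snap radius
    discrepancy_threshold: float = 5.0  # centerline jump forcing reinit
    n_rays: int = 360                  # visibility rays per section
    section_stride: int = 1            # sections every k-th centerline point
    require_mouths: bool = True        # channel selection prefers >= 2 mouths
    cold_start: bool = False           # disable warm starts entirely
    external_mesh: SurfaceMesh | None = None   # imported molecular surface


@dataclass
class FrameResult:
    """Per-frame outcome; failed frames carry a reason and no geometry."""

    index: int
    status: str                        # full_init | warm_start | reinitialized | failed
    reason: str | None = None
    channel_summary: dict | None = None
    centerline: Centerline | None = None
    sections: pd.DataFrame | None = None
    channel_mesh: SurfaceMesh | None = None
    radius_samples: tuple[np.ndarray, np.ndarray] | None = None   # (z, r)
    endpoints: np.ndarray | None = None   # (2, 3) entrance coordinates


def _analyze_frame(atoms: AtomSet, config: PipelineConfig,
                   guess_endpoints: np.ndarray | None):
    """Run the pipeline on one frame.

    Returns ``(result_fields, used_warm_start)``; raises PoreflowError on
    unrecoverable geometry failures (caller converts to a failed frame).
    """
    t = weighted_delaunay(atoms, probe=config.probe)
    comps = find_cavities(t)
    channel = select_channel(comps, require_mouths=config.require_mouths)
    mesh = config.external_mesh or build_surface(
        atoms, probe=config.probe, grid_spacing=config.grid_spacing)
    cs = extract_channel_surface(mesh, channel, t, atoms=atoms)
    g = build_skeleton(channel, t)

    warm = False
    endpoints_nodes = None
    if guess_endpoints is not None and g.n_nodes >= 2:
        tree = cKDTree(g.positions)
        d, i = tree.query(guess_endpoints)
        if np.all(d <= config.capture_radius) and i[0] != i[1]:
            endpoints_nodes = (int(i[0]), int(i[1]))
            warm = True
    if endpoints_nodes is None:
        path = prune_skeleton(g)
        endpoints_nodes = (int(path.node_ids[0]), int(path.node_ids[-1]))

    cl = compute_centerline(g, endpoints_nodes[0], endpoints_nodes[1],
                            step=config.step)
    local_radius(cl, cs)
    sections = _section_table(cl, cs, config)
    summary = {
        "class": channel.cls,
        "mouths": channel.mouth_count,
        "volume": channel.volume,
        "n_tets": int(len(channel.tet_ids)),
        "n_components": len(comps),
    }
    fields = dict(
        channel_summary=summary,
        centerline=cl,
        sections=sections,
        channel_mesh=cs.submesh(),
        radius_samples=(cl.points[:, 2].copy(), cl.radius.copy()),
        # carry the skeleton endpoint nodes (not the smoothed tips) so a
        # warm start on an identical frame snaps back to the same nodes
        endpoints=np.vstack([g.positions[endpoints_nodes[0]],
                             g.positions[endpoints_nodes[1]]]),
    )
    return fields, warm


def _section_table(cl: Centerline, cs, config: PipelineConfig) -> pd.DataFrame:
    from .sections import cut_section, section_metrics

    rows = []
    for k in range(0, len(cl), max(1, config.section_stride)):
        sec = cut_section(cs, cl.points[k], cl.tangents[k])
        if sec.empty:
            continue
        try:
            m = section_metrics(sec, n_rays=config.n_rays)
        except PoreflowError:
            continue
        rows.append({
            "arclength": cl.arclength[k],
            "d_min": m.d_min,
            "d_max": m.d_max,
            "a": m.a,
            "b": m.b,
            "eccentricity": m.eccentricity,
            "n_visible": m.n_visible,
            "n_components": m.n_components,
        })
    return pd.DataFrame(rows, columns=SECTION_COLUMNS)


def analyze_frame(atoms: AtomSet,
                  config: PipelineConfig | None = None) -> FrameResult:
    """Run the full pipeline (triangulation, flow, surface, skeleton,
    pruning, centerline, sections) on a single structure."""
    fields, _ = _analyze_frame(atoms, config or PipelineConfig(), None)
    return FrameResult(index=0, status="full_init", **fields)


def analyze_trajectory(frames: Sequence[AtomSet],
                       config: PipelineConfig | None = None) -> list[FrameResult]:
    """Run the pipeline over a frame sequence with warm starts.

    A failing frame yields ``status='failed'`` and the run continues; the
    per-status counts are logged at the end.
    """
    if not frames:
        raise PoreflowError("empty trajectory")
    config = config or PipelineConfig()
    results: list[FrameResult] = []
    prev_endpoints: np.ndarray | None = None
    prev_centerline: Centerline | None = None
    for i, atoms in enumerate(frames):
        guess = None if (config.cold_start or i == 0) else prev_endpoints
        try:
            fields, warm = _analyze_frame(atoms, config, guess)
            status = "warm_start" if warm else ("full_init" if i == 0 or guess is None
                                               else "reinitialized")
            if warm and prev_centerline is not None:
                disc = centerline_discrepancy(prev_centerline, fields["centerline"])
                if disc > config.discrepancy_threshold:
                    logger.info("frame %d: discrepancy %.2f A > %.2f, reinitializing",
                                i, disc, config.discrepancy_threshold)
                    fields, _ = _analyze_frame(atoms, config, None)
                    status = "reinitialized"
            res = FrameResult(index=i, status=status, **fields)
            prev_endpoints = res.endpoints
            prev_centerline = res.centerline
        except PoreflowError as exc:
            logger.warning("frame %d failed: %s", i, exc)
            res = FrameResult(index=i, status="failed", reason=str(exc))
        results.append(res)
    counts = pd.Series([r.status for r in results]).value_counts().to_dict()
    logger.info("trajectory done: %s", counts)
    return results


def _point_to_polyline(p: np.ndarray, poly: np.ndarray) -> float:
    """Distance from a point to a polyline (segment-wise, exact)."""
    if len(poly) == 1:
        return float(np.linalg.norm(p - poly[0]))
    a = poly[:-1]
    d = poly[1:] - a
    len2 = np.einsum("ij,ij->i", d, d)
    tpar = np.clip(np.einsum("ij,ij->i", p - a, d) / np.maximum(len2, 1e-30),
                   0.0, 1.0)
    proj = a + tpar[:, None] * d
    return float(np.linalg.norm(p - proj, axis=1).min())


def centerline_discrepancy(a: Centerline, b: Centerline) -> float:
    """Symmetric mean closest-point distance between two centerlines."""
    ta = cKDTree(a.points)
    tb = cKDTree(b.points)
    dab, _ = tb.query(a.points)
    dba, _ = ta.query(b.points)
    return 0.5 * (float(np.mean(dab)) + float(np.mean(dba)))


def compare_ion_paths(centerlines: Sequence[Centerline | None],
                      ion_records: np.ndarray,
                      bin_width: float = 1.0) -> pd.DataFrame:
    """Lateral displacement of ion positions from per-frame centerlines.

    ``ion_records`` rows are ``(frame, x, y, z)``; each ion position is
    measured against its frame's centerline (nearest-point distance) and
    binned along z.  Returns columns ``z_bin, mean_displacement, mean_x,
    mean_y, mean_z, n`` (empty DataFrame when no ions are in range).
    """
    cols = ["z_bin", "mean_displacement", "mean_x", "mean_y", "mean_z", "n"]
    records = np.asarray(ion_records, float).reshape(-1, 4)
    rows = []
    for rec in records:
        fi = int(rec[0])
        if fi < 0 or fi >= len(centerlines) or centerlines[fi] is None:
            continue
        cl = centerlines[fi]
        d = _point_to_polyline(rec[1:4], cl.points)
        rows.append({"z": rec[3], "disp": float(d),
                     "x": rec[1], "y": rec[2]})
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["bin"] = np.floor(df["z"] / bin_width).astype(int)
    out = df.groupby("bin").agg(
        mean_displacement=("disp", "mean"),
        mean_x=("x", "mean"), mean_y=("y", "mean"), mean_z=("z", "mean"),
        n=("disp", "size"),
    ).reset_index()
    out["z_bin"] = (out["bin"] + 0.5) * bin_width
    return out[cols].sort_values("z_bin").reset_index(drop=True)
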