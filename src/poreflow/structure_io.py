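"""On-disk formats: xyzr atom lists, multi-model PDB, OFF/PLY meshes, result tables.

The package's native atom input is the minimal ``xyzr`` dialect (one
``x y z r`` line per atom, Angstrom units, ``#`` comments and trailing columns
tolerated).  Multi-model PDB files are read through Biopython and annotated
with radii from a :class:`RadiusTable`; water and common ions are excluded by
residue name.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyStructureError,
    FormatError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger("poreflow")

#: Residue names dropped by default when reading PDB frames: waters and the
#: monatomic ions common in MD solvent boxes.
DEFAULT_EXCLUDE = frozenset(
    {"HOH", "WAT", "TIP", "TIP3", "SOL", "K", "CL", "NA", "MG", "CA", "ZN",
     "POT", "CLA", "SOD"}
)

#: Bondi-style van der Waals radii (Angstrom), element-keyed, used when no
#: per-(residue, atom) override is supplied.
DEFAULT_ELEMENT_RADII: Mapping[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

DEFAULT_RADIUS = 1.60


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class AtomSet:
    """A molecule as a set of balls: centers and radii in Angstrom.

    ``labels`` is an optional DataFrame with columns
    ``atom_name, res_name, res_id, chain`` (one row per atom) used only for
    lumen annotation; geometry never depends on it.
    """

    centers: np.ndarray
    radii: np.ndarray
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.centers) != len(self.radii):
            raise ValidationError(
                f"centers ({len(self.centers)}) and radii ({len(self.radii)}) differ in length"
            )
        if not np.all(np.isfinite(self.centers)):
            raise ValidationError("non-finite coordinates in atom centers")
        if np.any(self.radii <= 0) or not np.all(np.isfinite(self.radii)):
            bad = int(np.flatnonzero(~(self.radii > 0))[0])
            raise ValidationError(f"non-positive radius for atom {bad}")
        if self.labels is not None and len(self.labels) != len(self.radii):
            raise ValidationError("labels length does not match atom count")
        if len(self.radii) > 1:
            rows = np.column_stack([self.centers, self.radii])
            if len(np.unique(rows, axis=0)) != len(rows):
                raise ValidationError("exactly coincident atoms (same center and radius)")

    def __len__(self) -> int:
        return len(self.radii)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "AtomSet":
        """Return a rigidly moved copy (labels shared)."""
        c = self.centers
        if rotation is not None:
            c = c @ np.asarray(rotation, float).T
        if translation is not None:
            c = c + np.asarray(translation, float)
        return AtomSet(c, self.radii.copy(), self.labels)


@dataclass
class SurfaceMesh:
    """Triangle mesh: ``vertices`` (v, 3) float, ``triangles`` (t, 3) int,
    optional outward per-vertex normals."""

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def barycenters(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.triangle_areas().sum())


class RadiusTable:
    """Atomic radius lookup: per-(residue, atom) overrides, element fallback,
    declared default for anything unknown.  Every lookup returns > 0."""

    def __init__(
        self,
        element_radii: Mapping[str, float] | None = None,
        overrides: Mapping[tuple[str, str], float] | None = None,
        default: float = DEFAULT_RADIUS,
    ) -> None:
        self.element_radii = {k.upper(): float(v)
                              for k, v in (element_radii or DEFAULT_ELEMENT_RADII).items()}
        self.overrides = {(r.upper(), a.upper()): float(v)
                          for (r, a), v in (overrides or {}).items()}
        self.default = float(default)
        for name, val in list(self.element_radii.items()) + list(self.overrides.items()):
            if val <= 0:
                raise ValidationError(f"non-positive radius in table for {name!r}")
        if self.default <= 0:
            raise ValidationError("non-positive default radius")
        self._warned: set[str] = set()

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "RadiusTable":
        """Load overrides from a CSV with columns res_name, atom_name, radius."""
        overrides: dict[tuple[str, str], float] = {}
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                try:
                    overrides[(row["res_name"], row["atom_name"])] = float(row["radius"])
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}: bad override row {i + 2}: {exc}") from exc
        return cls(overrides=overrides, **kwargs)

    def lookup(self, res_name: str, atom_name: str, element: str | None = None) -> float:
        key = (res_name.upper().strip(), atom_name.upper().strip())
        if key in self.overrides:
            return self.overrides[key]
        el = (element or _element_from_atom_name(atom_name)).upper()
        if el in self.element_radii:
            return self.element_radii[el]
        if el not in self._warned:
            self._warned.add(el)
            logger.warning(
                "unknown element %r (atom %s/%s): using default radius %.2f",
                el, res_name, atom_name, self.default,
            )
        return self.default


def _element_from_atom_name(atom_name: str) -> str:
    """Guess the element from a PDB atom name (strip digits; two-letter
    elements like CL only when the name is exactly that element)."""
    name = atom_name.strip().upper()
    stripped = "".join(ch for ch in name if ch.isalpha())
    if stripped in DEFAULT_ELEMENT_RADII and len(stripped) > 1:
        return stripped
    return stripped[:1] if stripped else ""


# ---------------------------------------------------------------------------
# xyzr
# ---------------------------------------------------------------------------

def read_xyzr(path: str | Path) -> AtomSet:
    """Read a whitespace-separated ``x y z r`` file (one atom per line).

    Comment lines starting with ``#`` and blank lines are skipped; columns
    beyond the fourth are ignored.
    """
    centers: list[list[float]] = []
    radii: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >= 4 fields, got {len(fields)}")
            try:
                x, y, z, r = (float(v) for v in fields[:4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric field ({exc})") from exc
            if r <= 0:
                raise ValidationError(f"{path}: line {lineno}: non-positive radius {r}")
            centers.append([x, y, z])
            radii.append(r)
    if not centers:
        raise EmptyStructureError(f"{path}: no atoms")
    return AtomSet(np.array(centers), np.array(radii))


def write_xyzr(atoms: AtomSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (x, y, z), r in zip(atoms.centers, atoms.radii):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {r:.6f}\n")


# ---------------------------------------------------------------------------
# PDB frames
# ---------------------------------------------------------------------------

def read_pdb_frames(
    path: str | Path,
    table: RadiusTable | None = None,
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
) -> list[AtomSet]:
    """Read a (multi-model) PDB file into one :class:`AtomSet` per MODEL.

    Waters/ions in ``exclude`` are dropped by residue name; each remaining
    atom gets a radius from ``table`` (element fallback, logged default for
    unknowns).  A model-less file yields a single frame.
    """
    from Bio.PDB import PDBParser

    table = table or RadiusTable()
    exclude = {e.upper() for e in exclude}
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("frame", str(path))

    frames: list[AtomSet] = []
    for model in structure:
        centers, radii = [], []
        rows = {"atom_name": [], "res_name": [], "res_id": [], "chain": []}
        for chain in model:
            for residue in chain:
                res_name = residue.get_resname().strip().upper()
                if res_name in exclude:
                    continue
                for atom in residue:
                    centers.append(atom.get_coord())
                    radii.append(
                        table.lookup(res_name, atom.get_name(), atom.element or None)
                    )
                    rows["atom_name"].append(atom.get_name())
                    rows["res_name"].append(res_name)
                    rows["res_id"].append(residue.get_id()[1])
                    rows["chain"].append(chain.get_id())
        if not centers:
            raise EmptyStructureError(f"{path}: model {model.get_id()} empty after exclusion")
        frames.append(AtomSet(np.array(centers, float), np.array(radii), pd.DataFrame(rows)))
    if not frames:
        raise EmptyStructureError(f"{path}: no models")
    return frames


# ---------------------------------------------------------------------------
# Meshes (OFF parsed natively, PLY through trimesh)
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read an OFF or PLY triangle mesh.  Non-triangular faces are rejected."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        return _read_off(path)
    if suffix == ".ply":
        return _read_ply(path)
    raise FormatError(f"{path}: unsupported mesh format {suffix!r} (expected .off or .ply)")


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    elif path.suffix.lower() == ".ply":
        import trimesh

        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
        tm.export(str(path), encoding="ascii")
    else:
        raise FormatError(f"{path}: unsupported mesh format (expected .off or .ply)")


def _read_off(path: Path) -> SurfaceMesh:
    with open(path) as fh:
        tokens: list[str] = []
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0].upper() != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4  # header keyword + nv nf ne
        verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = np.empty((nf, 3), dtype=int)
        for i in range(nf):
            k = int(tokens[pos])
            if k != 3:
                raise FormatError(f"{path}: face {i} has {k} vertices; only triangles supported")
            faces[i] = [int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])]
            pos += 1 + k
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed OFF ({exc})") from exc
    return SurfaceMesh(verts, faces)


def _read_ply(path: Path) -> SurfaceMesh:
    import trimesh

    _check_ascii_ply_triangles(path)
    try:
        tm = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad headers
        raise FormatError(f"{path}: unreadable PLY ({exc})") from exc
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise FormatError(f"{path}: PLY contains no triangles")
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))


def _check_ascii_ply_triangles(path: Path) -> None:
    """Reject ascii PLY files with non-triangular faces (trimesh would
    silently triangulate them)."""
    with open(path, "rb") as fh:
        header = fh.readline()
        if not header.strip().lower().startswith(b"ply"):
            raise FormatError(f"{path}: missing PLY header")
        lines = [header]
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated PLY header")
            lines.append(line)
            if line.strip() == b"end_header":
                break
        text = b"".join(lines).decode("ascii", "replace")
        if "format ascii" not in text:
            return  # binary: defer to trimesh
        counts = {}
        order = []
        for ln in text.splitlines():
            parts = ln.split()
            if parts[:1] == ["element"]:
                counts[parts[1]] = int(parts[2])
                order.append(parts[1])
        body = fh.read().decode("ascii", "replace").split()
        # skip vertex data: assume position of face element after others is
        # only checkable for the common vertex-then-face layout
        if order[:2] != ["vertex", "face"] or set(order) - {"vertex", "face"}:
            return
        n_vertex_props = text.count("\nproperty") - 1  # one is the face list
        idx = counts["vertex"] * n_vertex_props
        for i in range(counts["face"]):
            k = int(body[idx])
            if k != 3:
                raise FormatError(f"{path}: face {i} has {k} vertices; only triangles supported")
            idx += 1 + k


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

CENTERLINE_COLUMNS = [
    "x", "y", "z", "tx", "ty", "tz", "curvature", "torsion", "radius", "arclength",
]

SECTION_COLUMNS = [
    "arclength", "d_min", "d_max", "a", "b", "eccentricity", "n_visible", "n_components",
]


def write_results(results: Sequence, out_dir: str | Path) -> list[Path]:
    """Write per-frame channel results (``frame_{i:06d}_*``) plus summary.csv.

    Each result must expose ``index``, ``status`` and, for successful frames,
    ``centerline`` (with points/tangents/curvature/torsion/radius/arclength),
    ``sections`` (DataFrame with :data:`SECTION_COLUMNS`) and optionally
    ``channel_mesh`` (a :class:`SurfaceMesh`).
    """
    if not results:
        raise ValidationError("empty results")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write to {out_dir}: {exc}") from exc

    written: list[Path] = []
    summary_rows = []
    for res in results:
        i = res.index
        row = {"frame": i, "status": res.status}
        cl = getattr(res, "centerline", None)
        if cl is not None:
            df = pd.DataFrame(
                np.column_stack([
                    cl.points,
                    cl.tangents,
                    cl.curvature,
                    cl.torsion,
                    cl.radius if cl.radius is not None else np.full(len(cl.points), np.nan),
                    cl.arclength,
                ]),
                columns=CENTERLINE_COLUMNS,
            )
            p = out_dir / f"frame_{i:06d}_centerline.csv"
            df.to_csv(p, index=False)
            written.append(p)
            row["n_centerline_points"] = len(df)
            if cl.radius is not None:
                row["mean_radius"] = float(np.mean(cl.radius))
        sections = getattr(res, "sections", None)
        if sections is not None:
            p = out_dir / f"frame_{i:06d}_sections.csv"
            sections.to_csv(p, index=False)
            written.append(p)
        mesh = getattr(res, "channel_mesh", None)
        if mesh is not None:
            p = out_dir / f"frame_{i:06d}_channel.off"
            write_mesh(mesh, p)
            written.append(p)
        if getattr(res, "reason", None):
            row["reason"] = res.reason
        summary_rows.append(row)
    summary = out_dir / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(summary, index=False)
    written.append(summary)

    samples = [res.radius_samples for res in results
               if getattr(res, "radius_samples", None) is not None]
    if samples:
        from .centerline import radius_profile

        prof = out_dir / "radius_profile.csv"
        radius_profile(samples).to_csv(prof, index=False)
        written.append(prof)
    return written
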