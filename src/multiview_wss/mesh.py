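"""Triangulated surface meshes with per-vertex scalar fields.

The mesh is the substrate of the whole pipeline: vessel geometries carry
curvature and wall-shear-stress fields as named per-vertex scalars, and
meshes from different patients may have different vertex counts (nothing
downstream assumes a uniform node count).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ScalarField",
    "TriMesh",
    "MeshFormatError",
    "MeshTopologyError",
    "load_mesh",
    "save_mesh",
    "mean_curvature",
]


class MeshFormatError(ValueError):
    """File could not be parsed as a supported surface-mesh format."""


class MeshTopologyError(ValueError):
    """Mesh connectivity violates the triangulated-surface contract."""


@dataclass
class ScalarField:
    """One real value per vertex, with units and a normalization range.

    ``range`` is the span used for color normalization; it must contain the
    data. It may be wider than ``(values.min(), values.max())`` (for example
    a shared range across a dataset).
    """

    name: str
    values: np.ndarray
    units: str = ""
    range: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(f"field {self.name!r}: values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field {self.name!r}: non-finite values")
        if self.range is None:
            lo, hi = float(self.values.min()), float(self.values.max())
            if lo == hi:  # constant field: widen to a valid span
                hi = lo + 1.0 if lo == hi else hi
            self.range = (lo, hi)
        lo, hi = float(self.range[0]), float(self.range[1])
        if lo > float(self.values.min()) + 1e-12 or hi < float(self.values.max()) - 1e-12:
            raise ValueError(f"field {self.name!r}: range {self.range} does not contain data")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin != vmax and not lo < hi:
            raise ValueError(f"field {self.name!r}: degenerate range for non-constant field")
        self.range = (lo, hi)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TriMesh:
    """Triangulated surface: vertices (mm), triangle faces, named fields."""

    vertices: np.ndarray
    faces: np.ndarray
    fields: dict[str, ScalarField] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise MeshTopologyError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise MeshTopologyError(
                    f"{int(degenerate.sum())} faces with repeated vertex indices"
                )
        for name, fld in self.fields.items():
            if len(fld) != n:
                raise ValueError(
                    f"field {name!r} has {len(fld)} values for {n} vertices"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def attach(self, fld: ScalarField) -> "TriMesh":
        if len(fld) != self.n_vertices:
            raise ValueError("field length does not match vertex count")
        self.fields[fld.name] = fld
        return self

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "TriMesh":
        """Rigidly transformed copy; fields ride along with their vertices."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces.copy(), dict(self.fields), dict(self.metadata))

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.to_trimesh().vertex_normals, dtype=float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GEOMETRY_ONLY = {".stl", ".obj"}


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (STL stores an unindexed soup)."""
    if tol <= 0 or len(vertices) == 0:
        return vertices, faces
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[faces]


def load_mesh(path: str | Path, weld_tolerance: float = 1e-6) -> TriMesh:
    """Read STL/PLY/OBJ/VTK-polydata into a :class:`TriMesh`.

    Duplicate vertices within ``weld_tolerance`` (mm) are merged. Per-vertex
    scalar fields are recovered from PLY and VTK files.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        return _read_vtk_polydata(path)
    if suffix == ".ply":
        return _read_ply(path, weld_tolerance)
    try:
        tm = _trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise MeshFormatError(f"could not read {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangulated surface")
    if tm.faces.shape[1] != 3:
        raise MeshTopologyError(f"{path}: non-triangular cells")
    v, f = _weld(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64), weld_tolerance)
    return TriMesh(v, f)


def save_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh; fields are preserved for PLY and VTK, dropped for STL/OBJ."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "vtk":
        _write_vtk_polydata(mesh, path)
        return
    if fmt == "ply":
        _write_ply(mesh, path)
        return
    if fmt in ("stl", "obj"):
        if mesh.fields:
            logger.warning("format %s cannot store per-vertex fields; dropping %s",
                           fmt, sorted(mesh.fields))
            warnings.warn(f"{fmt.upper()} cannot store fields; dropped", stacklevel=2)
        mesh.to_trimesh().export(str(path), file_type=fmt)
        return
    raise MeshFormatError(f"unsupported mesh format: {fmt!r}")


def _read_ply(path: Path, weld_tolerance: float) -> TriMesh:
    """ASCII/binary PLY via trimesh; extra vertex properties become fields."""
    tm = _trimesh.load(str(path), process=False, force="mesh")
    if not isinstance(tm, _trimesh.Trimesh):
        raise MeshFormatError(f"{path}: not a surface mesh")
    v = np.asarray(tm.vertices, float)
    f = np.asarray(tm.faces, np.int64)
    fields: dict[str, ScalarField] = {}
    candidates: dict[str, np.ndarray] = dict(getattr(tm, "vertex_attributes", {}))
    raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    if hasattr(raw, "dtype"):  # binary PLY: structured array
        candidates.update({name: raw[name] for name in raw.dtype.names})
    elif isinstance(raw, dict):
        candidates.update(raw)
    skip = {"x", "y", "z", "nx", "ny", "nz", "red", "green", "blue", "alpha"}
    for name, values in candidates.items():
        if name in skip:
            continue
        arr = np.asarray(values, dtype=float).reshape(-1)
        if len(arr) == len(v):
            fields[name] = ScalarField(name, arr)
    if not fields:
        v, f = _weld(v, f, weld_tolerance)
    m = TriMesh(v, f)
    for fld in fields.values():
        m.attach(fld)
    return m


def _write_ply(mesh: TriMesh, path: Path) -> None:
    """ASCII PLY with one float property per attached scalar field."""
    names = sorted(mesh.fields)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment multiview-wss\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in names:
            fh.write(f"property double {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = [mesh.vertices] + [mesh.fields[n].values[:, None] for n in names]
        for row in np.hstack(cols):
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")
        for tri in mesh.faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def _read_vtk_polydata(path: Path) -> TriMesh:
    """Minimal legacy ASCII VTK polydata reader (POINTS/POLYGONS/POINT_DATA)."""
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise MeshFormatError(f"{path}: not a legacy VTK file")
    if "ascii" not in lines[2].strip().lower():
        raise MeshFormatError(f"{path}: only ASCII VTK is supported")
    for ln in lines[4:]:
        tokens.extend(ln.split())
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = tokens[pos:pos + n]
        pos += n
        return out

    vertices = faces = None
    fields: dict[str, ScalarField] = {}
    while pos < len(tokens):
        kw = tokens[pos].upper()
        if kw == "POINTS":
            n = int(tokens[pos + 1]); pos += 3
            vertices = np.array(take(3 * n), dtype=float).reshape(n, 3)
        elif kw == "POLYGONS":
            n = int(tokens[pos + 1]); total = int(tokens[pos + 2]); pos += 3
            data = np.array(take(total), dtype=np.int64)
            rows, i = [], 0
            for _ in range(n):
                k = data[i]
                if k != 3:
                    raise MeshTopologyError(f"{path}: non-triangular cell ({k} vertices)")
                rows.append(data[i + 1:i + 4])
                i += k + 1
            faces = np.array(rows, dtype=np.int64)
        elif kw == "POINT_DATA":
            pos += 2
        elif kw == "FIELD":
            n_arrays = int(tokens[pos + 2]); pos += 3
            for _ in range(n_arrays):
                name = tokens[pos]
                ncomp, ntup = int(tokens[pos + 1]), int(tokens[pos + 2])
                pos += 4  # name ncomp ntuples dtype
                vals = np.array(take(ncomp * ntup), dtype=float)
                if ncomp == 1:
                    fields[name] = ScalarField(name, vals)
        elif kw == "SCALARS":
            name = tokens[pos + 1]; pos += 3
            if pos < len(tokens) and tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            nv = len(vertices) if vertices is not None else 0
            fields[name] = ScalarField(name, np.array(take(nv), dtype=float))
        else:
            pos += 1
    if vertices is None or faces is None:
        raise MeshFormatError(f"{path}: missing POINTS or POLYGONS")
    m = TriMesh(vertices, faces)
    for fld in fields.values():
        m.attach(fld)
    return m


def _write_vtk_polydata(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmultiview-wss surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for tri in mesh.faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if mesh.fields:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            fh.write(f"FIELD FieldData {len(mesh.fields)}\n")
            for name in sorted(mesh.fields):
                vals = mesh.fields[name].values
                fh.write(f"{name} 1 {len(vals)} double\n")
                for i in range(0, len(vals), 6):
                    fh.write(" ".join(f"{x:.17g}" for x in vals[i:i + 6]) + "\n")


# ---------------------------------------------------------------------------
# Mean curvature
# ---------------------------------------------------------------------------

def mean_curvature(
    mesh: TriMesh,
    clip_percentiles: tuple[float, float] | None = (1.0, 99.0),
) -> ScalarField:
    """Discrete signed mean curvature (1/mm) at every vertex.

    Uses the cotangent Laplacian with barycentric vertex areas: the
    Laplace–Beltrami operator applied to the coordinates gives the mean
    curvature normal, whose signed magnitude along the outward vertex normal
    is H. Convex bulges (sphere with outward normals) are positive.

    Zero-area triangles are excluded from the stencil with a warning.
    Boundary vertices inherit the value of the nearest interior vertex.
    Values are clipped to ``clip_percentiles`` of the per-mesh distribution
    (discrete estimators spike at sliver triangles; an unclipped range would
    crush the colormap). Pass ``clip_percentiles=None`` for raw values.
    """
    if mesh.n_vertices < 4:
        raise ValueError("mean curvature needs at least 4 vertices")
    V, F = mesh.vertices, mesh.faces

    e01 = V[F[:, 1]] - V[F[:, 0]]
    e02 = V[F[:, 2]] - V[F[:, 0]]
    cross = np.cross(e01, e02)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    ok = areas > 1e-12
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} degenerate triangles excluded from "
                      "curvature stencil", stacklevel=2)
    F, areas = F[ok], areas[ok]

    n = mesh.n_vertices
    Lx = np.zeros((n, 3))
    Adual = np.zeros(n)
    # cot at corner k is (e_a . e_b) / (2*area) for the two edges leaving k
    for k in range(3):
        i, j, opp = F[:, (k + 1) % 3], F[:, (k + 2) % 3], F[:, k]
        ea = V[i] - V[opp]
        eb = V[j] - V[opp]
        cot = np.einsum("ij,ij->i", ea, eb) / (2.0 * areas)
        w = 0.5 * cot
        d = V[j] - V[i]
        np.add.at(Lx, i, w[:, None] * d)
        np.add.at(Lx, j, -w[:, None] * d)
    for k in range(3):
        np.add.at(Adual, F[:, k], areas / 3.0)

    interior = Adual > 1e-14
    normals = mesh.vertex_normals()
    H = np.zeros(n)
    # mean curvature normal: (1/2A) * sum w (xj - xi) = -H n  (outward n)
    Hn = np.zeros((n, 3))
    Hn[interior] = Lx[interior] / (2.0 * Adual[interior, None])
    H[interior] = -np.einsum("ij,ij->i", Hn[interior], normals[interior])

    # boundary vertices (edges with a single incident face) take the nearest
    # interior value: the one-sided stencil there is meaningless
    boundary = _boundary_vertices(F, n)
    good = interior & ~boundary
    bad = ~good
    if bad.any():
        if not good.any():
            raise ValueError("no interior vertices for curvature estimation")
        tree = cKDTree(V[good])
        _, idx = tree.query(V[bad])
        H[bad] = H[good][idx]

    if clip_percentiles is not None:
        lo, hi = np.percentile(H, clip_percentiles)
        if lo < hi:
            H = np.clip(H, lo, hi)
    return ScalarField(
        "curvature", H, units="1/mm",
        meta={"estimator": "cotangent-laplacian", "signed": True,
              "clip_percentiles": clip_percentiles},
    )


def _boundary_vertices(faces: np.ndarray, n_vertices: int) -> np.ndarray:
    edges = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    out = np.zeros(n_vertices, dtype=bool)
    out[uniq[counts == 1].ravel()] = True
    return out
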