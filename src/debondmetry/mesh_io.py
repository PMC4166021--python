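"""Triangle-mesh ingestion, validation and export.

Tooth-surface scans enter the pipeline as open triangle meshes (PLY, STL or
OBJ, coordinates in millimetres) and every downstream stage operates on the
:class:`TriangleSurface` container defined here.  Coordinates are taken
verbatim as mm — optical-scanner exports are metric and no unit metadata is
parsed.

Validation is deliberately strict: the deviation and volume stages assume a
clean, consistently oriented open patch, so problems are reported up front
(invalid face indices, degenerate faces, non-manifold edges, inconsistent
winding) rather than surfacing later as sign errors in the deviation field.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleSurface",
    "MeshIOError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
]

_FORMATS = ("ply", "stl", "obj")


class MeshIOError(OSError):
    """A mesh file could not be read or written."""


class MeshValidationError(ValueError):
    """A parsed mesh violates the TriangleSurface invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid mesh: " + "; ".join(self.violations))


@dataclass
class TriangleSurface:
    """An open triangle mesh of a tooth buccal surface, coordinates in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Triangles as vertex-index triples, consistently wound so that face
        normals point away from the tooth body (toward the scanner).
    vertex_normals : (n, 3) float array, optional
        Outward unit normals; computed on demand (area-weighted average of
        incident face normals) when not supplied.
    metadata : dict
        Free-form tags (tooth id, stage: ``reference`` | ``measured`` ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertex_normals is not None:
            self.vertex_normals = np.ascontiguousarray(
                self.vertex_normals, dtype=np.float64
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def normals(self) -> np.ndarray:
        """Per-vertex outward unit normals (computed and cached if absent)."""
        if self.vertex_normals is None:
            tm = self.to_trimesh()
            self.vertex_normals = np.asarray(tm.vertex_normals, dtype=np.float64)
        return self.vertex_normals

    def face_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def copy(self) -> "TriangleSurface":
        return TriangleSurface(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
            dict(self.metadata),
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def bounding_box_diagonal(self) -> float:
        if self.n_vertices == 0:
            return 0.0
        span = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(span))


# ---------------------------------------------------------------------------
# validation

def validate_mesh(surface: TriangleSurface) -> list[str]:
    """Check all TriangleSurface invariants; return a list of violations.

    Total over well-typed input: never raises, an empty list means valid.
    Each entry names the invariant and the offending element indices.
    """
    out: list[str] = []
    v, f = surface.vertices, surface.faces
    if v.ndim != 2 or v.shape[1] != 3:
        return [f"vertices must be (n, 3), got {v.shape}"]
    if f.ndim != 2 or f.shape[1] != 3:
        return [f"faces must be (m, 3), got {f.shape}"]
    if len(v) == 0 or len(f) == 0:
        out.append("mesh is empty")
        return out

    if not np.isfinite(v).all():
        bad = np.unique(np.nonzero(~np.isfinite(v))[0])
        out.append(f"non-finite vertex coordinates at {_fmt(bad)}")
    if (f < 0).any() or (f >= len(v)).any():
        bad = np.unique(np.nonzero((f < 0) | (f >= len(v)))[0])
        out.append(f"face index out of range at faces {_fmt(bad)}")
        return out  # further checks need valid indices

    repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    if repeated.any():
        out.append(f"face repeats a vertex at faces {_fmt(np.nonzero(repeated)[0])}")

    areas = surface.face_areas()
    zero = ~repeated & (areas <= 0.0)
    if zero.any():
        out.append(f"zero-area face at faces {_fmt(np.nonzero(zero)[0])}")

    if np.isfinite(v).all() and surface.bounding_box_diagonal() <= 0.0:
        out.append("bounding-box diagonal is zero (all vertices coincide)")

    if surface.vertex_normals is not None:
        n = surface.vertex_normals
        if n.shape != v.shape:
            out.append(f"vertex_normals shape {n.shape} != vertices {v.shape}")
        else:
            lens = np.linalg.norm(n, axis=1)
            bad = np.nonzero(np.abs(lens - 1.0) > 1e-6)[0]
            if len(bad):
                out.append(f"non-unit vertex normals at {_fmt(bad)}")

    out.extend(_check_edges(f))
    return out


def _check_edges(faces: np.ndarray) -> list[str]:
    """Interior edges must be shared by exactly 2 faces with opposite winding."""
    out = []
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    lo = directed.min(axis=1)
    hi = directed.max(axis=1)
    und = lo.astype(np.int64) * (faces.max() + 1) + hi
    order = np.argsort(und, kind="stable")
    und_s = und[order]
    uniq, start, counts = np.unique(und_s, return_index=True, return_counts=True)

    over = counts > 2
    if over.any():
        edges = [_edge_of(directed[order[s]]) for s in start[over][:5]]
        out.append(f"non-manifold edge (shared by >2 faces): {edges}")

    # winding: an interior edge must appear once in each direction
    forward = directed[:, 0] < directed[:, 1]
    fwd_sorted = forward[order]
    starts2 = start[counts == 2]
    same_dir = fwd_sorted[starts2] == fwd_sorted[starts2 + 1]
    for s in starts2[same_dir][:5]:
        out.append(f"inconsistent winding at edge {_edge_of(directed[order[s]])}")
    return out


def _edge_of(e: np.ndarray) -> tuple[int, int]:
    return (int(min(e)), int(max(e)))


def _fmt(idx: np.ndarray, limit: int = 8) -> str:
    idx = np.asarray(idx)
    head = ", ".join(str(int(i)) for i in idx[:limit])
    return f"[{head}{', ...' if len(idx) > limit else ''}]"


# ---------------------------------------------------------------------------
# reading

def read_mesh(path: str | Path, format: str | None = None) -> TriangleSurface:
    """Read a PLY/STL/OBJ triangle mesh (mm) and validate it.

    ``format`` defaults to the file extension.  STL stores one vertex record
    per facet corner, so bit-identical duplicates are merged on load to
    recover shared topology; other formats are taken as stored.

    Raises
    ------
    MeshIOError
        If the file is missing or unparseable.
    MeshValidationError
        If the parsed mesh violates the TriangleSurface invariants.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    if not path.is_file():
        raise MeshIOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader failures
        raise MeshIOError(f"cannot parse {path} as {fmt.upper()}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshIOError(f"{path} contains no triangle geometry")

    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = _merge_exact_duplicates(vertices, faces)

    surface = TriangleSurface(vertices, faces, metadata={"source": str(path)})
    violations = validate_mesh(surface)
    if violations:
        raise MeshValidationError(violations)
    return surface


def _merge_exact_duplicates(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge bit-identical vertices, keeping first-occurrence order."""
    uniq, first, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first, kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    return uniq[order], rank[inverse][faces]


def _resolve_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


# ---------------------------------------------------------------------------
# writing

def write_mesh(
    surface: TriangleSurface,
    path: str | Path,
    format: str | None = None,
    *,
    vertex_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a surface to PLY (binary, float64), STL (binary) or OBJ.

    Binary PLY stores coordinates as 64-bit doubles so a write→read
    round-trip is bit-exact; STL is limited to 32-bit floats by the format.
    ``vertex_scalars`` attaches extra per-vertex float properties (PLY only),
    used to export deviation fields for external viewers.
    """
    path = Path(path)
    fmt = _resolve_format(path, format)
    violations = validate_mesh(surface)
    if violations:
        raise MeshValidationError(violations)
    if vertex_scalars and fmt != "ply":
        raise ValueError("per-vertex scalar properties require PLY output")
    try:
        if fmt == "ply":
            path.write_bytes(_export_ply_double(surface, vertex_scalars or {}))
        else:
            tm = surface.to_trimesh()
            data = tm.export(file_type=fmt)
            if isinstance(data, str):
                path.write_text(data)
            else:
                path.write_bytes(data)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


def _export_ply_double(
    surface: TriangleSurface, vertex_scalars: dict[str, np.ndarray]
) -> bytes:
    """Binary little-endian PLY with double-precision vertex coordinates."""
    n, m = surface.n_vertices, surface.n_faces
    names = ["x", "y", "z"]
    cols = [surface.vertices[:, 0], surface.vertices[:, 1], surface.vertices[:, 2]]
    for key, values in vertex_scalars.items():
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (n,):
            raise ValueError(f"vertex scalar {key!r} must have shape ({n},)")
        names.append(key)
        cols.append(values)

    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n}"]
    header += [f"property double {name}" for name in names]
    header += [
        f"element face {m}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    buf = io.BytesIO()
    buf.write(("\n".join(header) + "\n").encode("ascii"))

    vdata = np.empty((n, len(cols)), dtype="<f8")
    for j, col in enumerate(cols):
        vdata[:, j] = col
    buf.write(vdata.tobytes())

    fdata = np.empty(m, dtype=[("count", "u1"), ("idx", "<i4", (3,))])
    fdata["count"] = 3
    fdata["idx"] = surface.faces
    buf.write(fdata.tobytes())
    return buf.getvalue()


def read_ply_vertex_scalars(path: str | Path, names: list[str]) -> dict[str, np.ndarray]:
    """Read named per-vertex float properties back from a PLY file."""
    tm = trimesh.load(str(path), file_type="ply", process=False, force="mesh")
    meta = tm.metadata.get("_ply_raw", {})
    vert = meta.get("vertex", {}) if meta else {}
    data = vert.get("data") if vert else None
    out = {}
    for name in names:
        if data is not None and name in data.dtype.names:
            out[name] = np.asarray(data[name], dtype=np.float64)
        else:
            raise MeshIOError(f"property {name!r} not found in {path}")
    return out
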