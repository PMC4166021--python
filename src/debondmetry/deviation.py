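"""Per-point signed shape deviation of a measured surface from a reference.

After superimposition every vertex of the measured (post-debond) mesh is
compared with the reference (pre-bond) surface: the deviation is the exact
Euclidean distance to the closest point on the reference, signed by which
side of the reference the vertex lies on.  Positive deviations are material
above the original enamel (adhesive remnants), negative deviations are
material missing from it (enamel loss).

Sign convention: the reference normal at the closest point is interpolated
barycentrically from vertex normals (avoiding sign flips across face edges
on smooth surfaces); the deviation is positive iff the vertex lies on the
outward-normal side.  Vertices whose closest point lies on the open boundary
of the reference patch, or farther than ``max_distance``, are flagged
invalid — deviation there mixes real change with patch-trimming artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._queries import SurfaceQuery
from .mesh_io import TriangleSurface

__all__ = [
    "DeviationField",
    "FieldExtrema",
    "EmptyFieldError",
    "signed_deviation",
    "field_extrema",
    "save_deviation_ply",
]


class EmptyFieldError(ValueError):
    """A deviation field has no valid vertices."""


@dataclass
class DeviationField:
    """Signed normal deviation (mm) per vertex of the measured surface.

    ``deviation`` is finite exactly where ``valid`` is true (NaN elsewhere);
    ``closest_point`` is each vertex's exact nearest point on the reference
    (its footprint, used for volume integration), ``closest_face`` the
    reference triangle containing it.
    """

    host: TriangleSurface
    deviation: np.ndarray
    closest_face: np.ndarray
    closest_point: np.ndarray
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_deviations(self) -> np.ndarray:
        return self.deviation[self.valid]


@dataclass(frozen=True)
class FieldExtrema:
    """Per-sign extrema of deviation magnitudes; ``None`` marks an absent side."""

    max_positive: float | None
    min_positive: float | None
    max_negative_magnitude: float | None
    min_negative_magnitude: float | None


def signed_deviation(
    measured: TriangleSurface,
    reference: TriangleSurface,
    max_distance: float = 2.0,
) -> DeviationField:
    """Compare every measured vertex with the reference surface.

    ``measured`` must already be registered into the reference frame and the
    reference must have consistent outward orientation.  The default
    ``max_distance`` of 2 mm is far above any plausible debonding change and
    only rejects gross mismatches.
    """
    if reference.n_faces == 0 or reference.n_vertices == 0:
        raise ValueError("reference surface is empty")
    if measured.n_vertices == 0:
        raise ValueError("measured surface is empty")

    query = SurfaceQuery(reference)
    dist, cp, face, bary = query.query(measured.vertices)
    normals = query.interpolated_normal(face, bary)
    side = np.einsum("ij,ij->i", measured.vertices - cp, normals)
    signed = np.where(side >= 0, dist, -dist)

    valid = (dist <= max_distance) & ~query.on_boundary(face, bary)
    deviation = np.where(valid, signed, np.nan)
    return DeviationField(
        host=measured,
        deviation=deviation,
        closest_face=face,
        closest_point=cp,
        valid=valid,
    )


def save_deviation_ply(field: DeviationField, path) -> None:
    """Export the host mesh with per-vertex ``deviation_mm`` and ``valid``
    properties (binary PLY), for external color-mapped viewers."""
    from .mesh_io import write_mesh

    write_mesh(
        field.host,
        path,
        "ply",
        vertex_scalars={
            "deviation_mm": np.nan_to_num(field.deviation),
            "valid": field.valid.astype(np.float64),
        },
    )


def field_extrema(field: DeviationField) -> FieldExtrema:
    """Max/min deviation magnitudes, positives and negatives separately.

    Zero deviations belong to neither side; a side with no vertices is
    reported as absent (``None``), not as zero.
    """
    d = field.valid_deviations()
    if d.size == 0:
        raise EmptyFieldError("deviation field has no valid vertices")
    pos = d[d > 0]
    neg = -d[d < 0]
    return FieldExtrema(
        max_positive=float(pos.max()) if pos.size else None,
        min_positive=float(pos.min()) if pos.size else None,
        max_negative_magnitude=float(neg.max()) if neg.size else None,
        min_negative_magnitude=float(neg.min()) if neg.size else None,
    )
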