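"""Rigid superimposition of the post-debond scan onto the pre-bond reference.

The debonded tooth is rescanned in an arbitrary pose, so before any
comparison the measured mesh must be rigidly mapped into the reference
frame.  Because the bonded footprint genuinely changed shape (remnants,
gouges), a plain best-fit would be dragged by exactly the region under
study; the registration here is therefore *trimmed* iterative closest point:
each iteration pairs measured vertices with their exact closest points on
the reference surface, discards the largest-distance fraction of pairs, and
solves the optimal rigid transform on the remainder in closed form
(SVD/Kabsch).  An explicit exclusion mask (e.g. the bonded footprint) can be
supplied instead of — or in addition to — distance trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._queries import SurfaceQuery
from .mesh_io import TriangleSurface

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "DegenerateGeometryError",
    "TrimmingError",
    "kabsch",
    "prealign",
    "icp_register",
    "apply_transform",
]


class DegenerateGeometryError(ValueError):
    """Input geometry has no well-defined principal axes."""


class TrimmingError(ValueError):
    """Trimming/rejection left no correspondences to fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=np.float64))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``inner`` first, then this one."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def to_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix, row-major."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class RegistrationResult:
    """Diagnostics of one superimposition."""

    transform: RigidTransform
    rms_residual: float
    retained_fraction: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# closed-form rigid least squares

def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Rigid transform minimizing Σ‖R·sᵢ + t − tᵢ‖² (SVD, det-corrected)."""
    P = np.asarray(source, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, qc - R @ pc)


# ---------------------------------------------------------------------------
# initialization

def prealign(
    measured: TriangleSurface,
    reference: TriangleSurface,
    max_points: int = 2000,
) -> RigidTransform:
    """Coarse alignment by centroids and principal axes.

    The four rotations consistent with principal-axis sign ambiguity
    (det +1) are scored by nearest-neighbor RMS on a vertex subsample and
    the best is returned.
    """
    from scipy.spatial import cKDTree

    P = measured.vertices
    Q = reference.vertices
    if len(P) < 3 or len(Q) < 3:
        raise DegenerateGeometryError("need at least 3 vertices to prealign")

    pc, p_axes = _principal_axes(P)
    qc, q_axes = _principal_axes(Q)

    ref_sub = _subsample(Q, max_points)
    tree = cKDTree(ref_sub)
    meas_sub = _subsample(P, max_points)

    best = None
    best_rms = np.inf
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        signs = np.array([s1, s2, s1 * s2], dtype=float)  # keeps det = +1
        R = (q_axes * signs) @ p_axes.T
        T = RigidTransform(R, qc - R @ pc)
        d, _ = tree.query(T.apply(meas_sub))
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best_rms:
            best_rms = rms
            best = T
    return best


def _principal_axes(points: np.ndarray):
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1e-30):
        raise DegenerateGeometryError("vertex covariance is rank-deficient")
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    return c, evecs


def _subsample(points: np.ndarray, max_points: int) -> np.ndarray:
    if max_points is None or len(points) <= max_points:
        return points
    idx = np.unique(np.linspace(0, len(points) - 1, max_points).astype(np.int64))
    return points[idx]


# ---------------------------------------------------------------------------
# trimmed ICP

def icp_register(
    measured: TriangleSurface,
    reference: TriangleSurface,
    trim_fraction: float = 0.3,
    tol: float = 1e-6,
    max_iter: int = 100,
    init: RigidTransform | None = None,
    max_points: int | None = 5000,
    reject_boundary: bool = True,
    exclusion_mask: np.ndarray | None = None,
) -> RegistrationResult:
    """Trimmed point-to-triangle ICP of ``measured`` onto ``reference``.

    Parameters
    ----------
    trim_fraction : float in [0, 0.9]
        Fraction of correspondences with the largest distances discarded at
        every iteration.  The default 0.3 keeps the (changed) bonded
        footprint from driving the fit.
    tol : float, mm
        Convergence threshold on the RMS improvement between iterations.
    init : RigidTransform, optional
        Initial guess; identity if omitted (use :func:`prealign` upstream).
    max_points : int, optional
        Deterministic (even-stride) subsample of measured vertices used for
        correspondences; ``None`` uses all vertices.
    reject_boundary : bool
        Drop correspondences whose closest point lies on the reference
        boundary (overhang has no true counterpart on an open patch).
    exclusion_mask : bool array per measured vertex, optional
        ``True`` marks vertices excluded from correspondences (e.g. a known
        bonded-footprint polygon); applied before distance trimming.

    Notes
    -----
    Ties in the distance trimming are broken by vertex order, and the
    closest-point search tie-breaks on the lowest face index, so repeated
    runs are bit-identical.
    """
    if not 0.0 <= trim_fraction <= 0.9:
        raise ValueError("trim_fraction must be in [0, 0.9]")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    query = SurfaceQuery(reference)
    P_all = measured.vertices
    keep = np.ones(len(P_all), dtype=bool)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != (len(P_all),):
            raise ValueError("exclusion_mask must have one flag per measured vertex")
        keep &= ~exclusion_mask
    P = P_all[keep]
    if max_points is not None and len(P) > max_points:
        idx = np.unique(np.linspace(0, len(P) - 1, max_points).astype(np.int64))
        P = P[idx]
    if len(P) == 0:
        raise TrimmingError("exclusion mask removed every measured vertex")

    T = init if init is not None else RigidTransform.identity()
    prev_rms = np.inf
    rms_history: list[float] = []
    converged = False
    iterations = 0
    retained_fraction = 1.0

    for iterations in range(1, max_iter + 1):
        moved = T.apply(P)
        dist, cp, fidx, bary = query.query(moved)
        ok = np.ones(len(P), dtype=bool)
        if reject_boundary:
            ok &= ~query.on_boundary(fidx, bary)
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise TrimmingError("no correspondences survive boundary rejection")

        n_keep = max(3, int(np.ceil((1.0 - trim_fraction) * n_ok)))
        ok_idx = np.nonzero(ok)[0]
        order = np.argsort(dist[ok_idx], kind="stable")
        retained = ok_idx[order[:n_keep]]
        retained_fraction = len(retained) / len(P)

        rms = float(np.sqrt(np.mean(dist[retained] ** 2)))
        rms_history.append(rms)
        if rms <= tol or prev_rms - rms < tol:
            converged = True
            break
        prev_rms = rms

        T = kabsch(P[retained], cp[retained])

    return RegistrationResult(
        transform=T,
        rms_residual=rms_history[-1],
        retained_fraction=retained_fraction,
        iterations=iterations,
        converged=converged,
        rms_history=rms_history,
    )


def apply_transform(
    surface: TriangleSurface, transform: RigidTransform
) -> TriangleSurface:
    """Map every vertex by R·v + t; normals rotate, faces are unchanged."""
    normals = surface.vertex_normals
    return TriangleSurface(
        transform.apply(surface.vertices),
        surface.faces.copy(),
        None if normals is None else normals @ transform.rotation.T,
        dict(surface.metadata),
    )
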