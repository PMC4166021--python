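"""Synthetic tooth-surface phantoms with analytic ground truth.

No scan data accompanies the debonding experiment this package analyzes, so
validation rests on phantoms: smooth convex buccal-surface patches carrying
cosine-profile features (positive adhesive remnants, negative enamel
gouges), an unknown rigid misalignment between the two "scanning sessions",
and Gaussian displacement noise at the scanner's 2 μm precision.

The cosine bump profile h(r) = (H/2)(1 + cos(πr/R)) for r < R was chosen
over a Gaussian because it has compact support and the closed-form volume

    ∫₀ᴿ h(r)·2πr dr = H·R²·(π/2 − 2/π),

so every generated pair carries exact feature volumes and amplitudes against
which the measurement pipeline can be scored.  Features displace vertices
along the local surface normal (not global z) so the analytic volume matches
the normal-deviation definition used downstream on curved patches; the
radial coordinate is the 3-D chord distance on the undisplaced surface,
which approximates geodesic distance to well within the stated 0.5% volume
tolerance at these curvatures (principal radii ≥ 12 mm, R ≤ 2.5 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh_io import TriangleSurface
from .registration import RigidTransform

__all__ = [
    "Rect",
    "SurfaceFeature",
    "PhantomSpec",
    "PhantomTruth",
    "cosine_bump_volume",
    "generate_base_surface",
    "apply_feature",
    "apply_rigid_and_noise",
    "make_phantom_pair",
    "sample_phantom_spec",
]

#: magnitude envelope of plausible debonding change (mm): remnant heights
#: observed up to 0.76 mm, enamel-loss depths up to 0.207 mm
MAX_REMNANT_AMPLITUDE = 1.0
MAX_GOUGE_AMPLITUDE = 0.3


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in patch (x, y) coordinates, mm."""

    center: tuple[float, float] = (0.0, 0.0)
    width: float = 6.0
    height: float = 5.0

    def contains_disc(self, center: tuple[float, float], radius: float) -> bool:
        cx, cy = self.center
        return (
            abs(center[0] - cx) + radius <= self.width / 2
            and abs(center[1] - cy) + radius <= self.height / 2
        )


@dataclass(frozen=True)
class SurfaceFeature:
    """One compact surface feature: a remnant bump or an enamel gouge.

    ``amplitude`` is the peak height (remnant) or depth (gouge), always
    positive; the sign of the applied displacement follows ``kind``.
    """

    kind: str  # "remnant" (positive) or "gouge" (negative)
    center: tuple[float, float]
    radius: float
    amplitude: float

    def __post_init__(self):
        if self.kind not in ("remnant", "gouge"):
            raise ValueError(f"feature kind must be 'remnant' or 'gouge', got {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be > 0")
        if self.amplitude <= 0:
            raise ValueError("feature amplitude must be > 0")
        cap = MAX_REMNANT_AMPLITUDE if self.kind == "remnant" else MAX_GOUGE_AMPLITUDE
        if self.amplitude > cap:
            raise ValueError(
                f"{self.kind} amplitude {self.amplitude} mm exceeds the "
                f"plausible envelope ({cap} mm)"
            )

    @property
    def sign(self) -> float:
        return 1.0 if self.kind == "remnant" else -1.0

    def analytic_volume(self) -> float:
        return cosine_bump_volume(self.amplitude, self.radius)


def cosine_bump_volume(amplitude: float, radius: float) -> float:
    """Closed-form volume of the cosine bump: H·R²·(π/2 − 2/π)."""
    return amplitude * radius**2 * (np.pi / 2.0 - 2.0 / np.pi)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one pre-bond / post-debond phantom pair.

    Defaults emulate the study conditions: a ~10×8 mm buccal patch with
    principal curvature radii 12 and 20 mm (convex), triangulated at
    0.05 mm pitch; a centered bonded footprint; 2 μm Gaussian scanner
    noise; and a small rigid repositioning between scanning sessions.
    """

    patch_extent: tuple[float, float] = (10.0, 8.0)
    curvature_radii: tuple[float, float] = (12.0, 20.0)
    mesh_pitch: float = 0.05
    footprint: Rect | None = None
    features: tuple[SurfaceFeature, ...] = ()
    misalignment: RigidTransform = field(default_factory=RigidTransform.identity)
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self):
        w, h = self.patch_extent
        if self.mesh_pitch <= 0:
            raise ValueError("mesh_pitch must be > 0")
        if self.mesh_pitch >= min(w, h):
            raise ValueError("mesh_pitch must be smaller than the patch extent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.footprint is None:
            # bonded area defaults to the central 60% of the patch (6 x 5 mm
            # on the default buccal patch — a generous molar-tube footprint)
            object.__setattr__(
                self, "footprint", Rect((0.0, 0.0), 0.6 * w, 0.625 * h)
            )
        fx, fy = self.footprint.center
        if (
            abs(fx) + self.footprint.width / 2 > w / 2
            or abs(fy) + self.footprint.height / 2 > h / 2
        ):
            raise ValueError("footprint must lie within the patch extent")
        for feat in self.features:
            if not self.footprint.contains_disc(feat.center, feat.radius):
                raise ValueError(
                    f"feature at {feat.center} (R={feat.radius}) lies outside "
                    "the bonded footprint"
                )

    def to_dict(self) -> dict:
        return {
            "patch_extent": list(self.patch_extent),
            "curvature_radii": [
                None if np.isinf(r) else r for r in self.curvature_radii
            ],
            "mesh_pitch": self.mesh_pitch,
            "footprint": {
                "center": list(self.footprint.center),
                "width": self.footprint.width,
                "height": self.footprint.height,
            },
            "features": [
                {
                    "kind": f.kind,
                    "center": list(f.center),
                    "radius": f.radius,
                    "amplitude": f.amplitude,
                }
                for f in self.features
            ],
            "misalignment": self.misalignment.to_matrix().tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        fp = d.get("footprint", {})
        radii = d.get("curvature_radii", [12.0, 20.0])
        return cls(
            patch_extent=tuple(d.get("patch_extent", (10.0, 8.0))),
            curvature_radii=tuple(np.inf if r is None else float(r) for r in radii),
            mesh_pitch=float(d.get("mesh_pitch", 0.05)),
            footprint=Rect(
                center=tuple(fp.get("center", (0.0, 0.0))),
                width=float(fp.get("width", 6.0)),
                height=float(fp.get("height", 5.0)),
            ),
            features=tuple(
                SurfaceFeature(
                    kind=f["kind"],
                    center=tuple(f["center"]),
                    radius=float(f["radius"]),
                    amplitude=float(f["amplitude"]),
                )
                for f in d.get("features", [])
            ),
            misalignment=RigidTransform.from_matrix(
                d.get("misalignment", np.eye(4))
            ),
            noise_sd=float(d.get("noise_sd", 0.002)),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated pair."""

    feature_volumes: list[float]
    feature_amplitudes: list[float]
    feature_kinds: list[str]
    total_remnant_volume: float
    total_loss_volume: float
    misalignment: RigidTransform
    noise_sd: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_volumes": self.feature_volumes,
                "feature_amplitudes": self.feature_amplitudes,
                "feature_kinds": self.feature_kinds,
                "total_remnant_volume": self.total_remnant_volume,
                "total_loss_volume": self.total_loss_volume,
                "misalignment": self.misalignment.to_matrix().tolist(),
                "noise_sd": self.noise_sd,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhantomTruth":
        d = json.loads(text)
        return cls(
            feature_volumes=d["feature_volumes"],
            feature_amplitudes=d["feature_amplitudes"],
            feature_kinds=d["feature_kinds"],
            total_remnant_volume=d["total_remnant_volume"],
            total_loss_volume=d["total_loss_volume"],
            misalignment=RigidTransform.from_matrix(d["misalignment"]),
            noise_sd=d["noise_sd"],
        )


# ---------------------------------------------------------------------------
# base surface

def generate_base_surface(spec: PhantomSpec) -> TriangleSurface:
    """Smooth convex buccal-surface patch on a regular triangulated grid.

    z(x, y) = −x²/(2r₁) − y²/(2r₂) (bulging toward +z, the scanner side)
    plus a seeded low-frequency undulation of total amplitude ≤ 0.1 mm that
    breaks the symmetry of the pure quadric (real enamel is not a quadric,
    and registration needs non-degenerate geometry).  Deterministic given
    the spec's seed.
    """
    w, h = spec.patch_extent
    nx = int(round(w / spec.mesh_pitch)) + 1
    ny = int(round(h / spec.mesh_pitch)) + 1
    xs = np.linspace(-w / 2, w / 2, nx)
    ys = np.linspace(-h / 2, h / 2, ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    Z = _base_height(X, Y, spec)

    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = _grid_faces(nx, ny)
    return TriangleSurface(
        vertices,
        faces,
        metadata={"stage": "reference", "phantom_seed": spec.seed},
    )


def _base_height(X, Y, spec: PhantomSpec):
    r1, r2 = spec.curvature_radii
    Z = np.zeros_like(X, dtype=np.float64)
    if np.isfinite(r1):
        Z -= X**2 / (2.0 * r1)
    if np.isfinite(r2):
        Z -= Y**2 / (2.0 * r2)
    return Z + _undulation(X, Y, spec.seed)


def _undulation(X, Y, seed: int, n_terms: int = 3, total_amplitude: float = 0.06):
    """Deterministic low-frequency surface texture (amplitude ≤ 0.1 mm)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    amps = rng.uniform(0.5, 1.0, n_terms)
    amps *= total_amplitude / amps.sum()
    freqs = rng.uniform(0.05, 0.2, (n_terms, 2))  # cycles/mm: 5–20 mm waves
    phases = rng.uniform(0, 2 * np.pi, n_terms)
    Z = np.zeros_like(X, dtype=np.float64)
    for a, (fx, fy), p in zip(amps, freqs, phases):
        Z += a * np.cos(2 * np.pi * (fx * X + fy * Y) + p)
    return Z


def _grid_faces(nx: int, ny: int) -> np.ndarray:
    """Two triangles per grid cell, wound counterclockwise seen from +z."""
    idx = np.arange(nx * ny).reshape(ny, nx)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[:-1, 1:].ravel()
    v01 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    return np.concatenate(
        [
            np.column_stack([v00, v10, v11]),
            np.column_stack([v00, v11, v01]),
        ]
    )


# ---------------------------------------------------------------------------
# features

def apply_feature(
    surface: TriangleSurface, feature: SurfaceFeature
) -> tuple[TriangleSurface, float]:
    """Displace vertices inside the feature disc along local normals.

    Vertices with chord distance r < R from the feature's center point are
    moved by ±h(r), h(r) = (H/2)(1 + cos(πr/R)); the returned analytic
    volume is the closed form H·R²·(π/2 − 2/π).  The feature must be fully
    supported on the patch (its disc may not touch the boundary).
    """
    center_3d = _surface_point(surface, feature.center)
    xy = surface.vertices[:, :2]
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    if not (
        feature.center[0] - feature.radius > lo[0]
        and feature.center[0] + feature.radius < hi[0]
        and feature.center[1] - feature.radius > lo[1]
        and feature.center[1] + feature.radius < hi[1]
    ):
        raise ValueError("feature disc overlaps the patch boundary")

    r = np.linalg.norm(surface.vertices - center_3d, axis=1)
    inside = r < feature.radius
    h = np.zeros(surface.n_vertices)
    h[inside] = (feature.amplitude / 2.0) * (
        1.0 + np.cos(np.pi * r[inside] / feature.radius)
    )
    normals = surface.normals()
    vertices = surface.vertices + feature.sign * h[:, None] * normals
    out = TriangleSurface(vertices, surface.faces.copy(), None, dict(surface.metadata))
    return out, feature.analytic_volume()


def _surface_point(surface: TriangleSurface, xy: tuple[float, float]) -> np.ndarray:
    """Surface point above patch coordinates (x, y), by barycentric lookup."""
    from scipy.spatial import cKDTree

    p2 = np.asarray(xy, dtype=np.float64)
    v2 = surface.vertices[:, :2]
    tree = cKDTree(v2)
    _, nearest = tree.query(p2)
    # search faces incident to vertices near the target point
    _, ring = tree.query(p2, k=min(12, surface.n_vertices))
    ring = np.atleast_1d(ring)
    cand = np.nonzero(np.isin(surface.faces, ring).any(axis=1))[0]
    for fi in cand:
        tri = surface.faces[fi]
        a, b, c = v2[tri[0]], v2[tri[1]], v2[tri[2]]
        det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
        if det == 0:
            continue
        l1 = ((b[0] - p2[0]) * (c[1] - p2[1]) - (c[0] - p2[0]) * (b[1] - p2[1])) / det
        l2 = ((c[0] - p2[0]) * (a[1] - p2[1]) - (a[0] - p2[0]) * (c[1] - p2[1])) / det
        l3 = 1.0 - l1 - l2
        if l1 >= -1e-12 and l2 >= -1e-12 and l3 >= -1e-12:
            V = surface.vertices
            return l1 * V[tri[0]] + l2 * V[tri[1]] + l3 * V[tri[2]]
    return surface.vertices[int(nearest)]


# ---------------------------------------------------------------------------
# rigid motion + scanner noise

def apply_rigid_and_noise(
    surface: TriangleSurface,
    transform: RigidTransform,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
) -> TriangleSurface:
    """Map the surface by a rigid motion, then add scanner noise.

    Each vertex is displaced along its (rotated) outward normal by an
    independent Gaussian draw of standard deviation ``noise_sd`` (mm);
    deterministic given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    normals = surface.normals() @ transform.rotation.T
    vertices = transform.apply(surface.vertices)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vertices = vertices + rng.normal(0.0, noise_sd, surface.n_vertices)[:, None] * normals
    return TriangleSurface(vertices, surface.faces.copy(), None, dict(surface.metadata))


# ---------------------------------------------------------------------------
# pair assembly

def make_phantom_pair(
    spec: PhantomSpec,
) -> tuple[TriangleSurface, TriangleSurface, PhantomTruth]:
    """Generate a (pre-bond, post-debond, truth) triple.

    The pre mesh is the base surface plus one noise realization; the post
    mesh is the base surface plus all features, mapped by the spec's
    misalignment, plus an *independent* noise realization (the physical
    surface was scanned twice).  Truth records analytic feature volumes,
    amplitudes and the applied misalignment.
    """
    base = generate_base_surface(spec)
    pre = apply_rigid_and_noise(
        base,
        RigidTransform.identity(),
        spec.noise_sd,
        np.random.SeedSequence([spec.seed, 1]),
    )
    pre.metadata["stage"] = "reference"

    post = base
    volumes: list[float] = []
    for feat in spec.features:
        post, vol = apply_feature(post, feat)
        volumes.append(vol)
    post = apply_rigid_and_noise(
        post,
        spec.misalignment,
        spec.noise_sd,
        np.random.SeedSequence([spec.seed, 2]),
    )
    post.metadata["stage"] = "measured"

    truth = PhantomTruth(
        feature_volumes=volumes,
        feature_amplitudes=[f.amplitude for f in spec.features],
        feature_kinds=[f.kind for f in spec.features],
        total_remnant_volume=sum(
            v for v, f in zip(volumes, spec.features) if f.kind == "remnant"
        ),
        total_loss_volume=sum(
            v for v, f in zip(volumes, spec.features) if f.kind == "gouge"
        ),
        misalignment=spec.misalignment,
        noise_sd=spec.noise_sd,
    )
    return pre, post, truth


# ---------------------------------------------------------------------------
# randomized study-condition sampler

def sample_phantom_spec(
    seed: int,
    mesh_pitch: float = 0.05,
    noise_sd: float = 0.002,
    max_rotation_deg: float = 5.0,
    max_translation: float = 2.0,
) -> PhantomSpec:
    """Draw a random phantom within the study's observed envelope.

    One or two remnant bumps (peak height 0.05–0.76 mm) and one gouge
    (peak depth 0.04–0.2 mm, spanning the per-tooth maximum loss depths
    observed after molar-tube debonding) placed disjointly in the bonded
    footprint; a rigid
    misalignment of up to 5° rotation and 2 mm translation (teeth were
    repositioned between scanning sessions but held in a silicone bed, so
    misalignments are small).  Feature discs cover well under 30% of the
    patch so trimmed registration has a clean majority to fit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    footprint = Rect()

    specs = [("remnant", rng.uniform(1.2, 1.8), rng.uniform(0.1, 0.76))]
    if rng.random() < 0.5:
        specs.append(("remnant", rng.uniform(0.9, 1.1), rng.uniform(0.05, 0.4)))
    specs.append(("gouge", rng.uniform(0.8, 1.2), rng.uniform(0.04, 0.2)))

    features: list[SurfaceFeature] = []
    # place larger discs first; shrink a disc that cannot fit rather than
    # dropping it, so every phantom keeps both a remnant and a gouge
    for kind, radius, amplitude in sorted(specs, key=lambda s: -s[1]):
        placed = None
        for _ in range(6):
            placed = _place_disc(rng, footprint, radius, features)
            if placed is not None:
                break
            radius *= 0.8
        if placed is None:
            continue
        features.append(SurfaceFeature(kind, placed, radius, amplitude))

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(1.0, max_rotation_deg))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = direction * rng.uniform(0.5, max_translation)

    return PhantomSpec(
        mesh_pitch=mesh_pitch,
        footprint=footprint,
        features=tuple(features),
        misalignment=RigidTransform.from_axis_angle(axis, angle, translation),
        noise_sd=noise_sd,
        seed=seed,
    )


def _place_disc(rng, footprint: Rect, radius: float, existing, tries: int = 200):
    cx, cy = footprint.center
    half_w = footprint.width / 2 - radius
    half_h = footprint.height / 2 - radius
    if half_w <= 0 or half_h <= 0:
        return None
    for _ in range(tries):
        p = (
            cx + rng.uniform(-half_w, half_w),
            cy + rng.uniform(-half_h, half_h),
        )
        if all(
            np.hypot(p[0] - f.center[0], p[1] - f.center[1])
            >= radius + f.radius + 0.15
            for f in existing
        ):
            return p
    return None


def noise_free(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom with the scanner-noise model switched off."""
    return replace(spec, noise_sd=0.0)
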