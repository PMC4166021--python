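import numpy as np
import pytest
from scipy.integrate import quad

from debondmetry.mesh_io import validate_mesh
from debondmetry.phantom import (
    PhantomSpec,
    Rect,
    SurfaceFeature,
    apply_feature,
    apply_rigid_and_noise,
    cosine_bump_volume,
    generate_base_surface,
    make_phantom_pair,
    sample_phantom_spec,
)
from debondmetry.registration import RigidTransform


def quadrature_bump_volume(H, R):
    """Independent oracle: numerically integrate the bump profile."""
    val, _ = quad(lambda r: (H / 2.0) * (1 + np.cos(np.pi * r / R)) * 2 * np.pi * r, 0, R)
    return val


class TestBumpVolumeFormula:
    @pytest.mark.parametrize(
        "H, R, expected",
        [
            (0.5, 1.5, 1.0509),   # frozen from the quadrature oracle
            (0.05, 1.0, 0.0467),
            (0.3, 1.2, 0.4036),
            (0.04, 0.8, 0.0239),
        ],
    )
    def test_closed_form_matches_quadrature(self, H, R, expected):
        oracle = quadrature_bump_volume(H, R)
        assert cosine_bump_volume(H, R) == pytest.approx(oracle, rel=1e-12)
        assert cosine_bump_volume(H, R) == pytest.approx(expected, abs=5e-5)


class TestBaseSurface:
    def test_default_vertex_count_and_finiteness(self):
        spec = PhantomSpec()
        surf = generate_base_surface(spec)
        expected = (10 / 0.05 + 1) * (8 / 0.05 + 1)
        assert abs(surf.n_vertices - expected) / expected < 0.1
        assert np.isfinite(surf.vertices).all()
        assert validate_mesh(surf) == []

    def test_flat_limit_keeps_only_undulation(self):
        spec = PhantomSpec(curvature_radii=(np.inf, np.inf), mesh_pitch=0.2, seed=5)
        surf = generate_base_surface(spec)
        assert np.abs(surf.vertices[:, 2]).max() <= 0.1  # undulation cap

    def test_deterministic_given_seed(self):
        a = generate_base_surface(PhantomSpec(mesh_pitch=0.2, seed=3))
        b = generate_base_surface(PhantomSpec(mesh_pitch=0.2, seed=3))
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_pitch_larger_than_patch_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(mesh_pitch=20.0)


class TestApplyFeature:
    def test_returns_closed_form_volume(self):
        surf = generate_base_surface(PhantomSpec(mesh_pitch=0.1, seed=1))
        out, vol = apply_feature(surf, SurfaceFeature("remnant", (0, 0), 1.5, 0.5))
        assert vol == pytest.approx(1.0509, abs=5e-5)
        assert out.n_vertices == surf.n_vertices

    def test_displacement_bounded_by_amplitude(self):
        surf = generate_base_surface(PhantomSpec(mesh_pitch=0.1, seed=1))
        out, _ = apply_feature(surf, SurfaceFeature("gouge", (0.5, 0.3), 1.0, 0.05))
        moved = np.linalg.norm(out.vertices - surf.vertices, axis=1)
        assert moved.max() <= 0.05 + 1e-12
        assert (moved > 0).any()

    def test_feature_touching_patch_boundary_rejected(self):
        surf = generate_base_surface(PhantomSpec(mesh_pitch=0.2, seed=1))
        with pytest.raises(ValueError, match="boundary"):
            apply_feature(surf, SurfaceFeature("remnant", (4.5, 0.0), 1.0, 0.1))

    def test_amplitude_envelope_enforced(self):
        with pytest.raises(ValueError):
            SurfaceFeature("remnant", (0, 0), 1.0, 1.5)
        with pytest.raises(ValueError):
            SurfaceFeature("gouge", (0, 0), 1.0, 0.5)

    def test_envelope_extremes_are_constructible(self):
        # largest remnant and loss volumes seen in debonding studies
        big = SurfaceFeature("remnant", (0, 0), 2.42, 0.76)
        assert big.analytic_volume() == pytest.approx(4.16, abs=0.01)
        small = SurfaceFeature("remnant", (0, 0), 1.0, 0.05)
        assert small.analytic_volume() == pytest.approx(0.047, abs=0.001)
        deep = SurfaceFeature("gouge", (0, 0), 2.3, 0.3)
        assert deep.analytic_volume() == pytest.approx(1.48, abs=0.01)


class TestRigidAndNoise:
    def test_identity_no_noise_is_identity(self, unit_square):
        out = apply_rigid_and_noise(unit_square, RigidTransform.identity(), 0.0, 1)
        assert np.array_equal(out.vertices, unit_square.vertices)

    def test_pure_translation_shifts_exactly(self, unit_square):
        T = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        out = apply_rigid_and_noise(unit_square, T, 0.0, 1)
        assert np.allclose(out.vertices - unit_square.vertices, [1, 2, 3], atol=1e-15)

    def test_noise_sd_matches_request(self):
        surf = generate_base_surface(PhantomSpec(mesh_pitch=0.028, seed=8))
        assert surf.n_vertices >= 1e5
        out = apply_rigid_and_noise(surf, RigidTransform.identity(), 0.002, 123)
        disp = np.linalg.norm(out.vertices - surf.vertices, axis=1)
        # displacement magnitudes are |N(0, sd)|; recover sd from second moment
        sd_hat = np.sqrt((disp**2).mean())
        assert abs(sd_hat - 0.002) / 0.002 < 0.03

    def test_negative_noise_rejected(self, unit_square):
        with pytest.raises(ValueError):
            apply_rigid_and_noise(unit_square, RigidTransform.identity(), -1.0, 1)


class TestPhantomPair:
    def test_truth_totals_sum_feature_volumes(self):
        spec = PhantomSpec(
            mesh_pitch=0.1,
            noise_sd=0.0,
            features=(
                SurfaceFeature("remnant", (-1.0, 0.0), 1.2, 0.3),
                SurfaceFeature("gouge", (1.5, 0.5), 0.8, 0.04),
            ),
            seed=2,
        )
        pre, post, truth = make_phantom_pair(spec)
        assert truth.total_remnant_volume == pytest.approx(0.4036, abs=5e-4)
        assert truth.total_loss_volume == pytest.approx(0.0239, abs=5e-4)
        assert truth.total_remnant_volume == sum(
            v for v, k in zip(truth.feature_volumes, truth.feature_kinds) if k == "remnant"
        )

    def test_no_features_no_noise_identity_pair(self):
        spec = PhantomSpec(mesh_pitch=0.2, noise_sd=0.0, seed=4)
        pre, post, truth = make_phantom_pair(spec)
        assert np.array_equal(pre.vertices, post.vertices)
        assert truth.total_remnant_volume == 0.0

    def test_deterministic_given_seed(self):
        spec = sample_phantom_spec(5, mesh_pitch=0.2)
        a = make_phantom_pair(spec)
        b = make_phantom_pair(spec)
        assert np.array_equal(a[0].vertices, b[0].vertices)
        assert np.array_equal(a[1].vertices, b[1].vertices)

    def test_pre_and_post_noise_independent(self):
        spec = PhantomSpec(mesh_pitch=0.2, noise_sd=0.002, seed=4)
        pre, post, _ = make_phantom_pair(spec)
        assert not np.allclose(pre.vertices, post.vertices)

    def test_feature_outside_footprint_rejected(self):
        with pytest.raises(ValueError, match="footprint"):
            PhantomSpec(
                features=(SurfaceFeature("remnant", (4.0, 0.0), 1.0, 0.1),),
            )

    def test_truth_json_round_trip(self):
        from debondmetry.phantom import PhantomTruth

        spec = sample_phantom_spec(6, mesh_pitch=0.2)
        _, _, truth = make_phantom_pair(spec)
        back = PhantomTruth.from_json(truth.to_json())
        assert back.feature_volumes == truth.feature_volumes
        assert np.allclose(back.misalignment.to_matrix(), truth.misalignment.to_matrix())


class TestSampler:
    @pytest.mark.parametrize("seed", [1, 7, 8, 13])
    def test_sampled_specs_stay_in_envelope(self, seed):
        spec = sample_phantom_spec(seed)
        kinds = [f.kind for f in spec.features]
        assert "remnant" in kinds and "gouge" in kinds
        patch_area = spec.patch_extent[0] * spec.patch_extent[1]
        coverage = sum(np.pi * f.radius**2 for f in spec.features) / patch_area
        assert coverage <= 0.3
        assert spec.misalignment.rotation_angle() <= np.deg2rad(5.0) + 1e-12
        assert np.linalg.norm(spec.misalignment.translation) <= 2.0

    def test_footprint_disc_check(self):
        r = Rect(center=(0, 0), width=6, height=5)
        assert r.contains_disc((0, 0), 2.4)
        assert not r.contains_disc((2.0, 0), 1.5)
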