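import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import flat_patch
from debondmetry.deviation import DeviationField, signed_deviation
from debondmetry.phantom import (
    PhantomSpec,
    SurfaceFeature,
    cosine_bump_volume,
    make_phantom_pair,
)
from debondmetry.quantify import (
    EmptySideError,
    Label,
    ari_artun_bergland,
    ari_krell,
    ari_osorio,
    compute_ari,
    connected_regions,
    deviation_histogram,
    integrate_volume,
    label_field,
    side_statistics,
    vertex_areas,
)


def field_on(surface, deviations, valid=None):
    d = np.asarray(deviations, dtype=float)
    v = np.ones(len(d), dtype=bool) if valid is None else np.asarray(valid, bool)
    return DeviationField(
        host=surface,
        deviation=np.where(v, d, np.nan),
        closest_face=np.zeros(len(d), dtype=int),
        closest_point=surface.vertices.copy(),
        valid=v,
    )


@pytest.fixture(scope="module")
def flat():
    return flat_patch(width=4.0, height=4.0, pitch=0.2)


class TestLabeling:
    def test_soft_mode_keeps_sub_precision_flagged(self, flat):
        d = np.zeros(flat.n_vertices)
        d[:3] = [0.003, 0.001, -0.004]
        lab = label_field(field_on(flat, d), noise_floor=0.002)
        assert lab.labels[0] == Label.REMNANT
        assert lab.labels[1] == Label.REMNANT and lab.sub_precision[1]
        assert lab.labels[2] == Label.LOSS
        assert not lab.sub_precision[0]

    def test_hard_mode_zeroes_sub_precision(self, flat):
        d = np.zeros(flat.n_vertices)
        d[:3] = [0.003, 0.001, -0.004]
        lab = label_field(field_on(flat, d), noise_floor=0.002, hard_threshold=True)
        assert lab.labels[1] == Label.UNCHANGED
        assert lab.labels[0] == Label.REMNANT
        assert lab.labels[2] == Label.LOSS

    def test_all_zero_field_is_unchanged(self, flat):
        for hard in (False, True):
            lab = label_field(field_on(flat, np.zeros(flat.n_vertices)), 0.002, hard)
            assert (lab.labels == Label.UNCHANGED).all()

    def test_negative_floor_rejected(self, flat):
        with pytest.raises(ValueError):
            label_field(field_on(flat, np.zeros(flat.n_vertices)), -0.1)


class TestIntegrateVolume:
    def test_uniform_offset_gives_area_times_height(self):
        patch = flat_patch(width=2.0, height=2.0, pitch=0.2)
        h = 0.05
        fld = field_on(patch, np.full(patch.n_vertices, h))
        vol = integrate_volume(fld, None, "remnant")
        assert vol == pytest.approx(2.0 * 2.0 * h, rel=1e-12)

    def test_cosine_bump_volume_within_one_percent(self):
        spec = PhantomSpec(
            curvature_radii=(np.inf, np.inf),
            mesh_pitch=0.05,
            noise_sd=0.0,
            features=(SurfaceFeature("remnant", (0, 0), 1.5, 0.5),),
            seed=1,
        )
        pre, post, truth = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        vol = integrate_volume(fld, None, "remnant")
        assert abs(vol - cosine_bump_volume(0.5, 1.5)) / cosine_bump_volume(0.5, 1.5) < 0.01

    def test_loss_side_of_positive_field_is_zero(self, flat):
        d = np.full(flat.n_vertices, 0.1)
        assert integrate_volume(field_on(flat, d), None, "loss") == 0.0

    def test_additive_over_disjoint_masks(self, flat):
        rng = np.random.default_rng(3)
        d = rng.normal(0, 0.05, flat.n_vertices)
        fld = field_on(flat, d)
        mask_a = np.zeros(flat.n_vertices, bool)
        mask_a[: flat.n_vertices // 2] = True
        full = integrate_volume(fld, None, "remnant")
        split = integrate_volume(fld, mask_a, "remnant") + integrate_volume(
            fld, ~mask_a, "remnant"
        )
        assert split == pytest.approx(full, abs=1e-12)

    def test_voxel_brute_force_cross_check(self):
        """Prism integration vs dense-grid quadrature of the measured surface."""
        from scipy.interpolate import LinearNDInterpolator

        spec = PhantomSpec(
            curvature_radii=(np.inf, np.inf),
            mesh_pitch=0.05,
            noise_sd=0.0,
            features=(SurfaceFeature("remnant", (0, 0), 1.5, 0.5),),
            seed=1,
        )
        pre, post, truth = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        vol = integrate_volume(fld, None, "remnant")

        # 5 um grid over the bump support; the reference is exactly z = base
        interp = LinearNDInterpolator(post.vertices[:, :2], post.vertices[:, 2])
        base = LinearNDInterpolator(pre.vertices[:, :2], pre.vertices[:, 2])
        g = np.arange(-1.6, 1.6, 0.005)
        X, Y = np.meshgrid(g, g)
        gap = interp(X, Y) - base(X, Y)
        brute = np.nansum(np.maximum(gap, 0.0)) * 0.005**2
        assert abs(vol - brute) / brute < 0.01


class TestSideStatistics:
    def test_hand_arithmetic(self, flat):
        d = np.zeros(flat.n_vertices)
        d[:3] = [0.1, 0.2, 0.3]
        fld = field_on(flat, d)
        lab = label_field(fld)
        s = side_statistics(fld, lab, "remnant")
        assert s.mean == pytest.approx(0.2)
        assert s.max == pytest.approx(0.3)
        assert s.min == pytest.approx(0.1)
        assert s.sd == pytest.approx(0.1)  # sample convention
        assert s.n_vertices == 3

    def test_population_sd_convention(self, flat):
        d = np.zeros(flat.n_vertices)
        d[:3] = [0.1, 0.2, 0.3]
        fld = field_on(flat, d)
        s = side_statistics(fld, label_field(fld), "remnant", ddof=0)
        assert s.sd == pytest.approx(np.std([0.1, 0.2, 0.3]))

    def test_empty_side_marker_not_zeros(self, flat):
        d = np.full(flat.n_vertices, 0.01)
        fld = field_on(flat, d)
        s = side_statistics(fld, label_field(fld), "loss")
        assert s.is_empty
        assert s.mean is None and s.volume is None

    def test_phantom_remnant_stats_match_truth(self):
        spec = PhantomSpec(
            mesh_pitch=0.05,
            noise_sd=0.0,
            features=(SurfaceFeature("remnant", (0, 0), 1.2, 0.3),),
            seed=3,
        )
        pre, post, truth = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        s = side_statistics(fld, label_field(fld), "remnant")
        assert abs(s.max - 0.3) < 1e-3
        assert abs(s.volume - truth.total_remnant_volume) / truth.total_remnant_volume < 0.02


class TestConnectedRegions:
    def test_two_disjoint_remnants_found(self):
        spec = PhantomSpec(
            mesh_pitch=0.08,
            noise_sd=0.0,
            features=(
                SurfaceFeature("remnant", (-1.4, 0.0), 1.0, 0.2),
                SurfaceFeature("remnant", (1.4, 0.0), 1.0, 0.25),
            ),
            seed=5,
        )
        pre, post, _ = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        hard = label_field(fld, 0.002, hard_threshold=True)
        regions = connected_regions(fld, hard, min_area=0.2)
        remnants = [r for r in regions if r.side == "remnant"]
        assert len(remnants) == 2
        # sorted by volume descending
        assert remnants[0].volume >= remnants[1].volume

    def test_single_gouge_volume_within_two_percent(self):
        spec = PhantomSpec(
            mesh_pitch=0.05,
            noise_sd=0.0,
            features=(SurfaceFeature("gouge", (0, 0), 1.0, 0.05),),
            seed=6,
        )
        pre, post, truth = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        regions = connected_regions(fld, label_field(fld, 0.002, True), min_area=0.2)
        assert len(regions) == 1
        r = regions[0]
        assert r.side == "loss"
        assert abs(r.volume - truth.total_loss_volume) / truth.total_loss_volume < 0.02

    def test_no_labels_gives_empty_list(self, flat):
        fld = field_on(flat, np.zeros(flat.n_vertices))
        assert connected_regions(fld, label_field(fld, 0.002, True)) == []

    def test_monotone_in_amplitude(self):
        vols = []
        for H in (0.1, 0.2, 0.4):
            spec = PhantomSpec(
                mesh_pitch=0.08,
                noise_sd=0.0,
                features=(SurfaceFeature("remnant", (0, 0), 1.2, H),),
                seed=7,
            )
            pre, post, _ = make_phantom_pair(spec)
            fld = signed_deviation(post, pre)
            regions = connected_regions(fld, label_field(fld, 0.002, True), 0.2)
            vols.append(regions[0].volume)
        assert vols[0] < vols[1] < vols[2]

    def test_region_sum_equals_union_mask_integral(self):
        spec = PhantomSpec(
            mesh_pitch=0.08,
            noise_sd=0.0,
            features=(
                SurfaceFeature("remnant", (-1.4, 0.0), 1.0, 0.2),
                SurfaceFeature("remnant", (1.4, 0.0), 1.0, 0.25),
            ),
            seed=5,
        )
        pre, post, _ = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        regions = connected_regions(fld, label_field(fld, 0.002, True), 0.2)
        union = np.zeros(post.n_vertices, bool)
        for r in regions:
            union[r.vertex_indices] = True
        total_core = sum(r.core_volume for r in regions)
        assert total_core == pytest.approx(
            integrate_volume(fld, union, "remnant"), abs=1e-12
        )


class TestHistogram:
    def test_counting_example(self, flat):
        d = np.zeros(flat.n_vertices)
        d[:3] = [0.01, 0.01, 0.03]
        fld = field_on(flat, d)
        h = deviation_histogram(fld, label_field(fld), "remnant", bin_width=0.02)
        assert np.allclose(h.bin_edges, [0.0, 0.02, 0.04])
        assert h.percent == pytest.approx([200 / 3, 100 / 3])

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(1e-6, 0.75), min_size=1, max_size=50),
        st.floats(0.005, 0.1),
    )
    def test_percentages_always_sum_to_100(self, mags, bw):
        host = flat_patch(width=3.0, height=3.0, pitch=0.5)
        d = np.zeros(host.n_vertices)
        d[: len(mags)] = mags
        fld = field_on(host, d)
        h = deviation_histogram(fld, label_field(fld), "remnant", bin_width=bw)
        assert h.percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_side_raises(self, flat):
        fld = field_on(flat, np.zeros(flat.n_vertices))
        with pytest.raises(EmptySideError):
            deviation_histogram(fld, label_field(fld), "loss", 0.02)

    def test_bad_bin_width_rejected(self, flat):
        d = np.full(flat.n_vertices, 0.01)
        fld = field_on(flat, d)
        with pytest.raises(ValueError):
            deviation_histogram(fld, label_field(fld), "remnant", 0.0)

    def test_bump_histogram_mode_at_small_heights(self):
        # the bump periphery dominates by area, so low bins hold most mass
        spec = PhantomSpec(
            mesh_pitch=0.05,
            noise_sd=0.0,
            features=(SurfaceFeature("remnant", (0, 0), 1.5, 0.5),),
            seed=2,
        )
        pre, post, _ = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        lab = label_field(fld, hard_threshold=True)
        h = deviation_histogram(fld, lab, "remnant", bin_width=0.05)
        assert h.percent.argmax() == 0


class TestARI:
    @pytest.mark.parametrize(
        "fraction, expected",
        [(0.0, 0), (0.3, 1), (0.7, 2), (1.0, 3)],
    )
    def test_artun_bergland_criteria(self, fraction, expected):
        assert ari_artun_bergland(fraction) == expected

    @pytest.mark.parametrize(
        "fraction, expected",
        [(1.0, 1), (0.95, 2), (0.5, 3), (0.05, 4), (0.0, 5), (0.1, 4)],
    )
    def test_krell_criteria(self, fraction, expected):
        assert ari_krell(fraction) == expected

    @pytest.mark.parametrize(
        "remnant, base, expected", [(30.0, 60.0, 50.0), (0.0, 60.0, 0.0)]
    )
    def test_osorio_percentage(self, remnant, base, expected):
        assert ari_osorio(remnant, base) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            ari_artun_bergland(1.2)
        with pytest.raises(ValueError):
            ari_krell(-0.1)
        with pytest.raises(ValueError):
            ari_osorio(10.0, 0.0)

    def test_phantom_area_fraction_consistency(self):
        spec = PhantomSpec(
            mesh_pitch=0.08,
            noise_sd=0.0,
            features=(SurfaceFeature("remnant", (0, 0), 1.2, 0.3),),
            seed=9,
        )
        pre, post, _ = make_phantom_pair(spec)
        fld = signed_deviation(post, pre)
        regions = connected_regions(fld, label_field(fld, 0.002, True), 0.2)
        area = sum(r.area for r in regions if r.side == "remnant")
        base_area = 6.0 * 5.0
        scores = compute_ari(area, base_area)
        assert scores.osorio_percent == pytest.approx(100 * area / base_area, abs=1e-9)
        # direct face-area sum over the region must match ChangeRegion.area
        v_area = vertex_areas(post)
        direct = sum(v_area[r.vertex_indices].sum() for r in regions if r.side == "remnant")
        assert area == pytest.approx(direct, abs=1e-9)
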