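import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from junctionmap.profiles import (
    ProfileStack,
    align_and_normalize,
    apicobasal_reference,
    bilinear_sample,
    density_map_2d,
    planar_reference,
    pool_density,
    profile_junction,
    sample_perpendicular_profiles,
)
from junctionmap.synthetic import SceneParams, simulate_junction_scene
from junctionmap.types import APICO_BASAL, DensityProfile, ImagePair, JunctionTrace


class TestBilinearSample:
    def test_symmetric_2x2(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert bilinear_sample(img, (0.5, 0.5)) == pytest.approx(0.5)

    def test_reproduces_ramp_exactly(self):
        xx = np.tile(np.arange(8.0), (6, 1))
        for x, y in [(1.25, 2.0), (3.5, 4.75), (6.99, 0.01)]:
            assert bilinear_sample(xx, (x, y)) == pytest.approx(x)

    def test_closed_form_oracle(self, rng):
        img = rng.uniform(0, 10, size=(2, 2))
        x, y = 0.25, 0.75
        expected = (
            img[0, 0] * (1 - x) * (1 - y)
            + img[0, 1] * x * (1 - y)
            + img[1, 0] * (1 - x) * y
            + img[1, 1] * x * y
        )
        assert bilinear_sample(img, (x, y)) == pytest.approx(expected)

    def test_outside_interior_raises(self):
        img = np.zeros((4, 4))
        with pytest.raises(ValueError, match=r"3\.5"):
            bilinear_sample(img, (3.5, 1.0))

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        c=st.floats(-5, 5),
        x=st.floats(0, 6.999),
        y=st.floats(0, 4.999),
    )
    def test_affine_fields_exact(self, a, b, c, x, y):
        yy, xx = np.mgrid[0:6, 0:8].astype(float)
        img = a * xx + b * yy + c
        expected = a * x + b * y + c
        assert bilinear_sample(img, (x, y)) == pytest.approx(expected, abs=1e-9)


def _flat_pair(ref, target, px=20.0, orientation="planar"):
    return ImagePair(channel_ref=ref, channel_target=target, pixel_size=px,
                     orientation=orientation)


class TestSamplePerpendicularProfiles:
    def test_line_count_on_straight_trace(self):
        img = np.ones((64, 64))
        pair = _flat_pair(img, img)
        trace = JunctionTrace(points=np.array([[10.0, 32.0], [50.0, 32.0]]))
        # arc length 40 px = 800 nm, spacing 20 nm -> 41 lines
        stack = sample_perpendicular_profiles(pair, trace, half_length=100.0, step=20.0)
        assert stack.ref.shape[0] == int(np.floor(800 / 20)) + 1

    def test_constant_image(self):
        img = np.full((64, 64), 3.25)
        pair = _flat_pair(img, img)
        trace = JunctionTrace(points=np.array([[10.0, 32.0], [50.0, 32.0]]))
        stack = sample_perpendicular_profiles(pair, trace, half_length=100.0)
        assert np.all(stack.ref == 3.25)
        assert np.all(stack.target == 3.25)

    def test_ramp_oracle(self):
        # f(x, y) = y with a horizontal trace: each perpendicular profile is
        # linear in position with slope 1/pixel_size per nm
        yy = np.tile(np.arange(64.0)[:, None], (1, 64))
        pair = _flat_pair(yy, yy, px=20.0)
        trace = JunctionTrace(points=np.array([[10.0, 32.0], [50.0, 32.0]]))
        stack = sample_perpendicular_profiles(pair, trace, half_length=200.0, step=20.0)
        expected = 32.0 + stack.positions / 20.0
        for line in stack.target:
            np.testing.assert_allclose(line, expected, atol=1e-9)

    def test_out_of_bounds_lines_dropped(self):
        img = np.ones((64, 64))
        pair = _flat_pair(img, img)
        trace = JunctionTrace(points=np.array([[10.0, 32.0], [50.0, 32.0]]))
        stack = sample_perpendicular_profiles(pair, trace, half_length=500.0)
        assert stack.n_dropped == 0  # 32 +- 25 px stays inside 64 rows
        # slanted trace: stations near y=15 leave the interior at +-20 px
        trace2 = JunctionTrace(points=np.array([[10.0, 15.0], [50.0, 40.0]]))
        stack2 = sample_perpendicular_profiles(pair, trace2, half_length=400.0)
        assert stack2.n_dropped > 0
        assert stack2.ref.shape[0] > 0


class TestPlanarReference:
    def test_symmetric_three_point_peak(self):
        assert planar_reference([-20.0, 0.0, 20.0], [0, 1, 0]) == pytest.approx(0.0)

    def test_symmetric_five_point(self):
        pos = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        prof = np.array([0.0, 0.8, 1.0, 0.8, 0.0])
        assert planar_reference(pos, prof) == pytest.approx(0.0)

    def test_parabola_oracle(self):
        # three-point parabola through (0.6, 1.0, 0.9):
        # delta = 0.5*(y0 - y2)/(y0 - 2 y1 + y2) = 0.3 sample units
        pos = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        prof = np.array([0.0, 0.6, 1.0, 0.9, 0.0])
        y0, y1, y2 = 0.6, 1.0, 0.9
        delta = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
        assert planar_reference(pos, prof) == pytest.approx(delta * 20.0)

    def test_constant_profile_raises(self):
        with pytest.raises(ValueError, match="no reference"):
            planar_reference([0.0, 20.0, 40.0], [2.0, 2.0, 2.0])

    def test_tie_broken_toward_midpoint(self):
        pos = np.arange(5) * 20.0
        prof = np.array([1.0, 0.0, 0.0, 0.0, 1.0])
        # both ends attain the max; the tie resolves to the index nearest
        # the midline, here the left (index 0 vs 4 equidistant -> first)
        ref = planar_reference(pos, prof)
        assert ref in (pos[0], pos[4])


class TestApicobasalReference:
    def test_exact_hit(self):
        pos = np.arange(5) * 10.0
        prof = np.array([0.0, 1.5, 3.0, 9.0, 6.0])
        ref, flagged = apicobasal_reference(pos, prof)  # threshold = 3
        assert ref == pytest.approx(pos[2])
        assert not flagged

    def test_linear_interpolation_crossing(self):
        pos = np.arange(4, dtype=float)  # sample units
        prof = np.array([0.0, 2.0, 4.0, 8.0])
        ref, flagged = apicobasal_reference(pos, prof)  # threshold 8/3
        expected = 1 + (8.0 / 3.0 - 2.0) / (4.0 - 2.0)
        assert ref == pytest.approx(expected)
        assert not flagged

    def test_degenerate_apical_start(self):
        pos = np.arange(3, dtype=float)
        ref, flagged = apicobasal_reference(pos, np.array([9.0, 1.0, 0.5]))
        assert ref == pos[0]
        assert flagged

    def test_nonpositive_max_raises(self):
        with pytest.raises(ValueError):
            apicobasal_reference([0.0, 1.0], [0.0, 0.0])


def _stack_from_lines(lines_ref, lines_tgt, positions, step):
    return ProfileStack(
        positions=np.asarray(positions, float),
        ref=np.asarray(lines_ref, float),
        target=np.asarray(lines_tgt, float),
        step=step,
    )


class TestAlignAndNormalize:
    def _simple_stack(self, scale=1.0):
        positions = np.arange(-100.0, 101.0, 20.0)
        line = np.exp(-(positions**2) / (2 * 40.0**2)) * scale
        return _stack_from_lines([line, line], [line * 2, line * 2], positions, 20.0)

    def test_scale_invariance(self):
        a = align_and_normalize(self._simple_stack(1.0), [0.0, 0.0])
        b = align_and_normalize(self._simple_stack(5.0), [0.0, 0.0])
        np.testing.assert_allclose(a.target, b.target)
        np.testing.assert_allclose(a.ref, b.ref)

    def test_unit_integral(self):
        jp = align_and_normalize(self._simple_stack(), [0.0, 0.0], "unit_integral")
        valid = np.isfinite(jp.target)
        assert np.nansum(jp.target[valid]) * 20.0 == pytest.approx(1.0, abs=1e-9)

    def test_unit_max(self):
        jp = align_and_normalize(self._simple_stack(), [0.0, 0.0], "unit_max")
        assert np.nanmax(jp.target) == pytest.approx(1.0, abs=1e-12)

    def test_shift_alignment_oracle(self):
        # two identical shapes whose references differ by exactly 2 samples
        # must coincide after alignment (manual shift oracle)
        positions = np.arange(-200.0, 201.0, 20.0)
        shape = np.exp(-(positions**2) / (2 * 60.0**2))
        shifted = np.interp(positions - 40.0, positions, shape)
        stack = _stack_from_lines([shape, shifted], [shape, shifted], positions, 20.0)
        jp = align_and_normalize(stack, [0.0, 40.0])
        # after alignment both lines are the same shape; the mean equals it
        solo = align_and_normalize(
            _stack_from_lines([shape], [shape], positions, 20.0), [0.0]
        )
        both_valid = np.isfinite(jp.target) & np.isfinite(solo.target)
        inner = np.abs(positions) <= 120  # away from NaN edges
        np.testing.assert_allclose(
            jp.target[both_valid & inner], solo.target[both_valid & inner], atol=1e-9
        )

    def test_empty_stack_raises(self):
        stack = _stack_from_lines(
            np.empty((0, 5)), np.empty((0, 5)), np.arange(5.0), 1.0
        )
        with pytest.raises(ValueError, match="empty"):
            align_and_normalize(stack, [])


class TestPoolDensity:
    def _jp(self, values, positions=None):
        from junctionmap.profiles import JunctionProfile

        positions = np.arange(len(values), dtype=float) if positions is None else positions
        v = np.asarray(values, float)
        return JunctionProfile(positions=positions, ref=v, target=v, n_lines=1)

    def test_identical_profiles_sd_zero(self):
        prof = [0.1, 0.5, 0.3]
        pooled = pool_density([self._jp(prof), self._jp(prof)])
        np.testing.assert_allclose(pooled.mean, prof)
        np.testing.assert_allclose(pooled.sd, 0.0)
        assert pooled.n_junctions == 2

    def test_two_point_sd(self):
        pooled = pool_density([self._jp([0.0]), self._jp([1.0])])
        assert pooled.mean[0] == pytest.approx(0.5)
        assert pooled.sd[0] == pytest.approx(np.sqrt(0.5), abs=1e-4)  # 0.7071

    def test_single_junction_sd_zero(self):
        pooled = pool_density([self._jp([1.0, 2.0])])
        np.testing.assert_allclose(pooled.sd, 0.0)

    def test_mismatched_grids_raise(self):
        a = self._jp([1.0, 2.0])
        b = self._jp([1.0, 2.0], positions=np.array([0.0, 5.0]))
        with pytest.raises(ValueError, match="grid"):
            pool_density([a, b])


class TestSimulatedRecovery:
    @pytest.mark.parametrize("offset", [0.0, 100.0, 200.0, 300.0])
    def test_pooled_peak_recovers_offset(self, offset):
        profiles = []
        for seed in range(20):
            params = SceneParams(
                seed=seed,
                n_clusters=10,
                offset_perp_mean=offset,
                offset_perp_sd=30.0,
            )
            pair, trace, _ = simulate_junction_scene(params)
            profiles.append(profile_junction(pair, trace, half_length=600.0))
        pooled = pool_density(profiles, "target")
        peak = pooled.positions[np.argmax(pooled.mean)]
        assert abs(peak - offset) <= 20.0  # one sampling step

    def test_reference_channel_peaks_at_zero(self):
        params = SceneParams(seed=3, n_clusters=10, offset_perp_mean=200.0,
                             offset_perp_sd=30.0)
        pair, trace, _ = simulate_junction_scene(params)
        jp = profile_junction(pair, trace, half_length=600.0)
        pooled = pool_density([jp], "ref")
        peak = pooled.positions[np.argmax(pooled.mean)]
        assert abs(peak) <= 20.0

    def test_mean_plus_sd_at_least_mean(self):
        profiles = []
        for seed in range(5):
            params = SceneParams(seed=seed, n_clusters=10, offset_perp_mean=100.0,
                                 offset_perp_sd=30.0)
            pair, trace, _ = simulate_junction_scene(params)
            profiles.append(profile_junction(pair, trace, half_length=600.0))
        pooled = pool_density(profiles)
        assert np.all(pooled.mean + pooled.sd >= pooled.mean)


class TestApicobasalPipeline:
    def test_apicobasal_profile_runs(self):
        params = SceneParams(seed=9, n_clusters=8, offset_perp_mean=150.0,
                             offset_perp_sd=20.0, orientation="apico_basal")
        pair, trace, _ = simulate_junction_scene(params)
        trace.apical_direction = np.array([0.0, -1.0])  # apical = up (row 0)
        jp = profile_junction(pair, trace, half_length=600.0)
        assert np.isfinite(jp.target[np.isfinite(jp.target)]).all()
        assert jp.n_lines > 0


class TestDensityMap2D:
    def _profile(self, mean):
        mean = np.asarray(mean, float)
        return DensityProfile(
            positions=np.arange(len(mean), dtype=float),
            mean=mean,
            sd=np.zeros_like(mean),
            n_junctions=1,
        )

    def test_delta_profiles(self):
        m = density_map_2d(self._profile([0, 1, 0]), self._profile([0, 0, 2, 0]))
        assert m.shape == (4, 3)
        assert m[2, 1] == 2.0
        assert m.sum() == 2.0

    def test_uniform(self):
        m = density_map_2d(self._profile([1, 1]), self._profile([1, 1, 1]))
        assert np.all(m == 1.0)

    def test_outer_product_oracle(self, rng):
        a = self._profile(rng.uniform(0, 1, 5))
        b = self._profile(rng.uniform(0, 1, 7))
        m = density_map_2d(a, b)
        np.testing.assert_allclose(m, np.outer(b.mean, a.mean))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            density_map_2d(
                DensityProfile(np.array([0.0]), np.array([1.0]), np.array([0.0]), 1),
                DensityProfile(np.empty(0), np.empty(0), np.empty(0), 0),
            )
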