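"""Track statistics: displacement, persistence, all-pairs MSD, alpha, classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pilitrack.config import AnalysisConfig
from pilitrack.metrics import (
    MSDCurve,
    classify,
    compute_track_metrics,
    fit_alpha,
    msd_all_pairs,
    net_displacement,
    path_length,
    persistence_ratio,
)
from pilitrack.simulate import simulate_track, builtin_presets

from conftest import make_track, random_track


def brute_force_msd(track):
    """Independent O(n^2) oracle: enumerate every ordered pair explicitly."""
    t = track.times
    r = track.positions
    dt = track.frame_interval
    acc = {}
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            lag = t[j] - t[i]
            k = int(round(lag / dt))
            d2 = float(np.sum((r[j] - r[i]) ** 2))
            acc.setdefault(k, []).append(d2)
    lags = sorted(acc)
    return (np.array([k * dt for k in lags]),
            np.array([np.mean(acc[k]) for k in lags]),
            np.array([len(acc[k]) for k in lags]))


class TestDisplacementAndPath:
    def test_three_four_five(self):
        tr = make_track([(0, 0), (3, 4)])
        assert net_displacement(tr) == 5.0

    def test_closed_loop_zero(self):
        tr = make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert net_displacement(tr) == 0.0
        assert path_length(tr) == 4.0

    def test_matches_direct_formula_on_random_track(self):
        rng = np.random.default_rng(3)
        tr = random_track(rng, n=50)
        r = tr.positions
        assert net_displacement(tr) == pytest.approx(
            float(np.linalg.norm(r[-1] - r[0])), abs=0)

    def test_path_length_example(self):
        tr = make_track([(0, 0), (1, 0), (1, 1)])
        assert path_length(tr) == 2.0

    def test_straight_track_path_equals_net(self):
        tr = make_track([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert path_length(tr) == pytest.approx(net_displacement(tr))

    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_inequality(self, seed):
        tr = random_track(np.random.default_rng(seed), n=30)
        assert net_displacement(tr) <= path_length(tr) + 1e-12

    def test_single_point_rejected(self):
        tr = make_track([(0, 0)])
        for fn in (net_displacement, path_length, persistence_ratio):
            with pytest.raises(ValueError, match=">= 2"):
                fn(tr)


class TestPersistence:
    def test_straight_is_one(self):
        tr = make_track([(0, 0), (1, 0), (2, 0), (5, 0)])
        assert persistence_ratio(tr) == pytest.approx(1.0)

    def test_out_and_back_is_zero(self):
        tr = make_track([(0, 0), (2, 0), (0, 0)])
        assert persistence_ratio(tr) == 0.0

    def test_right_angle_value(self):
        tr = make_track([(0, 0), (1, 0), (1, 1)])
        assert persistence_ratio(tr) == pytest.approx(np.sqrt(2) / 2)

    def test_stationary_track_defined_as_zero(self):
        tr = make_track([(1, 1), (1, 1 + 0), (1, 1)])
        assert persistence_ratio(tr) == 0.0

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        tr = random_track(np.random.default_rng(seed), n=20)
        assert 0.0 <= persistence_ratio(tr) <= 1.0 + 1e-12


class TestMSD:
    def test_hand_enumerated_example(self):
        # points (0,0),(1,0),(1,1) at t=0,1,2: lag1 pairs d2={1,1}, lag2 d2={2}
        tr = make_track([(0, 0), (1, 0), (1, 1)])
        c = msd_all_pairs(tr)
        np.testing.assert_allclose(c.lags, [1, 2])
        np.testing.assert_allclose(c.msd, [1.0, 2.0])
        np.testing.assert_array_equal(c.n_pairs, [2, 1])

    def test_ballistic_closed_form(self):
        v = 0.7
        tr = make_track([(v * i, 0) for i in range(20)])
        c = msd_all_pairs(tr)
        np.testing.assert_allclose(c.msd, v ** 2 * c.lags ** 2, rtol=1e-12)

    @given(st.integers(0, 10_000), st.booleans())
    @settings(max_examples=30, deadline=None)
    def test_equals_brute_force_oracle(self, seed, gapped):
        rng = np.random.default_rng(seed)
        tr = random_track(rng, n=25, gap_prob=0.3 if gapped else 0.0)
        c = msd_all_pairs(tr)
        lags, msd, n_pairs = brute_force_msd(tr)
        np.testing.assert_allclose(c.lags, lags, rtol=0, atol=0)
        np.testing.assert_allclose(c.msd, msd, rtol=1e-12)
        np.testing.assert_array_equal(c.n_pairs, n_pairs)

    def test_gap_lags_omitted(self):
        # observed frames 0 and 3 only: the only lag is 3
        tr = make_track([(0, 0), (9, 9), (9, 9), (1, 1)])
        pts = [tr.points[0], tr.points[3]]
        from pilitrack.io import Track
        tr2 = Track("g", "rep1", "G", pts, frame_interval=1.0)
        c = msd_all_pairs(tr2)
        np.testing.assert_allclose(c.lags, [3.0])


class TestAlpha:
    def test_exact_power_laws(self):
        lags = np.arange(1.0, 11.0)
        for a in (1.0, 2.0):
            c = MSDCurve(lags, 3.0 * lags ** a, np.ones(10, int))
            assert fit_alpha(c, max_lag_fraction=1.0) == pytest.approx(a, abs=1e-9)

    def test_fit_range_restriction(self):
        # slope 2 below lag 5, slope 0 above: restricting the fit changes alpha
        lags = np.arange(1.0, 21.0)
        msd = np.where(lags <= 5, lags ** 2, 25.0)
        c = MSDCurve(lags, msd, np.ones(20, int))
        assert fit_alpha(c, 0.25, duration=20.0) == pytest.approx(2.0, abs=1e-9)
        assert fit_alpha(c, 1.0, duration=20.0) < 1.0

    def test_undefined_with_single_usable_lag(self):
        c = MSDCurve(np.array([1.0, 2.0]), np.array([1.0, 0.0]), np.array([1, 1]))
        assert fit_alpha(c, max_lag_fraction=1.0) is None

    def test_empty_curve_raises(self):
        c = MSDCurve(np.array([]), np.array([]), np.array([], dtype=int))
        with pytest.raises(ValueError):
            fit_alpha(c)

    def test_invariant_to_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(12)
        tr = random_track(rng, n=60)
        base = fit_alpha(msd_all_pairs(tr), 0.25, tr.duration)
        th = 0.6
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for transform in (
            lambda r: r + np.array([13.0, -4.5]),       # translation
            lambda r: r @ R.T,                          # rotation
            lambda r: 3.7 * r,                          # uniform rescale
        ):
            r2 = transform(tr.positions)
            tr2 = make_track(r2, track_id="x")
            assert fit_alpha(msd_all_pairs(tr2), 0.25, tr2.duration) == pytest.approx(
                base, abs=1e-9)

    def test_noiseless_roller_alpha_two(self, presets):
        import dataclasses
        p = dataclasses.replace(presets["daapB"], localization_noise_sd=0.0,
                                roller_dwell_mean_s=0.0)
        tr, _ = simulate_track(p, "roller", seed=4)
        a = fit_alpha(msd_all_pairs(tr), 0.25, tr.duration)
        assert a == pytest.approx(2.0, abs=1e-6)

    def test_long_tethered_track_subdiffusive(self, presets):
        tr, _ = simulate_track(presets["daapF"], "tethered", seed=4)
        a = fit_alpha(msd_all_pairs(tr), 0.25, tr.duration)
        assert a is not None and a < 0.5


class TestClassify:
    def test_threshold_rules(self):
        cfg = AnalysisConfig()
        assert classify(1.9, 0.1, 1.0, cfg)[0] == "non_motile"
        assert classify(2.1, 0.1, 1.0, cfg)[0] == "motile"
        assert classify(15.0, 0.9, 1.0, cfg)[0] == "roller"
        assert classify(15.0, 0.2, 1.0, cfg)[0] == "motile"

    def test_diffusion_classes(self):
        cfg = AnalysisConfig()
        assert classify(5, 0.1, 1.0, cfg)[1] == "diffusive"
        assert classify(5, 0.1, 1.3, cfg)[1] == "superdiffusive"
        assert classify(5, 0.1, 0.3, cfg)[1] == "subdiffusive"
        assert classify(5, 0.1, None, cfg)[1] == "undefined"

    def test_classification_consistent_with_threshold_override(self):
        cfg = AnalysisConfig(non_motile_threshold=3.0)
        tr = make_track([(0, 0), (1.0, 0), (2.5, 0)])
        m = compute_track_metrics(tr, cfg)
        assert m.motility_class == "non_motile"
        m2 = compute_track_metrics(tr, AnalysisConfig())
        assert m2.motility_class == "motile"
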