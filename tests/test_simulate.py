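"""Simulator contracts: determinism, mode mechanics, preset validation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from pilitrack.metrics import fit_alpha, msd_all_pairs, net_displacement, persistence_ratio
from pilitrack.simulate import (
    MODES,
    PhenotypePreset,
    builtin_presets,
    simulate_cohort,
    simulate_retraction_trace,
    simulate_track,
)


def quiet_preset(**overrides):
    base = dict(
        name="test",
        mode_fractions={"twitcher": 1.0, "tethered": 0.0, "roller": 0.0},
        localization_noise_sd=0.0,
        tether_jitter_sd=0.0,
        recoil_prob=0.0,
    )
    base.update(overrides)
    return PhenotypePreset(**base)


class TestPresetValidation:
    def test_builtins_present_and_valid(self, presets):
        for name in ("WT", "daapF", "darlJ", "daapB"):
            assert name in presets
            assert sum(presets[name].mode_fractions.values()) == pytest.approx(1.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PhenotypePreset(name="x", mode_fractions={"twitcher": 0.5, "tethered": 0.2,
                                                      "roller": 0.0})

    def test_speed_support_bounded(self):
        with pytest.raises(ValueError, match="0.3"):
            PhenotypePreset(name="x",
                            mode_fractions={"twitcher": 1, "tethered": 0, "roller": 0},
                            retraction_speed_params=(0.3, 0.3, 0.1, 2.0))

    def test_yaml_roundtrip(self, presets, tmp_path):
        p = tmp_path / "wt.yaml"
        presets["WT"].to_yaml(p)
        back = PhenotypePreset.from_yaml(p)
        assert back == presets["WT"]


class TestModes:
    def test_degenerate_tethered_is_stationary(self):
        p = quiet_preset(mode_fractions={"twitcher": 0, "tethered": 1, "roller": 0})
        tr, truth = simulate_track(p, "tethered", seed=0)
        assert truth.mode == "tethered"
        assert np.all(tr.positions == tr.positions[0])
        assert net_displacement(tr) == 0.0

    def test_noiseless_roller_straight_line(self):
        p = quiet_preset(mode_fractions={"twitcher": 0, "tethered": 0, "roller": 1},
                         roller_speed=0.1, roller_speed_sd=0.0, roller_dwell_mean_s=0.0)
        tr, _ = simulate_track(p, "roller", seed=1)
        assert persistence_ratio(tr) == pytest.approx(1.0)
        # collinearity: cross products vanish
        r = tr.positions - tr.positions[0]
        cross = r[1:, 0] * r[-1, 1] - r[1:, 1] * r[-1, 0]
        np.testing.assert_allclose(cross, 0, atol=1e-9)

    def test_twitcher_hand_stepped_single_pilus(self):
        # one pilus, 3 µm at 0.3 µm/s along +x: the cell must advance
        # exactly 0.3 µm per 1-s frame for 10 frames, then stop.
        p = quiet_preset(pilus_nucleation_rate=1e-9)
        tr, truth = simulate_track(p, "twitcher", seed=0,
                                   forced_pili=[(0.0, 0.0, 3.0, 0.3)])
        x = tr.positions[:, 0]
        np.testing.assert_allclose(x[:11], 0.3 * np.arange(11), atol=1e-9)
        np.testing.assert_allclose(x[11:], 3.0, atol=1e-9)
        np.testing.assert_allclose(tr.positions[:, 1], 0.0, atol=1e-12)
        assert truth.event_speeds == [0.3]

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown mode"):
            simulate_track(quiet_preset(), "flying", seed=0)


class TestCohort:
    def test_determinism_bit_identical(self, presets):
        a, _ = simulate_cohort(presets["WT"], 12, 3, seed=9)
        b, _ = simulate_cohort(presets["WT"], 12, 3, seed=9)
        for ta, tb in zip(a.tracks, b.tracks):
            assert ta.positions.tolist() == tb.positions.tolist()

    def test_different_seed_differs(self, presets):
        a, _ = simulate_cohort(presets["WT"], 4, 1, seed=1)
        b, _ = simulate_cohort(presets["WT"], 4, 1, seed=2)
        assert any(ta.positions.tolist() != tb.positions.tolist()
                   for ta, tb in zip(a.tracks, b.tracks))

    def test_pure_tethered_fractions(self):
        p = quiet_preset(mode_fractions={"twitcher": 0, "tethered": 1, "roller": 0})
        _, truths = simulate_cohort(p, 10, 2, seed=0)
        assert all(t.mode == "tethered" for t in truths.values())

    def test_round_robin_replicates(self, presets):
        cohort, _ = simulate_cohort(presets["WT"], 7, 3, seed=0)
        reps = [t.replicate_id for t in cohort.tracks]
        assert reps == ["rep1", "rep2", "rep3", "rep1", "rep2", "rep3", "rep1"]

    def test_mode_fractions_within_binomial_bounds(self, presets):
        # exact binomial 99% central bounds for the WT twitcher fraction
        p = presets["WT"]
        n = 200
        _, truths = simulate_cohort(p, n, 3, seed=21)
        k = sum(t.mode == "twitcher" for t in truths.values())
        frac = p.mode_fractions["twitcher"]
        lo, hi = sps.binom.ppf([0.005, 0.995], n, frac)
        assert lo <= k <= hi

    def test_isotropy_of_twitcher_ensemble(self):
        # ensemble-mean displacement vector indistinguishable from zero
        p = quiet_preset(localization_noise_sd=0.058, recoil_prob=0.3)
        disp = []
        for i in range(150):
            tr, _ = simulate_track(p, "twitcher", seed=np.random.default_rng([5, i]))
            disp.append(tr.positions[-1] - tr.positions[0])
        disp = np.array(disp)
        se = disp.std(axis=0, ddof=1) / np.sqrt(len(disp))
        assert np.all(np.abs(disp.mean(axis=0)) < 3.5 * se + 1e-9)

    def test_step_magnitude_bound(self):
        # noiseless single-pilus twitcher: per-frame step <= vmax*dt + recoil
        p = quiet_preset(multi_pilus_max=1, recoil_prob=0.3,
                         pilus_nucleation_rate=0.05)
        vmax = p.retraction_speed_params[3]
        for i in range(10):
            tr, _ = simulate_track(p, "twitcher", seed=i)
            steps = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
            assert steps.max() <= vmax * p.frame_interval + p.recoil_step + 1e-9


class TestRetractionTrace:
    def test_duration_is_L0_over_speed(self):
        tr, _ = simulate_retraction_trace(0.3, 3.0, noise_sd=0.0, seed=0)
        assert tr.times[-1] == pytest.approx(10.0)
        assert tr.lengths[0] == pytest.approx(3.0)
        assert tr.lengths[-1] == pytest.approx(0.0)

    def test_sampling_interval(self):
        tr, _ = simulate_retraction_trace(1.0, 4.0, noise_sd=0.0, frame_interval=0.5)
        np.testing.assert_allclose(np.diff(tr.times), 0.5)

    def test_lengths_clipped_nonnegative(self):
        tr, _ = simulate_retraction_trace(0.5, 2.0, noise_sd=0.3, seed=3)
        assert np.all(tr.lengths >= 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_retraction_trace(0.0, 3.0)
        with pytest.raises(ValueError):
            simulate_retraction_trace(0.3, 15.0)

    def test_monte_carlo_speed_recovery(self):
        # 19 noisy traces at 0.3 µm/s: mean estimate within 3 SE of truth
        from pilitrack.retraction import detect_retractions, principal_event
        est = []
        for i in range(19):
            rng = np.random.default_rng([13, i])
            tr, _ = simulate_retraction_trace(0.3, rng.uniform(2, 8), noise_sd=0.05,
                                              frame_interval=0.5, seed=rng)
            ev = principal_event(detect_retractions(tr))
            est.append(ev.speed)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.3) < 3 * se + 1e-3


class TestAlphaRecovery:
    def test_tethered_plateau_alpha_small(self, presets):
        p = presets["daapF"]
        alphas = []
        for i in range(20):
            tr, _ = simulate_track(p, "tethered", seed=np.random.default_rng([3, i]))
            alphas.append(fit_alpha(msd_all_pairs(tr), 0.25, tr.duration))
        assert np.mean(alphas) < 0.5
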