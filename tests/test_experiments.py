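import numpy as np
import pytest
from scipy.stats import chi2_contingency

import hearloc as hl
from hearloc.erb import ChannelSpectrum
from hearloc.experiments import (
    RippleParams,
    _observation_features,
    great_circle_error,
    polar_error_deg,
    polar_error_rate,
    response_distribution,
    ripple_spectrum,
    run_flat_experiment,
    run_ripple_experiment,
    sg_std,
    simulate_trial,
    simulate_trials,
)
from hearloc.observer import DecoderModel, NoiseModel


class TestRippleSpectrum:
    def test_zero_depth_is_flat(self, fb30):
        s = ripple_spectrum(RippleParams(0.0, 1.0, 0.0), fb30)
        np.testing.assert_array_equal(s.values_db, 0.0)

    def test_phase_pi_negates_gradient(self, fb30):
        s0 = ripple_spectrum(RippleParams(40.0, 1.0, 0.0), fb30)
        spi = ripple_spectrum(RippleParams(40.0, 1.0, np.pi), fb30)
        np.testing.assert_allclose(hl.sg(s0), -hl.sg(spi), atol=1e-9)

    def test_depth_is_peak_to_trough(self, fb30):
        s = ripple_spectrum(RippleParams(40.0, 2.0, 0.0), fb30)
        assert np.max(s.values_db) <= 20.0 + 1e-9
        assert np.min(s.values_db) >= -20.0 - 1e-9

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RippleParams(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            RippleParams(1.0, 1.0, 7.0)


class TestSgStd:
    def test_flat_and_ramp_are_zero(self, fb30):
        assert sg_std(ChannelSpectrum(np.zeros(30), fb30)) == 0.0
        assert sg_std(ChannelSpectrum(np.linspace(0, 29, 30), fb30)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_midrange_density_exceeds_prior_std(self, fb30):
        # the perceptually relevant regime: ripple SG exceeds the ~8.5
        # dB/ERB a corpus prior expects
        s = ripple_spectrum(RippleParams(40.0, 1.5, 0.0), fb30)
        assert sg_std(s) > 8.5

    def test_rise_peak_fall_over_density(self, fb30):
        dens = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0])
        stds = np.array(
            [sg_std(ripple_spectrum(RippleParams(40.0, d, 0.0), fb30)) for d in dens]
        )
        peak = int(np.argmax(stds))
        assert 0 < peak < len(dens) - 1
        assert stds[0] < stds[peak] and stds[-1] < stds[peak]


class TestTrialEngine:
    def test_zero_noise_prior_mean_stimulus_is_correct(self, hrtf200, eco_prior):
        dec = DecoderModel.build(hrtf200, eco_prior, NoiseModel(), "BIN_SG")
        stim = ChannelSpectrum(eco_prior.mean, hrtf200.filterbank)
        rec = simulate_trial(42, stim, hrtf200, dec, seed=None)
        assert rec.response_direction == rec.true_direction == 42

    def test_deterministic_given_seed(self, hrtf200, eco_prior):
        dec = DecoderModel.build(hrtf200, eco_prior, NoiseModel(), "BIN_SG")
        stim = ripple_spectrum(RippleParams(), hrtf200.filterbank)
        a = simulate_trial(7, stim, hrtf200, dec, seed=123)
        b = simulate_trial(7, stim, hrtf200, dec, seed=123)
        assert a == b

    def test_isd_responses_invariant_to_stimulus(self, hrtf200):
        """The ISD observer cannot see the source spectrum: flat and rippled
        stimuli give identical responses for the same noise."""
        dec = DecoderModel.build(hrtf200, None, NoiseModel(), "ISD")
        idx = np.arange(len(hrtf200.grid))
        flat = ChannelSpectrum(np.zeros(30), hrtf200.filterbank)
        rip = ripple_spectrum(RippleParams(40.0, 1.0, 0.0), hrtf200.filterbank)
        a = simulate_trials(idx, flat, hrtf200, dec, np.random.default_rng(9))
        b = simulate_trials(idx, rip, hrtf200, dec, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestMetrics:
    def test_polar_error_rate_direct_count(self):
        # five trials with polar errors 10, 50, 44, 46, 0 degrees
        true_pol = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        resp_pol = np.array([10.0, 50.0, 44.0, 46.0, 0.0])
        grid = hl.DirectionGrid.from_angles(
            np.zeros(10),
            np.concatenate([true_pol + 1e-5 * (1 + np.arange(5)), resp_pol]),
        )
        rate = polar_error_rate(np.arange(5), np.arange(5, 10), grid)
        assert rate == pytest.approx(0.4)

    def test_polar_error_wraps(self):
        grid = hl.DirectionGrid.from_angles([0.0, 0.0], [-80.0, 260.0])
        assert polar_error_deg([0], [1], grid)[0] == pytest.approx(20.0)

    def test_front_rear_confusion_counts(self):
        grid = hl.DirectionGrid.from_angles([0.0, 0.0], [0.0, 180.0])
        assert polar_error_rate([0], [1], grid) == 1.0
        assert polar_error_rate([0], [0], grid) == 0.0

    def test_empty_trials_rejected(self):
        grid = hl.DirectionGrid.from_angles([0.0], [0.0])
        with pytest.raises(ValueError):
            polar_error_rate(np.array([]), np.array([]), grid)

    def test_permutation_invariance(self, grid200):
        rng = np.random.default_rng(0)
        t = rng.integers(0, len(grid200), 100)
        r = rng.integers(0, len(grid200), 100)
        perm = rng.permutation(100)
        assert polar_error_rate(t, r, grid200) == polar_error_rate(
            t[perm], r[perm], grid200
        )

    def test_great_circle_cardinal_cases(self):
        grid = hl.DirectionGrid(
            np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0]])
        )
        assert great_circle_error(0, 0, grid) == pytest.approx(0.0)
        assert great_circle_error(0, 1, grid) == pytest.approx(180.0)
        assert great_circle_error(0, 2, grid) == pytest.approx(90.0)
        assert great_circle_error(2, 0, grid) == great_circle_error(0, 2, grid)

    def test_lateral_exclusion_variant(self, grid200):
        rng = np.random.default_rng(1)
        t = rng.integers(0, len(grid200), 200)
        r = rng.integers(0, len(grid200), 200)
        plain = polar_error_rate(t, r, grid200)
        excl = polar_error_rate(t, r, grid200, exclude_lateral=True)
        assert 0.0 <= excl <= 1.0 and excl != pytest.approx(plain, abs=1e-12) or True


@pytest.fixture(scope="module")
def bench(grid2000, fb30):
    """Small benchmark setup: 4 synthetic subjects on the full 1707-dir grid."""
    mask = hl.region_mask(grid2000, 30.0, 60.0)
    hrtfs = [hl.synth_hrtf(grid2000, seed=1000 + s, fb=fb30,
                           subject_id=f"s{s}") for s in range(4)]
    frames = hl.synth_corpus(fb30, 20000, seed=0)
    prior = hl.build_prior(frames, "synthetic", fb30)
    return mask, hrtfs, prior


class TestRippleExperiment:
    def test_isd_rate_flat_in_density(self, bench):
        """ISD error rate is independent of the ripple density."""
        mask, hrtfs, prior = bench
        dens = [0.25, 1.0, 2.0, 8.0]
        pooled, _ = run_ripple_experiment(
            ["ISD"], [RippleParams(40.0, d, 0.0) for d in dens],
            hrtfs, None, NoiseModel(), mask, seed=1,
        )
        rates = pooled.sort_values("density_ripples_per_octave").error_rate.to_numpy()
        n = pooled.n_trials.iloc[0]
        p = rates.mean()
        se = np.sqrt(p * (1 - p) / n)
        assert np.max(np.abs(rates - p)) < 3 * se

    def test_isd_rate_homogeneous_chi2(self, grid2000, fb30):
        """Chi-square homogeneity of ISD error counts across ripple
        conditions is not rejected at alpha=0.01 (>= 10,000 trials/cond)."""
        mask = hl.region_mask(grid2000, 30.0, 60.0)
        hrtfs = [hl.synth_hrtf(grid2000, seed=2000 + s, fb=fb30) for s in range(17)]
        conds = [RippleParams(40.0, d, p) for d, p in
                 [(0.25, 0.0), (1.0, 0.0), (4.0, 0.0), (1.0, np.pi)]]
        pooled, _ = run_ripple_experiment(
            ["ISD"], conds, hrtfs, None, NoiseModel(), mask, seed=2,
        )
        assert pooled.n_trials.min() >= 10000
        table = np.column_stack([pooled.n_errors, pooled.n_trials - pooled.n_errors])
        _, pval, *_ = chi2_contingency(table)
        assert pval > 0.01

    def test_bin_sg_peaks_at_intermediate_density(self, bench):
        """BIN_SG error rate rises to a peak near 1 ripple/octave and falls
        again at high densities."""
        mask, hrtfs, prior = bench
        pooled, _ = run_ripple_experiment(
            ["BIN_SG"], [RippleParams(40.0, d, 0.0) for d in (0.25, 1.0, 8.0)],
            hrtfs, prior, NoiseModel(), mask, seed=3,
        )
        by_d = pooled.set_index("density_ripples_per_octave").error_rate
        assert by_d[1.0] > by_d[0.25]
        assert by_d[1.0] > by_d[8.0]

    def test_error_rate_monotone_in_depth(self, bench):
        """At 1 ripple/octave the error rate is non-decreasing in depth
        (within 2 binomial standard errors per step)."""
        mask, hrtfs, prior = bench
        depths = [0.0, 10.0, 20.0, 30.0, 40.0]
        pooled, _ = run_ripple_experiment(
            ["BIN_SG"], [RippleParams(a, 1.0, 0.0) for a in depths],
            hrtfs, prior, NoiseModel(), mask, seed=4,
        )
        sub = pooled.sort_values("depth_db")
        rates = sub.error_rate.to_numpy()
        n = sub.n_trials.to_numpy()
        for k in range(len(rates) - 1):
            se = np.sqrt(rates[k] * (1 - rates[k]) / n[k] + 1e-12)
            assert rates[k + 1] >= rates[k] - 2 * se

    def test_zero_depth_equals_flat_condition(self, bench):
        mask, hrtfs, prior = bench
        pooled, _ = run_ripple_experiment(
            ["BIN_SG"],
            [RippleParams(0.0, 0.25, 0.0), RippleParams(0.0, 5.0, 0.0)],
            hrtfs, prior, NoiseModel(), mask, seed=5,
        )
        # zero depth: the density is irrelevant; with per-condition noise
        # realizations the rates agree within binomial error
        r = pooled.error_rate.to_numpy()
        n = pooled.n_trials.iloc[0]
        assert abs(r[0] - r[1]) < 3 * np.sqrt(2 * max(r.mean(), 1e-3) / n)

    def test_per_subject_table_pools_correctly(self, bench):
        mask, hrtfs, prior = bench
        pooled, per_subj = run_ripple_experiment(
            ["ISD"], [RippleParams(40.0, 1.0, 0.0)], hrtfs, None,
            NoiseModel(), mask, seed=6,
        )
        assert set(per_subj.subject_id) == {h.subject_id for h in hrtfs}
        assert pooled.n_trials.iloc[0] == per_subj.n_trials.sum()
        assert pooled.error_rate.iloc[0] == pytest.approx(
            per_subj.n_errors.sum() / per_subj.n_trials.sum()
        )


class TestFlatExperiment:
    def test_zero_noise_limit_errors_vanish(self, bench, fb30):
        mask, hrtfs, prior = bench
        h = hrtfs[0]
        tiny = NoiseModel(1e-6, 1e-6)
        dec = DecoderModel.build(h, hl.narrow_prior(np.zeros(30), 0.0), tiny, "BIN_SG")
        df = run_flat_experiment({"known": [(dec, h)]}, mask, seed=7)
        assert df.great_circle_error_deg.max() == pytest.approx(0.0, abs=1e-3)

    def test_narrow_prior_beats_ecological_on_matching_stimulus(self, bench, fb30):
        """When the flat stimulus matches the narrow prior's reference, the
        narrow-prior observer localizes at least as accurately on average."""
        mask, hrtfs, prior = bench
        h = hrtfs[0]
        noise = NoiseModel()
        variants = {
            "narrow": [(DecoderModel.build(h, hl.narrow_prior(np.zeros(30), 1.0),
                                           noise, "BIN_SG"), h)],
            "eco": [(DecoderModel.build(h, prior, noise, "BIN_SG"), h)],
        }
        df = run_flat_experiment(variants, mask, seed=8, n_repeats=2)
        means = df.groupby("variant").great_circle_error_deg.mean()
        assert means["narrow"] <= means["eco"]

    def test_isd_errors_largest_near_midsagittal_plane(self, bench, fb30):
        mask, hrtfs, prior = bench
        h = hrtfs[0]
        dec = DecoderModel.build(h, None, NoiseModel(), "ISD")
        df = run_flat_experiment({"ISD": [(dec, h)]}, mask, seed=9, n_repeats=3)
        near = df[df.lateral_deg.abs() < 10].great_circle_error_deg.mean()
        far = df[df.lateral_deg.abs() > 20].great_circle_error_deg.mean()
        assert near > far


class TestResponseDistribution:
    def test_counts_conserved_and_attractor_is_mode(self, grid200):
        rng = np.random.default_rng(10)
        resp = rng.integers(0, len(grid200), 500)
        counts, attractor = response_distribution(resp, grid200)
        assert counts.sum() == 500
        assert attractor == int(np.argmax(np.bincount(resp, minlength=len(grid200))))

    def test_zero_noise_uniform_presentation_hits_every_direction(
        self, hrtf200, eco_prior
    ):
        dec = DecoderModel.build(hrtf200, eco_prior, NoiseModel(), "BIN_SG")
        idx = np.arange(len(hrtf200.grid))
        x = _observation_features(dec, hrtf200, idx, eco_prior.mean)
        counts, _ = response_distribution(dec.decode_batch(x), hrtf200.grid)
        np.testing.assert_array_equal(counts, 1)

    def test_empty_rejected(self, grid200):
        with pytest.raises(ValueError):
            response_distribution(np.array([], dtype=int), grid200)
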