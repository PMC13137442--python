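"""Goodness of fit, observed-series contracts, and the mechanics of the
bounded multi-start estimator (quality bars live in the acceptance
suite; these tests use deliberately small budgets)."""

import numpy as np
import pytest

from snitr import (
    DEFAULT_INIT,
    FitConfig,
    GeneratorConfig,
    fit_and_validate,
    fit_snitr,
    generate_series,
    goodness_of_fit,
)
from snitr.fitting import ObservedSeries


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        obs = np.array([0.1, 0.4, 0.2])
        assert goodness_of_fit(obs, obs) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([0.1, 0.2, 0.3])
        pred = np.full_like(obs, obs.mean())
        assert goodness_of_fit(pred, obs) == pytest.approx(0.0)

    def test_three_point_hand_value(self):
        # SS_res = 0.01, SS_tot = 0.02 -> R^2 = 0.5
        obs = np.array([0.1, 0.2, 0.3])
        pred = np.array([0.1, 0.2, 0.4])
        assert goodness_of_fit(pred, obs) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            goodness_of_fit(np.array([0.1, 0.2]), np.array([0.3, 0.3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.array([0.1]), np.array([0.1, 0.2]))


class TestObservedSeries:
    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ObservedSeries(
                times=np.array([1.0, 0.5]), values=np.array([0.1, 0.2]),
                bin_width=0.5, fit_window_end=1.0, validation_end=2.0,
            )

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ObservedSeries(
                times=np.array([0.5, 1.0]), values=np.array([0.1, -0.2]),
                bin_width=0.5, fit_window_end=1.0, validation_end=2.0,
            )

    def test_window_order_enforced(self):
        with pytest.raises(ValueError, match="precede"):
            ObservedSeries(
                times=np.array([0.5, 1.0]), values=np.array([0.1, 0.2]),
                bin_width=0.5, fit_window_end=2.0, validation_end=1.0,
            )

    def test_masks_partition_by_window(self):
        s = ObservedSeries(
            times=np.array([0.5, 1.5, 2.5, 3.5]),
            values=np.array([0.1, 0.2, 0.2, 0.1]),
            bin_width=1.0, fit_window_end=2.0, validation_end=4.0,
        )
        assert s.fit_mask.tolist() == [True, True, False, False]
        assert s.validation_mask.tolist() == [False, False, True, True]


TINY = FitConfig(n_starts=1, n_samples=8, seed=11, max_nfev=40, polish=False,
                 pinned_init=DEFAULT_INIT)


@pytest.fixture(scope="module")
def short_series():
    """Noiseless short series: 60 bins over 10 h, 27 in the fit window."""
    series, _ = generate_series(GeneratorConfig(noise="none", duration=10.0))
    return series


class TestFitMechanics:
    def test_requires_enough_fit_points(self):
        series, _ = generate_series(GeneratorConfig(noise="none", duration=2.0))
        with pytest.raises(ValueError, match="at least 20"):
            fit_snitr(series, TINY)

    def test_monotone_improvement_over_starts(self, short_series):
        fit = fit_snitr(short_series, TINY)
        assert fit.rss <= np.min(fit.start_objectives) + 1e-12
        assert fit.rss >= 0

    def test_estimates_respect_box_bounds(self, short_series):
        fit = fit_snitr(short_series, TINY)
        for name, value in fit.params_hat.to_dict().items():
            assert 0.001 - 1e-12 <= value <= 0.999 + 1e-12, name

    def test_deterministic_given_seed(self, short_series):
        a = fit_snitr(short_series, TINY)
        b = fit_snitr(short_series, TINY)
        assert a.rss == b.rss
        assert a.params_hat == b.params_hat

    def test_single_free_rate_recovered(self, short_series):
        """With every other rate pinned to the generating truth, the one
        free rate is identified from the curve."""
        from snitr.presets import FIT_TRUTH

        fixed = FIT_TRUTH.to_dict()
        del fixed["alpha1"]
        cfg = FitConfig(n_starts=2, n_samples=16, seed=3, max_nfev=100,
                        polish=False, pinned_init=DEFAULT_INIT,
                        fixed_params=fixed)
        fit = fit_snitr(short_series, cfg)
        assert fit.params_hat.alpha1 == pytest.approx(FIT_TRUTH.alpha1, abs=1e-4)
        assert fit.fit_coefficient > 0.999

    def test_fit_window_score_degrades_with_noise(self):
        """More observation noise cannot improve the in-window score."""
        from snitr.presets import FIT_TRUTH

        fixed = FIT_TRUTH.to_dict()
        del fixed["alpha1"]
        cfg = FitConfig(n_starts=1, n_samples=8, seed=3, max_nfev=60,
                        polish=False, pinned_init=DEFAULT_INIT,
                        fixed_params=fixed)
        scores = []
        for scale in (0.0, 0.01, 0.05):
            per_seed = []
            for seed in (9, 10, 11):
                series, _ = generate_series(GeneratorConfig(
                    noise="gaussian", noise_scale=scale, seed=seed,
                ))
                per_seed.append(fit_snitr(series, cfg).fit_coefficient)
            scores.append(np.mean(per_seed))
        assert scores[0] > scores[1] > scores[2]

    def test_empty_validation_window_rejected(self, short_series):
        keep = short_series.fit_mask
        clipped = ObservedSeries(
            times=short_series.times[keep],
            values=short_series.values[keep],
            bin_width=short_series.bin_width,
            fit_window_end=short_series.fit_window_end,
            validation_end=short_series.validation_end,
        )
        with pytest.raises(ValueError, match="validation"):
            fit_and_validate(clipped, TINY)

    def test_invariant_to_pre_sort_shuffling(self, short_series, rng):
        """The objective is a sum over observations, so reordering the
        raw records before sorting changes nothing."""
        perm = rng.permutation(len(short_series.times))
        order = np.argsort(short_series.times[perm])
        rebuilt = ObservedSeries(
            times=short_series.times[perm][order],
            values=short_series.values[perm][order],
            bin_width=short_series.bin_width,
            fit_window_end=short_series.fit_window_end,
            validation_end=short_series.validation_end,
        )
        a = fit_snitr(short_series, TINY)
        b = fit_snitr(rebuilt, TINY)
        assert a.rss == b.rss
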