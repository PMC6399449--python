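"""Attenuated-cosine fitting, scoring, BIC and FNR calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perioscope import periodicity, preprocess, synthetic
from perioscope.periodicity import (
    CalibrationResult,
    GridConfig,
    PeriodicFit,
    bic_of_fit,
    calibrate_cutoffs,
    fit_periodic_model,
    periodicity_score,
    select_oscillating_genes,
)

SMALL_GRID = GridConfig(lambda_min=55, lambda_max=75, lambda_step=1.0)


def brute_force_fit(times, values, grid):
    """Independent literal scan of the same grid (per-point lstsq)."""
    best = None
    for lam in grid.lambdas():
        for phi in grid.phis(lam):
            for sig in grid.sigmas:
                c = np.exp(-sig * times) * np.cos(2 * np.pi * (times - phi) / lam)
                X = np.column_stack([np.ones_like(times), c])
                beta, *_ = np.linalg.lstsq(X, values, rcond=None)
                rss = float(((values - X @ beta) ** 2).sum())
                if best is None or rss < best[0] - 1e-12:
                    best = (rss, lam, phi, sig, beta[1])
    rss, lam, phi, sig, amp = best
    if amp < 0:
        amp, phi = -amp, (phi + lam / 2) % lam
    return rss, lam, phi, sig, amp


class TestModelFit:
    def test_constant_trajectory_fits_flat(self, time_grid):
        fit = fit_periodic_model(time_grid, np.zeros_like(time_grid))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.rss_periodic == pytest.approx(fit.rss_flat, abs=1e-12)
        assert fit.score == 0.0

    def test_noise_free_cosine_recovered_exactly(self, time_grid):
        y = np.cos(2 * np.pi * (time_grid - 20.0) / 64.0)
        fit = fit_periodic_model(time_grid, y)
        assert (fit.lambda_min, fit.phi_min, fit.decay) == (64.0, 20.0, 0.0)
        assert fit.amplitude == pytest.approx(1.0)
        assert fit.mean_level == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_periodic_model(np.array([0.0]), np.array([1.0]))

    def test_matches_brute_force_scan_on_random_trajectories(self, time_grid):
        rng = np.random.default_rng(7)
        for _ in range(12):
            y = rng.normal(0, 1, len(time_grid))
            fit = fit_periodic_model(time_grid, y, grid=SMALL_GRID)
            rss, lam, phi, sig, amp = brute_force_fit(time_grid, y, SMALL_GRID)
            assert fit.rss_periodic == pytest.approx(rss, rel=1e-9, abs=1e-9)
            assert (fit.lambda_min, fit.phi_min, fit.decay) == (lam, phi, sig)
            assert fit.amplitude == pytest.approx(amp, rel=1e-9, abs=1e-9)

    def test_shift_covariance_on_noise_free_input(self):
        # shifting the sampling times by delta shifts phi by delta mod lambda
        t = np.arange(0.0, 151.0, 5.0)
        y = np.cos(2 * np.pi * (t - 20.0) / 64.0)
        base = fit_periodic_model(t, y)
        shifted = fit_periodic_model(t + 7.0, np.cos(2 * np.pi * (t + 7.0 - 27.0) / 64.0))
        assert shifted.phi_min == pytest.approx((base.phi_min + 7.0) % 64.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_periodic_model_never_fits_worse_than_flat(self, time_grid, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, len(time_grid))
        fit = fit_periodic_model(time_grid, y, grid=SMALL_GRID)
        assert fit.rss_periodic <= fit.rss_flat + 1e-9
        assert 0 <= fit.phi_min < fit.lambda_min
        assert fit.amplitude >= 0
        assert fit.score >= 0

    def test_parameter_recovery_on_wild_type_ensemble(self, wt_preset):
        panel = synthetic.make_gene_panel(
            wt_preset, n_periodic=300, n_mbf=0, n_sbf=0, n_alpha=0, n_background=100, seed=4
        )
        m = synthetic.simulate_expression(wt_preset, panel, seed=5)
        fits = periodicity.fit_expression_matrix(preprocess.preprocess_counts(m))
        by_id = {f.gene_id: f for f in fits}
        lam_err, phi_err = [], []
        for g in panel:
            if g.gene_class.startswith("oscillating") and g.gene_id in by_id:
                f = by_id[g.gene_id]
                lam_err.append(abs(f.lambda_min - 64.0))
                d = (f.phi_min - g.phi_true) % 64.0
                phi_err.append(min(d, 64.0 - d))
        assert np.median(lam_err) <= 2.0
        assert np.median(phi_err) <= 2.0


class TestScoreAndBic:
    def test_score_formula(self):
        fit = PeriodicFit("g", 64, 0, 1, 0, 0, rss_periodic=1.0, rss_flat=2.0, n_valid=22)
        assert periodicity_score(fit) == pytest.approx(11 * math.log(2))

    def test_no_improvement_scores_zero(self):
        fit = PeriodicFit("g", 64, 0, 1, 0, 0, rss_periodic=2.0, rss_flat=2.0, n_valid=22)
        assert periodicity_score(fit) == 0.0

    def test_perfect_fit_capped_and_flagged(self):
        fit = PeriodicFit("g", 64, 0, 1, 0, 0, rss_periodic=0.0, rss_flat=2.0, n_valid=22)
        assert periodicity_score(fit) == periodicity.SCORE_CAP
        assert fit.score_capped

    def test_bic_formula(self):
        fit = PeriodicFit("g", 64, 0, 1, 0, 0, rss_periodic=2.2, rss_flat=3.0, n_valid=22)
        bic, bic_norm = bic_of_fit(fit)
        assert bic == pytest.approx(22 * math.log(0.1) + 5 * math.log(22))
        assert bic_norm == pytest.approx(bic / 1.0)

    def test_zero_amplitude_gets_infinite_bic_norm(self):
        fit = PeriodicFit("g", 64, 0, 0, 0, 0, rss_periodic=1.0, rss_flat=1.0, n_valid=22)
        assert bic_of_fit(fit)[1] == math.inf

    def test_noisier_copies_score_lower_in_expectation(self, wt_preset, time_grid):
        rng = np.random.default_rng(0)
        signal = 1.2 * np.cos(2 * np.pi * (time_grid - 20) / 64)
        low, high = [], []
        for _ in range(100):
            low.append(fit_periodic_model(time_grid, signal + rng.normal(0, 0.2, 22), grid=SMALL_GRID).score)
            high.append(fit_periodic_model(time_grid, signal + rng.normal(0, 0.6, 22), grid=SMALL_GRID).score)
        assert np.mean(low) > np.mean(high)


def _fits_with_scores(scores):
    return [
        PeriodicFit(f"g{i}", 64, 0, 1.0, 0, 0, rss_periodic=1.0, rss_flat=1.0,
                    n_valid=22, score=s, bic=-10.0, bic_norm=-10.0)
        for i, s in enumerate(scores)
    ]


class TestCalibration:
    def test_enumerated_example_ten_scores(self):
        cal = calibrate_cutoffs(_fits_with_scores(range(1, 11)), fnr=0.2)
        assert cal.score_cutoff == 3
        failing = [f.gene_id for f in _fits_with_scores(range(1, 11)) if f.score < 3]
        assert failing == ["g0", "g1"]

    def test_vanishing_fnr_cuts_nothing(self):
        cal = calibrate_cutoffs(_fits_with_scores(range(1, 11)), fnr=1e-6)
        assert cal.score_cutoff == 1
        assert sum(s < cal.score_cutoff for s in range(1, 11)) == 0

    def test_fnr_bounds_enforced(self):
        fits = _fits_with_scores(range(1, 11))
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError):
                calibrate_cutoffs(fits, fnr=bad)

    def test_reference_too_small(self):
        with pytest.raises(ValueError):
            calibrate_cutoffs(_fits_with_scores([1, 2, 3]), fnr=0.2)

    def test_marginal_fnr_exact_on_distinct_scores(self):
        rng = np.random.default_rng(1)
        fits = _fits_with_scores(rng.permutation(200) + rng.uniform(0, 0.5, 200))
        cal = calibrate_cutoffs(fits, fnr=0.2)
        assert sum(f.score < cal.score_cutoff for f in fits) == 40


class TestSelection:
    def _cal(self):
        return CalibrationResult(score_cutoff=5.0, bicnorm_cutoff=0.0, fnr=0.2, n_reference=200)

    def test_short_trajectory_fails_on_valid_points_despite_perfect_fit(self):
        fit = PeriodicFit("g", 64, 0, 1, 0, 0, rss_periodic=1e-9, rss_flat=5.0,
                          n_valid=12, score=100.0, bic=-50, bic_norm=-50)
        selected = select_oscillating_genes([fit], self._cal(), min_points=13)
        assert selected == [] and fit.fail_reason == "valid points"

    def test_flat_gene_fails_on_score(self):
        fit = PeriodicFit("g", 64, 0, 0, 0, 0, rss_periodic=1.0, rss_flat=1.0,
                          n_valid=22, score=0.0, bic=0.0, bic_norm=math.inf)
        select_oscillating_genes([fit], self._cal())
        assert "score" in fit.fail_reason

    def test_passing_gene_selected(self):
        fit = PeriodicFit("g", 64, 0, 1, 0, 0, rss_periodic=0.1, rss_flat=5.0,
                          n_valid=22, score=40.0, bic=-40, bic_norm=-40)
        assert select_oscillating_genes([fit], self._cal()) == ["g"]
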