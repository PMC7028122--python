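"""Normative fits, cutoffs, pointwise norms, power-law fit, associations."""

import numpy as np
import pytest
from scipy import stats

from tabvis.normative import (
    DegenerateFitWarning,
    RunDifferenceWarning,
    classify,
    combine_runs,
    fit_normative,
    fit_power,
    pointwise_norms,
    run_equivalence_p,
    spearman,
)


class TestFitNormative:
    def test_gaussian_cutoff_closed_form(self, rng):
        x = rng.normal(3.3, 0.15, 200)
        model = fit_normative(x, "gaussian")
        m, s = x.mean(), x.std(ddof=0)  # ML sd: n denominator
        assert model.params["mean"] == pytest.approx(m)
        assert model.params["sd"] == pytest.approx(s)
        assert model.cutoff99 == pytest.approx(m + 2.3263478740 * s, rel=1e-9)
        assert model.cdf(model.cutoff99) == pytest.approx(0.99, abs=1e-9)

    def test_gaussian_constant_data_flagged(self):
        with pytest.warns(DegenerateFitWarning):
            model = fit_normative(np.full(10, 3.0), "gaussian")
        assert model.cutoff99 == 3.0

    def test_gamma_parameter_recovery(self):
        rng = np.random.default_rng(99)
        x = rng.gamma(shape=9.0, scale=0.2, size=2000)
        model = fit_normative(x, "gamma")
        assert model.params["shape"] == pytest.approx(9.0, rel=0.10)
        true_q99 = stats.gamma.ppf(0.99, 9.0, scale=0.2)
        assert model.cutoff99 == pytest.approx(true_q99, rel=0.03)
        assert model.cdf(model.cutoff99) == pytest.approx(0.99, abs=1e-9)

    def test_gamma_requires_positive_data(self):
        with pytest.raises(ValueError, match="positive"):
            fit_normative([1.0, 2.0, -0.5, 1.1, 0.9], "gamma")

    def test_cutoff_monotone_in_location_and_scale(self, rng):
        x = rng.normal(3.0, 0.2, 100)
        base = fit_normative(x, "gaussian").cutoff99
        assert fit_normative(x + 0.5, "gaussian").cutoff99 > base
        assert fit_normative((x - 3.0) * 2 + 3.0, "gaussian").cutoff99 > base


class TestCombineRuns:
    def test_identical_runs_pool_without_warning(self, recwarn):
        r = np.array([3.0, 3.2, 3.4, 3.1, 3.3])
        pooled = combine_runs(r, r)
        assert len(pooled) == 10
        assert pooled.mean() == pytest.approx(r.mean())
        assert not any(isinstance(w.message, RunDifferenceWarning) for w in recwarn.list)

    def test_systematic_shift_fires_gate(self, rng):
        r1 = rng.normal(3.2, 0.1, 20)
        with pytest.warns(RunDifferenceWarning):
            combine_runs(r1, r1 + 0.5 + rng.normal(0, 0.05, 20))

    def test_pooled_mean_is_mean_of_run_means(self, rng):
        r1 = rng.normal(3.0, 0.2, 15)
        r2 = rng.normal(3.1, 0.2, 15)
        p = run_equivalence_p(r1, r2)
        pooled = np.concatenate([r1, r2]) if p >= 0 else None
        assert pooled.mean() == pytest.approx((r1.mean() + r2.mean()) / 2)

    def test_wilcoxon_gate_available(self, rng):
        r1 = rng.normal(3.2, 0.1, 20)
        assert 0 <= run_equivalence_p(r1, r1 + rng.normal(0, 0.05, 20), "wilcoxon") <= 1


class TestPointwiseNorms:
    def test_medians_track_eccentricity(self, cohort):
        rts1 = cohort.search_location_rts(1)
        rts2 = cohort.search_location_rts(2)
        pooled = {loc: np.concatenate([rts1[loc], rts2[loc]]) for loc in rts1}
        norms = pointwise_norms(pooled, cohort.grid)
        assert len(norms.table) == 62
        rho = stats.spearmanr(norms.table["ecc_deg"], norms.table["median_rt"]).statistic
        assert rho > 0.9
        assert np.all(norms.table["cutoff99"] >= norms.table["median_rt"])

    def test_minimum_observations_enforced(self, grid):
        with pytest.raises(ValueError, match="at least 5"):
            pointwise_norms({1: [1.0, 1.1]}, grid)


class TestFitPower:
    def test_constant_data_fits_like_constant(self, rng):
        ecc = np.linspace(1, 15, 40)
        y = 1.5 + rng.normal(0, 0.1, 40)  # centered noise, no ecc dependence
        fit = fit_power(ecc, y)
        assert fit.adj_r2 < 0.3

    def test_beats_random_restart_oracle(self, rng):
        ecc = np.linspace(2.5, 15.5, 62)
        y = 0.8 * ecc ** 0.35 + 0.3 + rng.normal(0, 0.05, 62)
        fit = fit_power(ecc, y)
        res_fit = np.sum((y - fit(ecc)) ** 2)
        # oracle: profile the exponent on a fine grid, solving a, c by
        # linear least squares at each candidate exponent
        best = np.inf
        for b in np.linspace(-2, 2, 100):
            design = np.column_stack([ecc ** b, np.ones_like(ecc)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            best = min(best, float(np.sum((y - design @ coef) ** 2)))
        assert res_fit <= best + 1e-8

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_power([1, 2, 3], [1, 2, 3])  # too few points
        with pytest.raises(ValueError):
            fit_power([0.0, 1, 2, 3, 4], [1, 2, 3, 4, 5])  # non-positive ecc


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_null_shuffle_not_significant(self):
        rng = np.random.default_rng(77)
        x = rng.normal(0, 1, 30)
        y = rng.permutation(x)
        rho, p = spearman(x, y)
        assert abs(rho) < 0.3
        assert p > 0.05

    def test_matches_rank_then_pearson_oracle(self, rng):
        for n in (8, 15, 30):  # exercises both p-value branches for rho
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n) + 0.4 * x
            x[0] = x[1]  # midrank tie handling
            rho, _ = spearman(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            expect = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(expect, abs=1e-12)

    def test_small_sample_p_is_permutation_based_and_seeded(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        assert spearman(x, y, seed=5) == spearman(x, y, seed=5)


class TestClassify:
    def test_boundary_is_within_norms(self, rng):
        model = fit_normative(rng.normal(3.2, 0.13, 100), "gaussian")
        assert classify(model.cutoff99, model) == "within_norms"
        assert classify(model.cutoff99 + 1e-9, model) == "outside_norms"
        assert classify(model.cutoff99 - 0.5, model) == "within_norms"
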