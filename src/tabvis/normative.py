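"""Normative reference limits and associated analyses.

Fits a reference distribution to healthy-observer scores by maximum
likelihood (Gaussian for face-discrimination thresholds, Gamma for
right-skewed search median RTs), reports the 99% upper cutoff — the value
below which 99% of the healthy population is expected to score; values
above it flag possibly abnormal performance — and provides the pointwise
(per-location) norms for the search grid, the eccentricity power-law fit
RT = a * ecc**b + c, run pooling with an equivalence gate, Spearman rank
associations with covariates, and score classification against a fitted
model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .search import SearchGrid


class RunDifferenceWarning(UserWarning):
    """Run 1 and run 2 differ systematically; pooling may be inappropriate."""


class DegenerateFitWarning(UserWarning):
    """The fitted reference distribution has (near-)zero spread."""


@dataclass(frozen=True)
class NormativeModel:
    """A maximum-likelihood reference distribution with its 99% cutoff.

    Gaussian parameters are (mean, sd) with the ML (n-denominator) SD —
    documented because the cutoff is sensitive to this choice; Gamma
    parameters are (shape, scale) with location fixed at zero.
    """

    family: str
    params: Mapping[str, float]
    cutoff99: float
    n: int
    loglik: float

    def cdf(self, x):
        return self._dist().cdf(x)

    def ppf(self, q):
        return self._dist().ppf(q)

    def _dist(self):
        if self.family == "gaussian":
            return stats.norm(self.params["mean"], self.params["sd"])
        return stats.gamma(self.params["shape"], scale=self.params["scale"])


@dataclass(frozen=True)
class PowerFit:
    """Least-squares fit of RT = a * ecc**b + c with adjusted R^2."""

    a: float
    b: float
    c: float
    adj_r2: float

    def __call__(self, ecc):
        return self.a * np.asarray(ecc, dtype=float) ** self.b + self.c


@dataclass(frozen=True)
class PointwiseNorms:
    """Per-location normative medians and 99% cutoffs for the search grid,
    joined to eccentricity, plus the eccentricity power-law fit of the
    medians."""

    table: pd.DataFrame  # columns: location, col, row, ecc_deg, median_rt, cutoff99
    power_fit: PowerFit


def fit_normative(values: Sequence[float], family: str = "gaussian") -> NormativeModel:
    """Maximum-likelihood fit of the reference distribution.

    family="gaussian": closed-form ML (mean, n-denominator SD).
    family="gamma": full ML with location fixed at 0 (shape solved through
    the digamma equation); requires strictly positive data.
    The 99% cutoff is the fitted inverse CDF at 0.99.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("need a 1-D sample of at least 5 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if family == "gaussian":
        mean = float(x.mean())
        sd = float(x.std(ddof=0))
        if sd == 0.0:
            warnings.warn(
                "all values identical: degenerate Gaussian fit, cutoff equals the constant",
                DegenerateFitWarning, stacklevel=2,
            )
            return NormativeModel("gaussian", {"mean": mean, "sd": 0.0},
                                  cutoff99=mean, n=len(x), loglik=math.inf)
        loglik = float(np.sum(stats.norm.logpdf(x, mean, sd)))
        cutoff = float(stats.norm.ppf(0.99, mean, sd))
        return NormativeModel("gaussian", {"mean": mean, "sd": sd}, cutoff, len(x), loglik)
    if family == "gamma":
        if np.any(x <= 0):
            raise ValueError("gamma fits require strictly positive values")
        if np.ptp(x) == 0.0:
            warnings.warn(
                "all values identical: degenerate Gamma fit, cutoff equals the constant",
                DegenerateFitWarning, stacklevel=2,
            )
            return NormativeModel("gamma", {"shape": math.inf, "scale": 0.0},
                                  cutoff99=float(x[0]), n=len(x), loglik=math.inf)
        shape, _loc, scale = stats.gamma.fit(x, floc=0)
        loglik = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
        cutoff = float(stats.gamma.ppf(0.99, shape, scale=scale))
        return NormativeModel("gamma", {"shape": float(shape), "scale": float(scale)},
                              cutoff, len(x), loglik)
    raise ValueError("family must be 'gaussian' or 'gamma'")


def run_equivalence_p(
    run1: Sequence[float], run2: Sequence[float], test: str = "t"
) -> float:
    """Paired test for a systematic run-1 vs run-2 difference
    (test="t" paired t-test, test="wilcoxon" signed-rank)."""
    r1 = np.asarray(run1, dtype=float)
    r2 = np.asarray(run2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("runs must be paired")
    if np.allclose(r1, r2):
        return 1.0
    if test == "t":
        return float(stats.ttest_rel(r1, r2).pvalue)
    if test == "wilcoxon":
        return float(stats.wilcoxon(r1, r2).pvalue)
    raise ValueError("test must be 't' or 'wilcoxon'")


def combine_runs(
    run1: Sequence[float],
    run2: Sequence[float],
    gate_alpha: float = 0.05,
    test: str = "t",
) -> np.ndarray:
    """Pool paired runs into one normative sample by concatenation.

    Pooling assumes no systematic run effect (no learning/fatigue); a
    paired-difference gate warns if the runs differ at ``gate_alpha``.
    Returns the concatenated 2n-value sample.
    """
    r1 = np.asarray(run1, dtype=float)
    r2 = np.asarray(run2, dtype=float)
    p = run_equivalence_p(r1, r2, test=test)
    if p < gate_alpha:
        warnings.warn(
            f"runs differ systematically (paired {test} test p={p:.3g} < "
            f"{gate_alpha}); pooled norms may be biased",
            RunDifferenceWarning, stacklevel=2,
        )
    return np.concatenate([r1, r2])


def fit_power(
    ecc: Sequence[float],
    rt: Sequence[float],
    n_starts: int = 8,
) -> PowerFit:
    """Nonlinear least squares for RT = a * ecc**b + c.

    The exponent surface is shallow, so the fit is restarted from a small
    grid of exponents (plus sign variants for a) and the best converged
    solution is kept; adjusted R^2 uses 3 parameters.
    """
    x = np.asarray(ecc, dtype=float)
    y = np.asarray(rt, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ecc and rt must be 1-D and the same length")
    if len(x) <= 3:
        raise ValueError("need more than 3 points to fit 3 parameters")
    if np.any(x <= 0):
        raise ValueError("eccentricities must be strictly positive")

    def model(xv, a, b, c):
        return a * xv**b + c

    b0s = np.concatenate([-np.geomspace(0.02, 2.0, n_starts // 2),
                          np.geomspace(0.02, 2.0, n_starts - n_starts // 2)])
    best, best_ss, last_err = None, np.inf, None
    for b0 in b0s:
        for a0 in (-1.0, 1.0):
            try:
                popt, _ = optimize.curve_fit(
                    model, x, y, p0=(a0 * np.std(y) if np.std(y) else a0, b0, y.mean()),
                    maxfev=20_000,
                )
            except RuntimeError as err:  # no convergence from this start
                last_err = err
                continue
            ss = float(np.sum((y - model(x, *popt)) ** 2))
            if ss < best_ss:
                best, best_ss = popt, ss
    if best is None:
        raise RuntimeError(
            f"power-law fit failed to converge from {2 * len(b0s)} starts; "
            f"last optimizer error: {last_err}"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = len(x), 3
    if ss_tot == 0.0:
        r2 = 1.0 if best_ss == 0.0 else 0.0
    else:
        r2 = 1.0 - best_ss / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else r2
    return PowerFit(a=float(best[0]), b=float(best[1]), c=float(best[2]),
                    adj_r2=float(adj_r2))


def pointwise_norms(
    location_rts: Mapping[int, Sequence[float]],
    grid: SearchGrid | None = None,
    family: str = "gamma",
) -> PointwiseNorms:
    """Per-location norms: median RT and 99% cutoff at each tested location,
    computed the same way as for the overall median, joined to the grid's
    eccentricities, with the eccentricity power law fitted to the medians.

    ``location_rts`` maps location index -> RTs across the (pooled) cohort;
    every location needs at least 5 observations.
    """
    grid = grid or SearchGrid()
    rows = []
    for loc in sorted(location_rts):
        rts = np.asarray(location_rts[loc], dtype=float)
        if len(rts) < 5:
            raise ValueError(f"location {loc}: need at least 5 observations")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFitWarning)
            cutoff = fit_normative(rts, family=family).cutoff99
        col, row = grid.col_row(loc)
        rows.append(
            {"location": loc, "col": col, "row": row,
             "ecc_deg": grid.eccentricity(loc),
             "median_rt": float(np.median(rts)), "cutoff99": cutoff}
        )
    table = pd.DataFrame(rows)
    fit = fit_power(table["ecc_deg"].to_numpy(), table["median_rt"].to_numpy())
    return PointwiseNorms(table=table, power_fit=fit)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    seed: int = 0,
    n_perm: int = 20_000,
) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p-value uses the t approximation for n >= 20 and a seeded
    permutation test (exact enumeration when feasible) for smaller samples,
    where the approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 5:
        raise ValueError("x and y must be 1-D, equal length, n >= 5")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) >= 20:
        return rho, float(res.pvalue)
    perm = stats.permutation_test(
        (x, y),
        lambda a, b: stats.spearmanr(a, b).statistic,
        permutation_type="pairings",
        n_resamples=n_perm,
        rng=np.random.default_rng(seed),
    )
    return rho, float(perm.pvalue)


def classify(score: float, model: NormativeModel) -> str:
    """"within_norms" if the score is at or below the 99% cutoff,
    "outside_norms" strictly above it (only values *greater* than the
    cutoff flag possible abnormality)."""
    return "outside_norms" if score > model.cutoff99 else "within_norms"
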