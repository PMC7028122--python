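"""Test-retest repeatability analysis.

Bland-Altman statistics on paired run-1/run-2 scores, the 95% Coefficient
of Repeatability (CoR95 = 1.96 x SD of the paired differences, the
half-width of the limits of agreement), bias-corrected and accelerated
(BCa) bootstrap confidence intervals, and the trials-versus-precision
refinement curves used to decide how many trials / locations each test
actually needs.

Note on conventions: CoR95 here is the Bland-Altman 1.96*SD(differences)
form.  An alternative estimator inflates the within-subject SD by sqrt(2)
(CoR = 1.96*sqrt(2)*Sw, identical for two runs up to the pairing of
definitions); the paired-difference form is used throughout because the
data are exactly two runs per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RepeatabilityResult:
    """Bland-Altman summary of paired test-retest scores (run2 - run1)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    cor95: float
    n_pairs: int
    ci95: tuple[float, float] | None = None
    n_boot: int | None = None

    def __post_init__(self) -> None:
        if self.cor95 < 0:
            raise ValueError("cor95 cannot be negative")
        if self.ci95 is not None and not (
            self.ci95[0] - 1e-12 <= self.cor95 <= self.ci95[1] + 1e-12
        ):
            raise ValueError("the point estimate must lie inside its own CI")


@dataclass(frozen=True)
class RefinementCurve:
    """CoR95 as a function of the number of trials (faces) or of sampled
    locations (search)."""

    sizes: tuple[int, ...]
    cor95: tuple[float, ...]
    test: str = ""

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.cor95):
            raise ValueError("one CoR95 per size")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")
        if any(c < 0 for c in self.cor95):
            raise ValueError("CoR95 values cannot be negative")


def bca_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    n_boot: int = 20_000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    vectorized: bool = False,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``data`` is an array whose first axis indexes independent observations
    (rows may be vectors, e.g. (run1, run2) pairs — resampling rows then
    preserves the pairing).  ``statistic`` maps a resample to a scalar; with
    ``vectorized=True`` it must instead accept a (n_boot, n, ...) stack and
    reduce along axis 1 (used for heavy simulations).

    The bias-correction z0 comes from the fraction of the bootstrap
    distribution below the point estimate (ties counted at half weight),
    the acceleration ``a`` from the jackknife skewness, and the percentile
    endpoints are adjusted accordingly.  A degenerate bootstrap
    distribution (all resample statistics equal) returns a point-mass
    interval with a warning.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to bootstrap")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)

    theta = float(statistic(data))
    idx = rng.integers(0, n, size=(n_boot, n))
    if vectorized:
        boot = np.asarray(statistic(data[idx]), dtype=float)
    else:
        boot = np.array([statistic(data[row]) for row in idx], dtype=float)

    if np.ptp(boot) == 0.0:
        warnings.warn(
            "degenerate bootstrap distribution (all resamples equal); "
            "returning a point-mass interval",
            stacklevel=2,
        )
        return (float(boot[0]), float(boot[0]))

    frac = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / n_boot
    frac = min(max(frac, 0.5 / n_boot), 1 - 0.5 / n_boot)
    z0 = stats.norm.ppf(frac)

    # jackknife acceleration
    jack = np.array(
        [statistic(np.delete(data, i, axis=0)) for i in range(n)], dtype=float
    )
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    lo, hi = [], []
    for z_alpha in (stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        (lo if z_alpha < 0 else hi).append(stats.norm.cdf(adj))
    return (
        float(np.quantile(boot, lo[0])),
        float(np.quantile(boot, hi[0])),
    )


def _cor95_of_pairs(pairs: np.ndarray) -> float:
    return 1.96 * float(np.std(pairs[..., 1] - pairs[..., 0], ddof=1, axis=-1))


def bland_altman(
    run1: Sequence[float],
    run2: Sequence[float],
    ci: bool = True,
    n_boot: int = 20_000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RepeatabilityResult:
    """Bland-Altman analysis of paired scores (same participant order).

    bias = mean(run2 - run1); sd_diff uses the n-1 denominator;
    limits of agreement = bias -/+ 1.96*sd_diff; CoR95 = 1.96*sd_diff.
    With ``ci=True`` a BCa bootstrap CI for CoR95 is computed by resampling
    participants (pairs), preserving the pairing.
    """
    r1 = np.asarray(run1, dtype=float)
    r2 = np.asarray(run2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("run1 and run2 must be 1-D and the same length")
    if len(r1) < 3:
        raise ValueError("need at least 3 participant pairs")
    diffs = r2 - r1
    bias = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    cor95 = 1.96 * sd_diff
    interval = None
    if ci:
        pairs = np.column_stack([r1, r2])
        interval = bca_ci(
            lambda p: 1.96 * np.std(p[:, 1] - p[:, 0], ddof=1),
            pairs, n_boot=n_boot, level=level, seed=seed, rng=rng,
        )
        # a bootstrap interval may just miss the point estimate on tiny
        # samples; widen minimally rather than report an inconsistent pair
        interval = (min(interval[0], cor95), max(interval[1], cor95))
    return RepeatabilityResult(
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - 1.96 * sd_diff,
        loa_high=bias + 1.96 * sd_diff,
        cor95=cor95,
        n_pairs=len(r1),
        ci95=interval,
        n_boot=n_boot if ci else None,
    )


def faces_refinement(
    trialwise_run1: np.ndarray,
    trialwise_run2: np.ndarray,
    n_values: Sequence[int] | None = None,
) -> RefinementCurve:
    """Precision versus staircase length for the faces test.

    The adaptive staircase provides an updated threshold estimate after
    every trial, so the first-N analysis simply takes column N-1 of each
    (participants x trials) running-estimate matrix and computes the CoR95
    of those truncated estimates across participants.
    """
    t1 = np.atleast_2d(np.asarray(trialwise_run1, dtype=float))
    t2 = np.atleast_2d(np.asarray(trialwise_run2, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError("both runs need the same (participants x trials) shape")
    if n_values is None:
        n_values = range(1, t1.shape[1] + 1)
    n_values = [int(n) for n in n_values]
    if any(not 1 <= n <= t1.shape[1] for n in n_values):
        raise ValueError("requested trial counts exceed the recorded history")
    cors = [
        bland_altman(t1[:, n - 1], t2[:, n - 1], ci=False).cor95 for n in n_values
    ]
    return RefinementCurve(sizes=tuple(n_values), cor95=tuple(cors), test="faces")


def search_refinement(
    run1: Sequence[Mapping[int, float]],
    run2: Sequence[Mapping[int, float]],
    ladder: Sequence[Sequence[int]],
) -> RefinementCurve:
    """Precision versus number of sampled locations for the search test.

    ``run1``/``run2`` hold each participant's per-location RT map for the
    two runs; for each subset in the (strictly growing) ladder, the CoR95 of
    the median RT computed over only that subset's locations is returned.
    """
    if len(run1) != len(run2):
        raise ValueError("both runs must cover the same participants")
    sizes, cors = [], []
    for subset in ladder:
        subset = [int(loc) for loc in subset]
        if len(set(subset)) != len(subset):
            raise ValueError(f"duplicate locations in subset of size {len(subset)}")
        missing = [
            loc for locs in (run1, run2) for m in locs for loc in subset if loc not in m
        ]
        if missing:
            raise ValueError(f"locations missing from the recorded RTs: {sorted(set(missing))}")
        m1 = [float(np.median([m[loc] for loc in subset])) for m in run1]
        m2 = [float(np.median([m[loc] for loc in subset])) for m in run2]
        sizes.append(len(subset))
        cors.append(bland_altman(m1, m2, ci=False).cor95)
    return RefinementCurve(sizes=tuple(sizes), cor95=tuple(cors), test="search")
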