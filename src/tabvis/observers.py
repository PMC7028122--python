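"""Generative simulated observers and the synthetic participant cohort.

An :class:`ObserverModel` answers 4AFC face-discrimination trials through a
Weibull psychometric function and produces visual-search response times
through an eccentricity power law ``RT(ecc) = a * ecc**b + c`` with
multiplicative lognormal noise.  :func:`generate_cohort` draws a population
of such observers and runs both test engines twice per participant,
producing the paired run-1/run-2 session data the analysis modules consume.

Population calibration
----------------------
The cohort defaults emulate the study conditions under which these tests
were evaluated in young, normally-sighted adults, using the published
summary statistics as calibration constraints:

* faces (analysed at the first 20 staircase trials): 95% coefficient of
  repeatability 0.27 d and Gaussian normative 99% limit 3.50 d.  With a
  population mean of 3.2 d (a choice inside the typical 3-4 d band) these
  imply a per-run measurement SD of 0.27/(1.96*sqrt(2)) ~ 0.097 d and a
  between-observer SD of sqrt(pooled^2 - within^2) ~ 0.084 d.  The
  staircase itself contributes ~0.088 d of estimation noise at 20 trials
  (measured by simulation at the default slope), so the residual run-to-run
  stability jitter is the variance difference, ~0.042 d.
* search (analysed over the refined 22-location subset): CoR95 0.84 s and
  Gamma normative 99% limit 3.1 s.  The noiseless 22-location median of the
  default power law is m0 ~ 1.75 s; a Gamma family with mean m0 and 0.99
  quantile 3.1 s fixes the total between-observer spread, and per-location
  lognormal noise of SD 0.35 (log scale, a typical RT coefficient of
  variation) plus a run-level jitter chosen by variance subtraction
  reproduces the repeatability.

These constants define the simulated study; they are not dials to be tuned
per analysis.  All of them remain config-exposed for power studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .faces import FaceSessionResult, PsychometricParams, QuestConfig, prob_correct, run_face_session
from .search import SearchGrid, SearchSessionResult, run_search_session

__all__ = [
    "ObserverModel",
    "CohortConfig",
    "Participant",
    "Cohort",
    "rt_mean",
    "sample_rt",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Calibrated study conditions (see module docstring).

#: Emulated normative / repeatability constraints for the faces test.
FACES_POP_MEAN = 3.2          # d; population mean threshold (choice in the 3-4 band)
FACES_CUTOFF99 = 3.50         # d; Gaussian normative 99% limit being emulated
FACES_COR95 = 0.27            # d; test-retest CoR95 being emulated
#: Staircase estimation SD at 20 trials, default slope (measured by simulation).
FACES_STAIRCASE_SD_20 = 0.088

_Z99 = float(stats.norm.ppf(0.99))
FACES_POOLED_SD = (FACES_CUTOFF99 - FACES_POP_MEAN) / _Z99
FACES_WITHIN_SD = FACES_COR95 / (1.96 * math.sqrt(2.0))
FACES_BETWEEN_SD = math.sqrt(FACES_POOLED_SD**2 - FACES_WITHIN_SD**2)
FACES_RUN_JITTER_SD = math.sqrt(
    max(0.0, FACES_WITHIN_SD**2 - FACES_STAIRCASE_SD_20**2)
)

#: Emulated constraints for the search test.
SEARCH_CUTOFF99 = 3.1         # s; Gamma normative 99% limit being emulated
SEARCH_COR95 = 0.84           # s; test-retest CoR95 being emulated
SEARCH_RT_NOISE_SD = 0.35     # per-location lognormal noise SD (log scale)
#: SD of the 22-location median induced by per-location noise alone, for a
#: unit-scale observer (measured by simulation at SEARCH_RT_NOISE_SD).
SEARCH_MEDIAN_NOISE_SD = 0.163

DEFAULT_RT_COEFFS = (-13.14, -0.05, 13.56)  # (a, b, c) of RT(ecc) = a*ecc**b + c
ECC_CLAMP_DEG = 0.5  # guards the power-law singularity at 0 eccentricity


def _search_population_constants() -> tuple[float, float, float]:
    """Solve the search population calibration: returns (m0, latent Gamma
    shape of the per-observer speed multiplier, run-jitter log-SD)."""
    grid = SearchGrid()
    a, b, c = DEFAULT_RT_COEFFS
    ecc = np.array([grid.eccentricity(loc) for loc in grid.refined_subset()])
    m0 = float(np.median(a * np.maximum(ecc, ECC_CLAMP_DEG) ** b + c))
    # Gamma family with mean m0 whose 0.99 quantile is the normative limit.
    shape_total = optimize.brentq(
        lambda k: stats.gamma.ppf(0.99, k, scale=m0 / k) - SEARCH_CUTOFF99, 0.5, 1e4
    )
    var_total = m0**2 / shape_total
    within_sd = SEARCH_COR95 / (1.96 * math.sqrt(2.0))
    run_jitter_sd = math.sqrt(max(0.0, within_sd**2 - SEARCH_MEDIAN_NOISE_SD**2)) / m0
    rel_var_latent = max(1e-6, (var_total - within_sd**2) / m0**2)
    return m0, 1.0 / rel_var_latent, run_jitter_sd


SEARCH_BASELINE_MEDIAN, SEARCH_SCALE_SHAPE, SEARCH_RUN_JITTER_SD = (
    _search_population_constants()
)


# ---------------------------------------------------------------------------
# Observer model.

@dataclass(frozen=True)
class ObserverModel:
    """Generative model of one participant.

    Faces: a true discrimination threshold (d-units) with the engine's
    Weibull psychometric function.  Search: mean RT follows
    ``rt_scale * (rt_a * ecc**rt_b + rt_c)`` seconds with lognormal noise of
    log-SD ``rt_noise_sd``.  ``face_run_jitter_sd`` / ``rt_run_jitter_sd``
    are between-run stability terms (additive in d; multiplicative log-SD
    for RT).  ``deterministic`` removes all response stochasticity: face
    responses become a step function at threshold and RTs equal their mean
    (useful as an idealised oracle observer).
    """

    face_true_threshold: float = FACES_POP_MEAN
    face_params: PsychometricParams = field(default_factory=PsychometricParams)
    rt_a: float = DEFAULT_RT_COEFFS[0]
    rt_b: float = DEFAULT_RT_COEFFS[1]
    rt_c: float = DEFAULT_RT_COEFFS[2]
    rt_scale: float = 1.0
    rt_noise_sd: float = SEARCH_RT_NOISE_SD
    face_run_jitter_sd: float = FACES_RUN_JITTER_SD
    rt_run_jitter_sd: float = SEARCH_RUN_JITTER_SD
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.face_true_threshold <= 0:
            raise ValueError("face_true_threshold must be positive")
        if self.rt_noise_sd < 0 or self.face_run_jitter_sd < 0 or self.rt_run_jitter_sd < 0:
            raise ValueError("noise/jitter SDs must be non-negative")
        if self.rt_scale <= 0:
            raise ValueError("rt_scale must be positive")
        # targets only occur at the grid's non-centre cells (ecc >= ~2.8 deg)
        ecc = np.linspace(2.8, 15.5, 64)
        if np.any(self.rt_scale * (self.rt_a * ecc**self.rt_b + self.rt_c) <= 0):
            raise ValueError("mean RT must be positive over the grid's eccentricity range")

    # engine-facing protocol -------------------------------------------------
    def face_prob_correct(self, level: float) -> float:
        if self.deterministic:
            return 1.0 if level >= self.face_true_threshold else 0.0
        return prob_correct(level, self.face_true_threshold, self.face_params)

    def search_rt(self, ecc_deg: float, rng: np.random.Generator) -> float:
        return sample_rt(ecc_deg, self, rng)

    def with_run_jitter(self, rng: np.random.Generator) -> "ObserverModel":
        """The observer as it presents on one particular run: threshold and
        overall speed perturbed by the between-run stability terms."""
        thr = self.face_true_threshold + rng.normal(0.0, self.face_run_jitter_sd)
        scale = self.rt_scale * math.exp(rng.normal(0.0, self.rt_run_jitter_sd))
        return replace(self, face_true_threshold=max(thr, 0.05), rt_scale=scale)


def rt_mean(ecc_deg: float, model: ObserverModel):
    """Mean search RT (seconds) at an eccentricity, ``rt_scale * (a*ecc**b + c)``.

    Eccentricities below 0.5 degrees are clamped to 0.5 (targets never appear
    at the centre, so this only guards misuse of the power law at 0).
    Vectorized over ``ecc_deg``.
    """
    ecc = np.maximum(np.asarray(ecc_deg, dtype=float), ECC_CLAMP_DEG)
    if np.any(np.asarray(ecc_deg) < 0):
        raise ValueError("eccentricity must be non-negative")
    out = model.rt_scale * (model.rt_a * ecc**model.rt_b + model.rt_c)
    # near the clamp the power law can dip non-physical; keep RT positive
    out = np.maximum(out, 0.05)
    return float(out) if out.ndim == 0 else out


def sample_rt(ecc_deg: float, model: ObserverModel, rng: np.random.Generator) -> float:
    """One RT draw: lognormal multiplicative noise around :func:`rt_mean`
    (the noise has log-mean 0, so the distribution's median equals the mean
    RT of the power law).  Strictly positive; exact when noise SD is 0."""
    mean = rt_mean(ecc_deg, model)
    if model.deterministic or model.rt_noise_sd == 0.0:
        return float(mean)
    return float(mean * math.exp(rng.normal(0.0, model.rt_noise_sd)))


# ---------------------------------------------------------------------------
# Cohort generation.

@dataclass(frozen=True)
class CohortConfig:
    """Population and protocol settings for the synthetic cohort.

    Defaults are the emulated study conditions: 50 participants with search
    data, the first 30 of whom also have reportable faces data; two runs of
    each test; 50 staircase trials (analyses typically use the first 20) and
    all 62 search locations (analyses typically use the 22-location subset).
    Cross-test ability correlation defaults to the weak association observed
    in normal cohorts (rho ~ 0.18); covariate-performance correlations
    default to 0 (null associations).  Usability ratings are integer 0-10
    with distributions whose means match the reported 9.6 (faces) and 9.7
    (search).
    """

    n_participants: int = 50
    n_faces_reported: int = 30
    n_face_trials: int = 50
    quest: QuestConfig = field(default_factory=QuestConfig)
    search_subset: str | Sequence[int] = "all"
    faces_pop_mean: float = FACES_POP_MEAN
    faces_between_sd: float = FACES_BETWEEN_SD
    face_run_jitter_sd: float = FACES_RUN_JITTER_SD
    rt_coeffs: tuple[float, float, float] = DEFAULT_RT_COEFFS
    rt_scale_shape: float = SEARCH_SCALE_SHAPE
    rt_noise_sd: float = SEARCH_RT_NOISE_SD
    rt_run_jitter_sd: float = SEARCH_RUN_JITTER_SD
    cross_test_rho: float = 0.18
    acuity_mean: float = -0.05    # logMAR; inclusion required <= 0.2
    acuity_sd: float = 0.08
    contrast_mean: float = 1.85   # logCS; inclusion required >= 1.5
    contrast_sd: float = 0.10
    digit_span_mean: float = 19.0
    digit_span_sd: float = 4.0
    acuity_search_rho: float = 0.0
    contrast_search_rho: float = 0.0
    digit_span_faces_rho: float = 0.0
    usability_faces_probs: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.05, 9: 0.30, 10: 0.65}
    )
    usability_search_probs: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.05, 9: 0.20, 10: 0.75}
    )
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("a cohort needs at least 2 participants")
        if not 0 <= self.n_faces_reported <= self.n_participants:
            raise ValueError("n_faces_reported must be within the cohort size")
        for probs in (self.usability_faces_probs, self.usability_search_probs):
            if abs(sum(probs.values()) - 1.0) > 1e-9 or not all(
                0 <= k <= 10 for k in probs
            ):
                raise ValueError("usability probabilities must sum to 1 over ratings 0..10")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    observer: ObserverModel
    faces_reported: bool
    face_runs: tuple[FaceSessionResult, ...]
    search_runs: tuple[SearchSessionResult, ...]
    covariates: Mapping[str, float]


@dataclass(frozen=True)
class Cohort:
    """A synthetic participant cohort with paired two-run session data."""

    participants: tuple[Participant, ...]
    config: CohortConfig
    grid: SearchGrid
    seed: int | None

    # -- analysis-facing views ------------------------------------------------
    def faces_pairs(self, n_trials: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Run-1 and run-2 threshold estimates (after the first ``n_trials``
        staircase trials; default: the full run) for faces-reported
        participants, paired by participant."""
        idx = -1 if n_trials is None else n_trials - 1
        r1, r2 = [], []
        for p in self.participants:
            if p.faces_reported:
                r1.append(p.face_runs[0].threshold_by_trial[idx])
                r2.append(p.face_runs[1].threshold_by_trial[idx])
        return np.array(r1), np.array(r2)

    def faces_trialwise(self, run: int) -> np.ndarray:
        """(participants x trials) matrix of running threshold estimates for
        one run (1 or 2), faces-reported participants only."""
        return np.array(
            [p.face_runs[run - 1].threshold_by_trial
             for p in self.participants if p.faces_reported]
        )

    def search_pairs(self, subset: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Run-1 and run-2 median RTs, optionally restricted to a location
        subset, paired by participant."""
        out = ([], [])
        for p in self.participants:
            for run, acc in zip(p.search_runs, out):
                if subset is None:
                    acc.append(run.median_rt)
                else:
                    acc.append(float(np.median([run.per_location_rt[loc] for loc in subset])))
        return np.array(out[0]), np.array(out[1])

    def search_location_rts(self, run: int) -> dict[int, np.ndarray]:
        """Per-location RT vectors across the cohort for one run."""
        locs = sorted(self.participants[0].search_runs[run - 1].per_location_rt)
        return {
            loc: np.array([p.search_runs[run - 1].per_location_rt[loc]
                           for p in self.participants])
            for loc in locs
        }

    def covariate(self, name: str, faces_only: bool = False) -> np.ndarray:
        return np.array(
            [p.covariates[name] for p in self.participants
             if p.faces_reported or not faces_only]
        )


def _correlated(z: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    return rho * z + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(len(z))


def generate_cohort(
    n: int | None = None,
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> Cohort:
    """Draw a synthetic cohort and run both engines twice per participant.

    Observer abilities come from the calibrated population model (Gaussian
    face thresholds; Gamma-distributed search speed multipliers coupled to
    the face latent through a Gaussian copula).  Every random stream derives
    from ``seed`` through named spawns, so the same seed reproduces the
    cohort byte for byte.
    """
    config = config or CohortConfig()
    if n is not None and n != config.n_participants:
        config = replace(config, n_participants=n,
                         n_faces_reported=min(config.n_faces_reported, n))
    nP = config.n_participants
    ss = np.random.SeedSequence(seed)
    pop_ss, *part_ss = ss.spawn(1 + nP)
    pop_rng = np.random.default_rng(pop_ss)

    z_face = pop_rng.standard_normal(nP)
    z_search = _correlated(z_face, config.cross_test_rho, pop_rng)
    thresholds = config.faces_pop_mean + config.faces_between_sd * z_face
    k = config.rt_scale_shape
    scales = stats.gamma.ppf(stats.norm.cdf(z_search), k, scale=1.0 / k)
    scales = np.clip(scales, 1e-3, None)

    acuity = config.acuity_mean + config.acuity_sd * _correlated(
        z_search, config.acuity_search_rho, pop_rng
    )
    contrast = config.contrast_mean + config.contrast_sd * _correlated(
        -z_search, config.contrast_search_rho, pop_rng
    )
    digit = config.digit_span_mean + config.digit_span_sd * _correlated(
        -z_face, config.digit_span_faces_rho, pop_rng
    )
    acuity = np.clip(acuity, -0.3, 0.2)          # inclusion: acuity <= 0.2 logMAR
    contrast = np.clip(contrast, 1.5, 2.25)      # inclusion: CS >= 1.5 logCS
    digit = np.clip(np.round(digit), 5, 30)

    def _rating(probs: Mapping[int, float], rng: np.random.Generator) -> int:
        vals = sorted(probs)
        return int(rng.choice(vals, p=[probs[v] for v in vals]))

    a, b, c = config.rt_coeffs
    grid = SearchGrid()
    participants = []
    for i in range(nP):
        p_rng = np.random.default_rng(part_ss[i])
        observer = ObserverModel(
            face_true_threshold=float(max(thresholds[i], 0.6)),
            face_params=config.quest.params,
            rt_a=a, rt_b=b, rt_c=c,
            rt_scale=float(scales[i]),
            rt_noise_sd=config.rt_noise_sd,
            face_run_jitter_sd=config.face_run_jitter_sd,
            rt_run_jitter_sd=config.rt_run_jitter_sd,
            deterministic=config.deterministic,
        )
        faces_reported = i < config.n_faces_reported
        face_runs, search_runs = [], []
        for _run in (1, 2):
            run_obs = observer if config.deterministic else observer.with_run_jitter(p_rng)
            if faces_reported:
                face_runs.append(
                    run_face_session(run_obs, config.n_face_trials,
                                     config=config.quest, rng=p_rng)
                )
            search_runs.append(
                run_search_session(run_obs, grid, config.search_subset, rng=p_rng)
            )
        covs = {
            "acuity_logmar": float(acuity[i]),
            "contrast_logcs": float(contrast[i]),
            "digit_span": float(digit[i]),
            "usability_faces": float(_rating(config.usability_faces_probs, p_rng)),
            "usability_search": float(_rating(config.usability_search_probs, p_rng)),
        }
        participants.append(
            Participant(
                participant_id=f"P{i + 1:03d}",
                observer=observer,
                faces_reported=faces_reported,
                face_runs=tuple(face_runs),
                search_runs=tuple(search_runs),
                covariates=covs,
            )
        )
    return Cohort(participants=tuple(participants), config=config, grid=grid, seed=seed)
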