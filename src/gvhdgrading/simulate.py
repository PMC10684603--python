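"""Seeded synthetic aGVHD cohorts with the dependence and outcome structure
the grading analyses assume.

Organ stages are drawn by thresholding a latent Gaussian copula so that the
per-organ stage marginals and the pairwise Spearman rank correlations hit
their targets (liver-GI mildly positive, skin-GI mildly negative by
default).  Event times come from competing exponential hazards whose log
hazard is linear in a canonical severity index (fixed reference loadings
that parameterize simulation truth only, never the fitted model), with
administrative censoring plus random dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gvhdgrading.cohort import (
    CohortTable,
    EVENT_CENSORED,
    EVENT_NRM,
    EVENT_RELAPSE,
    ORGANS,
    ORIGIN_HCT,
    enumerate_phenotypes,
)

#: reference loadings of the simulation-truth severity index, normalized
#: from a (skin, liver, GI) weighting of roughly 8/27/96 percent
REFERENCE_LOADINGS = np.array([0.08, 0.27, 0.96])
REFERENCE_LOADINGS = REFERENCE_LOADINGS / np.linalg.norm(REFERENCE_LOADINGS)

DEFAULT_MARGINALS: dict[str, tuple[float, ...]] = {
    # skin involvement common but mostly mild; liver mostly absent; GI
    # spans the full stage range and carries most of the variance, so the
    # leading principal component is GI-dominated
    "skin": (0.32, 0.38, 0.22, 0.06, 0.02),
    "liver": (0.62, 0.16, 0.11, 0.07, 0.04),
    "gi": (0.22, 0.20, 0.18, 0.18, 0.22),
}

DEFAULT_SPEARMAN = {("skin", "liver"): 0.0, ("skin", "gi"): -0.10, ("liver", "gi"): 0.20}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort generator.

    Hazards are per-day exponential rates; ``outcome_link`` entries are log
    hazard-ratio slopes per unit of the canonical severity index (range
    roughly 0..5.2 over the phenotype space).  ``censoring_horizon`` is the
    administrative cutoff in days and ``dropout_rate`` a per-day random
    dropout hazard.  ``agvhd_only`` resamples away (0,0,0) draws, matching
    cohorts of diagnosed aGVHD patients; ``include_full_repertoire``
    deterministically seats one patient on each of the 124 aGVHD phenotypes
    before random filling (a coverage device for exhaustive calibration and
    repertoire analyses).
    """

    n: int = 2319
    seed: int = 0
    stage_marginals: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    spearman_targets: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SPEARMAN)
    )
    baseline_hazard_nrm: float = 7e-5
    baseline_hazard_relapse: float = 3e-4
    outcome_link_nrm: float = 0.6
    outcome_link_relapse: float = 0.0
    relapse_death_prob: float = 0.5
    censoring_horizon: float = 1825.0
    dropout_rate: float = 1e-4
    agvhd_only: bool = True
    include_full_repertoire: bool = False
    origin: str = ORIGIN_HCT

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for organ in ORGANS:
            p = np.asarray(self.stage_marginals[organ], dtype=float)
            if p.shape != (5,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"marginals for {organ} must be 5 probabilities summing to 1")
        if self.baseline_hazard_nrm <= 0 or self.baseline_hazard_relapse <= 0:
            raise ValueError("baseline hazards must be > 0")
        if not 0 <= self.relapse_death_prob <= 1:
            raise ValueError("relapse_death_prob must be in [0, 1]")


def severity_of(stages: np.ndarray) -> np.ndarray:
    """Canonical simulation-truth severity index of (n, 3) stage rows."""
    return np.asarray(stages, dtype=float) @ REFERENCE_LOADINGS


# ---------------------------------------------------------------------------
# Copula calibration


def _thresholds(marginal: np.ndarray) -> np.ndarray:
    """Latent-normal cut points of a 5-category marginal (len 6, +-inf ends)."""
    cum = np.concatenate([[0.0], np.cumsum(marginal)])
    cum[-1] = 1.0
    return stats.norm.ppf(np.clip(cum, 0.0, 1.0))


def _pair_spearman_given_latent(
    rho: float, thr_a: np.ndarray, thr_b: np.ndarray, pa: np.ndarray, pb: np.ndarray
) -> float:
    """Population Spearman (midranks) of two thresholded ordinals whose
    latent normals have Pearson correlation rho."""
    if abs(rho) < 1e-12:
        return 0.0
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)
    grid = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            a, b = thr_a[i], thr_b[j]
            if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                grid[i, j] = 0.0
            elif np.isinf(a) and np.isinf(b):
                grid[i, j] = 1.0
            elif np.isinf(a):
                grid[i, j] = stats.norm.cdf(b)
            elif np.isinf(b):
                grid[i, j] = stats.norm.cdf(a)
            else:
                grid[i, j] = mvn.cdf([a, b])
    pmf = np.diff(np.diff(grid, axis=0), axis=1)
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    # midrank transforms on the [0, 1] scale
    ua = np.concatenate([[0.0], np.cumsum(pa)])[:-1] + pa / 2
    ub = np.concatenate([[0.0], np.cumsum(pb)])[:-1] + pb / 2
    mean_a = float(pa @ ua)
    mean_b = float(pb @ ub)
    var_a = float(pa @ (ua - mean_a) ** 2)
    var_b = float(pb @ (ub - mean_b) ** 2)
    cov_ab = float((pmf * np.outer(ua - mean_a, ub - mean_b)).sum())
    return cov_ab / np.sqrt(var_a * var_b)


def calibrate_latent_corr(
    marginal_a, marginal_b, target_spearman: float
) -> float:
    """Latent Pearson correlation achieving a target Spearman between two
    thresholded ordinals, by monotone bisection.  Raises with the nearest
    feasible value when the target is unreachable."""
    pa = np.asarray(marginal_a, dtype=float)
    pb = np.asarray(marginal_b, dtype=float)
    thr_a, thr_b = _thresholds(pa), _thresholds(pb)
    if abs(target_spearman) < 1e-12:
        return 0.0

    def f(rho: float) -> float:
        return _pair_spearman_given_latent(rho, thr_a, thr_b, pa, pb) - target_spearman

    lo, hi = -0.995, 0.995
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        nearest = target_spearman - (flo if abs(flo) < abs(fhi) else fhi)
        raise ValueError(
            f"target Spearman {target_spearman:+.3f} infeasible for these "
            f"marginals; nearest feasible is about {nearest:+.3f}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-4))


def _latent_correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    R = np.eye(3)
    idx = {o: i for i, o in enumerate(ORGANS)}
    for (a, b), target in config.spearman_targets.items():
        rho = calibrate_latent_corr(
            config.stage_marginals[a], config.stage_marginals[b], target
        )
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() <= 1e-10:
        raise ValueError(
            "calibrated latent correlation matrix is not positive definite; "
            "weaken the Spearman targets (nearest feasible: shrink all "
            f"off-diagonals by a factor {0.99 * 1 / (1 - eigvals.min()):.2f})"
        )
    return R


def _draw_stages(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    R = _latent_correlation_matrix(config)
    L = np.linalg.cholesky(R)
    thresholds = [
        _thresholds(np.asarray(config.stage_marginals[o], dtype=float))
        for o in ORGANS
    ]

    def draw(m: int) -> np.ndarray:
        Z = rng.standard_normal((m, 3)) @ L.T
        S = np.empty((m, 3), dtype=int)
        for j in range(3):
            S[:, j] = np.searchsorted(thresholds[j][1:-1], Z[:, j], side="right")
        return S

    stages = draw(n)
    if config.agvhd_only:
        for _ in range(1000):
            zero = (stages == 0).all(axis=1)
            if not zero.any():
                break
            stages[zero] = draw(int(zero.sum()))
        else:
            raise RuntimeError("could not resample away (0,0,0) draws")
    return stages


def _draw_outcomes(
    rng: np.random.Generator, stages: np.ndarray, config: GeneratorConfig
) -> pd.DataFrame:
    n = len(stages)
    s = severity_of(stages)
    h_nrm = config.baseline_hazard_nrm * np.exp(config.outcome_link_nrm * s)
    h_rel = config.baseline_hazard_relapse * np.exp(config.outcome_link_relapse * s)
    t_nrm = rng.exponential(1.0 / h_nrm)
    t_rel = rng.exponential(1.0 / h_rel)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.censoring_horizon)
    time = np.minimum.reduce([t_nrm, t_rel, t_cens])
    event = np.where(
        time == t_nrm, EVENT_NRM, np.where(time == t_rel, EVENT_RELAPSE, EVENT_CENSORED)
    )
    os_event = (event == EVENT_NRM).astype(int)
    relapsed = event == EVENT_RELAPSE
    # post-relapse deaths recorded at the relapse time (single-time schema)
    os_event[relapsed] = (
        rng.random(int(relapsed.sum())) < config.relapse_death_prob
    ).astype(int)
    return pd.DataFrame({"time_days": time, "event": event, "os_event": os_event})


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a fully reproducible synthetic cohort under ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = _draw_stages(rng, config.n, config)
    if config.include_full_repertoire:
        repertoire = np.array(
            [ph.stages.as_tuple() for ph in enumerate_phenotypes(include_zero=False)]
        )
        m = min(len(repertoire), config.n)
        stages[:m] = repertoire[:m]
    outcomes = _draw_outcomes(rng, stages, config)
    df = pd.DataFrame(stages, columns=list(ORGANS))
    df.insert(0, "id", [f"p{i:06d}" for i in range(config.n)])
    df = pd.concat([df, outcomes], axis=1)
    return CohortTable(df, origin=config.origin)


def generate_reference_cohort(
    n: int = 735,
    seed: int = 0,
    baseline_hazard_nrm: float = 7e-5,
    baseline_hazard_relapse: float = 3e-4,
) -> CohortTable:
    """A no-aGVHD reference cohort: all stages (0,0,0), outcomes drawn from
    the baseline hazards only."""
    config = GeneratorConfig(
        n=n,
        seed=seed,
        baseline_hazard_nrm=baseline_hazard_nrm,
        baseline_hazard_relapse=baseline_hazard_relapse,
        agvhd_only=False,
    )
    rng = np.random.default_rng(seed)
    stages = np.zeros((n, 3), dtype=int)
    outcomes = _draw_outcomes(rng, stages, config)
    df = pd.DataFrame(stages, columns=list(ORGANS))
    df.insert(0, "id", [f"r{i:06d}" for i in range(n)])
    df = pd.concat([df, outcomes], axis=1)
    return CohortTable(df, origin=config.origin)
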