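"""PCA-derived aGVHD severity index, discrete staging and grade consolidation.

The severity index of a patient with organ-stage vector ``p`` is the affine
projection onto the first principal component of the training cohort's
(skin, liver, GI) stages:

    s' = (p - p0) . c1 + s0

with ``p0`` the training mean, ``c1`` the unit-norm PC1 loadings
(sign-normalized so that higher index means more severe disease) and ``s0``
an arbitrary offset (0 here).  The continuous index is discretized into 12
(or 6) integer severity stages by an affine map calibrated on the 124
aGVHD phenotypes so that the least severe phenotype maps to stage 1 and
(4,4,4) to the maximum stage; stages 1-12 consolidate into four grades
(1-3 -> I, 4-6 -> II, 7-9 -> III, 10-12 -> IV).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from gvhdgrading.cohort import (
    CohortTable,
    ORGANS,
    OrganStages,
    enumerate_phenotypes,
)
from gvhdgrading.conventional import GradeAssignment


@dataclass(frozen=True)
class PC1Model:
    """Fitted PC1 severity model.

    center/loadings/eigenvalues are in organ order (skin, liver, gi);
    ``index_min``/``index_max`` span the severity index over the 124 aGVHD
    phenotypes and calibrate the discrete staging, making staging
    cohort-independent once the loadings are fixed.
    """

    center: tuple[float, float, float]
    loadings: tuple[float, float, float]
    eigenvalues: tuple[float, float, float]
    explained_variance: tuple[float, float, float]
    index_offset: float
    index_min: float
    index_max: float
    n_stages: int = 12

    def __post_init__(self) -> None:
        lo = np.asarray(self.loadings)
        if abs(np.linalg.norm(lo) - 1.0) > 1e-8:
            raise ValueError("loadings must have unit Euclidean norm")
        if np.any(lo < -1e-12):
            raise ValueError("loadings must be nonnegative after sign normalization")
        ev = np.asarray(self.eigenvalues)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")
        fr = np.asarray(self.explained_variance)
        if abs(fr.sum() - 1.0) > 1e-9 or np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("explained_variance must be fractions summing to 1")
        if not self.index_min < self.index_max:
            raise ValueError("index_min must be < index_max")
        if self.n_stages not in (6, 12):
            raise ValueError("n_stages must be 6 or 12")

    def loading_percentages(self) -> dict[str, dict[str, float]]:
        """Organ weights under both conventions: share of absolute loading
        and share of squared loading (percent)."""
        lo = np.abs(np.asarray(self.loadings))
        return {
            "abs": dict(zip(ORGANS, 100 * lo / lo.sum())),
            "squared": dict(zip(ORGANS, 100 * lo**2 / (lo**2).sum())),
        }

    # -- persistence ----------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PC1Model":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        for key in ("center", "loadings", "eigenvalues", "explained_variance"):
            raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)


def fit_pc1(
    cohort: CohortTable, n_stages: int = 12, loading_tolerance: float = 0.25
) -> PC1Model:
    """Fit the PC1 severity model on a training cohort.

    PCA is performed on the mean-centered raw stage triples (no per-organ
    standardization: the three organs share the 0-4 ordinal scale).  The
    eigenvector sign is normalized so its largest component is positive;
    a weakly negative residual loading (|v| <= loading_tolerance, at most a
    few percent of variance weight, typically skin when skin and GI
    involvement are negatively associated) is clamped to zero with a
    warning so that a higher index always means more severe disease.  A
    negative loading beyond the tolerance means the leading component is a
    contrast, not a severity axis, and is rejected with a diagnostic.
    """
    X = cohort.stage_matrix
    if len(X) < 3:
        raise ValueError("need at least 3 patients to fit the PC1 model")
    constant = [ORGANS[j] for j in range(3) if np.ptp(X[:, j]) == 0]
    if constant:
        raise ValueError(
            f"stage covariance is rank-deficient: constant organ(s) {constant}"
        )
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    loadings = eigenvectors[:, order[0]]
    # sign convention: GI (largest-magnitude component on realistic data)
    # positive; then all loadings must be nonnegative
    pivot = int(np.argmax(np.abs(loadings)))
    if loadings[pivot] < 0:
        loadings = -loadings
    negative = loadings < -1e-10
    if np.any(loadings < -loading_tolerance):
        bad = [ORGANS[j] for j in range(3) if loadings[j] < -loading_tolerance]
        raise ValueError(
            "PC1 is a contrast, not a severity axis: loading(s) for "
            f"{bad} are negative beyond tolerance {loading_tolerance} "
            f"(loadings={np.round(loadings, 4)})"
        )
    if np.any(negative):
        clamped = [ORGANS[j] for j in range(3) if negative[j]]
        warnings.warn(
            f"small negative PC1 loading(s) for {clamped} clamped to zero "
            "to keep the severity index monotone in every organ",
            stacklevel=2,
        )
    loadings = np.clip(loadings, 0.0, None)
    loadings = loadings / np.linalg.norm(loadings)
    explained = eigenvalues / eigenvalues.sum()
    model = PC1Model(
        center=tuple(map(float, center)),
        loadings=tuple(map(float, loadings)),
        eigenvalues=tuple(map(float, eigenvalues)),
        explained_variance=tuple(map(float, explained)),
        index_offset=0.0,
        index_min=0.0,
        index_max=1.0,
        n_stages=n_stages,
    )
    lo, hi = _calibrate(model)
    return dataclasses.replace(model, index_min=lo, index_max=hi)


def _calibrate(model: PC1Model) -> tuple[float, float]:
    """Severity-index range over the 124 aGVHD phenotypes."""
    values = [
        severity_index(model, ph.stages)
        for ph in enumerate_phenotypes(include_zero=False)
    ]
    return float(min(values)), float(max(values))


def severity_index(model: PC1Model, stages: OrganStages) -> float:
    """Continuous severity index s' = (p - p0) . c1 + s0 (affine in stages)."""
    p = stages.as_array()
    return float(
        (p - np.asarray(model.center)) @ np.asarray(model.loadings)
        + model.index_offset
    )


def _round_half_away(x: float) -> int:
    """round() with ties away from zero, not banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pc1_stage(
    model: PC1Model, stages: OrganStages, n_stages: int | None = None
) -> int:
    """Discrete PC1 severity stage in 1..n_stages; 0 for (0,0,0).

    The affine discretization ``stage = round(k (s' - min)) + 1`` with
    ``k = (n_stages - 1) / (max - min)`` pins the least severe aGVHD
    phenotype to stage 1 and (4,4,4) to n_stages for any fitted loadings;
    it reduces to the doubling map when the index span is (n_stages-1)/2.
    Rounding is half-away-from-zero.
    """
    if stages.is_zero:
        return 0
    n = model.n_stages if n_stages is None else n_stages
    k = (n - 1) / (model.index_max - model.index_min)
    s = severity_index(model, stages)
    stage = _round_half_away(k * (s - model.index_min)) + 1
    return int(min(max(stage, 1), n))


def consolidate_grade(stage: int) -> int:
    """Consolidate a 12-level PC1 stage into four grades: 1-3 -> I,
    4-6 -> II, 7-9 -> III, 10-12 -> IV; stage 0 passes through as grade 0."""
    if not isinstance(stage, (int, np.integer)) or not 0 <= stage <= 12:
        raise ValueError(f"stage must be an integer in 0..12, got {stage!r}")
    if stage == 0:
        return 0
    return math.ceil(stage / 3)


def pc1_six_grade(model: PC1Model, stages: OrganStages) -> int:
    """Six-grade PC1 variant (coarser discretization of the same index);
    0 for (0,0,0)."""
    return pc1_stage(model, stages, n_stages=6)


def grade_cohort_pc1(
    cohort: CohortTable, model: PC1Model, granularity: str = "grade4"
) -> list[GradeAssignment]:
    """Grade a cohort with a fitted PC1 model.

    granularity: ``grade4`` (stages consolidated to I-IV, the default),
    ``stage12`` (all 12 stages as grades) or ``grade6``.
    """
    out = []
    for s, l, g in cohort.df[["skin", "liver", "gi"]].itertuples(index=False):
        st = OrganStages(int(s), int(l), int(g))
        stage12 = pc1_stage(model, st, n_stages=12)
        if granularity == "grade4":
            out.append(GradeAssignment("pc1", consolidate_grade(stage12), stage12))
        elif granularity == "stage12":
            out.append(GradeAssignment("pc1", stage12, stage12))
        elif granularity == "grade6":
            out.append(GradeAssignment("pc1", pc1_six_grade(model, st), stage12))
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
    return out


def bootstrap_validate(
    cohort: CohortTable,
    n_resamples: int = 500,
    fraction: float = 2 / 3,
    seed: int = 0,
):
    """Internal PCA validation by repeated subsampling.

    Each resample draws ``round(fraction * n)`` patients without
    replacement and refits the PCA; the per-eigenvalue mean, min and max
    across resamples summarize stability.  Degenerate resamples (a constant
    organ) are redrawn and counted.
    """
    import pandas as pd

    if n_resamples < 1 or not 0 < fraction <= 1:
        raise ValueError("need n_resamples >= 1 and 0 < fraction <= 1")
    rng = np.random.default_rng(seed)
    X = cohort.stage_matrix
    m = int(round(fraction * len(X)))
    records = np.empty((n_resamples, 3))
    redraws = 0
    for b in range(n_resamples):
        while True:
            idx = rng.choice(len(X), size=m, replace=False)
            sub = X[idx]
            if np.all(np.ptp(sub, axis=0) > 0):
                break
            redraws += 1
        ev = np.linalg.eigvalsh(np.cov(sub, rowvar=False, ddof=1))[::-1]
        records[b] = ev
    if redraws:
        warnings.warn(f"{redraws} degenerate resample(s) redrawn", stacklevel=2)
    return pd.DataFrame(
        {
            "eigenvalue": [1, 2, 3],
            "mean": records.mean(axis=0),
            "min": records.min(axis=0),
            "max": records.max(axis=0),
        }
    )
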