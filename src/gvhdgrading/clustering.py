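"""Cluster-based aGVHD grading: hierarchical Ward clustering and K-means.

Patients' (skin, liver, GI) stage triples are clustered on the raw integer
coordinates (duplicated phenotypes carry their patient mass), the tree or
partition is cut at k clusters, and clusters are ordered by outcome
(12-month Kaplan-Meier overall survival, best outcome = grade I).  Unseen
phenotypes at test time are either mapped to the nearest cluster or
omitted, mirroring how a grading trained on one cohort is applied to an
independent one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from gvhdgrading.cohort import CohortTable, OrganStages, phenotype_label
from gvhdgrading.conventional import GradeAssignment

logger = logging.getLogger(__name__)

POLICY_NEAREST = "nearest"
POLICY_OMIT = "omit"


@dataclass(frozen=True)
class ClusterGradingModel:
    """A fitted cluster grading.

    ``assignment`` maps every training phenotype label to a cluster id
    (0..k-1); ``severity_order`` maps cluster id to ordinal grade
    (1 = best outcome); ``centroids`` and ``sizes`` describe the clusters
    in stage space and drive unseen-phenotype assignment.
    """

    method: str
    k: int
    assignment: dict[str, int]
    centroids: tuple[tuple[float, float, float], ...]
    sizes: tuple[int, ...]
    severity_order: dict[int, int] = field(default_factory=dict)
    training_os_summary: dict[int, float] = field(default_factory=dict)
    seed: Optional[int] = None
    inertia: Optional[float] = None

    def grade_of_cluster(self, cluster: int) -> int:
        if not self.severity_order:
            raise ValueError("model has no severity order; call rank_clusters first")
        return self.severity_order[cluster]

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["severity_order"] = {str(k): v for k, v in self.severity_order.items()}
        raw["training_os_summary"] = {
            str(k): v for k, v in self.training_os_summary.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(raw, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClusterGradingModel":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["assignment"] = {k: int(v) for k, v in raw["assignment"].items()}
        raw["centroids"] = tuple(tuple(map(float, c)) for c in raw["centroids"])
        raw["sizes"] = tuple(int(s) for s in raw["sizes"])
        raw["severity_order"] = {int(k): int(v) for k, v in raw["severity_order"].items()}
        raw["training_os_summary"] = {
            int(k): float(v) for k, v in raw["training_os_summary"].items()
        }
        return cls(**raw)


def _model_from_labels(
    cohort: CohortTable,
    labels: np.ndarray,
    method: str,
    k: int,
    seed: Optional[int],
    inertia: Optional[float],
) -> ClusterGradingModel:
    X = cohort.stage_matrix
    # relabel clusters to 0..k-1 in first-appearance order
    uniq = list(dict.fromkeys(labels.tolist()))
    remap = {c: i for i, c in enumerate(uniq)}
    labels = np.asarray([remap[c] for c in labels])
    assignment: dict[str, int] = {}
    for lab, cl in zip(cohort.phenotype_labels(), labels):
        if lab in assignment and assignment[lab] != cl:
            # identical points always co-cluster under Ward/K-means; guard
            # against pathological label mixing
            raise RuntimeError(f"phenotype {lab} split across clusters")
        assignment[lab] = int(cl)
    centroids = tuple(
        tuple(map(float, X[labels == c].mean(axis=0))) for c in range(k)
    )
    sizes = tuple(int((labels == c).sum()) for c in range(k))
    return ClusterGradingModel(
        method=method,
        k=k,
        assignment=assignment,
        centroids=centroids,
        sizes=sizes,
        seed=seed,
        inertia=inertia,
    )


def hclust_fit(
    cohort: CohortTable,
    k: int = 4,
    distance_threshold: Optional[float] = None,
    horizon: float = 365.0,
) -> ClusterGradingModel:
    """Agglomerative Ward (minimum increase of sum of squares) clustering.

    Patients (not unique phenotypes) are clustered, so phenotype mass
    shapes the merge order.  The tree is cut to exactly ``k`` clusters, or
    at ``distance_threshold`` if given.  Clusters are then severity-ordered
    by 12-month overall survival.
    """
    n_distinct = cohort.phenotype_labels().nunique()
    if k < 2 or k > n_distinct:
        raise ValueError(
            f"k must be in 2..{n_distinct} (number of distinct phenotypes)"
        )
    Z = linkage(cohort.stage_matrix, method="ward")
    if distance_threshold is not None:
        labels = fcluster(Z, t=distance_threshold, criterion="distance")
        k = int(labels.max())
    else:
        labels = fcluster(Z, t=k, criterion="maxclust")
    model = _model_from_labels(cohort, labels, "hclust", k, None, None)
    return rank_clusters(model, cohort, horizon=horizon)


def kmeans_fit(
    cohort: CohortTable,
    k: int = 4,
    seed: int = 0,
    n_init: int = 50,
    horizon: float = 365.0,
) -> ClusterGradingModel:
    """K-means clustering of patients' stage triples, best of ``n_init``
    k-means++ runs by the sum of squared distances; deterministic given
    ``seed``.  Clusters are severity-ordered by 12-month overall survival.
    """
    n_distinct = cohort.phenotype_labels().nunique()
    if k < 2 or k > n_distinct:
        raise ValueError(
            f"k must be in 2..{n_distinct} (number of distinct phenotypes)"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(cohort.stage_matrix)
    model = _model_from_labels(
        cohort, labels, "kmeans", k, seed, float(km.inertia_)
    )
    return rank_clusters(model, cohort, horizon=horizon)


def select_k(
    cohort: CohortTable,
    k_range: range | tuple[int, int] = (2, 14),
    seed: int = 0,
    n_init: int = 10,
):
    """K-means model-selection diagnostics over a range of k.

    Returns a DataFrame of (k, ssd, silhouette) plus the recommended k
    (silhouette argmax) and the SSD-elbow k (maximum second difference).
    """
    import pandas as pd

    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    n_distinct = cohort.phenotype_labels().nunique()
    ks = [k for k in k_range]
    if not ks or ks[0] < 2 or ks[-1] > n_distinct - 1:
        raise ValueError(f"k_range must lie within [2, {n_distinct - 1}]")
    X = cohort.stage_matrix
    rows = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        sil = silhouette_score(X, km.labels_)
        rows.append({"k": k, "ssd": float(km.inertia_), "silhouette": float(sil)})
    table = pd.DataFrame(rows)
    recommended = int(table.loc[table["silhouette"].idxmax(), "k"])
    elbow = None
    if len(table) >= 3:
        second_diff = np.diff(table["ssd"].to_numpy(), 2)
        elbow = int(table["k"].iloc[int(np.argmax(second_diff)) + 1])
    return table, recommended, elbow


def rank_clusters(
    model: ClusterGradingModel, cohort: CohortTable, horizon: float = 365.0
) -> ClusterGradingModel:
    """Order clusters by outcome: descending Kaplan-Meier overall survival
    at ``horizon`` days (rank 1 / grade I = best outcome); ties broken by
    ascending mean stage sum of member patients."""
    from lifelines import KaplanMeierFitter

    labels = cohort.phenotype_labels().map(model.assignment)
    if labels.isna().any():
        raise ValueError("cohort contains phenotypes outside the model assignment")
    clusters = labels.to_numpy(dtype=int)
    times, events = cohort.times, cohort.os_events
    stage_sum = cohort.stage_matrix.sum(axis=1)
    os_summary: dict[int, float] = {}
    keys = []
    for c in range(model.k):
        mask = clusters == c
        if mask.sum() == 0:
            logger.warning("cluster %d empty in ranking cohort; ranked last", c)
            os_summary[c] = 0.0
            keys.append((0.0, np.inf, c))
            continue
        kmf = KaplanMeierFitter().fit(times[mask], events[mask])
        if (times[mask] >= horizon).sum() == 0 and events[mask].sum() == 0:
            # no information at the horizon: fall back to mean observed time
            logger.warning(
                "cluster %d has no at-risk patients at %.0f days; "
                "falling back to mean follow-up time", c, horizon,
            )
            est = float(times[mask].mean())
        else:
            est = float(kmf.predict(horizon))
        os_summary[c] = est
        keys.append((-est, float(stage_sum[mask].mean()), c))
    order = sorted(keys)
    severity_order = {c: rank + 1 for rank, (_, _, c) in enumerate(order)}
    return dataclasses.replace(
        model, severity_order=severity_order, training_os_summary=os_summary
    )


def assign_phenotype(
    model: ClusterGradingModel,
    stages: OrganStages,
    policy: str = POLICY_NEAREST,
) -> Optional[GradeAssignment]:
    """Grade one phenotype under a fitted cluster grading.

    Phenotypes seen in training keep their training cluster.  Unseen
    phenotypes go to the nearest centroid (K-means) or the cluster whose
    Ward objective increases least (hclust) under ``policy='nearest'``, or
    are omitted (returns None) under ``policy='omit'``; ties break toward
    the lower (less severe) grade.  (0,0,0) is always grade 0.
    """
    if policy not in (POLICY_NEAREST, POLICY_OMIT):
        raise ValueError(f"unknown policy {policy!r}")
    if stages.is_zero:
        return GradeAssignment(model.method, 0)
    label = phenotype_label(*stages.as_tuple())
    if label in model.assignment:
        cluster = model.assignment[label]
        return GradeAssignment(model.method, model.grade_of_cluster(cluster))
    if policy == POLICY_OMIT:
        return None
    x = stages.as_array()
    costs = []
    for c in range(model.k):
        d2 = float(np.sum((x - np.asarray(model.centroids[c])) ** 2))
        if model.method == "hclust":
            # minimum increase of the Ward sum-of-squares objective
            n_c = model.sizes[c]
            d2 = n_c / (n_c + 1) * d2
        costs.append((d2, model.grade_of_cluster(c), c))
    _, grade, _ = min(costs)
    return GradeAssignment(model.method, grade)


def grade_cohort_clusters(
    cohort: CohortTable, model: ClusterGradingModel, policy: str = POLICY_NEAREST
) -> list[Optional[GradeAssignment]]:
    """Grade every patient; entries are None for omitted unseen phenotypes."""
    return [
        assign_phenotype(model, OrganStages(int(s), int(l), int(g)), policy=policy)
        for s, l, g in cohort.df[["skin", "liver", "gi"]].itertuples(index=False)
    ]
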