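"""Inter-grading agreement, phenotype repertoires, redistribution of
conventional grade-III patients and single-organ-stratified outcomes.

Cohen's kappa quantifies chance-corrected agreement between two grading
systems applied to the same patients; repertoire tables describe how many
distinct phenotypes and patients each grade of a system holds; the
redistribution analysis contrasts outcomes of patients a data-driven
system downgrades relative to a conventional grade III.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from gvhdgrading.cohort import CohortTable, ORGANS
from gvhdgrading.survival import (
    cumulative_incidence,
    gray_test,
    kaplan_meier,
    logrank_test,
)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Unweighted Cohen's kappa (p_o - p_e) / (1 - p_e), symmetric in its
    arguments and computed over the union of both category sets.

    Degenerate cases: two identical constant vectors agree fully
    (kappa = 1); two different constant vectors have kappa 0 with a
    warning (chance agreement is total, p_e = 1).
    """
    a = np.asarray(list(labels_a), dtype=object)
    b = np.asarray(list(labels_b), dtype=object)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("label vectors must be nonempty")
    cats = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    if len(cats) == 1:
        return 1.0
    if len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1:
        warnings.warn(
            "both labelings constant but different; kappa reported as 0",
            stacklevel=2,
        )
        return 0.0
    # kappa is invariant under common relabeling; normalize to strings so
    # mixed/object label dtypes are acceptable
    a_str = np.asarray([str(x) for x in a])
    b_str = np.asarray([str(x) for x in b])
    return float(cohen_kappa_score(a_str, b_str, labels=[str(c) for c in cats]))


def kappa_matrix(grade_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cohen's kappa between grading systems.

    ``grade_table`` holds one column of grades per system (NaN where a
    patient is ungradable, e.g. clustering omit policy); each pair is
    computed on its pairwise-complete subset.  Unit diagonal, symmetric.
    """
    systems = list(grade_table.columns)
    out = pd.DataFrame(np.eye(len(systems)), index=systems, columns=systems)
    for i, si in enumerate(systems):
        for j in range(i + 1, len(systems)):
            sj = systems[j]
            mask = grade_table[si].notna() & grade_table[sj].notna()
            if mask.sum() == 0:
                kappa = np.nan
            else:
                kappa = cohen_kappa(
                    grade_table.loc[mask, si].astype(int),
                    grade_table.loc[mask, sj].astype(int),
                )
            out.loc[si, sj] = out.loc[sj, si] = kappa
    return out


@dataclass
class RepertoireTable:
    """Per-grade phenotype repertoire of one grading system.

    ``summary`` has one row per grade (n_phenotypes, n_patients);
    ``detail`` is a long table (grade, phenotype, count, proportion) whose
    within-grade proportions sum to 1.
    """

    system: str
    summary: pd.DataFrame
    detail: pd.DataFrame


def repertoire_table(cohort: CohortTable, grades: Sequence, system: str = "") -> RepertoireTable:
    """Distinct-phenotype counts and per-phenotype patient proportions per
    grade.  Patients with missing grades (ungradable) are excluded."""
    df = pd.DataFrame(
        {"phenotype": cohort.phenotype_labels().to_numpy(), "grade": list(grades)}
    )
    df = df[df["grade"].notna()].copy()
    df["grade"] = df["grade"].astype(int)
    detail = (
        df.groupby(["grade", "phenotype"]).size().rename("count").reset_index()
    )
    detail["proportion"] = detail["count"] / detail.groupby("grade")["count"].transform("sum")
    summary = (
        detail.groupby("grade")
        .agg(n_phenotypes=("phenotype", "nunique"), n_patients=("count", "sum"))
        .reset_index()
    )
    return RepertoireTable(system=system, summary=summary, detail=detail)


def redistribution_analysis(
    cohort: CohortTable,
    grades_a: Sequence,
    grade_a: int,
    grades_b: Sequence,
    threshold_b: int,
    horizon: float = 365.0,
) -> dict:
    """Partition patients at ``grade_a`` of system A into those system B
    downgrades (grade <= threshold_b, the "redistributed" set) and the
    remaining "intersection", then compare their outcomes (Kaplan-Meier +
    log-rank for OS; cumulative incidence + Gray's test for NRM).
    """
    a = np.asarray(list(grades_a), dtype=float)
    b = np.asarray(list(grades_b), dtype=float)
    selected = a == grade_a
    redistributed = selected & (b <= threshold_b)
    intersection = selected & ~redistributed
    out: dict = {
        "n_selected": int(selected.sum()),
        "n_redistributed": int(redistributed.sum()),
        "n_intersection": int(intersection.sum()),
    }
    if redistributed.sum() == 0 or intersection.sum() == 0:
        out["note"] = "one subgroup empty; outcome comparison skipped"
        return out
    sub = cohort.subset(selected)
    labels = np.where(
        redistributed[selected], "redistributed", "intersection"
    )
    km = kaplan_meier(sub, labels)
    out["km"] = km
    out["os_at_horizon"] = {k: curve.at(horizon) for k, curve in km.items()}
    stat, df, p = logrank_test(sub, labels)
    out["logrank"] = {"statistic": stat, "df": df, "p": p}
    cif = cumulative_incidence(sub, "nrm", labels)
    out["cif"] = cif
    out["nrm_at_horizon"] = {k: curve.at(horizon) for k, curve in cif.items()}
    if all((sub.event_codes[labels == lab] == 1).sum() > 0 for lab in ("redistributed", "intersection")):
        gstat, gdf, gp = gray_test(sub, "nrm", labels)
        out["gray"] = {"statistic": gstat, "df": gdf, "p": gp}
    return out


def organ_stratified_outcomes(
    cohort: CohortTable, organ: str, horizon: float = 365.0
) -> dict:
    """Outcome tables stratified by the stage of one organ (0-4),
    irrespective of the other organs: Kaplan-Meier OS with log-rank, and
    NRM cumulative incidence with Gray's test.  Empty strata are omitted
    with a notice."""
    if organ not in ORGANS:
        raise ValueError(f"organ must be one of {ORGANS}")
    stages = cohort.df[organ].to_numpy()
    present = sorted(set(stages.tolist()))
    missing = [s for s in range(5) if s not in present]
    out: dict = {"organ": organ, "strata": present}
    if missing:
        out["note"] = f"empty strata omitted: {missing}"
    out["counts"] = {int(s): int((stages == s).sum()) for s in present}
    out["km"] = kaplan_meier(cohort, stages)
    out["os_at_horizon"] = {k: c.at(horizon) for k, c in out["km"].items()}
    if len(present) >= 2:
        stat, df, p = logrank_test(cohort, stages)
        out["logrank"] = {"statistic": stat, "df": df, "p": p}
    out["cif"] = cumulative_incidence(cohort, "nrm", stages)
    out["nrm_at_horizon"] = {k: c.at(horizon) for k, c in out["cif"].items()}
    if len(present) >= 2 and (cohort.event_codes == 1).sum() > 0:
        gstat, gdf, gp = gray_test(cohort, "nrm", stages)
        out["gray"] = {"statistic": gstat, "df": gdf, "p": gp}
    return out
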