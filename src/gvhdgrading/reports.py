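"""End-to-end comparison report: fit the data-driven gradings on a training
cohort, grade an independent test cohort under every requested system and
tabulate AIC, concordance, time-dependent AUROC, the kappa matrix,
repertoire tables and the grade-III redistribution summary as tidy CSVs
plus a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from gvhdgrading import __version__
from gvhdgrading.agreement import (
    kappa_matrix,
    redistribution_analysis,
    repertoire_table,
)
from gvhdgrading.clustering import hclust_fit, kmeans_fit
from gvhdgrading.cohort import CohortTable
from gvhdgrading.conventional import grade_cohort
from gvhdgrading.pc1 import fit_pc1
from gvhdgrading.survival import grading_aic, harrell_c, td_auroc

logger = logging.getLogger(__name__)

DEFAULT_SYSTEMS = ("pc1", "hclust", "kmeans", "magic", "consensus", "ibmtr", "minnesota")


@dataclass
class RunConfig:
    """Configuration of a full comparison run."""

    train: Optional[CohortTable]
    test: CohortTable
    systems: tuple[str, ...] = DEFAULT_SYSTEMS
    horizon: float = 365.0
    seed: int = 0
    k: int = 4
    unseen_policy: str = "nearest"
    p_convention: str = "categories"
    out_dir: Optional[Path] = None
    metadata: dict = field(default_factory=dict)


def _grade_frame(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Grade the test cohort under every requested system (NaN = ungradable)."""
    models: dict = {}
    needs_fit = {"pc1", "hclust", "kmeans"} & set(config.systems)
    if needs_fit and config.train is None:
        raise ValueError("data-driven systems require a training cohort")
    if "pc1" in config.systems:
        models["pc1"] = fit_pc1(config.train)
    if "hclust" in config.systems:
        models["hclust"] = hclust_fit(config.train, k=config.k, horizon=config.horizon)
    if "kmeans" in config.systems:
        models["kmeans"] = kmeans_fit(
            config.train, k=config.k, seed=config.seed, horizon=config.horizon
        )
    columns = {}
    for system in config.systems:
        kwargs = {}
        if system in ("hclust", "kmeans"):
            kwargs["policy"] = config.unseen_policy
        assignments = grade_cohort(
            config.test, system, model=models.get(system), **kwargs
        )
        columns[system] = [np.nan if a is None else a.grade for a in assignments]
    return pd.DataFrame(columns, index=config.test.df["id"]), models


def run_full_comparison(config: RunConfig) -> dict:
    """Run the complete grading comparison and return (and optionally write)
    the report bundle."""
    grades, models = _grade_frame(config)
    complete = grades.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "%d patient(s) ungradable in at least one system; "
            "comparisons use the remaining %d",
            n_dropped,
            int(complete.sum()),
        )
    sub = config.test.subset(complete)
    gsub = grades.loc[complete]

    rows_aic, rows_ci, rows_auc = [], [], []
    for system in config.systems:
        g = gsub[system].astype(int).to_numpy()
        rows_aic.append(
            {
                "system": system,
                "aic": grading_aic(sub, g, p_convention=config.p_convention),
            }
        )
        rows_ci.append({"system": system, "harrell_c": harrell_c(sub, g)})
        for outcome in ("os", "nrm"):
            auc, (lo, hi) = td_auroc(
                sub, g, horizon=config.horizon, outcome=outcome, seed=config.seed
            )
            rows_auc.append(
                {
                    "system": system,
                    "outcome": outcome,
                    "auroc": auc,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
    aic_table = pd.DataFrame(rows_aic).sort_values("aic").reset_index(drop=True)
    ci_table = (
        pd.DataFrame(rows_ci).sort_values("harrell_c", ascending=False).reset_index(drop=True)
    )
    auroc_table = pd.DataFrame(rows_auc)
    kappa = kappa_matrix(gsub)
    repertoires = {
        system: repertoire_table(sub, gsub[system].astype(int), system)
        for system in config.systems
    }
    redistribution = None
    if "magic" in config.systems and "pc1" in config.systems:
        redistribution = redistribution_analysis(
            sub,
            gsub["magic"].astype(int),
            3,
            gsub["pc1"].astype(int),
            2,
            horizon=config.horizon,
        )

    bundle = {
        "grades": grades,
        "aic": aic_table,
        "concordance": ci_table,
        "auroc": auroc_table,
        "kappa": kappa,
        "repertoires": repertoires,
        "redistribution": redistribution,
        "models": models,
        "n_evaluable": int(complete.sum()),
    }
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _config_hash(config: RunConfig) -> str:
    payload = {
        "systems": list(config.systems),
        "horizon": config.horizon,
        "seed": config.seed,
        "k": config.k,
        "unseen_policy": config.unseen_policy,
        "p_convention": config.p_convention,
        "n_train": None if config.train is None else len(config.train),
        "n_test": len(config.test),
        "test_ids_sha1": hashlib.sha1(
            ",".join(config.test.df["id"]).encode()
        ).hexdigest(),
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["grades"].to_csv(out / "grades.csv")
    bundle["aic"].to_csv(out / "aic.csv", index=False)
    bundle["concordance"].to_csv(out / "concordance.csv", index=False)
    bundle["auroc"].to_csv(out / "auroc.csv", index=False)
    bundle["kappa"].to_csv(out / "kappa_matrix.csv")
    for system, rep in bundle["repertoires"].items():
        rep.summary.to_csv(out / f"repertoire_{system}_summary.csv", index=False)
        rep.detail.to_csv(out / f"repertoire_{system}_detail.csv", index=False)
    if bundle["redistribution"] is not None:
        red = bundle["redistribution"]
        summary = {
            k: red[k]
            for k in (
                "n_selected",
                "n_redistributed",
                "n_intersection",
                "os_at_horizon",
                "nrm_at_horizon",
                "logrank",
                "gray",
                "note",
            )
            if k in red
        }
        (out / "redistribution.json").write_text(json.dumps(summary, indent=2))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "systems": list(config.systems),
        "horizon": config.horizon,
        "k": config.k,
        "unseen_policy": config.unseen_policy,
        "p_convention": config.p_convention,
        "n_evaluable": bundle["n_evaluable"],
        "config_hash": _config_hash(config),
        "metadata": config.metadata,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
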