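"""Domain types, cohort CSV input/output and exploratory structure summaries.

A patient is a point in the three-dimensional aGVHD organ-stage space
(skin, liver, gastrointestinal tract), each stage an integer 0-4, together
with a time-to-event outcome under competing risks (nonrelapse death vs.
relapse) and an explicit overall-survival event indicator.  A cohort is a
validated, ordered table of such patients with a common time origin.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

ORGANS = ("skin", "liver", "gi")
STAGES = (0, 1, 2, 3, 4)

#: event codes as stored in the cohort CSV
EVENT_CENSORED = "censored"
EVENT_NRM = "nrm"
EVENT_RELAPSE = "relapse"
EVENTS = (EVENT_CENSORED, EVENT_NRM, EVENT_RELAPSE)

#: numeric event coding used by the competing-risks estimators:
#: 0 = censored, 1 = nonrelapse death, 2 = relapse
EVENT_CODES = {EVENT_CENSORED: 0, EVENT_NRM: 1, EVENT_RELAPSE: 2}

ORIGIN_HCT = "hct_day"
ORIGIN_AGVHD = "agvhd_diagnosis_day"
ORIGINS = (ORIGIN_HCT, ORIGIN_AGVHD)

MANDATORY_COLUMNS = ("id", "skin", "liver", "gi", "time_days", "event", "os_event")

#: number of decimals preserved for event times on write (days)
TIME_DECIMALS = 6


class CohortValidationError(ValueError):
    """A cohort table violates the schema (bad stage, time, event or id)."""


@dataclass(frozen=True)
class OrganStages:
    """One patient's maximal (skin, liver, GI) aGVHD organ stages."""

    skin: int
    liver: int
    gi: int

    def __post_init__(self) -> None:
        for organ in ORGANS:
            value = getattr(self, organ)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise CohortValidationError(
                    f"{organ} stage must be an integer, got {value!r}"
                )
            if value not in STAGES:
                raise CohortValidationError(
                    f"{organ} stage must be in 0..4, got {value}"
                )

    def as_tuple(self) -> tuple[int, int, int]:
        return (int(self.skin), int(self.liver), int(self.gi))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=float)

    @property
    def is_zero(self) -> bool:
        """True for (0,0,0), i.e. absence of aGVHD ("grade 0")."""
        return self.as_tuple() == (0, 0, 0)


@dataclass(frozen=True)
class Phenotype:
    """An organ-stage combination with its canonical label.

    Labels have the form ``skin{a}-liver{b}-gi{c}`` and round-trip
    bijectively to the stage triple.
    """

    stages: OrganStages

    @property
    def label(self) -> str:
        s = self.stages
        return f"skin{s.skin}-liver{s.liver}-gi{s.gi}"

    @classmethod
    def from_label(cls, label: str) -> "Phenotype":
        parts = label.split("-")
        if len(parts) != 3:
            raise ValueError(f"malformed phenotype label {label!r}")
        values = {}
        for part, organ in zip(parts, ORGANS):
            if not part.startswith(organ):
                raise ValueError(f"malformed phenotype label {label!r}")
            values[organ] = int(part[len(organ):])
        return cls(OrganStages(**values))


def phenotype_label(skin: int, liver: int, gi: int) -> str:
    return f"skin{skin}-liver{liver}-gi{gi}"


@dataclass(frozen=True)
class OutcomeRecord:
    """Time-to-event outcome with competing-event coding.

    ``event`` is exactly one of censored / nrm / relapse; ``os_event``
    records death from any cause and is stored explicitly because relapse,
    as a competing event, is not itself death.
    """

    time: float
    event: str
    os_event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise CohortValidationError(f"time must be >= 0, got {self.time}")
        if self.event not in EVENTS:
            raise CohortValidationError(
                f"event must be one of {EVENTS}, got {self.event!r}"
            )
        if self.event == EVENT_NRM and not self.os_event:
            raise CohortValidationError(
                "os_event must be 1 whenever event is nrm (nonrelapse death)"
            )


@dataclass(frozen=True)
class PatientRecord:
    id: str
    stages: OrganStages
    outcome: OutcomeRecord
    covariates: Mapping[str, float] = field(default_factory=dict)
    center: Optional[str] = None


class CohortTable:
    """An ordered cohort of patients sharing one time origin.

    Internally a validated :class:`pandas.DataFrame` with columns
    ``id, skin, liver, gi, time_days, event, os_event`` plus optional
    ``center`` and arbitrary covariate columns.  Row order is preserved.
    """

    def __init__(self, df: pd.DataFrame, origin: str = ORIGIN_HCT) -> None:
        if origin not in ORIGINS:
            raise CohortValidationError(f"origin must be one of {ORIGINS}")
        self.origin = origin
        self.df = _validate_frame(df)

    # -- construction -------------------------------------------------

    @classmethod
    def from_patients(
        cls, patients: list[PatientRecord], origin: str = ORIGIN_HCT
    ) -> "CohortTable":
        rows = []
        for p in patients:
            row = {
                "id": p.id,
                "skin": p.stages.skin,
                "liver": p.stages.liver,
                "gi": p.stages.gi,
                "time_days": p.outcome.time,
                "event": p.outcome.event,
                "os_event": int(p.outcome.os_event),
            }
            if p.center is not None:
                row["center"] = p.center
            row.update(p.covariates)
            rows.append(row)
        return cls(pd.DataFrame(rows), origin=origin)

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def stage_matrix(self) -> np.ndarray:
        """(n, 3) float matrix of (skin, liver, gi) stages."""
        return self.df[list(ORGANS)].to_numpy(dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_days"].to_numpy(dtype=float)

    @property
    def os_events(self) -> np.ndarray:
        return self.df["os_event"].to_numpy(dtype=int)

    @property
    def event_codes(self) -> np.ndarray:
        """Numeric competing-event codes: 0 censored, 1 nrm, 2 relapse."""
        return self.df["event"].map(EVENT_CODES).to_numpy(dtype=int)

    @property
    def covariate_columns(self) -> list[str]:
        reserved = set(MANDATORY_COLUMNS) | {"center"}
        return [c for c in self.df.columns if c not in reserved]

    def phenotype_labels(self) -> pd.Series:
        df = self.df
        return (
            "skin" + df["skin"].astype(str)
            + "-liver" + df["liver"].astype(str)
            + "-gi" + df["gi"].astype(str)
        )

    def patients(self) -> Iterator[PatientRecord]:
        cov_cols = self.covariate_columns
        for _, row in self.df.iterrows():
            yield PatientRecord(
                id=str(row["id"]),
                stages=OrganStages(int(row["skin"]), int(row["liver"]), int(row["gi"])),
                outcome=OutcomeRecord(
                    float(row["time_days"]), str(row["event"]), bool(row["os_event"])
                ),
                covariates={c: row[c] for c in cov_cols},
                center=str(row["center"]) if "center" in row.index and pd.notna(row.get("center")) else None,
            )

    def subset(self, mask) -> "CohortTable":
        """Row-subset preserving order; mask is boolean array-like."""
        return CohortTable(self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True), self.origin)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        raise CohortValidationError("cohort must be nonempty")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"missing mandatory column {col!r}")
    df = df.copy().reset_index(drop=True)
    df["id"] = df["id"].astype(str)
    dup = df["id"].duplicated()
    if dup.any():
        raise CohortValidationError(
            f"duplicate patient id {df['id'][dup].iloc[0]!r}"
        )
    for organ in ORGANS:
        raw = df[organ]
        numeric = pd.to_numeric(raw, errors="coerce")
        for i, value in enumerate(numeric):
            if pd.isna(value) or float(value) != int(value):
                raise CohortValidationError(
                    f"row {i}, column {organ!r}: stage must be an integer, got {raw.iloc[i]!r}"
                )
            if not 0 <= int(value) <= 4:
                raise CohortValidationError(
                    f"row {i}, column {organ!r}: stage {int(value)} out of range 0..4"
                )
        df[organ] = numeric.astype(int)
    times = pd.to_numeric(df["time_days"], errors="coerce")
    if times.isna().any() or (times < 0).any():
        i = int(np.argmax(times.isna() | (times < 0)))
        raise CohortValidationError(f"row {i}: time_days must be a number >= 0")
    df["time_days"] = times.astype(float)
    bad_event = ~df["event"].isin(EVENTS)
    if bad_event.any():
        i = int(np.argmax(bad_event.to_numpy()))
        raise CohortValidationError(
            f"row {i}: unknown event {df['event'].iloc[i]!r}; expected one of {EVENTS}"
        )
    os_evt = pd.to_numeric(df["os_event"], errors="coerce")
    if os_evt.isna().any() or ~os_evt.isin([0, 1]).all():
        raise CohortValidationError("os_event must be 0 or 1")
    df["os_event"] = os_evt.astype(int)
    inconsistent = (df["event"] == EVENT_NRM) & (df["os_event"] == 0)
    if inconsistent.any():
        i = int(np.argmax(inconsistent.to_numpy()))
        raise CohortValidationError(
            f"row {i}: event is nrm but os_event is 0 (nonrelapse death is a death)"
        )
    return df


# ---------------------------------------------------------------------------
# CSV input/output


def read_cohort(path, origin: str = ORIGIN_HCT) -> CohortTable:
    """Read a cohort CSV (UTF-8, header required, LF or CRLF line ends).

    Mandatory columns: ``id, skin, liver, gi, time_days, event, os_event``;
    optional ``center`` and arbitrary covariate columns are preserved under
    their names.  Every row is validated; malformed stages, negative times,
    unknown event codes and duplicate ids raise
    :class:`CohortValidationError` naming row and column.
    """
    df = pd.read_csv(path, encoding="utf-8")
    return CohortTable(df, origin=origin)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV readable back by :func:`read_cohort`.

    Integer columns are written exactly; event times are rounded to
    ``TIME_DECIMALS`` decimals (microsecond-scale precision in days).
    """
    df = cohort.df.copy()
    df["time_days"] = df["time_days"].round(TIME_DECIMALS)
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Phenotype enumeration and summaries


def enumerate_phenotypes(include_zero: bool = True) -> list[Phenotype]:
    """All (skin, liver, GI) stage combinations in lexicographic order.

    125 combinations with the zero phenotype included, 124 without
    (the 5**3 combinations of three organs staged 0-4).
    """
    out = []
    for skin, liver, gi in itertools.product(STAGES, repeat=3):
        if not include_zero and (skin, liver, gi) == (0, 0, 0):
            continue
        out.append(Phenotype(OrganStages(skin, liver, gi)))
    return out


def phenotype_counts(cohort: CohortTable) -> dict[str, int]:
    """Patient count per observed phenotype label; absent phenotypes omitted."""
    counts = cohort.phenotype_labels().value_counts()
    return {str(k): int(v) for k, v in counts.items()}


def spearman_matrix(cohort: CohortTable) -> pd.DataFrame:
    """3x3 Spearman rank-correlation matrix of the organ stages.

    Ties are handled by midranks.  An organ with constant stage yields
    undefined (NaN) off-diagonal entries, reported with a warning rather
    than imputed.
    """
    X = cohort.stage_matrix
    out = pd.DataFrame(np.eye(3), index=ORGANS, columns=ORGANS)
    for i, j in itertools.combinations(range(3), 2):
        xi, xj = X[:, i], X[:, j]
        if np.all(xi == xi[0]) or np.all(xj == xj[0]):
            warnings.warn(
                f"Spearman correlation undefined for constant organ pair "
                f"({ORGANS[i]}, {ORGANS[j]}); reported as NaN",
                stacklevel=2,
            )
            rho = np.nan
        else:
            rho = stats.spearmanr(xi, xj).statistic
        out.iloc[i, j] = out.iloc[j, i] = rho
    return out
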