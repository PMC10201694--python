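"""Subject-level survival cohorts: container, validation, CSV round-trip,
and study-style descriptive summaries.

A cohort is a pandas DataFrame with columns ``subject_id``, ``time`` (months
of follow-up), ``event`` (1 = death, 0 = censored) and one 0/1 column per
covariate, wrapped with a :class:`CovariateSchema` that records level labels
and which covariates enter the incidence (Z) and latency (X) model parts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference


class CohortError(ValueError):
    """Raised for schema violations or invalid subject rows."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event indicator, binary covariates."""

    subject_id: str
    time: float
    event: int
    covariates: dict[str, float]  # values 0/1 or NaN when missing


@dataclass
class CovariateSchema:
    """Covariate metadata: display labels, level coding, model-part roles.

    ``levels[name] = (level coded 1, reference level coded 0)``.
    ``incidence`` / ``latency`` name the covariates entering the cure
    probability (Z) and the conditional survival (X) parts; by default both
    contain every covariate.
    """

    covariates: list[str]
    levels: dict[str, tuple[str, str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    incidence: list[str] | None = None
    latency: list[str] | None = None

    def __post_init__(self) -> None:
        for name in self.covariates:
            self.levels.setdefault(name, ("1", "0"))
            self.labels.setdefault(name, name)
        if self.incidence is None:
            self.incidence = list(self.covariates)
        if self.latency is None:
            self.latency = list(self.covariates)
        for role, names in (("incidence", self.incidence), ("latency", self.latency)):
            unknown = set(names) - set(self.covariates)
            if unknown:
                raise CohortError(f"{role} covariates not in schema: {sorted(unknown)}")

    @classmethod
    def default_hiv(cls) -> "CovariateSchema":
        """Schema of the ten binary covariates of the HIV reference cohort."""
        return cls(
            covariates=list(reference.COVARIATES),
            levels=dict(reference.LEVELS),
            labels=dict(reference.LABELS),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CovariateSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            covariates=list(raw["covariates"]),
            levels={k: tuple(v) for k, v in raw.get("levels", {}).items()},
            labels=dict(raw.get("labels", {})),
            incidence=raw.get("incidence"),
            latency=raw.get("latency"),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "covariates": self.covariates,
            "levels": {k: list(v) for k, v in self.levels.items()},
            "labels": self.labels,
            "incidence": self.incidence,
            "latency": self.latency,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class Cohort:
    """An ordered collection of survival records plus covariate metadata."""

    data: pd.DataFrame
    schema: CovariateSchema

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        required = {"subject_id", "time", "event"}
        missing = required - set(df.columns)
        if missing:
            raise CohortError(f"missing required columns: {sorted(missing)}")
        if len(df) < 1:
            raise CohortError("cohort must contain at least one subject")
        bad_time = df.index[(df["time"] < 0) | df["time"].isna()].tolist()
        if bad_time:
            raise CohortError(f"negative or unparseable time in rows {bad_time}")
        bad_event = df.index[~df["event"].isin([0, 1])].tolist()
        if bad_event:
            raise CohortError(f"event must be 0 or 1; offending rows {bad_event}")
        absent = set(self.schema.covariates) - set(df.columns)
        if absent:
            raise CohortError(f"schema covariates absent from data: {sorted(absent)}")
        for name in self.schema.covariates:
            col = df[name]
            ok = col.isna() | col.isin([0, 1])
            if not ok.all():
                raise CohortError(
                    f"covariate {name!r} must be 0/1 or missing; "
                    f"offending rows {df.index[~ok].tolist()}"
                )

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.schema.covariates)

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else self.covariate_names
        return self.data[names].to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.data[self.covariate_names].isna().any().any())

    @property
    def records(self) -> Iterator[SurvivalRecord]:
        for _, row in self.data.iterrows():
            yield SurvivalRecord(
                subject_id=str(row["subject_id"]),
                time=float(row["time"]),
                event=int(row["event"]),
                covariates={c: row[c] for c in self.covariate_names},
            )

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), dataclasses.replace(self.schema))


# -- CSV round-trip ---------------------------------------------------------


def read_cohort(path: str | Path, schema: CovariateSchema) -> Cohort:
    """Read a delimited cohort table, validating times, events, covariates.

    Rows with unparseable time or event are rejected with their row numbers;
    missing covariate cells are retained as missing (to be imputed later).
    """
    df = pd.read_csv(path)
    required = {"time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"{path}: missing required columns {sorted(missing)}")
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", [f"s{i}" for i in range(len(df))])
    for col in ("time", "event"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()].tolist()
        if bad:
            raise CohortError(f"{path}: unparseable {col} in rows {bad}")
        df[col] = parsed
    return Cohort(df.reset_index(drop=True), schema)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cols = ["subject_id", "time", "event", *cohort.covariate_names]
    cohort.data[cols].to_csv(path, index=False)


# -- descriptive summary ----------------------------------------------------


@dataclass
class CohortSummary:
    """Per-level counts/percentages overall and among deaths, plus the
    overall censoring proportion."""

    table: pd.DataFrame
    n: int
    n_events: int

    @property
    def censored_proportion(self) -> float:
        return 1.0 - self.n_events / self.n

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}, deaths = {self.n_events}, "
            f"censored = {100 * self.censored_proportion:.1f}%",
            self.table.to_string(index=False),
        ]
        return "\n".join(lines)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Descriptive table: per covariate level, N (%) overall and among deaths.

    Missing covariate cells are excluded from that covariate's rows (their
    count is reported in a ``missing`` column).
    """
    df = cohort.data
    dead = df[df["event"] == 1]
    n, n_dead = len(df), len(dead)
    rows = []
    for name in cohort.covariate_names:
        label = cohort.schema.labels[name]
        lvl1, lvl0 = cohort.schema.levels[name]
        col = df[name]
        n_miss = int(col.isna().sum())
        for level_label, value in ((lvl1, 1), (lvl0, 0)):
            total = int((col == value).sum())
            d = int((dead[name] == value).sum())
            rows.append(
                {
                    "variable": label,
                    "level": level_label,
                    "total_n": total,
                    "total_pct": 100 * total / max(n - n_miss, 1),
                    "dead_n": d,
                    "dead_pct": 100 * d / max(n_dead, 1) if n_dead else float("nan"),
                    "missing": n_miss,
                }
            )
    return CohortSummary(table=pd.DataFrame(rows), n=n, n_events=n_dead)
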