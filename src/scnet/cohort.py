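"""Cohort tables and covariate residualization.

A cohort table has one row per subject: ``subject_id``, ``group`` (exactly
two levels), the covariates ``age``, ``gender`` (0/1 dummy) and
``total_feature`` (the subject's whole-cortex value of the measure), then
one numeric column per atlas region.

Before any correlation is computed, each region is regressed on the
covariates (with an intercept) and the residuals replace the raw values —
this removes global confounds (age, gender, overall cortex size) that would
otherwise inflate every inter-regional correlation. Fits are ordinary least
squares, one per region, run per group by default so that group mean
differences cannot leak into within-group covariance; a pooled mode fits
across both groups at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ("subject_id", "group", "age", "gender", "total_feature")
DEFAULT_COVARIATES = ("age", "gender", "total_feature")

__all__ = [
    "Cohort",
    "ResidualMatrix",
    "load_cohort",
    "residualize",
    "residualize_matrix",
]


@dataclass
class Cohort:
    """A validated subject x region feature table plus its region list."""

    data: pd.DataFrame
    regions: list[str]

    def __post_init__(self) -> None:
        _validate(self.data, self.regions)

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def group_rows(self, group: str) -> pd.DataFrame:
        rows = self.data[self.data["group"] == group]
        if rows.empty:
            raise KeyError(f"no subjects in group {group!r}")
        return rows

    def features(self, group: str | None = None) -> np.ndarray:
        rows = self.data if group is None else self.group_rows(group)
        return rows[self.regions].to_numpy(dtype=float)

    def with_groups(self, labels: np.ndarray) -> "Cohort":
        """Copy of the cohort with the group column replaced (for permutations)."""
        data = self.data.copy()
        data["group"] = labels
        return Cohort(data=data, regions=self.regions)


def _validate(data: pd.DataFrame, regions: list[str]) -> None:
    for col in META_COLUMNS:
        if col not in data.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    missing = [r for r in regions if r not in data.columns]
    if missing:
        raise ValueError(f"cohort table is missing region column(s): {missing}")
    dup = data["subject_id"][data["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id(s): {sorted(dup.unique())}")
    levels = data["group"].unique()
    if len(levels) != 2:
        raise ValueError(f"group column must take exactly two values, found {list(levels)}")
    block = data[list(regions) + ["age", "gender", "total_feature"]]
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"missing values in column(s): {bad}")
    for col in regions:
        if not np.issubdtype(data[col].dtype, np.number):
            row = data.index[pd.to_numeric(data[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric feature value in column {col!r}, row(s) {list(row)}"
            )


def load_cohort(path: str | Path, atlas_labels: list[str] | None = None) -> Cohort:
    """Read and validate a cohort TSV/CSV.

    ``atlas_labels`` fixes the expected region columns (order enforced on
    the returned cohort); if omitted, every non-metadata column is treated
    as a region, in file order.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    data = pd.read_csv(path, sep=sep)
    if atlas_labels is None:
        regions = [c for c in data.columns if c not in META_COLUMNS]
    else:
        regions = list(atlas_labels)
    # reorder so region columns follow metadata in atlas order
    _validate(data, regions)
    ordered = [c for c in META_COLUMNS if c in data.columns] + regions
    return Cohort(data=data[ordered].reset_index(drop=True), regions=regions)


@dataclass
class ResidualMatrix:
    """Per-group OLS residuals: subjects x regions, covariates removed."""

    group: str
    values: np.ndarray
    regions: list[str]
    covariates_used: list[str] = field(default_factory=list)
    covariates_dropped: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def residualize_matrix(
    y: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """OLS residuals of every column of ``y`` on [1, covariates].

    Returns ``(residuals, beta)`` where ``beta`` is (1 + k) x n_regions.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None or covariates.size == 0:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, beta


def residualize(
    cohort: Cohort,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    pooled: bool = False,
) -> dict[str, ResidualMatrix]:
    """Regress out covariates from every region, per group (or pooled).

    For each group g and region j, fits ``y_j = X beta + r`` with
    ``X = [1, covariates]`` by OLS and keeps the residuals ``r``. A
    covariate that is constant within the fitted rows (e.g. single-gender
    permuted groups) is dropped with a warning rather than producing a
    rank-deficient fit.

    With ``pooled=True`` one fit per region uses all subjects; the pooled
    residuals are then split back by group.
    """
    for cov in covariates:
        if cov not in cohort.data.columns:
            raise ValueError(f"covariate column {cov!r} not in cohort table")
    groups = cohort.groups

    def _fit(rows: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
        n = len(rows)
        if n < len(covariates) + 2:
            raise ValueError(
                f"need at least {len(covariates) + 2} subjects to fit "
                f"{len(covariates)} covariates plus intercept; got {n}"
            )
        used, dropped = [], []
        cols = []
        for cov in covariates:
            v = rows[cov].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                dropped.append(cov)
            else:
                used.append(cov)
                cols.append(v)
        if dropped:
            warnings.warn(
                f"covariate(s) {dropped} constant within fitted rows; dropped",
                stacklevel=3,
            )
        x = np.column_stack(cols) if cols else None
        resid, _ = residualize_matrix(rows[cohort.regions].to_numpy(float), x)
        return resid, used, dropped

    out: dict[str, ResidualMatrix] = {}
    if pooled:
        resid, used, dropped = _fit(cohort.data)
        mask = {g: (cohort.data["group"] == g).to_numpy() for g in groups}
        for g in groups:
            out[g] = ResidualMatrix(g, resid[mask[g]], cohort.regions, used, dropped)
    else:
        for g in groups:
            resid, used, dropped = _fit(cohort.group_rows(g))
            out[g] = ResidualMatrix(g, resid, cohort.regions, used, dropped)
    return out
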