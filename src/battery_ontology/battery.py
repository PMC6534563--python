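"""Data model and I/O for behavioral measurement batteries.

A battery is a participants x DVs numeric matrix. Each DV (dependent
variable) is a single numeric measure extracted from a behavioral task or a
self-report survey (a condition contrast, a model parameter, a scale mean,
...), and carries metadata: the measure it came from and its category
(``task``, ``survey`` or ``outcome``). Everything downstream — reliability,
factor analysis, clustering, networks, prediction — consumes this container.

The pipeline expects an already-imputed matrix: NaNs are rejected here, not
filled in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("task", "survey", "outcome")


class BatteryError(ValueError):
    """Raised for invalid battery data or metadata."""


@dataclass
class DVMatrix:
    """Participants x DVs matrix with per-DV metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by participant id, one column per DV.
    meta:
        DataFrame indexed by dv_name with columns ``measure`` and
        ``category``; must cover exactly the DVs in ``data``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise BatteryError(f"duplicate dv_name(s): {dupes}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise BatteryError(f"duplicate participant id(s): {dupes}")
        missing = [c for c in self.data.columns if c not in self.meta.index]
        if missing:
            raise BatteryError(f"DVs missing from metadata: {missing}")
        extra = [c for c in self.meta.index if c not in self.data.columns]
        if extra:
            raise BatteryError(f"metadata for unknown DVs: {extra}")
        bad_cat = self.meta.loc[~self.meta["category"].isin(CATEGORIES)]
        if len(bad_cat):
            raise BatteryError(
                f"invalid category for {bad_cat.index.tolist()}; "
                f"must be one of {CATEGORIES}"
            )
        vals = self.data.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise BatteryError("non-numeric values in DV matrix")
        if vals.size and not np.isfinite(vals).all():
            rows, cols = np.where(~np.isfinite(vals))
            raise BatteryError(
                "non-finite value at participant "
                f"{self.data.index[rows[0]]!r}, DV {self.data.columns[cols[0]]!r}"
            )
        # align metadata to column order
        self.meta = self.meta.loc[self.data.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def dv_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_dvs(self) -> int:
        return self.data.shape[1]

    def categories(self) -> pd.Series:
        return self.meta["category"]

    def select_category(self, category: str) -> "DVMatrix":
        """Sub-battery containing only DVs of one category."""
        if category not in CATEGORIES:
            raise BatteryError(f"unknown category {category!r}")
        cols = self.meta.index[self.meta["category"] == category]
        return DVMatrix(self.data[list(cols)], self.meta.loc[cols].copy())

    def select_dvs(self, dv_names: Sequence[str]) -> "DVMatrix":
        missing = [d for d in dv_names if d not in self.data.columns]
        if missing:
            raise BatteryError(f"unknown DVs: {missing}")
        return DVMatrix(self.data[list(dv_names)], self.meta.loc[list(dv_names)].copy())

    def select_participants(self, ids: Sequence) -> "DVMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise BatteryError(f"unknown participants: {missing}")
        return DVMatrix(self.data.loc[list(ids)], self.meta.copy())


@dataclass
class RetestPair:
    """Two sessions of the same battery on a shared participant subset."""

    t1: DVMatrix
    t2: DVMatrix
    shared_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.t1.dv_names) != list(self.t2.dv_names):
            raise BatteryError("retest sessions have different DVs")
        if not self.t1.meta.equals(self.t2.meta):
            raise BatteryError("retest sessions have different metadata")
        if not self.shared_ids:
            self.shared_ids = [
                i for i in self.t1.participant_ids if i in set(self.t2.participant_ids)
            ]
        for i in self.shared_ids:
            if i not in self.t1.data.index or i not in self.t2.data.index:
                raise BatteryError(f"shared id {i!r} missing from a session")
        if len(self.shared_ids) < 3:
            raise BatteryError("need at least 3 shared retest participants")

    def aligned_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Session-1 and session-2 values row-aligned on shared participants."""
        a = self.t1.data.loc[self.shared_ids].to_numpy(dtype=float)
        b = self.t2.data.loc[self.shared_ids].to_numpy(dtype=float)
        return a, b


@dataclass
class CovariateTable:
    """Per-participant covariates (age in years, sex coded 0/1)."""

    table: pd.DataFrame  # index: participant id; columns include age, sex

    def __post_init__(self) -> None:
        for col in ("age", "sex"):
            if col not in self.table.columns:
                raise BatteryError(f"covariate table missing column {col!r}")
        if self.table.index.duplicated().any():
            raise BatteryError("duplicate participant ids in covariates")
        if self.table[["age", "sex"]].isna().any().any():
            raise BatteryError("missing covariate values")

    def aligned_to(self, participant_ids: Iterable) -> pd.DataFrame:
        ids = list(participant_ids)
        missing = [i for i in ids if i not in self.table.index]
        if missing:
            raise BatteryError(f"covariates missing for participants: {missing}")
        return self.table.loc[ids, ["age", "sex"]].astype(float)


# -- I/O ----------------------------------------------------------------------

def load_dv_matrix(path: str | Path, meta_path: str | Path) -> DVMatrix:
    """Load a battery from a CSV/TSV matrix plus sidecar JSON metadata.

    The matrix has a header row of dv_names and a first column of
    participant ids; the metadata file maps dv_name -> {measure, category}.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    data = pd.read_csv(path, sep=sep, index_col=0)
    data.index = data.index.astype(str)
    for col in data.columns:
        if not np.issubdtype(data[col].dtype, np.number):
            bad = data[col][pd.to_numeric(data[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise BatteryError(
                f"non-numeric cell in column {col!r}, participant {row!r}"
            )
    with open(meta_path) as fh:
        meta_raw = json.load(fh)
    missing = [c for c in data.columns if c not in meta_raw]
    if missing:
        raise BatteryError(f"DVs missing from metadata: {missing}")
    meta = pd.DataFrame.from_dict(meta_raw, orient="index").loc[list(data.columns)]
    meta.index.name = "dv_name"
    return DVMatrix(data, meta[["measure", "category"]])


def write_matrix(dvm: DVMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the matrix as CSV (participant_id first column) + sidecar JSON."""
    path = Path(path)
    out = dvm.data.copy()
    out.index.name = "participant_id"
    out.to_csv(path)
    if meta_path is None:
        meta_path = path.with_suffix(".meta.json")
    meta = {
        name: {"measure": row["measure"], "category": row["category"]}
        for name, row in dvm.meta.iterrows()
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, ensure_ascii=False)


# -- preprocessing ------------------------------------------------------------

def standardize(dvm: DVMatrix) -> DVMatrix:
    """Column-wise z-scoring with sample (n-1) variance.

    Downstream factor analysis operates on the correlation matrix, which is
    exactly the covariance of these standardized columns.
    """
    vals = dvm.values
    sd = vals.std(axis=0, ddof=1)
    bad = np.where(~(sd > 0))[0]
    if len(bad):
        raise BatteryError(
            f"constant column(s): {[dvm.dv_names[i] for i in bad]}"
        )
    z = (vals - vals.mean(axis=0)) / sd
    return DVMatrix(
        pd.DataFrame(z, index=dvm.data.index, columns=dvm.data.columns),
        dvm.meta.copy(),
    )


def residualize_covariates(dvm: DVMatrix, covariates: CovariateTable) -> DVMatrix:
    """OLS-residualize every column on intercept + age + sex.

    Used on outcome variables before factor-analyzing them, so that the
    derived outcome targets are orthogonal to basic demographics.
    """
    cov = covariates.aligned_to(dvm.participant_ids)
    X = np.column_stack([np.ones(len(cov)), cov["age"], cov["sex"]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise BatteryError("collinear or constant covariates (design rank-deficient)")
    Y = dvm.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return DVMatrix(
        pd.DataFrame(resid, index=dvm.data.index, columns=dvm.data.columns),
        dvm.meta.copy(),
    )
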