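"""Containers and validation for functional observations with scalar covariates.

A dataset holds N sample paths Y_i observed on per-curve grids t_i (length
n_i), together with an N x R matrix of scalar covariates.  Identifiability of
the mixed membership model rests on checkable design conditions (full-rank
standardized covariates with the intercept excluded from the column space, and
n_i > P observation points per curve); :func:`validate_inputs` reports them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalDataset",
    "CovariateDesign",
    "ValidationReport",
    "read_long_table",
    "write_long_table",
    "standardize_covariates",
    "validate_inputs",
]

#: relative threshold on singular values used for all rank decisions
RANK_RTOL = 1e-8


@dataclass
class FunctionalDataset:
    """N curves with per-curve time grids and an N x R covariate matrix."""

    curve_ids: list
    times: list[np.ndarray]
    values: list[np.ndarray]
    covariates: np.ndarray  # shape (N, R); R may be 0

    def __post_init__(self) -> None:
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.values = [np.asarray(y, dtype=float) for y in self.values]
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates.reshape(len(self.curve_ids), -1)
        n = len(self.curve_ids)
        if not (len(self.times) == len(self.values) == n):
            raise ValueError("curve_ids, times and values must have equal length")
        if self.covariates.shape[0] != n:
            raise ValueError(
                f"covariate rows ({self.covariates.shape[0]}) != number of curves ({n})"
            )
        for cid, t, y in zip(self.curve_ids, self.times, self.values):
            if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
                raise ValueError(f"curve {cid!r}: times/values must be 1-d of equal length")
            if t.size < 1:
                raise ValueError(f"curve {cid!r}: empty curve")
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"curve {cid!r}: times must be strictly increasing")
            if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
                raise ValueError(f"curve {cid!r}: non-finite times or values")

    @property
    def n_curves(self) -> int:
        return len(self.curve_ids)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_points(self) -> np.ndarray:
        return np.array([t.size for t in self.times])

    @property
    def domain(self) -> tuple[float, float]:
        return (min(t[0] for t in self.times), max(t[-1] for t in self.times))


@dataclass
class CovariateDesign:
    """Column-standardized covariates with the transform recorded.

    ``X_std`` has column means 0 and sample (n-1) standard deviations 1, so
    fitted covariate effects can be mapped back to the raw scale via
    ``centers`` and ``scales``.
    """

    X_std: np.ndarray
    centers: np.ndarray
    scales: np.ndarray

    @property
    def n_covariates(self) -> int:
        return self.X_std.shape[1]

    def to_raw(self, X_std: np.ndarray) -> np.ndarray:
        return X_std * self.scales + self.centers

    def transform(self, X_raw: np.ndarray) -> np.ndarray:
        return (np.asarray(X_raw, dtype=float) - self.centers) / self.scales


@dataclass
class ValidationReport:
    """Pass/fail results of the identifiability design checks."""

    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(self.checks.values())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"[{'PASS' if v else 'FAIL'}] {k}: {self.details.get(k, '')}"
            for k, v in self.checks.items()
        ]
        lines += [f"[WARN] {w}" for w in self.warnings]
        return "\n".join(lines)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_long_table(
    curve_path: str | Path, covariate_path: str | Path | None = None
) -> FunctionalDataset:
    """Read curves from a long-format table with columns ``id,t,y``.

    The optional covariate table has columns ``id,<name1>,...,<nameR>`` with
    exactly one row per distinct curve id.  Rows may arrive in any time order;
    output times are sorted ascending within each curve.  Duplicate ``(id, t)``
    pairs, missing columns, non-numeric entries and id mismatches between the
    two tables are errors reported with offending row numbers.
    """
    df = _read_table(curve_path)
    missing = [c for c in ("id", "t", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{curve_path}: missing required column(s) {missing}")
    for col in ("t", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(df.index[df[col].isna()])
        if len(bad):
            rows = [int(i) + 2 for i in bad[:10]]  # 1-based + header line
            raise ValueError(f"{curve_path}: non-numeric '{col}' at file row(s) {rows}")
        df[col] = coerced
    dup = df.duplicated(subset=["id", "t"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:10]]
        raise ValueError(f"{curve_path}: duplicate (id, t) pairs at file row(s) {rows}")

    ids = list(pd.unique(df["id"]))
    times, values = [], []
    for cid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("t")
        times.append(grp["t"].to_numpy(dtype=float))
        values.append(grp["y"].to_numpy(dtype=float))

    if covariate_path is None:
        X = np.empty((len(ids), 0))
    else:
        cov = _read_table(covariate_path)
        if "id" not in cov.columns:
            raise ValueError(f"{covariate_path}: missing required column 'id'")
        if cov["id"].duplicated().any():
            rows = [int(i) + 2 for i in cov.index[cov["id"].duplicated()][:10]]
            raise ValueError(f"{covariate_path}: duplicate id at file row(s) {rows}")
        cov_ids = set(cov["id"])
        missing_ids = [i for i in ids if i not in cov_ids]
        extra_ids = [i for i in cov["id"] if i not in set(ids)]
        if missing_ids or extra_ids:
            raise ValueError(
                f"id mismatch between tables: missing covariates for {missing_ids[:5]}, "
                f"covariates without curves {extra_ids[:5]}"
            )
        cov = cov.set_index("id").loc[ids]
        for col in cov.columns:
            coerced = pd.to_numeric(cov[col], errors="coerce")
            if coerced.isna().any():
                raise ValueError(f"{covariate_path}: non-numeric entries in column '{col}'")
            cov[col] = coerced
        X = cov.to_numpy(dtype=float)
    return FunctionalDataset(curve_ids=ids, times=times, values=values, covariates=X)


def write_long_table(
    dataset: FunctionalDataset,
    curve_path: str | Path,
    covariate_path: str | Path | None = None,
    covariate_names: Sequence[str] | None = None,
) -> None:
    """Write a dataset to the long-format CSV/TSV tables read_long_table reads."""
    rows = []
    for cid, t, y in zip(dataset.curve_ids, dataset.times, dataset.values):
        for tj, yj in zip(t, y):
            rows.append((cid, repr(float(tj)), repr(float(yj))))
    df = pd.DataFrame(rows, columns=["id", "t", "y"])
    sep = "\t" if Path(curve_path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(curve_path, sep=sep, index=False)
    if covariate_path is not None and dataset.n_covariates > 0:
        names = covariate_names or [f"x{r + 1}" for r in range(dataset.n_covariates)]
        cov = pd.DataFrame(
            {"id": dataset.curve_ids}
            | {nm: [repr(float(v)) for v in dataset.covariates[:, r]] for r, nm in enumerate(names)}
        )
        sep = "\t" if Path(covariate_path).suffix.lower() in {".tsv", ".tab"} else ","
        cov.to_csv(covariate_path, sep=sep, index=False)


def standardize_covariates(X_raw: np.ndarray) -> CovariateDesign:
    """Center and scale each covariate column to mean 0 and sample sd 1.

    A constant column is an error: after any affine rescaling it would place
    the all-ones vector inside the column space of the design, breaking the
    identifiability condition on the covariate design.
    """
    X = np.asarray(X_raw, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, r = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to standardize covariates")
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    const = np.where(scales == 0)[0]
    if const.size:
        raise ValueError(f"constant covariate column(s) at index {const.tolist()}")
    # exact idempotence for already-standardized columns
    centers = np.where(np.abs(centers) < 1e-12, 0.0, centers)
    scales = np.where(np.abs(scales - 1.0) < 1e-12, 1.0, scales)
    return CovariateDesign(X_std=(X - centers) / scales, centers=centers, scales=scales)


def _matrix_rank(A: np.ndarray) -> int:
    if A.size == 0:
        return 0
    s = np.linalg.svd(A, compute_uv=False)
    return int(np.sum(s > RANK_RTOL * s[0]))


def validate_inputs(
    dataset: FunctionalDataset, design: CovariateDesign | None, P: int
) -> ValidationReport:
    """Check the design conditions required for an identifiable fit.

    Checks: the standardized covariate matrix has full column rank R; the
    all-ones vector is not in its column space (rank([1|X]) = R+1); and every
    curve has n_i > P observation points.  Irregular within-curve grids only
    produce a warning, since the identifiability argument assumes regular
    sampling but estimation itself does not require it.
    """
    report = ValidationReport()
    X = design.X_std if design is not None else np.empty((dataset.n_curves, 0))
    R = X.shape[1]

    rank_x = _matrix_rank(X)
    report.checks["covariate_rank"] = rank_x == R
    report.details["covariate_rank"] = f"rank(X)={rank_x}, R={R}"

    ones = np.ones((dataset.n_curves, 1))
    rank_aug = _matrix_rank(np.hstack([ones, X]))
    report.checks["intercept_excluded"] = rank_aug == R + 1
    report.details["intercept_excluded"] = (
        f"rank([1|X])={rank_aug}, expected {R + 1}"
        if R
        else "no covariates; trivially satisfied"
    )

    n_i = dataset.n_points
    bad = [dataset.curve_ids[i] for i in np.where(n_i <= P)[0]]
    report.checks["points_exceed_basis"] = len(bad) == 0
    report.details["points_exceed_basis"] = (
        f"all n_i > P={P}" if not bad else f"curves with n_i <= P={P}: {bad[:5]}"
    )

    for cid, t in zip(dataset.curve_ids, dataset.times):
        if t.size >= 3:
            d = np.diff(t)
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
                report.warnings.append(
                    f"curve {cid!r}: irregular time grid (identifiability theory "
                    "assumes regular sampling)"
                )
    return report
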