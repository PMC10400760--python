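"""Data preparation: beta computation, age-correlation pre-filtering,
iterative outlier removal, and QC principal component analysis.

The pre-filter retains three CpG groups — strong positive age correlation,
strong negative age correlation, and near-zero correlation — mirroring the
feature-reduction step used before training methylation age clocks on
array data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_beta",
    "PrefilterResult",
    "prefilter_cpgs",
    "remove_outliers",
    "pca_qc",
    "pearson_by_row",
    "impute_missing",
]


def compute_beta(M, U):
    """Beta value from methylated (M) and unmethylated (U) intensities:
    max(M,0) / (max(M,0) + max(U,0) + 100).

    The +100 offset regularizes low-intensity probes and keeps the result
    strictly below 1.  Accepts scalars or arrays.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise ValueError("intensities must be finite")
    m = np.maximum(M, 0.0)
    u = np.maximum(U, 0.0)
    beta = m / (m + u + 100.0)
    return beta if beta.ndim else float(beta)


def impute_missing(beta: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG mean imputation of missing betas (logged)."""
    n_missing = int(beta.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputing %d missing beta values with per-CpG means", n_missing)
        row_means = beta.mean(axis=1)
        beta = beta.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return beta


def pearson_by_row(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``values`` against ``y`` (vectorized).

    Rows with zero variance get NaN.
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    xc = values - values.mean(axis=1, keepdims=True)
    num = xc @ yc
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


@dataclass
class PrefilterResult:
    """Outcome of the three-group CpG pre-filter."""

    pos_set: list[str]
    neg_set: list[str]
    null_set: list[str]
    r_by_cpg: pd.Series

    @property
    def selected(self) -> list[str]:
        return list(self.pos_set) + list(self.neg_set) + list(self.null_set)


def prefilter_cpgs(
    beta: pd.DataFrame,
    ages,
    n_pos: int = 1000,
    n_neg: int = 1000,
    eps_null: float = 0.02,
    n_null: int = 500,
) -> PrefilterResult:
    """Select CpGs with strong positive, strong negative, or near-zero age
    correlation.

    pos_set: top ``n_pos`` by r descending; neg_set: top ``n_neg`` by r
    ascending; null_set: up to ``n_null`` CpGs with smallest \\|r\\| subject to
    \\|r\\| <= ``eps_null``, drawn from CpGs not already taken.  Ties break on
    cpg_id so the result is independent of input row order.
    """
    ages = np.asarray(ages, dtype=float)
    if beta.shape[1] < 3:
        raise ValueError("need >= 3 samples to compute correlations")
    if n_pos + n_neg + n_null > beta.shape[0]:
        raise ValueError(
            f"requested {n_pos + n_neg + n_null} CpGs but only {beta.shape[0]} available"
        )
    r = pd.Series(pearson_by_row(beta.to_numpy(dtype=float), ages), index=beta.index)
    order = pd.DataFrame({"r": r, "cpg": r.index.astype(str)})
    usable = order.dropna(subset=["r"])

    by_desc = usable.sort_values(["r", "cpg"], ascending=[False, True])
    pos_set = list(by_desc.index[:n_pos])
    by_asc = usable.sort_values(["r", "cpg"], ascending=[True, True])
    neg_set = [c for c in by_asc.index[: n_neg + n_pos] if c not in set(pos_set)][:n_neg]

    taken = set(pos_set) | set(neg_set)
    null_pool = usable.loc[[c for c in usable.index if c not in taken]].copy()
    null_pool = null_pool[null_pool["r"].abs() <= eps_null]
    null_pool["absr"] = null_pool["r"].abs()
    null_pool = null_pool.sort_values(["absr", "cpg"])
    null_set = list(null_pool.index[:n_null])
    if len(null_set) < n_null:
        logger.warning(
            "only %d of %d requested null CpGs satisfy |r| <= %g",
            len(null_set), n_null, eps_null,
        )
    return PrefilterResult(pos_set, neg_set, null_set, r)


def remove_outliers(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    clock_builder,
    abs_resid_years: float = 30.0,
    max_iter: int = 3,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop samples whose preliminary-clock age prediction is off
    by more than ``abs_resid_years``.

    ``clock_builder(beta, sheet)`` must return an object with a
    ``predict(beta)`` method.  Intended to catch platemap/labeling errors,
    not biological variation, hence the generous default threshold.

    Returns (kept sample ids, report) where the report lists each removed
    sample with the iteration and residual at removal.
    """
    if not abs_resid_years > 0:
        raise ValueError("abs_resid_years must be > 0")
    kept = list(sheet["sample_id"])
    removed_rows = []
    for iteration in range(1, max_iter + 1):
        sub_sheet = sheet[sheet["sample_id"].isin(kept)].reset_index(drop=True)
        sub_beta = beta[sub_sheet["sample_id"]]
        model = clock_builder(sub_beta, sub_sheet)
        pred = np.asarray(model.predict(sub_beta), dtype=float)
        resid = pred - sub_sheet["age"].to_numpy(dtype=float)
        bad = np.abs(resid) > abs_resid_years
        if not bad.any():
            break
        for sid, res in zip(sub_sheet.loc[bad, "sample_id"], resid[bad]):
            removed_rows.append(
                {"sample_id": sid, "iteration": iteration, "residual_years": res}
            )
        kept = list(sub_sheet.loc[~bad, "sample_id"])
        if not kept:
            raise ValueError("outlier removal discarded every sample; check threshold")
    report = pd.DataFrame(
        removed_rows, columns=["sample_id", "iteration", "residual_years"]
    )
    return kept, report


def pca_qc(beta: pd.DataFrame, n_components: int = 5):
    """QC PCA of the sample x CpG matrix (columns mean-centered) via SVD.

    Returns (variance_explained, scores) where scores is a DataFrame of
    sample coordinates on the first ``n_components`` PCs.  Used to check
    that sex, not batch, dominates the leading components.
    """
    X = beta.to_numpy(dtype=float).T  # samples x CpGs
    n, p = X.shape
    if n == 0 or p == 0:
        raise ValueError("empty matrix")
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    var_explained = (s**2) / total if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components],
        index=beta.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return var_explained[:n_components], scores
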