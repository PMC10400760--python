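"""Nonlinear age trajectories of methylation.

LOWESS (locally weighted scatterplot smoothing: tricube-kernel local linear
regression with optional bisquare robustifying iterations) applied to
individual CpGs and to mean methylation within a chromatin state or PRC
layer, together with the Pearson r / p reported on the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "lowess",
    "state_mean_methylation",
    "TrajectoryReport",
    "trajectory_report",
]


def lowess(x, y, frac: float = 2.0 / 3.0, robust_iters: int = 3,
           weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted linear regression (Cleveland's LOWESS).

    For each point, a local linear fit is computed over the ``int(frac*n)``
    nearest neighbors with tricube distance weights; ``robust_iters``
    bisquare reweighting passes down-weight outliers.  Deterministic.

    Returns (x_sorted, fitted) over the sorted distinct x values (y values
    at duplicated x are averaged first).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need >= 5 points")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # collapse duplicated x to their mean y
    ux, inv, counts = np.unique(xs, return_inverse=True, return_counts=True)
    uy = np.bincount(inv, weights=ys) / counts
    n = len(ux)
    k = max(int(frac * n), 2)
    k = min(k, n)
    if k < 2:
        raise ValueError("window smaller than the 2-point local-linear minimum")

    delta = np.ones(n)
    fitted = np.empty(n)
    for it in range(robust_iters + 1):
        lo = 0
        for i in range(n):
            # slide the k-window to keep the nearest neighbors of ux[i]
            while lo + k < n and ux[lo + k] - ux[i] < ux[i] - ux[lo]:
                lo += 1
            hi = lo + k
            xw = ux[lo:hi]
            yw = uy[lo:hi]
            h = max(ux[i] - xw[0], xw[-1] - ux[i])
            if h <= 0:
                fitted[i] = np.average(yw, weights=delta[lo:hi]) \
                    if delta[lo:hi].sum() > 0 else yw.mean()
                continue
            d = np.abs(xw - ux[i]) / h
            w = np.clip(1.0 - d**3, 0.0, None) ** 3
            w *= delta[lo:hi]
            sw = w.sum()
            if sw <= 0:
                fitted[i] = yw.mean()
                continue
            xm = (w @ xw) / sw
            ym = (w @ yw) / sw
            sxx = w @ (xw - xm) ** 2
            if sxx <= 1e-12 * h**2:
                fitted[i] = ym
            else:
                b = (w @ ((xw - xm) * (yw - ym))) / sxx
                fitted[i] = ym + b * (ux[i] - xm)
        if it == robust_iters:
            break
        resid = uy - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        delta = np.clip(1.0 - u**2, 0.0, None) ** 2
    return ux, fitted


def state_mean_methylation(beta: pd.DataFrame, annotation: pd.DataFrame,
                           target: str) -> pd.Series:
    """Unweighted per-sample mean beta over the CpGs of a chromatin state or
    PRC layer (missing betas excluded per sample)."""
    ann = annotation.set_index("cpg_id")
    if target in ("PRC1", "PRC2"):
        col = target.lower()
        if col not in ann.columns:
            raise KeyError(f"annotation lacks {col} flags")
        cpgs = ann.index[ann[col].astype(int) == 1]
    else:
        cpgs = ann.index[ann["state"] == target]
    cpgs = [c for c in cpgs if c in beta.index]
    if len(cpgs) == 0:
        raise ValueError(f"no CpGs for target {target!r}")
    return beta.loc[cpgs].mean(axis=0, skipna=True)


@dataclass
class TrajectoryReport:
    """Age trajectory of one CpG or state: raw-value Pearson r/p plus the
    LOWESS curve evaluated at the distinct observed ages."""

    target_label: str
    n: int
    pearson_r: float
    p: float
    log10_p: float
    smooth_curve: pd.DataFrame  # columns: age, fitted


def trajectory_report(beta: pd.DataFrame, sheet: pd.DataFrame, targets,
                      annotation: pd.DataFrame | None = None,
                      frac: float = 2.0 / 3.0, robust_iters: int = 3
                      ) -> list[TrajectoryReport]:
    """LOWESS trajectory and raw-value correlation per target.

    A target is a CpG id (a row of ``beta``) or, when ``annotation`` is
    given, a chromatin-state name or "PRC1"/"PRC2" (mean methylation over
    the member CpGs).
    """
    ages = sheet["age"].to_numpy(dtype=float)
    reports = []
    for target in targets:
        if target in beta.index:
            values = beta.loc[target, sheet["sample_id"]].to_numpy(dtype=float)
        elif annotation is not None:
            values = state_mean_methylation(
                beta[sheet["sample_id"]], annotation, target).to_numpy()
        else:
            raise KeyError(f"target {target!r} not in the beta matrix and no "
                           "annotation given")
        ok = np.isfinite(values) & np.isfinite(ages)
        n = int(ok.sum())
        r, p = stats.pearsonr(ages[ok], values[ok])
        with np.errstate(divide="ignore"):
            log10_p = float(np.log10(p)) if p > 0 else -320.0
        ax, fit = lowess(ages[ok], values[ok], frac=frac,
                         robust_iters=robust_iters)
        curve = pd.DataFrame({"age": ax, "fitted": fit})
        reports.append(TrajectoryReport(target, n, float(r), float(p),
                                        log10_p, curve))
    return reports
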