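"""Epigenetic age acceleration and its association machinery.

Age acceleration (AgeAccel) is the raw residual of DNAm age regressed on
chronological age, so it is uncorrelated with age by construction.  Its
downstream associations are assessed with:

* Cox proportional-hazards regression for all-cause mortality (Newton
  iterations on the partial likelihood, Breslow handling of tied event
  times), fitted within strata and combined by inverse-variance weighted
  fixed-effect meta-analysis;
* biweight midcorrelation (bicor) — a median/MAD-based robust correlation —
  against clinical biomarkers, computed per stratum, Fisher-z transformed,
  meta-combined and back-transformed to the bicor scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "compute_age_accel",
    "CoxFit",
    "fit_cox",
    "MetaEstimate",
    "meta_fixed_effect",
    "bicor",
    "stratified_bicor_meta",
    "ConvergenceFlag",
]


def compute_age_accel(dnam_age, age, sample_ids=None) -> pd.Series:
    """Raw residuals of OLS of DNAm age on chronological age (with intercept).

    The residuals have mean zero and zero Pearson correlation with age to
    numerical precision.
    """
    dnam_age = np.asarray(dnam_age, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(dnam_age) != len(age):
        raise ValueError("dnam_age and age must have equal length")
    if len(age) < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; acceleration undefined")
    A = np.column_stack([np.ones_like(age), age])
    coef, *_ = np.linalg.lstsq(A, dnam_age, rcond=None)
    resid = dnam_age - A @ coef
    index = sample_ids if sample_ids is not None else np.arange(len(age))
    return pd.Series(resid, index=index, name="accel")


class ConvergenceFlag(UserWarning):
    """Raised as a warning when a Cox fit shows monotone-likelihood behavior."""


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Breslow ties)."""

    covariates: list[str]
    log_hr: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    n: int
    n_events: int
    log_likelihood: float
    stratum_label: str = ""

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.log_hr)

    def summary(self) -> str:
        lines = [
            f"Cox proportional hazards ({self.stratum_label or 'all samples'})",
            f"n = {self.n}, events = {self.n_events}, "
            f"log-likelihood = {self.log_likelihood:.4f}",
            f"{'covariate':<16}{'log HR':>10}{'HR':>9}{'SE':>9}{'z':>8}{'p':>12}",
        ]
        for c in self.covariates:
            lines.append(
                f"{c:<16}{self.log_hr[c]:>10.4f}{np.exp(self.log_hr[c]):>9.4f}"
                f"{self.se[c]:>9.4f}{self.z[c]:>8.2f}{self.p[c]:>12.3g}"
            )
        return "\n".join(lines)


def cox_partial_loglik(beta, time, event, X):
    """Breslow partial log-likelihood, gradient and Hessian at ``beta``."""
    order = np.argsort(-time, kind="stable")
    t, d, Xo = time[order], event[order], X[order]
    eta = Xo @ beta
    eta = eta - eta.max()  # overflow guard; constant shift cancels in ratios
    w = np.exp(eta)
    # running risk-set sums (descending time => cumulative)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xo, axis=0)
    p = X.shape[1]
    S2 = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # risk set at this time = everything up to index j-1
        dt = d[i:j].sum()
        if dt > 0:
            s0, s1, s2 = S0[j - 1], S1[j - 1], S2[j - 1]
            xbar = s1 / s0
            ll += eta[i:j][d[i:j] == 1].sum() - dt * np.log(s0)
            grad += Xo[i:j][d[i:j] == 1].sum(axis=0) - dt * xbar
            hess -= dt * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, hess


def fit_cox(time, event, covariates, stratum_label: str = "",
            tol: float = 1e-8, max_iter: int = 60) -> CoxFit:
    """Cox regression by Newton-Raphson on the Breslow partial likelihood.

    ``covariates`` is a DataFrame (or 2-D array) of finite covariates.
    Convergence requires the gradient norm below ``tol``.  Monotone
    likelihood (perfect separation, diverging coefficients) triggers a
    :class:`ConvergenceFlag` warning rather than a silent return.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != len(time):
            X = X.T
        names = [f"x{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if event.sum() == 0:
        raise ValueError("no events; Cox model undefined")

    # scale-invariance: constant covariates get coefficient 0 and NaN SE
    sds = X.std(axis=0)
    active = sds > 0
    beta = np.zeros(int(active.sum()))
    Xa = X[:, active]
    ll, grad, hess = cox_partial_loglik(beta, time, event, Xa)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving to keep the likelihood increasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = cox_partial_loglik(cand, time, event, Xa)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    # monotone likelihood: the gradient vanishes only as |beta| -> inf, so a
    # huge finite coefficient (HR beyond e^10) marks separation
    if np.any(np.abs(beta) > 10):
        warnings.warn(
            "Cox coefficients diverging; monotone likelihood "
            "(perfect separation) suspected",
            ConvergenceFlag,
        )
    cov = np.full((len(names), len(names)), np.nan)
    try:
        info_inv = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        info_inv = np.full((len(beta), len(beta)), np.nan)
    full_beta = np.zeros(len(names))
    full_beta[active] = beta
    se = np.full(len(names), np.nan)
    diag = np.diag(info_inv)
    se_active = np.sqrt(np.where(diag > 0, diag, np.nan))
    se[active] = se_active
    with np.errstate(invalid="ignore", divide="ignore"):
        z = full_beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        covariates=names,
        log_hr=pd.Series(full_beta, index=names),
        se=pd.Series(se, index=names),
        z=pd.Series(z, index=names),
        p=pd.Series(p, index=names),
        n=len(time),
        n_events=int(event.sum()),
        log_likelihood=float(ll),
        stratum_label=stratum_label,
    )


@dataclass
class MetaEstimate:
    """Inverse-variance weighted fixed-effect meta-analysis result."""

    estimates: np.ndarray
    ses: np.ndarray
    combined: float
    combined_se: float
    z: float
    p: float

    def summary(self) -> str:
        return (
            f"fixed-effect meta of {len(self.estimates)} strata: "
            f"estimate = {self.combined:.4f} (SE {self.combined_se:.4f}), "
            f"z = {self.z:.2f}, p = {self.p:.3g}"
        )


def meta_fixed_effect(estimates, ses) -> MetaEstimate:
    """Combine per-stratum estimates with weights 1/se^2.

    combined = sum(w * theta) / sum(w); combined SE = 1/sqrt(sum(w));
    two-sided normal p value.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(estimates) == 0:
        raise ValueError("need >= 1 stratum")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be > 0")
    w = 1.0 / ses**2
    combined = float((w * estimates).sum() / w.sum())
    combined_se = float(1.0 / np.sqrt(w.sum()))
    z = combined / combined_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaEstimate(estimates, ses, combined, combined_se, float(z), p)


def _biweight_deviation(v: np.ndarray):
    """Tukey biweight-weighted deviations; None when the MAD vanishes."""
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return None
    u = (v - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (v - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors.

    Robust to gross outliers: observations more than 9 MADs from the median
    get zero weight.  Falls back to Pearson (with a logged warning) when a
    MAD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 observations")
    a = _biweight_deviation(x)
    b = _biweight_deviation(y)
    if a is None or b is None:
        logger.warning("zero MAD; falling back to Pearson correlation")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("constant vector; correlation undefined")
        return float(np.corrcoef(x, y)[0, 1])
    na = np.sqrt((a**2).sum())
    nb = np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        raise ValueError("all observations down-weighted to zero")
    return float(np.clip((a / na) @ (b / nb), -1.0, 1.0))


def stratified_bicor_meta(accel, variables: pd.DataFrame, strata_labels,
                          min_stratum_n: int = 4) -> pd.DataFrame:
    """Per-variable robust correlation with age acceleration, stratified and
    meta-analyzed.

    Within each stratum with >= ``min_stratum_n`` complete observations the
    bicor is computed, Fisher-z transformed (SE 1/sqrt(n-3)), combined by
    fixed-effect meta-analysis and back-transformed.  Smaller strata are
    skipped with a log entry.

    Returns a table with columns variable, stratum_count, meta_bicor, z, p.
    """
    accel = np.asarray(accel, dtype=float)
    strata_labels = np.asarray(strata_labels)
    rows = []
    for var in variables.columns:
        vals = variables[var].to_numpy(dtype=float)
        est, ses = [], []
        for lab in pd.unique(strata_labels):
            m = (strata_labels == lab) & np.isfinite(vals) & np.isfinite(accel)
            n = int(m.sum())
            if n < max(min_stratum_n, 4):
                logger.info("stratum %s skipped for %s (n=%d)", lab, var, n)
                continue
            b = bicor(accel[m], vals[m])
            b = float(np.clip(b, -1 + 1e-12, 1 - 1e-12))
            est.append(np.arctanh(b))
            ses.append(1.0 / np.sqrt(n - 3))
        if not est:
            raise ValueError(f"no usable strata for variable {var!r}")
        meta = meta_fixed_effect(est, ses)
        rows.append(
            {
                "variable": var,
                "stratum_count": len(est),
                "meta_bicor": float(np.tanh(meta.combined)),
                "z": meta.z,
                "p": meta.p,
            }
        )
    return pd.DataFrame(rows)
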