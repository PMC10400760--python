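"""Methylation age clocks with centenarian up-weighting.

Two estimators are provided, both presented as model objects whose ``fit()``
returns a results object (coefficients, diagnostics, ``summary()``,
``predict``):

* :class:`ElasticNetClock` — weighted elastic net solved by cyclic
  coordinate descent with warm starts along a log-spaced penalty path,
  mixing parameter ``alpha`` (default 0.5) and the penalty chosen by
  weighted cross-validation.
* :class:`NeuralNetClock` — a small fully connected ReLU regressor trained
  by full-batch Adam on a weighted squared loss with a fixed, untuned
  architecture and epoch budget.

Samples aged >= 100 years receive a training weight of 10 by default
(:func:`sample_weights`), which counteracts the regression-to-the-mean
underestimation of centenarian ages that unweighted clocks exhibit.

The elastic-net objective, with weights w and Sigma w normalized to 1, is

    (1/2) sum_i w_i (y_i - b0 - x_i' b)^2
        + lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

Features are standardized with weighted means/SDs inside the fit; the
standardization constants are stored so a serialized clock is portable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "sample_weights",
    "AgeStratum",
    "DEFAULT_STRATA",
    "ElasticNetClock",
    "NeuralNetClock",
    "ClockResults",
    "CVResult",
    "fit_weighted_elastic_net",
    "select_lambda_cv",
    "fit_mlp",
    "predict_age",
    "crossvalidate_20fold",
    "stratified_metrics",
    "kkt_violations",
    "load_clock",
]


def sample_weights(ages, centenarian_weight: float = 10.0) -> np.ndarray:
    """Training weights: ``centenarian_weight`` for ages >= 100 (boundary
    inclusive), 1 otherwise."""
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    if centenarian_weight < 1:
        raise ValueError("centenarian_weight must be >= 1")
    return np.where(ages >= 100.0, float(centenarian_weight), 1.0)


@dataclass(frozen=True)
class AgeStratum:
    label: str
    min_age: float
    max_age: float

    def __post_init__(self):
        if not self.min_age < self.max_age:
            raise ValueError(f"stratum {self.label}: min_age must be < max_age")

    def mask(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return (ages >= self.min_age) & (ages <= self.max_age)


DEFAULT_STRATA = (
    AgeStratum("40plus", 40.0, math.inf),
    AgeStratum("80plus", 80.0, math.inf),
    AgeStratum("100plus", 100.0, math.inf),
)


# ---------------------------------------------------------------------------
# weighted elastic net by cyclic coordinate descent
# ---------------------------------------------------------------------------

def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_path_kernel(G, c, v, alpha, lambdas, thresh, max_iter):
    """Coordinate descent over a descending penalty path with warm starts.

    Works on the weighted Gram matrix G = X'WX, covariance c = X'Wy and
    feature variances v (W normalized to sum 1).  Active-set iterations are
    sandwiched between full passes.  Convergence follows the standard
    path-solver criterion: a pass converges when max_j v_j * (delta b_j)^2
    falls below ``thresh`` (the caller scales ``thresh`` by the null
    deviance).  Returns (coefficient matrix, status) with status 0 on
    convergence, 1 on hitting the pass cap.
    """
    p = len(c)
    n_lam = len(lambdas)
    coefs = np.zeros((n_lam, p))
    b = np.zeros(p)
    q = np.zeros(p)  # G @ b, maintained incrementally
    active = np.zeros(p, dtype=np.bool_)
    status = 0
    for il in range(n_lam):
        lam = lambdas[il]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        n_iter = 0
        while True:
            # full pass over all coordinates
            max_d = 0.0
            for j in range(p):
                bj = b[j]
                rho = c[j] - q[j] + v[j] * bj
                if rho > l1:
                    z = rho - l1
                elif rho < -l1:
                    z = rho + l1
                else:
                    z = 0.0
                bnew = z / (v[j] + l2) if z != 0.0 else 0.0
                d = bnew - bj
                if d != 0.0:
                    for i in range(p):
                        q[i] += G[i, j] * d
                    b[j] = bnew
                    crit = v[j] * d * d
                    if crit > max_d:
                        max_d = crit
                active[j] = b[j] != 0.0
            n_iter += 1
            if max_d < thresh:
                break
            # active-set passes until converged on the active set
            while True:
                max_d = 0.0
                for j in range(p):
                    if not active[j]:
                        continue
                    bj = b[j]
                    rho = c[j] - q[j] + v[j] * bj
                    if rho > l1:
                        z = rho - l1
                    elif rho < -l1:
                        z = rho + l1
                    else:
                        z = 0.0
                    bnew = z / (v[j] + l2) if z != 0.0 else 0.0
                    d = bnew - bj
                    if d != 0.0:
                        for i in range(p):
                            q[i] += G[i, j] * d
                        b[j] = bnew
                        crit = v[j] * d * d
                        if crit > max_d:
                            max_d = crit
                n_iter += 1
                if max_d < thresh or n_iter >= max_iter:
                    break
            if n_iter >= max_iter:
                status = 1
                break
        coefs[il] = b
    return coefs, status


try:  # jit-compiled kernel; the pure-python path is identical math
    from numba import njit as _njit

    _cd_path_fast = _njit(cache=True, fastmath=False)(_cd_path_kernel)
except ImportError:  # pragma: no cover
    _cd_path_fast = _cd_path_kernel


def _cd_solve(G, c, v, alpha, lambdas, tol, max_iter, dev_null=1.0):
    """Run the path kernel with the tolerance scaled by the null deviance
    (weighted variance of the centered response), glmnet-style."""
    coefs, status = _cd_path_fast(
        np.ascontiguousarray(G, dtype=np.float64),
        np.ascontiguousarray(c, dtype=np.float64),
        np.ascontiguousarray(v, dtype=np.float64),
        float(alpha),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        float(tol) * max(float(dev_null), 1e-300),
        int(max_iter),
    )
    if status != 0:
        raise RuntimeError(
            f"coordinate descent did not converge within {max_iter} passes")
    return coefs


def _weighted_design(X, y, weights, standardize):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    wn = w / w.sum()
    xm = wn @ X
    ym = float(wn @ y)
    Xc = X - xm
    if standardize:
        sd = np.sqrt(wn @ (Xc**2))
        if np.any(sd <= 0):
            bad = int(np.sum(sd <= 0))
            raise ValueError(f"{bad} zero-variance feature(s); drop them before fitting")
        Xs = Xc / sd
    else:
        sd = np.ones(X.shape[1])
        Xs = Xc
    yc = y - ym
    return Xs, yc, wn, xm, sd, ym


def lambda_max(Xs, yc, wn, alpha) -> float:
    """Smallest penalty at which the solution is all-zero."""
    grad = (Xs * wn[:, None]).T @ yc
    a = max(alpha, 1e-3)  # glmnet-style floor for the pure-ridge case
    return float(np.max(np.abs(grad)) / a)


def make_lambda_grid(lmax: float, n_lambdas: int = 100,
                     min_ratio: float = 1e-4) -> np.ndarray:
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def kkt_violations(Xs, yc, wn, alpha, lam, coef) -> float:
    """Max violation of the elastic-net stationarity (KKT) conditions.

    For active j: (1/Sw) sum_i w_i x_ij r_i - lam*(1-alpha)*b_j must equal
    lam*alpha*sign(b_j); for inactive j its magnitude must not exceed
    lam*alpha.  Returns the largest violation in the same units as lambda.
    """
    r = yc - Xs @ coef
    g = (Xs * wn[:, None]).T @ r - lam * (1.0 - alpha) * coef
    viol = np.where(
        coef != 0.0,
        np.abs(g - lam * alpha * np.sign(coef)),
        np.maximum(np.abs(g) - lam * alpha, 0.0),
    )
    return float(viol.max()) if len(viol) else 0.0


# ---------------------------------------------------------------------------
# results object shared by both clock kinds
# ---------------------------------------------------------------------------

@dataclass
class ClockResults:
    """Fitted age clock.

    For an elastic net, ``coef`` is a sparse-by-construction pandas Series on
    the standardized-feature scale; prediction is
    intercept + sum_j coef_j * (x_j - mean_j) / sd_j.
    For a neural net, ``layers`` holds (W, b) pairs applied to the
    standardized features, with the output rescaled by ``y_scale``/``y_mean``.
    """

    kind: str
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    intercept: float
    alpha: float | None = None
    lambda_: float | None = None
    coef: pd.Series | None = None
    layers: list | None = None
    y_mean: float | None = None
    y_scale: float | None = None
    training_age_min: float | None = None
    centenarian_weight: float | None = None
    seed: int | None = None
    n_train: int | None = None
    cv_path: pd.DataFrame | None = None

    # -- prediction --------------------------------------------------------
    def _design(self, beta) -> np.ndarray:
        """Samples x features matrix for the model's features.

        Accepts a CpG x sample DataFrame (features in the index), a
        samples x features DataFrame (features in the columns), or a bare
        samples x features array.
        """
        if isinstance(beta, pd.DataFrame):
            if set(self.feature_names).issubset(beta.index):
                X = beta.loc[self.feature_names].to_numpy(dtype=float).T
            elif set(self.feature_names).issubset(beta.columns):
                X = beta[self.feature_names].to_numpy(dtype=float)
            else:
                missing = sorted(
                    set(self.feature_names) - set(beta.index) - set(beta.columns)
                )[:5]
                raise KeyError(f"matrix lacks required model CpGs, e.g. {missing}")
        else:
            X = np.asarray(beta, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}"
                )
        if np.isnan(X).any():
            raise ValueError("NaN feature values; impute before prediction")
        return X

    def predict(self, beta) -> np.ndarray:
        X = self._design(beta)
        Z = (X - self.feature_means) / self.feature_sds
        if self.kind == "elastic_net":
            return self.intercept + Z @ self.coef.to_numpy()
        out = Z
        for i, (W, b) in enumerate(self.layers):
            out = out @ W + b
            if i < len(self.layers) - 1:
                out = np.maximum(out, 0.0)
        return self.y_mean + self.y_scale * out[:, 0]

    # -- reporting ---------------------------------------------------------
    @property
    def n_nonzero(self) -> int:
        if self.kind == "elastic_net":
            return int((self.coef.to_numpy() != 0).sum())
        return sum(W.size + b.size for W, b in self.layers)

    def summary(self) -> str:
        lines = [
            "Methylation age clock",
            "=" * 44,
            f"kind:                {self.kind}",
            f"features:            {len(self.feature_names)}",
            f"intercept (years):   {self.intercept:.4f}",
            f"training n:          {self.n_train}",
            f"training age min:    {self.training_age_min}",
            f"centenarian weight:  {self.centenarian_weight}",
        ]
        if self.kind == "elastic_net":
            lines += [
                f"alpha (mixing):      {self.alpha}",
                f"lambda (penalty):    {self.lambda_:.6g}",
                f"nonzero CpGs:        {self.n_nonzero}",
            ]
            top = self.coef[self.coef != 0].abs().sort_values(ascending=False).head(10)
            if len(top):
                lines.append("largest |weights| (standardized scale):")
                for name in top.index:
                    lines.append(f"  {name:<14s} {self.coef[name]:+.4f}")
        else:
            shape = " -> ".join(str(W.shape[0]) for W, _ in self.layers)
            lines.append(f"layer inputs:        {shape} -> 1")
            lines.append(f"trainable params:    {self.n_nonzero}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, outdir) -> None:
        """JSON metadata + CSV coefficients (first row __intercept__); network
        layers as flat JSON arrays."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind,
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "seed": self.seed,
            "training_age_min": self.training_age_min,
            "centenarian_weight": self.centenarian_weight,
            "intercept": self.intercept,
            "n_train": self.n_train,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "feature_names": list(self.feature_names),
            "feature_means": list(map(float, self.feature_means)),
            "feature_sds": list(map(float, self.feature_sds)),
        }
        if self.kind == "neural_net":
            meta["layers"] = [
                {"W": W.ravel().tolist(), "b": b.tolist(), "shape": list(W.shape)}
                for W, b in self.layers
            ]
        (outdir / "clock.json").write_text(json.dumps(meta, indent=1))
        if self.kind == "elastic_net":
            rows = [{"cpg_id": "__intercept__", "weight": self.intercept}]
            rows += [
                {"cpg_id": k, "weight": v}
                for k, v in self.coef.items()
                if v != 0.0
            ]
            pd.DataFrame(rows).to_csv(
                outdir / "coefficients.csv", index=False, float_format="%.17g"
            )

    @classmethod
    def load(cls, outdir) -> "ClockResults":
        outdir = Path(outdir)
        meta = json.loads((outdir / "clock.json").read_text())
        res = cls(
            kind=meta["kind"],
            feature_names=meta["feature_names"],
            feature_means=np.array(meta["feature_means"]),
            feature_sds=np.array(meta["feature_sds"]),
            intercept=meta["intercept"],
            alpha=meta["alpha"],
            lambda_=meta["lambda"],
            y_mean=meta["y_mean"],
            y_scale=meta["y_scale"],
            training_age_min=meta["training_age_min"],
            centenarian_weight=meta["centenarian_weight"],
            seed=meta["seed"],
            n_train=meta["n_train"],
        )
        if meta["kind"] == "elastic_net":
            tab = pd.read_csv(outdir / "coefficients.csv")
            coef = pd.Series(0.0, index=meta["feature_names"])
            for _, row in tab.iterrows():
                if row["cpg_id"] != "__intercept__":
                    coef[row["cpg_id"]] = row["weight"]
            res.coef = coef
        else:
            res.layers = [
                (np.array(d["W"]).reshape(d["shape"]), np.array(d["b"]))
                for d in meta["layers"]
            ]
        return res


def load_clock(outdir) -> ClockResults:
    return ClockResults.load(outdir)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class _ClockModelBase:
    """Shared construction: accepts a CpG x sample beta DataFrame plus an age
    vector, or a samples x features design directly."""

    def __init__(self, beta, ages, weights=None, centenarian_weight=None,
                 training_age_min=None, seed: int = 0):
        if isinstance(beta, pd.DataFrame):
            self.feature_names = list(beta.index.astype(str))
            X = beta.to_numpy(dtype=float).T
        else:
            X = np.asarray(beta, dtype=float)
            self.feature_names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(ages, dtype=float)
        if X.shape[0] != len(y):
            raise ValueError(
                f"{X.shape[0]} samples in matrix vs {len(y)} ages; for a "
                "DataFrame the CpGs must be the index and samples the columns"
            )
        if weights is None and centenarian_weight is not None:
            weights = sample_weights(y, centenarian_weight)
        self.X, self.y = X, y
        self.weights = None if weights is None else np.asarray(weights, float)
        self.centenarian_weight = centenarian_weight
        self.training_age_min = training_age_min
        self.seed = seed

    @classmethod
    def from_cohort(cls, beta: pd.DataFrame, sheet: pd.DataFrame,
                    training_age_min: float = 40.0,
                    centenarian_weight: float = 10.0, seed: int = 0, **kwargs):
        """Restrict to samples aged >= training_age_min and apply the
        centenarian weighting rule."""
        keep = sheet["age"].to_numpy(dtype=float) >= training_age_min
        sub = sheet.loc[keep]
        return cls(
            beta[sub["sample_id"]],
            sub["age"].to_numpy(dtype=float),
            centenarian_weight=centenarian_weight,
            training_age_min=training_age_min,
            seed=seed,
            **kwargs,
        )


class ElasticNetClock(_ClockModelBase):
    """Weighted elastic-net age clock.

    Parameters
    ----------
    beta, ages, weights : data (see :class:`_ClockModelBase`)
    alpha : elastic-net mixing parameter in [0, 1] (1 = lasso); default 0.5
    lambda_grid : descending penalty grid; default 100 log-spaced values from
        lambda_max down to 1e-4 * lambda_max
    standardize : standardize features with weighted mean/SD (default True)
    """

    kind = "elastic_net"

    def __init__(self, beta, ages, weights=None, alpha: float = 0.5,
                 lambda_grid=None, n_lambdas: int = 100,
                 lambda_min_ratio: float = 1e-4, standardize: bool = True,
                 tol: float = 1e-7, max_iter: int = 100_000,
                 centenarian_weight=None, training_age_min=None, seed: int = 0):
        super().__init__(beta, ages, weights, centenarian_weight,
                         training_age_min, seed)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        self.alpha = alpha
        self.lambda_grid = None if lambda_grid is None else np.asarray(
            lambda_grid, dtype=float)
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ValueError("empty lambda grid")
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    def _prepared(self):
        return _weighted_design(self.X, self.y, self.weights, self.standardize)

    def _grid(self, Xs, yc, wn):
        if self.lambda_grid is not None:
            return self.lambda_grid
        lmax = lambda_max(Xs, yc, wn, self.alpha)
        return make_lambda_grid(lmax, self.n_lambdas, self.lambda_min_ratio)

    def path(self):
        """Full coordinate-descent path: (lambdas, coefficient matrix)."""
        Xs, yc, wn, xm, sd, ym = self._prepared()
        lambdas = self._grid(Xs, yc, wn)
        G = (Xs * wn[:, None]).T @ Xs
        c = (Xs * wn[:, None]).T @ yc
        coefs = _cd_solve(G, c, np.diag(G).copy(), self.alpha, lambdas,
                          self.tol, self.max_iter, dev_null=wn @ yc**2)
        return lambdas, coefs

    def select_lambda(self, n_folds: int = 5, seed: int | None = None):
        """Penalty minimizing mean weighted out-of-fold squared error.

        Returns (lambda, cv table).  Ties go to the larger (sparser) lambda.
        """
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        n = len(self.y)
        w = np.ones(n) if self.weights is None else self.weights
        Xs_all, yc_all, wn_all, *_ = _weighted_design(
            self.X, self.y, self.weights, self.standardize)
        lambdas = self._grid(Xs_all, yc_all, wn_all)
        if len(lambdas) == 1:
            return float(lambdas[0]), pd.DataFrame(
                {"lambda": lambdas, "cv_mse": [np.nan]})
        folds = np.array_split(rng.permutation(n), n_folds)
        sse = np.zeros(len(lambdas))
        wsum = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            Xs, yc, wn, xm, sd, ym = _weighted_design(
                self.X[mask], self.y[mask], w[mask], self.standardize)
            G = (Xs * wn[:, None]).T @ Xs
            c = (Xs * wn[:, None]).T @ yc
            coefs = _cd_solve(G, c, np.diag(G).copy(), self.alpha, lambdas,
                              self.tol, self.max_iter, dev_null=wn @ yc**2)
            Zt = (self.X[fold] - xm) / sd
            pred = ym + Zt @ coefs.T  # n_test x n_lambda
            err = (pred - self.y[fold][:, None]) ** 2
            sse += (w[fold][:, None] * err).sum(axis=0)
            wsum += w[fold].sum()
        cv_mse = sse / wsum
        best = int(np.argmin(cv_mse))  # argmin takes the first = largest lambda
        table = pd.DataFrame({"lambda": lambdas, "cv_mse": cv_mse})
        return float(lambdas[best]), table

    def fit(self, lambda_: float | str = "cv", cv_folds: int = 5,
            seed: int | None = None) -> ClockResults:
        """Fit at a fixed penalty, or select it by weighted CV
        (``lambda_='cv'``, the default)."""
        Xs, yc, wn, xm, sd, ym = self._prepared()
        cv_table = None
        if isinstance(lambda_, str):
            if lambda_ != "cv":
                raise ValueError("lambda_ must be a number or 'cv'")
            lam, cv_table = self.select_lambda(cv_folds, seed)
        else:
            lam = float(lambda_)
        lambdas = self._grid(Xs, yc, wn)
        path = lambdas[lambdas > lam]
        path = np.append(path, lam)  # warm-start down to the target
        G = (Xs * wn[:, None]).T @ Xs
        c = (Xs * wn[:, None]).T @ yc
        coefs = _cd_solve(G, c, np.diag(G).copy(), self.alpha, path,
                          self.tol, self.max_iter, dev_null=wn @ yc**2)
        coef = pd.Series(coefs[-1], index=self.feature_names)
        return ClockResults(
            kind=self.kind,
            feature_names=self.feature_names,
            feature_means=xm,
            feature_sds=sd,
            intercept=ym,
            alpha=self.alpha,
            lambda_=lam,
            coef=coef,
            training_age_min=self.training_age_min,
            centenarian_weight=self.centenarian_weight,
            seed=self.seed,
            n_train=len(self.y),
            cv_path=cv_table,
        )


class NeuralNetClock(_ClockModelBase):
    """Fully connected ReLU age regressor with weighted squared loss.

    The architecture (hidden sizes 64, 32), learning rate and epoch budget
    are fixed a priori and deliberately not tuned per data set; the model
    relies on over-parameterization rather than hyperparameter search.
    Training is full-batch Adam, deterministic given the seed.
    """

    kind = "neural_net"

    def __init__(self, beta, ages, weights=None, hidden_sizes=(64, 32),
                 learning_rate: float = 0.01, epochs: int = 1500,
                 centenarian_weight=None, training_age_min=None, seed: int = 0):
        super().__init__(beta, ages, weights, centenarian_weight,
                         training_age_min, seed)
        self.hidden_sizes = tuple(hidden_sizes)
        self.learning_rate = learning_rate
        self.epochs = epochs

    def fit(self) -> ClockResults:
        X, y = self.X, self.y
        n, p = X.shape
        w = np.ones(n) if self.weights is None else self.weights
        wn = w / w.sum()
        xm = wn @ X
        sd = np.sqrt(wn @ (X - xm) ** 2)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - xm) / sd
        ym = float(wn @ y)
        ysd = float(np.sqrt(wn @ (y - ym) ** 2))
        ysd = ysd if ysd > 0 else 1.0
        t = (y - ym) / ysd

        rng = np.random.default_rng(self.seed)
        sizes = [p, *self.hidden_sizes, 1]
        layers = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            W = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            layers.append([W, np.zeros(fan_out)])

        # Adam state
        m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
        v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        L = len(layers)

        for step in range(1, self.epochs + 1):
            acts = [Z]
            out = Z
            pre = []
            for i, (W, bias) in enumerate(layers):
                out = out @ W + bias
                pre.append(out)
                if i < L - 1:
                    out = np.maximum(out, 0.0)
                acts.append(out)
            resid = acts[-1][:, 0] - t
            loss = float(wn @ resid**2)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "NaN/inf training loss; lower the learning rate")
            delta = (2.0 * wn * resid)[:, None]
            for i in range(L - 1, -1, -1):
                gW = acts[i].T @ delta
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ layers[i][0].T) * (pre[i - 1] > 0)
                for k, g in enumerate((gW, gb)):
                    m[i][k] = b1 * m[i][k] + (1 - b1) * g
                    v[i][k] = b2 * v[i][k] + (1 - b2) * g**2
                    mhat = m[i][k] / (1 - b1**step)
                    vhat = v[i][k] / (1 - b2**step)
                    layers[i][k] -= lr * mhat / (np.sqrt(vhat) + eps)

        return ClockResults(
            kind=self.kind,
            feature_names=self.feature_names,
            feature_means=xm,
            feature_sds=sd,
            intercept=ym,
            layers=[(W.copy(), bias.copy()) for W, bias in layers],
            y_mean=ym,
            y_scale=ysd,
            training_age_min=self.training_age_min,
            centenarian_weight=self.centenarian_weight,
            seed=self.seed,
            n_train=n,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_weighted_elastic_net(X, y, weights=None, alpha: float = 0.5,
                             lambda_grid=None, lambda_: float | str = "cv",
                             standardize: bool = True, seed: int = 0,
                             **kwargs) -> ClockResults:
    model = ElasticNetClock(X, y, weights=weights, alpha=alpha,
                            lambda_grid=lambda_grid, standardize=standardize,
                            seed=seed, **kwargs)
    return model.fit(lambda_=lambda_)


def select_lambda_cv(X, y, weights=None, alpha: float = 0.5, lambda_grid=None,
                     n_folds: int = 5, seed: int = 0) -> float:
    model = ElasticNetClock(X, y, weights=weights, alpha=alpha,
                            lambda_grid=lambda_grid, seed=seed)
    lam, _ = model.select_lambda(n_folds=n_folds, seed=seed)
    return lam


def fit_mlp(X, y, weights=None, hidden_sizes=(64, 32), seed: int = 0,
            **kwargs) -> ClockResults:
    model = NeuralNetClock(X, y, weights=weights, hidden_sizes=hidden_sizes,
                           seed=seed, **kwargs)
    return model.fit()


def predict_age(model: ClockResults, beta) -> np.ndarray:
    """DNAm age (predicted age in years) for every sample in ``beta``."""
    return model.predict(beta)


# ---------------------------------------------------------------------------
# cross-validation and metrics
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_assignment: pd.Series  # sample_id -> fold (1-based)
    oof_prediction: pd.Series  # sample_id -> out-of-fold DNAm age
    metrics: pd.DataFrame  # per-stratum n, pearson_r, mae_years


def stratified_metrics(pred, ages, strata=DEFAULT_STRATA) -> pd.DataFrame:
    """Per-stratum sample size, Pearson r and median absolute error.

    Strata with < 3 samples (or degenerate variance) report NaN r rather
    than raising.
    """
    pred = np.asarray(pred, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(pred) != len(ages):
        raise ValueError("pred and ages must have equal length")
    rows = []
    for st in strata:
        mask = st.mask(ages)
        n = int(mask.sum())
        if n >= 3 and np.std(ages[mask]) > 0 and np.std(pred[mask]) > 0:
            r = float(np.corrcoef(pred[mask], ages[mask])[0, 1])
        else:
            r = np.nan
        mae = float(np.median(np.abs(pred[mask] - ages[mask]))) if n else np.nan
        rows.append({"stratum": st.label, "n": n, "pearson_r": r,
                     "mae_years": mae})
    return pd.DataFrame(rows)


def crossvalidate_20fold(builder, beta: pd.DataFrame, sheet: pd.DataFrame,
                         weights=None, seed: int = 0, n_folds: int = 20,
                         strata=DEFAULT_STRATA) -> CVResult:
    """Random-split k-fold (default 20) cross-validation of a clock builder.

    ``builder(beta_train, sheet_train, weights_train)`` must return a fitted
    object with ``predict``.  Every sample lands in exactly one fold; fold
    sizes differ by at most one; a sample's out-of-fold prediction never
    comes from a model trained on its own fold.
    """
    n = len(sheet)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} samples, got {n}")
    ages = sheet["age"].to_numpy(dtype=float)
    sample_ids = sheet["sample_id"].to_numpy()
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    assignment = np.empty(n, dtype=int)
    oof = np.empty(n)
    for k, fold in enumerate(folds, start=1):
        assignment[fold] = k
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train_sheet = sheet.iloc[mask].reset_index(drop=True)
        model = builder(beta[sample_ids[mask]], train_sheet, w[mask])
        oof[fold] = model.predict(beta[sample_ids[fold]])
    return CVResult(
        fold_assignment=pd.Series(assignment, index=sample_ids, name="fold"),
        oof_prediction=pd.Series(oof, index=sample_ids, name="dnam_age"),
        metrics=stratified_metrics(oof, ages, strata),
    )
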