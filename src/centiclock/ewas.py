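"""Age-stratified epigenome-wide association study (EWAS).

Each CpG is correlated with chronological age (Pearson), with two-sided p
values from the t transform and signed normal Z scores obtained by probit-
transforming the p value with the sign of r.  All p values are handled on
the log scale internally: correlations at large n can be far beyond double
precision (p ~ 1e-2000), so the printable representation is -log10(p) with
the linear-scale p floored at 1e-320.

The study is run in three age groups by default — young [0, 40), middle
[40, 90), old [90, 115] — with lower-inclusive bounds and the final upper
bound inclusive, and cross-group concordance is the Pearson correlation of
the Z-score vectors over shared CpGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "EwasResult",
    "DEFAULT_GROUPS",
    "correlate_cpgs_age",
    "stratify_ewas",
    "top_k_cpgs",
    "crossgroup_concordance",
    "export_manhattan",
]

#: (label, lower bound inclusive, upper bound) age groups
DEFAULT_GROUPS = (("young", 0.0, 40.0), ("middle", 40.0, 90.0), ("old", 90.0, 115.0))

_LOG10_P_FLOOR = -320.0
_LN10 = np.log(10.0)


@dataclass
class EwasResult:
    """Per-CpG age-correlation screen for one age group.

    ``table`` is indexed by cpg_id with columns n, r, z, p, log10_p; CpGs
    with fewer than 4 usable samples or zero variance carry NaN statistics.
    """

    group_label: str
    age_bounds: tuple[float, float]
    table: pd.DataFrame

    @property
    def n_samples(self) -> int:
        n = self.table["n"].dropna()
        return int(n.max()) if len(n) else 0


def _corr_stats(values: np.ndarray, ages: np.ndarray):
    """Row-wise Pearson r, n, log p (natural log, two-sided), z for a
    CpG x sample matrix with possible NaNs."""
    finite = np.isfinite(values)
    n_per = finite.sum(axis=1).astype(float)
    vals = np.where(finite, values, 0.0)
    a = np.where(finite, ages[None, :], 0.0)
    sum_x = vals.sum(axis=1)
    sum_a = a.sum(axis=1)
    mean_x = np.divide(sum_x, n_per, out=np.zeros_like(sum_x), where=n_per > 0)
    mean_a = np.divide(sum_a, n_per, out=np.zeros_like(sum_a), where=n_per > 0)
    xc = np.where(finite, values - mean_x[:, None], 0.0)
    ac = np.where(finite, ages[None, :] - mean_a[:, None], 0.0)
    sxx = (xc**2).sum(axis=1)
    saa = (ac**2).sum(axis=1)
    sxa = (xc * ac).sum(axis=1)
    ok = (n_per >= 4) & (sxx > 0) & (saa > 0)
    r = np.full(len(values), np.nan)
    r[ok] = np.clip(sxa[ok] / np.sqrt(sxx[ok] * saa[ok]), -1.0, 1.0)

    log_p = np.full(len(values), np.nan)
    z = np.full(len(values), np.nan)
    df = n_per - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r**2))
    exact = ok & ~np.isfinite(t)  # |r| == 1
    good = ok & np.isfinite(t)
    log_p[good] = np.log(2.0) + stats.t.logsf(t[good], df[good])
    log_p[exact] = _LOG10_P_FLOOR * _LN10
    floor = _LOG10_P_FLOOR * _LN10
    log_p[ok] = np.maximum(log_p[ok], floor)
    # signed probit Z score: z = sign(r) * Phi^-1(1 - p/2), via log p
    z[ok] = -np.sign(r[ok]) * special.ndtri_exp(log_p[ok] - np.log(2.0))
    return r, n_per, log_p, z


def correlate_cpgs_age(beta: pd.DataFrame, ages) -> EwasResult:
    """Pearson correlation of every CpG with age.

    p is two-sided from t = r*sqrt((n-2)/(1-r^2)) on n-2 df; z is the
    signed probit of the p value.  CpGs with < 4 usable samples or constant
    values are reported with NaN statistics, not dropped.
    """
    ages = np.asarray(ages, dtype=float)
    if beta.shape[1] != len(ages):
        raise ValueError("ages must match the sample columns of beta")
    r, n_per, log_p, z = _corr_stats(beta.to_numpy(dtype=float), ages)
    log10_p = log_p / _LN10
    table = pd.DataFrame(
        {
            "n": n_per,
            "r": r,
            "z": z,
            "p": np.exp(np.maximum(log_p, _LOG10_P_FLOOR * _LN10)),
            "log10_p": log10_p,
        },
        index=beta.index,
    )
    table.loc[~np.isfinite(r), ["p", "log10_p"]] = np.nan
    lo = float(ages.min()) if len(ages) else np.nan
    hi = float(ages.max()) if len(ages) else np.nan
    return EwasResult("all", (lo, hi), table)


def stratify_ewas(beta: pd.DataFrame, sheet: pd.DataFrame,
                  groups=DEFAULT_GROUPS) -> dict[str, EwasResult]:
    """Run the EWAS separately in each age group.

    Bounds are lower-inclusive / upper-exclusive, except the overall final
    bound which is inclusive (a sample at exactly the top age belongs to
    the oldest group).  Empty groups yield an empty result with a warning.
    """
    bounds = [(lab, float(lo), float(hi)) for lab, lo, hi in groups]
    for (_, lo1, hi1), (_, lo2, _) in zip(bounds, bounds[1:]):
        if lo2 < hi1:
            raise ValueError("age groups must not overlap")
    final_hi = max(hi for _, _, hi in bounds)
    ages = sheet["age"].to_numpy(dtype=float)
    out = {}
    for lab, lo, hi in bounds:
        mask = (ages >= lo) & ((ages < hi) | ((hi == final_hi) & (ages == hi)))
        if not mask.any():
            logger.warning("age group %s [%g, %g) is empty", lab, lo, hi)
            res = EwasResult(lab, (lo, hi), pd.DataFrame(
                columns=["n", "r", "z", "p", "log10_p"], index=beta.index[:0]))
        else:
            res = correlate_cpgs_age(beta[sheet["sample_id"][mask]], ages[mask])
            res = EwasResult(lab, (lo, hi), res.table)
        out[lab] = res
    return out


def top_k_cpgs(ewas: EwasResult, k: int, direction: str) -> list[str]:
    """Top-k CpGs by Z in the requested direction.

    positive: k largest z among z > 0; negative: k smallest among z < 0.
    Ties break on cpg_id.  If fewer than k CpGs carry the requested sign,
    all of them are returned with a warning.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    tab = ewas.table.dropna(subset=["z"]).copy()
    if k > len(tab):
        raise ValueError(f"k={k} exceeds {len(tab)} CpGs with defined statistics")
    tab["cpg"] = tab.index.astype(str)
    if direction == "positive":
        tab = tab[tab["z"] > 0].sort_values(["z", "cpg"], ascending=[False, True])
    else:
        tab = tab[tab["z"] < 0].sort_values(["z", "cpg"], ascending=[True, True])
    if len(tab) < k:
        logger.warning(
            "only %d CpGs with %s age correlation (requested %d)",
            len(tab), direction, k,
        )
    return list(tab.index[:k])


def crossgroup_concordance(ewas_a: EwasResult, ewas_b: EwasResult):
    """Pearson correlation (and p value) of the Z-score vectors over CpGs
    with defined Z in both groups."""
    za = ewas_a.table["z"].dropna()
    zb = ewas_b.table["z"].dropna()
    shared = za.index.intersection(zb.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 CpGs shared between the two results")
    res = stats.pearsonr(za[shared], zb[shared])
    return float(res.statistic), float(res.pvalue)


def export_manhattan(ewas: EwasResult, annotation: pd.DataFrame,
                     genomewide_p: float = 1e-7) -> pd.DataFrame:
    """Per-CpG table for a Manhattan plot.

    Columns: chrom, pos, cpg_id, gene, r, z, p, minus_log10_p and a
    genome-wide significance flag (p strictly below ``genomewide_p``).
    CpGs missing from the annotation are dropped with a logged count.
    """
    tab = ewas.table.reset_index(names="cpg_id")
    ann = annotation[["chrom", "start", "cpg_id", "gene"]].rename(
        columns={"start": "pos"})
    merged = tab.merge(ann, on="cpg_id", how="inner")
    n_dropped = len(tab) - len(merged)
    if n_dropped:
        logger.warning("dropped %d CpGs without annotation", n_dropped)
    merged["minus_log10_p"] = -merged["log10_p"]
    merged["genomewide_flag"] = merged["log10_p"] < np.log10(genomewide_p)
    cols = ["chrom", "pos", "cpg_id", "gene", "r", "z", "p",
            "minus_log10_p", "genomewide_flag"]
    return merged[cols]
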