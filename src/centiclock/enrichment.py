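"""Chromatin-state and polycomb enrichment of age-related CpG sets.

Age-related CpG sets (e.g. the top 1000 positively and top 1000 negatively
age-correlated CpGs) are overlapped with a single-state chromatin
annotation and with PRC1/PRC2 binding layers.  Each overlap is scored by a
one-sided hypergeometric test against an explicit background, reported
alongside the sample 2x2 odds ratio; heatmap cells carry
-log10(min tail p) signed by the direction of the odds ratio.

Tail probabilities are accumulated in log space (logsumexp over the exact
hypergeometric pmf), so extreme enrichments do not underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from centiclock.synthetic import PRC1_MEMBERS, PRC2_MEMBERS

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_tail",
    "log_hypergeom_tail",
    "odds_ratio",
    "enrich_states",
    "prc_flags",
    "signed_log10p_matrix",
]


def _validate_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside the feasible range "
            f"[{max(0, K + n - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
        )


def log_hypergeom_tail(k: int, K: int, n: int, N: int, side: str) -> float:
    """Natural-log one-sided hypergeometric tail probability.

    X ~ Hypergeometric(N, K, n): upper = log P(X >= k), lower = log P(X <= k),
    both including the observed point mass.
    """
    _validate_counts(k, K, n, N)
    if side == "upper":
        js = np.arange(k, min(K, n) + 1)
    elif side == "lower":
        js = np.arange(max(0, K + n - N), k + 1)
    else:
        raise ValueError("side must be 'upper' or 'lower'")
    logp = logsumexp(stats.hypergeom.logpmf(js, N, K, n))
    return float(min(logp, 0.0))


def hypergeom_tail(k: int, K: int, n: int, N: int, side: str) -> float:
    """One-sided hypergeometric tail probability (see
    :func:`log_hypergeom_tail`)."""
    return float(np.exp(log_hypergeom_tail(k, K, n, N, side)))


def odds_ratio(k: int, K: int, n: int, N: int):
    """Sample odds ratio of the 2x2 overlap table.

    Cells: (k, n-k, K-k, N-K-n+k).  With any zero cell the Haldane-Anscombe
    correction (+0.5 on every cell) is applied and flagged.

    Returns (odds_ratio, corrected_flag).
    """
    _validate_counts(k, K, n, N)
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    corrected = min(a, b, c, d) == 0
    if corrected:
        logger.info("zero cell in 2x2 table; Haldane-Anscombe correction applied")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c)), corrected


def prc_flags(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG PRC1/PRC2 indicators: bound by at least two complex members.

    Requires the individual member flag columns (RING1, RNF2, BMI1 for PRC1;
    EED, SUZ12, EZH2 for PRC2).
    """
    missing = [m for m in PRC1_MEMBERS + PRC2_MEMBERS if m not in annotation.columns]
    if missing:
        raise KeyError(f"annotation lacks PRC member columns: {missing}")
    out = pd.DataFrame(index=annotation.index)
    out["cpg_id"] = annotation["cpg_id"].to_numpy()
    out["prc1"] = (annotation[list(PRC1_MEMBERS)].sum(axis=1) >= 2).astype(int)
    out["prc2"] = (annotation[list(PRC2_MEMBERS)].sum(axis=1) >= 2).astype(int)
    return out


def _one_enrichment(set_label, layer, k, K, n, N):
    log_up = log_hypergeom_tail(k, K, n, N, "upper")
    log_lo = log_hypergeom_tail(k, K, n, N, "lower")
    or_, corrected = odds_ratio(k, K, n, N)
    log10_up = log_up / np.log(10.0)
    log10_lo = log_lo / np.log(10.0)
    if or_ == 1.0:
        signed = 0.0
    else:
        signed = -min(log10_up, log10_lo) * (1.0 if or_ > 1.0 else -1.0)
    return {
        "set": set_label,
        "state": layer,
        "k": k,
        "n_set": n,
        "K_state": K,
        "N": N,
        "odds_ratio": or_,
        "or_corrected": corrected,
        "log10_p_enrich": log10_up,
        "log10_p_deplete": log10_lo,
        "p_enrich": float(np.exp(log_up)),
        "p_deplete": float(np.exp(log_lo)),
        "signed_score": signed,
    }


def enrich_states(query, annotation: pd.DataFrame, background=None,
                  set_label: str = "query", include_prc: bool = True
                  ) -> pd.DataFrame:
    """Hypergeometric enrichment of a CpG set across chromatin states.

    ``annotation`` maps cpg_id to a single chromatin state (and PRC member
    flags when ``include_prc``); ``background`` defaults to every annotated
    CpG.  The query must be a subset of the background.  One row per state
    present in the background, plus PRC1/PRC2 layers tested as a second,
    non-exclusive annotation.
    """
    ann = annotation.set_index("cpg_id")
    if background is None:
        background = list(ann.index)
    bg = pd.Index(sorted(set(map(str, background))))
    q = set(map(str, query))
    if not q.issubset(set(bg)):
        extra = sorted(q - set(bg))[:5]
        raise ValueError(f"query CpGs outside the background, e.g. {extra}")
    missing_ann = [c for c in bg if c not in ann.index]
    if missing_ann:
        raise ValueError(
            f"{len(missing_ann)} background CpGs lack annotation, "
            f"e.g. {missing_ann[:5]}"
        )
    states = ann.loc[bg, "state"]
    N = len(bg)
    n = len(q)
    q_states = states[states.index.isin(q)]
    rows = []
    for state, K in states.value_counts().sort_index().items():
        k = int((q_states == state).sum())
        rows.append(_one_enrichment(set_label, state, k, int(K), n, N))
    if include_prc and {"prc1", "prc2"}.issubset(ann.columns):
        for layer in ("prc1", "prc2"):
            flags = ann.loc[bg, layer].astype(int)
            K = int(flags.sum())
            if K == 0:
                continue
            k = int(flags[flags.index.isin(q)].sum())
            rows.append(_one_enrichment(set_label, layer.upper(), k, K, n, N))
    return pd.DataFrame(rows)


def signed_log10p_matrix(results: dict[str, pd.DataFrame],
                         p_threshold: float | None = None) -> pd.DataFrame:
    """States x sets matrix of signed -log10 p scores.

    ``results`` maps a set label to an :func:`enrich_states` table.  With
    ``p_threshold``, only states whose minimum tail p falls below it in at
    least one set are kept (the display filter used for enrichment heatmaps).
    """
    frames = []
    for label, tab in results.items():
        frames.append(tab.assign(set=label))
    allres = pd.concat(frames, ignore_index=True)
    mat = allres.pivot_table(index="state", columns="set",
                             values="signed_score", aggfunc="first")
    if p_threshold is not None:
        log10_thr = np.log10(p_threshold)
        minlog = allres.assign(
            best=np.minimum(allres["log10_p_enrich"], allres["log10_p_deplete"])
        ).groupby("state")["best"].min()
        keep = minlog[minlog < log10_thr].index
        mat = mat.loc[mat.index.intersection(keep)]
    return mat
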