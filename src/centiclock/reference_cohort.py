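"""Marginal characteristics of the multi-cohort training data that the
simulator defaults emulate.

The clocks this package implements were designed for a pooled blood/saliva
training set of 7039 samples aged 40-115 with a thin centenarian tail.
Only the marginal counts of that cohort are public; they are recorded here
(as counts, with percentages always recomputed from them) and serve two
purposes: they calibrate :class:`centiclock.synthetic.SimConfig` defaults,
and they make the cohort-composition arithmetic reproducible.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["TRAINING_COHORT_MARGINALS", "marginal_percentages"]

#: Nested age groups of the training cohort: total n, n female and tissue
#: counts per group.  Groups are cumulative (>= the age cutoff).
TRAINING_COHORT_MARGINALS = pd.DataFrame(
    [
        {"age_group": "110plus", "min_age": 110, "n": 25, "n_female": 20,
         "n_blood": 20, "n_saliva": 2, "n_buccal": 3},
        {"age_group": "100plus", "min_age": 100, "n": 184, "n_female": 128,
         "n_blood": 175, "n_saliva": 6, "n_buccal": 3},
        {"age_group": "90plus", "min_age": 90, "n": 358, "n_female": 220,
         "n_blood": 349, "n_saliva": 6, "n_buccal": 3},
        {"age_group": "80plus", "min_age": 80, "n": 1262, "n_female": 672,
         "n_blood": 1253, "n_saliva": 6, "n_buccal": 3},
        {"age_group": "40plus", "min_age": 40, "n": 7039, "n_female": 3838,
         "n_blood": 7030, "n_saliva": 6, "n_buccal": 3},
    ]
)


def marginal_percentages(decimals: int = 1) -> pd.DataFrame:
    """Female and tissue percentages recomputed from the stored counts,
    rounded to the reporting precision (1 decimal by default)."""
    t = TRAINING_COHORT_MARGINALS.copy()
    for col in ("female", "blood", "saliva", "buccal"):
        t[f"{col}_pct"] = (100.0 * t[f"n_{col}"] / t["n"]).round(decimals)
    t["centenarian_pct_of_40plus"] = round(
        100.0 * int(t.loc[t.age_group == "100plus", "n"].iloc[0])
        / int(t.loc[t.age_group == "40plus", "n"].iloc[0]),
        decimals,
    )
    return t
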