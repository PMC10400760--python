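"""EWAS statistics against textbook arithmetic, age-group stratification
conventions, top-K selection, concordance, and Manhattan export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from centiclock.ewas import (
    EwasResult,
    correlate_cpgs_age,
    crossgroup_concordance,
    export_manhattan,
    stratify_ewas,
    top_k_cpgs,
)


def _beta_from_rows(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T


class TestCorrelate:
    def test_proportional_cpg_hits_floor(self):
        ages = np.linspace(20, 90, 30)
        beta = _beta_from_rows({"cg1": ages / 120})
        res = correlate_cpgs_age(beta, ages)
        row = res.table.loc["cg1"]
        assert row["r"] == pytest.approx(1.0)
        assert row["log10_p"] <= -300

    def test_six_point_hand_oracle(self):
        ages = np.array([25.0, 37.0, 49.0, 61.0, 78.0, 92.0])
        vals = np.array([0.31, 0.30, 0.42, 0.44, 0.50, 0.48])
        res = correlate_cpgs_age(_beta_from_rows({"cg1": vals}), ages)
        row = res.table.loc["cg1"]
        # textbook formulas evaluated by brute force
        r = (((vals - vals.mean()) * (ages - ages.mean())).sum()
             / np.sqrt(((vals - vals.mean()) ** 2).sum()
                       * ((ages - ages.mean()) ** 2).sum()))
        t = r * np.sqrt(4 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 4)
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-10)
        assert row["z"] == pytest.approx(
            np.sign(r) * stats.norm.isf(p / 2), rel=1e-10)

    def test_constant_cpg_reported_missing(self):
        ages = np.linspace(20, 90, 10)
        beta = _beta_from_rows({"cgc": np.full(10, 0.5),
                                "cgv": ages / 200})
        res = correlate_cpgs_age(beta, ages)
        assert np.isnan(res.table.loc["cgc", "r"])
        assert "cgc" in res.table.index  # not silently dropped
        assert res.table.loc["cgv", "r"] > 0

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(20, 90, 25)
        beta = pd.DataFrame(rng.uniform(0, 1, (8, 25)),
                            index=[f"cg{i}" for i in range(8)])
        a = correlate_cpgs_age(beta, ages).table
        perm = rng.permutation(25)
        b = correlate_cpgs_age(beta.iloc[:, perm], ages[perm]).table
        pd.testing.assert_frame_equal(a, b)

    def test_z_monotone_in_signed_log_p(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 90, 40)
        beta = pd.DataFrame(
            np.clip(np.outer(np.linspace(0, 0.006, 10), ages)
                    + rng.normal(0.3, 0.05, (10, 40)), 0, 1),
            index=[f"cg{i}" for i in range(10)])
        tab = correlate_cpgs_age(beta, ages).table.dropna()
        pos = tab[tab.z > 0].sort_values("log10_p")
        assert (np.diff(pos["z"].to_numpy()) <= 1e-12).all()


class TestStratify:
    def test_all_middle_aged(self):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(rng.uniform(0, 1, (5, 10)),
                            index=[f"cg{i}" for i in range(5)],
                            columns=[f"S{i}" for i in range(10)])
        sheet = pd.DataFrame({"sample_id": beta.columns,
                              "age": np.full(10, 50.0)})
        res = stratify_ewas(beta, sheet)
        assert res["middle"].table["n"].max() == 10
        assert len(res["young"].table.dropna()) == 0
        assert len(res["old"].table.dropna()) == 0

    def test_boundary_forty_goes_to_middle(self):
        rng = np.random.default_rng(1)
        beta = pd.DataFrame(rng.uniform(0, 1, (4, 8)),
                            index=[f"cg{i}" for i in range(4)],
                            columns=[f"S{i}" for i in range(8)])
        ages = np.array([40.0, 40.0, 40.0, 40.0, 55.0, 60.0, 70.0, 80.0])
        sheet = pd.DataFrame({"sample_id": beta.columns, "age": ages})
        res = stratify_ewas(beta, sheet)
        assert res["middle"].table["n"].max() == 8

    def test_final_bound_inclusive(self):
        rng = np.random.default_rng(2)
        beta = pd.DataFrame(rng.uniform(0, 1, (4, 6)),
                            index=[f"cg{i}" for i in range(4)],
                            columns=[f"S{i}" for i in range(6)])
        ages = np.array([95.0, 100.0, 105.0, 110.0, 113.0, 115.0])
        sheet = pd.DataFrame({"sample_id": beta.columns, "age": ages})
        res = stratify_ewas(beta, sheet)
        assert res["old"].table["n"].max() == 6  # 115 included

    def test_overlapping_groups_rejected(self):
        beta = pd.DataFrame(np.zeros((1, 3)), index=["cg0"],
                            columns=["a", "b", "c"])
        sheet = pd.DataFrame({"sample_id": beta.columns,
                              "age": [30.0, 50.0, 95.0]})
        with pytest.raises(ValueError, match="overlap"):
            stratify_ewas(beta, sheet, [("a", 0, 50), ("b", 40, 90)])

    def test_planted_positive_cpg_positive_in_all_groups(self):
        from centiclock.synthetic import SimConfig, simulate_cohort
        beta, sheet, _, specs = simulate_cohort(
            SimConfig(n_samples=900, n_cpgs=300, age_range=(5.0, 115.0),
                      centenarian_frac=0.12, seed=3))
        res = stratify_ewas(beta, sheet)
        pos = specs.loc[specs.class_label == "pos_linear", "cpg_id"]
        fracs = [(res[g].table.loc[pos, "r"] > 0).mean()
                 for g in ("young", "middle", "old")]
        assert min(fracs) > 0.8


class TestTopK:
    def _fixture(self):
        z = pd.Series([3.1, 2.5, 2.5, -1.0, -4.0, 0.5, -2.2, 1.7, -0.1, 2.9],
                      index=[f"cg{i}" for i in range(10)])
        tab = pd.DataFrame({"n": 100.0, "r": np.sign(z) * 0.1, "z": z,
                            "p": 0.05, "log10_p": -1.3})
        return EwasResult("middle", (40, 90), tab)

    def test_selection_matches_bruteforce_sort(self):
        res = self._fixture()
        top3 = top_k_cpgs(res, 3, "positive")
        z = res.table["z"]
        expected = sorted(z[z > 0].index,
                          key=lambda c: (-z[c], c))[:3]
        assert top3 == expected
        bot2 = top_k_cpgs(res, 2, "negative")
        assert bot2 == ["cg4", "cg6"]

    def test_k_one_returns_extreme(self):
        res = self._fixture()
        assert top_k_cpgs(res, 1, "positive") == ["cg0"]
        assert top_k_cpgs(res, 1, "negative") == ["cg4"]

    def test_all_positive_whole_set(self):
        res = self._fixture()
        pos = top_k_cpgs(res, 6, "positive")
        assert set(pos) == set(res.table.index[res.table.z > 0])

    def test_insufficient_sign_returns_available(self, caplog):
        res = self._fixture()
        with caplog.at_level("WARNING"):
            got = top_k_cpgs(res, 6, "negative")
        assert len(got) == 4

    def test_tie_broken_by_cpg_id(self):
        res = self._fixture()
        top2 = top_k_cpgs(res, 3, "positive")
        assert top2 == ["cg0", "cg9", "cg1"]  # cg1 beats cg2 at equal z


class TestConcordance:
    def test_identical_results_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(20, 90, 30)
        beta = pd.DataFrame(rng.uniform(0, 1, (10, 30)),
                            index=[f"cg{i}" for i in range(10)])
        res = correlate_cpgs_age(beta, ages)
        r, p = crossgroup_concordance(res, res)
        assert r == pytest.approx(1.0)

    def test_negated_z_gives_minus_one(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(20, 90, 30)
        beta = pd.DataFrame(rng.uniform(0, 1, (10, 30)),
                            index=[f"cg{i}" for i in range(10)])
        res = correlate_cpgs_age(beta, ages)
        flipped = EwasResult(res.group_label, res.age_bounds,
                             res.table.assign(z=-res.table["z"]))
        r, _ = crossgroup_concordance(res, flipped)
        assert r == pytest.approx(-1.0)

    def test_shared_causal_cpgs_give_positive_concordance(self, default_cohort):
        beta, sheet, _, _ = default_cohort
        res = stratify_ewas(beta, sheet)
        r, _ = crossgroup_concordance(res["middle"], res["old"])
        assert r > 0.5

    def test_empty_intersection_rejected(self):
        a = EwasResult("a", (0, 1), pd.DataFrame(
            {"z": [1.0]}, index=["cg1"]))
        b = EwasResult("b", (0, 1), pd.DataFrame(
            {"z": [1.0]}, index=["cg2"]))
        with pytest.raises(ValueError):
            crossgroup_concordance(a, b)


class TestManhattanExport:
    def _result_with_p(self, pvals):
        idx = [f"cg{i}" for i in range(len(pvals))]
        tab = pd.DataFrame(
            {"n": 100.0, "r": 0.5, "z": 5.0, "p": pvals,
             "log10_p": np.log10(pvals)}, index=idx)
        return EwasResult("old", (90, 115), tab)

    def _annotation(self, n):
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 100, "end":
             np.arange(n) * 100 + 2, "cpg_id": [f"cg{i}" for i in range(n)],
             "gene": "GENE1"})

    def test_genomewide_flag_strict_inequality(self):
        res = self._result_with_p([1e-7, 1e-8, 1e-6])
        out = export_manhattan(res, self._annotation(3)).set_index("cpg_id")
        assert not out.loc["cg0", "genomewide_flag"]  # exactly 1e-7
        assert out.loc["cg1", "genomewide_flag"]
        assert not out.loc["cg2", "genomewide_flag"]

    def test_unannotated_cpgs_dropped_with_count(self, caplog):
        res = self._result_with_p([1e-3, 1e-4])
        with caplog.at_level("WARNING"):
            out = export_manhattan(res, self._annotation(1))
        assert len(out) == 1

    def test_round_trip_through_writer(self, tmp_path):
        from centiclock import io as cio
        res = self._result_with_p([1e-3, 1e-9, 0.5])
        out = export_manhattan(res, self._annotation(3))
        cio.write_table(out, tmp_path / "man.tsv")
        back = cio.read_table(tmp_path / "man.tsv")
        pd.testing.assert_frame_equal(out.reset_index(drop=True), back,
                                      check_dtype=False)
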