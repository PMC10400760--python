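"""End-to-end scenario runner.

Strings the stages together — simulate -> clean -> prefilter -> train ->
crossval -> ageaccel -> ewas -> enrich -> assoc -> trajectories — from a
single declarative YAML configuration, writing every stage's TSV/CSV/JSON
artifact plus a machine-readable manifest (stage, artifact hashes, seed,
runtime).  Rerunning with an identical config and seed reproduces
byte-identical artifacts: every random draw descends deterministically from
the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from centiclock import age_accel as aa
from centiclock import clocks, enrichment, ewas as ewas_mod, preprocess, trajectories
from centiclock import io as cio
from centiclock.synthetic import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "DEFAULT_CONFIG",
    "run_scenario",
    "out_of_distribution_scenario",
    "stage_seed",
]

STAGES = (
    "simulate",
    "clean",
    "prefilter",
    "train",
    "crossval",
    "ageaccel",
    "ewas",
    "enrich",
    "assoc",
    "trajectories",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},  # SimConfig field overrides
    "clean": {"abs_resid_years": 30.0, "max_iter": 3},
    "prefilter": {"n_pos": 150, "n_neg": 150, "eps_null": 0.05, "n_null": 100},
    "train": {
        "alpha": 0.5,
        "centenarian_weight": 10.0,
        "n_lambdas": 50,
        "cv_folds": 5,
        "nn_hidden": [64, 32],
        "nn_epochs": 800,
    },
    "crossval": {"n_folds": 20, "cv_folds": 3},
    "ewas": {"groups": [list(g) for g in ewas_mod.DEFAULT_GROUPS]},
    "enrich": {"top_k": 150, "p_threshold": None},
    "assoc": {"min_stratum_n": 10},
    "trajectories": {
        "targets": ["PRC2", "BivProm2", "PromF2", "EnhA1"],
        "n_top_cpgs": 1,
        "frac": 2.0 / 3.0,
        "robust_iters": 3,
    },
}


class PipelineConfig:
    """Validated scenario configuration.

    Unknown top-level or stage-level keys are errors, not warnings, to
    prevent silently ignored misconfiguration.
    """

    def __init__(self, overrides: dict | None = None):
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
        overrides = overrides or {}
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        for key, value in overrides.items():
            if key not in cfg:
                raise KeyError(f"unknown configuration key {key!r}")
            if isinstance(cfg[key], dict):
                allowed = sim_fields if key == "simulate" else set(cfg[key])
                for sub in value:
                    if sub not in allowed:
                        raise KeyError(f"unknown key {key}.{sub}")
                cfg[key].update(value)
            else:
                cfg[key] = value
        for st in cfg["stages"]:
            if st not in STAGES:
                raise ValueError(f"unknown stage {st!r}")
        self.cfg = cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def __getitem__(self, key):
        return self.cfg[key]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _quick_clock_builder(seed: int, n_features: int = 100,
                         n_lambdas: int = 20, cv_folds: int = 3):
    """Small elastic-net clock used by the outlier-removal stage: a handful
    of top age-correlated CpGs, a coarse penalty path."""

    def build(beta, sheet, weights=None):
        half = max(n_features // 2, 5)
        pre = preprocess.prefilter_cpgs(
            beta, sheet["age"], n_pos=half, n_neg=half, n_null=0)
        sub = beta.loc[pre.pos_set + pre.neg_set]
        model = clocks.ElasticNetClock(
            sub, sheet["age"].to_numpy(dtype=float),
            weights=weights, alpha=0.5, n_lambdas=n_lambdas, seed=seed)
        return model.fit(lambda_="cv", cv_folds=cv_folds)

    return build


def run_scenario(config: PipelineConfig | dict, out_dir,
                 seed: int | None = None) -> Path:
    """Run every enabled stage, writing artifacts and a run manifest.

    A stage failure halts the run with the failing stage named; artifacts
    written so far are retained for debugging.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    out = cio.ensure_dir(out_dir)
    global_seed = int(config["seed"] if seed is None else seed)
    manifest = {"global_seed": global_seed, "stages": []}
    state: dict = {}

    enabled = config["stages"]
    for stage in enabled:
        t0 = time.perf_counter()
        sseed = stage_seed(global_seed, stage)
        try:
            artifacts = _STAGE_FNS[stage](config, state, out, sseed)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": sseed,
                "runtime_s": round(time.perf_counter() - t0, 3),
                "artifacts": {
                    str(p.relative_to(out)): _sha256(p) for p in artifacts
                },
            }
        )
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, out, sseed):
    sim_kwargs = dict(config["simulate"])
    sim_kwargs.setdefault("seed", sseed)
    sim = SimConfig(**sim_kwargs)
    beta, sheet, annotation, specs = simulate_cohort(sim)
    state.update(beta=beta, sheet=sheet, annotation=annotation, specs=specs,
                 sim=sim)
    paths = [out / "beta.tsv", out / "samples.csv", out / "annotation.tsv",
             out / "cpg_specs.tsv"]
    cio.write_beta(beta, paths[0])
    cio.write_sheet(sheet, paths[1])
    cio.write_annotation(annotation, paths[2])
    cio.write_table(specs, paths[3])
    return paths


def _stage_clean(config, state, out, sseed):
    block = config["clean"]
    kept, report = preprocess.remove_outliers(
        state["beta"], state["sheet"], _quick_clock_builder(sseed),
        abs_resid_years=block["abs_resid_years"], max_iter=block["max_iter"])
    state["sheet"] = state["sheet"][
        state["sheet"]["sample_id"].isin(kept)].reset_index(drop=True)
    state["beta"] = state["beta"][state["sheet"]["sample_id"]]
    path = out / "outlier_report.csv"
    cio.write_sheet(report, path)
    return [path]


def _stage_prefilter(config, state, out, sseed):
    block = config["prefilter"]
    pre = preprocess.prefilter_cpgs(
        state["beta"], state["sheet"]["age"], n_pos=block["n_pos"],
        n_neg=block["n_neg"], eps_null=block["eps_null"],
        n_null=block["n_null"])
    state["prefilter"] = pre
    state["beta_filtered"] = state["beta"].loc[pre.selected]
    tab = pd.DataFrame(
        {
            "cpg_id": pre.selected,
            "group": (["pos"] * len(pre.pos_set) + ["neg"] * len(pre.neg_set)
                      + ["null"] * len(pre.null_set)),
            "r": pre.r_by_cpg[pre.selected].to_numpy(),
        }
    )
    path = out / "prefilter.tsv"
    cio.write_table(tab, path)
    return [path]


def _train_builder(config, which, sseed):
    block = config["train"]

    def build(beta, sheet, weights=None):
        age_min = 100.0 if which == "encen100" else 40.0
        keep = sheet["age"].to_numpy(dtype=float) >= age_min
        sub_sheet = sheet.loc[keep].reset_index(drop=True)
        sub_beta = beta[sub_sheet["sample_id"]]
        ages = sub_sheet["age"].to_numpy(dtype=float)
        w = clocks.sample_weights(ages, block["centenarian_weight"])
        if which == "nncen40":
            model = clocks.NeuralNetClock(
                sub_beta, ages, weights=w,
                hidden_sizes=tuple(block["nn_hidden"]),
                epochs=block["nn_epochs"],
                centenarian_weight=block["centenarian_weight"],
                training_age_min=age_min, seed=sseed)
            return model.fit()
        model = clocks.ElasticNetClock(
            sub_beta, ages, weights=w, alpha=block["alpha"],
            n_lambdas=block["n_lambdas"],
            centenarian_weight=block["centenarian_weight"],
            training_age_min=age_min, seed=sseed)
        n_sub = len(ages)
        folds = min(block["cv_folds"], max(2, n_sub // 4))
        return model.fit(lambda_="cv", cv_folds=folds)

    return build


def _stage_train(config, state, out, sseed):
    beta = state["beta_filtered"]
    sheet = state["sheet"]
    paths = []
    state["clocks"] = {}
    for which in ("encen40", "encen100", "nncen40"):
        res = _train_builder(config, which, sseed)(beta, sheet)
        state["clocks"][which] = res
        d = cio.ensure_dir(out / f"clock_{which}")
        res.save(d)
        paths.append(d / "clock.json")
        if (d / "coefficients.csv").exists():
            paths.append(d / "coefficients.csv")
    return paths


def _stage_crossval(config, state, out, sseed):
    block = config["crossval"]
    beta = state["beta_filtered"]
    sheet = state["sheet"]
    train_block = config["train"]

    def builder(b, s, w):
        ages = s["age"].to_numpy(dtype=float)
        model = clocks.ElasticNetClock(
            b, ages, weights=w, alpha=train_block["alpha"],
            n_lambdas=train_block["n_lambdas"],
            centenarian_weight=train_block["centenarian_weight"],
            training_age_min=40.0, seed=sseed)
        return model.fit(lambda_="cv", cv_folds=block["cv_folds"])

    w = clocks.sample_weights(sheet["age"], train_block["centenarian_weight"])
    cv = clocks.crossvalidate_20fold(
        builder, beta, sheet, weights=w, seed=sseed, n_folds=block["n_folds"])
    state["cv"] = cv
    p1 = out / "cv_predictions.csv"
    pred = pd.DataFrame(
        {
            "sample_id": cv.oof_prediction.index,
            "fold": cv.fold_assignment.to_numpy(),
            "dnam_age": cv.oof_prediction.to_numpy(),
            "age": sheet.set_index("sample_id").loc[
                cv.oof_prediction.index, "age"].to_numpy(),
        }
    )
    cio.write_sheet(pred, p1)
    p2 = out / "cv_metrics.tsv"
    cio.write_table(cv.metrics, p2)
    return [p1, p2]


def _stage_ageaccel(config, state, out, sseed):
    sheet = state["sheet"]
    cv = state["cv"]
    accel = aa.compute_age_accel(
        cv.oof_prediction.to_numpy(),
        sheet.set_index("sample_id").loc[cv.oof_prediction.index, "age"],
        sample_ids=cv.oof_prediction.index,
    )
    state["accel"] = accel
    path = out / "age_accel.csv"
    cio.write_sheet(
        pd.DataFrame({"sample_id": accel.index, "accel": accel.to_numpy()}),
        path)

    # Cox mortality: per-cohort fits on accel + age + sex, meta-combined
    merged = sheet.set_index("sample_id").loc[accel.index]
    rows = []
    est, ses = [], []
    for cohort, grp in merged.groupby("cohort"):
        if grp["event"].sum() < 5:
            logger.info("cohort %s skipped for Cox (too few events)", cohort)
            continue
        cov = pd.DataFrame(
            {
                "accel": accel[grp.index].to_numpy(),
                "age": grp["age"].to_numpy(),
                "female": (grp["sex"] == "F").astype(float).to_numpy(),
            }
        )
        fit = aa.fit_cox(grp["time"], grp["event"], cov, stratum_label=cohort)
        rows.append(
            {
                "stratum": cohort,
                "log_hr": fit.log_hr["accel"],
                "se": fit.se["accel"],
                "hr": float(np.exp(fit.log_hr["accel"])),
                "p": fit.p["accel"],
                "n": fit.n,
                "n_events": fit.n_events,
            }
        )
        est.append(fit.log_hr["accel"])
        ses.append(fit.se["accel"])
    if est:
        meta = aa.meta_fixed_effect(est, ses)
        rows.append(
            {
                "stratum": "meta",
                "log_hr": meta.combined,
                "se": meta.combined_se,
                "hr": float(np.exp(meta.combined)),
                "p": meta.p,
                "n": int(merged.shape[0]),
                "n_events": int(merged["event"].sum()),
            }
        )
        state["cox_meta"] = meta
    p2 = out / "mortality_cox.tsv"
    cio.write_table(pd.DataFrame(rows), p2)
    return [path, p2]


def _stage_ewas(config, state, out, sseed):
    groups = [tuple(g) for g in config["ewas"]["groups"]]
    results = ewas_mod.stratify_ewas(state["beta_filtered"], state["sheet"],
                                     groups)
    state["ewas"] = results
    paths = []
    frames = []
    for lab, res in results.items():
        if res.table.empty:
            continue
        t = res.table.reset_index(names="cpg_id")
        t.insert(1, "group", lab)
        frames.append(t)
    p = out / "ewas.tsv"
    cio.write_table(pd.concat(frames, ignore_index=True), p)
    paths.append(p)
    for lab, res in results.items():
        if len(res.table.dropna(subset=["z"])) == 0:
            continue
        man = ewas_mod.export_manhattan(res, state["annotation"])
        mp = out / f"manhattan_{lab}.tsv"
        cio.write_table(man, mp)
        paths.append(mp)
    # pairwise concordance of Z scores
    rows = []
    labs = [l for l, r in results.items() if len(r.table.dropna(subset=["z"]))]
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            r, pv = ewas_mod.crossgroup_concordance(results[a], results[b])
            rows.append({"group_a": a, "group_b": b, "r": r, "p": pv})
    cp = out / "ewas_concordance.tsv"
    cio.write_table(pd.DataFrame(rows), cp)
    paths.append(cp)
    return paths


def _stage_enrich(config, state, out, sseed):
    block = config["enrich"]
    ann = state["annotation"]
    background = [c for c in state["beta_filtered"].index if
                  c in set(ann["cpg_id"])]
    results = {}
    for lab, res in state["ewas"].items():
        tab = res.table.dropna(subset=["z"])
        if len(tab) == 0:
            continue
        k = min(block["top_k"], len(tab))
        for direction in ("positive", "negative"):
            sel = ewas_mod.top_k_cpgs(
                ewas_mod.EwasResult(lab, res.age_bounds,
                                    tab.loc[tab.index.isin(background)]),
                min(k, len(tab.loc[tab.index.isin(background)])), direction)
            label = f"{lab}_{'pos' if direction == 'positive' else 'neg'}"
            results[label] = enrichment.enrich_states(
                sel, ann, background=background, set_label=label)
    state["enrichment"] = results
    p1 = out / "enrichment.tsv"
    cio.write_table(pd.concat(results.values(), ignore_index=True), p1)
    mat = enrichment.signed_log10p_matrix(results,
                                          p_threshold=block["p_threshold"])
    p2 = out / "enrichment_matrix.tsv"
    mat.reset_index().to_csv(p2, sep="\t", index=False, float_format="%.10g")
    return [p1, p2]


def _stage_assoc(config, state, out, sseed):
    sheet = state["sheet"].set_index("sample_id").loc[state["accel"].index]
    bio_cols = [c for c in sheet.columns if c.startswith("biomarker_")]
    if not bio_cols:
        return []
    strata = (sheet["cohort"].astype(str) + "/" + sheet["sex"].astype(str))
    tab = aa.stratified_bicor_meta(
        state["accel"].to_numpy(), sheet[bio_cols], strata.to_numpy(),
        min_stratum_n=config["assoc"]["min_stratum_n"])
    path = out / "biomarker_assoc.tsv"
    cio.write_table(tab, path)
    return [path]


def _stage_trajectories(config, state, out, sseed):
    block = config["trajectories"]
    sheet = state["sheet"]
    beta = state["beta_filtered"]
    targets = list(block["targets"])
    # prepend the most age-correlated CpGs (ELOVL2-like linear exemplars)
    r = state["prefilter"].r_by_cpg.loc[beta.index].abs().sort_values(
        ascending=False)
    targets = list(r.index[: block["n_top_cpgs"]]) + targets
    ann = state["annotation"]
    usable = []
    for t in targets:
        if t in beta.index or t in set(ann["state"]) or t in ("PRC1", "PRC2"):
            usable.append(t)
        else:
            logger.warning("trajectory target %s not resolvable; skipped", t)
    reports = trajectories.trajectory_report(
        beta, sheet, usable, annotation=ann, frac=block["frac"],
        robust_iters=block["robust_iters"])
    summary = pd.DataFrame(
        [
            {"target": rep.target_label, "n": rep.n, "r": rep.pearson_r,
             "log10_p": rep.log10_p}
            for rep in reports
        ]
    )
    curves = pd.concat(
        [rep.smooth_curve.assign(target=rep.target_label) for rep in reports],
        ignore_index=True,
    )[["target", "age", "fitted"]]
    p1, p2 = out / "trajectories.tsv", out / "trajectory_curves.tsv"
    cio.write_table(summary, p1)
    cio.write_table(curves, p2)
    state["trajectories"] = reports
    return [p1, p2]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "clean": _stage_clean,
    "prefilter": _stage_prefilter,
    "train": _stage_train,
    "crossval": _stage_crossval,
    "ageaccel": _stage_ageaccel,
    "ewas": _stage_ewas,
    "enrich": _stage_enrich,
    "assoc": _stage_assoc,
    "trajectories": _stage_trajectories,
}


# ---------------------------------------------------------------------------
# out-of-distribution calibration scenario
# ---------------------------------------------------------------------------

def out_of_distribution_scenario(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    train_interval: tuple[float, float],
    eval_intervals,
    centenarian_weight: float = 1.0,
    alpha: float = 0.5,
    n_lambdas: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Train a clock on a restricted age interval and measure the mean signed
    residual in disjoint evaluation intervals.

    Exposes the regression-to-the-mean behavior: a clock trained on e.g.
    40-90 underestimates ages above 100.  Evaluation intervals overlapping
    the training interval are rejected, except an interval equal to the
    training interval itself (the in-distribution calibration check, which
    is evaluated out-of-fold via a held-out split).
    """
    lo, hi = train_interval
    ages = sheet["age"].to_numpy(dtype=float)
    for elo, ehi in eval_intervals:
        if (elo, ehi) != (lo, hi) and elo < hi and ehi > lo:
            raise ValueError(
                f"evaluation interval [{elo}, {ehi}] overlaps training "
                f"interval [{lo}, {hi}]")
    train_mask = (ages >= lo) & (ages <= hi)
    rng = np.random.default_rng(seed)
    holdout = np.zeros(len(ages), dtype=bool)
    idx = np.flatnonzero(train_mask)
    holdout[rng.permutation(idx)[: max(len(idx) // 5, 1)]] = True

    fit_mask = train_mask & ~holdout
    w = clocks.sample_weights(ages[fit_mask], centenarian_weight)
    model = clocks.ElasticNetClock(
        beta[sheet["sample_id"][fit_mask]], ages[fit_mask], weights=w,
        alpha=alpha, n_lambdas=n_lambdas,
        centenarian_weight=centenarian_weight, training_age_min=lo, seed=seed)
    res = model.fit(lambda_="cv", cv_folds=cv_folds)

    rows = []
    for elo, ehi in eval_intervals:
        if (elo, ehi) == (lo, hi):
            emask = train_mask & holdout
        else:
            emask = (ages >= elo) & (ages <= ehi)
        n = int(emask.sum())
        if n == 0:
            rows.append({"eval_min": elo, "eval_max": ehi, "n": 0,
                         "mean_signed_residual": np.nan})
            continue
        pred = res.predict(beta[sheet["sample_id"][emask]])
        rows.append(
            {
                "eval_min": elo,
                "eval_max": ehi,
                "n": n,
                "mean_signed_residual": float(np.mean(pred - ages[emask])),
            }
        )
    return pd.DataFrame(rows)
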