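"""Synthetic aging-methylome cohorts.

Generates beta-value matrices (CpG x sample), sample sheets with survival
and biomarker columns, and BED-like CpG annotations carrying chromatin
states and polycomb (PRC1/PRC2) member binding flags.  The generator
plants the structure the downstream analyses assume and must recover:

* ages 40-115 with a thin >=100 tail (a uniform 40-95 body mixed with a
  shifted-exponential centenarian tail),
* CpG classes with positive-linear, negative-linear, saturating and null
  mean age trajectories, plus a sex-linked block that separates sexes in
  a QC PCA,
* age-increasing residual variance on the beta scale,
* additive per-(cohort, CpG) batch offsets much weaker than the age signal,
* a latent per-sample epigenetic age acceleration that shifts causal CpGs,
  drives an exponential mortality hazard (multiplicative per year of
  acceleration) and is weakly correlated with simulated biomarkers,
* chromatin-state annotation in which positive-linear CpGs are placed in
  bivalent/PRC2-like states with a configurable enrichment odds.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical config + seed gives identical
output, byte for byte once written.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "CHROMATIN_STATES",
    "PRC_TARGET_STATES",
    "PRC1_MEMBERS",
    "PRC2_MEMBERS",
    "simulate_cohort",
    "mean_trajectory",
    "simulate_survival",
    "simulate_biomarkers",
]

#: Chromatin-state universe used by the toy annotation.  Names follow the
#: universal (cell-type-agnostic) annotation vocabulary: bivalent promoters,
#: polycomb-repressed, active enhancers, exonic transcription, flanking
#: promoters, TSS and quiescent states.
CHROMATIN_STATES = (
    "BivProm1",
    "BivProm2",
    "ReprPC1",
    "EnhA1",
    "EnhA2",
    "EnhA7",
    "TxEx4",
    "PromF2",
    "PromF6",
    "TSS1",
    "Quies1",
    "Quies2",
)

#: States treated as PRC2-associated; positive-linear CpGs are preferentially
#: placed here so state enrichment is recoverable by construction.
PRC_TARGET_STATES = ("BivProm1", "BivProm2", "ReprPC1")

PRC1_MEMBERS = ("RING1", "RNF2", "BMI1")
PRC2_MEMBERS = ("EED", "SUZ12", "EZH2")

_CLASS_LABELS = ("pos_linear", "neg_linear", "saturating", "null", "sex_linked")


@dataclass
class SimConfig:
    """Configuration of a simulated cohort.

    Defaults emulate the marginal structure of a large multi-cohort blood
    methylome training set: ages 40-115 with ~2.6% of samples aged >=100
    (mean ~105.6 in the tail), ~55% female, a handful of source cohorts,
    and per-year mortality hazard ratio 1.05 per year of epigenetic age
    acceleration, at a desk-scale default size of 600 samples x 2000 CpGs.
    """

    n_samples: int = 600
    n_cpgs: int = 2000
    frac_pos_linear: float = 0.10
    frac_neg_linear: float = 0.10
    frac_saturating: float = 0.05
    frac_null: float = 0.75
    age_range: tuple[float, float] = (40.0, 115.0)
    centenarian_frac: float = 184 / 7039  # ~0.026
    centenarian_tail_scale: float = 5.6  # mean excess years above 100
    female_frac: float = 0.545
    n_cohorts: int = 3
    batch_sd: float = 0.01
    noise_sd_base: float = 0.04
    noise_sd_age_slope: float = 0.0004
    effect_slope_range: tuple[float, float] = (0.001, 0.003)
    sex_linked_frac: float = 0.03  # carved out of the null class
    sex_offset: float = 0.15
    enrichment_odds: float = 5.0
    accel_sd: float = 3.0  # SD (years) of latent age acceleration
    baseline_hazard: float = 0.02
    hr_per_year_accel: float = 1.05
    follow_up_years: float = 15.0
    n_biomarkers: int = 3
    biomarker_bicor_range: tuple[float, float] = (0.04, 0.17)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_pos_linear": self.frac_pos_linear,
            "frac_neg_linear": self.frac_neg_linear,
            "frac_saturating": self.frac_saturating,
            "frac_null": self.frac_null,
            "centenarian_frac": self.centenarian_frac,
            "female_frac": self.female_frac,
            "sex_linked_frac": self.sex_linked_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        total = (
            self.frac_pos_linear
            + self.frac_neg_linear
            + self.frac_saturating
            + self.frac_null
        )
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range {self.age_range} requires min < max")
        if self.noise_sd_base <= 0 or self.noise_sd_age_slope < 0:
            raise ValueError("noise SDs must be positive")
        if self.n_samples < 1 or self.n_cpgs < 1:
            raise ValueError("n_samples and n_cpgs must be >= 1")
        if self.hr_per_year_accel <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be > 0")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def _class_counts(config: SimConfig) -> dict[str, int]:
    """Integer class sizes by largest remainder; sex_linked is carved out of
    the null block."""
    n = config.n_cpgs
    fracs = {
        "pos_linear": config.frac_pos_linear,
        "neg_linear": config.frac_neg_linear,
        "saturating": config.frac_saturating,
        "null": config.frac_null,
    }
    floors = {k: int(np.floor(v * n)) for k, v in fracs.items()}
    short = n - sum(floors.values())
    remainders = sorted(
        fracs, key=lambda k: (fracs[k] * n - floors[k], k), reverse=True
    )
    for k in remainders[:short]:
        floors[k] += 1
    n_sex = min(int(round(config.sex_linked_frac * n)), floors["null"])
    floors["sex_linked"] = n_sex
    floors["null"] -= n_sex
    n_causal = floors["pos_linear"] + floors["neg_linear"] + floors["saturating"]
    if n_causal > 0 and n < len([c for c in floors.values() if c > 0]):
        raise ValueError("n_cpgs too small for the requested class mix")
    return floors


def _draw_ages(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.age_range
    n = config.n_samples
    n_cent = int(round(config.centenarian_frac * n)) if hi >= 100 else 0
    body_hi = min(95.0, hi)
    ages = np.empty(n)
    ages[: n - n_cent] = rng.uniform(lo, body_hi, size=n - n_cent)
    if n_cent:
        # shifted exponential above 100, truncated at hi by inverse CDF
        u = rng.uniform(size=n_cent)
        scale = config.centenarian_tail_scale
        cap = 1.0 - np.exp(-(hi - 100.0) / scale)
        ages[n - n_cent :] = 100.0 - scale * np.log1p(-u * cap)
    rng.shuffle(ages)
    return ages


def _draw_cpg_specs(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = _class_counts(config)
    labels = np.concatenate(
        [np.repeat(lab, counts[lab]) for lab in _CLASS_LABELS]
    )
    rng.shuffle(labels)
    n = config.n_cpgs
    age_max = config.age_range[1]
    lo_s, hi_s = config.effect_slope_range

    slopes = np.zeros(n)
    baselines = np.empty(n)
    saturation_age = np.full(n, np.nan)

    mag = rng.uniform(lo_s, hi_s, size=n)
    sat_age = rng.uniform(55.0, 75.0, size=n)
    sat_sign = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
    u = rng.uniform(size=n)

    for i, lab in enumerate(labels):
        if lab == "pos_linear":
            slopes[i] = mag[i]
            top = max(0.06, 0.95 - mag[i] * age_max)
            baselines[i] = 0.05 + u[i] * (top - 0.05)
        elif lab == "neg_linear":
            slopes[i] = -mag[i]
            bot = min(0.94, 0.05 + mag[i] * age_max)
            baselines[i] = bot + u[i] * (0.95 - bot)
        elif lab == "saturating":
            slopes[i] = sat_sign[i] * mag[i]
            saturation_age[i] = sat_age[i]
            span = mag[i] * sat_age[i]
            if sat_sign[i] > 0:
                top = max(0.06, 0.95 - span)
                baselines[i] = 0.05 + u[i] * (top - 0.05)
            else:
                bot = min(0.94, 0.05 + span)
                baselines[i] = bot + u[i] * (0.95 - bot)
        elif lab == "sex_linked":
            baselines[i] = 0.15 + u[i] * (0.80 - config.sex_offset - 0.15)
        else:  # null
            baselines[i] = 0.10 + u[i] * 0.80

    # chromatin-state assignment with planted enrichment for pos_linear CpGs
    base_w = np.ones(len(CHROMATIN_STATES))
    enr_w = base_w.copy()
    target_idx = [CHROMATIN_STATES.index(s) for s in PRC_TARGET_STATES]
    enr_w[target_idx] *= config.enrichment_odds
    states = np.empty(n, dtype=object)
    for i, lab in enumerate(labels):
        w = enr_w if lab == "pos_linear" else base_w
        states[i] = CHROMATIN_STATES[rng.choice(len(CHROMATIN_STATES), p=w / w.sum())]

    # PRC member binding flags, denser in the PRC-like states
    in_prc_state = np.isin(states, PRC_TARGET_STATES)
    member_flags = {}
    for m in PRC2_MEMBERS:
        p = np.where(in_prc_state, 0.75, 0.10)
        member_flags[m] = (rng.uniform(size=n) < p).astype(int)
    for m in PRC1_MEMBERS:
        p = np.where(in_prc_state, 0.25, 0.04)
        member_flags[m] = (rng.uniform(size=n) < p).astype(int)

    chrom = np.array([f"chr{(i % 22) + 1}" for i in range(n)])
    # positions strictly increasing within each chromosome
    pos = np.array([1000 + 100 * (i // 22) for i in range(n)])

    spec = pd.DataFrame(
        {
            "cpg_id": [f"cg{i:07d}" for i in range(n)],
            "class_label": labels,
            "baseline_beta": baselines,
            "slope": slopes,
            "saturation_age": saturation_age,
            "chrom": chrom,
            "pos": pos,
            "gene": [f"GENE{i % 500:03d}" for i in range(n)],
            "state": states,
        }
    )
    for m in PRC1_MEMBERS + PRC2_MEMBERS:
        spec[m] = member_flags[m]
    spec["prc1"] = (spec[list(PRC1_MEMBERS)].sum(axis=1) >= 2).astype(int)
    spec["prc2"] = (spec[list(PRC2_MEMBERS)].sum(axis=1) >= 2).astype(int)
    return spec


def mean_trajectory(spec, age: float) -> float:
    """Mean beta of a CpG at a given age, clamped to [0, 1].

    ``spec`` is a mapping (or DataFrame row) with ``class_label``,
    ``baseline_beta``, ``slope`` and, for saturating CpGs,
    ``saturation_age``.  Linear classes follow baseline + slope*age;
    saturating CpGs follow the line until saturation_age and stay flat
    after; null and sex-linked CpGs sit at baseline.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    label = spec["class_label"]
    base = spec["baseline_beta"]
    if label in ("null", "sex_linked"):
        value = base
    elif label in ("pos_linear", "neg_linear"):
        value = base + spec["slope"] * age
    elif label == "saturating":
        value = base + spec["slope"] * min(age, spec["saturation_age"])
    else:
        raise ValueError(f"unknown class_label {label!r}")
    return float(min(1.0, max(0.0, value)))


def _mean_matrix(spec: pd.DataFrame, ages: np.ndarray, female: np.ndarray,
                 sex_offset: float) -> np.ndarray:
    """Vectorised mean_trajectory over all CpGs and samples."""
    labels = spec["class_label"].to_numpy()
    base = spec["baseline_beta"].to_numpy()[:, None]
    slope = spec["slope"].to_numpy()[:, None]
    sat = spec["saturation_age"].to_numpy()[:, None]
    eff_age = np.broadcast_to(ages[None, :], (len(spec), len(ages))).copy()
    is_sat = labels == "saturating"
    eff_age[is_sat] = np.minimum(eff_age[is_sat], sat[is_sat])
    is_flat = np.isin(labels, ("null", "sex_linked"))
    eff_age[is_flat] = 0.0
    mean = base + slope * eff_age
    is_sex = labels == "sex_linked"
    mean[is_sex] += sex_offset * female[None, :]
    return mean


def simulate_survival(
    age_accel: np.ndarray,
    baseline_hazard: float,
    hr_per_year: float,
    follow_up: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival times with hazard baseline * hr^accel, censored
    administratively at ``follow_up`` years.

    Returns (time, event) arrays; event is 1 for an observed death.
    """
    age_accel = np.asarray(age_accel, dtype=float)
    if not np.all(np.isfinite(age_accel)):
        raise ValueError("age_accel must be finite")
    if baseline_hazard <= 0 or hr_per_year <= 0:
        raise ValueError("baseline_hazard and hr_per_year must be > 0")
    if follow_up <= 0:
        raise ValueError("follow_up must be > 0 (0 would censor everything)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hazard = baseline_hazard * hr_per_year**age_accel
    t = rng.exponential(1.0 / hazard)
    event = (t <= follow_up).astype(int)
    time = np.minimum(t, follow_up)
    return time, event


def simulate_biomarkers(
    age_accel: np.ndarray,
    targets,
    seed: int | np.random.Generator = 0,
    names=None,
) -> pd.DataFrame:
    """Biomarkers with prescribed correlation to age acceleration.

    Each biomarker is target * standardized(accel) + sqrt(1-target^2) * noise,
    so its population correlation with acceleration equals the target.
    """
    age_accel = np.asarray(age_accel, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if np.any(np.abs(targets) >= 1):
        raise ValueError("biomarker correlation targets must satisfy |t| < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = age_accel.std()
    z = (age_accel - age_accel.mean()) / (sd if sd > 0 else 1.0)
    cols = {}
    if names is None:
        names = [f"biomarker_{i + 1}" for i in range(len(targets))]
    for name, t in zip(names, targets):
        noise = rng.standard_normal(len(age_accel))
        cols[name] = t * z + np.sqrt(1.0 - t**2) * noise
    return pd.DataFrame(cols)


def default_biomarker_targets(config: SimConfig) -> np.ndarray:
    """Alternating-sign targets spanning the configured bicor magnitude range,
    strongest first and negative (a beta-carotene-like protective marker)."""
    lo, hi = config.biomarker_bicor_range
    mags = np.linspace(hi, lo, max(config.n_biomarkers, 1))
    signs = np.array([-1.0 if i % 2 == 0 else 1.0 for i in range(len(mags))])
    return mags * signs


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns
    -------
    beta : DataFrame, CpG x sample beta values in [0, 1] (index cpg_id)
    sheet : DataFrame with sample_id, age, sex, cohort, tissue, time, event,
        true_accel (latent ground-truth acceleration) and biomarker_* columns
    annotation : BED-like DataFrame (chrom, start, end, cpg_id, gene, state,
        prc1, prc2 plus individual PRC member flags)
    cpg_specs : ground-truth per-CpG table (class, baseline, slope, ...)
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    ages = _draw_ages(config, rng)
    n_female = int(round(config.female_frac * n))
    female = np.zeros(n, dtype=int)
    female[rng.permutation(n)[:n_female]] = 1
    cohort = rng.integers(config.n_cohorts, size=n)
    tissue = rng.choice(["blood", "saliva", "buccal"], size=n, p=[0.96, 0.03, 0.01])

    spec = _draw_cpg_specs(config, rng)

    # latent per-sample age acceleration shifts every causal CpG through an
    # effective age of (age + accel), so a trained clock's residual tracks it
    accel = rng.normal(0.0, config.accel_sd, size=n)
    mean = _mean_matrix(spec, ages + accel, female.astype(float), config.sex_offset)

    batch = rng.normal(0.0, config.batch_sd, size=(config.n_cohorts, config.n_cpgs))
    mean = mean + batch[cohort, :].T

    sd = config.noise_sd_base + config.noise_sd_age_slope * ages
    noise = rng.standard_normal((config.n_cpgs, n)) * sd[None, :]
    values = np.clip(mean + noise, 0.0, 1.0)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    beta = pd.DataFrame(values, index=spec["cpg_id"].to_numpy(), columns=sample_ids)
    beta.index.name = "cpg_id"

    time, event = simulate_survival(
        accel,
        config.baseline_hazard,
        config.hr_per_year_accel,
        config.follow_up_years,
        rng,
    )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": np.where(female == 1, "F", "M"),
            "cohort": [f"cohort{c + 1}" for c in cohort],
            "tissue": tissue,
            "time": time,
            "event": event,
            "true_accel": accel,
        }
    )
    if config.n_biomarkers > 0:
        bio = simulate_biomarkers(accel, default_biomarker_targets(config), rng)
        sheet = pd.concat([sheet, bio], axis=1)

    annotation = spec[
        ["chrom", "pos", "cpg_id", "gene", "state"]
        + list(PRC1_MEMBERS)
        + list(PRC2_MEMBERS)
        + ["prc1", "prc2"]
    ].copy()
    annotation.insert(1, "start", annotation.pop("pos"))
    annotation.insert(2, "end", annotation["start"] + 2)
    return beta, sheet, annotation, spec
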