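"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators mirror the three data modalities of a hyperglycemia
methylation study:

* :func:`simulate_array_study` — a paired two-timepoint methylation-array
  beta matrix (each subject measured at stage 1 and stage 5) over case and
  control arms in one or more OGTT-defined subgroups, with *planted*
  stage-specific shifts (both arms move between stages) and case-specific
  shifts (only cases move), plus logit-normal measurement noise.
* :func:`simulate_traits` — a clinical trait table (glucose, insulin,
  HbA1c, BMI, blood counts) with a configurable linear dependence of each
  trait on target-CpG methylation.
* :func:`simulate_wgbs_counts` — per-cytosine bisulfite counts over a
  genomic region for a donor cohort, with binomial sampling around
  group-specific methylation levels and a planted control-minus-case
  difference; both strands of every CpG are emitted as separate records.

All generators are pure functions of (config, seed): the master seed is
split into independent child streams with ``numpy.random.SeedSequence.spawn``
(one child per draw component, in a fixed documented order), so identical
configs reproduce byte-identical outputs and adding probes/sites perturbs
no other stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ArraySimConfig",
    "TraitSimConfig",
    "WgbsSimConfig",
    "simulate_array_study",
    "simulate_traits",
    "simulate_wgbs_counts",
    "default_islet_donors",
]

logger = logging.getLogger(__name__)

_EPS = 1e-6


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fixed-order child generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# methylation array


@dataclass
class ArraySimConfig:
    """Paired two-timepoint array study design.

    ``stage_effect`` maps probe index -> beta-scale shift applied at stage 5
    in *both* arms (a time/age effect); ``case_effect`` maps probe index ->
    shift applied at stage 5 in the *case* arm only (the condition-specific
    signal the cascade is meant to isolate).  ``noise_sd`` is the
    approximate per-measurement standard deviation on the beta scale; noise
    is drawn logit-normally so values stay inside (0, 1).
    """

    n_probes: int = 1000
    n_subjects_per_arm: int = 8
    subgroups: tuple = ("hiGlu60",)
    baseline_beta_mean: float = 0.5
    baseline_beta_concentration: float = 50.0
    stage_effect: dict = field(default_factory=dict)
    case_effect: dict = field(default_factory=dict)
    noise_sd: float = 0.03
    subject_sd: float = 0.05
    seed: int = 0

    def validate(self):
        if self.n_probes <= 0 or self.n_subjects_per_arm <= 0:
            raise ValueError("n_probes and n_subjects_per_arm must be positive")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be nonnegative")
        for name, eff in (("stage_effect", self.stage_effect),
                          ("case_effect", self.case_effect)):
            for idx in eff:
                if not 0 <= idx < self.n_probes:
                    raise ValueError(f"{name} probe index {idx} outside "
                                     f"[0, {self.n_probes})")


def _beta_noise(rng, mean: np.ndarray, sd_beta: float) -> np.ndarray:
    """Logit-normal draw around ``mean`` with approximate beta-scale sd."""
    mean = np.clip(mean, _EPS, 1 - _EPS)
    if sd_beta == 0:
        return mean
    # delta method: sd on logit scale that maps to sd_beta near the mean
    sd_logit = sd_beta / (mean * (1 - mean))
    return expit(logit(mean) + rng.normal(0.0, sd_logit, size=mean.shape))


def simulate_array_study(config: ArraySimConfig):
    """Generate (beta matrix, sample sheet, truth table) for one array study.

    The beta matrix has one column per (subject, stage) sample, named
    ``<subject>_s<stage>``; the sample sheet carries ``sample_id,
    subject_id, stage, arm, subgroup``.  The truth table lists every
    planted probe with its effect kind and delta.
    """
    config.validate()
    rng_base, rng_subj, rng_noise = _rngs(config.seed, 3)

    m = config.baseline_beta_mean
    c = config.baseline_beta_concentration
    base_means = rng_base.beta(m * c, (1 - m) * c, size=config.n_probes)

    stage_delta = np.zeros(config.n_probes)
    for idx, d in config.stage_effect.items():
        stage_delta[idx] = d
    case_delta = np.zeros(config.n_probes)
    for idx, d in config.case_effect.items():
        case_delta[idx] = d

    # reject deltas that push a planted probe's mean outside [0, 1]
    shifted = base_means + stage_delta + case_delta
    bad = np.flatnonzero((shifted <= 0) | (shifted >= 1))
    if bad.size:
        raise ValueError(
            f"planted delta pushes mean beta outside [0, 1] at probe index "
            f"{bad[:5].tolist()} (baseline {base_means[bad[:5]].round(3).tolist()})")

    probe_ids = [f"cg{i:07d}" for i in range(config.n_probes)]
    sheet_rows = []
    columns: dict[str, np.ndarray] = {}
    for sg in config.subgroups:
        for arm in ("control", "case"):
            for s in range(config.n_subjects_per_arm):
                subject = f"{sg}_{arm}_{s:02d}"
                # stable per-subject offset (logit scale) shared by both stages
                offset = rng_subj.normal(0.0, 1.0, size=config.n_probes)
                for stage in (1, 5):
                    mu = base_means.copy()
                    if stage == 5:
                        mu = mu + stage_delta
                        if arm == "case":
                            mu = mu + case_delta
                    mu = np.clip(mu, _EPS, 1 - _EPS)
                    sd_logit = (config.subject_sd / (mu * (1 - mu))
                                if config.subject_sd else 0.0)
                    mu = expit(logit(mu) + offset * sd_logit)
                    sample = f"{subject}_s{stage}"
                    columns[sample] = _beta_noise(rng_noise, mu, config.noise_sd)
                    sheet_rows.append({"sample_id": sample,
                                       "subject_id": subject,
                                       "stage": stage, "arm": arm,
                                       "subgroup": sg})

    beta = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    sheet = pd.DataFrame(sheet_rows)

    truth_rows = [{"probe_id": probe_ids[i], "effect": "stage", "delta": d}
                  for i, d in sorted(config.stage_effect.items())]
    truth_rows += [{"probe_id": probe_ids[i], "effect": "case", "delta": d}
                   for i, d in sorted(config.case_effect.items())]
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "effect", "delta"])
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# clinical traits

#: Per-arm (mean, sd) defaults emulating a replication cohort of elderly
#: T2D cases and matched controls.  Glucose in mg/dL, insulin in uU/mL,
#: HbA1c percent, BMI kg/m^2, WBC 10^3/uL, RBC 10^6/uL.
DEFAULT_TRAIT_SPECS = {
    "age":    {"control": (61.1, 9.3), "case": (60.1, 8.0)},
    "BMI":    {"control": (23.8, 3.1), "case": (25.6, 3.0)},
    "HbA1c":  {"control": (5.4, 0.5),  "case": (7.6, 1.3)},
    "Glu0":   {"control": (92.2, 7.6), "case": (165.5, 54.3)},
    "Glu60":  {"control": (120.0, 25.0), "case": (280.0, 60.0)},
    "Glu120": {"control": (110.0, 25.0), "case": (250.0, 50.0)},
    "Ins0":   {"control": (8.3, 3.4),  "case": (16.7, 8.0)},
    "WBC":    {"control": (6.3, 1.7),  "case": (6.4, 1.7)},
    "RBC":    {"control": (4.7, 0.45), "case": (4.7, 0.45)},
}

#: Per-arm (mean, sd) of percent methylation at the target CpG.
DEFAULT_METHYLATION_SPEC = {"control": (29.5, 3.7), "case": (26.4, 3.3)}

_POSITIVE_TRAITS = ("Glu0", "Glu60", "Glu120", "Ins0", "HbA1c", "BMI",
                    "WBC", "RBC")


@dataclass
class TraitSimConfig:
    """Case/control trait-table design with a methylation-trait link.

    ``methylation_trait_slope`` maps trait -> slope: the trait mean shifts
    by ``slope`` per percentage point of target-CpG methylation (centred
    within the cohort, so arm means are preserved).
    """

    n_per_arm: int = 220
    trait_specs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TRAIT_SPECS.items()})
    methylation_spec: dict = field(default_factory=lambda: dict(
        DEFAULT_METHYLATION_SPEC))
    methylation_trait_slope: dict = field(default_factory=dict)
    female_fraction: float = 0.46
    seed: int = 0

    def validate(self):
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")


def simulate_traits(config: TraitSimConfig, methylation=None) -> pd.DataFrame:
    """Generate a subject trait table with a planted methylation-trait link.

    ``methylation`` is an optional per-subject percent-methylation vector
    (controls first, then cases; length 2 * n_per_arm); if omitted it is
    drawn from the per-arm ``methylation_spec``.  Traits whose draws must
    be positive (glucose, insulin, counts, ...) are redrawn up to 100
    times; any value still non-positive is clamped to a small positive
    floor with a warning.
    """
    config.validate()
    rng_meth, rng_traits, rng_sex = _rngs(config.seed, 3)
    n = config.n_per_arm
    arms = ["control"] * n + ["case"] * n

    if methylation is None:
        meth = np.concatenate([
            rng_meth.normal(*config.methylation_spec["control"], size=n),
            rng_meth.normal(*config.methylation_spec["case"], size=n)])
        meth = np.clip(meth, 0.0, 100.0)
    else:
        meth = np.asarray(methylation, dtype=float)
        if meth.size != 2 * n:
            raise ValueError(f"methylation vector length {meth.size} != "
                             f"{2 * n} subjects")

    table = pd.DataFrame({
        "subject_id": [f"subj_{i:04d}" for i in range(2 * n)],
        "arm": arms,
        "sex": np.where(rng_sex.random(2 * n) < config.female_fraction,
                        "female", "male"),
        "methylation_target": meth,
    })

    meth_centered = meth - meth.mean()
    for trait, spec in config.trait_specs.items():
        mu = np.array([spec[a][0] for a in arms])
        sd = np.array([spec[a][1] for a in arms])
        slope = config.methylation_trait_slope.get(trait, 0.0)
        loc = mu + slope * meth_centered
        vals = rng_traits.normal(loc, sd)
        if trait in _POSITIVE_TRAITS:
            for _ in range(100):
                neg = vals <= 0
                if not neg.any():
                    break
                vals[neg] = rng_traits.normal(loc[neg], sd[neg])
            if (vals <= 0).any():
                logger.warning("%d non-positive %s draw(s) clamped to 0.01",
                               int((vals <= 0).sum()), trait)
                vals = np.maximum(vals, 0.01)
        table[trait] = vals
    return table


# ---------------------------------------------------------------------------
# WGBS counts


def default_islet_donors() -> pd.DataFrame:
    """Deterministic 18-donor roster emulating an islet WGBS cohort:
    2 T2D cases (both male, over 40), 8 males / 10 females overall,
    5 donors under 40."""
    rows = []
    ages_young = [28, 32, 35, 37, 39]
    ages_old = [42, 45, 48, 51, 54, 57, 60, 63, 66, 69, 72, 75, 78]
    sexes = (["male"] * 8 + ["female"] * 10)
    ages = ages_young + ages_old
    for i in range(18):
        rows.append({"donor_id": f"donor_{i + 1:02d}",
                     "age": ages[i], "sex": sexes[i],
                     "t2d": i in (5, 6)})      # two old males
    return pd.DataFrame(rows)


@dataclass
class WgbsSimConfig:
    """Per-cytosine bisulfite count design over one genomic region.

    CpG positions are laid down with geometric inter-CpG gaps (default mean
    34 bp, matching a density of roughly 290 strand-specific sites per
    10 kb); each CpG contributes a plus-strand record at ``pos`` and a
    minus-strand record at ``pos + 1``.  Per donor and record, coverage is
    Poisson around ``mean_coverage`` and the C count binomial at the
    donor-group methylation level.  ``planted_delta`` is the
    control-minus-case methylation difference (methylation fraction scale)
    at every site.
    """

    chrom: str = "chr17"
    start: int = 55479635
    end: int = 55489635
    mean_gap: float = 34.0
    control_level: float = 0.72
    planted_delta: float = 0.16
    mean_coverage: float = 30.0
    donors: pd.DataFrame = None
    seed: int = 0

    def validate(self):
        if self.end < self.start:
            raise ValueError("empty region: end < start")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.mean_gap < 2:
            raise ValueError("mean_gap must be at least 2 (CpGs occupy 2 bp)")
        case = self.control_level - self.planted_delta
        if not (0 <= self.control_level <= 1 and 0 <= case <= 1):
            raise ValueError("group methylation levels must lie in [0, 1]")


def simulate_wgbs_counts(config: WgbsSimConfig):
    """Generate (per-donor call tables, donor metadata, truth table).

    Returns a dict donor_id -> methratio-style DataFrame (chrom, pos,
    strand, context, ratio, eff_ct, c_count), the donor metadata used
    (default: :func:`default_islet_donors`), and a truth table of site
    positions with the group methylation levels and the planted delta.
    T2D donors methylate at ``control_level - planted_delta``.
    """
    config.validate()
    donors = (config.donors if config.donors is not None
              else default_islet_donors())
    rng_sites, rng_counts = _rngs(config.seed, 2)

    positions = []
    pos = config.start + int(rng_sites.geometric(1.0 / config.mean_gap))
    while pos + 1 <= config.end:
        positions.append(pos)
        pos += max(2, int(rng_sites.geometric(1.0 / config.mean_gap)))
    if not positions:
        raise ValueError("region too short: no CpG sites generated")

    case_level = config.control_level - config.planted_delta
    records_pos = []
    records_strand = []
    for p in positions:
        records_pos.extend([p, p + 1])
        records_strand.extend(["+", "-"])
    records_pos = np.array(records_pos)
    n_rec = records_pos.size

    tables = {}
    for _, donor in donors.iterrows():
        level = case_level if bool(donor["t2d"]) else config.control_level
        cov = rng_counts.poisson(config.mean_coverage, size=n_rec)
        c = rng_counts.binomial(cov, level)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(cov > 0, c / np.maximum(cov, 1), np.nan)
        tables[donor["donor_id"]] = pd.DataFrame({
            "chrom": config.chrom,
            "pos": records_pos,
            "strand": records_strand,
            "context": "CG",
            "ratio": ratio,
            "eff_ct": cov,
            "c_count": c,
        })

    truth = pd.DataFrame({
        "pos": positions,
        "control_level": config.control_level,
        "case_level": case_level,
        "delta": config.planted_delta,
    })
    return tables, donors.copy(), truth
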