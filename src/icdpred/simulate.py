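"""Synthetic longitudinal PD cohort generator with known ground truth.

Real impulse-control-disorder (ICD) cohorts are access-restricted, so this
module generates cohorts with the statistical structure the downstream
analysis assumes: subject-level visit sequences at roughly annual irregular
intervals, Gaussian AR(1) clinical scales around subject-level means,
Hardy-Weinberg SNP dosages, piecewise-constant dopamine-agonist (DA)
exposure, and a binary ICD outcome generated by a first-order Markov
logistic hazard whose coefficients are known, so that signal recovery is
testable.

Two dialects are provided.  ``drugnaive_baseline`` emulates a de novo
cohort (no medication exposure at baseline, longer follow-up, lower ICD
prevalence); ``treated_baseline`` emulates an already-treated cohort
(possible exposure at time 0, fewer visits, higher prevalence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (
    SCALE_COLUMNS,
    Cohort,
    MedicationInterval,
    SubjectRecord,
    Visit,
)
from .features import derive_da_features

DIALECTS = ("drugnaive_baseline", "treated_baseline")

# reference scales used to put exposure covariates on a ~unit scale inside
# the hazard's linear predictor (years of DA exposure, LEDD-years of dose)
DUR_SCALE_YEARS = 2.0
DOSE_SCALE_LEDD_YEARS = 400.0
AGE_REF_MEAN, AGE_REF_SD = 60.0, 10.0


class ConfigurationError(ValueError):
    """A cohort configuration violates its invariants."""


@dataclass(frozen=True)
class ScaleSpec:
    """Population mean/sd and AR(1) autocorrelation of one clinical scale."""

    mean: float
    sd: float
    rho: float = 0.7

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError("scale sd must be positive")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("AR(1) autocorrelation must be in [0, 1)")


@dataclass(frozen=True)
class EffectSizes:
    """Named coefficients of the Markov logistic outcome model.

    All covariates enter the linear predictor on a standardized scale.
    Default signs follow the direction of the known clinical risk factors:
    male sex, prior ICD status, depression, REM sleep disturbance, motor
    severity and cumulative DA duration increase risk; older age and
    anxiety decrease it.
    """

    beta0: float = -2.85
    beta_prev: float = 2.5
    beta_dur: float = 0.6
    beta_dose: float = -0.2
    beta_age: float = -0.3
    beta_sex: float = 0.4
    beta_dep: float = 0.3
    beta_rem: float = 0.3
    beta_anx: float = -0.2
    beta_mot: float = 0.3
    gamma_snp: tuple[float, ...] = ()

    def as_dict(self) -> dict[str, float | tuple[float, ...]]:
        return {
            "beta0": self.beta0,
            "beta_prev": self.beta_prev,
            "beta_dur": self.beta_dur,
            "beta_dose": self.beta_dose,
            "beta_age": self.beta_age,
            "beta_sex": self.beta_sex,
            "beta_dep": self.beta_dep,
            "beta_rem": self.beta_rem,
            "beta_anx": self.beta_anx,
            "beta_mot": self.beta_mot,
            "gamma_snp": tuple(self.gamma_snp),
        }


@dataclass(frozen=True)
class TreatmentPolicy:
    """Probabilities and dose ranges governing medication exposure.

    Dopamine-agonist episodes start at a visit with per-visit probability
    ``da_start_prob`` (geometric over visits), carry a daily dose drawn
    uniformly from ``da_dose_range`` (levodopa equivalents), stay constant
    between visits and stop with per-visit probability ``da_stop_prob``.
    Levodopa and other-medication are tracked as binary flags only.
    """

    da_start_prob: float = 0.18
    da_stop_prob: float = 0.05
    da_dose_range: tuple[float, float] = (50.0, 300.0)
    da_on_at_baseline: float = 0.0
    levodopa_start_prob: float = 0.35
    levodopa_on_at_baseline: float = 0.0
    other_start_prob: float = 0.10
    other_on_at_baseline: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.da_dose_range
        if not (0 < lo <= hi):
            raise ConfigurationError("DA dose range must be positive and ordered")
        for p in (
            self.da_start_prob,
            self.da_stop_prob,
            self.da_on_at_baseline,
            self.levodopa_start_prob,
            self.levodopa_on_at_baseline,
            self.other_start_prob,
            self.other_on_at_baseline,
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError("policy probabilities must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_subjects: int = 380
    dialect: str = "drugnaive_baseline"
    visits_mean: float = 7.18
    visits_sd: float = 2.96
    visits_min: int = 2
    visits_max: int = 15
    interval_mean: float = 0.95
    interval_sd: float = 0.35
    interval_floor: float = 0.25
    n_snps: int = 31
    maf_range: tuple[float, float] = (0.05, 0.5)
    scale_specs: dict[str, ScaleSpec] = field(
        default_factory=lambda: {
            "anxiety": ScaleSpec(93.55, 7.96),
            "depression": ScaleSpec(5.25, 1.47),
            "rem": ScaleSpec(4.17, 2.71),
            "updrs3": ScaleSpec(20.87, 8.86),
        }
    )
    missing_rate: dict[str, float] = field(
        default_factory=lambda: {s: 0.05 for s in SCALE_COLUMNS}
    )
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    treatment_policy: TreatmentPolicy = field(default_factory=TreatmentPolicy)
    baseline_icd_prevalence: float = 0.13
    age_mean: float = 60.67
    age_sd: float = 9.71
    male_fraction: float = 0.66
    #: subject-id prefix; None derives one from the dialect so that two
    #: default cohorts never share subject identifiers
    id_prefix: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if self.dialect not in DIALECTS:
            raise ConfigurationError(f"unknown dialect {self.dialect!r}")
        if self.visits_min < 2:
            raise ConfigurationError(
                "visits_per_subject minimum is 2 (a baseline visit and at "
                "least another visit)"
            )
        if self.visits_sd < 0 or self.interval_sd < 0:
            raise ConfigurationError("distribution sd must be non-negative")
        if self.interval_floor <= 0:
            raise ConfigurationError("interval truncation floor must be > 0")
        if self.n_snps < 0:
            raise ConfigurationError("n_snps must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name, rate in self.missing_rate.items():
            if not 0 <= rate < 1:
                raise ConfigurationError(f"missing rate for {name} must be in [0,1)")
        if not 0 < self.baseline_icd_prevalence < 1:
            raise ConfigurationError("baseline prevalence must be in (0, 1)")
        gammas = self.effect_sizes.gamma_snp
        if gammas and len(gammas) != self.n_snps:
            raise ConfigurationError("gamma_snp length must equal n_snps")


def treated_baseline_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default configuration of the already-treated dialect.

    Fewer visits at slightly longer intervals, different anxiety/depression
    instruments, possible medication exposure at baseline and a higher ICD
    prevalence, mirroring the contrast between a de novo cohort and a
    cohort recruited within five years of diagnosis.
    """
    base = dict(
        n_subjects=388,
        dialect="treated_baseline",
        visits_mean=5.41,
        visits_sd=1.66,
        interval_mean=1.09,
        interval_sd=0.33,
        scale_specs={
            "anxiety": ScaleSpec(6.82, 3.77),
            "depression": ScaleSpec(4.59, 3.16),
            "rem": ScaleSpec(0.22, 0.41),
            "updrs3": ScaleSpec(9.91, 5.33),
        },
        effect_sizes=EffectSizes(beta0=-2.3),
        treatment_policy=TreatmentPolicy(
            da_on_at_baseline=0.35,
            levodopa_on_at_baseline=0.55,
            other_on_at_baseline=0.10,
        ),
        baseline_icd_prevalence=0.20,
        age_mean=58.99,
        age_sd=9.75,
        male_fraction=0.60,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis is supposed to recover."""

    coefficients: dict
    subject_ids: list[str]
    #: per (subject, visit>=2) true event probability, aligned with
    #: observation order (subject by subject, visit 2..n)
    true_probabilities: np.ndarray
    #: latent (noise-free) subject-level scale means
    subject_scale_means: dict[str, np.ndarray]


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def generate_genotypes(
    n_subjects: int, n_snps: int, maf_range: tuple[float, float], seed: int
) -> np.ndarray:
    """Biallelic SNP dosages in {0,1,2}, Hardy-Weinberg by construction.

    SNP j has a minor allele frequency drawn uniformly from ``maf_range``;
    each subject's dosage is Binomial(2, MAF_j).
    """
    if n_subjects <= 0 or n_snps < 0:
        raise ConfigurationError("counts must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigurationError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    return rng.binomial(2, mafs, size=(n_subjects, n_snps)).astype(float)


def _simulate_scales(
    rng: np.random.Generator, spec: ScaleSpec, n_visits: int
) -> tuple[float, np.ndarray]:
    """Gaussian AR(1) around a subject-level mean.

    The total variance spec.sd**2 is split 40/60 between the subject-level
    mean and the stationary within-subject process, giving the temporal
    autocorrelation that forward-fill imputation presumes.
    """
    sd_between = spec.sd * np.sqrt(0.4)
    sd_within = spec.sd * np.sqrt(0.6)
    mu = rng.normal(spec.mean, sd_between)
    values = np.empty(n_visits)
    values[0] = mu + rng.normal(0, sd_within)
    for k in range(1, n_visits):
        values[k] = mu + spec.rho * (values[k - 1] - mu) + rng.normal(
            0, sd_within * np.sqrt(1 - spec.rho**2)
        )
    return mu, values


def _flag_sequence(
    rng: np.random.Generator,
    n_visits: int,
    on_at_baseline: float,
    start_prob: float,
    stop_prob: float = 0.0,
) -> np.ndarray:
    on = np.zeros(n_visits, dtype=int)
    state = int(rng.random() < on_at_baseline)
    for k in range(n_visits):
        if state == 0 and k > 0:
            state = int(rng.random() < start_prob)
        elif state == 1 and k > 0 and stop_prob > 0:
            state = 0 if rng.random() < stop_prob else 1
        on[k] = state
    return on


def _da_intervals(
    rng: np.random.Generator,
    times: np.ndarray,
    on: np.ndarray,
    dose_range: tuple[float, float],
) -> list[MedicationInterval]:
    """Consecutive on-visits become constant-dose exposure intervals.

    Each on-visit contributes exposure from its time to the next visit's
    time (the last visit contributes nothing beyond follow-up); a new dose
    is drawn whenever an episode starts.
    """
    intervals: list[MedicationInterval] = []
    dose = None
    for k in range(len(times) - 1):
        if on[k]:
            if dose is None:
                dose = float(rng.uniform(*dose_range))
            intervals.append(
                MedicationInterval(
                    "dopamine_agonist", float(times[k]), float(times[k + 1]), dose
                )
            )
        else:
            dose = None
    # merge back-to-back same-dose intervals for a tidy record
    merged: list[MedicationInterval] = []
    for iv in intervals:
        if (
            merged
            and merged[-1].end_years == iv.start_years
            and merged[-1].daily_dose_ledd == iv.daily_dose_ledd
        ):
            merged[-1] = replace(merged[-1], end_years=iv.end_years)
        else:
            merged.append(iv)
    return merged


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and the ground truth that produced it.

    ICD statuses are generated sequentially: the status at visit t+1 is
    Bernoulli with logit equal to the linear predictor over the subject's
    standardized covariates current at t+1, the ICD status at t, and the
    cumulative DA exposure accrued by t+1.  The baseline status uses the
    same covariates without the persistence term, around a configured
    baseline prevalence.  Identical config (including seed) gives an
    identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    eff = config.effect_sizes
    gammas = np.asarray(
        eff.gamma_snp if eff.gamma_snp else np.zeros(config.n_snps), dtype=float
    )

    genotypes = generate_genotypes(
        config.n_subjects,
        config.n_snps,
        config.maf_range,
        seed=int(rng.integers(2**31)),
    )
    # center dosages at their expected scale so gamma acts on ~unit inputs
    geno_centered = genotypes - genotypes.mean(axis=0, keepdims=True)

    drugnaive = config.dialect == "drugnaive_baseline"
    policy = config.treatment_policy
    if drugnaive and policy.da_on_at_baseline > 0:
        raise ConfigurationError(
            "drugnaive_baseline dialect requires zero exposure at time 0"
        )
    logit_base = _logit(config.baseline_icd_prevalence)

    subjects: list[SubjectRecord] = []
    true_probs: list[float] = []
    scale_means: dict[str, list[float]] = {s: [] for s in SCALE_COLUMNS}

    prefix = config.id_prefix or (
        "S" if config.dialect == "drugnaive_baseline" else "T"
    )
    for i in range(config.n_subjects):
        sid = f"{prefix}{i + 1:04d}"
        age = float(rng.normal(config.age_mean, config.age_sd))
        sex = int(rng.random() < config.male_fraction)

        n_visits = int(
            np.clip(
                round(rng.normal(config.visits_mean, config.visits_sd)),
                config.visits_min,
                config.visits_max,
            )
        )
        intervals = np.maximum(
            rng.normal(config.interval_mean, config.interval_sd, size=n_visits - 1),
            config.interval_floor,
        )
        times = np.concatenate([[0.0], np.cumsum(intervals)])

        scales = {}
        for name in SCALE_COLUMNS:
            mu, vals = _simulate_scales(rng, config.scale_specs[name], n_visits)
            scales[name] = vals
            scale_means[name].append(mu)

        da_on = _flag_sequence(
            rng,
            n_visits,
            policy.da_on_at_baseline,
            policy.da_start_prob,
            policy.da_stop_prob,
        )
        ld_on = _flag_sequence(
            rng, n_visits, policy.levodopa_on_at_baseline, policy.levodopa_start_prob
        )
        ot_on = _flag_sequence(
            rng, n_visits, policy.other_on_at_baseline, policy.other_start_prob
        )
        medication = _da_intervals(rng, times, da_on, policy.da_dose_range)

        # standardized covariate contributions shared by all visits;
        # sex is centered at the configured male fraction so beta_sex
        # shifts risk between sexes without moving the overall prevalence
        static_eta = (
            eff.beta_age * (age - AGE_REF_MEAN) / AGE_REF_SD
            + eff.beta_sex * (sex - config.male_fraction)
            + float(geno_centered[i] @ gammas)
        )

        def visit_eta(k: int) -> float:
            z = {
                name: (scales[name][k] - config.scale_specs[name].mean)
                / config.scale_specs[name].sd
                for name in SCALE_COLUMNS
            }
            _, _, total_dose, cum_dur = derive_da_features_from_intervals(
                medication, float(times[k])
            )
            return (
                static_eta
                + eff.beta_dep * z["depression"]
                + eff.beta_rem * z["rem"]
                + eff.beta_anx * z["anxiety"]
                + eff.beta_mot * z["updrs3"]
                + eff.beta_dur * cum_dur / DUR_SCALE_YEARS
                + eff.beta_dose * total_dose / DOSE_SCALE_LEDD_YEARS
            )

        icd = np.zeros(n_visits, dtype=int)
        p0 = 1 / (1 + np.exp(-(logit_base + visit_eta(0))))
        icd[0] = int(rng.random() < p0)
        for k in range(1, n_visits):
            eta = eff.beta0 + eff.beta_prev * icd[k - 1] + visit_eta(k)
            p = 1 / (1 + np.exp(-eta))
            true_probs.append(p)
            icd[k] = int(rng.random() < p)

        visits = [
            Visit(
                time_years=float(times[k]),
                anxiety=float(scales["anxiety"][k]),
                depression=float(scales["depression"][k]),
                rem=float(scales["rem"][k]),
                updrs3=float(scales["updrs3"][k]),
                icd=int(icd[k]),
                on_levodopa=int(ld_on[k]),
                on_dopamine_agonist=int(da_on[k]),
                on_other=int(ot_on[k]),
                da_daily_dose=float(
                    next(
                        (
                            m.daily_dose_ledd
                            for m in medication
                            if m.start_years <= times[k] < m.end_years
                        ),
                        0.0,
                    )
                )
                if da_on[k]
                else 0.0,
            )
            for k in range(n_visits)
        ]
        subjects.append(
            SubjectRecord(sid, age, sex, genotypes[i], visits, medication)
        )

    cohort = Cohort(subjects, config.dialect)
    if any(r > 0 for r in config.missing_rate.values()):
        cohort = inject_missingness(
            cohort, config.missing_rate, seed=(config.seed * 7919 + 13) % 2**31
        )
    truth = GroundTruth(
        coefficients=eff.as_dict(),
        subject_ids=cohort.subject_ids,
        true_probabilities=np.array(true_probs),
        subject_scale_means={k: np.array(v) for k, v in scale_means.items()},
    )
    return cohort, truth


def derive_da_features_from_intervals(
    intervals: list[MedicationInterval], t: float
) -> tuple[float, float, float, float]:
    """Dopamine-agonist exposure summaries over [0, t] from raw intervals."""
    return derive_da_features(intervals, t)


def inject_missingness(
    cohort: Cohort, missing_rate: dict[str, float], seed: int
) -> Cohort:
    """Set clinical scale values missing completely at random.

    ICD status, sex, age and medication variables are never masked.  For
    each scale at least one baseline value is retained cohort-wide so that
    baseline-mean imputation stays computable.
    """
    for name, rate in missing_rate.items():
        if not 0 <= rate < 1:
            raise ConfigurationError(f"missing rate for {name} must be in [0,1)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for name in SCALE_COLUMNS:
        rate = missing_rate.get(name, 0.0)
        if rate == 0:
            continue
        baseline_kept = 0
        first_masked_subject: int | None = None
        for si, subj in enumerate(out.subjects):
            for j, v in enumerate(subj.visits):
                if rng.random() < rate:
                    if j == 0 and first_masked_subject is None:
                        first_masked_subject = si
                    setattr(v, name, np.nan)
                elif j == 0:
                    baseline_kept += 1
        if baseline_kept == 0 and first_masked_subject is not None:
            # restore that subject's original baseline value so the
            # training mean exists; only triggers at extreme rates on
            # tiny cohorts
            original = cohort.subjects[first_masked_subject].visits[0]
            setattr(
                out.subjects[first_masked_subject].visits[0],
                name,
                original.scale_value(name),
            )
    return out
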