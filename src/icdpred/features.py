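"""From raw visit histories to supervised next-visit observations.

The prediction task is longitudinal: given a subject's clinical history up
to visit t and their static covariates, predict the binary ICD status at
visit t+1.  A subject with n visits therefore contributes n-1 observations,
one per visit except the last.

This module houses imputation (forward fill, then training-set baseline
means), derived dopamine-agonist exposure features, observation
construction and train-set-only standardization.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SCALE_COLUMNS, Cohort, MedicationInterval, SubjectRecord

#: order of the per-visit (sequential) features
CLINICAL_FEATURES = (
    "anxiety",
    "depression",
    "rem",
    "updrs3",
    "icd",
    "on_levodopa",
    "on_dopamine_agonist",
    "on_other",
    "da_mean_daily",
    "da_max_daily",
    "da_total_dose",
    "da_cum_duration",
    "time_to_next",
    "followup_length",
)


class ImputationError(ValueError):
    """A feature cannot be imputed (e.g. missing at every training baseline)."""


class InclusionCriterionError(ValueError):
    """A subject fails the >= 2 visits inclusion criterion."""


class SchemaError(ValueError):
    """Observation feature schema does not match the fitted schema."""


# --------------------------------------------------------------- imputation


def forward_fill(cohort: Cohort) -> Cohort:
    """Impute each missing scale value with the subject's most recent one.

    Baseline missing values (no earlier value exists) remain missing.
    Idempotent: applying twice equals applying once.
    """
    out = cohort.copy()
    for subj in out.subjects:
        for name in SCALE_COLUMNS:
            last = np.nan
            for v in subj.visits:
                val = v.scale_value(name)
                if np.isnan(val):
                    if not np.isnan(last):
                        setattr(v, name, last)
                else:
                    last = val
    return out


def baseline_means(cohort: Cohort, subject_ids=None) -> dict[str, float]:
    """Per-scale mean over baseline visits, restricted to given subjects.

    These are the statistics a training set contributes; computing them on
    training subjects only is what keeps the imputation leak-free.
    """
    wanted = set(subject_ids) if subject_ids is not None else None
    means: dict[str, float] = {}
    for name in SCALE_COLUMNS:
        vals = [
            s.visits[0].scale_value(name)
            for s in cohort.subjects
            if wanted is None or s.subject_id in wanted
        ]
        vals = [v for v in vals if not np.isnan(v)]
        if not vals:
            raise ImputationError(
                f"feature {name!r} is missing at every training baseline"
            )
        means[name] = float(np.mean(vals))
    return means


def baseline_mean_impute(
    cohort: Cohort, train_baseline_means: dict[str, float]
) -> Cohort:
    """Replace remaining baseline missing values with training means.

    After :func:`forward_fill` followed by this step no missing clinical
    value remains anywhere in the cohort.
    """
    out = cohort.copy()
    for subj in out.subjects:
        for name in SCALE_COLUMNS:
            filled = train_baseline_means[name]
            last = np.nan
            for v in subj.visits:
                val = v.scale_value(name)
                if np.isnan(val):
                    setattr(v, name, filled if np.isnan(last) else last)
                else:
                    last = val
    return out


def impute(cohort: Cohort, train_baseline_means: dict[str, float]) -> Cohort:
    """Forward fill then baseline-mean impute; the full imputation pipeline."""
    return baseline_mean_impute(forward_fill(cohort), train_baseline_means)


# ------------------------------------------------- dopamine-agonist features


def derive_da_features(
    intervals: list[MedicationInterval] | SubjectRecord, t: float
) -> tuple[float, float, float, float]:
    """Dopamine-agonist exposure summaries over [0, t].

    Returns ``(mean_daily, max_daily, total_dose, cum_duration)`` where
    ``cum_duration`` is the total time (years) on a dopamine agonist within
    [0, t], ``total_dose`` the integral of the daily LEDD dose over that
    time (LEDD-years), ``max_daily`` the maximum daily dose attained, and
    ``mean_daily`` = total_dose / cum_duration (0 with no exposure).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if isinstance(intervals, SubjectRecord):
        intervals = intervals.medication
    total_dose = 0.0
    cum_duration = 0.0
    max_daily = 0.0
    for m in intervals:
        if m.drug_class != "dopamine_agonist":
            continue
        overlap = min(m.end_years, t) - max(m.start_years, 0.0)
        if overlap > 0:
            cum_duration += overlap
            total_dose += m.daily_dose_ledd * overlap
            max_daily = max(max_daily, m.daily_dose_ledd)
    mean_daily = total_dose / cum_duration if cum_duration > 0 else 0.0
    return mean_daily, max_daily, total_dose, cum_duration


# ------------------------------------------------------------- observations


@dataclass
class ObservationSet:
    """Supervised next-visit prediction instances.

    ``X_hist`` is a zero-padded ``(n_obs, max_len, d_clin)`` array of
    per-visit clinical features (only the first ``lengths[i]`` rows of
    observation i are valid); ``X_static`` holds age, sex and SNP dosages;
    ``y`` is the ICD status at the following visit.  ``current_icd`` keeps
    the raw (unstandardized) ICD status at the most recent history visit
    for the trivial persistence model.
    """

    X_hist: np.ndarray
    lengths: np.ndarray
    X_static: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    t_index: np.ndarray
    current_icd: np.ndarray
    clinical_names: tuple[str, ...] = CLINICAL_FEATURES
    static_names: tuple[str, ...] = ()

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.y))

    def mask(self) -> np.ndarray:
        """(n_obs, max_len) boolean validity mask for the padded history."""
        return np.arange(self.X_hist.shape[1])[None, :] < self.lengths[:, None]

    def last_rows(self) -> np.ndarray:
        """The most recent valid history row of each observation."""
        return self.X_hist[np.arange(self.n_obs), self.lengths - 1]

    def subset(self, idx: np.ndarray) -> "ObservationSet":
        return ObservationSet(
            self.X_hist[idx],
            self.lengths[idx],
            self.X_static[idx],
            self.y[idx],
            self.subject_ids[idx],
            self.t_index[idx],
            self.current_icd[idx],
            self.clinical_names,
            self.static_names,
        )

    def subset_subjects(self, subject_ids) -> "ObservationSet":
        wanted = set(subject_ids)
        idx = np.array([sid in wanted for sid in self.subject_ids])
        return self.subset(idx)

    def schema(self) -> dict:
        return {
            "clinical": list(self.clinical_names),
            "static": list(self.static_names),
        }


def _visit_features(subj: SubjectRecord, k: int, times: np.ndarray) -> list[float]:
    v = subj.visits[k]
    mean_d, max_d, tot_d, dur = derive_da_features(subj, float(times[k]))
    return [
        v.anxiety,
        v.depression,
        v.rem,
        v.updrs3,
        float(v.icd),
        float(v.on_levodopa),
        float(v.on_dopamine_agonist),
        float(v.on_other),
        mean_d,
        max_d,
        tot_d,
        dur,
        float(times[k + 1] - times[k]),  # time to the subject's next visit
        float(times[k]),  # length of follow-up at this visit
    ]


def build_observations(cohort: Cohort) -> ObservationSet:
    """One observation per (subject, visit t) with t before the last visit.

    The label is the ICD status at visit t+1; the history contains visits
    1..t only, so no future information leaks into the features.  The
    observation count equals the sum over subjects of (n_visits - 1).
    """
    n_snps = cohort.n_snps
    static_names = ("age", "sex") + tuple(f"snp_{j + 1}" for j in range(n_snps))
    max_len = max(s.n_visits for s in cohort.subjects) - 1

    rows_hist, lengths, statics, ys, sids, tidx, cur = [], [], [], [], [], [], []
    for subj in cohort.subjects:
        if subj.n_visits < 2:  # unreachable for valid SubjectRecords
            raise InclusionCriterionError(subj.subject_id)
        times = subj.visit_times
        for name in SCALE_COLUMNS:
            if any(np.isnan(v.scale_value(name)) for v in subj.visits):
                raise ImputationError(
                    f"subject {subj.subject_id}: {name} still missing; "
                    "impute before building observations"
                )
        feats = [_visit_features(subj, k, times) for k in range(subj.n_visits - 1)]
        static = [subj.age_baseline, float(subj.sex), *subj.genotype.tolist()]
        for t in range(1, subj.n_visits):
            hist = np.zeros((max_len, len(CLINICAL_FEATURES)))
            hist[:t] = feats[:t]
            rows_hist.append(hist)
            lengths.append(t)
            statics.append(static)
            ys.append(subj.visits[t].icd)
            sids.append(subj.subject_id)
            tidx.append(t)
            cur.append(subj.visits[t - 1].icd)

    return ObservationSet(
        X_hist=np.array(rows_hist),
        lengths=np.array(lengths, dtype=int),
        X_static=np.array(statics, dtype=float),
        y=np.array(ys, dtype=int),
        subject_ids=np.array(sids, dtype=object),
        t_index=np.array(tidx, dtype=int),
        current_icd=np.array(cur, dtype=int),
        static_names=static_names,
    )


# ---------------------------------------------------------- standardization


def _fingerprint(subject_ids) -> str:
    blob = ",".join(sorted(map(str, set(subject_ids)))).encode()
    return hashlib.sha256(blob).hexdigest()


class Standardizer:
    """Per-feature z-scoring fitted on training observations only.

    Clinical (sequential) statistics are computed over all valid history
    cells of the training set, static statistics over training rows; both
    use the population standard deviation.  Zero-variance features are
    scaled by 1 (centering only) with a warning.  The fit records a
    fingerprint of the training subject ids so downstream code can audit
    that no test subject contributed to the statistics.
    """

    def __init__(self) -> None:
        self.clin_mean_: np.ndarray | None = None
        self.clin_sd_: np.ndarray | None = None
        self.static_mean_: np.ndarray | None = None
        self.static_sd_: np.ndarray | None = None
        self.schema_: dict | None = None
        self.fit_fingerprint_: str | None = None
        self.fit_subject_ids_: frozenset | None = None

    def fit(self, obs: ObservationSet) -> "Standardizer":
        if obs.n_obs == 0:
            raise ValueError("cannot fit a standardizer on an empty set")
        mask = obs.mask()
        cells = obs.X_hist[mask]  # (n_valid, d_clin)
        self.clin_mean_ = cells.mean(axis=0)
        self.clin_sd_ = cells.std(axis=0)
        self.static_mean_ = obs.X_static.mean(axis=0)
        self.static_sd_ = obs.X_static.std(axis=0)
        for sd, names in (
            (self.clin_sd_, obs.clinical_names),
            (self.static_sd_, obs.static_names),
        ):
            zero = sd == 0
            if zero.any():
                warnings.warn(
                    "zero-variance features scaled by 1: "
                    + ", ".join(np.array(names)[zero]),
                    stacklevel=2,
                )
                sd[zero] = 1.0
        self.schema_ = obs.schema()
        self.fit_fingerprint_ = _fingerprint(obs.subject_ids)
        self.fit_subject_ids_ = frozenset(map(str, obs.subject_ids))
        return self

    def transform(self, obs: ObservationSet) -> ObservationSet:
        if self.clin_mean_ is None:
            raise ValueError("standardizer is not fitted")
        if obs.schema() != self.schema_:
            mine = self.schema_["clinical"] + self.schema_["static"]
            theirs = obs.schema()["clinical"] + obs.schema()["static"]
            bad = next(
                (a for a, b in zip(theirs, mine) if a != b),
                "column count" if len(mine) != len(theirs) else "?",
            )
            raise SchemaError(f"schema mismatch at column {bad!r}")
        mask = obs.mask()
        hist = (obs.X_hist - self.clin_mean_) / self.clin_sd_
        hist[~mask] = 0.0  # padding stays neutral
        static = (obs.X_static - self.static_mean_) / self.static_sd_
        return ObservationSet(
            hist,
            obs.lengths.copy(),
            static,
            obs.y.copy(),
            obs.subject_ids.copy(),
            obs.t_index.copy(),
            obs.current_icd.copy(),
            obs.clinical_names,
            obs.static_names,
        )

    def fit_transform(self, obs: ObservationSet) -> ObservationSet:
        return self.fit(obs).transform(obs)

    def inverse_transform(self, obs: ObservationSet) -> ObservationSet:
        if self.clin_mean_ is None:
            raise ValueError("standardizer is not fitted")
        mask = obs.mask()
        hist = obs.X_hist * self.clin_sd_ + self.clin_mean_
        hist[~mask] = 0.0
        static = obs.X_static * self.static_sd_ + self.static_mean_
        return ObservationSet(
            hist,
            obs.lengths.copy(),
            static,
            obs.y.copy(),
            obs.subject_ids.copy(),
            obs.t_index.copy(),
            obs.current_icd.copy(),
            obs.clinical_names,
            obs.static_names,
        )

    def assert_disjoint_from(self, obs: ObservationSet) -> None:
        """Raise if any subject in ``obs`` contributed to the fit."""
        if self.fit_subject_ids_ is None:
            raise ValueError("standardizer is not fitted")
        overlap = self.fit_subject_ids_ & set(map(str, obs.subject_ids))
        if overlap:
            raise LeakageError(
                f"standardizer was fitted on evaluation subjects: "
                f"{sorted(overlap)[:5]}"
            )


class LeakageError(RuntimeError):
    """Training-set statistics were derived from evaluation subjects."""


# ---------------------------------------------------------------- CSV export


def write_observations(obs: ObservationSet, hist_path, static_path, schema_path):
    """Write an observation set as long-format history + static CSVs."""
    hist_rows = []
    for i in range(obs.n_obs):
        for k in range(obs.lengths[i]):
            hist_rows.append(
                {
                    "obs_id": i,
                    "subject_id": obs.subject_ids[i],
                    "visit_rank": k + 1,
                    **dict(zip(obs.clinical_names, obs.X_hist[i, k])),
                }
            )
    pd.DataFrame(hist_rows).to_csv(hist_path, index=False)
    static = pd.DataFrame(obs.X_static, columns=list(obs.static_names))
    static.insert(0, "obs_id", np.arange(obs.n_obs))
    static.insert(1, "subject_id", obs.subject_ids)
    static["t_index"] = obs.t_index
    static["current_icd"] = obs.current_icd
    static["label"] = obs.y
    static.to_csv(static_path, index=False)
    with open(schema_path, "w") as fh:
        json.dump(obs.schema(), fh, indent=2)
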