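"""Nested subject-level cross-validation and model comparison.

The harness mirrors a discovery/replication design: the training cohort is
split 80/20 at the subject level (outer loop); a 5-fold subject-level
cross-validation on the outer-training subjects selects hyperparameters by
mean inner ROC AUC (inner loop); the selected model is refit on the full
outer-training set and evaluated on the held-out outer-test subjects and on
the entire replication cohort.  Every preprocessing statistic (baseline
imputation means, standardization parameters) is computed from the subjects
a model is fitted on, never from evaluation subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .cohort import Cohort
from .features import (
    LeakageError,
    ObservationSet,
    Standardizer,
    baseline_means,
    build_observations,
    impute,
)
from .metrics import (
    DeLongResult,
    MetricReport,
    bonferroni,
    delong_test,
    metric_report,
    roc_auc,
    significance_stars,
)
from .models import (
    GRUFusionClassifier,
    ReducedHistoryLogistic,
    TrivialNextVisitClassifier,
)
from .reduction import ReductionScheme


class PlanningError(ValueError):
    """The cohort is too small for the requested cross-validation plan."""


@dataclass(frozen=True)
class CVPlan:
    """Subject-level nested cross-validation plan."""

    outer_train: tuple[str, ...]
    outer_test: tuple[str, ...]
    inner_folds: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.outer_train), set(self.outer_test)
        if train & test:
            raise LeakageError("outer train and test subjects overlap")
        fold_union: set[str] = set()
        for fold in self.inner_folds:
            fold_set = set(fold)
            if fold_set & fold_union:
                raise PlanningError("inner folds are not disjoint")
            fold_union |= fold_set
        if fold_union != train:
            raise PlanningError("inner folds do not partition outer-train")


def _stratified_split(ids, strata, test_frac, rng):
    """Subject-level split with floor convention on the test count.

    Test subjects are allocated across strata by largest remainder so the
    outcome prevalence stays comparable between the two sides.
    """
    ids = np.asarray(ids, dtype=object)
    strata = np.asarray(strata)
    n_test = int(np.floor(test_frac * len(ids)))
    levels = np.unique(strata)
    quotas = {}
    fracs = {}
    for lv in levels:
        exact = test_frac * (strata == lv).sum()
        quotas[lv] = int(np.floor(exact))
        fracs[lv] = exact - quotas[lv]
    short = n_test - sum(quotas.values())
    for lv in sorted(levels, key=lambda l: -fracs[l])[: max(short, 0)]:
        quotas[lv] += 1
    test: list[str] = []
    for lv in levels:
        members = ids[strata == lv].copy()
        rng.shuffle(members)
        test.extend(members[: quotas[lv]])
    test_set = set(test)
    train = [s for s in ids if s not in test_set]
    return train, sorted(test_set, key=list(ids).index)


def make_cv_plan(
    cohort: Cohort, seed: int, n_inner: int = 5, test_frac: float = 0.2
) -> CVPlan:
    """Outer 80/20 split + inner subject-level folds, stratified by
    whether the subject ever has an ICD."""
    if len(cohort) < 2 * n_inner:
        raise PlanningError(
            f"{len(cohort)} subjects is too few for {n_inner} inner folds"
        )
    rng = np.random.default_rng(seed)
    any_icd = np.array(
        [int(any(v.icd for v in s.visits)) for s in cohort.subjects]
    )
    train, test = _stratified_split(cohort.subject_ids, any_icd, test_frac, rng)
    train_arr = np.array(train, dtype=object)
    rng.shuffle(train_arr)
    folds = tuple(tuple(f.tolist()) for f in np.array_split(train_arr, n_inner))
    return CVPlan(tuple(train), tuple(test), folds, seed)


# ------------------------------------------------------------ preprocessing


def preprocess(
    fit_cohort: Cohort, eval_cohorts: dict[str, Cohort]
) -> tuple[ObservationSet, dict[str, ObservationSet], Standardizer]:
    """Impute, build observations and standardize with fit-cohort statistics.

    ``fit_cohort`` supplies the baseline imputation means and the
    standardization parameters; every cohort in ``eval_cohorts`` is
    transformed with those statistics only.
    """
    means = baseline_means(fit_cohort)
    fit_obs = build_observations(impute(fit_cohort, means))
    std = Standardizer().fit(fit_obs)
    fit_std = std.transform(fit_obs)
    out = {}
    for name, cohort in eval_cohorts.items():
        obs = build_observations(impute(cohort, means))
        std.assert_disjoint_from(obs)
        out[name] = std.transform(obs)
    return fit_std, out, std


# ---------------------------------------------------------------- model spec


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter grid for the inner loop."""

    name: str
    estimator: object
    grid: list[dict] = field(default_factory=lambda: [{}])

    @property
    def needs_tuning(self) -> bool:
        return len(self.grid) > 1


def default_lambda_grid() -> list[float]:
    """Logarithmic regularization-strength grid, 1e-3 .. 1e3, 13 points."""
    return list(np.logspace(-3, 3, 13))


def default_model_specs(seed: int = 0, lambdas=None) -> list[ModelSpec]:
    """The five compared models: trivial, three logistic reductions, GRU."""
    lams = default_lambda_grid() if lambdas is None else lambdas
    logistic_grid = [
        {"penalty": p, "lam": lam} for p in ("l1", "l2") for lam in lams
    ]
    specs = [ModelSpec("trivial", TrivialNextVisitClassifier(), [{}])]
    for label, scheme in (
        ("logistic_baseline", ReductionScheme("baseline_only")),
        ("logistic_last", ReductionScheme("last_only")),
        ("logistic_mean", ReductionScheme("uniform")),
    ):
        specs.append(
            ModelSpec(
                label,
                ReducedHistoryLogistic(scheme=scheme),
                [dict(g) for g in logistic_grid],
            )
        )
    specs.append(ModelSpec("gru", GRUFusionClassifier(seed=seed), [{}]))
    return specs


# ----------------------------------------------------------------- CV engine


def _sort_key(params: dict):
    # ties break toward smaller lam, then earlier grid position
    return -params.get("lam", 0.0)


def inner_cv_select(
    spec: ModelSpec, cohort: Cohort, plan: CVPlan, seed: int
) -> tuple[dict, float]:
    """Pick the grid point with the best mean inner-fold ROC AUC.

    Each inner fold is preprocessed from scratch with the fold-training
    subjects' statistics.  Ties break toward smaller lam, then grid order.
    """
    if not spec.needs_tuning:
        return dict(spec.grid[0]), np.nan
    fold_data = []
    for k, fold in enumerate(plan.inner_folds):
        fit_ids = [s for s in plan.outer_train if s not in set(fold)]
        fit_cohort = cohort.subset(fit_ids)
        val_cohort = cohort.subset(fold)
        fit_obs, evals, _ = preprocess(fit_cohort, {"val": val_cohort})
        fold_data.append((fit_obs, evals["val"]))

    results = []
    for gi, params in enumerate(spec.grid):
        aucs = []
        for fit_obs, val_obs in fold_data:
            est = clone(spec.estimator)
            est.set_params(**params)
            if isinstance(est, GRUFusionClassifier):
                est.set_params(seed=seed)
                est.fit(fit_obs, val=val_obs)
            else:
                est.fit(fit_obs)
            aucs.append(roc_auc(val_obs.y, est.decision_scores(val_obs)))
        results.append((float(np.mean(aucs)), _sort_key(params), -gi, params))
    results.sort(key=lambda r: (r[0], r[1], r[2]), reverse=True)
    best = results[0]
    return dict(best[3]), best[0]


@dataclass
class ModelResult:
    name: str
    params: dict
    inner_auc: float
    metrics: dict[str, MetricReport]
    scores: dict[str, np.ndarray]
    estimator: object


@dataclass
class ComparisonReport:
    """Per-model metrics per cohort plus pairwise DeLong comparisons."""

    results: list[ModelResult]
    delong: dict[tuple[str, str, str], DeLongResult]  # (model_a, model_b, cohort)
    adjusted_p: dict[tuple[str, str, str], float]
    n_comparisons: int
    seed: int
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for cohort_name, rep in r.metrics.items():
                rows.append(
                    {"model": r.name, "cohort": cohort_name, **rep.as_dict()}
                )
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b, cohort), res in self.delong.items():
            p_adj = self.adjusted_p[(a, b, cohort)]
            rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "cohort": cohort,
                    "auc_a": res.auc_a,
                    "auc_b": res.auc_b,
                    "auc_diff": res.diff,
                    "z": res.z,
                    "p_value": res.p_value,
                    "p_adjusted": p_adj,
                    "significant": p_adj <= 0.05,
                    "stars": significance_stars(p_adj),
                    "ci_a_low": res.ci_a[0],
                    "ci_a_high": res.ci_a[1],
                    "ci_b_low": res.ci_b[0],
                    "ci_b_high": res.ci_b[1],
                }
            )
        return pd.DataFrame(rows)


def run_experiment(
    train_cohort: Cohort,
    replication_cohort: Cohort | None,
    model_specs: list[ModelSpec],
    seed: int = 0,
    plan: CVPlan | None = None,
    baseline_model: str = "trivial",
) -> ComparisonReport:
    """Nested CV on the training cohort + external replication evaluation.

    For each model: inner-CV grid search, refit on the full outer-training
    set, evaluation on the outer-test subjects and on the whole replication
    cohort; then a DeLong test of every model against the baseline model on
    each evaluation cohort, Bonferroni-adjusted over all comparisons made.
    Swapping the roles of the cohorts is just calling this function with
    the arguments exchanged.
    """
    if plan is None:
        plan = make_cv_plan(train_cohort, seed=seed)
    outer_train = train_cohort.subset(plan.outer_train)
    outer_test = train_cohort.subset(plan.outer_test)
    eval_cohorts = {"train_cohort_test": outer_test}
    if replication_cohort is not None:
        eval_cohorts["replication_cohort"] = replication_cohort

    fit_obs, eval_obs, std = preprocess(outer_train, eval_cohorts)
    std.assert_disjoint_from(eval_obs["train_cohort_test"])

    results: list[ModelResult] = []
    for spec in model_specs:
        params, inner_auc = inner_cv_select(spec, train_cohort, plan, seed)
        est = clone(spec.estimator)
        est.set_params(**params)
        if isinstance(est, GRUFusionClassifier):
            est.set_params(seed=seed)
        est.fit(fit_obs)
        metrics, scores = {}, {}
        for cohort_name, obs in eval_obs.items():
            s = est.decision_scores(obs)
            scores[cohort_name] = s
            metrics[cohort_name] = metric_report(obs.y, s)
        results.append(ModelResult(spec.name, params, inner_auc, metrics, scores, est))

    by_name = {r.name: r for r in results}
    base = by_name[baseline_model]
    delong: dict[tuple[str, str, str], DeLongResult] = {}
    for r in results:
        if r.name == baseline_model:
            continue
        for cohort_name, obs in eval_obs.items():
            delong[(r.name, baseline_model, cohort_name)] = delong_test(
                obs.y, r.scores[cohort_name], base.scores[cohort_name]
            )
    m = max(len(delong), 1)
    adjusted = {
        key: float(bonferroni([res.p_value], m)[0]) for key, res in delong.items()
    }
    eval_labels = {name: obs.y.copy() for name, obs in eval_obs.items()}
    return ComparisonReport(results, delong, adjusted, m, seed, eval_labels)


def repeat_experiment(
    train_cohort: Cohort,
    replication_cohort: Cohort | None,
    model_specs: list[ModelSpec],
    seeds: list[int],
) -> list[ComparisonReport]:
    """Repeat the outer split R times to gauge split sensitivity."""
    return [
        run_experiment(train_cohort, replication_cohort, model_specs, seed=s)
        for s in seeds
    ]


# ------------------------------------------------- cluster bootstrap (option)


def cluster_bootstrap_auc_diff(
    labels, scores_a, scores_b, subject_ids, n_boot: int = 2000, seed: int = 0
) -> float:
    """Subject-level bootstrap p-value for an AUC difference.

    Observations of the same subject are resampled together, a sensitivity
    analysis for the DeLong test's independence assumption on repeated
    visits (which tends to understate p-values).
    """
    labels = np.asarray(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    subject_ids = np.asarray(subject_ids, dtype=object)
    subjects = np.unique(subject_ids.astype(str))
    idx_by_subject = {
        s: np.flatnonzero(subject_ids.astype(str) == s) for s in subjects
    }
    rng = np.random.default_rng(seed)
    observed = roc_auc(labels, scores_a) - roc_auc(labels, scores_b)
    diffs = []
    for _ in range(n_boot):
        chosen = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([idx_by_subject[s] for s in chosen])
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        diffs.append(roc_auc(lb, scores_a[idx]) - roc_auc(lb, scores_b[idx]))
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1)
    if se == 0:
        return 1.0
    from scipy.stats import norm

    return float(2 * norm.sf(abs(observed) / se))


def curve_points(labels, scores) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROC and precision-recall curves as plain point tables."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    prec, rec, thr2 = precision_recall_curve(labels, scores)
    pr = pd.DataFrame(
        {
            "threshold": np.append(thr2, np.inf),
            "precision": prec,
            "recall": rec,
        }
    )
    return roc, pr
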