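"""The three model families compared by the evaluation harness.

* :class:`TrivialNextVisitClassifier` — the persistence baseline: predicts
  the ICD status at the next visit to equal the status at the most recent
  visit.  It is the benchmark any learned model must beat.
* :class:`ReducedHistoryLogistic` — a regularized logistic regression on a
  convex-combination summary of the visit history plus static covariates.
* :class:`GRUFusionClassifier` — a gated-recurrent-unit network over the
  visit sequence whose final hidden state is fused with the static vector
  by a fully connected layer and a sigmoid; trained end-to-end.

All three are scikit-learn-style estimators (``fit``/``predict_proba``/
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore), except that they consume
:class:`~icdpred.features.ObservationSet` objects instead of flat design
matrices, since the task's inputs are variable-length sequences.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .features import LeakageError, ObservationSet
from .nn import Adam, GRUFusionNet
from .metrics import roc_auc
from .reduction import ReductionScheme, reduce_history


class TrivialNextVisitClassifier(BaseEstimator):
    """Persistence baseline: next-visit status = most recent status.

    Stateless; ``fit`` only validates input.  Scores are exactly 0 or 1,
    which makes its ROC AUC equal its balanced accuracy on any dataset.
    """

    def fit(self, obs: ObservationSet, y=None) -> "TrivialNextVisitClassifier":
        self.n_features_in_ = 0
        return self

    def predict_proba(self, obs: ObservationSet) -> np.ndarray:
        scores = obs.current_icd.astype(float)
        return np.column_stack([1 - scores, scores])

    def predict(self, obs: ObservationSet) -> np.ndarray:
        return obs.current_icd.astype(int)

    def decision_scores(self, obs: ObservationSet) -> np.ndarray:
        return obs.current_icd.astype(float)


class ReducedHistoryLogistic(BaseEstimator):
    """Penalized logistic regression on a reduced history + static features.

    Parameters
    ----------
    scheme : ReductionScheme
        How the visit history collapses into one summary visit
        (baseline_only, last_only, uniform or exponential_recency).
    penalty : {"l1", "l2", None}
        Regularization type; the intercept is never penalized.  ``None``
        gives an unpenalized fit (used for coefficient-sign recovery).
    lam : float
        Regularization strength; the sklearn ``C`` is ``1 / lam``.
    """

    def __init__(
        self,
        scheme: ReductionScheme = ReductionScheme("last_only"),
        penalty: str | None = "l2",
        lam: float = 1.0,
        max_iter: int = 2000,
    ):
        self.scheme = scheme
        self.penalty = penalty
        self.lam = lam
        self.max_iter = max_iter

    def _design(self, obs: ObservationSet) -> np.ndarray:
        reduced = reduce_history(obs.X_hist, obs.lengths, self.scheme)
        return np.concatenate([reduced, obs.X_static], axis=1)

    def fit(self, obs: ObservationSet, y=None) -> "ReducedHistoryLogistic":
        if self.penalty is not None and not self.lam > 0:
            raise ValueError("lam must be positive")
        X = self._design(obs)
        if not np.isfinite(X).all():
            raise ValueError("non-finite features passed to logistic fit")
        target = obs.y if y is None else y
        # lbfgs (l2) and saga (l1) leave the intercept unpenalized
        if self.penalty is None:
            est = LogisticRegression(C=np.inf, max_iter=self.max_iter)
        elif self.penalty == "l2":
            est = LogisticRegression(C=1.0 / self.lam, max_iter=self.max_iter)
        elif self.penalty == "l1":
            # saga converges slowly at weak penalties; give it headroom
            est = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / self.lam,
                solver="saga",
                max_iter=max(self.max_iter, 5000),
            )
        else:
            raise ValueError(f"unknown penalty {self.penalty!r}")
        est.fit(X, target)
        self.est_ = est
        self.coef_ = est.coef_[0]
        self.intercept_ = float(est.intercept_[0])
        self.feature_names_ = list(obs.clinical_names) + list(obs.static_names)
        self.schema_ = obs.schema()
        return self

    def _check_schema(self, obs: ObservationSet) -> None:
        if obs.schema() != self.schema_:
            mine = self.schema_["clinical"] + self.schema_["static"]
            theirs = obs.schema()["clinical"] + obs.schema()["static"]
            bad = next((a for a, b in zip(theirs, mine) if a != b), "column count")
            raise ValueError(f"schema mismatch at column {bad!r}")

    def predict_proba(self, obs: ObservationSet) -> np.ndarray:
        self._check_schema(obs)
        return self.est_.predict_proba(self._design(obs))

    def decision_scores(self, obs: ObservationSet) -> np.ndarray:
        return self.predict_proba(obs)[:, 1]

    def predict(self, obs: ObservationSet) -> np.ndarray:
        return (self.decision_scores(obs) > 0.5).astype(int)

    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.feature_names_, self.coef_))

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "logistic",
                "scheme": {"name": self.scheme.name, "decay": self.scheme.decay},
                "penalty": self.penalty,
                "lam": self.lam,
                "intercept": self.intercept_,
                "coef": dict(zip(self.feature_names_, map(float, self.coef_))),
                "schema": self.schema_,
            },
            indent=2,
        )


class GRUFusionClassifier(BaseEstimator):
    """GRU over the visit sequence fused with static covariates.

    Trained end-to-end by Adam on binary cross-entropy; the checkpoint with
    the best validation ROC AUC is kept (early stopping).  If no validation
    set is passed to ``fit``, a subject-level fraction of the training set
    is held out internally.  Deterministic under a fixed seed.

    Parameters
    ----------
    hidden_size : int
        GRU hidden-state dimension.
    lr : float
        Adam learning rate.
    max_epochs, patience : int
        Epoch budget and early-stopping patience on validation ROC AUC.
    batch_size : int
        Minibatch size over observations.
    weight_decay : float
        Decoupled L2 weight decay on non-bias parameters; the network's
        counterpart of the logistic models' ridge penalty.
    pos_weight : float or None
        Optional positive-class weight in the loss; None = unweighted.
    val_fraction : float
        Subject fraction held out when ``fit`` receives no validation set.
    """

    def __init__(
        self,
        hidden_size: int = 16,
        lr: float = 1e-2,
        max_epochs: int = 200,
        patience: int = 20,
        batch_size: int = 64,
        weight_decay: float = 3.0,
        pos_weight: float | None = None,
        val_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.hidden_size = hidden_size
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.pos_weight = pos_weight
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(
        self, obs: ObservationSet, y=None, val: ObservationSet | None = None
    ) -> "GRUFusionClassifier":
        rng = np.random.default_rng(self.seed)
        if val is None:
            subjects = np.unique(obs.subject_ids.astype(str))
            rng.shuffle(subjects)
            n_val = max(1, int(round(self.val_fraction * len(subjects))))
            val_subj = set(subjects[:n_val])
            val = obs.subset_subjects(val_subj)
            train = obs.subset_subjects(set(subjects) - val_subj)
        else:
            overlap = set(map(str, obs.subject_ids)) & set(map(str, val.subject_ids))
            if overlap:
                raise LeakageError(
                    f"validation set shares subjects with training set: "
                    f"{sorted(overlap)[:5]}"
                )
            train = obs

        net = GRUFusionNet(
            d_clin=train.X_hist.shape[2],
            d_static=train.X_static.shape[1],
            hidden=self.hidden_size,
            seed=int(rng.integers(2**31)),
        )
        opt = Adam(net.params, lr=self.lr, weight_decay=self.weight_decay)
        Xtr, Mtr, Str, ytr = (
            train.X_hist,
            train.mask(),
            train.X_static,
            train.y.astype(float),
        )
        weights = None
        if self.pos_weight is not None:
            weights = np.where(ytr == 1, self.pos_weight, 1.0)
        Xv, Mv, Sv, yv = val.X_hist, val.mask(), val.X_static, val.y

        best_auc, best_params, best_epoch, since_best = -np.inf, None, 0, 0
        n = len(ytr)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                prob, cache = net.forward(Xtr[idx], Mtr[idx], Str[idx], cache=True)
                grads = net.backward(
                    prob,
                    ytr[idx],
                    cache,
                    None if weights is None else weights[idx],
                )
                opt.step(net.params, grads)
            val_scores = net.forward(Xv, Mv, Sv)
            if len(np.unique(yv)) < 2:
                auc = 0.5  # degenerate validation split: no early signal
            else:
                auc = roc_auc(yv, val_scores)
            if auc > best_auc + 1e-12:
                best_auc, best_params, best_epoch = auc, net.get_flat(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_params is not None:
            net.set_flat(best_params)
        self.net_ = net
        self.best_val_auc_ = float(best_auc)
        self.best_epoch_ = best_epoch
        self.schema_ = obs.schema()
        return self

    def decision_scores(self, obs: ObservationSet) -> np.ndarray:
        if obs.schema() != self.schema_:
            raise ValueError("schema mismatch with fit-time schema")
        return self.net_.forward(obs.X_hist, obs.mask(), obs.X_static)

    def predict_proba(self, obs: ObservationSet) -> np.ndarray:
        s = self.decision_scores(obs)
        return np.column_stack([1 - s, s])

    def predict(self, obs: ObservationSet) -> np.ndarray:
        return (self.decision_scores(obs) > 0.5).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "gru_fusion",
                "hidden_size": self.hidden_size,
                "params": {k: v.tolist() for k, v in self.net_.params.items()},
                "schema": self.schema_,
            }
        )
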