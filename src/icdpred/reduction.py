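"""Convex-combination reduction of a visit history to one summary visit.

Fixed-input learners (logistic regression here) cannot consume a
variable-length visit sequence directly.  The history is collapsed into a
single "summary" visit by a convex combination: non-negative weights that
sum to one, one per visit.  Weight 1 on the first visit reproduces the
baseline visit, weight 1 on the last reproduces the most recent visit,
uniform weights average all past visits (including the current one), and
an exponential-recency family puts geometrically higher weight on more
recent visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCHEME_NAMES = ("baseline_only", "last_only", "uniform", "exponential_recency")


@dataclass(frozen=True)
class ReductionScheme:
    """A named weight-generating rule over history lengths."""

    name: str = "last_only"
    decay: float | None = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown reduction scheme {self.name!r}")
        if self.name == "exponential_recency":
            if self.decay is None or not 0 < self.decay < 1:
                raise ValueError("exponential_recency needs decay in (0, 1)")

    def weights_for(self, t: int) -> np.ndarray:
        return weights_for(self, t)


def weights_for(scheme: ReductionScheme, t: int) -> np.ndarray:
    """Convex weights w(1..t): w_i >= 0 and sum to 1 for any t >= 1."""
    if t < 1:
        raise ValueError("history length must be >= 1")
    if scheme.name == "baseline_only":
        w = np.zeros(t)
        w[0] = 1.0
    elif scheme.name == "last_only":
        w = np.zeros(t)
        w[-1] = 1.0
    elif scheme.name == "uniform":
        w = np.full(t, 1.0 / t)
    else:  # exponential_recency: w_i proportional to decay**(t - i)
        w = scheme.decay ** np.arange(t - 1, -1, -1, dtype=float)
        w /= w.sum()
    return w


def summarize(history: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted average of history rows: sum_i w_i x(i).

    The result lies in the convex hull of the rows; in particular each
    component stays within the [min, max] of its column.
    """
    history = np.asarray(history, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if history.ndim != 2 or weights.ndim != 1 or len(weights) != history.shape[0]:
        raise ValueError("weights must have one entry per history row")
    if (weights < -1e-12).any() or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to one")
    return weights @ history


def reduce_history(obs_hist: np.ndarray, lengths: np.ndarray,
                   scheme: ReductionScheme) -> np.ndarray:
    """Apply a scheme to every padded history in an observation set."""
    n, max_len, d = obs_hist.shape
    out = np.empty((n, d))
    weight_cache = {t: weights_for(scheme, t) for t in np.unique(lengths)}
    for i in range(n):
        t = int(lengths[i])
        out[i] = weight_cache[t] @ obs_hist[i, :t]
    return out
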