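"""A compact NumPy gated-recurrent-unit network with static-covariate fusion.

The architecture: a single-layer GRU reads the per-visit clinical feature
sequence x(1..t) into a hidden state h(t); h(t) is concatenated with the
static vector s (socio-demographics and SNP dosages) and passed through one
fully connected layer with a sigmoid, giving the probability of an ICD at
the next visit.  The whole network is trained end-to-end by minimizing
binary cross-entropy with Adam; h(t) is never estimated separately.

The GRU cell follows the standard update/reset-gate formulation:

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    n_t = tanh(W_n x_t + r_t * (U_n h_{t-1} + b_hn) + b_in)
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

Variable-length sequences are batched by right-padding with a validity
mask: at padded steps the hidden state is carried through unchanged, so a
padded batch forward pass is exactly equal to per-sequence evaluation.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRUFusionNet:
    """Parameters and forward/backward passes; no training loop here."""

    def __init__(self, d_clin: int, d_static: int, hidden: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(hidden)
        u = lambda *shape: rng.uniform(-k, k, size=shape)
        self.params = {
            "Wz": u(d_clin, hidden), "Uz": u(hidden, hidden), "bz": u(hidden),
            "Wr": u(d_clin, hidden), "Ur": u(hidden, hidden), "br": u(hidden),
            "Wn": u(d_clin, hidden), "Un": u(hidden, hidden),
            "bin": u(hidden), "bhn": u(hidden),
            "w_fc": u(hidden + d_static), "b_fc": np.zeros(1),
        }
        self.d_clin, self.d_static, self.hidden = d_clin, d_static, hidden

    # ------------------------------------------------------------- forward

    def forward(self, X, mask, S, cache: bool = False):
        """Probabilities for a padded batch.

        X: (B, T, d_clin); mask: (B, T) validity; S: (B, d_static).
        Returns (B,) probabilities, plus intermediates when ``cache``.
        """
        p = self.params
        B, T, _ = X.shape
        h = np.zeros((B, self.hidden))
        steps = []
        for t in range(T):
            x = X[:, t, :]
            m = mask[:, t][:, None]
            z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
            hn_lin = h @ p["Un"] + p["bhn"]
            n = np.tanh(x @ p["Wn"] + r * hn_lin + p["bin"])
            h_new = (1 - z) * n + z * h
            h_next = np.where(m, h_new, h)
            if cache:
                steps.append((x, h, z, r, n, hn_lin, m))
            h = h_next
        logits = np.concatenate([h, S], axis=1) @ p["w_fc"] + p["b_fc"][0]
        prob = _sigmoid(logits)
        if cache:
            return prob, (steps, h, S)
        return prob

    # ------------------------------------------------------------ backward

    def backward(self, prob, y, cache, sample_weight=None):
        """Gradients of mean weighted binary cross-entropy wrt parameters."""
        p = self.params
        steps, hT, S = cache
        B = len(y)
        w = np.ones(B) if sample_weight is None else sample_weight
        # d loss / d logits for BCE with sigmoid
        dlogit = (prob - y) * w / w.sum()
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        feat = np.concatenate([hT, S], axis=1)
        grads["w_fc"] = feat.T @ dlogit
        grads["b_fc"] = np.array([dlogit.sum()])
        dh = np.outer(dlogit, p["w_fc"][: self.hidden])
        for x, h_prev, z, r, n, hn_lin, m in reversed(steps):
            dh_step = dh * m  # padded steps pass gradient straight through
            dh_carry = dh * (~m.astype(bool))
            dz = dh_step * (h_prev - n) * z * (1 - z)
            dn = dh_step * (1 - z) * (1 - n**2)
            dr = dn * hn_lin * r * (1 - r)
            grads["Wz"] += x.T @ dz
            grads["Uz"] += h_prev.T @ dz
            grads["bz"] += dz.sum(axis=0)
            grads["Wr"] += x.T @ dr
            grads["Ur"] += h_prev.T @ dr
            grads["br"] += dr.sum(axis=0)
            grads["Wn"] += x.T @ dn
            grads["bin"] += dn.sum(axis=0)
            grads["Un"] += h_prev.T @ (dn * r)
            grads["bhn"] += (dn * r).sum(axis=0)
            dh = (
                dh_carry
                + dh_step * z
                + dz @ p["Uz"].T
                + dr @ p["Ur"].T
                + (dn * r) @ p["Un"].T
            )
        return grads

    def loss(self, prob, y, sample_weight=None, eps: float = 1e-12):
        w = np.ones(len(y)) if sample_weight is None else sample_weight
        ll = y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)
        return float(-(w * ll).sum() / w.sum())

    def get_flat(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_flat(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: np.array(v, dtype=float) for k, v in params.items()}


class Adam:
    """Adam over a dict of parameter arrays, with optional decoupled
    weight decay (not applied to biases)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay=0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            if self.weight_decay and not k.startswith("b"):
                params[k] *= 1.0 - self.lr * self.weight_decay
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
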