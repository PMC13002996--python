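"""Self-attention classifier over variable-length CpG state profiles.

The model maps an enhancer's ordered per-CpG 4-state vectors
(x_ambiguous_modC, x_mC, x_hmC, x_C) to one of three functional-state labels
(0 active, 1 poised, 2 primed).  Architecture: a linear projection of each
4-vector to d_model = 32; one multi-head self-attention layer (4 heads,
query = key = value) with a residual connection and a two-layer feed-forward
block of 256 hidden units (elu, dropout 0.2); masked mean-pooling over CpG
positions; a two-layer classifier head with 256 hidden units per layer (elu,
dropout); softmax over the 3 classes, trained with cross-entropy.

Implemented directly in NumPy with hand-derived gradients (checked against
finite differences in the test suite) and Adam.  No positional encoding by
default, so with mean pooling the logits are invariant to CpG permutation
within a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError


@dataclass
class ModelConfig:
    """Hyperparameters; the architectural defaults are the published ones."""

    d_model: int = 32
    num_head: int = 4
    ff_dim: int = 256
    mlp_h_dim: int = 256
    dropp: float = 0.2
    n_classes: int = 3
    n_features: int = 4
    max_len: int | None = None      # None: 95th percentile of training lengths
    positional_encoding: bool = False
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 80
    patience: int = 10
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.d_model % self.num_head != 0:
            raise InvalidParameterError("d_model must be divisible by num_head")
        if not 0.0 <= self.dropp < 1.0:
            raise InvalidParameterError("dropp must be in [0, 1)")


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class AttentionClassifier:
    """Trainable enhancer-state classifier; see the module docstring."""

    _WEIGHT_SHAPES = (
        ("W_in", ("F", "d")), ("b_in", ("d",)),
        ("Wq", ("d", "d")), ("bq", ("d",)),
        ("Wk", ("d", "d")), ("bk", ("d",)),
        ("Wv", ("d", "d")), ("bv", ("d",)),
        ("Wo", ("d", "d")), ("bo", ("d",)),
        ("W1", ("d", "ff")), ("b1", ("ff",)),
        ("W2", ("ff", "d")), ("b2", ("d",)),
        ("Wh1", ("d", "mlp")), ("bh1", ("mlp",)),
        ("Wh2", ("mlp", "mlp")), ("bh2", ("mlp",)),
        ("Wout", ("mlp", "C")), ("bout", ("C",)),
    )

    def __init__(self, config: ModelConfig | None = None) -> None:
        self.config = config or ModelConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.max_len: int | None = self.config.max_len
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        dims = {"F": self.config.n_features, "d": self.config.d_model,
                "ff": self.config.ff_dim, "mlp": self.config.mlp_h_dim,
                "C": self.config.n_classes}
        self.params: dict[str, np.ndarray] = {}
        for name, shape_spec in self._WEIGHT_SHAPES:
            shape = tuple(dims[s] for s in shape_spec)
            if len(shape) == 1:
                self.params[name] = np.zeros(shape)
            else:
                limit = math.sqrt(6.0 / sum(shape))
                self.params[name] = self.rng.uniform(-limit, limit, size=shape)

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------------

    def _dropout_mask(self, shape, rng) -> np.ndarray:
        p = self.config.dropp
        if p == 0.0 or rng is None:
            return np.ones(shape)
        return (rng.random(shape) >= p) / (1.0 - p)

    def _forward(self, X: np.ndarray, mask: np.ndarray,
                 train: bool = False, rng=None) -> tuple[np.ndarray, dict]:
        """X (B, T, F), mask (B, T) in {0,1} -> logits (B, C) plus cache."""
        cfg = self.config
        P = self.params
        B, T, _ = X.shape
        h, dh = cfg.num_head, cfg.d_model // cfg.num_head
        drop = (lambda s: self._dropout_mask(s, rng)) if train else \
               (lambda s: 1.0)

        H0 = X @ P["W_in"] + P["b_in"]
        if cfg.positional_encoding:
            H0 = H0 + self._positional(T)[None, :, :]
        Q = H0 @ P["Wq"] + P["bq"]
        K = H0 @ P["Wk"] + P["bk"]
        V = H0 @ P["Wv"] + P["bv"]
        Qh = Q.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        Kh = K.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        Vh = V.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        scale = 1.0 / math.sqrt(dh)
        S = Qh @ Kh.transpose(0, 1, 3, 2) * scale
        S = S + (mask[:, None, None, :] - 1.0) * 1e9  # mask padded keys
        A = _softmax(S, axis=-1)
        Z = (A @ Vh).transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
        attn = Z @ P["Wo"] + P["bo"]
        m_attn = drop(attn.shape)
        H1 = H0 + attn * m_attn

        U1 = H1 @ P["W1"] + P["b1"]
        E1 = _elu(U1)
        m_ff = drop(E1.shape)
        F2 = (E1 * m_ff) @ P["W2"] + P["b2"]
        H2 = H1 + F2

        cnt = mask.sum(axis=1).clip(min=1.0)
        pooled = (H2 * mask[:, :, None]).sum(axis=1) / cnt[:, None]

        P1 = pooled @ P["Wh1"] + P["bh1"]
        G1 = _elu(P1)
        m_g1 = drop(G1.shape)
        G1d = G1 * m_g1
        P2 = G1d @ P["Wh2"] + P["bh2"]
        G2 = _elu(P2)
        m_g2 = drop(G2.shape)
        G2d = G2 * m_g2
        logits = G2d @ P["Wout"] + P["bout"]

        cache = dict(X=X, mask=mask, H0=H0, Qh=Qh, Kh=Kh, Vh=Vh, A=A, Z=Z,
                     m_attn=m_attn, H1=H1, U1=U1, E1=E1, m_ff=m_ff, H2=H2,
                     cnt=cnt, pooled=pooled, P1=P1, G1d=G1d, m_g1=m_g1,
                     P2=P2, m_g2=m_g2, G2d=G2d, scale=scale)
        return logits, cache

    def _positional(self, T: int) -> np.ndarray:
        d = self.config.d_model
        pos = np.arange(T)[:, None]
        i = np.arange(d)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
        enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        return enc

    def loss_and_grads(self, X, mask, y, train=True, rng=None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        cfg = self.config
        P = self.params
        B, T, _ = X.shape
        h, dh = cfg.num_head, cfg.d_model // cfg.num_head
        logits, c = self._forward(X, mask, train=train, rng=rng)
        probs = _softmax(logits)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))

        g: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        g["Wout"] = c["G2d"].T @ dlogits
        g["bout"] = dlogits.sum(0)
        dG2d = dlogits @ P["Wout"].T
        dG2 = dG2d * c["m_g2"]
        dP2 = dG2 * _elu_grad(c["P2"])
        g["Wh2"] = c["G1d"].T @ dP2
        g["bh2"] = dP2.sum(0)
        dG1d = dP2 @ P["Wh2"].T
        dG1 = dG1d * c["m_g1"]
        dP1 = dG1 * _elu_grad(c["P1"])
        g["Wh1"] = c["pooled"].T @ dP1
        g["bh1"] = dP1.sum(0)
        dpooled = dP1 @ P["Wh1"].T

        dH2 = dpooled[:, None, :] * c["mask"][:, :, None] \
            / c["cnt"][:, None, None]
        dH1 = dH2.copy()
        dF2 = dH2
        E1d = c["E1"] * c["m_ff"]
        d = cfg.d_model
        g["W2"] = E1d.reshape(-1, cfg.ff_dim).T @ dF2.reshape(-1, d)
        g["b2"] = dF2.sum(axis=(0, 1))
        dE1d = dF2 @ P["W2"].T
        dE1 = dE1d * c["m_ff"]
        dU1 = dE1 * _elu_grad(c["U1"])
        g["W1"] = c["H1"].reshape(-1, d).T @ dU1.reshape(-1, cfg.ff_dim)
        g["b1"] = dU1.sum(axis=(0, 1))
        dH1 += dU1 @ P["W1"].T

        dH0 = dH1.copy()
        dattn = dH1 * c["m_attn"]
        g["Wo"] = c["Z"].reshape(-1, d).T @ dattn.reshape(-1, d)
        g["bo"] = dattn.sum(axis=(0, 1))
        dZ = dattn @ P["Wo"].T
        dZh = dZ.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        dA = dZh @ c["Vh"].transpose(0, 1, 3, 2)
        dVh = c["A"].transpose(0, 1, 3, 2) @ dZh
        A = c["A"]
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = dS @ c["Kh"] * c["scale"]
        dKh = dS.transpose(0, 1, 3, 2) @ c["Qh"] * c["scale"]

        def merge(dXh):
            return dXh.transpose(0, 2, 1, 3).reshape(B, T, d)

        dQ, dK, dV = merge(dQh), merge(dKh), merge(dVh)
        H0f = c["H0"].reshape(-1, d)
        for name, dM in (("q", dQ), ("k", dK), ("v", dV)):
            g["W" + name] = H0f.T @ dM.reshape(-1, d)
            g["b" + name] = dM.sum(axis=(0, 1))
            dH0 += dM @ P["W" + name].T

        g["W_in"] = c["X"].reshape(-1, cfg.n_features).T @ dH0.reshape(-1, d)
        g["b_in"] = dH0.sum(axis=(0, 1))
        return loss, g

    # -- data plumbing ------------------------------------------------------

    def _pad(self, vectors: Sequence[np.ndarray]
             ) -> tuple[np.ndarray, np.ndarray]:
        T = self.max_len
        B = len(vectors)
        X = np.zeros((B, T, self.config.n_features))
        mask = np.zeros((B, T))
        for i, v in enumerate(vectors):
            k = min(len(v), T)
            X[i, :k] = v[:k]
            mask[i, :k] = 1.0
        return X, mask

    # -- training -----------------------------------------------------------

    def fit(self, vectors: Sequence[np.ndarray], labels: Sequence[int]
            ) -> "AttentionClassifier":
        """Train with Adam, early-stopping on a held-out validation split.

        ``vectors`` are per-sample (k_i, 4) arrays; reproducible for a fixed
        config seed.
        """
        cfg = self.config
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise InvalidParameterError("training data must contain >= 2 classes")
        if self.max_len is None:
            lengths = np.array([len(v) for v in vectors])
            self.max_len = max(1, int(np.ceil(np.percentile(lengths, 95))))
        X, mask = self._pad(vectors)
        n = len(y)
        rng = self.rng

        n_val = int(round(cfg.val_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xv, mv, yv = X[val_idx], mask[val_idx], y[val_idx]
        Xt, mt, yt = X[tr_idx], mask[tr_idx], y[tr_idx]

        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stall = 0
        step = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(yt))
            ep_loss = 0.0
            n_batches = 0
            for s in range(0, len(yt), cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                loss, grads = self.loss_and_grads(
                    Xt[idx], mt[idx], yt[idx], train=True, rng=rng)
                ep_loss += loss
                n_batches += 1
                step += 1
                for k2, gk in grads.items():
                    m_state[k2] = 0.9 * m_state[k2] + 0.1 * gk
                    v_state[k2] = 0.999 * v_state[k2] + 0.001 * gk ** 2
                    mhat = m_state[k2] / (1 - 0.9 ** step)
                    vhat = v_state[k2] / (1 - 0.999 ** step)
                    self.params[k2] -= cfg.learning_rate * mhat / \
                        (np.sqrt(vhat) + 1e-8)
            self.history["train_loss"].append(ep_loss / max(n_batches, 1))
            if len(yv):
                val_loss, _ = self.loss_and_grads(Xv, mv, yv, train=False)
            else:
                val_loss = self.history["train_loss"][-1]
            self.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-5:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        self.params = best_params
        return self

    def predict_proba(self, vectors: Sequence[np.ndarray]) -> np.ndarray:
        if self.max_len is None:
            raise InvalidParameterError("model is not fitted")
        X, mask = self._pad(vectors)
        logits, _ = self._forward(X, mask, train=False)
        return _softmax(logits)

    def predict(self, vectors: Sequence[np.ndarray]) -> np.ndarray:
        return self.predict_proba(vectors).argmax(axis=1)
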