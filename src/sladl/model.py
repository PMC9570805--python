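"""Per-timestep recurrent sequence classifier: GRU -> biLSTM -> dense -> softmax.

The network reads an unnormalized T x D sensor sequence and emits one
probability vector over the eight activity classes per 10 Hz timestep.
Layer stack:

    sequence input (no normalization)
    GRU, 100 hidden units (unidirectional)
    bidirectional LSTM, 200 units per direction (400-dim concatenated output)
    fully connected to 8 logits
    softmax + categorical cross-entropy

Implementation notes
--------------------
Forward, backward (backpropagation through time) and the Adam update are
written directly on numpy arrays.  Batches of variable-length sequences are
zero-padded; a per-sequence length vector masks the loss, and the backward
direction of the biLSTM is realized by per-sequence time reversal of the
valid samples (padding stays at the tail, where it can influence neither
the valid outputs nor the gradients).  Input-to-hidden projections for all
timesteps are computed as single matrix products outside the recurrent
loops, which keeps the per-step work to the recurrent terms.

Gate conventions: GRU gates (r, z, n) with
``h_t = (1 - z) * h_{t-1} + z * n`` and candidate
``n = tanh(x W_n + (r * h_{t-1}) U_n + b_n)``; LSTM gates (i, f, g, o) with
forget bias initialized to 1.  Input kernels are Glorot-uniform, recurrent
kernels orthogonal, all draws from a generator seeded by the model seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .activities import N_CLASSES


@dataclass
class ModelConfig:
    input_dim: int
    gru_units: int = 100
    bilstm_units: int = 200      # per direction
    n_classes: int = N_CLASSES
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        for name in ("input_dim", "gru_units", "bilstm_units", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


def _sigmoid(x):
    # stable on both tails (plain 1/(1+exp(-x)) overflows in float32)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, shape, dtype):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng, n, dtype):
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return (q * np.sign(np.diag(r))).astype(dtype)


def _orth_stack(rng, n, gates, dtype):
    return np.concatenate([_orthogonal(rng, n, dtype) for _ in range(gates)],
                          axis=1)


class SequenceClassifier:
    """GRU -> biLSTM -> dense -> softmax per-timestep classifier."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        dt = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        D, H1, H2, K = cfg.input_dim, cfg.gru_units, cfg.bilstm_units, cfg.n_classes
        p = {}
        p["gru_Wx"] = np.concatenate(
            [_glorot(rng, (D, H1), dt) for _ in range(3)], axis=1)
        p["gru_U"] = _orth_stack(rng, H1, 3, dt)
        p["gru_b"] = np.zeros(3 * H1, dtype=dt)
        for d in ("f", "b"):
            p[f"lstm{d}_Wx"] = np.concatenate(
                [_glorot(rng, (H1, H2), dt) for _ in range(4)], axis=1)
            p[f"lstm{d}_U"] = _orth_stack(rng, H2, 4, dt)
            b = np.zeros(4 * H2, dtype=dt)
            b[H2:2 * H2] = 1.0  # forget gate bias
            p[f"lstm{d}_b"] = b
        p["out_W"] = _glorot(rng, (2 * H2, K), dt)
        p["out_b"] = np.zeros(K, dtype=dt)
        self.params = p

    # -- parameter plumbing -------------------------------------------------

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, path) -> "SequenceClassifier":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _reverse_padded(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        out = np.zeros_like(X)
        for b, L in enumerate(lengths):
            out[b, :L] = X[b, L - 1::-1]
        return out

    def _gru_forward(self, X):
        p, H1 = self.params, self.cfg.gru_units
        B, T, _ = X.shape
        pre = X @ p["gru_Wx"] + p["gru_b"]
        U_rz, U_n = p["gru_U"][:, :2 * H1], p["gru_U"][:, 2 * H1:]
        R = np.empty((B, T, H1), dtype=pre.dtype)
        Z = np.empty_like(R)
        Nc = np.empty_like(R)
        Hs = np.empty_like(R)
        RH = np.empty_like(R)
        h = np.zeros((B, H1), dtype=pre.dtype)
        for t in range(T):
            a = pre[:, t, :2 * H1] + h @ U_rz
            r = _sigmoid(a[:, :H1])
            z = _sigmoid(a[:, H1:])
            rh = r * h
            n = np.tanh(pre[:, t, 2 * H1:] + rh @ U_n)
            h = (1.0 - z) * h + z * n
            R[:, t], Z[:, t], Nc[:, t], Hs[:, t], RH[:, t] = r, z, n, h, rh
        return {"X": X, "R": R, "Z": Z, "N": Nc, "H": Hs, "RH": RH}

    def _gru_backward(self, cache, dH_out):
        p, H1 = self.params, self.cfg.gru_units
        X, R, Z, Nc, Hs, RH = (cache[k] for k in ("X", "R", "Z", "N", "H", "RH"))
        B, T, _ = X.shape
        U = p["gru_U"]
        U_rz, U_n = U[:, :2 * H1], U[:, 2 * H1:]
        dA = np.zeros((B, T, 3 * H1), dtype=X.dtype)
        dh = np.zeros((B, H1), dtype=X.dtype)
        for t in range(T - 1, -1, -1):
            dh_t = dH_out[:, t] + dh
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            r, z, n = R[:, t], Z[:, t], Nc[:, t]
            dz = dh_t * (n - h_prev)
            dan = dh_t * z * (1.0 - n * n)
            dh = dh_t * (1.0 - z)
            drh = dan @ U_n.T
            dar = drh * h_prev * r * (1.0 - r)
            dh += drh * r
            daz = dz * z * (1.0 - z)
            dA[:, t, :H1] = dar
            dA[:, t, H1:2 * H1] = daz
            dA[:, t, 2 * H1:] = dan
            dh += np.concatenate([dar, daz], axis=1) @ U_rz.T
        flat = dA.reshape(B * T, -1)
        H_prev = np.concatenate(
            [np.zeros((B, 1, H1), dtype=X.dtype), Hs[:, :-1]], axis=1)
        grads = {
            "gru_Wx": X.reshape(B * T, -1).T @ flat,
            "gru_b": flat.sum(axis=0),
        }
        dU = np.empty_like(U)
        dU[:, :2 * H1] = H_prev.reshape(B * T, -1).T @ flat[:, :2 * H1]
        dU[:, 2 * H1:] = RH.reshape(B * T, -1).T @ flat[:, 2 * H1:]
        grads["gru_U"] = dU
        dX = dA @ p["gru_Wx"].T
        return grads, dX

    def _lstm_forward(self, G, key):
        p, H2 = self.params, self.cfg.bilstm_units
        B, T, _ = G.shape
        pre = G @ p[f"{key}_Wx"] + p[f"{key}_b"]
        U = p[f"{key}_U"]
        gates = np.empty((B, T, 4 * H2), dtype=pre.dtype)
        Cs = np.empty((B, T, H2), dtype=pre.dtype)
        Hs = np.empty_like(Cs)
        h = np.zeros((B, H2), dtype=pre.dtype)
        c = np.zeros_like(h)
        for t in range(T):
            a = pre[:, t] + h @ U
            i = _sigmoid(a[:, :H2])
            f = _sigmoid(a[:, H2:2 * H2])
            g = np.tanh(a[:, 2 * H2:3 * H2])
            o = _sigmoid(a[:, 3 * H2:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t, :H2] = i
            gates[:, t, H2:2 * H2] = f
            gates[:, t, 2 * H2:3 * H2] = g
            gates[:, t, 3 * H2:] = o
            Cs[:, t], Hs[:, t] = c, h
        return {"G": G, "gates": gates, "C": Cs, "H": Hs}

    def _lstm_backward(self, cache, dH_out, key):
        p, H2 = self.params, self.cfg.bilstm_units
        G, gates, Cs, Hs = (cache[k] for k in ("G", "gates", "C", "H"))
        B, T, _ = G.shape
        U = p[f"{key}_U"]
        dA = np.zeros((B, T, 4 * H2), dtype=G.dtype)
        dh = np.zeros((B, H2), dtype=G.dtype)
        dc = np.zeros_like(dh)
        for t in range(T - 1, -1, -1):
            dh_t = dH_out[:, t] + dh
            i = gates[:, t, :H2]
            f = gates[:, t, H2:2 * H2]
            g = gates[:, t, 2 * H2:3 * H2]
            o = gates[:, t, 3 * H2:]
            c = Cs[:, t]
            c_prev = Cs[:, t - 1] if t > 0 else np.zeros_like(c)
            tc = np.tanh(c)
            do = dh_t * tc
            dc = dc + dh_t * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dA[:, t] = da
            dh = da @ U.T
        flat = dA.reshape(B * T, -1)
        H_prev = np.concatenate(
            [np.zeros((B, 1, H2), dtype=G.dtype), Hs[:, :-1]], axis=1)
        grads = {
            f"{key}_Wx": G.reshape(B * T, -1).T @ flat,
            f"{key}_U": H_prev.reshape(B * T, -1).T @ flat,
            f"{key}_b": flat.sum(axis=0),
        }
        dG = dA @ p[f"{key}_Wx"].T
        return grads, dG

    def _forward_full(self, X, lengths):
        """Full forward pass on a padded batch; returns caches and probs."""
        p = self.params
        gru = self._gru_forward(X)
        G = gru["H"]
        G_rev = self._reverse_padded(G, lengths)
        lf = self._lstm_forward(G, "lstmf")
        lb = self._lstm_forward(G_rev, "lstmb")
        Hb = self._reverse_padded(lb["H"], lengths)
        Hcat = np.concatenate([lf["H"], Hb], axis=2)
        logits = Hcat @ p["out_W"] + p["out_b"]
        m = logits.max(axis=2, keepdims=True)
        e = np.exp(logits - m)
        probs = e / e.sum(axis=2, keepdims=True)
        return {"gru": gru, "lf": lf, "lb": lb, "Hcat": Hcat,
                "probs": probs, "lengths": lengths}

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Probabilities (T, n_classes) for a single (T, D) sequence."""
        X = np.asarray(X, dtype=self.cfg.dtype)
        if X.ndim != 2 or X.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"expected (T, {self.cfg.input_dim}) input, got {X.shape}")
        cache = self._forward_full(X[None], np.array([X.shape[0]]))
        return cache["probs"][0].astype(np.float64)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-timestep argmax labels; ties resolve to the lowest index."""
        return np.argmax(self.forward(X), axis=1)

    # -- training-side computation -----------------------------------------

    def loss_and_grads(self, X, Y, lengths):
        """Masked mean cross-entropy and gradients on a padded batch.

        X: (B, Tmax, D), Y: (B, Tmax) int labels, lengths: (B,).
        """
        cache = self._forward_full(X, lengths)
        probs = cache["probs"]
        B, T, K = probs.shape
        mask = (np.arange(T)[None, :] < np.asarray(lengths)[:, None])
        n_valid = int(mask.sum())
        idx_b, idx_t = np.nonzero(mask)
        picked = probs[idx_b, idx_t, Y[idx_b, idx_t]]
        loss = float(-np.log(np.maximum(picked, 1e-12)).mean())

        dlogits = probs.copy()
        dlogits[idx_b, idx_t, Y[idx_b, idx_t]] -= 1.0
        dlogits[~mask] = 0.0
        dlogits /= n_valid
        dlogits = dlogits.astype(probs.dtype)

        p = self.params
        Hcat = cache["Hcat"]
        flat = dlogits.reshape(B * T, K)
        grads = {
            "out_W": Hcat.reshape(B * T, -1).T @ flat,
            "out_b": flat.sum(axis=0),
        }
        dHcat = dlogits @ p["out_W"].T
        H2 = self.cfg.bilstm_units
        g_lf, dGf = self._lstm_backward(cache["lf"], dHcat[:, :, :H2], "lstmf")
        dHb_rev = self._reverse_padded(dHcat[:, :, H2:], lengths)
        g_lb, dGb_rev = self._lstm_backward(cache["lb"], dHb_rev, "lstmb")
        dG = dGf + self._reverse_padded(dGb_rev, lengths)
        g_gru, _ = self._gru_backward(cache["gru"], dG)
        grads.update(g_lf)
        grads.update(g_lb)
        grads.update(g_gru)
        return loss, grads, cache


def build_model(cfg: ModelConfig) -> SequenceClassifier:
    """Construct a seeded, untrained classifier from its configuration."""
    return SequenceClassifier(cfg)


def loss(P: np.ndarray, y: np.ndarray) -> float:
    """Mean per-timestep categorical cross-entropy (natural log)."""
    P = np.asarray(P, dtype=float)
    y = np.asarray(y)
    if P.ndim != 2 or y.ndim != 1 or P.shape[0] != y.shape[0]:
        raise ValueError("P must be (T, K) with matching label vector")
    if y.size and (y.min() < 0 or y.max() >= P.shape[1]):
        raise ValueError("label outside the class range")
    return float(-np.log(np.maximum(P[np.arange(y.size), y], 1e-300)).mean())


def predict_from_probs(P: np.ndarray) -> np.ndarray:
    """Argmax decoding with ties broken toward the lowest class index."""
    return np.argmax(np.asarray(P), axis=-1)


class Adam:
    """Adam with global-norm gradient clipping (default clip at 1.0)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            params[k] -= (self.lr * (m / b1t)
                          / (np.sqrt(v / b2t) + self.eps)).astype(params[k].dtype)
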