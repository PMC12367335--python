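"""LSTM sequence regressor: gate equations, batched BPTT, and Adam.

The cell follows the standard formulation

    f_t = sigma(X_t U_f + H_{t-1} W_f [+ b_f])
    c~_t = tanh (X_t U_c + H_{t-1} W_c [+ b_c])
    i_t = sigma(X_t U_i + H_{t-1} W_i [+ b_i])
    O_t = sigma(X_t U_o + H_{t-1} W_o [+ b_o])
    C_t = f_t * C_{t-1} + i_t * c~_t
    H_t = O_t * tanh(C_t)

with element-wise products; a linear head w_out . H_T + b_out maps the
final hidden state to the predicted length-of-stay in days.  Bias vectors
are optional: with ``bias=False`` they are pinned at zero, matching the
bias-free gate equations; training enables them by default.

Everything here is plain NumPy.  The batched forward keeps per-step caches
so the analytic backward pass (verified against finite differences in the
test suite) can run in one sweep; variable-length sequences are padded at
the end and masked so padded steps leave the state untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LSTMWeights",
    "CellState",
    "cell_step",
    "forward_sequence",
    "predict_los",
    "init_weights",
    "pack_sequences",
]

GATES = ("f", "c", "i", "o")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMWeights:
    """Full parameter set of the LSTM regressor.

    ``U_*`` are input-to-gate matrices (input_dim x h), ``W_*`` recurrent
    matrices (h x h), ``b_*`` optional gate biases (h,), and
    ``w_out``/``b_out`` the linear output head.
    """

    U_f: np.ndarray
    U_c: np.ndarray
    U_i: np.ndarray
    U_o: np.ndarray
    W_f: np.ndarray
    W_c: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    w_out: np.ndarray
    b_out: float
    bias_enabled: bool = True

    def __post_init__(self) -> None:
        d, h = np.asarray(self.U_f).shape
        for g in GATES:
            U = np.asarray(getattr(self, f"U_{g}"), dtype=float)
            W = np.asarray(getattr(self, f"W_{g}"), dtype=float)
            b = np.asarray(getattr(self, f"b_{g}"), dtype=float)
            if U.shape != (d, h) or W.shape != (h, h) or b.shape != (h,):
                raise ValueError(
                    f"inconsistent shapes for gate '{g}': U {U.shape}, W {W.shape}, b {b.shape}"
                )
            if not (np.all(np.isfinite(U)) and np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError(f"non-finite values in gate '{g}' weights")
            if not self.bias_enabled and np.any(b != 0.0):
                raise ValueError("bias_enabled=False requires all gate biases to be zero")
            setattr(self, f"U_{g}", U)
            setattr(self, f"W_{g}", W)
            setattr(self, f"b_{g}", b)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_out.shape != (h,):
            raise ValueError(f"w_out must have shape ({h},), got {self.w_out.shape}")
        self.b_out = float(self.b_out)

    @property
    def input_dim(self) -> int:
        return self.U_f.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.U_f.shape[1]

    def to_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for g in GATES:
            out[f"U_{g}"] = getattr(self, f"U_{g}")
            out[f"W_{g}"] = getattr(self, f"W_{g}")
            if self.bias_enabled:
                out[f"b_{g}"] = getattr(self, f"b_{g}")
        out["w_out"] = self.w_out
        out["b_out"] = np.array([self.b_out])
        return out

    def update_from_dict(self, params: dict[str, np.ndarray]) -> None:
        for key, val in params.items():
            if key == "b_out":
                self.b_out = float(val[0])
            else:
                setattr(self, key, val)


def init_weights(
    input_dim: int,
    hidden_dim: int,
    rng: np.random.Generator,
    bias: bool = True,
) -> LSTMWeights:
    """Uniform +-1/sqrt(h) initialization of all weights, seeded by ``rng``.

    Gate biases start at zero (and stay there when ``bias=False``).
    """
    h = hidden_dim
    bound = 1.0 / np.sqrt(h)

    def u(shape):
        return rng.uniform(-bound, bound, size=shape)

    kw = {}
    for g in GATES:
        kw[f"U_{g}"] = u((input_dim, h))
        kw[f"W_{g}"] = u((h, h))
        kw[f"b_{g}"] = np.zeros(h)
    return LSTMWeights(**kw, w_out=u(h), b_out=0.0, bias_enabled=bias)


@dataclass
class CellState:
    """Hidden output H and cell memory C of one LSTM layer."""

    H: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, hidden_dim: int) -> "CellState":
        return cls(H=np.zeros(hidden_dim), C=np.zeros(hidden_dim))


def cell_step(x_t: Sequence[float], state: CellState, weights: LSTMWeights) -> CellState:
    """One application of the six gate equations."""
    x = np.asarray(x_t, dtype=float)
    if x.shape != (weights.input_dim,):
        raise ValueError(
            f"input vector has shape {x.shape}, expected ({weights.input_dim},)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input vector")
    H, C = np.asarray(state.H, float), np.asarray(state.C, float)
    if H.shape != (weights.hidden_dim,) or C.shape != (weights.hidden_dim,):
        raise ValueError("state shape does not match hidden_dim")
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(C))):
        raise ValueError("non-finite state")

    f = _sigmoid(x @ weights.U_f + H @ weights.W_f + weights.b_f)
    c_tilde = np.tanh(x @ weights.U_c + H @ weights.W_c + weights.b_c)
    i = _sigmoid(x @ weights.U_i + H @ weights.W_i + weights.b_i)
    o = _sigmoid(x @ weights.U_o + H @ weights.W_o + weights.b_o)
    C_new = f * C + i * c_tilde
    H_new = o * np.tanh(C_new)
    return CellState(H=H_new, C=C_new)


def forward_sequence(
    series: Sequence[Sequence[float]],
    weights: LSTMWeights,
    initial_state: CellState | None = None,
) -> tuple[CellState, np.ndarray]:
    """Run the cell left-to-right over a (T, input_dim) series.

    Returns the final state and the full (T, h) hidden-state sequence.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty series")
    state = initial_state or CellState.zeros(weights.hidden_dim)
    hidden = np.empty((X.shape[0], weights.hidden_dim))
    for t in range(X.shape[0]):
        state = cell_step(X[t], state, weights)
        hidden[t] = state.H
    return state, hidden


def predict_los(
    series: Sequence[Sequence[float]],
    weights: LSTMWeights,
    initial_state: CellState | None = None,
) -> float:
    """Linear head on the final hidden state: predicted length-of-stay (days)."""
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 1:
        raise ValueError(
            "series has no time steps after preprocessing; use a smaller "
            "wavelet/level or a longer window"
        )
    final, _ = forward_sequence(X, weights, initial_state)
    return float(final.H @ weights.w_out + weights.b_out)


# ---------------------------------------------------------------------------
# batched training path


def pack_sequences(seqs: Iterable[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad a list of (T_i, d) arrays into (B, T_max, d) plus a (B, T_max) mask."""
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in seqs]
    if not seqs:
        raise ValueError("empty batch")
    d = seqs[0].shape[1]
    T = max(s.shape[0] for s in seqs)
    X = np.zeros((len(seqs), T, d))
    mask = np.zeros((len(seqs), T))
    for b, s in enumerate(seqs):
        X[b, : s.shape[0]] = s
        mask[b, : s.shape[0]] = 1.0
    return X, mask


def forward_batch(
    weights: LSTMWeights, X: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Masked batched forward pass.

    Returns predictions (B,) and the cache needed by ``backward_batch``.
    Padded steps (mask 0) copy the previous state through unchanged.
    """
    B, T, d = X.shape
    h = weights.hidden_dim
    H = np.zeros((B, h))
    C = np.zeros((B, h))
    cache = {"X": X, "mask": mask, "H_prev": [], "C_prev": [], "f": [], "i": [],
             "o": [], "ct": [], "C": [], "tC": []}
    for t in range(T):
        m = mask[:, t][:, None]
        x = X[:, t]
        f = _sigmoid(x @ weights.U_f + H @ weights.W_f + weights.b_f)
        ct = np.tanh(x @ weights.U_c + H @ weights.W_c + weights.b_c)
        i = _sigmoid(x @ weights.U_i + H @ weights.W_i + weights.b_i)
        o = _sigmoid(x @ weights.U_o + H @ weights.W_o + weights.b_o)
        C_new = f * C + i * ct
        tC = np.tanh(C_new)
        H_new = o * tC
        cache["H_prev"].append(H)
        cache["C_prev"].append(C)
        for key, val in (("f", f), ("i", i), ("o", o), ("ct", ct), ("C", C_new), ("tC", tC)):
            cache[key].append(val)
        H = m * H_new + (1.0 - m) * H
        C = m * C_new + (1.0 - m) * C
    preds = H @ weights.w_out + weights.b_out
    cache["H_final"] = H
    return preds, cache


def backward_batch(
    weights: LSTMWeights, cache: dict, d_preds: np.ndarray
) -> dict[str, np.ndarray]:
    """Analytic gradients of ``sum(d_preds * preds)`` w.r.t. all parameters."""
    X, mask = cache["X"], cache["mask"]
    B, T, d = X.shape
    h = weights.hidden_dim
    grads = {k: np.zeros_like(v) for k, v in weights.to_dict().items()}
    grads["w_out"] = cache["H_final"].T @ d_preds
    grads["b_out"] = np.array([d_preds.sum()])

    dH = d_preds[:, None] * weights.w_out[None, :]
    dC = np.zeros((B, h))
    for t in range(T - 1, -1, -1):
        m = mask[:, t][:, None]
        dH_eff = m * dH
        dC_eff = m * dC
        f, i, o, ct = cache["f"][t], cache["i"][t], cache["o"][t], cache["ct"][t]
        tC = cache["tC"][t]
        H_prev, C_prev = cache["H_prev"][t], cache["C_prev"][t]
        x = X[:, t]

        do = dH_eff * tC
        dC_tot = dC_eff + dH_eff * o * (1.0 - tC**2)
        df = dC_tot * C_prev
        di = dC_tot * ct
        dct = dC_tot * i
        dzf = df * f * (1.0 - f)
        dzi = di * i * (1.0 - i)
        dzo = do * o * (1.0 - o)
        dzc = dct * (1.0 - ct**2)

        dH_prev = (1.0 - m) * dH
        for g, dz in (("f", dzf), ("c", dzc), ("i", dzi), ("o", dzo)):
            grads[f"U_{g}"] += x.T @ dz
            grads[f"W_{g}"] += H_prev.T @ dz
            if weights.bias_enabled:
                grads[f"b_{g}"] += dz.sum(axis=0)
            dH_prev = dH_prev + dz @ getattr(weights, f"W_{g}").T
        dH = dH_prev
        dC = dC_tot * f + (1.0 - m) * dC
    return grads


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            out[k] = p - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return out
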