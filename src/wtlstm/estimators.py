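"""scikit-learn style estimators for length-of-stay regression.

All regressors consume ``X`` as a list of per-stay ``(T_i, 3)`` channel
matrices (variable length) and ``y`` as LOS in days, and follow the
scikit-learn contract: parameters set in ``__init__``, fitted attributes
with a trailing underscore, ``get_params``/``set_params``/``clone``
compatible.

Training follows a fixed protocol: for each learning rate in ``lr_grid``,
minimize the MSE with Adam on minibatches of ``batch_size``, up to
``max_epochs`` epochs with early stopping on validation loss (patience
``patience``), restoring the best-validation checkpoint; the grid winner is
the learning rate with the lowest validation loss.  A validation set may be
passed to ``fit`` explicitly (the hold-out protocol) or is carved from the
training data.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression

from . import lstm as L
from .wavelets import DenoiseConfig, WaveletSpec, denoise

__all__ = [
    "WaveletDenoiser",
    "LSTMRegressor",
    "WTLSTMRegressor",
    "BiLSTMRegressor",
    "VitalsSummaryRegressor",
    "TrainingDiverged",
]

DEFAULT_LR_GRID = (0.08, 0.1, 0.12, 0.15)


class TrainingDiverged(RuntimeError):
    """Raised when every learning rate in the grid produced non-finite loss."""


def _as_seq_list(X) -> list[np.ndarray]:
    out = []
    for x in X:
        a = np.asarray(x, dtype=float)
        if a.ndim == 1:
            a = a[:, None]
        if a.shape[0] < 1:
            raise ValueError("empty sequence in X")
        out.append(a)
    if not out:
        raise ValueError("X is empty")
    return out


class WaveletDenoiser(BaseEstimator):
    """Per-channel wavelet low-pass denoiser (stateless transformer).

    ``transform`` maps each (T, d) sequence to its level-``level``
    approximation coefficients (length ~ T/2**level) or, with
    ``output_mode='reconstruction'``, to a same-length smoothed sequence.
    """

    def __init__(self, wavelet: str = "db4", level: int = 2,
                 output_mode: str = "approximation", padding_mode: str = "symmetric"):
        self.wavelet = wavelet
        self.level = level
        self.output_mode = output_mode
        self.padding_mode = padding_mode

    def _config(self) -> tuple[DenoiseConfig, WaveletSpec]:
        return (
            DenoiseConfig(level=self.level, output_mode=self.output_mode,
                          padding_mode=self.padding_mode),
            WaveletSpec.from_name(self.wavelet),
        )

    def fit(self, X=None, y=None):
        self._config()  # validate parameters
        return self

    def transform(self, X) -> list[np.ndarray]:
        cfg, spec = self._config()
        out = []
        for seq in _as_seq_list(X):
            cols = [denoise(seq[:, j], cfg, spec) for j in range(seq.shape[1])]
            out.append(np.column_stack(cols))
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class _ChannelStats:
    """Per-channel z-score statistics shared by the sequence regressors."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean, self.sd = mean, sd

    @classmethod
    def fit(cls, seqs: list[np.ndarray]) -> "_ChannelStats":
        stacked = np.concatenate(seqs, axis=0)
        mean = stacked.mean(axis=0)
        sd = stacked.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean, sd)

    def apply(self, seqs: list[np.ndarray]) -> list[np.ndarray]:
        return [(s - self.mean) / self.sd for s in seqs]


class LSTMRegressor(BaseEstimator, RegressorMixin):
    """Sequence-to-one LSTM regressor trained with Adam + early stopping.

    Parameters
    ----------
    hidden_dim : int
        Size of the hidden/cell state (default 32).
    lr_grid : tuple of float
        Learning rates tried; the winner is chosen by validation loss.
    batch_size, max_epochs, patience : int
        Minibatch size, epoch cap, and early-stopping patience (epochs
        without validation improvement).
    bias : bool
        Whether the gates carry trainable bias vectors.
    normalize : bool
        Fit per-channel z-score statistics on the training sequences and
        apply them everywhere (training statistics only).
    val_fraction : float
        Fraction carved from the training data when ``fit`` is not given an
        explicit validation set.
    random_state : int or None
        Seeds initialization and data order.
    """

    def __init__(self, hidden_dim: int = 32, lr_grid: Sequence[float] = DEFAULT_LR_GRID,
                 batch_size: int = 16, max_epochs: int = 100, patience: int = 10,
                 bias: bool = True, normalize: bool = True, val_fraction: float = 0.25,
                 random_state: int | None = None):
        self.hidden_dim = hidden_dim
        self.lr_grid = lr_grid
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.bias = bias
        self.normalize = normalize
        self.val_fraction = val_fraction
        self.random_state = random_state

    # hook for subclasses (wavelet front end)
    def _transform(self, seqs: list[np.ndarray]) -> list[np.ndarray]:
        return seqs

    # ---- forward machinery (overridden by the bidirectional subclass) ----

    def _init_params(self, input_dim: int, rng) -> dict:
        w = L.init_weights(input_dim, self.hidden_dim, rng, bias=self.bias)
        self._weights_obj = w
        return w.to_dict()

    def _predict_batch(self, params: dict, X: np.ndarray, mask: np.ndarray):
        if not hasattr(self, "_weights_obj"):
            # rebuilt estimator (e.g. loaded from an artifact): shell object
            # whose values are immediately overwritten from params
            self._weights_obj = L.init_weights(
                X.shape[2], self.hidden_dim, np.random.default_rng(0), bias=self.bias
            )
        self._weights_obj.update_from_dict(params)
        return L.forward_batch(self._weights_obj, X, mask)

    def _grad_batch(self, params: dict, cache, d_preds: np.ndarray) -> dict:
        return L.backward_batch(self._weights_obj, cache, d_preds)

    # ----------------------------------------------------------------------

    def _pack(self, seqs):
        return L.pack_sequences(seqs)

    def _val_loss(self, params, Xv, mv, yv) -> float:
        preds, _ = self._predict_batch(params, Xv, mv)
        return float(np.mean((preds - yv) ** 2))

    def fit(self, X, y, X_val=None, y_val=None):
        seqs = self._transform(_as_seq_list(X))
        y = np.asarray(y, dtype=float)
        if len(seqs) != len(y):
            raise ValueError(f"X has {len(seqs)} sequences but y has {len(y)} targets")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            n = len(seqs)
            n_val = max(1, int(round(self.val_fraction * n)))
            if n - n_val < 1:
                raise ValueError("not enough sequences to carve a validation set")
            order = rng.permutation(n)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            val_seqs = [seqs[i] for i in val_idx]
            y_v = y[val_idx]
            seqs = [seqs[i] for i in tr_idx]
            y = y[tr_idx]
        else:
            val_seqs = self._transform(_as_seq_list(X_val))
            y_v = np.asarray(y_val, dtype=float)

        if self.normalize:
            self.scaler_ = _ChannelStats.fit(seqs)
            seqs = self.scaler_.apply(seqs)
            val_seqs = self.scaler_.apply(val_seqs)
        else:
            self.scaler_ = None

        Xtr, mtr = self._pack(seqs)
        Xv, mv = self._pack(val_seqs)
        input_dim = Xtr.shape[2]
        n = len(seqs)

        init_seed = int(rng.integers(2**31))
        order_seed = int(rng.integers(2**31))

        best = None  # (val_loss, lr, params, history, n_epochs)
        self.history_ = {}
        for lr in self.lr_grid:
            params = self._init_params(input_dim, np.random.default_rng(init_seed))
            opt = L.Adam(params, lr=lr)
            order_rng = np.random.default_rng(order_seed)
            best_val = np.inf
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = 0
            hist = []
            diverged = False
            for epoch in range(self.max_epochs):
                order = order_rng.permutation(n)
                tr_loss = 0.0
                for start in range(0, n, self.batch_size):
                    idx = order[start : start + self.batch_size]
                    Xb, mb, yb = Xtr[idx], mtr[idx], y[idx]
                    preds, cache = self._predict_batch(params, Xb, mb)
                    err = preds - yb
                    loss = float(np.mean(err**2))
                    if not np.isfinite(loss):
                        diverged = True
                        break
                    tr_loss += loss * len(idx)
                    grads = self._grad_batch(params, cache, 2.0 / len(idx) * err)
                    params = opt.step(params, grads)
                if diverged:
                    warnings.warn(f"training diverged at lr={lr}; skipping this rate")
                    break
                val_loss = self._val_loss(params, Xv, mv, y_v)
                hist.append({"epoch": epoch, "train_mse": tr_loss / n, "val_mse": val_loss})
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_params = {k: v.copy() for k, v in params.items()}
                    best_epoch = epoch
                elif epoch - best_epoch >= self.patience:
                    break
            self.history_[lr] = hist
            if not diverged and np.isfinite(best_val):
                if best is None or best_val < best[0]:
                    best = (best_val, lr, best_params, len(hist))

        if best is None:
            raise TrainingDiverged("all learning rates in the grid diverged")
        self.best_val_loss_, self.lr_, self.params_, self.n_epochs_ = best
        self.input_dim_ = input_dim
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        seqs = self._transform(_as_seq_list(X))
        if self.scaler_ is not None:
            seqs = self.scaler_.apply(seqs)
        Xp, mp = self._pack(seqs)
        preds, _ = self._predict_batch(self.params_, Xp, mp)
        return np.asarray(preds)


class WTLSTMRegressor(LSTMRegressor):
    """Wavelet-denoised LSTM: a level-``level`` low-pass filter bank on each
    channel feeding the LSTM regressor.

    With ``level=0`` the front end is the identity and the estimator is
    exactly the plain :class:`LSTMRegressor` (same seeds give identical
    fits).
    """

    def __init__(self, hidden_dim: int = 32, lr_grid: Sequence[float] = DEFAULT_LR_GRID,
                 batch_size: int = 16, max_epochs: int = 100, patience: int = 10,
                 bias: bool = True, normalize: bool = True, val_fraction: float = 0.25,
                 random_state: int | None = None, wavelet: str = "db4", level: int = 2,
                 output_mode: str = "approximation", padding_mode: str = "symmetric"):
        super().__init__(hidden_dim=hidden_dim, lr_grid=lr_grid, batch_size=batch_size,
                         max_epochs=max_epochs, patience=patience, bias=bias,
                         normalize=normalize, val_fraction=val_fraction,
                         random_state=random_state)
        self.wavelet = wavelet
        self.level = level
        self.output_mode = output_mode
        self.padding_mode = padding_mode

    def _transform(self, seqs: list[np.ndarray]) -> list[np.ndarray]:
        if self.level == 0:
            return seqs
        return WaveletDenoiser(self.wavelet, self.level, self.output_mode,
                               self.padding_mode).transform(seqs)


class BiLSTMRegressor(LSTMRegressor):
    """Bidirectional baseline: independent forward passes over the series
    and its reversal, concatenated final hidden states feeding one linear
    head.  With the backward weights and its head half zeroed it reproduces
    the unidirectional prediction exactly."""

    def _init_params(self, input_dim: int, rng) -> dict:
        wf = L.init_weights(input_dim, self.hidden_dim, rng, bias=self.bias)
        wb = L.init_weights(input_dim, self.hidden_dim, rng, bias=self.bias)
        self._fw, self._bw = wf, wb
        h = self.hidden_dim
        bound = 1.0 / np.sqrt(h)
        params = {}
        for tag, w in (("fw", wf), ("bw", wb)):
            for k, v in w.to_dict().items():
                if k in ("w_out", "b_out"):
                    continue
                params[f"{tag}.{k}"] = v
        params["w_out"] = rng.uniform(-bound, bound, size=2 * h)
        params["b_out"] = np.array([0.0])
        return params

    @staticmethod
    def _reverse(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Reverse each sequence within its own valid length (padding stays
        at the end)."""
        B, T, d = X.shape
        out = np.zeros_like(X)
        lengths = mask.sum(axis=1).astype(int)
        for b in range(B):
            n = lengths[b]
            out[b, :n] = X[b, :n][::-1]
        return out

    def _split_params(self, params: dict):
        if not hasattr(self, "_fw"):
            d = params["fw.U_f"].shape[0]
            rng = np.random.default_rng(0)
            self._fw = L.init_weights(d, self.hidden_dim, rng, bias=self.bias)
            self._bw = L.init_weights(d, self.hidden_dim, rng, bias=self.bias)
        for tag, w in (("fw", self._fw), ("bw", self._bw)):
            sub = {k.split(".", 1)[1]: v for k, v in params.items() if k.startswith(tag + ".")}
            sub["w_out"] = np.zeros(self.hidden_dim)
            sub["b_out"] = np.array([0.0])
            w.update_from_dict(sub)

    def _predict_batch(self, params: dict, X: np.ndarray, mask: np.ndarray):
        self._split_params(params)
        h = self.hidden_dim
        Xr = self._reverse(X, mask)
        _, cache_f = L.forward_batch(self._fw, X, mask)
        _, cache_b = L.forward_batch(self._bw, Xr, mask)
        Hcat = np.concatenate([cache_f["H_final"], cache_b["H_final"]], axis=1)
        preds = Hcat @ params["w_out"] + params["b_out"][0]
        return preds, {"f": cache_f, "b": cache_b, "Hcat": Hcat}

    def _grad_batch(self, params: dict, cache, d_preds: np.ndarray) -> dict:
        h = self.hidden_dim
        w = params["w_out"]
        grads = {"w_out": cache["Hcat"].T @ d_preds, "b_out": np.array([d_preds.sum()])}
        for tag, wobj, sub, half in (("fw", self._fw, cache["f"], w[:h]),
                                     ("bw", self._bw, cache["b"], w[h:])):
            wobj.w_out = half  # route d_preds through the right head half
            g = L.backward_batch(wobj, sub, d_preds)
            for k, v in g.items():
                if k in ("w_out", "b_out"):
                    continue
                grads[f"{tag}.{k}"] = v
        return grads


class VitalsSummaryRegressor(BaseEstimator, RegressorMixin):
    """Ordinary least squares on 9 per-stay summary features (mean, min,
    max of each windowed channel) — the classical vitals baseline.

    ``features='flat'`` instead flattens the whole (padded) window.
    """

    def __init__(self, features: str = "summary"):
        self.features = features

    def _featurize(self, X) -> np.ndarray:
        seqs = _as_seq_list(X)
        if self.features == "summary":
            return np.array(
                [np.concatenate([s.mean(0), s.min(0), s.max(0)]) for s in seqs]
            )
        if self.features == "flat":
            T = max(s.shape[0] for s in seqs)
            if hasattr(self, "n_cols_"):
                T = max(T, self.n_cols_ // seqs[0].shape[1])
            out = np.zeros((len(seqs), T * seqs[0].shape[1]))
            for b, s in enumerate(seqs):
                flat = s[:T].ravel()
                out[b, : flat.size] = flat
            return out
        raise ValueError(f"unknown feature mode {self.features!r}")

    def fit(self, X, y):
        F = self._featurize(X)
        self.n_cols_ = F.shape[1]
        self.ols_ = LinearRegression().fit(F, np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        F = self._featurize(X)
        if F.shape[1] < self.n_cols_:
            F = np.pad(F, ((0, 0), (0, self.n_cols_ - F.shape[1])))
        return self.ols_.predict(F[:, : self.n_cols_])
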