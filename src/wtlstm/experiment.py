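"""Training protocol, hold-out split, evaluation, and the ablation harness.

The protocol: stratified hold-out split of stays into training (56.25%),
validation (18.75%) and test (25%) by LOS-quantile strata; Adam training
with a learning-rate grid, minibatches of 16, up to 100 epochs with early
stopping and best-checkpoint restoration; the whole experiment repeated
over seeded runs.  The ablation harness compares model kinds across
real-time input windows (3/6/12/24 h) and reports per-cell mean/sd test
MSE plus the percentage improvement of the wavelet-denoised model over the
plain LSTM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import CohortTable, DataError, StayRecord, extract_window, impute_missing
from .estimators import (
    DEFAULT_LR_GRID,
    BiLSTMRegressor,
    LSTMRegressor,
    VitalsSummaryRegressor,
    WTLSTMRegressor,
)
from .wavelets import DenoiseConfig

__all__ = [
    "TrainConfig",
    "EvalReport",
    "split_holdout",
    "train_model",
    "evaluate",
    "improvement_pct",
    "run_experiment",
    "summarize_experiment",
]

MODEL_KINDS = ("wtlstm", "lstm", "bilstm", "linreg")
SPLIT_FRACTIONS = (0.5625, 0.1875, 0.25)
QUANTILE_LEVELS = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run.

    Defaults encode the reference protocol: lr grid {0.08, 0.1, 0.12,
    0.15}, batch 16, up to 100 epochs, patience 10, 30 seeded repeats, a
    56.25/18.75/25 stratified hold-out over 4 LOS-quartile strata.
    """

    model_kind: str = "wtlstm"
    window_hours: float = 24.0
    hidden_dim: int = 32
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    n_repeats: int = 30
    split_fractions: tuple[float, float, float] = SPLIT_FRACTIONS
    stratify_bins: int = 4
    seed: int = 0
    bias: bool = True
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    wavelet: str = "db4"
    resplit_each_repeat: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {self.model_kind!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not self.lr_grid:
            raise ValueError("lr_grid must be non-empty")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class EvalReport:
    """Test-set metrics and prediction-distribution summaries."""

    mse: float
    rmse: float
    r2: float
    prediction_quantiles: tuple[float, ...]
    truth_quantiles: tuple[float, ...]
    n_test: int
    n_floored: int = 0  # negative predictions floored in the quantile view

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "prediction_quantiles": list(self.prediction_quantiles),
            "truth_quantiles": list(self.truth_quantiles),
            "n_test": self.n_test,
            "n_floored": self.n_floored,
        }


def split_holdout(
    table: CohortTable, config: TrainConfig
) -> tuple[CohortTable, CohortTable, CohortTable]:
    """Stratified hold-out split by LOS quantile bins.

    Records are binned into ``stratify_bins`` LOS-quantile strata; within
    each stratum they are shuffled with the run seed and assigned to
    train/validation/test at the configured fractions, so every split
    mirrors the pooled LOS composition.
    """
    los = table.los
    n = len(table)
    bins = config.stratify_bins
    try:
        strata = pd.qcut(los, q=bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise DataError(f"cannot form {bins} LOS strata: {exc}") from exc
    rng = np.random.default_rng(config.seed)
    f_tr, f_val, _ = config.split_fractions
    tr_idx: list[int] = []
    val_idx: list[int] = []
    te_idx: list[int] = []
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        if len(members) < 3:
            raise DataError(
                f"stratum {s} has only {len(members)} records; use fewer stratify_bins"
            )
        members = members[rng.permutation(len(members))]
        n_tr = int(round(f_tr * len(members)))
        n_val = int(round((f_tr + f_val) * len(members))) - n_tr
        n_tr = max(n_tr, 1)
        n_val = max(n_val, 1)
        if n_tr + n_val >= len(members):
            raise DataError(
                f"stratum {s} too small for the requested fractions; use fewer stratify_bins"
            )
        tr_idx.extend(members[:n_tr])
        val_idx.extend(members[n_tr : n_tr + n_val])
        te_idx.extend(members[n_tr + n_val :])
    return (
        table.subset(sorted(tr_idx), "train"),
        table.subset(sorted(val_idx), "validation"),
        table.subset(sorted(te_idx), "test"),
    )


def _build_estimator(config: TrainConfig):
    common = dict(
        hidden_dim=config.hidden_dim,
        lr_grid=config.lr_grid,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        bias=config.bias,
        random_state=config.seed,
    )
    if config.model_kind == "wtlstm":
        return WTLSTMRegressor(
            wavelet=config.wavelet,
            level=config.denoise.level,
            output_mode=config.denoise.output_mode.value,
            padding_mode=config.denoise.padding_mode.value,
            **common,
        )
    if config.model_kind == "lstm":
        return LSTMRegressor(**common)
    if config.model_kind == "bilstm":
        return BiLSTMRegressor(**common)
    return VitalsSummaryRegressor()


def _prepare(table: CohortTable, window_hours: float) -> tuple[list[np.ndarray], np.ndarray]:
    """window -> impute -> (X sequences, y) for one split."""
    X, y = [], []
    for r in table:
        r = impute_missing(extract_window(r, window_hours))
        X.append(r.channel_matrix())
        y.append(r.los)
    return X, np.asarray(y)


def train_model(train: CohortTable, validation: CohortTable, config: TrainConfig):
    """Fit the configured model kind on the train split, early-stopping and
    lr-grid selection on the validation split.  Returns the fitted
    estimator (training history on its ``history_`` attribute)."""
    if len(train) == 0 or len(validation) == 0:
        raise DataError("train and validation splits must be non-empty")
    Xtr, ytr = _prepare(train, config.window_hours)
    Xv, yv = _prepare(validation, config.window_hours)
    est = _build_estimator(config)
    if isinstance(est, VitalsSummaryRegressor):
        est.fit(Xtr, ytr)
    else:
        est.fit(Xtr, ytr, X_val=Xv, y_val=yv)
    return est


def evaluate(model, test: CohortTable, window_hours: float) -> EvalReport:
    """Test-set MSE/RMSE/R2 and prediction/truth quantile summaries."""
    if len(test) == 0:
        raise DataError("test split is empty")
    Xte, yte = _prepare(test, window_hours)
    preds = np.asarray(model.predict(Xte), dtype=float)
    mse = float(np.mean((preds - yte) ** 2))
    sst = float(np.sum((yte - yte.mean()) ** 2))
    r2 = 1.0 - float(np.sum((preds - yte) ** 2)) / sst if sst > 0 else 0.0
    n_floored = int(np.sum(preds < 0))
    floored = np.maximum(preds, 0.0)
    return EvalReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r2=r2,
        prediction_quantiles=tuple(np.percentile(floored, QUANTILE_LEVELS)),
        truth_quantiles=tuple(np.percentile(yte, QUANTILE_LEVELS)),
        n_test=len(yte),
        n_floored=n_floored,
    )


def improvement_pct(mse_base: float, mse_new: float) -> float:
    """Signed percentage reduction in MSE relative to a baseline.

    ``(mse_base - mse_new) / mse_base * 100`` — negative when the new
    model is worse than the baseline.
    """
    if mse_base <= 0:
        raise ValueError(f"mse_base must be > 0, got {mse_base}")
    return (mse_base - mse_new) / mse_base * 100.0


def run_experiment(
    table: CohortTable,
    config: TrainConfig,
    model_kinds: Sequence[str] = ("wtlstm", "lstm"),
    windows: Sequence[float] = (24.0,),
) -> pd.DataFrame:
    """The ablation harness: repeat x model kind x window grid.

    For every (model kind, window, repeat) cell: split -> window -> impute
    -> (denoise iff wtlstm) -> normalize -> train -> evaluate.  Repeat r
    uses seed ``config.seed + r``; by default each repeat re-splits the
    cohort and re-initializes the model.  Returns a tidy frame with one
    row per cell and columns ``model, window_hours, repeat, seed, mse,
    rmse, r2, lr, n_epochs``.
    """
    if not model_kinds:
        raise ValueError("model_kinds must be non-empty")
    for mk in model_kinds:
        if mk not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {mk!r}")
    rows = []
    base_split = None
    for rep in range(config.n_repeats):
        seed_r = config.seed + rep
        cfg_r = replace(config, seed=seed_r)
        if config.resplit_each_repeat or base_split is None:
            base_split = split_holdout(table, cfg_r)
        train, val, test = base_split
        for window in windows:
            for kind in model_kinds:
                cfg = replace(cfg_r, model_kind=kind, window_hours=window)
                try:
                    model = train_model(train, val, cfg)
                    report = evaluate(model, test, window)
                except Exception as exc:
                    raise RuntimeError(
                        f"experiment cell failed (model={kind}, window={window}, "
                        f"seed={seed_r}): {exc}"
                    ) from exc
                rows.append(
                    {
                        "model": kind,
                        "window_hours": window,
                        "repeat": rep,
                        "seed": seed_r,
                        "mse": report.mse,
                        "rmse": report.rmse,
                        "r2": report.r2,
                        "lr": getattr(model, "lr_", np.nan),
                        "n_epochs": getattr(model, "n_epochs_", 0),
                    }
                )
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean/sd MSE plus wtlstm-vs-lstm improvement per window."""
    summary = (
        results.groupby(["model", "window_hours"])["mse"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "mse_mean", "std": "mse_sd", "count": "n_repeats"})
    )
    if {"wtlstm", "lstm"}.issubset(set(results["model"])):
        imp_rows = []
        for window, sub in summary.groupby("window_hours"):
            by_model = sub.set_index("model")["mse_mean"]
            if {"wtlstm", "lstm"}.issubset(by_model.index):
                imp_rows.append(
                    {
                        "window_hours": window,
                        "improvement_pct_wtlstm_vs_lstm": improvement_pct(
                            by_model["lstm"], by_model["wtlstm"]
                        ),
                    }
                )
        if imp_rows:
            summary = summary.merge(pd.DataFrame(imp_rows), on="window_hours", how="left")
    return summary
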