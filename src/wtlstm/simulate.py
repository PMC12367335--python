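"""Synthetic ICU-cohort generator.

Emulates the statistical structure the length-of-stay method assumes,
without any access to real patient data:

* a right-skewed lognormal LOS driven by a latent severity z ~ N(0, 1)
  (so severity and LOS have Spearman correlation exactly 1);
* severity-coupled vital-sign trends — higher severity raises heart rate
  and respiration and lowers SaO2, with the coupling amplified in the
  early phase of the stay so that short observation windows carry signal;
* a slow AR(1) noise component plus white high-frequency noise (the part
  a low-pass wavelet filter bank is meant to remove);
* occasional independently-missing samples.

Channels are sampled on the 5-minute grid; SaO2 is clipped to [0, 100].
A preset name plus a seed fully determines the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from .data import CHANNELS, CohortTable, StayRecord

__all__ = ["CohortSimParams", "simulate_stay", "simulate_cohort", "preset", "PRESETS"]


@dataclass(frozen=True)
class CohortSimParams:
    """Generative settings of the synthetic cohort.

    ``severity_coupling`` maps one unit of latent severity to a shift of
    each channel's level (bpm, breaths/min, %); the early-phase ramp
    multiplies that shift by ``1 + early_gain`` at admission, decaying
    linearly to 1 over ``early_hours``.
    """

    n_stays: int = 1000
    los_mu: float = float(np.log(2.5))  # median 2.5 days
    los_sigma: float = 0.7
    channel_baseline: tuple[float, float, float] = (85.0, 18.0, 96.0)
    channel_sd: tuple[float, float, float] = (10.0, 3.0, 1.5)
    severity_coupling: tuple[float, float, float] = (8.0, 3.0, -2.0)
    early_gain: float = 1.0
    early_hours: float = 6.0
    ar_coef: float = 0.9
    ar_sd: tuple[float, float, float] = (3.0, 1.5, 0.8)
    noise_sd: tuple[float, float, float] = (4.0, 2.0, 1.0)
    missing_rate: float = 0.02
    max_window_hours: float = 24.0
    sample_interval: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.los_sigma >= 0:
            raise ValueError("los_sigma must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")


# analogues of diagnosis cohorts where the vitals carry strong vs weak
# severity signal
PRESETS: Mapping[str, dict] = {
    "signal-rich": {"severity_coupling": (8.0, 3.0, -2.0), "early_gain": 1.0},
    "signal-poor": {"severity_coupling": (1.5, 0.5, -0.3), "early_gain": 0.3},
}


def preset(name: str, **overrides) -> CohortSimParams:
    """Named parameter preset ('signal-rich' or 'signal-poor')."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return CohortSimParams(**{**PRESETS[name], **overrides})


def _stay_trend(
    params: CohortSimParams, z: float, offsets_h: np.ndarray, subject_offset: np.ndarray
) -> np.ndarray:
    """Noise-free (T, 3) channel trend for severity z."""
    ramp = 1.0 + params.early_gain * np.clip(1.0 - offsets_h / params.early_hours, 0.0, 1.0)
    trend = np.empty((len(offsets_h), 3))
    for j in range(3):
        trend[:, j] = (
            params.channel_baseline[j]
            + subject_offset[j]
            + params.severity_coupling[j] * z * ramp
        )
    trend[:, 2] = np.clip(trend[:, 2], 0.0, 100.0)
    return trend


def simulate_stay(
    params: CohortSimParams,
    rng: np.random.Generator,
    stay_id: str = "sim-0",
    diagnosis: str = "SYN",
    return_trend: bool = False,
):
    """Draw one synthetic stay.

    With ``return_trend=True`` also returns the (T, 3) noise-free trend
    (before missingness), used to quantify the denoising benefit.
    """
    z = rng.standard_normal()
    los = float(np.exp(params.los_mu + params.los_sigma * z))
    per_day = int(round(24 * 60 / params.sample_interval))  # 288
    n = int(min(np.ceil(los * per_day), params.max_window_hours * 60 / params.sample_interval))
    n = max(n, 2)
    offsets_h = np.arange(n) * params.sample_interval / 60.0

    subject_offset = rng.standard_normal(3) * np.asarray(params.channel_sd)
    trend = _stay_trend(params, z, offsets_h, subject_offset)

    channels = np.empty_like(trend)
    for j in range(3):
        # AR(1) low-frequency noise with stationary sd ar_sd[j]
        innov_sd = params.ar_sd[j] * np.sqrt(1.0 - params.ar_coef**2)
        e = rng.standard_normal(n) * innov_sd
        slow = lfilter([1.0], [1.0, -params.ar_coef], e)
        white = rng.standard_normal(n) * params.noise_sd[j]
        channels[:, j] = trend[:, j] + slow + white
    channels[:, 0] = np.maximum(channels[:, 0], 0.0)
    channels[:, 1] = np.maximum(channels[:, 1], 0.0)
    channels[:, 2] = np.clip(channels[:, 2], 0.0, 100.0)

    if params.missing_rate > 0:
        mask = rng.random(size=channels.shape) < params.missing_rate
        channels = np.where(mask, np.nan, channels)

    record = StayRecord(
        stay_id=stay_id,
        diagnosis=diagnosis,
        los=los,
        heartrate=channels[:, 0],
        respiration=channels[:, 1],
        sao2=channels[:, 2],
        sample_interval=params.sample_interval,
    )
    if return_trend:
        return record, trend, z
    return record


def simulate_cohort(params: CohortSimParams) -> CohortTable:
    """n_stays independent stays from a generator seeded by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    records = [
        simulate_stay(params, rng, stay_id=f"sim-{k}") for k in range(params.n_stays)
    ]
    prov = {"simulator": "wtlstm.simulate", "seed": params.seed,
            "params": {f.name: getattr(params, f.name) for f in params.__dataclass_fields__.values()}}
    return CohortTable(records, provenance=prov)
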