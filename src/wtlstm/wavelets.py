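"""Discrete wavelet transform filter bank for denoising vital-sign series.

A vital-sign series is passed through a two-channel filter bank: the
low-pass branch captures the slow physiological trend (the *approximation*
coefficients) and the high-pass branch captures high-frequency content that
is treated as monitor noise and discarded.  Cascading the low-pass branch
``level`` times yields a level-``j`` filter bank; the default ``level=2``
keeps only frequency content below f_s/8.

Filters follow the orthonormal convention ``sum(dec_lo) == sqrt(2)``, so a
constant series maps to a sqrt(2)-scaled constant at each level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pywt

__all__ = [
    "WaveletSpec",
    "DenoiseConfig",
    "PaddingMode",
    "OutputMode",
    "analysis_step",
    "synthesis_step",
    "denoise",
]

_SQRT2 = np.sqrt(2.0)


class PaddingMode(str, Enum):
    """Boundary extension applied before filtering."""

    symmetric = "symmetric"
    zero = "zero"
    periodic = "periodic"


class OutputMode(str, Enum):
    """What ``denoise`` returns: downsampled coefficients or a same-length
    low-pass reconstruction."""

    approximation = "approximation"
    reconstruction = "reconstruction"


@dataclass(frozen=True)
class WaveletSpec:
    """A named wavelet's analysis/synthesis filter coefficients.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"haar"`` or ``"db4"``.
    dec_lo, dec_hi : ndarray
        Decomposition (analysis) low/high-pass filters.
    rec_lo, rec_hi : ndarray
        Reconstruction (synthesis) filters.
    orthogonal : bool
        True for orthonormal filter banks (perfect reconstruction via the
        transpose operator).
    """

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray
    orthogonal: bool = True

    def __post_init__(self) -> None:
        for attr in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        L = len(self.dec_lo)
        if L < 2 or L % 2 != 0:
            raise ValueError(f"dec_lo must have even length >= 2, got {L}")
        if len(self.dec_hi) != L:
            raise ValueError("dec_lo and dec_hi must have equal length")
        if self.orthogonal:
            if abs(self.dec_lo.sum() - _SQRT2) > 1e-10:
                raise ValueError(
                    "orthogonal wavelet requires sum(dec_lo) == sqrt(2), "
                    f"got {self.dec_lo.sum()!r}"
                )
            # quadrature-mirror relation: alternating-sign time reversal
            k = np.arange(L)
            qmf = ((-1.0) ** (k + 1)) * self.dec_lo[::-1]
            if np.max(np.abs(self.dec_hi - qmf)) > 1e-12:
                raise ValueError("dec_hi is not the quadrature mirror of dec_lo")

    @property
    def filter_length(self) -> int:
        return len(self.dec_lo)

    @classmethod
    def from_name(cls, name: str) -> "WaveletSpec":
        """Build a spec from a standard wavelet name ("haar", "db2", "db4", ...)."""
        w = pywt.Wavelet(name)
        return cls(
            name=name,
            dec_lo=np.asarray(w.dec_lo),
            dec_hi=np.asarray(w.dec_hi),
            rec_lo=np.asarray(w.rec_lo),
            rec_hi=np.asarray(w.rec_hi),
            orthogonal=bool(w.orthogonal),
        )


@dataclass(frozen=True)
class DenoiseConfig:
    """Settings of the denoising cascade.

    ``level=0`` is a pass-through.  ``approximation`` output returns the
    final-level low-pass coefficients (length ~ n / 2**level);
    ``reconstruction`` inverts the cascade with all detail branches zeroed
    and returns a series of the original length.
    """

    level: int = 2
    output_mode: OutputMode = OutputMode.approximation
    padding_mode: PaddingMode = PaddingMode.symmetric

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"level must be >= 0, got {self.level}")
        object.__setattr__(self, "output_mode", OutputMode(self.output_mode))
        object.__setattr__(self, "padding_mode", PaddingMode(self.padding_mode))


def _validate_signal(signal: Sequence[float], min_len: int, what: str = "signal") -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite values")
    if len(x) < min_len:
        raise ValueError(
            f"series too short for this wavelet: length {len(x)} < "
            f"minimum admissible length {min_len}"
        )
    return x


def _extend(x: np.ndarray, pad: int, mode: PaddingMode) -> np.ndarray:
    if mode == PaddingMode.zero:
        return np.pad(x, pad, mode="constant")
    if mode == PaddingMode.symmetric:
        return np.pad(x, pad, mode="symmetric")
    return np.pad(x, pad, mode="wrap")


def analysis_step(
    signal: Sequence[float],
    spec: WaveletSpec,
    padding_mode: PaddingMode = PaddingMode.symmetric,
) -> tuple[np.ndarray, np.ndarray]:
    """One stage of the analysis filter bank: filter and downsample by 2.

    Returns ``(approx, detail)``.  For ``periodic`` padding the transform is
    the periodized orthogonal DWT (output length ceil(n/2), odd input
    wrapped to even length); for ``zero``/``symmetric`` the signal is
    extended by ``filter_length - 1`` on each side, fully convolved, and
    every second sample kept (output length floor((n + L - 1) / 2)).
    """
    padding_mode = PaddingMode(padding_mode)
    L = spec.filter_length
    x = _validate_signal(signal, min_len=L)

    if padding_mode == PaddingMode.periodic:
        if len(x) % 2 == 1:
            x = np.concatenate([x, x[:1]])
        n = len(x)
        k = np.arange(n // 2)[:, None]
        m = np.arange(L)[None, :]
        idx = (2 * k + 1 - m) % n
        windows = x[idx]
        return windows @ spec.dec_lo, windows @ spec.dec_hi

    x_ext = _extend(x, L - 1, padding_mode)
    # correlation with the time-reversed filter == true convolution
    windows = np.lib.stride_tricks.sliding_window_view(x_ext, L)
    full_lo = windows @ spec.dec_lo[::-1]
    full_hi = windows @ spec.dec_hi[::-1]
    return full_lo[1::2], full_hi[1::2]


def synthesis_step(
    approx: Sequence[float],
    detail: Sequence[float],
    spec: WaveletSpec,
    original_length: int,
    padding_mode: PaddingMode = PaddingMode.symmetric,
) -> np.ndarray:
    """Invert one analysis stage: upsample by 2, filter, sum, trim.

    For ``periodic`` padding this is the exact transpose of the periodized
    analysis operator (perfect reconstruction for orthogonal wavelets).
    """
    padding_mode = PaddingMode(padding_mode)
    a = np.asarray(approx, dtype=float)
    d = np.asarray(detail, dtype=float)
    if a.shape != d.shape or a.ndim != 1:
        raise ValueError(
            f"approx and detail must be 1-d of equal length, got {a.shape} and {d.shape}"
        )
    L = spec.filter_length

    if padding_mode == PaddingMode.periodic:
        n = 2 * len(a)
        k = np.arange(len(a))[:, None]
        m = np.arange(L)[None, :]
        idx = (2 * k + 1 - m) % n
        x = np.zeros(n)
        np.add.at(x, idx, a[:, None] * spec.dec_lo[None, :])
        np.add.at(x, idx, d[:, None] * spec.dec_hi[None, :])
        return x[:original_length]

    # upsample (coefficient at even slots), filter, overlap-add, then cut
    # the L-2 transient samples from each end
    up_a = np.zeros(2 * len(a) - 1)
    up_a[::2] = a
    up_d = np.zeros(2 * len(d) - 1)
    up_d[::2] = d
    full = np.convolve(up_a, spec.rec_lo) + np.convolve(up_d, spec.rec_hi)
    if L > 2:
        full = full[L - 2 : len(full) - (L - 2)]
    return full[:original_length]


def _min_length(spec: WaveletSpec, level: int) -> int:
    return spec.filter_length * 2**max(level, 1) // 2 * 2 if level else 1


def denoise(
    series: Sequence[float],
    config: DenoiseConfig = DenoiseConfig(),
    spec: WaveletSpec | None = None,
) -> np.ndarray:
    """Low-pass denoise a series through a level-``j`` filter bank.

    Applies ``analysis_step`` ``config.level`` times to successive
    approximations.  With ``output_mode="approximation"`` the final-level
    approximation coefficients are returned (the downsampled trend); with
    ``"reconstruction"`` the cascade is inverted with every detail branch
    zeroed, giving a smoothed series of the original length.
    """
    if spec is None:
        spec = WaveletSpec.from_name("db4")
    x = _validate_signal(series, min_len=1, what="series")
    if config.level == 0:
        return x.copy()

    min_len = spec.filter_length * 2 ** (config.level - 1)
    if len(x) < min_len:
        raise ValueError(
            f"series of length {len(x)} too short for level {config.level} with "
            f"'{spec.name}': minimum admissible length is {min_len}"
        )

    lengths: list[int] = []
    approx = x
    for _ in range(config.level):
        lengths.append(len(approx))
        approx, _detail = analysis_step(approx, spec, config.padding_mode)
    if config.output_mode == OutputMode.approximation:
        return approx
    for orig_len in reversed(lengths):
        approx = synthesis_step(
            approx, np.zeros_like(approx), spec, orig_len, config.padding_mode
        )
    return approx
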