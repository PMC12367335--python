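"""ICU-stay data model, real-time windowing, imputation, normalization, I/O.

A stay is three aligned vital-sign series — heart rate (bpm), respiration
rate (breaths/min), SaO2 (%) — on an implicit 5-minute grid from ICU
admission, plus a length-of-stay target in days.  Cohorts are exchanged as
two delimited tables mirroring the eICU ``vitalPeriodic`` layout:

* vitals: ``stay_id, offset_minutes, heartrate, respiration, sao2``
* stays:  ``stay_id, diagnosis, los_days``

Missing samples are empty cells (NaN in memory).  Offsets that are not
multiples of the sampling interval are snapped to the nearest grid point;
duplicates on one grid point are averaged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "StayRecord",
    "CohortTable",
    "Normalizer",
    "DataError",
    "extract_window",
    "impute_missing",
    "fit_normalizer",
    "apply_normalizer",
    "read_cohort",
    "write_cohort",
]

CHANNELS = ("heartrate", "respiration", "sao2")


class DataError(ValueError):
    """Invalid or inconsistent cohort data."""


@dataclass
class StayRecord:
    """One ICU stay: three aligned vital-sign series and the LOS target."""

    stay_id: str
    diagnosis: str
    los: float
    heartrate: np.ndarray
    respiration: np.ndarray
    sao2: np.ndarray
    sample_interval: float = 5.0
    n_imputed: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            setattr(self, ch, np.asarray(getattr(self, ch), dtype=float))
        lengths = {len(getattr(self, ch)) for ch in CHANNELS}
        if len(lengths) != 1:
            raise DataError(
                f"stay {self.stay_id}: channel lengths differ "
                f"({ {ch: len(getattr(self, ch)) for ch in CHANNELS} })"
            )
        if not self.los > 0:
            raise DataError(f"stay {self.stay_id}: los must be > 0, got {self.los}")
        if self.normalized:
            return
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.sao2, initial=100.0) < 0 or np.nanmax(self.sao2, initial=0.0) > 100:
                raise DataError(f"stay {self.stay_id}: sao2 outside [0, 100]")
            for ch in ("heartrate", "respiration"):
                if np.nanmin(getattr(self, ch), initial=0.0) < 0:
                    raise DataError(f"stay {self.stay_id}: negative {ch}")

    def __len__(self) -> int:
        return len(self.heartrate)

    @property
    def offsets_minutes(self) -> np.ndarray:
        return np.arange(len(self)) * self.sample_interval

    def channel_matrix(self) -> np.ndarray:
        """(T, 3) array in fixed channel order heartrate, respiration, sao2."""
        return np.column_stack([getattr(self, ch) for ch in CHANNELS])

    def replace(self, **kw) -> "StayRecord":
        return dataclasses.replace(self, **kw)


@dataclass
class CohortTable:
    """A collection of stays plus provenance metadata."""

    records: list[StayRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.stay_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate stay_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def los(self) -> np.ndarray:
        return np.array([r.los for r in self.records])

    def subset(self, indices: Iterable[int], note: str | None = None) -> "CohortTable":
        prov = dict(self.provenance)
        if note:
            prov["subset"] = note
        return CohortTable([self.records[i] for i in indices], prov)


def extract_window(record: StayRecord, hours: float) -> StayRecord:
    """Keep only samples recorded before the cutoff (offset < hours*60 min).

    Stays shorter than the window contribute their complete available data;
    the LOS target is never altered.
    """
    if hours <= 0:
        raise ValueError(f"window hours must be positive, got {hours}")
    n_keep = int(np.sum(record.offsets_minutes < hours * 60.0))
    if n_keep == 0:
        raise DataError(f"stay {record.stay_id}: no samples before the {hours} h cutoff")
    if n_keep == len(record):
        return record
    return record.replace(**{ch: getattr(record, ch)[:n_keep] for ch in CHANNELS})


def impute_missing(record: StayRecord, policy: str = "ffill") -> StayRecord:
    """Fill missing samples (NaN): forward-fill, then back-fill leading gaps.

    The returned record's ``n_imputed`` counts the filled cells.
    """
    if policy != "ffill":
        raise ValueError(f"unknown imputation policy {policy!r}")
    filled = {}
    n_imputed = 0
    for ch in CHANNELS:
        s = pd.Series(getattr(record, ch))
        n_missing = int(s.isna().sum())
        if n_missing == len(s):
            raise DataError(f"stay {record.stay_id}: channel {ch} has no observed values")
        if n_missing:
            s = s.ffill().bfill()
        filled[ch] = s.to_numpy()
        n_imputed += n_missing
    if n_imputed == 0:
        return record
    return record.replace(n_imputed=record.n_imputed + n_imputed, **filled)


@dataclass(frozen=True)
class Normalizer:
    """Per-channel z-score statistics fitted on the training pool only."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,)

    def transform(self, record: StayRecord) -> StayRecord:
        kw = {
            ch: (getattr(record, ch) - self.mean[j]) / self.sd[j]
            for j, ch in enumerate(CHANNELS)
        }
        return record.replace(normalized=True, **kw)

    def inverse(self, record: StayRecord) -> StayRecord:
        kw = {
            ch: getattr(record, ch) * self.sd[j] + self.mean[j]
            for j, ch in enumerate(CHANNELS)
        }
        return record.replace(normalized=False, **kw)

    def transform_matrix(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def inverse_transform_matrix(self, X: np.ndarray) -> np.ndarray:
        return X * self.sd + self.mean


def fit_normalizer(train_records: Iterable[StayRecord]) -> Normalizer:
    """Per-channel mean/sd over all samples of the training pool.

    A channel with zero spread gets sd 1 (with a warning), so constant
    channels normalize to zero rather than dividing by zero.
    """
    records = list(train_records)
    if not records:
        raise DataError("cannot fit a normalizer on an empty pool")
    stacked = np.concatenate([r.channel_matrix() for r in records], axis=0)
    mean = np.nanmean(stacked, axis=0)
    sd = np.nanstd(stacked, axis=0)
    if np.any(sd == 0):
        import warnings

        warnings.warn("zero-variance channel(s) in training pool; using sd=1")
        sd = np.where(sd == 0, 1.0, sd)
    return Normalizer(mean=mean, sd=sd)


def apply_normalizer(record: StayRecord, normalizer: Normalizer) -> StayRecord:
    """Z-score a stay's channels with training statistics."""
    return normalizer.transform(record)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _snap_to_grid(df: pd.DataFrame, interval: float) -> pd.DataFrame:
    df = df.copy()
    df["grid"] = np.rint(df["offset_minutes"] / interval).astype(int)
    return df.groupby("grid", as_index=False).agg(
        {ch: "mean" for ch in CHANNELS}
    )


def read_cohort(
    vitals_file, stays_file, sample_interval: float = 5.0
) -> CohortTable:
    """Read and join the vitals and stays tables into a CohortTable.

    Raises :class:`DataError` for orphan stay_ids on either side or
    unparseable numeric cells (reported with their row number).
    """
    try:
        vitals = pd.read_csv(vitals_file, float_precision="round_trip")
        stays = pd.read_csv(stays_file, dtype={"stay_id": str},
                            float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DataError(f"cannot read cohort files: {exc}") from exc

    required_v = {"stay_id", "offset_minutes", *CHANNELS}
    if not required_v.issubset(vitals.columns):
        raise DataError(f"vitals file missing columns {sorted(required_v - set(vitals.columns))}")
    required_s = {"stay_id", "diagnosis", "los_days"}
    if not required_s.issubset(stays.columns):
        raise DataError(f"stays file missing columns {sorted(required_s - set(stays.columns))}")

    vitals["stay_id"] = vitals["stay_id"].astype(str)
    for col in ("offset_minutes", *CHANNELS):
        try:
            vitals[col] = pd.to_numeric(vitals[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(vitals[col], errors="coerce")
            bad = vitals.index[coerced.isna() & vitals[col].notna()]
            raise DataError(
                f"unparseable numeric cell in vitals column {col!r}, "
                f"data row {int(bad[0]) + 1}"
            )
    try:
        stays["los_days"] = pd.to_numeric(stays["los_days"])
    except (ValueError, TypeError):
        coerced = pd.to_numeric(stays["los_days"], errors="coerce")
        bad = stays.index[coerced.isna() & stays["los_days"].notna()]
        raise DataError(f"unparseable los_days in stays file, data row {int(bad[0]) + 1}")

    v_ids = set(vitals["stay_id"]) if len(vitals) else set()
    s_ids = set(stays["stay_id"])
    orphans_v = sorted(v_ids - s_ids)
    orphans_s = sorted(s_ids - v_ids)
    if orphans_v or orphans_s:
        raise DataError(
            f"orphan stay_ids: in vitals only {orphans_v}, in stays only {orphans_s}"
        )

    records = []
    for _, row in stays.iterrows():
        sub = vitals[vitals["stay_id"] == row["stay_id"]].sort_values("offset_minutes")
        sub = _snap_to_grid(sub, sample_interval)
        grid = sub["grid"].to_numpy()
        n = grid.max() + 1 if len(grid) else 0
        series = {ch: np.full(n, np.nan) for ch in CHANNELS}
        for ch in CHANNELS:
            series[ch][grid] = sub[ch].to_numpy()
        records.append(
            StayRecord(
                stay_id=str(row["stay_id"]),
                diagnosis=str(row["diagnosis"]),
                los=float(row["los_days"]),
                sample_interval=sample_interval,
                **series,
            )
        )
    return CohortTable(
        records, provenance={"vitals_file": str(vitals_file), "stays_file": str(stays_file)}
    )


def write_cohort(table: CohortTable, vitals_file, stays_file) -> None:
    """Write a cohort back to the two delimited tables (lossless round trip)."""
    v_rows = []
    s_rows = []
    for r in table:
        offs = r.offsets_minutes
        mat = r.channel_matrix()
        for t in range(len(r)):
            if np.all(np.isnan(mat[t])):
                continue
            v_rows.append((r.stay_id, offs[t], *mat[t]))
        s_rows.append((r.stay_id, r.diagnosis, r.los))
    # %.17g keeps the write -> read round trip bit-exact for float64
    pd.DataFrame(
        v_rows, columns=["stay_id", "offset_minutes", *CHANNELS]
    ).to_csv(vitals_file, index=False, float_format="%.17g")
    pd.DataFrame(s_rows, columns=["stay_id", "diagnosis", "los_days"]).to_csv(
        stays_file, index=False, float_format="%.17g"
    )
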