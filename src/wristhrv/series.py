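"""Core data model for heart-rate and inter-beat-interval series.

Wrist wearables export instantaneous heart rate (IHR) as a timestamped
series in beats per minute, typically with gaps where the optical sensor
lost contact.  A chest-strap reference records the same quantity with far
fewer dropouts.  This module holds both in a common container
(:class:`HeartRateSeries`), converts between HR and pseudo inter-beat
intervals, and provides the plumbing every later stage relies on: CSV
ingest, resampling onto a uniform grid (so gaps become explicit missing
slots), and time alignment of a wrist/reference pair.

Missing samples are represented as ``NaN`` values on an explicit grid, not
as absent rows, so that imputation methods can operate on a regular index.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeviceLabel",
    "BeatFlag",
    "HeartRateSeries",
    "IBISeries",
    "HRVSummary",
    "SeriesValidationError",
    "read_hr_csv",
    "write_hrv_summary",
    "read_hrv_summary",
    "resample_uniform",
    "align_pair",
]

#: Default physiological plausibility band for heart rate, in bpm.  Values
#: outside it are sensor glitches, not physiology.
DEFAULT_HR_BAND = (20.0, 260.0)


class SeriesValidationError(ValueError):
    """Raised when series data violate a structural or plausibility invariant."""


class DeviceLabel(str, Enum):
    WRIST = "wrist"
    REFERENCE = "reference"


class BeatFlag(str, Enum):
    NORMAL = "normal"
    ARTIFACT = "artifact"
    INTERPOLATED = "interpolated"


@dataclass(frozen=True)
class HeartRateSeries:
    """Timestamped instantaneous heart rate with explicit missing slots.

    Parameters
    ----------
    subject_id : str
        Cohort label of the recording's subject.
    device_label : DeviceLabel
        Which device produced the series (``wrist`` or ``reference``).
    timestamps : ndarray of float
        Epoch seconds, strictly increasing.
    values : ndarray of float
        Heart rate in bpm per timestamp; ``NaN`` marks a missing sample.
    nominal_period_s : float
        Nominal sampling period of the device in seconds.
    hr_band : tuple of float
        Plausibility band; non-missing values outside it are rejected.
    """

    subject_id: str
    device_label: DeviceLabel
    timestamps: np.ndarray
    values: np.ndarray
    nominal_period_s: float = 1.0
    hr_band: tuple[float, float] = DEFAULT_HR_BAND

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "device_label", DeviceLabel(self.device_label))
        if ts.ndim != 1 or vals.ndim != 1 or ts.size != vals.size:
            raise SeriesValidationError("timestamps and values must be 1-D and equal length")
        if ts.size < 1:
            raise SeriesValidationError("series must contain at least one sample")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise SeriesValidationError("timestamps must be strictly increasing")
        lo, hi = self.hr_band
        observed = vals[~np.isnan(vals)]
        bad = observed[(observed <= lo) | (observed >= hi)]
        if bad.size:
            raise SeriesValidationError(
                f"heart-rate values outside plausibility band ({lo}, {hi}) bpm: "
                f"{np.unique(bad)[:10].tolist()}"
            )

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def with_values(self, values: np.ndarray) -> "HeartRateSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class IBISeries:
    """Sequence of inter-beat intervals in milliseconds with per-slot flags.

    The intervals here are pseudo-intervals derived from uniformly sampled
    heart rate (60000 / HR), not true beat detections; flags record whether
    a slot is an accepted beat, a detected artifact, or a spline-replaced
    value.
    """

    intervals_ms: np.ndarray
    flags: np.ndarray  # array of BeatFlag values (object dtype or str)
    origin: str = "derived_from_hr"
    subject_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        # keep flags as an object array: numpy would otherwise coerce the
        # str-enum members into truncated fixed-width strings
        items = [f if isinstance(f, BeatFlag) else BeatFlag(f) for f in self.flags]
        fl = np.empty(len(items), dtype=object)
        fl[:] = items
        object.__setattr__(self, "intervals_ms", iv)
        object.__setattr__(self, "flags", fl)
        if iv.ndim != 1:
            raise SeriesValidationError("intervals must be 1-D")
        if iv.size != fl.size:
            raise SeriesValidationError("flags and intervals must have equal length")
        if not np.all(np.isfinite(iv)) or np.any(iv <= 0):
            raise SeriesValidationError("all intervals must be strictly positive and finite")

    def __len__(self) -> int:
        return int(self.intervals_ms.size)

    def _where_flag(self, flag: BeatFlag) -> np.ndarray:
        # numpy equality against a str-enum scalar stringifies it; compare
        # member identity instead
        return np.fromiter(
            (i for i, f in enumerate(self.flags) if f is flag), dtype=int
        )

    @property
    def artifact_indices(self) -> np.ndarray:
        return self._where_flag(BeatFlag.ARTIFACT)

    @property
    def interpolated_indices(self) -> np.ndarray:
        return self._where_flag(BeatFlag.INTERPOLATED)


_HRV_FIELDS = ("min_hr", "max_hr", "mean_hr", "sdnn", "sdnn_index", "rmssd", "pnn50", "sdann")


@dataclass(frozen=True)
class HRVSummary:
    """Time-domain HRV indices for one recording.

    ``sdnn``, ``rmssd``, ``sdnn_index`` and ``sdann`` are in milliseconds,
    ``pnn50`` in percent, HR statistics in bpm.  ``sdann``/``sdnn_index``
    are ``NaN`` when fewer than two complete segments exist.
    """

    sdnn: float
    rmssd: float
    pnn50: float
    sdnn_index: float
    sdann: float
    min_hr: float
    max_hr: float
    mean_hr: float
    n_intervals: int = 0
    n_artifacts_corrected: int = 0
    segment_minutes: float = 5.0
    subject_id: str = ""

    def as_dict(self) -> dict[str, float]:
        """Metric fields in the canonical serialisation order."""
        return {name: getattr(self, name) for name in _HRV_FIELDS}


# ---------------------------------------------------------------------------
# CSV ingest


def read_hr_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    device_label: DeviceLabel | str = DeviceLabel.WRIST,
    nominal_period_s: float = 1.0,
    hr_band: tuple[float, float] = DEFAULT_HR_BAND,
    out_of_band: str = "error",
) -> HeartRateSeries:
    """Read a heart-rate CSV into a :class:`HeartRateSeries`.

    The file must carry a header with columns for subject id, timestamp
    (ISO-8601 or epoch seconds) and heart rate in bpm; ``schema`` remaps
    nonstandard column names onto ``{"subject_id", "timestamp", "hr_bpm"}``.
    Empty or NaN heart-rate cells become missing slots.  ``out_of_band``
    selects whether implausible values raise (``"error"``) or are coerced
    to missing (``"coerce"``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = {"subject_id": "subject_id", "timestamp": "timestamp", "hr_bpm": "hr_bpm"}
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype={cols["subject_id"]: str}, float_precision="round_trip")
    for canonical, name in cols.items():
        if name not in df.columns:
            raise SeriesValidationError(f"missing column {name!r} (for {canonical})")

    raw_ts = df[cols["timestamp"]]
    try:
        ts = pd.to_numeric(raw_ts)
        ts = ts.astype(float)
    except (ValueError, TypeError):
        try:
            ts = pd.to_datetime(raw_ts, format="ISO8601")
        except (ValueError, TypeError) as exc:
            bad_row = _first_bad_timestamp(raw_ts)
            raise SeriesValidationError(
                f"malformed timestamp at row {bad_row}: {raw_ts.iloc[bad_row]!r}"
            ) from exc
        ts = ts.astype("int64") / 1e9

    order = np.argsort(ts.to_numpy(), kind="stable")
    ts_sorted = ts.to_numpy()[order]
    hr = pd.to_numeric(df[cols["hr_bpm"]], errors="coerce").to_numpy(dtype=float)[order]

    dup = np.flatnonzero(np.diff(ts_sorted) == 0)
    if dup.size:
        raise SeriesValidationError(
            f"duplicate timestamps at t={np.unique(ts_sorted[dup])[:5].tolist()}"
        )

    lo, hi = hr_band
    with np.errstate(invalid="ignore"):
        bad = (~np.isnan(hr)) & ((hr <= lo) | (hr >= hi))
    if bad.any():
        if out_of_band == "coerce":
            hr = hr.copy()
            hr[bad] = np.nan
        else:
            raise SeriesValidationError(
                f"heart-rate values outside ({lo}, {hi}) bpm at rows "
                f"{np.flatnonzero(bad)[:10].tolist()}: {hr[bad][:10].tolist()}"
            )

    subjects = df[cols["subject_id"]].astype(str).unique()
    if len(subjects) != 1:
        raise SeriesValidationError(f"expected a single subject per file, got {list(subjects)}")

    return HeartRateSeries(
        subject_id=subjects[0],
        device_label=DeviceLabel(device_label),
        timestamps=ts_sorted,
        values=hr,
        nominal_period_s=nominal_period_s,
        hr_band=hr_band,
    )


def _first_bad_timestamp(raw: pd.Series) -> int:
    for i, v in enumerate(raw):
        try:
            pd.to_datetime(v, format="ISO8601")
        except (ValueError, TypeError):
            return i
    return 0


# ---------------------------------------------------------------------------
# HRV summary serialisation


def _nan_to_none(x: float) -> float | None:
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def write_hrv_summary(summary: HRVSummary, path: str | Path, format: str = "json") -> None:
    """Serialise an :class:`HRVSummary` as JSON or single-row CSV.

    Undefined metrics (NaN, e.g. SDANN with fewer than two segments) are
    written as JSON ``null`` / empty CSV cells.
    """
    path = Path(path)
    fields = summary.as_dict()
    if format == "json":
        payload = {k: _nan_to_none(v) for k, v in fields.items()}
        payload["subject_id"] = summary.subject_id
        payload["n_intervals"] = summary.n_intervals
        payload["n_artifacts_corrected"] = summary.n_artifacts_corrected
        payload["segment_minutes"] = summary.segment_minutes
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(fields))
            writer.writerow(["" if _nan_to_none(v) is None else repr(float(v)) for v in fields.values()])
    else:
        raise ValueError(f"unknown format {format!r}")


def read_hrv_summary(path: str | Path) -> HRVSummary:
    """Read back a JSON summary written by :func:`write_hrv_summary`."""
    payload = json.loads(Path(path).read_text())
    kwargs = {k: (math.nan if payload[k] is None else float(payload[k])) for k in _HRV_FIELDS}
    return HRVSummary(
        subject_id=payload.get("subject_id", ""),
        n_intervals=int(payload.get("n_intervals", 0)),
        n_artifacts_corrected=int(payload.get("n_artifacts_corrected", 0)),
        segment_minutes=float(payload.get("segment_minutes", 5.0)),
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Resampling and alignment


def resample_uniform(series: HeartRateSeries, period_s: float) -> HeartRateSeries:
    """Snap a series onto a uniform grid spanning [first, last] timestamp.

    Each observation maps to its nearest grid slot (ties to the earlier
    slot); slots with no observation within ``period_s / 2`` become
    missing.  When several observations contend for one slot the nearest
    (then earliest) wins and the rest are dropped with a warning.
    """
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    if len(series) == 0:
        raise SeriesValidationError("cannot resample an empty series")
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    n_slots = int(round((t1 - t0) / period_s)) + 1
    grid = t0 + period_s * np.arange(n_slots)

    values = np.full(n_slots, np.nan)
    best_dist = np.full(n_slots, np.inf)
    dropped = 0
    half = period_s / 2
    for t, v in zip(series.timestamps, series.values):
        if np.isnan(v):
            continue
        slot_f = (t - t0) / period_s
        slot = int(math.floor(slot_f + 0.5))
        # exact half-way ties snap to the earlier slot
        if abs(slot_f + 0.5 - round(slot_f + 0.5)) == 0 and slot_f % 1 == 0.5:
            slot = int(math.floor(slot_f))
        slot = min(max(slot, 0), n_slots - 1)
        dist = abs(t - grid[slot])
        if dist > half:
            dropped += 1
            continue
        if dist < best_dist[slot]:
            if not np.isnan(values[slot]):
                dropped += 1
            values[slot] = v
            best_dist[slot] = dist
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"resample_uniform dropped {dropped} contending sample(s)", stacklevel=2)
    return replace(series, timestamps=grid, values=values, nominal_period_s=period_s)


def align_pair(
    wrist: HeartRateSeries,
    reference: HeartRateSeries,
    tolerance_s: float = 0.5,
) -> pd.DataFrame:
    """Pair wrist and reference samples slot-by-slot.

    Both series must belong to the same subject and share a resampling
    period.  Returns a DataFrame with columns ``timestamp``, ``wrist_hr``,
    ``reference_hr``, ``subject_id`` containing one row per grid slot where
    both devices have a non-missing value within ``tolerance_s``; the
    paired fraction is attached as ``df.attrs["paired_fraction"]``.
    Disjoint time ranges produce an empty frame and a warning, not an
    exception.
    """
    if wrist.subject_id != reference.subject_id:
        raise SeriesValidationError(
            f"subject mismatch: {wrist.subject_id!r} vs {reference.subject_id!r}"
        )
    if not math.isclose(wrist.nominal_period_s, reference.nominal_period_s):
        raise SeriesValidationError("series must share a common resampling period")

    cols = {"timestamp": [], "wrist_hr": [], "reference_hr": []}
    ref_ts = reference.timestamps
    j = 0
    for t, v in zip(wrist.timestamps, wrist.values):
        if np.isnan(v):
            continue
        while j < len(ref_ts) and ref_ts[j] < t - tolerance_s:
            j += 1
        if j >= len(ref_ts) or abs(ref_ts[j] - t) > tolerance_s:
            continue
        rv = reference.values[j]
        if np.isnan(rv):
            continue
        cols["timestamp"].append(t)
        cols["wrist_hr"].append(v)
        cols["reference_hr"].append(rv)
    df = pd.DataFrame(cols)
    df["subject_id"] = wrist.subject_id
    n_slots = min(len(wrist), len(reference))
    df.attrs["paired_fraction"] = len(df) / n_slots if n_slots else 0.0
    if df.empty:
        warnings.warn(
            f"no overlapping non-missing slots for subject {wrist.subject_id!r}", stacklevel=2
        )
    return df
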