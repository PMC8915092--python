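"""Synthetic paired wrist/reference cohort with known ground-truth HRV.

Emulates a resting-protocol study: each subject sits for ~15 minutes
wearing a chest-strap reference and a wrist optical device.  The
reference heart rate is a baseline plus a respiratory-sinus-arrhythmia
sinusoid, an AR(1) fluctuation, and a slow linear trend (the trend gives
the series the non-stationary character typical of resting recordings, so
an ADF test on it fails to reject the unit root).  The wrist series is
the reference degraded phenomenologically: additive bias, Gaussian
measurement noise, random gaps, and ectopic-beat events (a shortened
interval followed by a compensatory lengthened one, expressed in the HR
domain).

Because the clean reference is generated first, every downstream stage
can be validated against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ibi import compute_hrv_summary, hr_to_ibi
from .imputation import inject_missingness
from .series import DeviceLabel, HeartRateSeries, HRVSummary, IBISeries

__all__ = [
    "SubjectProfile",
    "DegradationProfile",
    "DEGRADATION_PRESETS",
    "simulate_reference",
    "degrade_to_wrist",
    "make_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one subject's clean heart-rate process."""

    subject_id: str = "S01"
    baseline_hr: float = 70.0  # bpm, resting
    rsa_amplitude: float = 3.5  # bpm, respiratory sinus arrhythmia proxy
    rsa_period_s: float = 12.0  # s, ~5 breaths/min resting respiration
    ar_coefficient: float = 0.995  # AR(1) pole, < 1; near-unit-root drift
    process_noise_sd: float = 0.25  # bpm, AR innovation SD
    beat_noise_sd: float = 1.2  # bpm, white beat-to-beat (fast vagal) component
    trend_bpm: float = 3.0  # slow linear drift over the whole recording
    duration_s: float = 900.0  # 15-minute resting protocol
    period_s: float = 1.0  # reference device sampling period
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if not 20 < self.baseline_hr < 260:
            raise ValueError("baseline_hr outside the plausibility band")
        if self.duration_s <= 0 or self.period_s <= 0:
            raise ValueError("duration and period must be positive")


@dataclass(frozen=True)
class DegradationProfile:
    """Phenomenological wrist-sensor degradation applied to the reference."""

    additive_bias: float = 0.0  # bpm
    measurement_noise_sd: float = 0.0  # bpm
    missing_fraction: float = 0.0  # in [0, 1)
    mean_gap_len: float = 3.0  # slots
    ectopic_rate: float = 0.0  # per-interval probability
    ectopic_shortening: float = 0.4  # fraction of the interval removed
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0 <= self.ectopic_rate <= 1:
            raise ValueError("ectopic_rate must be a probability")
        if not 0 < self.ectopic_shortening < 1:
            raise ValueError("ectopic_shortening must be in (0, 1)")

    @property
    def is_null(self) -> bool:
        return (
            self.additive_bias == 0
            and self.measurement_noise_sd == 0
            and self.missing_fraction == 0
            and self.ectopic_rate == 0
        )


DEGRADATION_PRESETS = {
    "none": DegradationProfile(),
    "mild": DegradationProfile(
        additive_bias=1.0, measurement_noise_sd=1.0, missing_fraction=0.05,
        ectopic_rate=0.005,
    ),
    "heavy": DegradationProfile(
        additive_bias=3.0, measurement_noise_sd=2.5, missing_fraction=0.15,
        ectopic_rate=0.02,
    ),
}


def simulate_reference(profile: SubjectProfile) -> dict:
    """Generate one subject's clean recording and its ground truth.

    Returns ``{"reference": HeartRateSeries, "ground_truth_ibi": IBISeries,
    "ground_truth_hrv": HRVSummary}``.  HR(t) = baseline +
    rsa_amplitude * sin(2*pi*t / rsa_period) + AR(1) noise + linear trend;
    fully reproducible under the profile's seed.
    """
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration_s / profile.period_s))
    t = profile.period_s * np.arange(n)
    rsa = profile.rsa_amplitude * np.sin(2 * np.pi * t / profile.rsa_period_s)
    trend = profile.trend_bpm * (t / t[-1]) if n > 1 else np.zeros(n)
    ar = np.zeros(n)
    if profile.process_noise_sd > 0:
        # stationary start, then AR(1) recursion
        ar[0] = rng.normal(0, profile.process_noise_sd /
                           np.sqrt(1 - profile.ar_coefficient**2))
        innov = rng.normal(0, profile.process_noise_sd, size=n)
        for i in range(1, n):
            ar[i] = profile.ar_coefficient * ar[i - 1] + innov[i]
    beat = (rng.normal(0, profile.beat_noise_sd, size=n)
            if profile.beat_noise_sd > 0 else np.zeros(n))
    hr = profile.baseline_hr + rsa + ar + trend + beat
    hr = np.clip(hr, 25.0, 250.0)  # stay inside the plausibility band

    reference = HeartRateSeries(
        subject_id=profile.subject_id,
        device_label=DeviceLabel.REFERENCE,
        timestamps=t,
        values=hr,
        nominal_period_s=profile.period_s,
    )
    ibi = hr_to_ibi(reference)
    hrv = compute_hrv_summary(ibi)
    return {"reference": reference, "ground_truth_ibi": ibi, "ground_truth_hrv": hrv}


def degrade_to_wrist(
    reference: HeartRateSeries, degradation: DegradationProfile
) -> HeartRateSeries:
    """Turn a clean reference recording into a wrist-like one.

    Applies, in order: additive bias, Gaussian measurement noise, ectopic
    events (interval shortened by ``ectopic_shortening`` then
    compensatorily lengthened, expressed in the HR domain), and random
    gaps.  Seed-reproducible; a null profile returns the reference values
    unchanged.
    """
    rng = np.random.default_rng(degradation.seed)
    values = reference.values.copy()
    values = values + degradation.additive_bias
    if degradation.measurement_noise_sd > 0:
        values = values + rng.normal(0, degradation.measurement_noise_sd, size=values.size)
    if degradation.ectopic_rate > 0:
        s = degradation.ectopic_shortening
        hits = np.flatnonzero(rng.random(values.size - 1) < degradation.ectopic_rate)
        for i in hits:
            values[i] = values[i] / (1.0 - s)  # premature beat: short interval
            values[i + 1] = values[i + 1] / (1.0 + s)  # compensatory pause
    values = np.clip(values, 25.0, 250.0)
    wrist = HeartRateSeries(
        subject_id=reference.subject_id,
        device_label=DeviceLabel.WRIST,
        timestamps=reference.timestamps.copy(),
        values=values,
        nominal_period_s=reference.nominal_period_s,
    )
    if degradation.missing_fraction > 0:
        wrist, _ = inject_missingness(
            wrist,
            degradation.missing_fraction,
            mean_gap_len=degradation.mean_gap_len,
            seed=int(rng.integers(2**31 - 1)),
        )
    return wrist


def make_cohort(
    n_subjects: int = 10,
    degradation: DegradationProfile = DEGRADATION_PRESETS["none"],
    master_seed: int = 0,
    *,
    baseline_range: tuple[float, float] = (60.0, 90.0),
    rsa_amplitude_range: tuple[float, float] = (2.0, 5.0),
    rsa_period_range: tuple[float, float] = (10.0, 15.0),
    process_noise_range: tuple[float, float] = (0.15, 0.35),
    beat_noise_range: tuple[float, float] = (0.8, 1.6),
    duration_s: float = 900.0,
    period_s: float = 1.0,
) -> list[dict]:
    """Simulate a paired cohort of ``n_subjects`` resting recordings.

    Per-subject profiles are drawn within the stated ranges (baselines
    reflect older-adult resting HR); all per-subject seeds derive
    deterministically from ``master_seed``.  Each bundle entry carries the
    subject's profile, reference and wrist series, and ground-truth IBI
    and HRV.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    for lo, hi in (baseline_range, rsa_amplitude_range, rsa_period_range,
                   process_noise_range):
        if not lo <= hi:
            raise ValueError("range bounds must satisfy lo <= hi")
    rng = np.random.default_rng(master_seed)
    bundle = []
    for i in range(n_subjects):
        profile = SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            baseline_hr=float(rng.uniform(*baseline_range)),
            rsa_amplitude=float(rng.uniform(*rsa_amplitude_range)),
            rsa_period_s=float(rng.uniform(*rsa_period_range)),
            process_noise_sd=float(rng.uniform(*process_noise_range)),
            beat_noise_sd=float(rng.uniform(*beat_noise_range)),
            duration_s=duration_s,
            period_s=period_s,
            seed=int(rng.integers(2**31 - 1)),
        )
        sim = simulate_reference(profile)
        deg = dataclasses.replace(degradation, seed=int(rng.integers(2**31 - 1)))
        wrist = degrade_to_wrist(sim["reference"], deg)
        bundle.append({
            "profile": profile,
            "degradation": deg,
            "reference": sim["reference"],
            "wrist": wrist,
            "ground_truth_ibi": sim["ground_truth_ibi"],
            "ground_truth_hrv": sim["ground_truth_hrv"],
        })
    return bundle


def write_cohort(bundle: list[dict], out_dir: str | Path) -> None:
    """Write per-subject CSVs plus a ground-truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = {}
    for entry in bundle:
        sid = entry["profile"].subject_id
        for role in ("reference", "wrist"):
            series = entry[role]
            pd.DataFrame({
                "subject_id": sid,
                "timestamp": series.timestamps,
                "hr_bpm": series.values,
            }).to_csv(out / f"{sid}_{role}.csv", index=False)
        truths[sid] = {k: v for k, v in entry["ground_truth_hrv"].as_dict().items()}
    (out / "ground_truth.json").write_text(json.dumps(truths, indent=2, default=float) + "\n")
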