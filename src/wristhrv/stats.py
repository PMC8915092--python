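"""Paired agreement statistics between two HRV pipelines.

Given per-subject HRV summaries from a wrist pipeline and from a reference
(chest-strap) pipeline, the paired Student t-test asks whether their means
differ; RMSE and the squared Pearson correlation quantify the residual
error and agreement strength.  Critical values are one-tailed t-table
entries (the convention of HRV validation reports), while reported
p-values are two-tailed; the decision is driven by the p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import series as _series

__all__ = [
    "rmse",
    "r_squared",
    "paired_t_test",
    "t_critical",
    "PairedComparison",
    "compare_platforms",
]


def rmse(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean square error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two vectors (in [0, 1])."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("r_squared needs two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r_squared is degenerate when either vector has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Paired Student t-test on per-subject values.

    t = mean(d) / (sd(d) / sqrt(n)) with sample sd of the differences
    d = a - b; df = n - 1; p is two-tailed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors with n >= 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("paired t-test is degenerate: differences have zero variance")
    n = d.size
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return {"t": t, "p_two_tailed": p, "df": df}


def t_critical(confidence: float, df: int) -> float:
    """One-tailed Student-t table value: upper quantile at ``confidence``."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(sps.t.ppf(confidence, df))


def _five_number(v: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(np.min(v)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(np.max(v)),
    }


@dataclass(frozen=True)
class PairedComparison:
    """Per-metric platform comparison: paired t-test plus boxplot summaries."""

    metric_name: str
    pipeline_values: np.ndarray
    reference_values: np.ndarray
    t_value: float
    p_value: float
    df: int
    critical_t_95: float
    critical_t_99: float
    alpha: float
    decision: str  # "no_difference" | "difference"
    boxplot_pipeline: dict[str, float]
    boxplot_reference: dict[str, float]

    def as_row(self) -> dict:
        return {
            "metric": self.metric_name,
            "t_value": self.t_value,
            "p_value": self.p_value,
            "df": self.df,
            "critical_t_95": self.critical_t_95,
            "critical_t_99": self.critical_t_99,
            "decision": self.decision,
            "boxplot_pipeline": self.boxplot_pipeline,
            "boxplot_reference": self.boxplot_reference,
        }


def compare_platforms(
    pipeline_summaries: Sequence["_series.HRVSummary"],
    reference_summaries: Sequence["_series.HRVSummary"],
    metrics: Sequence[str] = ("sdnn", "rmssd", "pnn50"),
    alpha: float = 0.05,
) -> dict[str, PairedComparison]:
    """Paired per-metric comparison of two pipelines over the same subjects.

    Subjects must match pairwise (same ids, same order).  Returns one
    :class:`PairedComparison` per metric with the two-tailed t-test, both
    one-tailed critical values, the alpha-level decision, and five-number
    boxplot summaries per group.
    """
    if len(pipeline_summaries) != len(reference_summaries) or len(pipeline_summaries) < 2:
        raise ValueError("need matched summary lists with n >= 2 subjects")
    for p_s, r_s in zip(pipeline_summaries, reference_summaries):
        if p_s.subject_id and r_s.subject_id and p_s.subject_id != r_s.subject_id:
            raise ValueError(f"subject mismatch: {p_s.subject_id!r} vs {r_s.subject_id!r}")
    out: dict[str, PairedComparison] = {}
    df = len(pipeline_summaries) - 1
    for metric in metrics:
        pipe = np.array([getattr(s, metric) for s in pipeline_summaries], dtype=float)
        ref = np.array([getattr(s, metric) for s in reference_summaries], dtype=float)
        if np.ptp(pipe - ref) == 0 and np.all(pipe == ref):
            # identical platforms: agreement is exact, the t statistic degenerate
            test = {"t": 0.0, "p_two_tailed": 1.0, "df": df}
        else:
            test = paired_t_test(pipe, ref)
        out[metric] = PairedComparison(
            metric_name=metric,
            pipeline_values=pipe,
            reference_values=ref,
            t_value=test["t"],
            p_value=test["p_two_tailed"],
            df=test["df"],
            critical_t_95=t_critical(0.95, df),
            critical_t_99=t_critical(0.99, df),
            alpha=alpha,
            decision="difference" if test["p_two_tailed"] < alpha else "no_difference",
            boxplot_pipeline=_five_number(pipe),
            boxplot_reference=_five_number(ref),
        )
    return out


def write_comparison_report(
    comparisons: dict[str, PairedComparison], path: str | Path
) -> None:
    """Write the per-metric comparison table as JSON."""
    payload = {m: c.as_row() for m, c in comparisons.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
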