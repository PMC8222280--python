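"""HU time traces, per-contour baseline/peak measurements, and bin statistics.

The central measurement is the percent change in mean HU between the
pre-RT and post-RT scan of a contour:

    dHU% = (HU_post − HU_pre) / HU_pre × 100

Aerated lung has a negative baseline (≈ −850 HU), so the literal quotient
sign-inverts a density *increase*; the default "magnitude" convention
divides by |HU_pre| instead so that increases in density are positive.
Baselines come from the first (pre-contrast) frame of a dynamic series, or
from the exhale-phase volume when no dynamic series exists; the in-vessel
peak is the maximum of the mean-HU trace.  Per-bin cohort statistics use a
paired two-tailed t test with Kolmogorov–Smirnov normality checking and a
Bonferroni-adjusted significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gridio import BinaryMask, DynamicSeries, assert_same_geometry

__all__ = [
    "HUTrace",
    "BinMeasurement",
    "BinStats",
    "extract_trace",
    "baseline_hu",
    "peak_hu",
    "delta_hu_percent",
    "bonferroni_threshold",
    "bin_statistics",
    "average_replicates",
]


@dataclass
class HUTrace:
    """Mean HU over a contour per frame of a dynamic series."""

    times: np.ndarray
    mean_hu: np.ndarray
    label: str = ""
    n_voxels: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_hu = np.asarray(self.mean_hu, dtype=float)
        if self.times.shape != self.mean_hu.shape:
            raise ValueError("times and mean_hu must have equal length")
        if self.n_voxels <= 0:
            raise ValueError("trace requires a non-empty contour")


@dataclass
class BinMeasurement:
    """One subject × timepoint × bin × compartment measurement."""

    subject: str
    timepoint: str
    bin_label: str
    compartment: str  # "parenchyma" | "vessel"
    baseline_hu: float
    peak_hu: float = float("nan")
    delta_hu_pct: float = float("nan")


@dataclass
class BinStats:
    """Cohort statistics for one bin at one timepoint."""

    bin_label: str
    timepoint: str
    n: int
    mean_delta_pct: float
    sd_delta_pct: float
    t_pvalue: float
    ks_pvalue: float
    significant: bool


def extract_trace(series: DynamicSeries, mask: BinaryMask, label: str = "") -> HUTrace:
    """Per-frame arithmetic mean of the in-mask voxels."""
    assert_same_geometry(series.geometry, mask)
    n = mask.n_voxels
    if n == 0:
        raise ValueError("cannot extract a trace from an empty mask")
    sel = mask.values
    means = np.array([float(f.values[sel].mean()) for f in series.frames])
    return HUTrace(series.times.copy(), means, label=label, n_voxels=n)


def baseline_hu(trace: HUTrace) -> float:
    """Baseline = the first (pre-contrast) frame's mean HU."""
    return float(trace.mean_hu[0])


def peak_hu(trace: HUTrace) -> float:
    """Peak enhancement = maximum of the mean-HU trace (vessel contours)."""
    return float(trace.mean_hu.max())


def delta_hu_percent(hu_pre: float, hu_post: float, convention: str = "magnitude") -> float:
    """Percent HU change between timepoints.

    ``magnitude`` (default): (post − pre) / |pre| × 100, so a density
    increase in negative-HU lung reads positive.  ``literal``: the raw
    quotient (post − pre) / pre × 100.
    """
    if hu_pre == 0:
        raise ZeroDivisionError("baseline HU is zero; percent change undefined")
    denom = abs(hu_pre) if convention == "magnitude" else hu_pre
    if convention not in ("magnitude", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    return (hu_post - hu_pre) / denom * 100.0


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Adjusted per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def bin_statistics(
    cohort: pd.DataFrame,
    timepoint: str,
    compartment: str = "parenchyma",
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    value_pre: str = "baseline_pre",
    value_post: str = "baseline_post",
) -> list[BinStats]:
    """Paired pre/post tests per dose bin across subjects.

    ``cohort`` is a tidy table with one row per subject × bin holding the
    paired pre and post values (columns ``value_pre``/``value_post``) plus
    ``delta_hu_pct``, ``bin_label``, ``timepoint``, ``compartment``.  Each
    bin gets a paired two-tailed t test on the pre/post values, a KS
    normality test on the standardised paired differences, and a
    significance flag at the Bonferroni-adjusted threshold (default family
    size = number of bins tested).
    """
    sub = cohort[(cohort["timepoint"] == timepoint)
                 & (cohort["compartment"] == compartment)]
    labels = sorted(sub["bin_label"].unique(), key=_bin_sort_key)
    m = n_comparisons if n_comparisons is not None else max(len(labels), 1)
    thr = bonferroni_threshold(alpha, m)

    out: list[BinStats] = []
    for label in labels:
        rows = sub[sub["bin_label"] == label]
        if len(rows) < 2:
            warnings.warn(f"bin {label}: fewer than 2 subjects, skipped", stacklevel=2)
            continue
        pre = rows[value_pre].to_numpy(dtype=float)
        post = rows[value_post].to_numpy(dtype=float)
        diffs = post - pre
        if np.allclose(diffs, diffs[0]):
            # zero-variance differences: t test undefined; no evidence of
            # subject-level variability -> not significant unless shift != 0
            t_p = 1.0 if np.allclose(diffs, 0) else 0.0
            ks_p = float("nan")
        else:
            t_p = float(stats.ttest_rel(pre, post).pvalue)
            z = (diffs - diffs.mean()) / diffs.std(ddof=1)
            ks_p = float(stats.kstest(z, "norm").pvalue)
        deltas = rows["delta_hu_pct"].to_numpy(dtype=float)
        out.append(BinStats(
            bin_label=label, timepoint=timepoint, n=len(rows),
            mean_delta_pct=float(deltas.mean()),
            sd_delta_pct=float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
            t_pvalue=t_p, ks_pvalue=ks_p,
            significant=bool(t_p < thr),
        ))
    return out


def _bin_sort_key(label: str) -> float:
    try:
        return float(str(label).replace("Gy", ""))
    except ValueError:
        return float("inf")


def average_replicates(measurements: list[BinMeasurement]) -> BinMeasurement:
    """Average repeat scans of one subject/timepoint/bin/compartment.

    Repeat acquisitions (e.g. two 4DCTs five minutes apart) are averaged
    at the measurement level: arithmetic mean of the baseline (and peak,
    where present).
    """
    if not measurements:
        raise ValueError("no measurements to average")
    first = measurements[0]
    key = (first.subject, first.timepoint, first.bin_label, first.compartment)
    for m in measurements[1:]:
        if (m.subject, m.timepoint, m.bin_label, m.compartment) != key:
            raise ValueError("replicates must share subject/timepoint/bin/compartment")
    baseline = float(np.mean([m.baseline_hu for m in measurements]))
    peaks = [m.peak_hu for m in measurements]
    peak = float(np.mean(peaks)) if not np.any(np.isnan(peaks)) else float("nan")
    return replace(first, baseline_hu=baseline, peak_hu=peak)
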