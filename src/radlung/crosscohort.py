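"""Dose-response fits and swine-to-human cross-cohort correlation.

The swine and human cohorts were treated under different fractionation
schemes, so per-bin percent HU changes are compared on the EQD2 axis.
Because the cohorts' bins land at different EQD2 values, an "adjusted"
swine dataset is built by evaluating the swine linear dose-response fit at
the human bin EQD2 values; human per-bin changes are then regressed on
these adjusted swine changes (human on y).  A slope near 1 means the swine
response at its measured timepoint models the human response at the
compared timepoint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFit",
    "AdjustedDataset",
    "linear_fit",
    "adjusted_swine",
    "cross_cohort_correlation",
    "vessel_coupling_fit",
    "emit_report",
]


@dataclass
class LinearFit:
    """Ordinary least squares line plus the Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class AdjustedDataset:
    """Swine dose-response evaluated at the human bin EQD2 values."""

    eqd2: np.ndarray
    swine_pred_pct: np.ndarray
    human_pct: np.ndarray
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.eqd2 = np.asarray(self.eqd2, dtype=float)
        self.swine_pred_pct = np.asarray(self.swine_pred_pct, dtype=float)
        self.human_pct = np.asarray(self.human_pct, dtype=float)
        if not (len(self.eqd2) == len(self.swine_pred_pct) == len(self.human_pct)):
            raise ValueError("adjusted dataset arrays must have equal length")
        if len(self.eqd2) > 1 and not np.all(np.diff(self.eqd2) > 0):
            raise ValueError("eqd2 values must be strictly increasing")


def linear_fit(x, y) -> LinearFit:
    """OLS fit of y on x with Pearson r and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("linear_fit needs two same-length vectors of n >= 2")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2, pearson_r=float(res.rvalue),
        p_value=float(res.pvalue), n=int(x.size),
    )


def adjusted_swine(fit: LinearFit, human_eqd2, human_pct=None,
                   timepoint: str = "") -> AdjustedDataset:
    """Evaluate the swine dose-response line at the human bin EQD2 values."""
    human_eqd2 = np.asarray(human_eqd2, dtype=float)
    if human_eqd2.size == 0:
        raise ValueError("no human EQD2 values supplied")
    pred = fit.predict(human_eqd2)
    if human_pct is None:
        human_pct = np.full_like(pred, np.nan)
    return AdjustedDataset(human_eqd2, pred, np.asarray(human_pct, dtype=float),
                           timepoint=timepoint)


def cross_cohort_correlation(adjusted: AdjustedDataset) -> LinearFit:
    """Regress human per-bin dHU% (y) on adjusted swine dHU% (x).

    The slope reads "% change in human per % change in swine".
    """
    if len(adjusted.eqd2) < 3:
        raise ValueError("cross-cohort correlation needs at least 3 paired bins")
    if np.any(np.isnan(adjusted.human_pct)):
        raise ValueError("adjusted dataset has no paired human measurements")
    return linear_fit(adjusted.swine_pred_pct, adjusted.human_pct)


def vessel_coupling_fit(in_vessel_pct, out_vessel_pct) -> tuple[LinearFit, float]:
    """Fit of in-vessel peak change (y) on out-of-vessel change (x), per bin.

    Inputs are cohort-averaged per-bin values.  Also returns the Pearson
    correlation between the out-of-vessel *increase* and the magnitude of
    the in-vessel *reduction* (positive when leakage-like coupling holds).
    """
    x = np.asarray(out_vessel_pct, dtype=float)
    y = np.asarray(in_vessel_pct, dtype=float)
    if x.size < 3:
        raise ValueError("vessel coupling fit needs at least 3 bins")
    fit = linear_fit(x, y)
    reduction = -y  # magnitude of the in-vessel drop
    r = float(stats.pearsonr(x, reduction).statistic)
    return fit, r


def emit_report(
    measurements: pd.DataFrame,
    fits: dict[str, LinearFit | dict],
    csv_path: str | Path,
    json_path: str | Path,
) -> None:
    """Write the tidy per-measurement CSV and the JSON summary of fits.

    Output ordering is deterministic: rows sorted on all key columns,
    JSON keys sorted.
    """
    csv_path, json_path = Path(csv_path), Path(json_path)
    key_cols = [c for c in ("subject", "timepoint", "bin_label", "compartment",
                            "laterality") if c in measurements.columns]
    df = measurements.sort_values(key_cols).reset_index(drop=True) if key_cols \
        else measurements
    df.to_csv(csv_path, index=False)
    payload = {
        name: (asdict(f) if isinstance(f, LinearFit) else f)
        for name, f in fits.items()
    }
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
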