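"""Isodose bin contours, contralateral controls, and EQD2 conversion.

Analysis of radiation response is discretised into 10 Gy-wide dose bins
built from the planned dose grid: the bin labelled "20 Gy" is the set of
lung voxels receiving [15, 25) Gy.  Bins under 30 cc are excluded from
statistics (small contours make the mean-HU measurement noisy).  Each bin
is mirrored across the mid-sagittal plane onto the unirradiated
contralateral lung (< 5 Gy) as a within-subject control.  Physical bin
doses are harmonised across fractionation schemes as the equivalent dose
in 2 Gy fractions, EQD2 = D (d + alpha/beta) / (2 + alpha/beta), with
alpha/beta = 3 Gy for lung.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gridio import BinaryMask, GeometryMismatchError, ImageGrid, assert_same_geometry

__all__ = [
    "DoseBin",
    "FractionationScheme",
    "ContaminatedControlError",
    "eqd2",
    "bin_eqd2",
    "make_dose_bins",
    "mirror_contours",
    "DEFAULT_EDGES",
]

#: default bin edges in Gy: [5,15), [15,25), ... [55,65]
DEFAULT_EDGES = (5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0)

#: contour volume below which a bin is excluded from statistics
MIN_BIN_CC = 30.0

#: maximum dose tolerated inside a contralateral control contour
CONTROL_MAX_GY = 5.0


class ContaminatedControlError(ValueError):
    """A mirrored control contour receives >= 5 Gy."""


@dataclass
class FractionationScheme:
    """Prescription: total dose, fraction count, and lung alpha/beta ratio."""

    rx_total: float
    n_fractions: int
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.rx_total <= 0 or self.n_fractions <= 0 or self.alpha_beta <= 0:
            raise ValueError("fractionation parameters must be positive")

    @property
    def dose_per_fraction(self) -> float:
        return self.rx_total / self.n_fractions


@dataclass
class DoseBin:
    """One isodose shell: half-open physical-dose interval, mask, EQD2, laterality."""

    lo: float
    hi: float
    mask: BinaryMask
    eqd2: float = float("nan")
    laterality: str = "irradiated"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"bin interval must satisfy lo < hi, got [{self.lo}, {self.hi})")
        if self.laterality not in ("irradiated", "control"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def midpoint(self) -> float:
        """Representative physical dose: the bin midpoint (e.g. 20 for [15,25))."""
        return 0.5 * (self.lo + self.hi)

    @property
    def label(self) -> str:
        return f"{self.midpoint:g}Gy"

    @property
    def volume_cc(self) -> float:
        return self.mask.volume_cc


def eqd2(total_dose: float, dose_per_fraction: float, alpha_beta: float = 3.0) -> float:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    ``EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)`` where D is the total
    dose and d the dose per fraction.
    """
    if total_dose <= 0 or dose_per_fraction <= 0 or alpha_beta <= 0:
        raise ValueError("eqd2 inputs must be positive")
    return total_dose * (dose_per_fraction + alpha_beta) / (2.0 + alpha_beta)


def bin_eqd2(
    dose_bin: DoseBin | float,
    scheme: FractionationScheme,
    convention: str = "prescription_fraction",
) -> float:
    """EQD2 of a dose bin's representative dose D.

    ``prescription_fraction`` (default): d is the prescription dose per
    fraction regardless of bin — the only convention consistent with the
    printed human mapping 5–15 Gy -> EQD2 13–39 Gy at 50 Gy/5 fx.
    ``bin_fraction``: d = D / n_fractions (the bin dose itself delivered
    over the prescription's fraction count).
    """
    d_total = dose_bin.midpoint if isinstance(dose_bin, DoseBin) else float(dose_bin)
    if convention == "prescription_fraction":
        d_frac = scheme.dose_per_fraction
    elif convention == "bin_fraction":
        d_frac = d_total / scheme.n_fractions
    else:
        raise ValueError(f"unknown EQD2 convention {convention!r}")
    return eqd2(d_total, d_frac, scheme.alpha_beta)


def make_dose_bins(
    dose: ImageGrid,
    lung: BinaryMask,
    edges=DEFAULT_EDGES,
    min_cc: float = MIN_BIN_CC,
    scheme: FractionationScheme | None = None,
    convention: str = "prescription_fraction",
) -> list[DoseBin]:
    """Partition the in-lung >= edges[0] region into isodose bins.

    Bin *b* holds lung voxels with ``lo <= dose < hi``; the final bin is
    closed at the top so a voxel at exactly the prescription maximum is
    kept.  Bins under ``min_cc`` are excluded (with a warning) — the bin
    width was chosen so that retained contours are large enough for a
    stable mean-HU measurement.  Returned bins are pairwise disjoint.
    """
    assert_same_geometry(dose, lung)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be an ascending 1D sequence of at least two doses")
    bins: list[DoseBin] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = lung.values & (dose.values >= lo)
        if hi == edges[-1]:
            sel &= dose.values <= hi  # closed top bin
        else:
            sel &= dose.values < hi
        mask = BinaryMask.like(lung, sel)
        if mask.n_voxels == 0:
            continue
        b = DoseBin(float(lo), float(hi), mask)
        if scheme is not None:
            b.eqd2 = bin_eqd2(b, scheme, convention)
        if b.volume_cc < min_cc:
            warnings.warn(
                f"dose bin {b.label} has {b.volume_cc:.1f} cc < {min_cc:g} cc; "
                "excluded from statistics", stacklevel=2)
            continue
        bins.append(b)
    return bins


def _mirror_index(mask_values: np.ndarray, plane_x: float) -> np.ndarray:
    """Reflect a boolean volume across the plane ``i = plane_x`` (index units)."""
    out = np.zeros_like(mask_values)
    idx = np.argwhere(mask_values)
    if idx.size == 0:
        return out
    mi = np.round(2.0 * plane_x - idx[:, 0]).astype(int)
    keep = (mi >= 0) & (mi < mask_values.shape[0])
    out[mi[keep], idx[keep, 1], idx[keep, 2]] = True
    return out


def mirror_contours(
    bins: list[DoseBin],
    left_lung: BinaryMask,
    right_lung: BinaryMask,
    dose: ImageGrid,
) -> list[DoseBin]:
    """Copy dose-bin contours onto the contralateral lung as controls.

    Each bin mask is reflected across the mid-sagittal plane (the plane
    halfway between the two lung centroids along the left-right axis) and
    intersected with the contralateral lung mask.  Every control must
    receive < 5 Gy; contamination raises, an empty intersection drops the
    bin with a warning.
    """
    assert_same_geometry(left_lung, right_lung)
    assert_same_geometry(left_lung, dose)
    cl = np.argwhere(left_lung.values)[:, 0].mean()
    cr = np.argwhere(right_lung.values)[:, 0].mean()
    plane_x = 0.5 * (cl + cr)

    controls: list[DoseBin] = []
    for b in bins:
        # which lung hosts this bin -> mirror into the other one
        in_left = np.count_nonzero(b.mask.values & left_lung.values)
        in_right = np.count_nonzero(b.mask.values & right_lung.values)
        target = left_lung if in_right >= in_left else right_lung
        reflected = _mirror_index(b.mask.values, plane_x) & target.values
        if not reflected.any():
            warnings.warn(f"control for bin {b.label} is empty after mirroring; dropped",
                          stacklevel=2)
            continue
        dmax = float(dose.values[reflected].max())
        if dmax >= CONTROL_MAX_GY:
            raise ContaminatedControlError(
                f"control contour for bin {b.label} receives {dmax:.1f} Gy "
                f"(>= {CONTROL_MAX_GY:g} Gy)")
        controls.append(DoseBin(b.lo, b.hi, BinaryMask.like(b.mask, reflected),
                                eqd2=b.eqd2, laterality="control"))
    return controls
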