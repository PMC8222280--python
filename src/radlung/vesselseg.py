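"""Contrast-based vessel segmentation from a dynamic CT series.

The contrast-carrying vasculature is segmented in three steps: (1) a
maximum-intensity projection (MIP) over all frames captures the peak
enhancement of every voxel regardless of when the bolus passed; (2) the
pre-contrast first frame's in-lung HU histogram is bimodal — aerated
parenchyma near −850 HU and soft tissue/blood near +40 HU — and the second
mode's mean and width set a threshold of mean + 2 sigma, with sigma taken
from the full width at half maximum via FWHM = 2.35 sigma; (3) any in-lung
voxel whose MIP value exceeds the threshold is vessel.  The complementary
parenchyma contour is the lung with the vessels subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gridio import BinaryMask, DynamicSeries, ImageGrid, assert_same_geometry

__all__ = [
    "ModeFit",
    "NotBimodalError",
    "FWHM_PER_SIGMA",
    "build_mip",
    "fit_bimodal_histogram",
    "vessel_threshold",
    "segment_vessels",
    "parenchyma_mask",
]

#: Gaussian FWHM-to-sigma conversion used throughout (2.35, not 2.3548)
FWHM_PER_SIGMA = 2.35

# histogram construction defaults; the source method does not pin these,
# they are explicit configuration
HIST_RANGE_HU = (-1100.0, 300.0)
HIST_BIN_HU = 5.0
SMOOTH_BINS = 3
MIN_MODE_SEPARATION_HU = 100.0
#: a candidate mode must reach this fraction of the tallest peak, so a few
#: stray outlier voxels cannot masquerade as a second mode
MIN_MODE_PEAK_FRACTION = 0.01


class NotBimodalError(ValueError):
    """The in-lung HU histogram does not show two separated modes."""


@dataclass
class ModeFit:
    """Bimodal-histogram fit of the pre-contrast in-lung HU distribution."""

    mode1_mean: float
    mode2_mean: float
    mode2_fwhm: float
    hist_centers: np.ndarray
    hist_counts: np.ndarray

    def __post_init__(self) -> None:
        if not self.mode1_mean < self.mode2_mean:
            raise ValueError("mode1_mean must be below mode2_mean")
        if self.mode2_fwhm <= 0:
            raise ValueError("mode2_fwhm must be positive")

    @property
    def mode2_sigma(self) -> float:
        return self.mode2_fwhm / FWHM_PER_SIGMA


def build_mip(series: DynamicSeries) -> ImageGrid:
    """Voxel-wise maximum across all frames (the temporal MIP)."""
    stack = series.stack()
    return series.geometry.copy(values=stack.max(axis=0))


def _local_maxima(counts: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1D array."""
    idx = []
    n = len(counts)
    for i in range(n):
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[i + 1] if i < n - 1 else -np.inf
        if counts[i] > left and counts[i] >= right and counts[i] > 0:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def fit_bimodal_histogram(
    volume: ImageGrid,
    lung: BinaryMask,
    bin_hu: float = HIST_BIN_HU,
    hist_range: tuple[float, float] = HIST_RANGE_HU,
    min_separation_hu: float = MIN_MODE_SEPARATION_HU,
) -> ModeFit:
    """Locate the two modes of the in-lung HU histogram of a pre-contrast frame.

    The histogram uses fixed-width bins (default 5 HU over [−1100, 300]),
    smoothed by a 3-bin moving average.  The two largest local maxima at
    least ``min_separation_hu`` apart are the modes; the upper mode's FWHM
    is measured by linear interpolation of the half-maximum crossings and
    converted to sigma with FWHM = 2.35 sigma.
    """
    assert_same_geometry(volume, lung)
    if lung.n_voxels == 0:
        raise ValueError("lung mask is empty")
    hu = volume.values[lung.values]
    edges = np.arange(hist_range[0], hist_range[1] + bin_hu, bin_hu)
    counts, edges = np.histogram(hu, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts.astype(float), np.ones(SMOOTH_BINS) / SMOOTH_BINS,
                         mode="same")

    maxima = _local_maxima(smooth)
    # pick the two largest maxima subject to the separation requirement;
    # a mode must also carry a non-trivial share of the tallest peak
    floor = MIN_MODE_PEAK_FRACTION * smooth.max()
    maxima = maxima[smooth[maxima] >= floor]
    order = maxima[np.argsort(smooth[maxima])[::-1]]
    chosen: list[int] = []
    for i in order:
        if all(abs(centers[i] - centers[j]) >= min_separation_hu for j in chosen):
            chosen.append(i)
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise NotBimodalError(
            "histogram not bimodal: fewer than two local maxima separated by "
            f">= {min_separation_hu:g} HU")
    i1, i2 = sorted(chosen, key=lambda i: centers[i])
    fwhm = _interpolated_fwhm(centers, smooth, i2)
    return ModeFit(float(centers[i1]), float(centers[i2]), fwhm,
                   hist_centers=centers, hist_counts=smooth)


def _interpolated_fwhm(centers: np.ndarray, counts: np.ndarray, peak: int) -> float:
    """FWHM of the mode at index ``peak`` by linear interpolation of half-max crossings."""
    half = counts[peak] / 2.0

    def cross(direction: int) -> float:
        i = peak
        while 0 < i < len(counts) - 1:
            j = i + direction
            if counts[j] <= half:
                # interpolate between i (above half) and j (at/below half)
                if counts[i] == counts[j]:
                    return centers[j]
                t = (counts[i] - half) / (counts[i] - counts[j])
                return centers[i] + t * (centers[j] - centers[i])
            i = j
        return centers[i]  # ran off the histogram edge

    return float(cross(+1) - cross(-1))


def vessel_threshold(fit: ModeFit, n_sigma: float = 2.0) -> float:
    """Segmentation threshold: second-mode mean + 2 standard deviations."""
    return fit.mode2_mean + n_sigma * fit.mode2_sigma


def segment_vessels(mip: ImageGrid, lung: BinaryMask, threshold: float) -> BinaryMask:
    """In-lung voxels whose MIP intensity strictly exceeds the threshold."""
    assert_same_geometry(mip, lung)
    return BinaryMask.like(lung, lung.values & (mip.values > threshold))


def parenchyma_mask(lung: BinaryMask, vessels: BinaryMask, dilate_voxels: int = 0) -> BinaryMask:
    """Lung with the vasculature subtracted.

    ``dilate_voxels`` optionally grows the vessel mask before subtraction to
    guard against partial-volume contamination at vessel edges (default 0,
    plain subtraction).
    """
    assert_same_geometry(lung, vessels)
    v = vessels.values & lung.values
    if dilate_voxels > 0:
        v = ndimage.binary_dilation(v, iterations=dilate_voxels)
    return BinaryMask.like(lung, lung.values & ~v)
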