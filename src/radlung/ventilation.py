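"""Jacobian-determinant ventilation analysis.

The Jacobian determinant of a breathing deformation, det(I + grad u) for a
displacement field u (mm), is the local volume-change factor: 1 means no
change, > 1 expansion, < 1 contraction.  Longitudinal ventilation change
is the voxel-wise ratio J_post / J_pre between the post-RT and pre-RT
inhale-to-exhale deformations; a voxel whose ratio is 0.95 or lower (a 5%
or greater loss of expansion) is counted as damaged.  Breathing phases for
the two epochs are matched by equivalent tidal volume (ETV): the
inhale/exhale pair whose lung-volume difference is closest to a target
tidal volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crosscohort import LinearFit, linear_fit
from .gridio import BinaryMask, ImageGrid, VectorField, assert_same_geometry

__all__ = [
    "JacobianMap",
    "DamageSummary",
    "DAMAGE_THRESHOLD",
    "INVALID_RATIO",
    "jacobian_map",
    "jacobian_ratio",
    "damaged_fraction",
    "select_phases_etv",
    "damage_vs_hu",
]

#: Jacobian-ratio value at or below which a voxel counts as damaged
DAMAGE_THRESHOLD = 0.95

#: j_pre values at or below this are treated as invalid in the ratio
_RATIO_EPS = 1e-6


@dataclass
class JacobianMap:
    """Per-voxel volume-change factor of a deformation, plus folding count."""

    grid: ImageGrid
    epoch: str = ""
    n_nonpositive: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class DamageSummary:
    """Damaged-voxel fraction of one contour at one timepoint."""

    bin_label: str
    timepoint: str
    fraction_damaged: float
    n_voxels: int
    threshold: float = DAMAGE_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_damaged <= 1.0:
            raise ValueError("fraction_damaged must lie in [0, 1]")


def _gradient_axis(u_comp: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Spacing-aware central differences, one-sided at the boundary slices."""
    return np.gradient(u_comp, h, axis=axis)


def jacobian_map(field: VectorField, epoch: str = "") -> JacobianMap:
    """det(I + grad u) with central differences (one-sided at boundaries).

    Displacements are in mm; gradients are taken with respect to world
    coordinates using the grid spacing.  Non-positive determinants
    (folding) are counted in the result's metadata.
    """
    if min(field.shape) < 3:
        raise ValueError("jacobian_map needs at least 3 voxels along every axis")
    F = np.empty(field.shape + (3, 3))
    for comp in range(3):
        for axis in range(3):
            F[..., comp, axis] = _gradient_axis(field.u[..., comp], axis,
                                                float(field.spacing[axis]))
        F[..., comp, comp] += 1.0
    det = np.linalg.det(F)
    n_nonpos = int(np.count_nonzero(det <= 0))
    return JacobianMap(ImageGrid(det, field.spacing.copy(), field.origin.copy()),
                       epoch=epoch, n_nonpositive=n_nonpos)


#: sentinel stored at invalid ratio voxels (valid ratios are always > 0)
INVALID_RATIO = -1.0


def jacobian_ratio(j_post: JacobianMap, j_pre: JacobianMap) -> ImageGrid:
    """Voxel-wise J_post / J_pre.

    Voxels where either Jacobian is non-positive (within eps) are physically
    invalid (folding); they are marked with the negative ``INVALID_RATIO``
    sentinel and excluded from downstream statistics.  Valid ratios are
    strictly positive.
    """
    assert_same_geometry(j_post.grid, j_pre.grid)
    pre, post = j_pre.values, j_post.values
    valid = (pre > _RATIO_EPS) & (post > _RATIO_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, post / np.where(valid, pre, 1.0), INVALID_RATIO)
    return j_pre.grid.copy(values=ratio)


def damaged_fraction(
    ratio: ImageGrid,
    mask: BinaryMask,
    threshold: float = DAMAGE_THRESHOLD,
    bin_label: str = "",
    timepoint: str = "",
) -> DamageSummary:
    """Fraction of valid in-mask voxels with ratio <= threshold (inclusive).

    Voxels carrying the non-positive invalid-ratio sentinel are excluded
    from both numerator and denominator.
    """
    assert_same_geometry(ratio, mask)
    if mask.n_voxels == 0:
        raise ValueError("damaged_fraction requires a non-empty mask")
    vals = ratio.values[mask.values]
    valid = vals[np.isfinite(vals) & (vals > 0.0)]
    if valid.size == 0:
        raise ValueError("no valid Jacobian-ratio voxels in mask")
    frac = float(np.count_nonzero(valid <= threshold)) / valid.size
    return DamageSummary(bin_label=bin_label, timepoint=timepoint,
                         fraction_damaged=frac, n_voxels=int(valid.size),
                         threshold=threshold)


def select_phases_etv(
    phase_volumes: list[tuple[str, float]],
    target_tidal: float,
) -> tuple[str, str]:
    """Pick the (inhale, exhale) phase pair by equivalent tidal volume.

    Over all ordered pairs (larger volume, smaller volume), choose the one
    whose volume difference is closest to ``target_tidal``; ties break
    toward the pair containing the global end-exhale (minimum-volume)
    phase.
    """
    if len(phase_volumes) < 2:
        raise ValueError("need at least two phases")
    end_exhale = min(phase_volumes, key=lambda pv: pv[1])[0]
    best: tuple[str, str] | None = None
    best_err = np.inf
    for i, (li, vi) in enumerate(phase_volumes):
        for lj, vj in phase_volumes[i + 1:]:
            hi, lo = ((li, lj) if vi >= vj else (lj, li))
            dv = abs(vi - vj)
            err = abs(dv - target_tidal)
            if err < best_err - 1e-12:
                best, best_err = (hi, lo), err
            elif abs(err - best_err) <= 1e-12 and best is not None:
                if end_exhale in (hi, lo) and end_exhale not in best:
                    best = (hi, lo)
    assert best is not None
    return best


def damage_vs_hu(
    damage: list[DamageSummary],
    hu_stats,
) -> tuple["np.ndarray", "np.ndarray", LinearFit]:
    """Pair per-bin damaged-% with per-bin mean dHU% and fit a line.

    ``hu_stats`` is a list of :class:`radlung.huchange.BinStats`.  Returns
    (dHU% array, damaged-% array, fit of damaged-% on dHU%).  A near-zero
    slope means the HU response carries no information about the
    ventilation loss.
    """
    dmap = {d.bin_label: d.fraction_damaged * 100.0 for d in damage}
    hmap = {s.bin_label: s.mean_delta_pct for s in hu_stats}
    common = [b for b in hmap if b in dmap]
    if not common:
        raise ValueError("no common bins between damage and HU statistics")
    x = np.array([hmap[b] for b in common])
    y = np.array([dmap[b] for b in common])
    return x, y, linear_fit(x, y)
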