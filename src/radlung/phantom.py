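"""Synthetic thorax and radiation-response generator with ground truth.

The phantom emulates the statistical structure the analysis pipeline
assumes, on a desk-scale grid (default 96 x 96 x 64 voxels at 2 mm
isotropic):

* two ellipsoidal lungs filled with aerated parenchyma (mode near
  −850 HU) threaded by a random vessel tree drawn from the soft-tissue /
  blood mode (near +40 HU), so the in-lung HU histogram is bimodal;
* a dynamic contrast series: a gamma-variate first-pass bolus riding on
  the vessel voxels, with four pre-contrast frames;
* an SBRT-like dose grid: monotone ellipsoidal-radial falloff from the
  prescription at a target centred in one lung, constructed so every
  10 Gy bin holds a configurable volume (default 45 cc, comfortably above
  the 30 cc analysis floor) and the contralateral lung receives 0 Gy;
* a radiation response at a given timepoint: out-of-vessel HU gain linear
  in bin EQD2 (default slope 0.167 %/Gy), a systemic reduction of the
  in-vessel peak enhancement, in-vessel reduction coupled linearly to the
  out-of-vessel gain (default slope −0.87 %in per %out), and a leakage
  attribution ledger above a 25 Gy onset dose;
* breathing deformations whose discrete Jacobian is prescribed exactly:
  expansion of about 1.15 pre-RT, multiplied by 0.90 on a damaged-voxel
  mask post-RT (per-bin damaged fractions drawn from U(0.40, 0.50), the
  centre of the 30–60% band, approximately dose-flat).

Human presets scale the swine response by per-timepoint factors (0.785,
0.588, 0.955 at 3/6/12 months — the generator's encoding of the swine's
accelerated response), have no dynamic series, and are imaged twice per
timepoint as independent noise draws.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .dosebins import FractionationScheme, bin_eqd2, make_dose_bins
from .gridio import BinaryMask, DynamicSeries, ImageGrid, VectorField

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_anatomy",
    "generate_dose",
    "apply_radiation_response",
    "generate_static_volume",
    "generate_dynamic_series",
    "generate_breathing_fields",
    "bolus_profile",
]


@dataclass
class PhantomConfig:
    """All tunable parameters of the synthetic thorax and its response."""

    # lattice
    shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    # anatomy
    lung_semiaxes_mm: tuple[float, float, float] = (36.0, 55.0, 45.0)
    lung_offset_mm: float = 46.0  # lung centres at grid centre +/- offset along x
    n_branches: int = 60          # vessel segments per lung
    n_core_branches: int = 8      # of which seeded at the lung centre
    branch_radius_mm: tuple[float, float] = (1.5, 3.5)
    branch_length_mm: tuple[float, float] = (20.0, 60.0)

    # HU model
    mu_parenchyma_hu: float = -850.0
    mu_vessel_hu: float = 40.0
    parenchyma_sigma_hu: float = 0.0   # frozen tissue heterogeneity
    vessel_sigma_hu: float = 0.0
    noise_sigma_hu: float = 40.0       # per-acquisition additive noise

    # contrast kinetics (gamma-variate bolus, peak normalised to 1)
    bolus_amplitude_hu: float = 400.0
    n_frames: int = 30
    n_precontrast: int = 4
    frame_interval_s: float = 1.5
    bolus_delay_s: float = 3.0   # after the last pre-contrast frame
    bolus_shape: float = 3.0
    bolus_scale_s: float = 2.5

    # dose model
    rx_gy: float = 60.0
    n_fractions: int = 5
    alpha_beta: float = 3.0
    bin_target_cc: float = 45.0
    min_bin_cc: float = 30.0

    # response model
    slope_pct_per_gy: float = 0.167       # out-of-vessel dHU% per Gy EQD2
    systemic_peak_reduction: float = 0.15  # fraction of bolus amplitude, both lungs
    leak_coupling_slope: float = -0.87     # d(in-vessel %)/d(out-of-vessel %)
    leak_onset_gy: float = 25.0            # physical dose above which leakage is booked
    damaged_fraction_range: tuple[float, float] = (0.40, 0.50)
    jacobian_damage_factor: float = 0.90   # multiplies J_pre on damaged voxels
    jacobian_pre_mean: float = 0.15        # J_pre ~ 1 + mean +/- var inside lung
    jacobian_pre_var: float = 0.04
    timepoint_factors: Mapping[str, float] = dc_field(
        default_factory=lambda: {"3m": 1.0})

    # cohort / replicate model
    species: str = "swine"
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.mu_parenchyma_hu >= self.mu_vessel_hu:
            raise ValueError("parenchyma mode must lie below the vessel mode")
        s1 = np.hypot(self.parenchyma_sigma_hu, self.noise_sigma_hu)
        s2 = np.hypot(self.vessel_sigma_hu, self.noise_sigma_hu)
        if self.mu_vessel_hu - self.mu_parenchyma_hu <= 4.0 * (s1 + s2):
            raise ValueError("HU modes must be separated by > 4 combined std devs")
        lo, hi = self.damaged_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("damaged fraction range must lie inside (0, 1)")
        if not 0 < self.n_precontrast < self.n_frames:
            raise ValueError("n_precontrast must lie in (0, n_frames)")
        if min(self.shape) < 8:
            raise ValueError("phantom grid must be at least 8 voxels per axis")

    # -- derived quantities ------------------------------------------------

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def bolus_t0_s(self) -> float:
        """Contrast arrival time: injection after the pre-contrast frames plus transit."""
        return self.n_precontrast * self.frame_interval_s + self.bolus_delay_s

    @property
    def parenchyma_mode_sigma(self) -> float:
        """Effective first-frame std dev of the parenchyma mode."""
        return float(np.hypot(self.parenchyma_sigma_hu, self.noise_sigma_hu))

    @property
    def vessel_mode_sigma(self) -> float:
        """Effective first-frame std dev of the soft-tissue/blood mode."""
        return float(np.hypot(self.vessel_sigma_hu, self.noise_sigma_hu))

    @property
    def scheme(self) -> FractionationScheme:
        return FractionationScheme(self.rx_gy, self.n_fractions, self.alpha_beta)

    @property
    def dose_edges(self) -> np.ndarray:
        """10 Gy bin edges from 5 Gy up to just above the prescription."""
        top = 5.0 + 10.0 * np.ceil((self.rx_gy - 5.0) / 10.0)
        return np.arange(5.0, top + 1e-9, 10.0)

    # -- presets -----------------------------------------------------------

    @classmethod
    def swine(cls, **overrides) -> "PhantomConfig":
        """Default preclinical swine study: 60 Gy / 5 fx, dynamic contrast CT at 3 months."""
        return cls(**overrides)

    @classmethod
    def human(cls, **overrides) -> "PhantomConfig":
        """SBRT human study: 50 Gy / 5 fx, non-contrast 4DCT, two repeat scans,
        response scaled per timepoint relative to the swine."""
        defaults = dict(
            species="human", rx_gy=50.0, n_replicates=2,
            timepoint_factors={"3m": 0.785, "6m": 0.588, "12m": 0.955},
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    lung_left: BinaryMask
    lung_right: BinaryMask
    lung: BinaryMask
    vessel_mask: BinaryMask
    irradiated_side: str  # "left" | "right"
    tissue: np.ndarray    # frozen pre-RT tissue HU map (no acquisition noise)
    dose: ImageGrid | None = None
    tissue_post: np.ndarray | None = None
    amplitude_pre: np.ndarray | None = None   # per-voxel bolus amplitude maps
    amplitude_post: np.ndarray | None = None
    damaged_mask: BinaryMask | None = None
    bins_true: pd.DataFrame | None = None     # per-bin true response values
    leak_ledger: dict | None = None
    timepoint: str | None = None
    seed: int | None = None

    @property
    def lung_irradiated(self) -> BinaryMask:
        return self.lung_right if self.irradiated_side == "right" else self.lung_left

    @property
    def lung_control(self) -> BinaryMask:
        return self.lung_left if self.irradiated_side == "right" else self.lung_right

    def validate(self) -> None:
        """Check the truth invariants (vessels and damage inside the lung,
        unirradiated contralateral lung)."""
        assert not np.any(self.vessel_mask.values & ~self.lung.values), \
            "vessel mask must lie inside the lung"
        if self.damaged_mask is not None:
            assert not np.any(self.damaged_mask.values & ~self.lung.values), \
                "damaged mask must lie inside the lung"
        if self.dose is not None:
            ctrl = self.dose.values[self.lung_control.values]
            assert ctrl.max(initial=0.0) < 5.0, "contralateral lung must receive < 5 Gy"


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def _world_axes(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sp = config.spacing
    return tuple(np.arange(n) * sp[a] for a, n in enumerate(config.shape))  # type: ignore


def _ellipsoid_mask(config: PhantomConfig, center: np.ndarray,
                    semiaxes: np.ndarray) -> np.ndarray:
    xs, ys, zs = _world_axes(config)
    dx = (xs - center[0]) / semiaxes[0]
    dy = (ys - center[1]) / semiaxes[1]
    dz = (zs - center[2]) / semiaxes[2]
    return (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
            + dz[None, None, :] ** 2) <= 1.0


def _grid_center(config: PhantomConfig) -> np.ndarray:
    return (np.asarray(config.shape) - 1) / 2.0 * config.spacing


def _rasterize_segment(mask: np.ndarray, config: PhantomConfig,
                       p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Mark voxels within ``radius`` mm of the segment p0-p1 (in place)."""
    sp = config.spacing
    lo = np.minimum(p0, p1) - radius - sp
    hi = np.maximum(p0, p1) + radius + sp
    i0 = np.maximum(np.floor(lo / sp).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / sp).astype(int) + 1, np.asarray(config.shape))
    if np.any(i0 >= i1):
        return
    xs = np.arange(i0[0], i1[0]) * sp[0]
    ys = np.arange(i0[1], i1[1]) * sp[1]
    zs = np.arange(i0[2], i1[2]) * sp[2]
    q = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        t = np.zeros(q.shape[:3])
    else:
        t = np.clip(((q - p0) @ d) / L2, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((q - closest) ** 2, axis=-1)
    mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= dist2 <= radius ** 2


def _vessel_tree(config: PhantomConfig, lung_values: np.ndarray,
                 center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random vessel segments inside one lung: a few seeded at the lung
    centre (so every isodose shell is perfused), the rest radiating from
    the medial hilum or scattered through the lung."""
    semi = np.asarray(config.lung_semiaxes_mm)
    gx = _grid_center(config)[0]
    medial_sign = -1.0 if center[0] > gx else 1.0
    hilum = center + np.array([medial_sign * 0.7 * semi[0], 0.0, 0.0])
    mask = np.zeros(config.shape, dtype=bool)
    r_lo, r_hi = config.branch_radius_mm
    l_lo, l_hi = config.branch_length_mm
    for b in range(config.n_branches):
        if b < config.n_core_branches:
            start = center + rng.normal(0.0, 5.0, size=3)
        elif b < config.n_branches // 2:
            start = hilum + rng.normal(0.0, 8.0, size=3)
        else:
            # uniform point inside the lung ellipsoid
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            start = center + v * semi * rng.uniform() ** (1.0 / 3.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(l_lo, l_hi)
        radius = rng.uniform(r_lo, r_hi)
        _rasterize_segment(mask, config, start, start + direction * length, radius)
    return mask & lung_values


def generate_anatomy(config: PhantomConfig,
                     seed: int | np.random.SeedSequence = 0,
                     ) -> tuple[ImageGrid, PhantomTruth]:
    """Build the pre-RT thorax: lungs, vessel tree, tissue HU map.

    Returns the pre-RT static volume (tissue plus one acquisition-noise
    draw) and the :class:`PhantomTruth` holding the masks and the frozen
    tissue map.  Deterministic given (config, seed).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    anat_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(anat_ss)

    gc = _grid_center(config)
    semi = np.asarray(config.lung_semiaxes_mm)
    off = np.array([config.lung_offset_mm, 0.0, 0.0])
    left_v = _ellipsoid_mask(config, gc - off, semi)
    right_v = _ellipsoid_mask(config, gc + off, semi)
    if not left_v.any() or not right_v.any():
        raise ValueError("lungs not constructible at the requested grid size")
    lung_v = left_v | right_v

    vessels_v = (_vessel_tree(config, left_v, gc - off, rng)
                 | _vessel_tree(config, right_v, gc + off, rng))
    if not vessels_v.any():
        raise ValueError("vessel tree not constructible at the requested grid size")

    tissue = np.full(config.shape, config.mu_vessel_hu, dtype=np.float32)
    tissue[lung_v] = config.mu_parenchyma_hu
    if config.parenchyma_sigma_hu > 0:
        n_par = int(np.count_nonzero(lung_v))
        tissue[lung_v] += rng.normal(0.0, config.parenchyma_sigma_hu,
                                     size=n_par).astype(np.float32)
    tissue[vessels_v] = config.mu_vessel_hu
    if config.vessel_sigma_hu > 0:
        n_ves = int(np.count_nonzero(vessels_v))
        tissue[vessels_v] += rng.normal(0.0, config.vessel_sigma_hu,
                                        size=n_ves).astype(np.float32)

    origin = np.zeros(3)
    ref = ImageGrid(tissue, config.spacing, origin)
    truth = PhantomTruth(
        lung_left=BinaryMask.like(ref, left_v),
        lung_right=BinaryMask.like(ref, right_v),
        lung=BinaryMask.like(ref, lung_v),
        vessel_mask=BinaryMask.like(ref, vessels_v),
        irradiated_side="right",
        tissue=tissue,
    )
    pre_rt = generate_static_volume(config, truth, epoch="pre",
                                    seed=noise_ss)
    return pre_rt, truth


# ---------------------------------------------------------------------------
# dose
# ---------------------------------------------------------------------------

def generate_dose(config: PhantomConfig, truth: PhantomTruth) -> ImageGrid:
    """SBRT-like dose grid: prescription at the irradiated-lung centre with
    monotone falloff along an ellipsoidal radius shaped like the lung.

    The isodose radii are placed at volume quantiles of the in-lung radius
    distribution so that every 10 Gy bin intersected with the irradiated
    lung holds ``bin_target_cc`` (defaults to 45 cc, above the 30 cc
    analysis floor); the dose reaches zero well before the contralateral
    lung.  Deterministic (no randomness).
    """
    gc = _grid_center(config)
    semi = np.asarray(config.lung_semiaxes_mm)
    sign = 1.0 if truth.irradiated_side == "right" else -1.0
    center = gc + sign * np.array([config.lung_offset_mm, 0.0, 0.0])

    xs, ys, zs = _world_axes(config)
    u = np.sqrt(((xs - center[0]) / semi[0])[:, None, None] ** 2
                + ((ys - center[1]) / semi[1])[None, :, None] ** 2
                + ((zs - center[2]) / semi[2])[None, None, :] ** 2)

    edges = config.dose_edges  # e.g. [5, 15, ..., 65]
    n_bins = len(edges) - 1
    n_per = int(round(config.bin_target_cc * 1000.0 / config.voxel_volume_mm3))
    lung_u = np.sort(u[truth.lung_irradiated.values])
    if n_bins * n_per >= lung_u.size:
        raise ValueError(
            f"irradiated lung too small for {n_bins} bins of "
            f"{config.bin_target_cc:g} cc each")

    # radius knots: after k*n_per voxels the dose has fallen to the k-th
    # bin edge (descending); interior of the innermost shell carries Rx
    knots_u = [0.0]
    knots_d = [config.rx_gy]
    desc_edges = edges[::-1]  # e.g. 65 (unused top), 55, 45, ..., 5
    for k in range(1, n_bins + 1):
        uk = 0.5 * (lung_u[k * n_per - 1] + lung_u[k * n_per])
        knots_u.append(float(uk))
        knots_d.append(float(desc_edges[k]))
    knots_u.append(knots_u[-1] * 1.1)  # dose reaches zero just outside the 5 Gy shell
    knots_d.append(0.0)

    dose_values = np.interp(u, knots_u, knots_d, right=0.0)
    dose = ImageGrid(dose_values, config.spacing, np.zeros(3))

    # verify the construction satisfied its own contract
    ctrl_max = float(dose.values[truth.lung_control.values].max(initial=0.0))
    if ctrl_max >= 5.0:
        raise ValueError(f"contralateral lung receives {ctrl_max:.1f} Gy (>= 5 Gy)")
    bins = make_dose_bins(dose, truth.lung, edges=edges,
                          min_cc=config.min_bin_cc, scheme=config.scheme)
    if len(bins) != n_bins:
        raise ValueError("dose construction failed to populate every 10 Gy bin "
                         f"with >= {config.min_bin_cc:g} cc")
    truth.dose = dose
    return dose


# ---------------------------------------------------------------------------
# radiation response
# ---------------------------------------------------------------------------

def apply_radiation_response(
    config: PhantomConfig,
    truth: PhantomTruth,
    timepoint: str = "3m",
    seed: int | np.random.SeedSequence = 0,
) -> PhantomTruth:
    """Imprint the post-RT state at ``timepoint`` onto the truth.

    Out-of-vessel voxels in each dose bin gain HU linearly in the bin's
    EQD2 (scaled by the per-timepoint factor); in-vessel peak enhancement
    drops systemically in both lungs and, per bin, linearly in the
    out-of-vessel gain with the configured coupling slope; voxels below
    5 Gy receive no parenchymal response.  A damaged-voxel mask with
    per-bin fractions drawn from the configured range is laid down for the
    ventilation analysis, and a leakage-attribution ledger is recorded for
    bins above the onset dose.
    """
    if truth.dose is None:
        generate_dose(config, truth)
    if timepoint not in config.timepoint_factors:
        raise KeyError(
            f"no response scaling configured for timepoint {timepoint!r}; "
            f"known: {sorted(config.timepoint_factors)}")
    f_t = float(config.timepoint_factors[timepoint])
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    dose = truth.dose
    assert dose is not None
    bins = make_dose_bins(dose, truth.lung, edges=config.dose_edges,
                          min_cc=config.min_bin_cc, scheme=config.scheme)
    paren_v = truth.lung.values & ~truth.vessel_mask.values
    A = config.bolus_amplitude_hu
    peak_ref = config.mu_vessel_hu + A
    # systemic in-vessel change (both lungs), in percent of the pre peak
    base_in_pct = -config.systemic_peak_reduction * A / peak_ref * 100.0

    out_pct = {b.label: f_t * config.slope_pct_per_gy * b.eqd2 for b in bins}
    x_min = min(out_pct.values())
    onset_eqd2 = bin_eqd2(config.leak_onset_gy, config.scheme)
    x_onset = f_t * config.slope_pct_per_gy * onset_eqd2

    tissue_post = truth.tissue.copy()
    amp_pre = np.where(truth.vessel_mask.values, np.float32(A), np.float32(0.0))
    amp_post = np.where(truth.vessel_mask.values,
                        np.float32(A * (1.0 - config.systemic_peak_reduction)),
                        np.float32(0.0))
    damaged = np.zeros(config.shape, dtype=bool)
    smooth_w = ndimage.gaussian_filter(rng.standard_normal(config.shape), sigma=2.0)

    vox_mm3 = config.voxel_volume_mm3
    records = []
    extra_deficit: dict[str, float] = {}  # in-vessel deficit beyond systemic, HU*mm3
    leak_weight: dict[str, float] = {}
    f_lo, f_hi = config.damaged_fraction_range
    for b in bins:
        x_b = out_pct[b.label]
        y_b = base_in_pct + config.leak_coupling_slope * (x_b - x_min)
        # parenchymal gain, per voxel, proportional to |baseline|
        sel_p = b.mask.values & paren_v
        gains = x_b / 100.0 * np.abs(truth.tissue[sel_p])
        tissue_post[sel_p] += gains.astype(np.float32)
        # in-vessel amplitude so the measured per-bin peak change equals y_b
        sel_v = b.mask.values & truth.vessel_mask.values
        amp_b = A + y_b / 100.0 * peak_ref
        amp_post[sel_v] = np.float32(amp_b)
        extra_deficit[b.label] = float(
            (A * (1.0 - config.systemic_peak_reduction) - amp_b)
            * np.count_nonzero(sel_v) * vox_mm3)
        leak_weight[b.label] = (max(x_b - x_onset, 0.0)
                                * np.count_nonzero(sel_p) * vox_mm3)
        # damaged-voxel mask: exact per-bin fraction, spatially coherent blobs
        frac = rng.uniform(f_lo, f_hi)
        idx = np.argwhere(b.mask.values)
        w = smooth_w[b.mask.values]
        k = int(round(frac * len(idx)))
        chosen = idx[np.argsort(w, kind="stable")[:k]]
        damaged[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
        records.append(dict(
            bin_label=b.label, lo=b.lo, hi=b.hi, mid=b.midpoint, eqd2=b.eqd2,
            volume_cc=b.volume_cc, true_out_pct=x_b, true_in_pct=y_b,
            damaged_fraction=k / len(idx),
        ))

    # leakage attribution: the in-vessel peak deficit beyond the systemic
    # reduction is contrast lost from the circulating pool; it reappears as
    # part of the out-of-vessel gain in the bins above the onset dose
    # (distributed by their above-onset response volume).  The rest of the
    # parenchymal gain is non-vascular damage (inflammation, fibrosis).
    leak_pool = float(sum(extra_deficit.values()))
    wsum = sum(leak_weight.values())
    leaked = {lbl: (leak_pool * w / wsum if wsum > 0 else 0.0)
              for lbl, w in leak_weight.items()}
    for rec in records:
        rec["leaked_out_hu_mm3"] = leaked[rec["bin_label"]]
    total_in_deficit = float(np.sum((amp_pre - amp_post)[truth.vessel_mask.values])
                             * vox_mm3)
    truth.tissue_post = tissue_post
    truth.amplitude_pre = amp_pre
    truth.amplitude_post = amp_post
    truth.damaged_mask = BinaryMask.like(truth.lung, damaged)
    truth.bins_true = pd.DataFrame.from_records(records)
    truth.leak_ledger = {
        "leaked_out_hu_mm3": leaked,
        "in_vessel_leak_deficit_hu_mm3": leak_pool,
        "in_vessel_total_deficit_hu_mm3": total_in_deficit,
    }
    truth.timepoint = timepoint
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# acquisitions
# ---------------------------------------------------------------------------

def _tissue_for_epoch(truth: PhantomTruth, epoch: str) -> np.ndarray:
    if epoch == "pre":
        return truth.tissue
    if epoch == "post":
        if truth.tissue_post is None:
            raise ValueError("post-RT state not generated; call apply_radiation_response")
        return truth.tissue_post
    raise ValueError(f"unknown epoch {epoch!r}")


def generate_static_volume(config: PhantomConfig, truth: PhantomTruth,
                           epoch: str = "pre",
                           seed: int | np.random.SeedSequence = 0) -> ImageGrid:
    """One exhale-phase acquisition: tissue map plus acquisition noise."""
    rng = np.random.default_rng(seed)
    tissue = _tissue_for_epoch(truth, epoch)
    values = tissue.copy()
    if config.noise_sigma_hu > 0:
        values = values + (config.noise_sigma_hu
                           * rng.standard_normal(config.shape).astype(np.float32))
    return ImageGrid(values, config.spacing, np.zeros(3))


def bolus_profile(times: np.ndarray, t0: float, shape: float, scale: float) -> np.ndarray:
    """Gamma-variate first-pass bolus, normalised to peak 1 at t0 + shape*scale."""
    t = np.asarray(times, dtype=float) - t0
    tp = shape * scale
    g = np.zeros_like(t)
    pos = t > 0
    g[pos] = (t[pos] / tp) ** shape * np.exp(shape * (1.0 - t[pos] / tp))
    return g


def generate_dynamic_series(config: PhantomConfig, truth: PhantomTruth,
                            epoch: str = "pre",
                            seed: int | np.random.SeedSequence = 0) -> DynamicSeries:
    """The dynamic contrast acquisition for one epoch.

    Frame values are the epoch's tissue map plus the per-voxel bolus
    amplitude times the gamma-variate profile, plus fresh acquisition
    noise per frame.  The first ``n_precontrast`` frames predate contrast
    arrival by construction.
    """
    rng = np.random.default_rng(seed)
    tissue = _tissue_for_epoch(truth, epoch)
    if epoch == "pre" or truth.amplitude_post is None:
        amp = np.where(truth.vessel_mask.values,
                       np.float32(config.bolus_amplitude_hu), np.float32(0.0))
    else:
        amp = truth.amplitude_post
    times = config.frame_times
    t0 = config.bolus_t0_s
    if t0 < times[config.n_precontrast - 1]:
        raise ValueError(
            f"contrast arrival t0={t0:g}s precedes the last pre-contrast frame "
            f"at {times[config.n_precontrast - 1]:g}s")
    g = bolus_profile(times, t0, config.bolus_shape, config.bolus_scale_s)
    frames = []
    for gt in g:
        vals = tissue + amp * np.float32(gt)
        if config.noise_sigma_hu > 0:
            vals = vals + (config.noise_sigma_hu
                           * rng.standard_normal(config.shape).astype(np.float32))
        frames.append(ImageGrid(vals, config.spacing, np.zeros(3)))
    return DynamicSeries(frames, times, n_precontrast=config.n_precontrast)


# ---------------------------------------------------------------------------
# breathing deformations
# ---------------------------------------------------------------------------

def _displacement_from_jacobian_target(g: np.ndarray, h: float) -> np.ndarray:
    """z-displacement whose discrete central-difference z-derivative equals g.

    For a field with only a z-component the Jacobian determinant is exactly
    1 + du_z/dz, so prescribing the discrete derivative prescribes the
    discrete Jacobian.  Solves the three-term recurrence
    U[k+1] = U[k-1] + 2h g[k] with U[0] = 0, U[1] = h g[0] per column,
    which also satisfies the one-sided difference at the bottom slice.
    """
    nz = g.shape[2]
    U = np.zeros_like(g)
    if nz >= 2:
        U[:, :, 1] = h * g[:, :, 0]
    # even indices accumulate g at odd slice positions and vice versa
    for k in range(2, nz):
        U[:, :, k] = U[:, :, k - 2] + 2.0 * h * g[:, :, k - 1]
    return U


def generate_breathing_fields(
    config: PhantomConfig,
    truth: PhantomTruth,
    epoch: str = "pre",
    seed: int | np.random.SeedSequence = 0,
    n_phases: int = 10,
) -> tuple[VectorField, list[tuple[str, float]]]:
    """Inhale-to-exhale displacement field and per-phase lung volumes.

    Pre-RT the in-lung Jacobian sits at 1 + jacobian_pre_mean with a
    smooth spatial variation of +/- jacobian_pre_var; post-RT the target
    Jacobian is multiplied by the damage factor on the damaged mask and
    left untouched elsewhere, so the analysis-side Jacobian ratio is
    exactly the damage factor on damaged voxels and exactly 1 elsewhere.
    Phase volumes trace a cosine breathing curve between the exhale lung
    volume and the inhale volume implied by the mean Jacobian.
    """
    rng = np.random.default_rng(seed)
    smooth = ndimage.gaussian_filter(rng.standard_normal(config.shape), sigma=4.0)
    peak = float(np.abs(smooth).max())
    variation = smooth / peak if peak > 0 else smooth

    g_pre = np.where(truth.lung.values,
                     config.jacobian_pre_mean + config.jacobian_pre_var * variation,
                     0.0)
    if epoch == "pre":
        g = g_pre
    elif epoch == "post":
        if truth.damaged_mask is None:
            raise ValueError("post-RT state not generated; call apply_radiation_response")
        m = np.where(truth.damaged_mask.values, config.jacobian_damage_factor, 1.0)
        g = (1.0 + g_pre) * m - 1.0
    else:
        raise ValueError(f"unknown epoch {epoch!r}")

    h = float(config.spacing[2])
    u = np.zeros(config.shape + (3,))
    u[..., 2] = _displacement_from_jacobian_target(g, h)
    field = VectorField(u, config.spacing, np.zeros(3))

    exhale_l = truth.lung.volume_cc / 1000.0
    inhale_l = exhale_l * (1.0 + config.jacobian_pre_mean)
    phases = []
    for p in range(n_phases):
        frac = 0.5 * (1.0 - np.cos(2.0 * np.pi * p / n_phases))
        phases.append((f"phase{p:02d}", exhale_l + frac * (inhale_l - exhale_l)))
    return field, phases
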