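"""End-to-end subject and cohort analysis.

Glue between the phantom generator and the measurement modules: generate a
subject, segment its vasculature, build dose-bin and control contours,
extract per-bin baseline/peak HU and Jacobian-damage measurements, and
aggregate cohorts into tidy tables ready for the statistics and
cross-cohort fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phantom as ph
from .crosscohort import LinearFit, linear_fit
from .dosebins import DoseBin, make_dose_bins, mirror_contours
from .gridio import BinaryMask, DynamicSeries, ImageGrid, VectorField
from .huchange import BinMeasurement, average_replicates, delta_hu_percent, extract_trace
from .ventilation import damaged_fraction, jacobian_map, jacobian_ratio
from .vesselseg import (build_mip, fit_bimodal_histogram, parenchyma_mask,
                        segment_vessels, vessel_threshold)

__all__ = [
    "Subject",
    "generate_subject",
    "measure_subject",
    "run_cohort",
    "cohort_bin_means",
    "dose_response_fit",
]


@dataclass
class Subject:
    """All acquisitions for one synthetic subject at one timepoint."""

    subject_id: str
    config: ph.PhantomConfig
    truth: ph.PhantomTruth
    dose: ImageGrid
    timepoint: str
    # swine-mode acquisitions (dynamic contrast series, one per epoch)
    series_pre: DynamicSeries | None = None
    series_post: DynamicSeries | None = None
    # human-mode acquisitions (repeat exhale-phase volumes per epoch)
    volumes_pre: list[ImageGrid] | None = None
    volumes_post: list[ImageGrid] | None = None
    field_pre: VectorField | None = None
    field_post: VectorField | None = None


def generate_subject(
    config: ph.PhantomConfig,
    seed,
    timepoint: str = "3m",
    noise_seed=None,
    subject_id: str | None = None,
) -> Subject:
    """Generate one complete subject deterministically from (config, seed).

    ``noise_seed`` optionally replaces the acquisition-noise stream while
    keeping the anatomy, dose and response fixed (for repeat-scan /
    replicate experiments).  ``seed`` may be an int or a sequence of ints.
    """
    ss = np.random.SeedSequence(seed)
    anat_ss, resp_ss, breath_ss, default_noise_ss = ss.spawn(4)
    noise_ss = (np.random.SeedSequence(noise_seed) if noise_seed is not None
                else default_noise_ss)
    noise_children = noise_ss.spawn(2 + 2 * max(config.n_replicates, 1))

    _, truth = ph.generate_anatomy(config, anat_ss)
    dose = ph.generate_dose(config, truth)
    ph.apply_radiation_response(config, truth, timepoint=timepoint, seed=resp_ss)
    # the same breathing seed for both epochs: the post-RT deformation is
    # the pre-RT one modulated by damage, not an independent draw
    field_pre, _ = ph.generate_breathing_fields(config, truth, "pre", breath_ss)
    field_post, _ = ph.generate_breathing_fields(config, truth, "post", breath_ss)

    sid = subject_id or f"{config.species}"
    subj = Subject(subject_id=sid, config=config, truth=truth, dose=dose,
                   timepoint=timepoint, field_pre=field_pre, field_post=field_post)
    if config.species == "swine":
        subj.series_pre = ph.generate_dynamic_series(config, truth, "pre",
                                                     noise_children[0])
        subj.series_post = ph.generate_dynamic_series(config, truth, "post",
                                                      noise_children[1])
    else:
        n = max(config.n_replicates, 1)
        subj.volumes_pre = [ph.generate_static_volume(config, truth, "pre",
                                                      noise_children[2 + i])
                            for i in range(n)]
        subj.volumes_post = [ph.generate_static_volume(config, truth, "post",
                                                       noise_children[2 + n + i])
                             for i in range(n)]
    return subj


def _swine_rows(subj: Subject, bins: list[DoseBin], vessels: BinaryMask,
                paren: BinaryMask, damage_by_bin: dict[str, float]) -> list[dict]:
    rows = []
    assert subj.series_pre is not None and subj.series_post is not None
    for b in bins:
        row_common = dict(subject=subj.subject_id, timepoint=subj.timepoint,
                          bin_label=b.label, laterality=b.laterality,
                          eqd2=b.eqd2, volume_cc=b.volume_cc,
                          damaged_pct=damage_by_bin.get((b.laterality, b.label),
                                                        float("nan")))
        for compartment, comp_mask in (("parenchyma", paren), ("vessel", vessels)):
            sel = BinaryMask.like(b.mask, b.mask.values & comp_mask.values)
            if sel.n_voxels == 0:
                continue
            tr_pre = extract_trace(subj.series_pre, sel, label=b.label)
            tr_post = extract_trace(subj.series_post, sel, label=b.label)
            if compartment == "parenchyma":
                pre_v, post_v = tr_pre.mean_hu[0], tr_post.mean_hu[0]
                peak_pre = peak_post = float("nan")
            else:
                pre_v, post_v = tr_pre.mean_hu.max(), tr_post.mean_hu.max()
                peak_pre, peak_post = pre_v, post_v
            rows.append(dict(row_common, compartment=compartment,
                             baseline_pre=float(tr_pre.mean_hu[0]),
                             baseline_post=float(tr_post.mean_hu[0]),
                             peak_pre=float(peak_pre), peak_post=float(peak_post),
                             n_voxels=sel.n_voxels,
                             delta_hu_pct=delta_hu_percent(float(pre_v), float(post_v))))
    return rows


def _human_rows(subj: Subject, bins: list[DoseBin],
                damage_by_bin: dict[str, float]) -> list[dict]:
    rows = []
    assert subj.volumes_pre is not None and subj.volumes_post is not None

    def averaged_baseline(volumes: list[ImageGrid], b: DoseBin) -> float:
        reps = [BinMeasurement(subj.subject_id, subj.timepoint, b.label,
                               "parenchyma",
                               float(v.values[b.mask.values].mean()))
                for v in volumes]
        return average_replicates(reps).baseline_hu

    for b in bins:
        pre_v = averaged_baseline(subj.volumes_pre, b)
        post_v = averaged_baseline(subj.volumes_post, b)
        rows.append(dict(subject=subj.subject_id, timepoint=subj.timepoint,
                         bin_label=b.label, laterality=b.laterality,
                         compartment="parenchyma", eqd2=b.eqd2,
                         volume_cc=b.volume_cc, n_voxels=b.mask.n_voxels,
                         baseline_pre=pre_v, baseline_post=post_v,
                         peak_pre=float("nan"), peak_post=float("nan"),
                         delta_hu_pct=delta_hu_percent(pre_v, post_v),
                         damaged_pct=damage_by_bin.get((b.laterality, b.label),
                                                       float("nan"))))
    return rows


def measure_subject(subj: Subject, dilate_vessels: int = 0) -> pd.DataFrame:
    """Run the full measurement pipeline on one subject.

    Swine mode: vessel segmentation from the pre-RT dynamic series (first
    frame histogram -> threshold, temporal MIP -> mask), then per-bin
    parenchyma baseline dHU% and vessel peak dHU%.  Human mode: per-bin
    mean HU of the exhale-phase volumes, averaged over repeat scans.  Both
    modes add mirrored contralateral controls and per-bin Jacobian-damage
    fractions.
    """
    cfg = subj.config
    truth = subj.truth
    bins = make_dose_bins(subj.dose, truth.lung, edges=cfg.dose_edges,
                          min_cc=cfg.min_bin_cc, scheme=cfg.scheme)
    controls = mirror_contours(bins, truth.lung_left, truth.lung_right, subj.dose)

    # ventilation damage on the irradiated bins (the same contours as the
    # HU analysis)
    damage_by_bin: dict[tuple[str, str], float] = {}
    if subj.field_pre is not None and subj.field_post is not None:
        ratio = jacobian_ratio(jacobian_map(subj.field_post, "post"),
                               jacobian_map(subj.field_pre, "pre"))
        for b in bins + controls:
            d = damaged_fraction(ratio, b.mask, bin_label=b.label,
                                 timepoint=subj.timepoint)
            damage_by_bin[(b.laterality, b.label)] = d.fraction_damaged * 100.0

    if cfg.species == "swine":
        assert subj.series_pre is not None
        fit = fit_bimodal_histogram(subj.series_pre.frames[0], truth.lung)
        thr = vessel_threshold(fit)
        vessels = segment_vessels(build_mip(subj.series_pre), truth.lung, thr)
        paren = parenchyma_mask(truth.lung, vessels, dilate_voxels=dilate_vessels)
        rows = _swine_rows(subj, bins + controls, vessels, paren, damage_by_bin)
    else:
        rows = _human_rows(subj, bins + controls, damage_by_bin)
    return pd.DataFrame.from_records(rows)


def run_cohort(
    config: ph.PhantomConfig,
    n_subjects: int,
    base_seed: int,
    timepoint: str = "3m",
) -> pd.DataFrame:
    """Generate and measure a cohort; returns the tidy concatenated table.

    Subject *i* is generated from seed ``[base_seed, i + 1]`` so cohorts
    are reproducible from a single integer.
    """
    frames = []
    for i in range(n_subjects):
        subj = generate_subject(config, [base_seed, i + 1], timepoint=timepoint,
                                subject_id=f"{config.species}{i + 1:02d}")
        frames.append(measure_subject(subj))
    return pd.concat(frames, ignore_index=True)


def cohort_bin_means(
    cohort: pd.DataFrame,
    compartment: str = "parenchyma",
    laterality: str = "irradiated",
) -> pd.DataFrame:
    """Per-bin cohort means of dHU% (and damage), sorted by EQD2."""
    sub = cohort[(cohort["compartment"] == compartment)
                 & (cohort["laterality"] == laterality)]
    out = (sub.groupby("bin_label", as_index=False)
           .agg(eqd2=("eqd2", "mean"),
                mean_delta_pct=("delta_hu_pct", "mean"),
                sd_delta_pct=("delta_hu_pct", "std"),
                mean_damaged_pct=("damaged_pct", "mean"),
                n=("delta_hu_pct", "size")))
    return out.sort_values("eqd2").reset_index(drop=True)


def dose_response_fit(cohort: pd.DataFrame, compartment: str = "parenchyma",
                      laterality: str = "irradiated") -> tuple[pd.DataFrame, LinearFit]:
    """OLS of per-bin cohort-mean dHU% against bin EQD2."""
    means = cohort_bin_means(cohort, compartment, laterality)
    fit = linear_fit(means["eqd2"].to_numpy(), means["mean_delta_pct"].to_numpy())
    return means, fit
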