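"""Synthetic-thorax generator: determinism, anatomy, dose, kinetics, response."""

import numpy as np
import pytest

import radlung as rl
from radlung import phantom as ph


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = rl.PhantomConfig.swine()
        v1, t1 = ph.generate_anatomy(cfg, seed=7)
        v2, t2 = ph.generate_anatomy(cfg, seed=7)
        np.testing.assert_array_equal(v1.values, v2.values)
        np.testing.assert_array_equal(t1.vessel_mask.values, t2.vessel_mask.values)

    def test_different_seed_differs(self):
        cfg = rl.PhantomConfig.swine()
        v1, _ = ph.generate_anatomy(cfg, seed=7)
        v2, _ = ph.generate_anatomy(cfg, seed=8)
        assert not np.array_equal(v1.values, v2.values)


class TestAnatomy:
    def test_noiseless_parenchyma_is_exactly_mode_one(self):
        cfg = rl.PhantomConfig.swine(noise_sigma_hu=0.0)
        vol, truth = ph.generate_anatomy(cfg, seed=3)
        paren = truth.lung.values & ~truth.vessel_mask.values
        assert np.all(vol.values[paren] == cfg.mu_parenchyma_hu)
        assert np.all(vol.values[truth.vessel_mask.values] == cfg.mu_vessel_hu)

    def test_histogram_is_bimodal_at_configured_modes(self, swine_subject):
        fit = rl.fit_bimodal_histogram(swine_subject.series_pre.frames[0],
                                       swine_subject.truth.lung)
        cfg = swine_subject.config
        assert fit.mode1_mean == pytest.approx(cfg.mu_parenchyma_hu, abs=10)
        assert fit.mode2_mean == pytest.approx(cfg.mu_vessel_hu, abs=10)

    def test_truth_invariants_over_seed_sweep(self):
        cfg = rl.PhantomConfig.swine()
        for seed in range(20):
            _, truth = ph.generate_anatomy(cfg, seed=seed)
            ph.generate_dose(cfg, truth)
            truth.validate()
            assert truth.vessel_mask.n_voxels > 0


class TestDose:
    def test_all_bins_above_volume_floor(self, swine_subject):
        assert np.all(swine_subject.truth.bins_true["volume_cc"] >= 30.0)
        assert len(swine_subject.truth.bins_true) == 6  # [5,15) .. [55,65]

    def test_contralateral_below_5gy(self, swine_subject):
        truth = swine_subject.truth
        ctrl = swine_subject.dose.values[truth.lung_control.values]
        assert float(ctrl.max()) < 5.0

    def test_prescription_at_target_center(self, swine_subject):
        cfg = swine_subject.config
        gc = (np.asarray(cfg.shape) - 1) / 2.0 * cfg.spacing
        center = gc + [cfg.lung_offset_mm, 0, 0]
        idx = tuple(np.round(center / cfg.spacing).astype(int))
        assert swine_subject.dose.values[idx] == pytest.approx(cfg.rx_gy, rel=0.01)

    def test_too_small_lung_rejected(self):
        cfg = rl.PhantomConfig.swine(shape=(24, 24, 16))
        _, truth = ph.generate_anatomy(cfg, seed=0)
        with pytest.raises(ValueError):
            ph.generate_dose(cfg, truth)


class TestDynamicSeries:
    def test_precontrast_frames_unenhanced(self, swine_subject):
        """The first four frames predate contrast arrival."""
        cfg = swine_subject.config
        truth = swine_subject.truth
        sel = truth.vessel_mask.values
        for frame in swine_subject.series_pre.frames[:cfg.n_precontrast]:
            mean_v = float(frame.values[sel].mean())
            assert mean_v == pytest.approx(cfg.mu_vessel_hu, abs=3.0)

    def test_zero_amplitude_leaves_frames_at_baseline(self):
        cfg = rl.PhantomConfig.swine(bolus_amplitude_hu=0.0, noise_sigma_hu=0.0)
        _, truth = ph.generate_anatomy(cfg, seed=2)
        series = ph.generate_dynamic_series(cfg, truth, "pre", seed=5)
        for frame in series.frames:
            np.testing.assert_array_equal(frame.values, truth.tissue)

    def test_peak_mean_equals_baseline_plus_amplitude(self, swine_subject):
        cfg = swine_subject.config
        tr = rl.extract_trace(swine_subject.series_pre,
                              swine_subject.truth.vessel_mask)
        # the frame grid hits the gamma-variate maximum exactly
        g = ph.bolus_profile(cfg.frame_times, cfg.bolus_t0_s, cfg.bolus_shape,
                             cfg.bolus_scale_s)
        assert g.max() == pytest.approx(1.0)
        assert rl.peak_hu(tr) == pytest.approx(
            cfg.mu_vessel_hu + cfg.bolus_amplitude_hu, abs=3.0)

    def test_trace_rises_then_falls(self, swine_subject):
        tr = rl.extract_trace(swine_subject.series_pre,
                              swine_subject.truth.vessel_mask)
        peak_idx = int(np.argmax(tr.mean_hu))
        assert swine_subject.config.n_precontrast <= peak_idx < tr.mean_hu.size - 1
        assert tr.mean_hu[-1] < tr.mean_hu[peak_idx] - 50

    def test_early_bolus_rejected(self):
        cfg = rl.PhantomConfig.swine(bolus_delay_s=-10.0)
        _, truth = ph.generate_anatomy(cfg, seed=2)
        with pytest.raises(ValueError, match="pre-contrast"):
            ph.generate_dynamic_series(cfg, truth, "pre", seed=0)


class TestRadiationResponse:
    def test_true_out_pct_is_slope_times_eqd2(self, swine_subject):
        bt = swine_subject.truth.bins_true
        cfg = swine_subject.config
        np.testing.assert_allclose(bt["true_out_pct"],
                                   cfg.slope_pct_per_gy * bt["eqd2"])
        # 0.167 %/Gy at EQD2 = 60 Gy -> 10.02%
        row = bt[bt["bin_label"] == "20Gy"].iloc[0]
        assert row["eqd2"] == 60.0 and row["true_out_pct"] == pytest.approx(10.02)

    def test_null_response_leaves_tissue_unchanged(self):
        cfg = rl.PhantomConfig.swine(slope_pct_per_gy=0.0,
                                     systemic_peak_reduction=0.0,
                                     leak_coupling_slope=0.0)
        _, truth = ph.generate_anatomy(cfg, seed=4)
        ph.apply_radiation_response(cfg, truth, seed=4)
        np.testing.assert_array_equal(truth.tissue_post, truth.tissue)
        np.testing.assert_array_equal(truth.amplitude_post, truth.amplitude_pre)

    def test_unknown_timepoint_rejected(self):
        cfg = rl.PhantomConfig.swine()
        _, truth = ph.generate_anatomy(cfg, seed=4)
        with pytest.raises(KeyError, match="12m"):
            ph.apply_radiation_response(cfg, truth, timepoint="12m")

    def test_in_vessel_coupling_is_linear_in_out_pct(self, swine_subject):
        bt = swine_subject.truth.bins_true
        cfg = swine_subject.config
        slopes = np.diff(bt["true_in_pct"]) / np.diff(bt["true_out_pct"])
        np.testing.assert_allclose(slopes, cfg.leak_coupling_slope)

    def test_leak_ledger_conservation(self, swine_subject):
        """The leaked out-of-vessel contrast must balance the in-vessel
        deficit attributed to leakage within 1%, recomputed from the
        stored amplitude maps."""
        truth = swine_subject.truth
        cfg = swine_subject.config
        led = truth.leak_ledger
        vox = cfg.voxel_volume_mm3
        systemic_amp = cfg.bolus_amplitude_hu * (1 - cfg.systemic_peak_reduction)
        sel = truth.vessel_mask.values
        extra = float(np.sum(systemic_amp - truth.amplitude_post[sel].clip(
            max=systemic_amp)) * vox)
        leaked_total = sum(led["leaked_out_hu_mm3"].values())
        assert leaked_total == pytest.approx(led["in_vessel_leak_deficit_hu_mm3"],
                                             rel=0.01)
        assert leaked_total == pytest.approx(extra, rel=0.01)
        # and the attributed leak cannot exceed the total measured deficit
        assert leaked_total <= led["in_vessel_total_deficit_hu_mm3"] * 1.01

    def test_damaged_fractions_in_configured_range(self, swine_subject):
        lo, hi = swine_subject.config.damaged_fraction_range
        fr = swine_subject.truth.bins_true["damaged_fraction"]
        assert np.all((fr >= lo - 0.01) & (fr <= hi + 0.01))


class TestBreathingFields:
    def test_pre_jacobian_inside_expansion_band(self, swine_subject):
        j = rl.jacobian_map(swine_subject.field_pre).values
        in_lung = j[swine_subject.truth.lung.values]
        assert in_lung.min() >= 1.05 and in_lung.max() <= 1.25

    def test_ratio_on_damaged_and_spared_voxels(self, swine_subject):
        truth = swine_subject.truth
        ratio = rl.jacobian_ratio(rl.jacobian_map(swine_subject.field_post),
                                  rl.jacobian_map(swine_subject.field_pre))
        dam = ratio.values[truth.damaged_mask.values]
        assert np.mean(dam < 0.95) >= 0.99
        spared = truth.lung.values & ~truth.damaged_mask.values
        spared[:, :, -1] = False  # top slice uses a one-sided stencil
        sp = ratio.values[spared]
        assert sp.min() >= 0.98 and sp.max() <= 1.02

    def test_measured_damage_matches_truth_fractions(self, swine_table,
                                                     swine_subject):
        bt = swine_subject.truth.bins_true.set_index("bin_label")
        sub = swine_table[(swine_table["laterality"] == "irradiated")
                          & (swine_table["compartment"] == "parenchyma")]
        for _, row in sub.iterrows():
            assert row["damaged_pct"] / 100.0 == pytest.approx(
                bt.loc[row["bin_label"], "damaged_fraction"], abs=0.01)

    def test_phase_volumes_support_etv(self, swine_subject):
        _, phases = ph.generate_breathing_fields(swine_subject.config,
                                                 swine_subject.truth, "pre",
                                                 seed=0)
        assert len(phases) == 10
        inhale, exhale = rl.select_phases_etv(phases, target_tidal=0.1)
        vols = dict(phases)
        assert vols[inhale] > vols[exhale]
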