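"""EQD2 arithmetic, isodose binning, and contralateral mirroring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radlung as rl
from radlung.dosebins import ContaminatedControlError, DoseBin

from conftest import small_grid, small_mask


class TestEqd2:
    @pytest.mark.parametrize("D,d,ab,expected", [
        (60, 12, 3, 180.0),
        (2, 2, 3, 2.0),      # 2 Gy in one 2 Gy fraction is its own EQD2
        (15, 10, 3, 39.0),   # human 5-15 Gy bin edges at 50 Gy / 5 fx
        (5, 10, 3, 13.0),
    ])
    def test_values(self, D, d, ab, expected):
        assert rl.eqd2(D, d, ab) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rl.eqd2(0, 10, 3)
        with pytest.raises(ValueError):
            rl.eqd2(10, -1, 3)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.5, 100), st.floats(0.5, 100), st.floats(0.5, 20),
           st.floats(1.01, 3.0))
    def test_linear_in_total_dose_and_increasing_in_fraction(self, D, d, ab, k):
        assert rl.eqd2(k * D, d, ab) == pytest.approx(k * rl.eqd2(D, d, ab))
        assert rl.eqd2(D, k * d, ab) > rl.eqd2(D, d, ab)


class TestBinEqd2:
    def test_prescription_convention_reproduces_human_anchors(self):
        scheme = rl.FractionationScheme(50, 5, 3)
        assert rl.bin_eqd2(5.0, scheme) == pytest.approx(13.0)
        assert rl.bin_eqd2(15.0, scheme) == pytest.approx(39.0)

    def test_swine_bin_midpoint(self):
        scheme = rl.FractionationScheme(60, 5, 3)
        b = DoseBin(15, 25, small_mask(np.ones((8, 8, 8), bool)))
        assert rl.bin_eqd2(b, scheme) == pytest.approx(60.0)  # 20*(12+3)/5

    def test_bin_fraction_convention(self):
        scheme = rl.FractionationScheme(50, 5, 3)
        assert rl.bin_eqd2(5.0, scheme, convention="bin_fraction") == pytest.approx(4.0)

    def test_prescription_convention_scales_swine_by_three(self):
        scheme = rl.FractionationScheme(60, 5, 3)
        for mid in (10.0, 30.0, 60.0):
            assert rl.bin_eqd2(mid, scheme) == pytest.approx(3.0 * mid)


class TestMakeDoseBins:
    # 10 mm voxels: 1 voxel = 1 cc, so the 30 cc floor is 30 voxels
    sp = (10.0, 10.0, 10.0)

    def _lung(self):
        return small_mask(np.ones((8, 8, 8), bool), self.sp)

    def test_zero_dose_yields_no_bins(self):
        dose = small_grid(np.zeros((8, 8, 8)), spacing=self.sp)
        assert rl.make_dose_bins(dose, self._lung()) == []

    def test_volume_floor_boundary(self):
        dose = small_grid(np.zeros((8, 8, 8)), spacing=self.sp)
        dose.values.ravel()[:30] = 10.0   # exactly 30 cc in [5,15)
        dose.values.ravel()[100:129] = 20.0  # 29 cc in [15,25)
        with pytest.warns(UserWarning, match="29.0 cc"):
            bins = rl.make_dose_bins(dose, self._lung())
        assert [b.label for b in bins] == ["10Gy"]
        assert bins[0].volume_cc == pytest.approx(30.0)

    def test_non_ascending_edges_rejected(self):
        dose = small_grid(np.zeros((8, 8, 8)), spacing=self.sp)
        with pytest.raises(ValueError):
            rl.make_dose_bins(dose, self._lung(), edges=[5, 25, 15])

    def test_bins_partition_high_dose_lung(self, swine_subject):
        """Bins are disjoint and cover the >= 5 Gy in-lung region exactly."""
        cfg = swine_subject.config
        truth = swine_subject.truth
        bins = rl.make_dose_bins(swine_subject.dose, truth.lung,
                                 edges=cfg.dose_edges, scheme=cfg.scheme)
        union = np.zeros(cfg.shape, dtype=bool)
        total = 0
        for b in bins:
            assert not np.any(union & b.mask.values), "bins overlap"
            union |= b.mask.values
            total += b.mask.n_voxels
        expected = truth.lung.values & (swine_subject.dose.values >= 5.0)
        np.testing.assert_array_equal(union, expected)
        assert total == int(np.count_nonzero(expected))


class TestMirrorContours:
    def _two_lungs(self):
        left = np.zeros((20, 12, 12), bool)
        right = np.zeros((20, 12, 12), bool)
        left[2:8, 2:10, 2:10] = True
        right[12:18, 2:10, 2:10] = True
        return small_mask(left), small_mask(right)

    def test_mirror_near_involution(self):
        # zero dose everywhere so mirroring both ways stays uncontaminated
        left, right = self._two_lungs()
        dose = small_grid(np.zeros((20, 12, 12)))
        src = np.zeros((20, 12, 12), bool)
        src[13:17, 3:9, 3:9] = True
        b = DoseBin(5, 15, small_mask(src))
        ctrl = rl.mirror_contours([b], left, right, dose)[0]
        assert ctrl.laterality == "control"
        back = rl.mirror_contours([DoseBin(5, 15, ctrl.mask)], left, right, dose)[0]
        inter = np.count_nonzero(back.mask.values & src)
        dice = 2 * inter / (back.mask.n_voxels + int(src.sum()))
        assert dice >= 0.95

    def test_contaminated_control_raises(self):
        left, right = self._two_lungs()
        dose = small_grid(np.full((20, 12, 12), 10.0))  # both lungs irradiated
        src = np.zeros((20, 12, 12), bool)
        src[13:17, 3:9, 3:9] = True
        with pytest.raises(ContaminatedControlError, match="10Gy"):
            rl.mirror_contours([DoseBin(5, 15, small_mask(src))], left, right, dose)

    def test_empty_intersection_dropped(self):
        left, right = self._two_lungs()
        dose = small_grid(np.zeros((20, 12, 12)))
        src = np.zeros((20, 12, 12), bool)
        src[18:20, 0:2, 0:2] = True  # mirrors outside the left lung
        with pytest.warns(UserWarning, match="empty"):
            out = rl.mirror_contours([DoseBin(5, 15, small_mask(src))],
                                     left, right, dose)
        assert out == []

    def test_phantom_controls_unirradiated(self, swine_subject):
        cfg = swine_subject.config
        truth = swine_subject.truth
        bins = rl.make_dose_bins(swine_subject.dose, truth.lung,
                                 edges=cfg.dose_edges, scheme=cfg.scheme)
        controls = rl.mirror_contours(bins, truth.lung_left, truth.lung_right,
                                      swine_subject.dose)
        assert len(controls) == len(bins)
        for c in controls:
            assert float(swine_subject.dose.values[c.mask.values].max()) < 5.0
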