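"""Vessel quantification: EDT calibre maps, Dice, bins, and VVRs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepavol.volumetry import (
    LABEL_HEPATIC,
    LABEL_LIVER,
    LABEL_PORTAL,
    bin_fractions,
    dice,
    dice_by_bin,
    edt_diameter,
    organ_volume,
    vessel_to_volume_ratios,
)


def brute_force_edt(mask, spacing):
    """Exhaustive nearest-background distance, the independent oracle."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    bg = np.argwhere(~mask) * spacing
    out = np.full(mask.shape, np.nan)
    for idx in np.argwhere(mask):
        p = idx * spacing
        out[tuple(idx)] = np.sqrt(((bg - p) ** 2).sum(axis=1)).min() if len(bg) else np.inf
    return out


class TestEdtDiameter:
    def test_single_voxel_unit_spacing(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        dmap = edt_diameter(mask, (1.0, 1.0, 1.0))
        assert dmap.values_mm[2, 2, 2] == pytest.approx(1.0)

    def test_cylinder_centerline_value(self):
        # long axis-aligned cylinder of radius 4 voxels at unit spacing:
        # the centreline EDT should be ~4 mm
        shape = (30, 11, 11)
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        mask = ((yy - 5) ** 2 + (xx - 5) ** 2) <= 16
        dmap = edt_diameter(mask, (1.0, 1.0, 1.0))
        centerline = dmap.values_mm[15, 5, 5]
        assert centerline == pytest.approx(4.0, abs=0.5)
        oracle = brute_force_edt(mask[10:20], (1.0, 1.0, 1.0))
        np.testing.assert_allclose(dmap.values_mm[10:20][mask[10:20]], oracle[mask[10:20]])

    def test_anisotropic_slab(self):
        # one-voxel-thick slab; background adjacent only along the 3 mm axis
        mask = np.zeros((7, 7, 3), dtype=bool)
        mask[:, :, 1] = True
        dmap = edt_diameter(mask, (1.0, 1.0, 3.0))
        assert dmap.values_mm[3, 3, 1] == pytest.approx(3.0)
        oracle = brute_force_edt(mask, (1.0, 1.0, 3.0))
        np.testing.assert_allclose(dmap.values_mm[mask], oracle[mask])

    def test_empty_mask_is_not_an_error(self):
        dmap = edt_diameter(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
        assert not dmap.mask.any()
        assert np.isnan(dmap.values_mm).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_oracle_equivalence_random_grids(self, trial):
        rng = np.random.default_rng(trial)
        shape = tuple(rng.integers(4, 13, size=3))
        spacing = tuple(rng.choice([0.5, 1.0, 1.5, 3.0], size=3))
        mask = rng.random(shape) < 0.4
        dmap = edt_diameter(mask, spacing)
        oracle = brute_force_edt(mask, spacing)
        np.testing.assert_allclose(dmap.values_mm[mask], oracle[mask], rtol=1e-10)


class TestBinFractions:
    def test_all_small(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        dmap = edt_diameter(mask, (2, 2, 2))
        fr = bin_fractions(dmap)
        assert fr["0-5mm"] == 1.0 and fr["5-10mm"] == 0.0

    def test_one_voxel_per_bin(self):
        from hepavol.volumetry import DiameterMap

        values = np.array([[[4.0, 6.0, 12.0]]])
        mask = np.ones_like(values, dtype=bool)
        fr = bin_fractions(DiameterMap(values, mask))
        assert fr == {"0-5mm": pytest.approx(1 / 3), "5-10mm": pytest.approx(1 / 3),
                      ">10mm": pytest.approx(1 / 3)}

    def test_boundary_five_goes_to_middle_bin(self):
        from hepavol.volumetry import DiameterMap

        values = np.array([[[5.0]]])
        fr = bin_fractions(DiameterMap(values, np.ones_like(values, dtype=bool)))
        assert fr["5-10mm"] == 1.0

    def test_empty_map_raises(self):
        from hepavol.volumetry import DiameterMap

        empty = DiameterMap(np.full((2, 2, 2), np.nan), np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError):
            bin_fractions(empty)


class TestDice:
    def test_identical_and_disjoint_and_half(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :2] = True
        b = np.zeros_like(a)
        b[0, 0, 1:3] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(a, b) == 0.5  # |A|=|B|=2, overlap 1

    def test_both_empty_defined_as_one(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        assert dice(empty, empty) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    @given(st.integers(0, 2**24 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_property(self, packed):
        bits = np.array([(packed >> i) & 1 for i in range(24)], dtype=bool)
        a, b = bits[:12].reshape(3, 2, 2), bits[12:].reshape(3, 2, 2)
        assert dice(a, b) == dice(b, a)
        assert 0.0 <= dice(a, b) <= 1.0


class TestDiceByBin:
    @staticmethod
    def two_calibre_phantom():
        """Radius-2 mm branch plus radius-6 mm trunk, unit spacing."""
        shape = (40, 30, 30)
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        trunk = ((yy - 15) ** 2 + (xx - 15) ** 2) <= 36
        branch = ((zz - 20) ** 2 + (xx - 15) ** 2) <= 4
        branch &= yy < 9  # keep the thin branch away from the trunk
        return trunk | branch, trunk, branch

    def test_perfect_prediction_scores_one_everywhere(self):
        gt, _, _ = self.two_calibre_phantom()
        rep = dice_by_bin(gt, gt, (1, 1, 1))
        assert rep.overall_dice == 1.0
        defined = {k: v for k, v in rep.bin_dice.items() if np.isfinite(v)}
        assert defined and all(v == 1.0 for v in defined.values())

    def test_missing_thin_branch(self):
        """Dropping the thin branch from the prediction lowers only the
        small-calibre bin (the trunk's own shell voxels also live in the
        0-5 mm bin under the raw-EDT convention, so the drop is partial,
        not to zero)."""
        gt, trunk, branch = self.two_calibre_phantom()
        rep = dice_by_bin(trunk, gt, (1, 1, 1))
        perfect = dice_by_bin(gt, gt, (1, 1, 1))
        assert rep.bin_dice["0-5mm"] < perfect.bin_dice["0-5mm"] == 1.0
        assert rep.bin_dice["5-10mm"] == pytest.approx(1.0, abs=0.01)
        # voxel-count oracle: expected Dice of the 0-5 mm bin region
        from hepavol.volumetry import edt_diameter
        from scipy import ndimage as ndi

        dmap = edt_diameter(gt, (1, 1, 1))
        small = gt & (dmap.values_mm < 5)
        region = ndi.binary_dilation(small)
        a, b = trunk & region, gt & region
        expected = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert rep.bin_dice["0-5mm"] == pytest.approx(expected)

    def test_empty_prediction_zero_on_defined_bins(self):
        gt, _, _ = self.two_calibre_phantom()
        rep = dice_by_bin(np.zeros_like(gt), gt, (1, 1, 1))
        for v in rep.bin_dice.values():
            assert not np.isfinite(v) or v == 0.0
        assert rep.overall_dice == 0.0

    def test_empty_gt_bins_undefined(self):
        gt = np.zeros((8, 8, 8), dtype=bool)
        gt[4, 4, 4] = True  # only a sub-5mm structure
        rep = dice_by_bin(gt, gt, (1, 1, 1))
        assert rep.bin_dice["0-5mm"] == 1.0
        assert np.isnan(rep.bin_dice[">10mm"])


class TestVolumesAndRatios:
    def test_organ_volume_units(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        assert organ_volume(mask, (1, 1, 1)) == pytest.approx(1.0)
        assert organ_volume(mask, (1, 1, 2)) == pytest.approx(2.0)
        assert organ_volume(np.zeros((3, 3, 3)), (1, 1, 1)) == 0.0

    def test_ratio_arithmetic(self):
        # 21 cc hepatic, 17 cc portal inside a 1000 cc liver
        labels = np.zeros((100, 100, 100), dtype=np.uint8)
        flat = labels.reshape(-1)
        flat[:] = LABEL_LIVER
        flat[:21000] = LABEL_HEPATIC
        flat[21000:38000] = LABEL_PORTAL
        res = vessel_to_volume_ratios(flat.reshape(100, 100, 100), (1.0, 1.0, 1.0))
        assert res.hvvr_pct == pytest.approx(2.1)
        assert res.pvvr_pct == pytest.approx(1.7)
        assert res.tvvr_pct == pytest.approx(3.8)

    def test_no_vessels(self):
        labels = np.full((5, 5, 5), LABEL_LIVER, dtype=np.uint8)
        res = vessel_to_volume_ratios(labels, (1, 1, 1))
        assert res.tvvr_pct == res.hvvr_pct == res.pvvr_pct == 0.0

    def test_zero_liver_errors(self):
        with pytest.raises(ValueError):
            vessel_to_volume_ratios(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))

    @pytest.mark.parametrize("seed", range(8))
    def test_random_label_map_identities(self, seed):
        """TVVR = HVVR + PVVR exactly; spacing rescale leaves ratios fixed."""
        rng = np.random.default_rng(seed)
        labels = rng.choice([0, 1, 2, 3], size=(9, 9, 9), p=[0.3, 0.1, 0.1, 0.5]).astype(np.uint8)
        if not (labels > 0).any():
            labels[0, 0, 0] = 3
        r1 = vessel_to_volume_ratios(labels, (1.0, 1.5, 2.0))
        assert r1.tvvr_pct == r1.hvvr_pct + r1.pvvr_pct
        r2 = vessel_to_volume_ratios(labels, (2.0, 3.0, 4.0))
        assert r2.hvvr_pct == pytest.approx(r1.hvvr_pct)
        assert r2.pvvr_pct == pytest.approx(r1.pvvr_pct)
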