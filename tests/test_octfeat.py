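"""Extraction tests: trim geometry, band splitting, distances, composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhpredict import octfeat
from mhpredict.octfeat import (
    BACKGROUND,
    BLUE,
    GREEN,
    ONL_SDL,
    RED,
    SKY_BLUE,
    YELLOW,
    AmbiguousBandError,
    LayerMask,
    MissingDataError,
    MissingLayerError,
    NoHoleError,
    band_areas,
    compose_features,
    crop_to_trim,
    defect_length,
    hole_diameters,
    shortest_defect_length,
    split_band,
    trim_extent_mm,
    trim_field_degrees,
)


def flat_mask(gap_per_band=None, pitch=3.83, size=64, thicknesses=(8, 6, 4, 4), top=20):
    """Horizontal bands with optional centred per-band gaps (missing columns)."""
    gaps = gap_per_band or {}
    labels = np.zeros((size, size), dtype=np.int64)
    r = top
    cx = size // 2
    for cls, t in zip((GREEN, YELLOW, SKY_BLUE, BLUE), thicknesses):
        labels[r:r + t, :] = cls
        g = gaps.get(cls, 0)
        if g:
            labels[r:r + t, cx - g // 2:cx - g // 2 + g] = BACKGROUND
        r += t
    return LayerMask(labels, pitch, pitch)


class TestTrimGeometry:
    def test_crop_pitch_and_extent(self):
        src = np.zeros((496, 768), dtype=np.int64)
        mask = crop_to_trim(src, center=(248, 384))
        assert mask.shape == (256, 256)
        # 256 px at the axial pitch is 0.98 mm, subtending 3.26 deg (truncated)
        assert mask.pixel_pitch_x == pytest.approx(1900 / 496)
        assert round(trim_extent_mm(), 2) == 0.98
        assert math.floor(trim_field_degrees() * 100) / 100 == 3.26

    def test_corner_center_out_of_bounds(self):
        src = np.zeros((496, 768), dtype=np.int64)
        with pytest.raises(octfeat.OutOfBoundsError):
            crop_to_trim(src, center=(0, 0))

    def test_crop_idempotent(self):
        rng = np.random.default_rng(0)
        src = rng.integers(0, 6, size=(496, 768))
        once = crop_to_trim(src, center=(248, 384))
        twice = crop_to_trim(once.labels, center=(128, 128))
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestLayerMaskValidation:
    def test_rejects_bad_classes(self):
        with pytest.raises(octfeat.MaskError):
            LayerMask(np.full((4, 4), 9))

    def test_rejects_nonpositive_pitch(self):
        with pytest.raises(octfeat.MaskError):
            LayerMask(np.zeros((4, 4), dtype=np.int64), pixel_pitch_x=0.0)


class TestSplitBand:
    def test_two_flanking_components(self):
        labels = np.zeros((8, 256), dtype=np.int64)
        labels[2:4, 0:100] = SKY_BLUE
        labels[2:4, 180:256] = SKY_BLUE
        comps = split_band(LayerMask(labels), SKY_BLUE)
        assert comps.defect
        assert comps.left[:, 1].max() == 99
        assert comps.right[:, 1].min() == 180

    def test_unbroken_band_flags_no_defect(self):
        comps = split_band(flat_mask(), GREEN)
        assert not comps.defect and comps.right is None

    def test_missing_class(self):
        labels = np.zeros((8, 8), dtype=np.int64)
        labels[1] = GREEN
        with pytest.raises(MissingLayerError):
            split_band(LayerMask(labels), SKY_BLUE)

    def test_three_components_ambiguous(self):
        labels = np.zeros((8, 64), dtype=np.int64)
        labels[2, 0:10] = labels[2, 20:30] = labels[2, 50:60] = YELLOW
        with pytest.raises(AmbiguousBandError):
            split_band(LayerMask(labels), YELLOW)


class TestDefectLength:
    def test_flat_gap_is_missing_columns_times_pitch(self):
        mask = flat_mask({GREEN: 80, YELLOW: 80}, size=256, top=60)
        assert defect_length(mask, "OPL") == pytest.approx(80 * 3.83)  # 306.4 um

    def test_unbroken_interface_is_zero(self):
        assert defect_length(flat_mask(), "OPL") == 0.0

    def test_diagonal_endpoints_pythagorean(self):
        # 80 missing columns (88..167) with the right shoulder 18 px lower:
        # endpoints (19, 87) and (37, 168) -> DL = hypot(80, 18) px
        labels = np.zeros((64, 256), dtype=np.int64)
        labels[10:20, :88] = GREEN
        labels[20:30, :88] = YELLOW
        labels[28:38, 168:] = GREEN
        labels[38:48, 168:] = YELLOW
        mask = LayerMask(labels, 3.83, 3.83)
        expected = math.hypot(80, 18) * 3.83  # 314.1 um
        assert defect_length(mask, "OPL") == pytest.approx(expected)
        assert expected == pytest.approx(314.1, abs=0.05)

    def test_missing_layer(self):
        labels = np.zeros((8, 8), dtype=np.int64)
        labels[1] = GREEN
        with pytest.raises(MissingLayerError):
            defect_length(LayerMask(labels), "OPL")

    def test_unknown_boundary_name(self):
        with pytest.raises(ValueError):
            defect_length(flat_mask(), "RPE")


class TestShortestDefectLength:
    def test_collinear_single_pixels(self):
        labels = np.zeros((8, 64), dtype=np.int64)
        labels[3, 10] = labels[3, 20] = BLUE
        mask = LayerMask(labels, 3.83, 3.83)
        assert shortest_defect_length(mask, BLUE) == pytest.approx(10 * 3.83)

    def test_unbroken_band_is_zero(self):
        assert shortest_defect_length(flat_mask(), YELLOW) == 0.0

    def test_known_nearest_pair(self):
        # nearest pixels at (120, 99) and (124, 180): sqrt(81^2 + 4^2) px
        labels = np.zeros((200, 256), dtype=np.int64)
        labels[110:120, 0:99] = SKY_BLUE
        labels[120, 0:100] = SKY_BLUE
        labels[125:135, 181:256] = SKY_BLUE
        labels[124, 180:256] = SKY_BLUE
        mask = LayerMask(labels, 3.83, 3.83)
        expected = math.hypot(81, 4) * 3.83  # 310.6 um
        assert shortest_defect_length(mask, SKY_BLUE) == pytest.approx(expected)
        assert expected == pytest.approx(310.6, abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        """KD-tree minimum equals brute-force O(n^2) on small random masks."""
        rng = np.random.default_rng(seed)
        size = int(rng.integers(16, 64))
        labels = np.zeros((size, size), dtype=np.int64)
        r0 = int(rng.integers(2, size - 6))
        t = int(rng.integers(1, 4))
        gap = int(rng.integers(1, size // 2))
        cx = size // 2
        labels[r0:r0 + t, :cx - gap // 2] = YELLOW
        labels[r0:r0 + t, cx - gap // 2 + gap:] = YELLOW
        # jitter the component edges
        for _ in range(int(rng.integers(0, 8))):
            rr = int(rng.integers(max(0, r0 - 2), min(size, r0 + t + 2)))
            cc = int(rng.integers(0, size))
            if labels[rr, cc] == 0 and (cc < cx - gap // 2 - 1 or cc > cx - gap // 2 + gap):
                labels[rr, cc] = YELLOW
        mask = LayerMask(labels, 2.0, 2.0)
        try:
            result = shortest_defect_length(mask, YELLOW)
        except (AmbiguousBandError, MissingLayerError):
            return
        comps = split_band(mask, YELLOW)
        if not comps.defect:
            assert result == 0.0
            return
        brute = min(
            math.hypot((a[0] - b[0]) * 2.0, (a[1] - b[1]) * 2.0)
            for a in comps.left for b in comps.right
        )
        assert result == pytest.approx(brute)


class TestHoleDiameters:
    def test_rectangular_hole_min_equals_base(self):
        mask = flat_mask({GREEN: 40, YELLOW: 40, SKY_BLUE: 40, BLUE: 40})
        hole_min, bdm = hole_diameters(mask)
        assert hole_min == bdm == pytest.approx(40 * 3.83)

    def test_funnel_hole(self):
        # narrow waist 20 px, base 50 px
        labels = np.zeros((64, 64), dtype=np.int64)
        cx = 32
        labels[20:24, :] = GREEN
        labels[24:28, :] = YELLOW
        labels[28:30, :] = SKY_BLUE
        labels[30:34, :] = BLUE
        for r in range(20, 28):
            g = 20
            labels[r, cx - g // 2:cx - g // 2 + g] = BACKGROUND
        for r in range(28, 34):
            g = 50
            labels[r, cx - g // 2:cx - g // 2 + g] = BACKGROUND
        hole_min, bdm = hole_diameters(LayerMask(labels, 1.0, 1.0))
        assert hole_min == 20.0 and bdm == 50.0

    def test_no_cavity_raises(self):
        with pytest.raises(NoHoleError):
            hole_diameters(flat_mask())


class TestBandAreas:
    def test_rectangle_count(self):
        labels = np.zeros((64, 128), dtype=np.int64)
        labels[10:40, 5:105] = GREEN  # 30 x 100
        areas = band_areas(LayerMask(labels))
        assert areas["Area-green"] == 3000
        assert areas["Area IRF"] == 0

    def test_um2_flag(self):
        labels = np.zeros((8, 8), dtype=np.int64)
        labels[2, 2:4] = RED
        areas = band_areas(LayerMask(labels, 2.0, 3.0), in_um2=True)
        assert areas["Area IRF"] == pytest.approx(2 * 2.0 * 3.0)


class TestScaleEquivariance:
    def test_doubling_pitch_doubles_lengths_not_areas(self):
        mask1 = flat_mask({GREEN: 30, YELLOW: 24, SKY_BLUE: 20, BLUE: 26}, pitch=3.83)
        mask2 = LayerMask(mask1.labels, 2 * 3.83, 2 * 3.83)
        from mhpredict.octfeat import extract_morphometrics

        f1 = extract_morphometrics(mask1)
        f2 = extract_morphometrics(mask2)
        for name in ("OPL-DL", "ELM-DL", "EZ-DL", "Green-sDL", ONL_SDL,
                     "Sky blue-sDL", "Blue-sDL", "Hole-min", "BDM"):
            assert f2[name] == pytest.approx(2 * f1[name])
        for name in ("Area IRF", "Area-green", "Area-yellow", "Area-sky_blue", "Area-blue"):
            assert f2[name] == f1[name]


class TestComposeFeatures:
    @staticmethod
    def base_morpho(**overrides):
        morpho = {
            "BDM": 724.66, "Hole-min": 295.50, "OPL-DL": 465.09, "ELM-DL": 320.63,
            "EZ-DL": 359.00, "Green-sDL": 462.91, ONL_SDL: 313.28,
            "Sky blue-sDL": 297.13, "Blue-sDL": 372.25,
            "Area IRF": 1437.72, "Area-green": 7268.78, "Area-yellow": 5263.59,
            "Area-sky_blue": 1585.31, "Area-blue": 1701.56,
        }
        morpho.update(overrides)
        return morpho

    @staticmethod
    def base_clinical():
        return {
            "Sex": "Woman", "Age": 65.59, "Preoperative BCVA": 0.46,
            "Method": "Phaco+PPV", "Affected eye": "Right", "Axial length": 23.98,
            "Stage": "3", "Disease duration": 1.72, "ILM": "Peel",
            "VMT": "Present", "PVD": "Complete",
        }

    def test_published_mean_difference_identity(self):
        rec = compose_features(self.base_morpho(), self.base_clinical())
        # group-mean OPL-DL minus ONL-DL reproduces the printed difference row
        assert rec["(OPL-DL) - (ONL-DL)"] == pytest.approx(151.81, abs=1e-9)

    def test_equal_lengths_give_zero_diff_unit_ratio(self):
        rec = compose_features(self.base_morpho(**{"OPL-DL": 300.0, ONL_SDL: 300.0}),
                               self.base_clinical())
        assert rec["(OPL-DL) - (ONL-DL)"] == 0.0
        assert rec["(OPL-DL)/(ONL-DL)"] == 1.0

    def test_record_has_41_features(self):
        rec = compose_features(self.base_morpho(), self.base_clinical())
        assert len(rec) == 41
        assert set(rec) == set(octfeat.FEATURE_NAMES)

    def test_zero_denominator_flags_missing_data(self):
        with pytest.raises(MissingDataError):
            compose_features(self.base_morpho(**{"Hole-min": 0.0}), self.base_clinical())

    def test_unknown_categorical_level_rejected(self):
        clinical = self.base_clinical()
        clinical["Sex"] = "Unknown"
        with pytest.raises(MissingDataError):
            compose_features(self.base_morpho(), clinical)
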