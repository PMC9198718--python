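"""Gel lane synthesis and densitometry fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clc4pipe import (
    GelBand,
    GelLaneSpec,
    glycosylation_fraction,
    heterodimer_fraction,
    quantify_roi,
    synth_gel_lane,
)

HRCNE_BANDS = (
    GelBand("clc3_monomer", 134, 10.0),
    GelBand("clc4_monomer", 111, 10.0),
    GelBand("clc3_homodimer", 267, 10.0),
    GelBand("clc4_homodimer", 222, 10.0),
    GelBand("heterodimer_nonglyc", 245, 10.0),
    GelBand("heterodimer_glyc", 250, 10.0),
)


class TestLaneSynthesis:
    def test_single_band_area_preserved(self):
        spec = GelLaneSpec(bands=[GelBand("b", 100.0, 50.0)], noise_sd=0.0)
        lane = synth_gel_lane(spec, seed=0)
        area = quantify_roi(lane, 80, 140)["total"]
        assert area == pytest.approx(50.0, rel=1e-3)

    def test_band_outside_roi_contributes_nothing(self):
        spec = GelLaneSpec(bands=[GelBand("b", 300.0, 50.0)], noise_sd=0.0)
        lane = synth_gel_lane(spec, seed=0)
        assert abs(quantify_roi(lane, 80, 140)["total"]) < 0.5

    def test_migration_monotone_in_log_mw(self):
        spec = GelLaneSpec(bands=HRCNE_BANDS, noise_sd=0.0)
        lane = synth_gel_lane(spec, seed=0)
        mws = np.array([300, 250, 200, 150, 100, 50.0])
        pos = lane.mw_to_pos(mws)
        assert np.all(np.diff(pos) > 0)  # lighter species migrate farther
        np.testing.assert_allclose(lane.pos_to_mw(pos), mws, rtol=1e-10)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GelLaneSpec(bands=[GelBand("x", 100, 1.0), GelBand("x", 120, 1.0)])

    def test_determinism(self):
        spec = GelLaneSpec(bands=HRCNE_BANDS, noise_sd=1.0)
        a = synth_gel_lane(spec, seed=5)
        b = synth_gel_lane(spec, seed=5)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestFractions:
    def test_one_to_three_ratio_gives_25_percent(self):
        bands = (GelBand("glyc", 120.0, 1.0), GelBand("nonglyc", 100.0, 3.0))
        lane = synth_gel_lane(GelLaneSpec(bands=bands, noise_sd=0.0), seed=0)
        areas = quantify_roi(lane, 80, 140, bands=bands)
        frac = glycosylation_fraction(areas["glyc"], areas["nonglyc"])
        assert frac.fraction == pytest.approx(0.25, abs=0.01)

    def test_glycosylation_arithmetic_and_edge_cases(self):
        assert glycosylation_fraction(25, 75).fraction == pytest.approx(0.25)
        assert glycosylation_fraction(0, 10).fraction == 0.0
        with pytest.raises(ValueError):
            glycosylation_fraction(0.0, 0.0)

    def test_heterodimer_only_bands_give_one(self):
        res = heterodimer_fraction({"heterodimer_glyc": 2.0,
                                    "heterodimer_nonglyc": 3.0})
        assert res.fraction == 1.0

    def test_equal_six_bands_two_heterodimeric_give_one_third(self):
        table = {b.label: 1.0 for b in HRCNE_BANDS}
        assert heterodimer_fraction(table).fraction == pytest.approx(1 / 3)

    def test_missing_heterodimer_label_rejected(self):
        with pytest.raises(ValueError):
            heterodimer_fraction({"clc4_monomer": 1.0})
        with pytest.raises(ValueError):
            heterodimer_fraction({"heterodimer_glyc": 1.0},
                                 hetero_labels=["absent_band"])

    def test_hrcne_lane_round_trip(self):
        """Designed species proportions recovered from a noisy lane."""
        spec = GelLaneSpec(bands=HRCNE_BANDS, noise_sd=0.5)
        lane = synth_gel_lane(spec, seed=2)
        areas = quantify_roi(lane, 90, 320, bands=HRCNE_BANDS)
        frac = heterodimer_fraction({k: v for k, v in areas.items()
                                     if k != "total"})
        assert frac.fraction == pytest.approx(1 / 3, abs=0.02)

    def test_overlapping_bands_decomposed_within_5_percent(self):
        bands = (GelBand("a", 240.0, 30.0), GelBand("b", 260.0, 18.0))
        lane = synth_gel_lane(GelLaneSpec(bands=bands, noise_sd=0.0), seed=0)
        areas = quantify_roi(lane, 180, 320, bands=bands)
        assert areas["a"] == pytest.approx(30.0, rel=0.05)
        assert areas["b"] == pytest.approx(18.0, rel=0.05)


class TestInvariances:
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_fractions_invariant_under_exposure_rescaling(self, scale):
        g, n = 12.0, 30.0
        base = glycosylation_fraction(g, n).fraction
        assert glycosylation_fraction(scale * g, scale * n).fraction == \
            pytest.approx(base, rel=1e-12)
        table = {b.label: i + 1.0 for i, b in enumerate(HRCNE_BANDS)}
        base_h = heterodimer_fraction(table).fraction
        scaled = {k: scale * v for k, v in table.items()}
        assert heterodimer_fraction(scaled).fraction == \
            pytest.approx(base_h, rel=1e-12)

    def test_roi_additivity_over_disjoint_regions(self):
        bands = (GelBand("a", 100.0, 20.0), GelBand("b", 200.0, 40.0))
        lane = synth_gel_lane(GelLaneSpec(bands=bands, noise_sd=0.0), seed=0)
        full = quantify_roi(lane, 80, 320)["total"]
        left = quantify_roi(lane, 80, 150)["total"]
        right = quantify_roi(lane, 150, 320)["total"]
        assert left + right == pytest.approx(full, rel=1e-6)

    @given(f=st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=10, deadline=None)
    def test_designed_fraction_round_trip(self, f):
        """Any designed glycosylated fraction is recovered within 2%."""
        total = 40.0
        bands = (GelBand("glyc", 120.0, f * total),
                 GelBand("nonglyc", 100.0, (1 - f) * total))
        lane = synth_gel_lane(GelLaneSpec(bands=bands, noise_sd=0.3), seed=1)
        areas = quantify_roi(lane, 80, 140, bands=bands)
        frac = glycosylation_fraction(areas["glyc"], areas["nonglyc"])
        assert frac.fraction == pytest.approx(f, abs=0.02)

    def test_roi_outside_calibration_rejected(self):
        lane = synth_gel_lane(
            GelLaneSpec(bands=[GelBand("b", 100.0, 1.0)]), seed=0)
        with pytest.raises(ValueError):
            quantify_roi(lane, 1.0, 2.0)
        with pytest.raises(ValueError):
            quantify_roi(lane, 140.0, 80.0)
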