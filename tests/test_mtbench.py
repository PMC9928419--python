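"""Spot detection, filtering, slope scoring, SSMD, hit calls, dose-response."""

import numpy as np
import pandas as pd
import pytest

from rpitriage import synthetic
from rpitriage.mtbench import (
    call_hits,
    detect_spots,
    enrichment,
    filter_spots,
    fit_dose_response,
    normalize_plate,
    score_plate,
    slopes_by_well,
    ssmd,
    well_slope,
)


def bars_and_disks_image():
    """5 horizontal 3×20 px bars and 3 disks of radius 5 on flat background."""
    gfp = np.full((120, 120), 10.0)
    mrna = np.full((120, 120), 50.0)
    planted = []
    for i in range(5):
        sl = (slice(10 + 20 * i, 13 + 20 * i), slice(5, 25))
        gfp[sl] = 200.0
        mrna[sl] = 50.0 * (1.0 + 0.1 * i)
        planted.append(50.0 * (1.0 + 0.1 * i))
    yy, xx = np.mgrid[:120, :120]
    for cy in (20, 60, 100):
        disk = (yy - cy) ** 2 + (xx - 60) ** 2 <= 25
        gfp[disk] = 200.0
        mrna[disk] = 60.0
    return gfp, mrna, planted


class TestDetectSpots:
    def test_blank_image_gives_no_spots(self):
        blank = np.full((50, 50), 7.0)
        assert len(detect_spots(blank, blank)) == 0

    def test_constructed_geometry(self):
        gfp, mrna, _ = bars_and_disks_image()
        spots = detect_spots(gfp, mrna)
        assert len(spots) == 8
        ratios = (spots["width"] / spots["length"]).sort_values()
        assert np.allclose(ratios.iloc[:5], 0.15, atol=0.01)   # bars
        assert np.allclose(ratios.iloc[5:], 1.0, atol=0.01)    # disks
        lengths = spots["length"].sort_values()
        # bar long axis: 4·sqrt(20²/12); disk: 2r within quantisation
        assert np.allclose(lengths.iloc[3:8][:5].iloc[:3], 4 * np.sqrt(400 / 12),
                           atol=0.2)

    def test_planted_mrna_means_recovered(self):
        gfp, mrna, planted = bars_and_disks_image()
        spots = detect_spots(gfp, mrna)
        bars = spots[spots["width"] / spots["length"] < 0.22]
        got = sorted(bars["mrna_spot"].round(6))
        assert got == pytest.approx(sorted(planted))

    def test_saturated_image_warns(self):
        img = np.full((30, 30), 100, dtype=np.uint16)
        img[5:8, 5:25] = np.iinfo(np.uint16).max
        with pytest.warns(UserWarning, match="saturated"):
            detect_spots(img, np.asarray(img, float))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((5, 5)), np.zeros((6, 5)))


class TestFilterSpots:
    def spot_frame(self, ratios):
        return pd.DataFrame({
            "well": "W1", "cell": 0, "spot": range(len(ratios)),
            "gfp_mean": 100.0, "mrna_spot": 50.0, "mrna_cyto": 50.0,
            "width": [20.0 * r for r in ratios], "length": 20.0,
        })

    def test_boundary_ratio_excluded(self):
        out = filter_spots(self.spot_frame([0.22]))
        assert len(out) == 0

    def test_hand_survivor_count(self):
        out = filter_spots(self.spot_frame([0.10, 0.21, 0.22, 0.30, 0.15]))
        assert len(out) == 3

    def test_subset_and_idempotent(self):
        df = self.spot_frame([0.1, 0.25, 0.18, 0.3])
        once = filter_spots(df)
        assert set(once.index) <= set(df.index)
        pd.testing.assert_frame_equal(filter_spots(once), once)

    def test_bait_enrichment_cutoff(self):
        df = self.spot_frame([0.1, 0.1])
        df["gfp_cyto"] = [10.0, 60.0]   # second spot only 1.7× cytoplasm
        assert len(filter_spots(df)) == 1


class TestEnrichmentAndSlope:
    def test_spot_equals_cytoplasm(self):
        df = pd.DataFrame({"mrna_spot": [50.0], "mrna_cyto": [50.0]})
        assert enrichment(df).iloc[0] == 1.0

    def test_hand_ratio_and_zero_cyto_dropped(self):
        df = pd.DataFrame({"mrna_spot": [150.0, 80.0], "mrna_cyto": [100.0, 0.0]})
        with pytest.warns(UserWarning, match="cytoplasm"):
            out = enrichment(df)
        assert list(out) == [1.5]

    def well(self, x, y):
        return pd.DataFrame({"well": "W1", "cell": 0, "spot": range(len(x)),
                             "gfp_mean": x, "mrna_spot": 100 * np.asarray(y),
                             "mrna_cyto": 100.0,
                             "width": 2.0, "length": 20.0})

    def test_constant_enrichment_zero_slope(self):
        fit = well_slope(self.well(np.arange(40.0), np.ones(40)), min_spots=30)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols(self):
        fit = well_slope(self.well([1.0, 2.0, 3.0], [1.0, 1.2, 1.4]),
                         min_spots=3)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(0.8)
        assert fit.ci95_low <= fit.slope <= fit.ci95_high

    def test_too_few_spots_flagged(self):
        fit = well_slope(self.well([1.0, 2.0], [1.0, 1.2]))
        assert not fit.usable

    def test_zero_bait_variance_flagged(self):
        fit = well_slope(self.well(np.ones(40), np.ones(40)), min_spots=30)
        assert not fit.usable

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 100)
        y = 1 + 0.15 * x + rng.normal(0, 0.05, 100)
        f1 = well_slope(self.well(x, y), min_spots=30)
        f3 = well_slope(self.well(3 * x, y), min_spots=30)
        assert f3.slope == pytest.approx(f1.slope / 3)


class TestPlateStats:
    def layout(self):
        return synthetic.default_layout(n_dmso=4, n_negative=4,
                                        compounds={"A": 10.0})

    def test_normalization_anchors(self):
        lay = self.layout()
        slopes = pd.Series({"W001": 0.14, "W002": 0.16, "W003": 0.15,
                            "W004": 0.15, "W005": 0.0, "W006": 0.02,
                            "W007": -0.02, "W008": 0.0,
                            "W009": 0.075, "W010": 0.075, "W011": 0.075,
                            "W012": 0.075})
        norm = normalize_plate(slopes, lay)
        dmso = lay.loc[lay.role == "dmso", "well"]
        gfp = lay.loc[lay.role == "negative", "well"]
        assert norm[dmso].mean() == pytest.approx(1.0)
        assert norm[gfp].mean() == pytest.approx(0.0, abs=1e-12)
        # halfway between control means → 0.5
        assert norm["W009"] == pytest.approx(0.5)
        # already-normalized slopes are a fixed point
        pd.testing.assert_series_equal(normalize_plate(norm, lay), norm)

    def test_missing_controls_rejected(self):
        lay = self.layout()
        slopes = pd.Series({"W001": 0.15})
        with pytest.raises(ValueError, match="wells"):
            normalize_plate(slopes, lay)

    def test_ssmd_identical_groups_zero(self):
        g = [1.0, 1.1, 0.9, 1.0]
        assert ssmd(g, g) == 0.0

    def test_ssmd_antisymmetric_and_affine_invariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 0.1, 48), rng.normal(0, 0.1, 48)
        v = ssmd(a, b)
        assert ssmd(b, a) == pytest.approx(-v)
        assert ssmd(3 * a + 2, 3 * b + 2) == pytest.approx(v)

    def test_ssmd_pooled_variant_sqrt2_for_equal_sds(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 0.1, 500), rng.normal(0, 0.1, 500)
        assert (ssmd(a, b, variant="pooled")
                == pytest.approx(np.sqrt(2) * ssmd(a, b), rel=0.05))

    def test_ssmd_degenerate_inputs(self):
        with pytest.raises(ValueError, match="2 wells"):
            ssmd([1.0], [0.0, 0.1])
        with pytest.raises(ValueError, match="variance"):
            ssmd([1.0, 1.0], [0.0, 0.0])


class TestCallHits:
    def layout(self, compounds=("A", "B")):
        return synthetic.default_layout(n_dmso=4, n_negative=0,
                                        compounds={c: 10.0 for c in compounds})

    def slopes(self, lay, values):
        return pd.Series(values, index=lay["well"].tolist())

    def test_jittered_dmso_equivalent_not_significant(self):
        lay = self.layout(compounds=("A",))
        vals = [1.00, 1.02, 0.98, 1.01, 0.99, 1.03, 0.97, 1.00]
        hits = call_hits(self.slopes(lay, vals), lay)
        assert not hits.loc["A", "significant"]

    def test_hand_paired_decrease_is_significant(self):
        lay = self.layout(compounds=("A",))
        vals = [1.00, 1.02, 0.98, 1.01, 0.80, 0.82, 0.78, 0.81]
        hits = call_hits(self.slopes(lay, vals), lay)
        assert hits.loc["A", "significant"]
        assert hits.loc["A", "p_value"] < 0.05

    def test_increase_never_called_hit(self):
        lay = self.layout(compounds=("A",))
        vals = [1.00, 1.02, 0.98, 1.01, 1.20, 1.22, 1.18, 1.21]
        hits = call_hits(self.slopes(lay, vals), lay)
        assert hits.loc["A", "p_value"] < 0.05
        assert not hits.loc["A", "significant"]

    def test_bh_correction_available(self):
        lay = self.layout()
        vals = [1.00, 1.02, 0.98, 1.01,
                0.80, 0.82, 0.78, 0.81, 0.99, 1.01, 1.00, 0.98]
        hits = call_hits(self.slopes(lay, vals), lay, correction="bh")
        assert "p_adjusted" in hits.columns
        assert hits["p_adjusted"].ge(hits["p_value"] - 1e-15).all()


class TestScorePlateAndDose:
    def test_planted_inhibitor_called_and_null_spared(self):
        lay = synthetic.default_layout(n_dmso=6, n_negative=6,
                                       compounds={"HIT": 10.0, "NULL": 10.0})
        spots, truth = synthetic.gen_plate(
            seed=13, layout=lay, compound_slope_factors={"HIT": 0.5})
        stats = score_plate(spots, lay)
        assert stats.hit_calls.loc["HIT", "significant"]
        assert not stats.hit_calls.loc["NULL", "significant"]
        assert stats.ssmd > 3.0

    def test_flat_dose_response_flagged(self):
        pts = pd.DataFrame({"conc_uM": np.geomspace(0.098, 50, 10),
                            "response": np.ones(10)})
        fit = fit_dose_response(pts, "flat")
        assert not fit.fit_ok
        assert "flat" in fit.note

    def test_recovers_planted_ec50_in_median(self):
        # EC50 from a noisy 10-point twofold series is itself noisy; the
        # median recovery over seeds is the meaningful accuracy measure
        ec50s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            conc = 50.0 / 2 ** np.arange(10)  # 0.098–50 µM twofold series
            resp = 0.1 + 0.9 / (1 + (conc / 10.0)) + rng.normal(0, 0.05, 10)
            fit = fit_dose_response(pd.DataFrame({"conc_uM": conc,
                                                  "response": resp}), "P1")
            if fit.fit_ok:
                ec50s.append(fit.ec50)
        assert len(ec50s) >= 15
        assert np.median(ec50s) == pytest.approx(10.0, rel=0.15)

    def test_narrow_range_rejected(self):
        pts = pd.DataFrame({"conc_uM": [1.0, 2.0, 3.0, 4.0, 5.0],
                            "response": [1.0, 0.9, 0.8, 0.7, 0.6]})
        with pytest.raises(ValueError, match="log units"):
            fit_dose_response(pts)


def test_slopes_by_well_recovers_planted_slopes():
    spots, truth = synthetic.gen_plate(
        seed=3, layout=synthetic.default_layout(n_dmso=3, n_negative=3),
        well_slope_jitter=0.0)
    fits = slopes_by_well(spots)
    covered = 0
    for well, fit in fits.iterrows():
        assert fit["slope"] == pytest.approx(truth.slopes[well], abs=0.02)
        if fit["ci95_low"] <= truth.slopes[well] <= fit["ci95_high"]:
            covered += 1
    assert covered >= len(fits) - 1  # individual CIs miss ~5% of the time
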