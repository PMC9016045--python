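import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats as sps

from iraequant import (
    CohortSpec,
    IraeEvent,
    PhantomSpecError,
    PhantomSpec,
    apply_irae,
    build_phantom,
    invert_ci,
    organ_percentiles,
    sample_uptake,
    simulate_cohort,
    simulate_profile_table,
)
from iraequant.imaging import ORGANS
from iraequant.phantom import OrganUptakeParams, UptakeModel, focal_region

from conftest import COARSE_PHANTOM


class TestBuildPhantom:
    def test_default_phantom_has_disjoint_organs(self, default_mask):
        counts = default_mask.organ_counts()
        assert all(counts[o] >= 10 for o in ORGANS)
        # disjoint by construction: one label per voxel, so the sum of organ
        # counts must equal the number of labelled voxels
        assert sum(counts.values()) == int((default_mask.labels > 0).sum())

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(PhantomSpecError):
            build_phantom(PhantomSpec(thyroid_semiaxes=(0.0, 9.0, 18.0)))

    def test_organ_exceeding_grid_rejected(self):
        with pytest.raises(PhantomSpecError):
            build_phantom(PhantomSpec(lung_semiaxes=(34.0, 40.0, 300.0)))

    def test_deterministic(self):
        a = build_phantom(PhantomSpec())
        b = build_phantom(PhantomSpec())
        assert np.array_equal(a.labels, b.labels)

    def test_voxel_counts_scale_with_resolution(self, default_mask):
        fine = build_phantom(PhantomSpec(dims=(128, 128, 192), spacing=(2.0, 2.0, 2.0)))
        for organ in ORGANS:
            ratio = fine.organ_counts()[organ] / default_mask.organ_counts()[organ]
            assert 8 * 0.8 <= ratio <= 8 * 1.2


class TestSampleUptake:
    def test_same_seed_bit_identical(self, coarse_mask, uptake_model):
        a = sample_uptake(coarse_mask, uptake_model, 7)
        b = sample_uptake(coarse_mask, uptake_model, 7)
        assert np.array_equal(a.voxels, b.voxels)

    def test_degenerate_model_gives_exact_location(self, coarse_mask):
        model = UptakeModel(
            organs={"bowel": OrganUptakeParams(location=0.5, scale=0.0, patient_sd=0.0)},
            background_sd=0.0, psf_fwhm_mm=0.0, noise_sd=0.0,
        )
        suv = sample_uptake(coarse_mask, model, 0)
        organ_vals = suv.voxels[coarse_mask.organ_voxels("bowel")]
        assert np.allclose(organ_vals, np.exp(0.5), rtol=1e-6)

    def test_organ_median_matches_lognormal_closed_form(self, default_mask):
        model = UptakeModel(
            organs={"lung": OrganUptakeParams(location=0.2, scale=0.3, patient_sd=0.0)},
            background_sd=0.0, psf_fwhm_mm=0.0, noise_sd=0.0,
        )
        suv = sample_uptake(default_mask, model, 1)
        vals = suv.voxels[default_mask.organ_voxels("lung")]  # ~1e4 voxels
        # log-normal median = exp(location); MC error ~ 1.25 sigma/sqrt(n)
        tol = 3 * 1.25 * 0.3 / np.sqrt(vals.size)
        assert np.log(np.median(vals)) == pytest.approx(0.2, abs=tol)


def uniform_organ_suv(mask, value=1.0):
    from iraequant import ScanMeta, SUVVolume

    vox = np.full(mask.grid.dims, 0.1, dtype=np.float32)
    vox[mask.labels > 0] = value
    return SUVVolume(grid=mask.grid, voxels=vox,
                     meta=ScanMeta("P", 0, suv_precomputed=True))


class TestApplyIrae:
    def test_pre_onset_scan_unchanged(self, coarse_mask):
        suv = uniform_organ_suv(coarse_mask)
        event = IraeEvent(organ="bowel", pattern="diffuse", onset_day=100, k=2.0)
        out = apply_irae(suv, coarse_mask, event, scan_day=50)
        assert np.array_equal(out.voxels, suv.voxels)

    def test_diffuse_plateau_doubles_every_percentile(self, coarse_mask, uptake_model):
        suv = sample_uptake(coarse_mask, replace(uptake_model, noise_sd=0.0), 3)
        event = IraeEvent(organ="thyroid", pattern="diffuse", onset_day=0, k=2.0)
        out = apply_irae(suv, coarse_mask, event, scan_day=60)  # past the 30-day ramp
        grid = list(range(5, 101, 5))
        base = organ_percentiles(suv.voxels[coarse_mask.organ_voxels("thyroid")], grid).suv
        bumped = organ_percentiles(out.voxels[coarse_mask.organ_voxels("thyroid")], grid).suv
        assert np.allclose(bumped, 2.0 * base, rtol=1e-6)

    def test_focal_order_statistics(self, coarse_mask):
        # 10% of a uniform organ multiplied by 3: SUV_95% -> 3, SUV_75% stays 1
        suv = uniform_organ_suv(coarse_mask, value=1.0)
        event = IraeEvent(organ="bowel", pattern="focal", onset_day=0, k=3.0,
                          focal_fraction=0.10)
        out = apply_irae(suv, coarse_mask, event, scan_day=90)
        vals = out.voxels[coarse_mask.organ_voxels("bowel")]
        prof = organ_percentiles(vals, [75, 95])
        assert prof.suv[0] == pytest.approx(1.0)
        assert prof.suv[1] == pytest.approx(3.0)

    def test_focal_raises_high_percentiles_more_than_low(self, coarse_mask, uptake_model):
        suv = sample_uptake(coarse_mask, replace(uptake_model, noise_sd=0.0), 5)
        event = IraeEvent(organ="lung", pattern="focal", onset_day=0, k=2.5,
                          focal_fraction=0.1)
        out = apply_irae(suv, coarse_mask, event, scan_day=60)
        sel = coarse_mask.organ_voxels("lung")
        base = organ_percentiles(suv.voxels[sel], [25, 50, 95, 100]).suv
        bumped = organ_percentiles(out.voxels[sel], [25, 50, 95, 100]).suv
        lifts = bumped / base
        assert lifts[2] > lifts[0] and lifts[3] > lifts[1]

    def test_focal_region_connected_and_sized(self, default_mask):
        region = focal_region(default_mask, "bowel", 0.1, seed=9)
        n_organ = default_mask.organ_counts()["bowel"]
        assert region.sum() == round(0.1 * n_organ)
        from scipy import ndimage

        _, n_components = ndimage.label(region)
        assert n_components == 1

    def test_ramp_boundaries(self):
        e = IraeEvent(organ="bowel", pattern="diffuse", onset_day=10, k=3.0)
        assert e.multiplier(9) == 1.0
        assert e.multiplier(10) == 1.0
        assert e.multiplier(25) == pytest.approx(2.0)  # midpoint: half the rise
        assert e.multiplier(40) == 3.0
        assert e.multiplier(1000) == 3.0

    def test_resolution_decay(self):
        e = IraeEvent(organ="bowel", pattern="diffuse", onset_day=0, k=3.0,
                      resolution_day=100, recovery_days=60)
        assert e.multiplier(99) == 3.0
        assert e.multiplier(130) == pytest.approx(2.0)
        assert e.multiplier(160) == 1.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(PhantomSpecError):
            IraeEvent(organ="bowel", pattern="focal", onset_day=0, k=2.0, focal_fraction=1.5)


class TestCohortSimulation:
    def test_fixed_seed_reproducible(self):
        spec = CohortSpec(n_patients=3, seed=5)
        p1, l1, t1 = simulate_profile_table(spec, COARSE_PHANTOM)
        p2, l2, t2 = simulate_profile_table(spec, COARSE_PHANTOM)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_prevalence_cohort_has_no_events(self):
        spec = CohortSpec(n_patients=4, prevalence={o: 0.0 for o in ORGANS}, seed=1)
        cohort = simulate_cohort(spec, COARSE_PHANTOM, keep_volumes=False)
        assert cohort.truth_table().empty
        labels = cohort.labels_table()
        assert (labels["label"] == 0).all()

    def test_event_counts_match_binomial_expectation(self):
        # mean per-organ event counts over seeds ~ n * prevalence
        from iraequant.phantom import simulate_truth_only

        counts = {o: [] for o in ORGANS}
        spec0 = CohortSpec(n_patients=58)
        for seed in range(20):
            spec = CohortSpec(n_patients=58, seed=seed)
            truth = simulate_truth_only(spec).truth_table()
            by = truth.groupby("organ").size() if not truth.empty else {}
            for o in ORGANS:
                counts[o].append(int(by.get(o, 0)))
        for o, expected in (("bowel", 6), ("lung", 5), ("thyroid", 9)):
            n, p = 58, spec0.prevalence[o]
            se = np.sqrt(n * p * (1 - p) / 20)
            assert abs(np.mean(counts[o]) - expected) < 4 * se

    def test_truth_table_consistent_with_profiles(self):
        spec = CohortSpec(n_patients=6, prevalence={"bowel": 0.0, "lung": 0.0, "thyroid": 1.0},
                          onset_range=(10, 20), k_range=(2.5, 3.0), seed=3)
        profiles, labels, truth = simulate_profile_table(spec, COARSE_PHANTOM)
        assert set(truth["organ"]) == {"thyroid"}
        # flagged organs actually modified: late thyroid scans exceed baselines
        for pid in truth["patient_id"]:
            sub = profiles[(profiles.patient_id == pid) & (profiles.organ == "thyroid")
                           & (profiles.percentile == 75)].sort_values("scan_day")
            assert sub["suv_gml"].iloc[-1] > 1.5 * sub["suv_gml"].iloc[0]

    def test_unaffected_organs_show_no_trend(self):
        spec = CohortSpec(n_patients=25, prevalence={o: 0.0 for o in ORGANS},
                          extra_scans_mean=2.0, seed=11)
        profiles, _, _ = simulate_profile_table(spec, COARSE_PHANTOM, grid=[95])
        on = profiles[profiles.scan_day >= 0].copy()
        on["centered"] = on.groupby(["patient_id", "organ"])["suv_gml"].transform(
            lambda v: v - v.mean()
        )
        res = sps.linregress(on["scan_day"], on["centered"])
        assert res.pvalue > 0.01  # slope indistinguishable from zero


class TestCalibrateBaseline:
    def test_round_trip_reproduces_published_bands(self):
        """Calibrating from a perturbed start recovers baseline statistics whose
        normative band matches the published endpoints within 10% relative."""
        from iraequant import calibrate_baseline, default_uptake_model, normal_range
        from iraequant.phantom import PUBLISHED_NORMAL_RANGES, simulate_baseline_opt_values

        start = default_uptake_model()
        organs = {
            o: replace(p, location=p.location + 0.15, patient_sd=p.patient_sd * 1.3)
            for o, p in start.organs.items()
        }
        cal = calibrate_baseline(replace(start, organs=organs),
                                 n_patients=200, max_iter=12, seed=314)
        draws = simulate_baseline_opt_values(cal, 200, seed=315)
        for organ, band in PUBLISHED_NORMAL_RANGES.items():
            got = normal_range(draws.loc[draws.organ == organ, "value"], organ=organ)
            assert got.lo == pytest.approx(band["lo"], rel=0.10)
            assert got.hi == pytest.approx(band["hi"], rel=0.10)

    def test_non_convergence_reports_diagnostics(self):
        from iraequant import CalibrationError, calibrate_baseline, default_uptake_model

        targets = {"bowel": {"percentile": 95, "mu": 50.0, "sigma": 0.01}}
        with pytest.raises(CalibrationError) as err:
            calibrate_baseline(default_uptake_model(), targets,
                               n_patients=5, max_iter=2, seed=0)
        assert "history" in err.value.diagnostics


class TestCalibrationTargets:
    def test_ci_inversion_round_trip(self):
        for lo, hi in [(1.74, 2.86), (0.73, 1.46), (0.86, 1.99)]:
            mu, sigma = invert_ci(lo, hi)
            assert mu - 1.96 * sigma == pytest.approx(lo)
            assert mu + 1.96 * sigma == pytest.approx(hi)

    def test_printed_band_inversions(self):
        assert invert_ci(1.74, 2.86) == pytest.approx((2.30, 0.2857), abs=1e-4)
        assert invert_ci(0.73, 1.46) == pytest.approx((1.095, 0.1862), abs=1e-4)
        assert invert_ci(0.86, 1.99) == pytest.approx((1.425, 0.2883), abs=1e-4)
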