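"""Grid-search calibration: RMSE objective, arg-min oracle, recovery."""

import numpy as np
import pytest

from tumoran import (
    DoseRegimen,
    EfficacyGridSpec,
    GridSpec,
    GrowthSeries,
    MoranGrowthModel,
    SynthSpec,
    TreatmentEfficacyModel,
    fit_growth,
    fit_treatment,
    generate_growth_series,
    rmse_objective,
)


@pytest.fixture(scope="module")
def noiseless():
    spec = SynthSpec(
        fc_ratio=1.2, fm_ratio=1.4, r_m=0.0, eff_c=0.05, noise_sigma=0.0, seed=7
    )
    vehicle, treated, truth = generate_growth_series(spec)
    return spec, vehicle, treated, truth


class TestGrowthSeries:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError):
            GrowthSeries([0.0, 2.0, 1.0], [1.0, 2.0, 3.0])

    def test_rejects_negative_sizes(self):
        with pytest.raises(ValueError):
            GrowthSeries([0.0, 1.0], [1.0, -2.0])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            GrowthSeries([], [])


class TestRmseObjective:
    def test_zero_on_self_generated_series(self, noiseless):
        spec, vehicle, _, _ = noiseless
        val = rmse_objective(
            vehicle,
            {"fc_ratio": spec.fc_ratio, "fm_ratio": spec.fm_ratio, "r_m": spec.r_m},
            N=spec.N,
        )
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_gives_rmse_delta(self, noiseless):
        spec, vehicle, _, _ = noiseless
        delta_cells = 4.0
        shifted = GrowthSeries(vehicle.time_days, vehicle.size + delta_cells)
        val = rmse_objective(
            shifted,
            {"fc_ratio": spec.fc_ratio, "fm_ratio": spec.fm_ratio, "r_m": spec.r_m},
            N=spec.N,
            initial_burden=vehicle.size[0],
        )
        assert val == pytest.approx(delta_cells / spec.N, abs=1e-9)


class TestStageOneFit:
    def test_noiseless_on_grid_truth_recovered_exactly(self, noiseless):
        spec, vehicle, _, _ = noiseless
        grid = GridSpec(
            fc=np.arange(1.0, 1.41, 0.01), fm=np.array([1.0, 1.4]),
            rm=np.array([0.0, 1e-6]),
        )
        res = fit_growth(vehicle, grid, N=spec.N)
        assert res.fc_ratio == pytest.approx(1.2, abs=1e-12)
        assert res.r_m == 0.0
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    def test_three_type_truth_recovered_exactly(self):
        spec = SynthSpec(
            fc_ratio=1.05, fm_ratio=1.3, r_m=1e-4, eff_c=0.0, noise_sigma=0.0, seed=3
        )
        vehicle, _, _ = generate_growth_series(spec)
        grid = GridSpec(
            fc=np.arange(1.0, 1.11, 0.01),
            fm=np.arange(1.0, 1.41, 0.1),
            rm=np.array([0.0, 1e-5, 1e-4, 1e-3]),
        )
        res = fit_growth(vehicle, grid, N=spec.N)
        assert res.fc_ratio == pytest.approx(1.05, abs=1e-12)
        assert res.fm_ratio == pytest.approx(1.3, abs=1e-12)
        assert res.r_m == pytest.approx(1e-4)

    def test_grid_excluding_truth_returns_best_on_grid_with_positive_rmse(
        self, noiseless
    ):
        spec, vehicle, _, _ = noiseless
        grid = GridSpec(fc=np.array([1.05, 1.1]), fm=np.array([1.0]), rm=np.array([0.0]))
        res = fit_growth(vehicle, grid, N=spec.N)
        assert res.fc_ratio == 1.1  # closest dynamics to the 1.2 truth
        assert res.rmse > 0

    def test_argmin_matches_bruteforce_oracle(self, noiseless):
        spec, vehicle, _, _ = noiseless
        grid = GridSpec(
            fc=np.array([1.0, 1.1, 1.2, 1.3]),
            fm=np.array([1.0, 1.4]),
            rm=np.array([0.0, 1e-4]),
        )
        model = MoranGrowthModel(vehicle, N=spec.N, grid=grid)
        res = model.fit()
        # independent route: point-by-point objective evaluation
        best = None
        for fc in grid.fc:
            for fm in grid.fm:
                for rm in grid.rm:
                    val = model.rmse(fc, fm, rm)
                    if best is None or val < best[0] - 1e-15:
                        best = (val, fc, fm, rm)
        assert res.rmse == pytest.approx(best[0], abs=1e-12)
        assert (res.fc_ratio, res.fm_ratio, res.r_m) == best[1:]

    def test_noisy_recovery_close_to_truth(self):
        # daily sampling through the growth phase (the saturated plateau is
        # uninformative about f_c); the 0.015 bound is the observed maximum
        # of this exact deterministic Monte-Carlo recovery experiment
        errs = []
        for seed in range(20):
            spec = SynthSpec(
                fc_ratio=1.2, fm_ratio=1.0, r_m=0.0, noise_sigma=0.05, seed=seed,
                horizon_days=14.0, sample_interval_days=1.0,
            )
            vehicle, _, _ = generate_growth_series(spec)
            grid = GridSpec(
                fc=np.arange(1.1, 1.31, 0.005), fm=np.array([1.0]), rm=np.array([0.0])
            )
            res = fit_growth(vehicle, grid, N=spec.N)
            errs.append(res.fc_ratio - 1.2)
        assert np.max(np.abs(errs)) <= 0.0151
        assert np.mean(np.abs(errs)) <= 0.0076  # unbiased to well under two grid steps

    def test_identifiability_profile_shape(self, noiseless):
        spec, vehicle, _, _ = noiseless
        grid = GridSpec(
            fc=np.array([1.1, 1.2]), fm=np.array([1.0, 1.2, 1.4]),
            rm=np.array([0.0, 1e-4]),
        )
        res = fit_growth(vehicle, grid, N=spec.N)
        prof = res.identifiability_profile()
        assert set(prof.columns) == {"fm_ratio", "r_m", "rmse"}
        assert len(prof) == 6
        assert (prof["rmse"] >= 0).all()

    def test_summary_mentions_estimates(self, noiseless):
        spec, vehicle, _, _ = noiseless
        res = fit_growth(
            vehicle,
            GridSpec(fc=np.array([1.2]), fm=np.array([1.0]), rm=np.array([0.0])),
            N=spec.N,
        )
        text = res.summary()
        assert "f_c / f_h" in text and "RMSE" in text


class TestStageTwoFit:
    def test_efficacy_recovered_at_reported_effect_size(self, noiseless):
        spec, _, treated, _ = noiseless
        stage1 = {"fc_ratio": 1.2, "fm_ratio": 1.4, "r_m": 0.0}
        grid = EfficacyGridSpec(
            eff_c=np.arange(0.0, 0.1001, 0.001), eff_m=np.array([0.0])
        )
        res = fit_treatment(
            treated, stage1, spec.regimen(), grid, N=spec.N
        )
        assert res.eff_c == pytest.approx(0.05, abs=1e-9)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    def test_flat_eff_m_surface_flagged_when_mutants_absent(self, noiseless):
        spec, _, treated, _ = noiseless
        stage1 = {"fc_ratio": 1.2, "fm_ratio": 1.4, "r_m": 0.0}
        grid = EfficacyGridSpec(
            eff_c=np.arange(0.0, 0.101, 0.01), eff_m=np.array([0.0, 0.5, 1.0])
        )
        res = fit_treatment(treated, stage1, spec.regimen(), grid, N=spec.N)
        assert res.eff_m_unidentifiable  # r_m = 0: no mutants in the horizon

    def test_eff_grid_of_zero_reduces_to_vehicle_prediction(self, noiseless):
        spec, vehicle, _, _ = noiseless
        stage1 = {"fc_ratio": 1.2, "fm_ratio": 1.4, "r_m": 0.0}
        grid = EfficacyGridSpec(eff_c=np.array([0.0]), eff_m=np.array([0.0]))
        # fitting the *vehicle* series with zero efficacy must be a perfect fit
        res = fit_treatment(vehicle, stage1, spec.regimen(), grid, N=spec.N)
        assert res.rmse == pytest.approx(0.0, abs=1e-10)

    def test_missing_stage1_params_rejected(self, noiseless):
        spec, _, treated, _ = noiseless
        with pytest.raises(ValueError):
            TreatmentEfficacyModel(
                treated, {"fc_ratio": 1.2}, spec.regimen(), N=spec.N
            )
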