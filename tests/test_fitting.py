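import math

import numpy as np
import pytest

from tftgrad.core_models import make_model, default_params, LN2
from tftgrad.pde_engine import Grid, simulate
from tftgrad.timer_model import MaturationParams, TFTProfile, \
    intensities_from_state
from tftgrad.fitting import (
    FIT_GRID, ObjectiveError, decay_length, fit_model, grid_scan,
    interval_estimates, iso_lambda_contour, objective,
)

T_NC14 = 2.5 * 3600.0


@pytest.fixture(scope="module")
def sdd_truth_data(maturation):
    """Noiseless SDD forward data on the fit grid (eps = 0.8, amplitude 5)."""
    spec = make_model("SDD", default_params("SDD"))
    state = simulate(spec, FIT_GRID, T_NC14, T_NC14, maturation=maturation)[-1]
    prof = intensities_from_state(state, eps=0.8)
    return TFTProfile(positions=prof.positions, green=5.0 * prof.green,
                      red=5.0 * prof.red, ratio=prof.ratio)


class TestObjective:
    O = {"green": np.array([1.0, 2.0, 3.0]), "ratio": np.array([0.5, 0.6, 0.7])}

    def test_perfect_fit_is_zero(self):
        comps = objective(self.O, self.O)
        assert comps["total"] == 0.0

    def test_offset_by_mean_gives_unity(self):
        E = {k: v + v.mean() for k, v in self.O.items()}
        comps = objective(E, self.O)
        assert comps["green"] == pytest.approx(1.0)
        assert comps["ratio"] == pytest.approx(1.0)
        assert comps["total"] == pytest.approx(2.0)

    def test_scale_invariance(self):
        E = {k: 1.1 * v for k, v in self.O.items()}
        a = objective(E, self.O)
        b = objective({k: 2 * v for k, v in E.items()},
                      {k: 2 * v for k, v in self.O.items()})
        assert a["total"] == pytest.approx(b["total"])

    def test_total_is_sum_of_components(self):
        E = {k: v * 1.3 for k, v in self.O.items()}
        comps = objective(E, self.O)
        assert comps["total"] == pytest.approx(comps["green"] + comps["ratio"])

    def test_grid_mismatch_raises(self):
        with pytest.raises(ObjectiveError):
            objective({"green": np.ones(4)}, {"green": np.ones(3)})

    def test_zero_mean_observation_raises(self):
        with pytest.raises(ObjectiveError):
            objective({"green": np.ones(3)}, {"green": np.zeros(3)})


class TestFitModel:
    def test_self_consistency_from_truth(self, sdd_truth_data, maturation):
        res = fit_model("SDD", sdd_truth_data, maturation_prior=maturation,
                        n_restarts=1, seed=0,
                        x0={"D_protein": 3.6, "protein_half_life": 26.0})
        assert res.r2 < 1e-8
        assert res.params["D_protein"] == pytest.approx(3.6, rel=1e-3)
        assert res.params["protein_half_life"] == pytest.approx(26.0,
                                                                rel=1e-3)
        assert res.eps == pytest.approx(0.8, rel=1e-3)
        assert res.amplitude == pytest.approx(5.0, rel=1e-3)
        assert res.r2 == pytest.approx(res.r2_green + res.r2_ratio)

    def test_deterministic_for_fixed_seed(self, sdd_truth_data, maturation):
        kw = dict(maturation_prior=maturation, n_restarts=2, seed=7,
                  maxfev=40)
        a = fit_model("SDD", sdd_truth_data, **kw)
        b = fit_model("SDD", sdd_truth_data, **kw)
        assert a.r2 == b.r2
        assert a.params == b.params

    def test_objective_invariant_to_channel_rescaling(self, sdd_truth_data,
                                                      maturation):
        scaled = TFTProfile(
            positions=sdd_truth_data.positions,
            green=3.0 * sdd_truth_data.green, red=3.0 * sdd_truth_data.red,
            ratio=sdd_truth_data.ratio)
        kw = dict(maturation_prior=maturation, n_restarts=1, seed=0,
                  x0={"D_protein": 3.0, "protein_half_life": 30.0},
                  maxfev=60)
        a = fit_model("SDD", sdd_truth_data, **kw)
        b = fit_model("SDD", scaled, **kw)
        assert b.r2 == pytest.approx(a.r2, rel=1e-6, abs=1e-12)
        assert b.amplitude == pytest.approx(3.0 * a.amplitude, rel=1e-6)

    def test_sdd_beats_other_models_on_sdd_truth(self, sdd_truth_data,
                                                 maturation):
        results = {name: fit_model(name, sdd_truth_data,
                                   maturation_prior=maturation,
                                   n_restarts=2, seed=1)
                   for name in ("SDD", "NucSh", "RNA-grad", "RNA-diff")}
        r2 = {k: v.r2 for k, v in results.items()}
        assert r2["SDD"] < min(v for k, v in r2.items() if k != "SDD") / 10

    def test_rna_diff_predicts_opposite_ratio_slope(self, sdd_truth_data,
                                                    maturation):
        from tftgrad.fitting import predict_observables
        res = fit_model("RNA-diff", sdd_truth_data,
                        maturation_prior=maturation, n_restarts=2, seed=3)
        x = sdd_truth_data.positions
        sel = (x >= 100) & (x <= 400)
        _, ratio_pred = predict_observables(
            "RNA-diff", {k: res.params[k] for k in res.free}, res.maturation,
            x)
        slope_pred = np.polyfit(x[sel], ratio_pred[sel], 1)[0]
        slope_obs = np.polyfit(x[sel], sdd_truth_data.ratio[sel], 1)[0]
        assert slope_obs > 0 and slope_pred < 0
        # and the ratio component dominates its residual
        assert res.r2_ratio > res.r2_green

    def test_unknown_model(self, sdd_truth_data):
        with pytest.raises(ValueError):
            fit_model("SSD", sdd_truth_data)


class TestGridScan:
    def test_contour_algebra(self):
        # lambda = 75 um at D = 3.0 um^2/s implies
        # t_half = ln2 * 75^2 / (3.0 * 60) min
        th = iso_lambda_contour(75.0, np.array([3.0]))[0]
        assert th == pytest.approx(LN2 * 75.0 ** 2 / (3.0 * 60.0))
        assert decay_length(3.0, th) == pytest.approx(75.0)

    def test_minimum_lands_on_truth_cell(self, sdd_truth_data, maturation):
        D_grid = np.array([2.6, 3.1, 3.6, 4.1, 4.6])
        th_grid = np.array([16.0, 21.0, 26.0, 31.0, 36.0])
        scan = grid_scan(sdd_truth_data, D_grid, th_grid,
                         maturation=maturation)
        i, j = np.unravel_index(np.nanargmin(scan.score), scan.score.shape)
        assert D_grid[i] == 3.6
        assert th_grid[j] == 26.0

    def test_interval_estimates_nested_in_tolerance(self, sdd_truth_data,
                                                    maturation):
        rng = np.random.default_rng(5)
        noisy = TFTProfile(
            positions=sdd_truth_data.positions,
            green=sdd_truth_data.green * (1 + 0.02 * rng.normal(
                size=sdd_truth_data.green.size)),
            red=sdd_truth_data.red,
            ratio=sdd_truth_data.ratio * (1 + 0.02 * rng.normal(
                size=sdd_truth_data.ratio.size)))
        D_grid = np.linspace(2.0, 6.0, 5)
        th_grid = np.linspace(14.0, 40.0, 5)
        scan = grid_scan(noisy, D_grid, th_grid, maturation=maturation)
        est0 = interval_estimates(scan, tolerance=0.0)
        est1 = interval_estimates(scan, tolerance=0.1)
        est3 = interval_estimates(scan, tolerance=0.3)
        assert est0["n_cells"] == 1
        assert est1["n_cells"] <= est3["n_cells"]
        for key in ("D_range", "half_life_range", "lambda_range"):
            assert est3[key][0] <= est1[key][0]
            assert est3[key][1] >= est1[key][1]

    def test_ten_pct_band_straddles_the_iso_lambda_valley(
            self, sdd_truth_data, maturation):
        rng = np.random.default_rng(11)
        noisy = TFTProfile(
            positions=sdd_truth_data.positions,
            green=sdd_truth_data.green * (1 + 0.02 * rng.normal(
                size=sdd_truth_data.green.size)),
            red=sdd_truth_data.red,
            ratio=sdd_truth_data.ratio * (1 + 0.02 * rng.normal(
                size=sdd_truth_data.ratio.size)))
        D_grid = np.linspace(2.2, 5.4, 6)
        th_grid = np.linspace(16.0, 38.0, 6)
        scan = grid_scan(noisy, D_grid, th_grid, maturation=maturation)
        est = interval_estimates(scan, tolerance=0.1)
        lo, hi = est["lambda_range"]
        # the band of acceptable cells tracks the observed decay length
        assert lo < 95.0 and hi > 80.0
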