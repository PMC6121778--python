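import math

import numpy as np
import pytest

from tftgrad.core_models import ModelParams, make_model, default_params
from tftgrad.pde_engine import Grid, simulate
from tftgrad.timer_model import MaturationParams
from tftgrad.phase_diagram import classify_quadrant, Trajectory
from tftgrad.synthetic_data import (
    BackgroundModel, NoiseModel, batch_mean_profile, correct_autofluorescence,
    generate_embryo, generate_timecourse,
)

T_NC14 = 2.5 * 3600.0
NO_NOISE = NoiseModel(0.0, 0.0, 0.0)
NO_BACKGROUND = BackgroundModel(amplitude=0.0, bump=0.0, pedestal=1.0)


@pytest.fixture(scope="module")
def mat():
    return MaturationParams(27.0, 40.0, 9.0)


@pytest.fixture(scope="module")
def sdd_state(mat):
    spec = make_model("SDD", default_params("SDD"))
    return simulate(spec, Grid(500.0, 250), T_NC14, T_NC14,
                    maturation=mat)[-1]


class TestGenerateEmbryo:
    def test_zero_noise_zero_background_is_forward_model(self, sdd_spec, mat,
                                                         sdd_state):
        e = generate_embryo(sdd_spec, mat, eps=0.8, seed=1, noise=NO_NOISE,
                            background=NO_BACKGROUND, amplitude_cv=0.0,
                            state=sdd_state)
        assert np.array_equal(e.green_raw, e.green_true)
        assert np.array_equal(e.red_raw, e.red_true)
        assert e.amplitude_factor == 1.0

    def test_same_seed_identical_different_seed_differs(self, sdd_spec, mat,
                                                        sdd_state):
        a = generate_embryo(sdd_spec, mat, seed=5, state=sdd_state)
        b = generate_embryo(sdd_spec, mat, seed=5, state=sdd_state)
        c = generate_embryo(sdd_spec, mat, seed=6, state=sdd_state)
        assert np.array_equal(a.green_raw, b.green_raw)
        assert a.amplitude_factor != c.amplitude_factor

    def test_channels_nonnegative_and_truth_recorded(self, sdd_spec, mat,
                                                     sdd_state):
        e = generate_embryo(sdd_spec, mat, eps=0.8, seed=2, state=sdd_state)
        assert np.all(e.green_raw >= 0) and np.all(e.red_raw >= 0)
        assert e.truth["model"] == "SDD"
        assert e.truth["params"]["D_protein"] == 3.6
        assert e.truth["eps"] == 0.8

    def test_batch_mean_ratio_increases_along_axis(self, sdd_spec, mat,
                                                   sdd_state):
        corrected = [correct_autofluorescence(
            generate_embryo(sdd_spec, mat, eps=0.8, seed=s, state=sdd_state))
            for s in range(4)]
        data = batch_mean_profile(corrected)
        ok = np.isfinite(data.ratio)
        slope = np.polyfit(data.positions[ok], data.ratio[ok], 1)[0]
        assert slope > 0

    def test_ten_micron_bins(self, sdd_spec, mat, sdd_state):
        e = generate_embryo(sdd_spec, mat, seed=0, state=sdd_state)
        assert e.positions[0] == 5.0
        assert np.allclose(np.diff(e.positions), 10.0)
        assert e.positions.size == 50


class TestCorrectAutofluorescence:
    def test_zero_background_gives_near_zero_weight(self, sdd_spec, mat,
                                                    sdd_state):
        # steep gradient truth: posterior window genuinely reporter-free
        spec = make_model("SDD", ModelParams(D_protein=2.0,
                                             protein_half_life=20.0))
        e = generate_embryo(spec, mat, seed=3,
                            background=BackgroundModel(amplitude=1e-12))
        c = correct_autofluorescence(e)
        assert abs(c.meta["w_green"]) < 0.02 * e.green_raw.max()

    def test_corrected_green_within_propagated_noise(self, mat):
        # steep gradient (lambda ~ 59 um): the posterior window is
        # reporter-free, so the correction is unbiased and errors follow
        # the propagated per-bin + weight uncertainty
        spec = make_model("SDD", ModelParams(D_protein=2.0,
                                             protein_half_life=20.0))
        state = simulate(spec, Grid(500.0, 250), T_NC14, T_NC14,
                         maturation=mat)[-1]
        hits = []
        for s in range(20):
            e = generate_embryo(spec, mat, eps=0.8, seed=s, state=state)
            c = correct_autofluorescence(e)
            shape = e.background.shape(e.positions)
            bg = e.truth["background_peak"] * shape
            sd_bin = e.noise.sd(e.green_true + bg)
            win = (e.positions >= 460) & (e.positions <= 500)
            # uncertainty of the corrected estimate: per-bin noise, the
            # windowed weight estimate, and the correction-channel noise
            sd_w = sd_bin[win].mean() / math.sqrt(win.sum())
            sd_af = e.truth["background_peak"] * e.noise.af_noise * shape
            sd_tot = np.sqrt(sd_bin ** 2 + (sd_w * shape) ** 2 + sd_af ** 2)
            ok = np.isfinite(c.green)
            hits.append(np.abs(c.green[ok] - e.green_true[ok])
                        <= 2 * sd_tot[ok])
        assert np.mean(np.concatenate(hits)) >= 0.95

    def test_window_with_true_signal_biases_weight_up(self, sdd_spec, mat,
                                                      sdd_state):
        e = generate_embryo(sdd_spec, mat, seed=4, state=sdd_state)
        good = correct_autofluorescence(e, refine_tail=False)
        biased = correct_autofluorescence(e, posterior_window=(250.0, 300.0),
                                          refine_tail=False)
        assert biased.meta["w_green"] > good.meta["w_green"]

    def test_all_zero_correction_channel_raises(self, sdd_spec, mat,
                                                sdd_state):
        e = generate_embryo(sdd_spec, mat, seed=4, state=sdd_state)
        e.af_channel = np.zeros_like(e.af_channel)
        with pytest.raises(ValueError):
            correct_autofluorescence(e)

    def test_ratio_independent_of_amplitude_factor(self, sdd_spec, mat,
                                                   sdd_state):
        ratios = []
        for s in (1, 2):  # different amplitude draws, no noise
            e = generate_embryo(sdd_spec, mat, eps=0.8, seed=s,
                                noise=NO_NOISE, state=sdd_state)
            ratios.append(correct_autofluorescence(e).ratio)
        both = np.isfinite(ratios[0]) & np.isfinite(ratios[1])
        assert both.sum() > 10
        assert np.allclose(ratios[0][both], ratios[1][both], atol=1e-9)


class TestGenerateTimecourse:
    def test_constant_parameters_reach_stationarity(self, mat):
        spec = make_model("SDD", ModelParams(D_protein=3.6,
                                             protein_half_life=20.0))
        tc = generate_timecourse(spec, mat, schedule=(), t_end=4.0 * 3600.0,
                                 seed=1, noise=NO_NOISE)
        totals = np.array([e.green_true.sum() for e in tc])
        late = totals[-5:]
        assert np.ptp(late) / late.mean() < 0.02

    def test_production_stop_red_peak_trails_green(self, sdd_spec, mat):
        tc = generate_timecourse(sdd_spec, mat,
                                 schedule=[(T_NC14, 0.0, 1.0)],
                                 t_end=4.2 * 3600.0, seed=2, noise=NO_NOISE)
        times = np.array([e.truth["time_s"] for e in tc])
        green = np.array([e.green_true.sum() for e in tc])
        red = np.array([e.red_true.sum() for e in tc])
        lag = times[np.argmax(red)] - times[np.argmax(green)]
        assert lag > 0  # two-step red maturation delays the red peak

    def test_timecourse_quadrant_recovery(self, sdd_spec, mat):
        # the generating scenario label survives the noisy pipeline
        hits = 0
        n = 10
        for s in range(n):
            tc = generate_timecourse(sdd_spec, mat,
                                     schedule=[(T_NC14, 0.0, 1.0)],
                                     t_end=3.6 * 3600.0, seed=s)
            times = np.array([e.truth["time_s"] for e in tc])
            x = tc[0].positions
            sel = x <= 125.0
            intensity = []
            ratio = []
            for e in tc:
                c = correct_autofluorescence(e)
                intensity.append(np.nanmean(c.green[sel]))
                ratio.append(np.nanmean(c.red[sel]) /
                             np.nanmean(c.green[sel]))
            traj = Trajectory(times=times, intensity=np.array(intensity),
                              ratio=np.array(ratio), region=(0, 0.25),
                              production_factor=0.0, degradation_factor=1.0,
                              t_switch=T_NC14)
            res = classify_quadrant(traj)
            hits += res["label"] == "production down / degradation steady"
        assert hits >= 9
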