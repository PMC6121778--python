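"""Age/levels phase-plane analysis of production and degradation changes.

Out of steady state the timer ratio carries information about *how* a
protein pool is being cleared: stopping production leaves old protein
behind (intensity falls, ratio rises), while accelerating degradation
removes protein before the slow fluorophore matures (intensity falls,
ratio falls).  Plotting the mean ratio against the mean intensity of a
region over time therefore separates the four sign combinations of
production/degradation changes into four quadrants.

The trajectories here are computed from the six-state timer system for an
anterior region (default the anterior 25% of the axis), sampled at the
cadence of the live-imaging time courses (6 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_models import ModelSpec, ModelParams, make_model, MIN
from .pde_engine import Grid, GradientState, simulate
from .timer_model import MaturationParams, intensities_from_state

ANTERIOR_REGION = (0.0, 0.25)      # fraction of embryo length
SAMPLE_CADENCE = 6.0 * MIN         # s, matching the experimental time courses
QSS_DRIFT_TOL = 0.01               # relative drift per 10 min counted as steady
DEAD_BAND = 0.02                   # |relative change| below this = "no change"

QUADRANT_LABELS = {
    (-1, +1): "production down / degradation steady",
    (-1, -1): "production steady / degradation up",
    (+1, -1): "production up / degradation steady",
    (+1, +1): "production steady / degradation down",
}


@dataclass
class Trajectory:
    """Region-mean intensity and ratio over time for one perturbation."""

    times: np.ndarray              # s
    intensity: np.ndarray          # mean green in the region (arb. units)
    ratio: np.ndarray              # mean red/green in the region
    region: tuple                  # fraction of embryo length
    production_factor: float
    degradation_factor: float
    t_switch: float                # s
    steady_at_switch: bool = True  # warning-grade flag, not an exception

    def index_at(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))


def region_means(state: GradientState, eps: float,
                 region: tuple = ANTERIOR_REGION) -> tuple:
    """(mean green, mean ratio) of a maturation state over a region."""
    prof = intensities_from_state(state, eps=eps)
    x = state.grid.positions
    lo, hi = region
    sel = (x >= lo * state.grid.L) & (x <= hi * state.grid.L)
    green = prof.green[sel].mean()
    red = prof.red[sel].mean()
    return float(green), float(red / green) if green > 0 else math.nan


def simulate_perturbation(spec: ModelSpec, maturation: MaturationParams,
                          t_switch: float, production_factor: float,
                          degradation_factor: float, t_end: float,
                          grid: Optional[Grid] = None, eps: float = 1.0,
                          region: tuple = ANTERIOR_REGION,
                          cadence: float = SAMPLE_CADENCE) -> Trajectory:
    """Step-change production/degradation at ``t_switch`` and record the
    age/levels trajectory at fixed cadence.

    Quasi-steady state at the switch is checked (anterior-mean intensity
    drift < 1% per 10 min); failure sets ``steady_at_switch = False`` on
    the returned trajectory rather than raising.
    """
    grid = grid or Grid(500.0, 100)
    pre = simulate(spec, grid, t_end=t_switch, dt_out=cadence,
                   maturation=maturation)
    post = simulate(spec, grid, t_end=t_end, dt_out=cadence,
                    maturation=maturation, t_start=t_switch,
                    initial=pre[-1],
                    production_factor=production_factor,
                    degradation_factor=degradation_factor)
    states = pre + post[1:]
    times = np.array([s.time for s in states])
    means = [region_means(s, eps, region) for s in states]
    intensity = np.array([m[0] for m in means])
    ratio = np.array([m[1] for m in means])

    # drift of the anterior mean over the last 10 min before the switch
    i_switch = int(np.argmin(np.abs(times - t_switch)))
    i_prev = int(np.argmin(np.abs(times - (t_switch - 10.0 * MIN))))
    steady = True
    if intensity[i_switch] > 0 and i_prev < i_switch:
        drift = abs(intensity[i_switch] - intensity[i_prev]) / intensity[i_switch]
        steady = drift < QSS_DRIFT_TOL
    return Trajectory(times=times, intensity=intensity, ratio=ratio,
                      region=region, production_factor=production_factor,
                      degradation_factor=degradation_factor,
                      t_switch=t_switch, steady_at_switch=steady)


def classify_quadrant(traj: Trajectory, t_switch: Optional[float] = None,
                      window: Optional[float] = None,
                      dead_band: float = DEAD_BAND) -> dict:
    """Quadrant label from the signs of the post-switch intensity and ratio
    changes; |relative change| below the dead band counts as no change.

    Returns the label plus the raw relative deltas.
    """
    t_switch = traj.t_switch if t_switch is None else t_switch
    i0 = traj.index_at(t_switch)
    post = traj.times > t_switch + 1e-9
    if post.sum() < 3:
        raise ValueError("need >= 3 samples after the switch")
    if window is not None:
        post &= traj.times <= t_switch + window
        if post.sum() < 2:
            raise ValueError("post-switch window holds fewer than 2 samples")
    i1 = int(np.nonzero(post)[0][-1])
    d_int = (traj.intensity[i1] - traj.intensity[i0]) / traj.intensity[i0]
    d_ratio = (traj.ratio[i1] - traj.ratio[i0]) / traj.ratio[i0]
    s_int = 0 if abs(d_int) < dead_band else int(math.copysign(1, d_int))
    s_ratio = 0 if abs(d_ratio) < dead_band else int(math.copysign(1, d_ratio))
    if s_int == 0 and s_ratio == 0:
        label = "no change"
    else:
        label = QUADRANT_LABELS.get((s_int, s_ratio),
                                    f"intensity {s_int:+d} / ratio {s_ratio:+d}")
    return {"label": label, "d_intensity": float(d_int),
            "d_ratio": float(d_ratio), "signs": (s_int, s_ratio)}


def lifetime_shift_experiment(spec: ModelSpec,
                              maturation: MaturationParams,
                              half_life_after: Optional[float],
                              t_switch: float = 2.5 * 3600.0,
                              t_observe: float = 60.0 * MIN,
                              grid: Optional[Grid] = None,
                              eps: float = 1.0,
                              region: tuple = ANTERIOR_REGION) -> dict:
    """Step the protein half-life at ``t_switch`` and report anterior
    intensity/ratio changes after ``t_observe``, relative to an unperturbed
    control run observed at the same final time (the paired-injection
    design: treated vs. vehicle-injected embryos).

    ``half_life_after = None`` (with a non-degrading spec) is the
    stable-construct control: both runs are identical and the changes are
    exactly zero.
    """
    grid = grid or Grid(500.0, 100)
    t_half_before = spec.params.protein_half_life
    if t_half_before is None and half_life_after is not None:
        raise ValueError("cannot introduce degradation into a "
                         "non-degrading model via a lifetime shift")
    if t_half_before is None:
        factor = 1.0
    else:
        factor = (0.0 if half_life_after is None
                  else t_half_before / half_life_after)
        if half_life_after is not None and half_life_after <= 0:
            raise ValueError("half_life_after must be positive")

    t_end = t_switch + t_observe
    pre = simulate(spec, grid, t_end=t_switch, dt_out=t_switch,
                   maturation=maturation)
    control = simulate(spec, grid, t_end=t_end, dt_out=t_observe,
                       maturation=maturation, t_start=t_switch,
                       initial=pre[-1])
    shifted = simulate(spec, grid, t_end=t_end, dt_out=t_observe,
                       maturation=maturation, t_start=t_switch,
                       initial=pre[-1], degradation_factor=factor)
    int_c, ratio_c = region_means(control[-1], eps, region)
    int_s, ratio_s = region_means(shifted[-1], eps, region)
    return {
        "intensity_change": (int_s - int_c) / int_c,
        "ratio_change": (ratio_s - ratio_c) / ratio_c,
        "half_life_before": t_half_before,
        "half_life_after": half_life_after,
    }
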