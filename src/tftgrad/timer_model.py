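"""Tandem-fluorescent-timer forward model: maturation states to intensities.

A tandem timer fuses a fast-maturing green fluorophore (sfGFP) to a
slow-maturing red one (mCherry, which matures in two sequential steps
through a dark intermediate).  New protein is dark; it becomes green after
the fast step and additionally red after both slow steps, so the red/green
intensity ratio of a protein pool reports its mean age.

Channel model (per position, from the six maturation sub-states):

    green = sum(green-matured states) - f * (doubly matured state) + free-GFP pool
    red   = eps * sum(red-matured states)
    ratio = red / green   (masked where green is below floor)

``eps`` is the free scaling between red and green detected intensity per
matured fluorophore; ``f`` models FRET as pure donor quenching of the
doubly-matured species; ``phi`` is the fraction of green fluorophore that
survives degradation of the tagged protein as a stable, immobile free-GFP
pool (an artifact that inflates the green channel).

For a well-mixed pool at steady state with protein degradation rate k the
matured fractions are closed-form:

    green fraction = m_g / (m_g + k)
    red fraction   = m_r1 m_r2 / ((m_r1 + k)(m_r2 + k))
    ratio          = eps * red fraction / green fraction

which is strictly increasing in the protein half-life whenever red
maturation is slower than green overall, and decreasing for a
faster-than-green red fluorophore (the fmCherry reversal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_models import MIN, LN2, half_life_to_rate
from .pde_engine import (
    GradientState, GREEN_MATURE_IDX, RED_MATURE_IDX, BOTH_MATURE_IDX,
)

#: measured maturation half-times (min) and their Gaussian SDs:
#: (green, red step 1, red step 2)
PRESETS = {
    "sfGFP-mCherry": {"half_times": (27.0, 40.0, 9.0), "sds": (2.7, 4.0, 0.9)},
    "sfGFP-fmCherry": {"half_times": (27.0, 6.0, 6.0), "sds": (2.7, 2.0, 2.0)},
}

GREEN_FLOOR_REL = 1e-9   # ratio undefined where green below this x max


@dataclass
class MaturationParams:
    """Fluorophore maturation half-times (min); rates are ln2 / T."""

    green_half_time: float = 27.0
    red_half_time_1: float = 40.0
    red_half_time_2: float = 9.0
    green_sd: float = 0.0
    red_sd_1: float = 0.0
    red_sd_2: float = 0.0

    def __post_init__(self):
        for name in ("green_half_time", "red_half_time_1", "red_half_time_2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def m_g(self) -> float:
        return LN2 / (self.green_half_time * MIN)

    @property
    def m_r1(self) -> float:
        return LN2 / (self.red_half_time_1 * MIN)

    @property
    def m_r2(self) -> float:
        return LN2 / (self.red_half_time_2 * MIN)

    @classmethod
    def preset(cls, name: str) -> "MaturationParams":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; "
                             f"available: {sorted(PRESETS)}")
        p = PRESETS[name]
        t1, t2, t3 = p["half_times"]
        s1, s2, s3 = p["sds"]
        return cls(t1, t2, t3, s1, s2, s3)

    def draw(self, rng: np.random.Generator,
             min_half_time: float = 1.0) -> "MaturationParams":
        """Gaussian prior draw of the three half-times, truncated > 1 min."""
        def trunc(mean, sd):
            if sd == 0:
                return mean
            while True:
                v = rng.normal(mean, sd)
                if v > min_half_time:
                    return float(v)
        return MaturationParams(
            trunc(self.green_half_time, self.green_sd),
            trunc(self.red_half_time_1, self.red_sd_1),
            trunc(self.red_half_time_2, self.red_sd_2))


@dataclass
class TFTProfile:
    """Observed or predicted green/red intensities and their ratio."""

    positions: np.ndarray
    green: np.ndarray
    red: np.ndarray
    ratio: np.ndarray            # NaN where green below floor
    eps: float = 1.0
    fret_fraction: float = 0.0
    free_gfp_fraction: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def _ratio(red: np.ndarray, green: np.ndarray) -> np.ndarray:
    floor = GREEN_FLOOR_REL * max(float(np.max(green)), np.finfo(float).tiny)
    out = np.full_like(green, np.nan, dtype=float)
    ok = green > floor
    out[ok] = red[ok] / green[ok]
    return out


def intensities_from_state(state: GradientState, eps: float = 1.0,
                           fret_fraction: float = 0.0,
                           free_gfp: Optional[np.ndarray] = None) -> TFTProfile:
    """Map a six-state concentration field to green/red/ratio profiles.

    ``free_gfp`` is an optional stable green pool (from
    :func:`free_gfp_pool`) added to the green channel.
    """
    if not (0.0 <= fret_fraction <= 1.0):
        raise ValueError("fret_fraction must be in [0, 1]")
    stack = state.maturation_stack()   # raises if states missing
    green = stack[list(GREEN_MATURE_IDX)].sum(axis=0)
    green = green - fret_fraction * stack[BOTH_MATURE_IDX]
    phi = 0.0
    if free_gfp is not None:
        green = green + free_gfp
        phi = float("nan")  # recorded via meta by callers that know phi
    red = eps * stack[list(RED_MATURE_IDX)].sum(axis=0)
    return TFTProfile(positions=state.grid.positions, green=green, red=red,
                      ratio=_ratio(red, green), eps=eps,
                      fret_fraction=fret_fraction,
                      free_gfp_fraction=0.0 if free_gfp is None else phi)


def steady_state_ratio(protein_half_life: float,
                       maturation: MaturationParams,
                       eps: float = 1.0) -> float:
    """Closed-form red/green ratio of a well-mixed pool at steady state."""
    if protein_half_life <= 0:
        raise ValueError("protein_half_life must be positive")
    k = half_life_to_rate(protein_half_life)
    m_g, m_r1, m_r2 = maturation.m_g, maturation.m_r1, maturation.m_r2
    green_frac = m_g / (m_g + k)
    red_frac = m_r1 * m_r2 / ((m_r1 + k) * (m_r2 + k))
    return eps * red_frac / green_frac


def ratio_uncertainty_band(half_life_grid: Sequence[float],
                           maturation: MaturationParams,
                           n_draws: int, seed: int,
                           eps: float = 1.0) -> tuple:
    """Monte Carlo band of the ratio-lifetime curve under maturation priors.

    Returns ``(mean, sd, curves)`` with one curve per prior draw, each
    evaluated on the half-life grid.
    """
    rng = np.random.default_rng(seed)
    half_life_grid = np.asarray(half_life_grid, dtype=float)
    curves = np.empty((n_draws, half_life_grid.size))
    for i in range(n_draws):
        mat = maturation.draw(rng)
        curves[i] = [steady_state_ratio(t, mat, eps) for t in half_life_grid]
    return curves.mean(axis=0), curves.std(axis=0, ddof=0), curves


def free_gfp_pool(states: Sequence[GradientState], phi: float,
                  k_protein: float) -> np.ndarray:
    """Stable green pool from incomplete degradation of the timer.

    A fraction ``phi`` of the green fluorophore survives each degradation
    event of a green-matured protein, accumulating as a non-degrading,
    non-diffusing green-only pool:

        dG_free/dt = phi * k * sum(green-matured states),

    integrated (trapezoidal) over the supplied state history, where ``k``
    is the protein degradation rate (1/s) of the generating model.  With
    ``phi = 0`` the pool is identically zero and the channels are unchanged.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must be in [0, 1]")
    if len(states) < 2:
        raise ValueError("need a state history (>= 2 snapshots)")
    n = states[0].grid.n_bins
    if phi == 0.0 or k_protein == 0.0:
        return np.zeros(n)
    pool = np.zeros(n)
    prev_flux = prev_t = None
    for st in states:
        stack = st.maturation_stack()
        flux = k_protein * stack[list(GREEN_MATURE_IDX)].sum(axis=0)
        if prev_flux is not None:
            pool += 0.5 * (flux + prev_flux) * (st.time - prev_t)
        prev_flux, prev_t = flux, st.time
    return phi * pool
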