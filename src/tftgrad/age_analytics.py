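"""Mean protein age along the axis via first age-moment PDEs.

For a linear reaction-transport system dC/dt = T[C] - kC + s(x), the first
age moment m(x,t) = C(x,t) * Abar(x,t) obeys

    dm/dt = T[m] - k m + C,

because every protein ages at unit rate, degradation removes age-mass in
proportion to its local share, transport carries age-mass with the protein,
and newly synthesized protein enters with age zero (so the source s does
not appear).  The mean age is Abar = m / C wherever C is above floor.

The four gradient-formation models make qualitatively different predictions
for Abar(x) at the observation stage (~2.5 h): both anterior-synthesis
models (SDD, nuclear shuttling) predict age increasing toward the
posterior; the static-RNA-gradient model predicts a flat age profile; the
RNA-diffusion model predicts the inverse (younger protein posteriorly,
since posterior protein is translated later from late-arriving mRNA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .core_models import (
    ModelSpec, ModelParams, make_model, default_params, screening_filter,
    DEFAULT_FIT_RANGE, MIN, LN2,
)
from .pde_engine import (
    Grid, GradientState, SolverError, assemble_operator, initial_vector,
    _subspecies, simulate,
)

SIGNATURE_WINDOW = (100.0, 400.0)   # um window used to classify age slopes
FLAT_THRESHOLD = 0.2                # |change| < 20% of the SDD reference = flat
EXPECTED_SIGNATURES = {
    "SDD": "increasing",
    "NucSh": "increasing",
    "RNA-grad": "flat",
    "RNA-diff": "decreasing",
}


@dataclass
class AgeProfile:
    """Mean protein age vs position with its defining moment field."""

    positions: np.ndarray       # um
    mean_age_min: np.ndarray    # minutes; NaN-free, see `defined`
    moment: np.ndarray          # C(x) * Abar(x), age-mass density (age in s)
    conc: np.ndarray            # total protein C(x)
    time: float                 # seconds
    defined: np.ndarray         # bool per bin; False where C below floor

    def change_over(self, window=SIGNATURE_WINDOW) -> float:
        """Linear-trend age change (min) across a window."""
        lo, hi = window
        sel = (self.positions >= lo) & (self.positions <= hi) & self.defined
        if sel.sum() < 3:
            raise ValueError("too few defined bins in window")
        slope = np.polyfit(self.positions[sel], self.mean_age_min[sel], 1)[0]
        return float(slope * (hi - lo))


def _moment_system(spec: ModelSpec, grid: Grid, t: float):
    """Augmented operator for y = [C, m]: dy/dt = A y + [s, 0]."""
    M, s, subs = assemble_operator(spec, grid, t=t)
    # the moment field shares transport/degradation/trapping with C, but
    # synthesis-like couplings must not inject RNA "age" into protein
    if spec.translation_rate > 0:
        spec_m = replace(spec, translation_rate=0.0)
        Mm, _, _ = assemble_operator(spec_m, grid, t=t)
    else:
        Mm = M
    n = grid.n_bins
    # aging source: dm/dt += C for protein sub-species only
    diag = np.zeros(len(subs) * n)
    for i, (species, _) in enumerate(subs):
        if species.startswith("protein"):
            diag[i * n:(i + 1) * n] = 1.0
    E = sp.diags(diag)
    A = sp.bmat([[M, None], [E, Mm]], format="csc")
    s_aug = np.concatenate([s, np.zeros_like(s)])
    return A, s_aug, subs


def mean_age(spec: ModelSpec, grid: Grid, t: float,
             initial: Optional[GradientState] = None,
             rtol: float = 1e-7, atol: float = 1e-12,
             floor_rel: float = 1e-12) -> AgeProfile:
    """Mean protein age profile at time ``t`` (s) from the moment PDE.

    ``initial`` supplies a starting concentration field whose protein is
    taken to have age zero at t = 0 (e.g. a bolus).  Bins where the total
    protein falls below ``floor_rel`` times its maximum are flagged as
    undefined rather than returned as NaN.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    n = grid.n_bins
    subs = _subspecies(spec, None)
    y0_c = initial_vector(spec, grid, subs, initial)
    y = np.concatenate([y0_c, np.zeros_like(y0_c)])

    seg_edges = [0.0] + spec.cycle_boundaries(t) + [t]
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        A, s_aug, _ = _moment_system(spec, grid, t=a)
        sol = solve_ivp(lambda tt, yy: A @ yy + s_aug, (a, b), y,
                        method="BDF", jac=A, rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(f"age-moment integration failed: {sol.message}")
        y = sol.y[:, -1]

    half = y.size // 2
    C = np.zeros(n)
    m = np.zeros(n)
    for i, (species, _) in enumerate(subs):
        if species.startswith("protein"):
            C += y[i * n:(i + 1) * n]
            m += y[half + i * n: half + (i + 1) * n]
    floor = floor_rel * max(C.max(), np.finfo(float).tiny)
    defined = C > floor
    age_min = np.zeros(n)
    age_min[defined] = m[defined] / C[defined] / MIN
    return AgeProfile(positions=grid.positions, mean_age_min=age_min,
                      moment=m, conc=C, time=t, defined=defined)


def classify_slope(profile: AgeProfile, reference_change: float,
                   window=SIGNATURE_WINDOW,
                   flat_threshold: float = FLAT_THRESHOLD) -> str:
    delta = profile.change_over(window)
    if abs(delta) < flat_threshold * abs(reference_change):
        return "flat"
    return "increasing" if delta > 0 else "decreasing"


def age_signature(specs: Dict[str, ModelSpec], grid: Grid,
                  t: float = 2.5 * 3600, window=SIGNATURE_WINDOW,
                  flat_threshold: float = FLAT_THRESHOLD) -> Dict[str, str]:
    """Classify each model's age profile as increasing/flat/decreasing.

    Every model must pass the concentration screening filter (decay length
    70-100 um at ``t``); a failing model raises ValueError rather than being
    silently classified.  The flat/sloped threshold is relative to the SDD
    model's age change over the window (SDD must be among the inputs, or a
    reference spec is constructed from its defaults).
    """
    profiles = {}
    for name, spec in specs.items():
        conc = simulate(spec, grid, t_end=t, dt_out=t)[-1].total_protein()
        ok, lam = screening_filter(grid.positions, conc)
        if not ok:
            raise ValueError(
                f"model {name}: concentration profile fails screening "
                f"(lambda = {lam:.1f} um outside 70-100 um); refusing to "
                "classify its age profile")
        profiles[name] = mean_age(spec, grid, t)

    if "SDD" in profiles:
        ref = profiles["SDD"].change_over(window)
    else:
        ref_spec = make_model("SDD", default_params("SDD"))
        ref = mean_age(ref_spec, grid, t).change_over(window)
    return {name: classify_slope(p, ref, window, flat_threshold)
            for name, p in profiles.items()}


# ---------------------------------------------------------------------------
# parameter sweeps (robustness envelopes of the age predictions)
# ---------------------------------------------------------------------------

#: physiological sampling ranges: D (um^2/s) and half-lives (min) are
#: log-uniform (span ~2 decades); lengths (um) are uniform
SWEEP_RANGES = {
    "D": (0.1, 10.0),
    "half_life": (10.0, 120.0),
    "rna_length": (20.0, 200.0),
    "k_on0": (5e-5, 1e-3),
    "k_off": (5e-5, 1e-3),
}


@dataclass
class AgeEnvelope:
    """Mean +/- SD of normalized age profiles over accepted parameter sets."""

    positions: np.ndarray
    mean: Optional[np.ndarray]   # None when no parameter set was accepted
    sd: Optional[np.ndarray]
    n_accepted: int
    n_sampled: int
    accepted_params: list


def _draw_params(model: str, rng: np.random.Generator,
                 ranges: dict) -> ModelParams:
    def logu(key):
        lo, hi = ranges[key]
        return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

    def uni(key):
        lo, hi = ranges[key]
        return float(rng.uniform(lo, hi))

    if model == "SDD":
        return ModelParams(D_protein=logu("D"), protein_half_life=logu("half_life"))
    if model == "NucSh":
        return ModelParams(D_protein=logu("D"), protein_half_life=None,
                           k_on0=logu("k_on0"), k_off=logu("k_off"))
    if model == "RNA-grad":
        return ModelParams(D_protein=min(logu("D"), 0.5),
                           protein_half_life=logu("half_life"),
                           rna_gradient_length=uni("rna_length"))
    if model == "RNA-diff":
        return ModelParams(D_protein=0.0, protein_half_life=None,
                           D_rna=logu("D"), rna_half_life=logu("half_life"))
    raise ValueError(f"unknown model {model!r}")


def parameter_sweep_ages(model: str, n_samples: int, seed: int,
                         grid: Optional[Grid] = None,
                         t: float = 2.5 * 3600,
                         ranges: Optional[dict] = None,
                         window=SIGNATURE_WINDOW) -> AgeEnvelope:
    """Sample parameter sets, keep those passing the screening filter, and
    return mean +/- SD of the window-normalized age profiles.

    Age profiles are normalized to their mean over the classification window
    so that the envelope reflects shape, not absolute age scale.  A model
    with zero accepted sets yields an explicit empty envelope.
    """
    grid = grid or Grid(500.0, 125)
    ranges = {**SWEEP_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    lo, hi = window
    sel = (grid.positions >= lo) & (grid.positions <= hi)
    accepted = []
    kept_params = []
    for _ in range(n_samples):
        params = _draw_params(model, rng, ranges)
        try:
            spec = make_model(model, params)
            conc = simulate(spec, grid, t_end=t, dt_out=t)[-1].total_protein()
            ok, _ = screening_filter(grid.positions, conc)
        except (ValueError, SolverError):
            ok = False
        if not ok:
            continue
        prof = mean_age(spec, grid, t)
        norm = prof.mean_age_min[sel & prof.defined].mean()
        if norm <= 0:
            continue
        accepted.append(prof.mean_age_min / norm)
        kept_params.append(params)
    if not accepted:
        return AgeEnvelope(grid.positions, None, None, 0, n_samples, [])
    arr = np.asarray(accepted)
    return AgeEnvelope(grid.positions, arr.mean(axis=0),
                       arr.std(axis=0, ddof=0), len(accepted), n_samples,
                       kept_params)
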