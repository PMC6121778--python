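"""Deterministic 1-D reaction-diffusion integration with maturation states.

Method of lines: second-order central differences on a uniform grid with
no-flux boundaries at both ends (the source enters as an influx into the
first cell, equivalent to a boundary flux at x = 0), integrated with a
stiff implicit scheme (BDF) with adaptive error control and the exact
sparse Jacobian.  All model variants reduce to a linear system

    dy/dt = M(t) y + s,

where ``M`` is piecewise constant in time (it only changes at nuclear-cycle
boundaries of the shuttling model, or continuously when a time-dependent
diffusion coefficient is requested) — so the integrator is restarted at
each breakpoint with a constant sparse Jacobian.

When maturation parameters are supplied the protein compartments are
expanded into six sub-states: green (fast fluorophore) immature/mature
crossed with red (slow fluorophore) immature/intermediate/mature.  All six
states share the protein's transport and degradation; synthesis enters the
fully immature state only; green matures at rate m_g, red sequentially at
m_r1 then m_r2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .core_models import (
    ModelSpec,
    fit_exponential,  # noqa: F401  (re-export: profile fitting lives with the engine too)
    MIN,
)

# six maturation states: green in {0 immature, 1 mature} x red in
# {0 immature, 1 intermediate, 2 mature}
MATURATION_STATES = ("g0r0", "g1r0", "g0r1", "g1r1", "g0r2", "g1r2")
STATE_GREEN = tuple(int(s[1]) for s in MATURATION_STATES)
STATE_RED = tuple(int(s[3]) for s in MATURATION_STATES)

#: indices of states with a matured green fluorophore
GREEN_MATURE_IDX = tuple(i for i, g in enumerate(STATE_GREEN) if g == 1)
#: indices of states with a fully matured red fluorophore
RED_MATURE_IDX = tuple(i for i, r in enumerate(STATE_RED) if r == 2)
#: index of the doubly matured state (FRET-susceptible)
BOTH_MATURE_IDX = MATURATION_STATES.index("g1r2")
#: index of the fully immature state (receives synthesis)
IMMATURE_IDX = MATURATION_STATES.index("g0r0")


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class Grid:
    """Uniform 1-D grid over [0, L]; positions are bin centres."""

    L: float = 500.0
    n_bins: int = 250

    def __post_init__(self):
        if self.L <= 0 or self.n_bins < 2:
            raise ValueError("grid requires L > 0 and n_bins >= 2")

    @property
    def dx(self) -> float:
        return self.L / self.n_bins

    @property
    def positions(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.dx


@dataclass
class GradientState:
    """Concentrations per species (and maturation sub-state) at one time.

    ``data[species]`` is shape ``(n_bins,)`` without maturation and
    ``(6, n_bins)`` for protein species of a maturation run.
    """

    time: float                      # seconds
    grid: Grid
    data: dict = field(default_factory=dict)

    @property
    def has_maturation(self) -> bool:
        return any(v.ndim == 2 for v in self.data.values())

    def total(self, species: str) -> np.ndarray:
        arr = self.data[species]
        return arr.sum(axis=0) if arr.ndim == 2 else arr

    def total_protein(self) -> np.ndarray:
        out = np.zeros(self.grid.n_bins)
        for sp_name in self.data:
            if sp_name.startswith("protein"):
                out += self.total(sp_name)
        return out

    def maturation_stack(self) -> np.ndarray:
        """Summed (6, n_bins) maturation array over all protein compartments."""
        stacks = [self.data[s] for s in self.data
                  if s.startswith("protein") and self.data[s].ndim == 2]
        if not stacks:
            raise ValueError("state carries no maturation sub-arrays")
        return np.sum(stacks, axis=0)


def laplacian(grid: Grid) -> sp.csr_matrix:
    """Second-order central-difference Laplacian with no-flux ends (1/um^2)."""
    n = grid.n_bins
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0  # reflecting: ghost cell mirrors the boundary cell
    off = np.ones(n - 1)
    return sp.diags([off, main, off], [-1, 0, 1], format="csr") / grid.dx ** 2


def _subspecies(spec: ModelSpec, maturation) -> List[tuple]:
    subs = []
    for species in spec.species:
        if species.startswith("protein") and maturation is not None:
            subs.extend((species, st) for st in MATURATION_STATES)
        else:
            subs.append((species, None))
    return subs


def synthesis_profile(spec: ModelSpec, grid: Grid) -> np.ndarray:
    """Spatial source density (molecules / um / s) integrating to J."""
    x = grid.positions
    J = spec.synthesis_rate
    if J == 0.0:
        return np.zeros(grid.n_bins)
    if spec.synthesis_profile == "point":
        s = np.zeros(grid.n_bins)
        s[0] = J / grid.dx
        return s
    lam = spec.synthesis_length
    w = np.exp(-x / lam)
    w /= w.sum() * grid.dx
    return J * w


def rna_bolus(spec: ModelSpec, grid: Grid) -> np.ndarray:
    """Initial RNA density: a uniform anterior bolus (RNA-diff model)."""
    x = grid.positions
    width = spec.params.rna_bolus_width
    inside = x < width
    dens = np.zeros(grid.n_bins)
    if inside.sum() == 0:
        inside[0] = True
    dens[inside] = spec.params.rna_bolus_amount / (inside.sum() * grid.dx)
    return dens


def assemble_operator(spec: ModelSpec, grid: Grid, maturation=None,
                      t: float = 0.0, production_factor: float = 1.0,
                      degradation_factor: float = 1.0):
    """Sparse generator M and source s of dy/dt = M y + s at time t.

    Returns ``(M, s, subs)`` where ``subs`` lists (species, state) per block
    of ``grid.n_bins`` entries in the state vector.
    """
    subs = _subspecies(spec, maturation)
    n = grid.n_bins
    n_sub = len(subs)
    lap = laplacian(grid)

    # reaction coupling between sub-species (same spatial bin)
    R = np.zeros((n_sub, n_sub))
    index = {sub: i for i, sub in enumerate(subs)}

    def add_flow(src, dst, rate):
        i, j = index[dst], index[src]
        R[i, j] += rate
        R[j, j] -= rate

    for species, state in subs:
        i = index[(species, state)]
        k = spec.degradation[species]
        if species.startswith("protein"):
            k *= degradation_factor
        R[i, i] -= k
        if state is not None:
            si = MATURATION_STATES.index(state)
            g, r = STATE_GREEN[si], STATE_RED[si]
            if g == 0:
                add_flow((species, state), (species, f"g1r{r}"), maturation.m_g)
            if r == 0:
                add_flow((species, state), (species, f"g{g}r1"), maturation.m_r1)
            elif r == 1:
                add_flow((species, state), (species, f"g{g}r2"), maturation.m_r2)

    if spec.name == "NucSh":
        k_on = spec.trapping_rate(t)
        states = MATURATION_STATES if maturation is not None else (None,)
        for st in states:
            add_flow(("protein_cyt", st), ("protein_nuc", st), k_on)
            add_flow(("protein_nuc", st), ("protein_cyt", st), spec.k_off)

    # translation: RNA sources protein (fully immature state) at rate beta,
    # without consuming the RNA (RNA turnover is its own degradation term)
    if spec.translation_rate > 0 and "rna" in spec.species:
        j = index[("rna", None)]
        target_state = MATURATION_STATES[IMMATURE_IDX] if maturation is not None else None
        i = index[("protein", target_state)]
        R[i, j] += spec.translation_rate

    blocks = []
    for species, state in subs:
        D = spec.diffusion_at(species, t)
        blocks.append(D * lap if D > 0 else sp.csr_matrix((n, n)))
    M = (sp.block_diag(blocks, format="csr")
         + sp.kron(sp.csr_matrix(R), sp.identity(n, format="csr"), format="csr"))

    s = np.zeros(n_sub * n)
    prof = synthesis_profile(spec, grid) * production_factor
    if prof.any():
        target_state = (MATURATION_STATES[IMMATURE_IDX]
                        if maturation is not None and
                        spec.synthesis_species.startswith("protein") else None)
        i = index[(spec.synthesis_species, target_state)]
        s[i * n:(i + 1) * n] = prof
    return sp.csc_matrix(M), s, subs


def initial_vector(spec: ModelSpec, grid: Grid, subs: List[tuple],
                   initial: Optional[GradientState]) -> np.ndarray:
    n = grid.n_bins
    y0 = np.zeros(len(subs) * n)
    if initial is not None:
        for i, (species, state) in enumerate(subs):
            arr = initial.data[species]
            if state is None:
                y0[i * n:(i + 1) * n] = arr if arr.ndim == 1 else arr.sum(axis=0)
            else:
                y0[i * n:(i + 1) * n] = arr[MATURATION_STATES.index(state)]
        return y0
    if spec.name == "RNA-diff":
        i = subs.index(("rna", None))
        y0[i * n:(i + 1) * n] = rna_bolus(spec, grid)
    return y0


def _vector_to_state(y: np.ndarray, t: float, grid: Grid,
                     subs: List[tuple], maturation) -> GradientState:
    n = grid.n_bins
    data = {}
    for species in dict.fromkeys(s for s, _ in subs):
        states = [st for sp_name, st in subs if sp_name == species]
        if states == [None]:
            i = subs.index((species, None))
            data[species] = y[i * n:(i + 1) * n].copy()
        else:
            arr = np.empty((len(states), n))
            for k, st in enumerate(states):
                i = subs.index((species, st))
                arr[k] = y[i * n:(i + 1) * n]
            data[species] = arr
    return GradientState(time=t, grid=grid, data=data)


def _clip_negatives(y: np.ndarray) -> np.ndarray:
    scale = np.max(np.abs(y)) if y.size else 0.0
    if scale == 0.0:
        return y
    tol = 1e-7 * scale
    if y.min() < -tol:
        raise SolverError(
            f"negative concentrations beyond tolerance: min={y.min():.3e}, "
            f"scale={scale:.3e}; refine the grid or tighten solver tolerances")
    return np.clip(y, 0.0, None)


def simulate(spec: ModelSpec, grid: Grid, t_end: float, dt_out: float,
             maturation=None, t_start: float = 0.0,
             initial: Optional[GradientState] = None,
             production_factor: float = 1.0, degradation_factor: float = 1.0,
             rtol: float = 1e-6, atol: float = 1e-9) -> List[GradientState]:
    """Integrate a model to ``t_end`` (s), returning states at every
    ``dt_out`` from ``t_start`` (both endpoints included).

    ``initial``/``t_start`` allow chaining runs (e.g. step perturbations);
    ``production_factor``/``degradation_factor`` rescale the source term and
    the protein degradation rate for this segment.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    subs = _subspecies(spec, maturation)
    y0 = initial_vector(spec, grid, subs, initial)
    n_out = int(round((t_end - t_start) / dt_out))
    t_eval = t_start + dt_out * np.arange(n_out + 1)
    t_eval[-1] = min(t_eval[-1], t_end)

    # integration breakpoints: trapping-rate steps (nuclear cycles)
    breaks = [t for t in spec.cycle_boundaries(t_end) if t > t_start]
    seg_edges = [t_start] + breaks + [t_end]

    states: List[GradientState] = []
    y = y0.copy()
    time_dependent_D = spec.params.D_time_dependence is not None
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        M, s, _ = assemble_operator(spec, grid, maturation, t=a,
                                    production_factor=production_factor,
                                    degradation_factor=degradation_factor)

        if time_dependent_D:
            def rhs(t, yv):
                Mt, st, _ = assemble_operator(
                    spec, grid, maturation, t=t,
                    production_factor=production_factor,
                    degradation_factor=degradation_factor)
                return Mt @ yv + st

            def jac(t, yv):
                Mt, _, _ = assemble_operator(
                    spec, grid, maturation, t=t,
                    production_factor=production_factor,
                    degradation_factor=degradation_factor)
                return Mt
        else:
            def rhs(t, yv, M=M, s=s):
                return M @ yv + s

            jac = M

        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        # always land exactly on the segment end to continue integration
        sol = solve_ivp(rhs, (a, b), y, method="BDF", jac=jac,
                        t_eval=np.unique(np.concatenate([seg_eval, [b]])),
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(f"integration failed on [{a}, {b}]: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SolverError("non-finite values in solution")
        for idx, t in enumerate(sol.t):
            if np.any(np.isclose(t, seg_eval, rtol=0, atol=1e-9)) and not (
                    states and np.isclose(states[-1].time, t, rtol=0, atol=1e-9)):
                yv = _clip_negatives(sol.y[:, idx].copy())
                states.append(_vector_to_state(yv, t, grid, subs, maturation))
        y = _clip_negatives(sol.y[:, -1].copy())
    return states


def fit_cosh(positions: np.ndarray, values: np.ndarray, L: float,
             fit_range: Optional[tuple] = None) -> tuple:
    """Least-squares fit of A*cosh((L-x)/lam) -- the steady-state profile of
    a diffusing, degrading species with no-flux boundaries.  Returns
    ``(A, lam)``.  Unlike a pure exponential fit, this recovers the decay
    length correctly even when lam is comparable to the domain length.
    """
    from scipy.optimize import curve_fit

    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if fit_range is not None:
        sel = (positions >= fit_range[0]) & (positions <= fit_range[1])
        positions, values = positions[sel], values[sel]
    if positions.size < 5:
        raise ValueError("need >= 5 points for the cosh fit")
    try:
        _, lam0 = fit_exponential(positions, values,
                                  (positions[0], positions[-1]))
    except ValueError:
        lam0 = L / 5.0
    popt, _ = curve_fit(lambda x, A, lam: A * np.cosh((L - x) / lam),
                        positions, values,
                        p0=(values[-1], lam0), maxfev=10000)
    A, lam = float(popt[0]), float(abs(popt[1]))
    if not (np.isfinite(A) and np.isfinite(lam)) or lam <= 0:
        raise ValueError("cosh fit returned a degenerate solution")
    return A, lam


def steady_state(spec: ModelSpec, grid: Grid, maturation=None,
                 production_factor: float = 1.0,
                 degradation_factor: float = 1.0) -> GradientState:
    """Direct steady state M y = -s (only for models with a steady state)."""
    M, s, subs = assemble_operator(spec, grid, maturation,
                                   production_factor=production_factor,
                                   degradation_factor=degradation_factor)
    if not s.any():
        raise ValueError("model has no inhomogeneous steady state")
    y = sp.linalg.spsolve(M, -s)
    y = _clip_negatives(np.asarray(y))
    return _vector_to_state(y, math.inf, grid, subs, maturation)
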