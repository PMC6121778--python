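"""Particle-level Monte Carlo realization of the gradient models.

Serves as the independent oracle for the age-moment PDEs and the timer
forward model: each particle carries its own birth time, position and
fluorophore maturation state, so binned mean ages and channel intensities
can be compared against the deterministic predictions without sharing any
numerics with them.

Dynamics per time step dt:
  * diffusion: Euler-Maruyama, step SD = sqrt(2 D dt), reflecting at both
    boundaries (matching the no-flux PDE condition);
  * birth: Poisson(J dt) new particles in the anterior source strip (or an
    exponential source profile), entering fully immature;
  * degradation and maturation: exponential clocks drawn at birth
    (constant-rate processes, so the clocks are exact); nuclear trapping /
    release use per-step Bernoulli events because the trapping rate is
    time-dependent;
  * RNA-diffusion model: RNA particles diffuse and die by exponential
    clocks; each live RNA spawns protein particles at rate beta at its
    current position; protein particles are immobile and immortal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_models import ModelSpec, MIN
from .age_analytics import AgeProfile

SOURCE_STRIP_UM = 2.0   # anterior strip receiving point-source births
MAX_EVENT_PROB = 0.1    # per-step probability bound enforced on all rates


@dataclass
class ParticleEnsemble:
    """Protein particles at the final clock time.

    ``red_state``: 0 immature, 1 intermediate, 2 mature.  Dead particles are
    retained with ``alive = False`` so lineage statistics stay available.
    """

    clock: float                 # s
    L: float                     # um
    seed: int
    position: np.ndarray         # um
    birth_time: np.ndarray       # s
    alive: np.ndarray            # bool
    green_mature: np.ndarray     # bool
    red_state: np.ndarray        # int8
    dt: float = 0.0

    @property
    def ages(self) -> np.ndarray:
        return self.clock - self.birth_time

    def alive_ages(self) -> np.ndarray:
        return self.ages[self.alive]


def _check_dt(dt: float, rates: dict) -> None:
    for name, r in rates.items():
        if r * dt > MAX_EVENT_PROB:
            raise ValueError(
                f"per-step event probability for {name} is {r * dt:.3f} > "
                f"{MAX_EVENT_PROB}; use dt <= {MAX_EVENT_PROB / r:.1f} s")


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    # fold positions back into [0, L]; a single fold suffices for step << L
    x = np.abs(x)
    over = x > L
    x[over] = 2.0 * L - x[over]
    return np.clip(x, 0.0, L)


def _source_positions(spec: ModelSpec, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    if spec.synthesis_profile in ("exp_source", "rna_gradient"):
        lam = spec.synthesis_length
        x = rng.exponential(lam, size=n)
        # resample the rare tail beyond the domain
        while np.any(x > spec.params.domain_length):
            bad = x > spec.params.domain_length
            x[bad] = rng.exponential(lam, size=bad.sum())
        return x
    return rng.uniform(0.0, SOURCE_STRIP_UM, size=n)


def run_particles(spec: ModelSpec, t_end: float, dt: float, seed: int,
                  birth_rate: Optional[float] = None,
                  n_initial: Optional[int] = None) -> ParticleEnsemble:
    """Simulate protein particles under ``spec`` until ``t_end`` seconds.

    ``birth_rate`` (particles/s) overrides the spec's synthesis rate;
    ``n_initial`` overrides the RNA bolus size (RNA-diff) or seeds an
    initial protein bolus when the model has no source.  A fixed ``seed``
    gives bitwise-identical ensembles.
    """
    rng = np.random.default_rng(seed)
    L = spec.params.domain_length
    n_steps = int(round(t_end / dt))
    k = spec.k_protein
    D = spec.diffusion.get("protein", spec.diffusion.get("protein_cyt", 0.0))

    rates = {"degradation": k}
    if spec.name == "NucSh":
        rates["trapping"] = spec.trapping_rate(t_end)
        rates["release"] = spec.k_off
    if spec.name == "RNA-diff":
        rates["rna decay"] = spec.degradation["rna"]
        rates["translation"] = spec.translation_rate
    _check_dt(dt, rates)

    if spec.name == "RNA-diff":
        return _run_rna_diff(spec, t_end, dt, rng, seed, n_initial)

    J = birth_rate if birth_rate is not None else spec.synthesis_rate
    births_per_step = rng.poisson(J * dt, size=n_steps)
    n_total = int(births_per_step.sum())
    birth_step = np.repeat(np.arange(n_steps), births_per_step)
    birth_time = (birth_step + 1) * dt
    position = _source_positions(spec, n_total, rng)
    if n_initial:
        position = np.concatenate([
            rng.uniform(0.0, SOURCE_STRIP_UM, size=n_initial), position])
        birth_time = np.concatenate([np.zeros(n_initial), birth_time])
        birth_step = np.concatenate(
            [np.full(n_initial, -1, dtype=int), birth_step])
        n_total += n_initial

    death_time = (birth_time + rng.exponential(1.0 / k, size=n_total)
                  if k > 0 else np.full(n_total, np.inf))
    trapped = np.zeros(n_total, dtype=bool)  # NucSh only
    step_sd = math.sqrt(2.0 * D * dt) if D > 0 else 0.0

    for step in range(n_steps):
        t0, t1 = step * dt, (step + 1) * dt
        active = (birth_step < step) & (death_time > t0)
        if spec.name == "NucSh":
            k_on = spec.trapping_rate(t0)
            free = active & ~trapped
            caught = free & (rng.random(n_total) < -np.expm1(-k_on * dt))
            released = (active & trapped
                        & (rng.random(n_total) < -np.expm1(-spec.k_off * dt)))
            trapped[caught] = True
            trapped[released] = False
            mobile = active & ~trapped
        else:
            mobile = active
        if step_sd > 0 and mobile.any():
            position[mobile] = _reflect(
                position[mobile] + rng.normal(0.0, step_sd, mobile.sum()), L)

    alive = death_time > t_end
    return ParticleEnsemble(
        clock=t_end, L=L, seed=seed, position=position,
        birth_time=birth_time, alive=alive,
        green_mature=np.zeros(n_total, dtype=bool),
        red_state=np.zeros(n_total, dtype=np.int8), dt=dt)


def _run_rna_diff(spec: ModelSpec, t_end: float, dt: float,
                  rng: np.random.Generator, seed: int,
                  n_rna: Optional[int]) -> ParticleEnsemble:
    L = spec.params.domain_length
    n_steps = int(round(t_end / dt))
    n_rna = int(n_rna if n_rna is not None else spec.params.rna_bolus_amount)
    k_rna = spec.degradation["rna"]
    beta = spec.translation_rate
    D_rna = spec.diffusion["rna"]

    rna_x = rng.uniform(0.0, spec.params.rna_bolus_width, size=n_rna)
    rna_death = rng.exponential(1.0 / k_rna, size=n_rna)
    step_sd = math.sqrt(2.0 * D_rna * dt)

    prot_x = []
    prot_t = []
    for step in range(n_steps):
        t0 = step * dt
        live = rna_death > t0
        n_live = int(live.sum())
        if n_live == 0:
            break
        n_births = rng.poisson(beta * dt * n_live)
        if n_births:
            idx = rng.choice(np.flatnonzero(live), size=n_births)
            prot_x.append(rna_x[idx].copy())
            prot_t.append(np.full(n_births, t0 + dt))
        rna_x[live] = _reflect(
            rna_x[live] + rng.normal(0.0, step_sd, n_live), L)

    position = np.concatenate(prot_x) if prot_x else np.empty(0)
    birth_time = np.concatenate(prot_t) if prot_t else np.empty(0)
    n_total = position.size
    return ParticleEnsemble(
        clock=t_end, L=L, seed=seed, position=position,
        birth_time=birth_time, alive=np.ones(n_total, dtype=bool),
        green_mature=np.zeros(n_total, dtype=bool),
        red_state=np.zeros(n_total, dtype=np.int8), dt=dt)


def assign_maturation(ensemble: ParticleEnsemble, maturation,
                      seed: Optional[int] = None) -> ParticleEnsemble:
    """Draw fluorophore maturation states from exponential clocks.

    Maturation is independent of position and survival, so states can be
    assigned after the spatial simulation: green matures after Exp(m_g);
    red reaches the intermediate state after Exp(m_r1) and full maturity
    after a further Exp(m_r2).
    """
    rng = np.random.default_rng(ensemble.seed + 1 if seed is None else seed)
    n = ensemble.position.size
    ages = ensemble.ages
    t_green = rng.exponential(1.0 / maturation.m_g, size=n)
    t_red1 = rng.exponential(1.0 / maturation.m_r1, size=n)
    t_red2 = t_red1 + rng.exponential(1.0 / maturation.m_r2, size=n)
    ensemble.green_mature = t_green <= ages
    red = np.zeros(n, dtype=np.int8)
    red[t_red1 <= ages] = 1
    red[t_red2 <= ages] = 2
    ensemble.red_state = red
    return ensemble


MIN_BIN_COUNT = 20


def binned_age(ensemble: ParticleEnsemble, bin_width: float = 10.0):
    """Mean age, standard error and particle count per spatial bin.

    Returns an :class:`AgeProfile` (ages in minutes) plus ``(se_min,
    counts)`` arrays.  Bins with fewer than 20 particles are flagged as
    undefined; SE is NaN for bins with fewer than 2 particles.
    """
    if ensemble.position.size == 0 or not ensemble.alive.any():
        raise ValueError("empty ensemble")
    n_bins = int(round(ensemble.L / bin_width))
    edges = np.linspace(0.0, ensemble.L, n_bins + 1)
    pos = ensemble.position[ensemble.alive]
    ages = ensemble.alive_ages() / MIN
    idx = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=ages, minlength=n_bins)
    sumsq = np.bincount(idx, weights=ages ** 2, minlength=n_bins)
    mean = np.zeros(n_bins)
    se = np.full(n_bins, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    mult = counts > 1
    var = np.zeros(n_bins)
    var[mult] = (sumsq[mult] - counts[mult] * mean[mult] ** 2) / (counts[mult] - 1)
    se[mult] = np.sqrt(np.maximum(var[mult], 0.0) / counts[mult])
    centres = 0.5 * (edges[:-1] + edges[1:])
    profile = AgeProfile(positions=centres, mean_age_min=mean,
                         moment=mean * counts, conc=counts.astype(float),
                         time=ensemble.clock,
                         defined=counts >= MIN_BIN_COUNT)
    return profile, se, counts
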