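"""Gradient-formation models for an anterior-posterior morphogen axis.

Four candidate mechanisms for how a morphogen such as Bicoid builds its
exponential-like concentration gradient along a 1-D embryo axis:

``SDD``
    Synthesis-diffusion-degradation: protein is injected at the anterior
    pole, diffuses with coefficient ``D`` and is degraded everywhere with
    first-order rate ``k = ln2 / t_half``.  Steady-state decay length
    ``lambda = sqrt(D / k)``.
``NucSh``
    Nuclear shuttling: protein is injected anteriorly and diffuses, but is
    never degraded.  Instead it is reversibly trapped by nuclei whose
    number doubles every division cycle, so the trapping rate grows as
    ``k_on(t) = k_on0 * 2**cycle``.
``RNA-grad``
    A fixed, exponentially decaying mRNA profile ``exp(-x / lambda_RNA)``
    sources protein everywhere; protein degrades and diffuses only slowly.
``RNA-diff``
    mRNA starts as an anterior bolus, diffuses and degrades; protein is
    translated locally from the mRNA and neither diffuses nor degrades.
    The protein gradient freezes once the mRNA is gone.

All four produce similar concentration profiles at the relevant stage
(early nuclear cycle 14, ~2.5 h after egg laying) but make distinct
predictions for the *age* of the protein as a function of position, which
is what the rest of this package measures and exploits.

Units: lengths in micrometres, diffusion in um^2/s, half-lives in minutes
(converted to first-order rates in 1/s when a model is resolved), synthesis
in molecules per second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

MIN = 60.0  # seconds per minute
LN2 = math.log(2.0)

MODEL_NAMES = ("SDD", "NucSh", "RNA-grad", "RNA-diff")

#: models whose protein species is not degraded (half-life must be None)
NON_DEGRADING_MODELS = frozenset({"NucSh", "RNA-diff"})

#: default nuclear-division schedule: (start_min, duration_min) per cycle,
#: n.c. 10-13 at 10 min each starting 90 min after egg laying, then n.c. 14
#: open-ended (duration None).  Each cycle start doubles the trapping rate.
DEFAULT_NUCLEI_SCHEDULE: tuple = (
    (90.0, 10.0),
    (100.0, 10.0),
    (110.0, 10.0),
    (120.0, 10.0),
    (130.0, None),
)


class ModelValidationError(ValueError):
    """A parameter set violates a model's structural invariants."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def half_life_to_rate(t_half_min: Optional[float]) -> float:
    """First-order rate (1/s) from a half-life in minutes; None -> 0."""
    if t_half_min is None:
        return 0.0
    return LN2 / (t_half_min * MIN)


@dataclass
class ModelParams:
    """Kinetic, transport and source parameters for a gradient model.

    Half-lives (and maturation half-times elsewhere in the package) follow
    the convention rate = ln2 / T.  ``protein_half_life`` must be None for
    the non-degrading models (NucSh, RNA-diff).
    """

    D_protein: float = 3.6              # um^2/s
    protein_half_life: Optional[float] = 26.0   # min; None = no degradation
    synthesis_rate: float = 1.0         # molecules/s injected at the source
    source_decay_length: float = 0.0    # um; ~0 means a point source at x=0
    D_rna: Optional[float] = None       # um^2/s (RNA-diff only)
    rna_half_life: Optional[float] = None   # min (RNA-diff only)
    rna_gradient_length: Optional[float] = None  # um (RNA-grad only)
    translation_rate: float = 1.0 / MIN  # protein per RNA per second
    k_on0: Optional[float] = None       # 1/s base trapping rate (NucSh only)
    k_off: Optional[float] = None       # 1/s release rate (NucSh only)
    nuclei_doubling_schedule: Sequence = DEFAULT_NUCLEI_SCHEDULE
    domain_length: float = 500.0        # um
    rna_bolus_width: float = 20.0       # um, RNA-diff initial condition
    rna_bolus_amount: float = 1000.0    # molecules in the initial RNA bolus
    D_time_dependence: Optional[tuple] = None  # (D0, D1, t0_min): D(t)=D0-D1*sqrt(t/t0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nuclei_doubling_schedule"] = [list(c) for c in self.nuclei_doubling_schedule]
        if self.D_time_dependence is not None:
            d["D_time_dependence"] = list(self.D_time_dependence)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        if "nuclei_doubling_schedule" in d:
            d["nuclei_doubling_schedule"] = tuple(
                tuple(c) for c in d["nuclei_doubling_schedule"]
            )
        if d.get("D_time_dependence") is not None:
            d["D_time_dependence"] = tuple(d["D_time_dependence"])
        return cls(**d)


@dataclass
class ModelSpec:
    """A fully resolved model: every reaction and transport term numeric.

    ``species`` lists the compartments integrated by the solvers:
    ``protein`` (SDD, RNA-grad), ``protein_cyt``/``protein_nuc`` (NucSh),
    ``rna`` + ``protein`` (RNA-diff).  ``diffusion`` and ``degradation``
    map species name to D (um^2/s) and k (1/s).
    """

    name: str
    params: ModelParams
    species: tuple
    diffusion: dict          # species -> D (um^2/s)
    degradation: dict        # species -> k (1/s)
    synthesis_species: str   # species receiving the source term
    synthesis_rate: float    # molecules/s total influx
    synthesis_profile: str   # "point" | "exp_source" | "rna_gradient"
    synthesis_length: float = 0.0   # um, decay length of extended source
    translation_rate: float = 0.0   # 1/s, RNA -> protein (RNA-diff)
    k_on0: float = 0.0
    k_off: float = 0.0

    @property
    def protein_species(self) -> tuple:
        return tuple(s for s in self.species if s.startswith("protein"))

    @property
    def k_protein(self) -> float:
        return self.degradation[self.protein_species[0]]

    def trapping_rate(self, t: float) -> float:
        """Nuclear trapping rate k_on(t) = k_on0 * 2**(cycles started by t)."""
        if self.k_on0 == 0.0:
            return 0.0
        n = sum(1 for start, _ in self.params.nuclei_doubling_schedule
                if t >= start * MIN)
        return self.k_on0 * 2.0 ** n

    def cycle_boundaries(self, t_end: float) -> list:
        """Times (s) in (0, t_end) where the trapping rate steps."""
        if self.k_on0 == 0.0:
            return []
        return [s * MIN for s, _ in self.params.nuclei_doubling_schedule
                if 0.0 < s * MIN < t_end]

    def diffusion_at(self, species: str, t: float) -> float:
        """Diffusion coefficient, honouring optional D(t) = D0 - D1*sqrt(t/t0)."""
        D = self.diffusion[species]
        td = self.params.D_time_dependence
        if td is not None and species.startswith("protein") and D > 0:
            D0, D1, t0_min = td
            D = max(D0 - D1 * math.sqrt(max(t, 0.0) / (t0_min * MIN)), 0.0)
        return D

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return make_model(d["name"], ModelParams.from_dict(d["params"]))


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ModelValidationError(field_name, msg)


def validate_params(name: str, p: ModelParams) -> None:
    if name not in MODEL_NAMES:
        raise ModelValidationError("name", f"unknown model {name!r}; "
                                   f"expected one of {MODEL_NAMES}")
    _require(p.domain_length > 0, "domain_length", "must be positive")
    _require(p.D_protein >= 0, "D_protein", "must be non-negative")
    _require(p.synthesis_rate >= 0, "synthesis_rate", "must be non-negative")
    _require(p.source_decay_length >= 0, "source_decay_length",
             "must be non-negative")
    if name in NON_DEGRADING_MODELS:
        _require(p.protein_half_life is None, "protein_half_life",
                 f"the {name} protein does not degrade; half-life must be None")
    else:
        _require(p.protein_half_life is not None and p.protein_half_life > 0,
                 "protein_half_life", f"the {name} model requires a positive "
                 "protein half-life")
    if name == "RNA-grad":
        _require(p.rna_gradient_length is not None and p.rna_gradient_length > 0,
                 "rna_gradient_length", "required (positive) for RNA-grad")
    else:
        _require(p.rna_gradient_length is None, "rna_gradient_length",
                 "only meaningful for the RNA-grad model")
    if name == "RNA-diff":
        _require(p.D_rna is not None and p.D_rna >= 0, "D_rna",
                 "required for RNA-diff")
        _require(p.rna_half_life is not None and p.rna_half_life > 0,
                 "rna_half_life", "required (positive) for RNA-diff")
        _require(p.translation_rate > 0, "translation_rate",
                 "must be positive for RNA-diff")
        _require(p.rna_bolus_width > 0, "rna_bolus_width", "must be positive")
    if name == "NucSh":
        _require(p.k_on0 is not None and p.k_on0 > 0, "k_on0",
                 "required (positive) for NucSh")
        _require(p.k_off is not None and p.k_off >= 0, "k_off",
                 "required for NucSh")


def make_model(name: str, params: ModelParams) -> ModelSpec:
    """Resolve a named model + parameters into a numeric specification.

    Deterministic; round-trips through :meth:`ModelSpec.to_dict`.
    Raises :class:`ModelValidationError` naming the offending field when the
    parameters violate the model's invariants.
    """
    validate_params(name, params)
    k = half_life_to_rate(params.protein_half_life)
    profile = "exp_source" if params.source_decay_length > 1e-9 else "point"

    if name == "SDD":
        return ModelSpec(
            name=name, params=params, species=("protein",),
            diffusion={"protein": params.D_protein},
            degradation={"protein": k},
            synthesis_species="protein", synthesis_rate=params.synthesis_rate,
            synthesis_profile=profile,
            synthesis_length=params.source_decay_length,
        )
    if name == "NucSh":
        return ModelSpec(
            name=name, params=params,
            species=("protein_cyt", "protein_nuc"),
            diffusion={"protein_cyt": params.D_protein, "protein_nuc": 0.0},
            degradation={"protein_cyt": 0.0, "protein_nuc": 0.0},
            synthesis_species="protein_cyt",
            synthesis_rate=params.synthesis_rate,
            synthesis_profile=profile,
            synthesis_length=params.source_decay_length,
            k_on0=float(params.k_on0), k_off=float(params.k_off),
        )
    if name == "RNA-grad":
        return ModelSpec(
            name=name, params=params, species=("protein",),
            diffusion={"protein": params.D_protein},
            degradation={"protein": k},
            synthesis_species="protein", synthesis_rate=params.synthesis_rate,
            synthesis_profile="rna_gradient",
            synthesis_length=float(params.rna_gradient_length),
        )
    # RNA-diff
    return ModelSpec(
        name=name, params=params, species=("rna", "protein"),
        diffusion={"rna": float(params.D_rna), "protein": 0.0},
        degradation={"rna": half_life_to_rate(params.rna_half_life),
                     "protein": 0.0},
        synthesis_species="rna", synthesis_rate=0.0,  # RNA enters as a bolus
        synthesis_profile="point",
        translation_rate=params.translation_rate,
    )


def default_params(name: str) -> ModelParams:
    """Reference parameterization per model, each passing the screening
    filter (decay length 70-100 um at 2.5 h) -- the same viability criterion
    applied when scanning parameter space."""
    if name == "SDD":
        return ModelParams(D_protein=3.6, protein_half_life=26.0)
    if name == "NucSh":
        return ModelParams(D_protein=3.0, protein_half_life=None,
                           k_on0=2e-4, k_off=2e-4)
    if name == "RNA-grad":
        return ModelParams(D_protein=0.1, protein_half_life=26.0,
                           rna_gradient_length=90.0)
    if name == "RNA-diff":
        return ModelParams(D_protein=0.0, protein_half_life=None,
                           D_rna=3.5, rna_half_life=26.0,
                           translation_rate=1.0 / MIN)
    raise ModelValidationError("name", f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# screening: does a simulated profile look like the observed gradient?
# ---------------------------------------------------------------------------

DEFAULT_FIT_RANGE = (100.0, 400.0)   # um from the anterior pole
SCREEN_LAMBDA_BAND = (70.0, 100.0)   # um; accepted decay lengths


def fit_exponential(positions: np.ndarray, values: np.ndarray,
                    fit_range: tuple = DEFAULT_FIT_RANGE) -> tuple:
    """Nonlinear least-squares fit of A*exp(-x/lambda) over a window.

    Returns ``(A, lam)``.  Raises ValueError on degenerate input (fewer than
    5 points in range, non-positive values) or non-convergence.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = fit_range
    sel = (positions >= lo) & (positions <= hi)
    x, y = positions[sel], values[sel]
    if x.size < 5:
        raise ValueError(f"need >= 5 points in range {fit_range}, got {x.size}")
    if np.any(y <= 0):
        raise ValueError("profile must be strictly positive over the fit range")
    # log-linear regression provides the starting point
    slope, intercept = np.polyfit(x, np.log(y), 1)
    if slope >= 0:
        raise ValueError("profile does not decay over the fit range "
                         "(lambda would be infinite or negative)")
    lam0 = -1.0 / slope
    A0 = math.exp(intercept)

    def model(x, A, lam):
        # clip the exponent: curve_fit may probe extreme lam values
        return A * np.exp(np.clip(-x / lam, -700.0, 700.0))

    try:
        with np.errstate(over="ignore"):
            popt, _ = curve_fit(model, x, y, p0=(A0, lam0), maxfev=10000)
    except RuntimeError as e:  # pragma: no cover - curve_fit nonconvergence
        raise ValueError(f"exponential fit did not converge: {e}") from e
    A, lam = float(popt[0]), float(popt[1])
    if not (np.isfinite(A) and np.isfinite(lam)) or lam <= 0:
        raise ValueError("exponential fit returned a degenerate solution")
    return A, lam


def screening_filter(positions: np.ndarray, values: np.ndarray,
                     fit_range: tuple = DEFAULT_FIT_RANGE,
                     band: tuple = SCREEN_LAMBDA_BAND) -> tuple:
    """Accept a concentration profile iff its fitted decay length lies in
    the observed band (default 70-100 um, fit window 100-400 um).

    Returns ``(accepted, lam)``.
    """
    _, lam = fit_exponential(positions, values, fit_range)
    lo, hi = band
    return (lo <= lam <= hi), lam
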