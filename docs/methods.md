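# Methods

## The problem

A morphogen gradient along the anterior-posterior (AP) axis of the early
*Drosophila* embryo can arise from several mechanisms that all produce an
exponential-like concentration profile at the stage where it is read out
(early nuclear cycle 14, ~2.5 h after egg laying).  Concentration snapshots
therefore cannot discriminate the mechanisms.  The *age* of the protein as
a function of position can: it is measured by a tandem fluorescent timer
(tFT) — a fast-maturing green fluorophore fused to a slow-maturing red one
— whose red/green intensity ratio increases with the mean age of the local
protein pool.

This package implements the full analysis chain: the four candidate
gradient-formation models, deterministic and stochastic simulation with
fluorophore maturation states, mean-age analytics, the timer forward model,
simultaneous fitting of green-intensity and ratio profiles, phase-plane
analysis of production/degradation changes, and a synthetic-data generator
that emulates extracted light-sheet AP profiles so every stage can be
validated end to end.

## Models

All models live on a 1-D axis of length L = 500 μm with no-flux boundaries;
protein is inserted at x = 0 (flux into the first grid cell) unless noted.
Rates follow the half-life convention k = ln2 / T throughout, for
degradation and for fluorophore maturation alike.

* **SDD** (synthesis–diffusion–degradation): ∂C/∂t = D ∂²C/∂x² − kC + s(x).
  Steady-state decay length λ = √(D/k); defaults D = 3.6 μm²/s, protein
  half-life 26 min (λ ≈ 90 μm).
* **NucSh** (nuclear shuttling): no degradation; cytoplasmic protein
  diffuses and is reversibly trapped by nuclei whose number doubles every
  division cycle, k_on(t) = k_on0·2^(cycles started).  The trapping
  constants and cycle schedule are not printed in the sources available to
  us; the defaults (D = 3.0 μm²/s, k_on0 = 2·10⁻⁴ s⁻¹, k_off = 2·10⁻⁴ s⁻¹,
  cycles starting at 90, 100, 110, 120 min with cycle 14 open-ended from
  130 min) were chosen once so that the model passes the same screening
  filter applied to every model (decay length 70–100 μm at 2.5 h) — the
  viability criterion the analysis itself imposes — and are exposed in the
  configuration.
* **RNA-grad**: a static mRNA profile e^(−x/λ_RNA) sources protein
  everywhere; protein degrades (t½ = 26 min) and diffuses slowly
  (D = 0.1 μm²/s); default λ_RNA = 90 μm.
* **RNA-diff**: mRNA starts as an anterior bolus (uniform over the first
  20 μm), diffuses (D = 3.5 μm²/s) and degrades (t½ = 26 min); protein is
  translated locally and neither moves nor degrades.  The protein gradient
  freezes once the mRNA is gone; λ → √(D_RNA/k_RNA) ≈ 89 μm.

## Numerics

Method of lines with second-order central differences (default 250 bins,
dx = 2 μm), integrated with BDF (adaptive, stiff) using the exact sparse
Jacobian.  Every model is linear, dy/dt = M(t)y + s, with M piecewise
constant in time; the integrator restarts at nuclear-cycle boundaries.
Optional time-dependent diffusion D(t) = D0 − D1·√(t/t0) is supported with
a per-step Jacobian.  Convergence: doubling the resolution changes the
fitted decay length by < 1% (tested).  Negative concentrations from the
adaptive integrator are clipped at 10⁻⁷ of the field maximum; anything
larger raises a solver error (at BDF tolerance rtol = 10⁻⁶ the legitimate
undershoot near sharp fronts exceeds machine-level thresholds, so a
stricter clip would reject healthy solutions).

With maturation enabled, each protein compartment splits into six
sub-states: green ∈ {immature, mature} × red ∈ {immature, intermediate,
mature}.  Synthesis enters the fully immature state; green matures at
m_g, red sequentially at m_r1 then m_r2 (the red intermediate is dark);
all states share the protein's transport and degradation.  Presets:
sfGFP–mCherry = (27, 40, 9) min half-times with Gaussian prior SDs
(2.7, 4, 0.9) min; sfGFP–fmCherry = (27, 6, 6) min with SDs (2.7, 2, 2)
min (the sources give 6 ± 2 per fmCherry step; the green SD follows the
mCherry preset).

## Protein age

The first age moment m(x,t) = C·Ā obeys ∂m/∂t = T[m] − km + C for any
linear transport T: age-mass is carried with the protein, destroyed
proportionally by degradation, and grows at rate C because every molecule
ages at unit rate; new synthesis enters at age zero and so does not appear.
For the RNA-diffusion model the translation coupling is removed from the
moment operator (mRNA age must not leak into protein age).  Mean age is
m/C where C exceeds 10⁻¹² of its maximum; lower bins are flagged rather
than returned as NaN.

Three independent oracles validate the implementation: a decaying bolus
has Ā = t exactly; a well-mixed source–degradation balance has Ā = 1/k
(exponential age distribution); and a particle-level Monte Carlo
simulation — Euler–Maruyama diffusion (step SD √(2D dt)), reflecting
boundaries, Poisson births, exponential degradation/maturation clocks,
per-step Bernoulli trapping for the shuttling model — reproduces the
binned moment-PDE ages within 3 standard errors for all four models at
2.5 h (default 2×10⁴ particles alive, dt = 2 s, sized so 3-SE agreement is
a meaningful test).

Age-profile classification over 100–400 μm: a model is "flat" when its
linear-trend age change is below 20% of the SDD reference change, a
threshold that cleanly separates the four models' predictions; it is
configurable.  Parameter sweeps sample log-uniformly for rates and
diffusion (two decades) and uniformly for lengths, keep only parameter
sets passing the screening filter (λ ∈ [70, 100] μm fit over 100–400 μm),
and report mean ± SD envelopes of window-normalized age profiles.

## Timer forward model and artifacts

green = Σ(green-matured states) − f·(doubly matured state) + free-GFP pool;
red = ε·Σ(red-matured states); ratio = red/green masked where green is
below 10⁻⁹ of its peak.  ε is the free scaling between the channels.  FRET
is modelled as pure donor quenching of the doubly matured species
(default f = 0, sensitivity runs at 0.15–0.20): the slow red maturation
makes the doubly matured pool oldest, so quenching raises the apparent
ratio.  The free-GFP artifact integrates φ × (degradation flux of
green-matured protein) into a stable, immobile green-only pool
(trapezoidal over the stored state history), lowering the ratio.  The
well-mixed steady-state ratio has the closed form

    ratio = ε · [m_r1 m_r2 / ((m_r1+k)(m_r2+k))] / [m_g / (m_g+k)],

validated against long-time ODE integration to < 0.1%; it is strictly
increasing in protein half-life for sfGFP–mCherry, and decreasing (above
t½ ≈ 12 min) for sfGFP–fmCherry, producing the spatial ratio-slope
reversal between the two reporters.

## Fitting

Objective: r² = r²_green + r²_ratio with
r²_O = (1/N_O) Σ ((E_i − O_i)/⟨O⟩)², ⟨O⟩ the mean observed value.  The
printed form of this normalization is typographically ambiguous in our
sources; dividing the squared residuals by N·⟨O⟩² makes both components
dimensionless and balances their contributions, which is the stated intent.
Both observables' N are recorded separately in the result.

Minimization: Nelder–Mead over the model's nonlinear parameters on a log
scale (default 16 restarts; maturation half-times drawn from their Gaussian
priors per restart, restart 0 at the prior means; simplex tolerances 10⁻⁸
on the objective and 10⁻⁶ on parameters).  The green amplitude A and the
channel scaling ε enter the prediction linearly, so they are profiled out
exactly by linear least squares inside every evaluation — a standard
variable-projection reformulation that leaves them free parameters while
halving the simplex dimension.  When the channel scaling has been
calibrated independently, ε can instead be pinned (`eps_fixed`), which
makes the absolute ratio level informative about the degradation rate.
The physiological bounds (D 0.1–10 μm²/s,
lifetimes 10–120 min, RNA range 20–200 μm) are hard constraints.  Fitting
window 60–450 μm (excludes the source cell and the far boundary);
forward-model grid 100 bins (dx = 5 μm; the decay length differs from the
250-bin grid by < 1%, below all tolerances used).

Grid scans fix (D, t½) per cell, profile A and ε analytically, and report
the score map with iso-λ contours D·t½/ln2 = λ² for λ ∈ {75, 95} μm;
interval estimates take the envelope of all cells within (1 + tolerance)
of the best score (default 10%).

## Phase-plane (age/levels) analysis

Trajectories record the anterior-region (0–25% of embryo length) mean green
intensity and mean ratio at 6-min cadence.  Quasi-steady state before a
perturbation is verified as < 1% relative drift of the anterior mean per
10 min (violations flag the trajectory rather than raising).  Step changes
in production and degradation map to quadrants by the signs of the
post-switch intensity and ratio changes with a 2% dead band: production
↓ → intensity ↓, ratio ↑; degradation ↑ → both ↓; production ↑ → intensity
↑, ratio ↓; degradation ↓ → both ↑.  Lifetime-shift experiments compare a
perturbed run against an unperturbed control at the same final time (the
paired-injection design), so a stable construct yields exactly zero change.

## Synthetic data and its calibration

The generator emulates extracted, 10-μm-binned AP profiles: forward-model
green/red channels, an embryo-specific amplitude factor (CV 15%), a
yolk-like autofluorescence background (pedestal 1.0 + raised-cosine bump
0.2 over 100–450 μm, scaled to 30% of the peak green signal; the pedestal
keeps the posterior correction window measurable, and a flat-ish field is
what a bright yolk looks like after projection), shot-like noise
(SD = α√(peak·signal) + floor), and a separate correction channel carrying
the background shape with 1% noise.

Autofluorescence correction follows the posterior-window design: the weight
w zeroes the mean corrected green over 460–500 μm, where the reporter
signal is smallest.  On a 500-μm no-flux domain the gradient retains a
~2% residual tail there, which would bias w.  The weight is therefore
refined: the decay length is pinned from the strong-signal region
(100–400 μm) of the pass-1 corrected profile, and (w, tail amplitude) are
then solved by a two-parameter linear least squares over the posterior
half, raw ≈ w·af + A·cosh((L−x)/λ).  The refinement only engages when the
estimated tail is detectable above the fit's residual scatter, and falls
back to the pass-1 weight when the joint solution is implausible.  A ~2%
under-subtraction bias remains (the green channel is not exactly a cosh —
its matured fraction grows posteriorly); because the background field is
nearly flat, this residual acts as a small uniform offset.  Corrected bins
below the detection limit (2× the posterior residual SD) are censored; the
ratio additionally requires green above max(10% of peak, 3× detection SD).
The red channel is corrected only when the background model leaks into red
(default: green-only background, matching a correction channel chosen for
its correlation with green autofluorescence).  Batch averaging normalizes
each embryo to its anterior-window green before combining, so bins where
censoring drops different embryos do not mix amplitude factors.

The end-to-end recovery experiment mirrors the measurement design: four
embryos per replicate, background-corrected and batch-averaged; the
channel scaling ε is treated as known (a calibrated instrument constant),
so the absolute ratio level — not just its shape — constrains the
degradation rate; maturation half-times are drawn from their priors per
fit restart; and the ratio observable is restricted to bins where the
batch-mean corrected green exceeds 25% of its maximum, where a residual
background cannot bias the level.  With ε left free instead, the ratio
level is absorbed by the scaling and the (D, t½) objective is an iso-λ
valley whose floor is set by noise: per-replicate half-life recovery to
±20% is then unattainable at realistic noise — the same degeneracy that
widens the envelope-based uncertainty intervals of the scan.

Noise calibration: α = 0.005 with a detection floor of 0.1% of peak.  These
were calibrated so that the full generate → correct → fit pipeline on
4-embryo batches reproduces the precision reported for such measurements —
best-fit quality r² ~ 10⁻³ and point estimates D to about ±5% and
half-life to about ±12% — rather than by matching the visual breadth of
published across-embryo ratio bands.  Each 10-μm bin aggregates thousands
of projected pixels, so sub-percent per-bin noise is the realistic regime
for single-snapshot imaging.

What the generator does **not** emulate: pixels and point-spread functions,
nuclear texture, embryo-to-embryo variation in gradient shape or
background shape (only amplitude varies), photobleaching, and stage
uncertainty.  Passing recovery tests therefore demonstrates correctness of
the analysis chain under the stated statistical structure, not robustness
to every feature of real embryo data.

## Problem sizes used in the shipped tests

Deterministic runs use 250 bins (100 for fitting forward models); Monte
Carlo comparisons use ~2×10⁴ alive particles; model selection fits 4
models × 2 restarts; recovery uses 20 replicates × 4 embryos × 2 restarts.
These sizes give the oracle agreements their stated resolution (3 SE per
bin; ±15%/±20% recovery) while keeping the full suite fast.

## Known limitations

* The shuttling-model trapping constants are package defaults, not
  published values; conclusions about NucSh age ordering are robust to
  them (no degradation ⇒ older everywhere), but absolute NucSh ages are
  parameterization-dependent.
* The free-GFP pool uses the stored state history (trapezoidal in the
  output cadence); very coarse `dt_out` underestimates the pool.
* The posterior-window correction assumes the background shape is exactly
  proportional to the correction channel; spectral mismatch between yolk
  autofluorescence in the two channels is not modelled.
* Closed-form age results (Ā = (1 + x/λ)/(2k) for SDD at steady state) are
  derived here and validated against the Monte Carlo oracle, not taken
  from an external source.
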