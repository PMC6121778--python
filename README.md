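# tftgrad

Morphogen-gradient formation models with a protein-age readout.

Several mechanisms can build the exponential anterior–posterior (AP)
concentration gradient of a morphogen such as Bicoid in the early
*Drosophila* embryo — localized synthesis with diffusion and degradation
(SDD), nuclear shuttling without degradation, translation from a static
mRNA gradient, or translation from diffusing, decaying mRNA.  Because all
of them reproduce the observed concentration profile, concentration alone
cannot tell them apart.  The *age* of the protein along the axis can, and
it is measurable with a tandem fluorescent timer (tFT): a fast-maturing
green fluorophore (sfGFP, maturation half-time 27 min) fused to a
slow-maturing red one (mCherry, two sequential steps of 40 and 9 min).
The local red/green intensity ratio rises with the mean age of the protein
pool; for a well-mixed pool with degradation rate k the steady-state ratio
is

    ratio = ε · [m_r1 m_r2 / ((m_r1+k)(m_r2+k))] / [m_g / (m_g+k)],

with m = ln2 / T for each maturation half-time T and ε the free scaling
between the channels.

`tftgrad` is for quantitative biologists who want to simulate these
mechanisms (deterministic reaction–diffusion with six fluorophore
maturation states, or particle-level Monte Carlo), predict mean protein
age via first age-moment PDEs, fit models simultaneously to
green-intensity and red/green-ratio profiles, scan (D, half-life) space,
classify production/degradation changes on an age/levels phase diagram,
and validate the entire pipeline on synthetic light-sheet-like AP
profiles with known ground truth.

## Worked example

```python
import numpy as np
from tftgrad import (Grid, MaturationParams, default_params, make_model,
                     simulate, fit_exponential, intensities_from_state,
                     mean_age, steady_state_ratio)

grid = Grid(L=500.0, n_bins=250)                  # 2-um bins
spec = make_model("SDD", default_params("SDD"))   # D=3.6 um^2/s, t1/2=26 min
mat = MaturationParams(27.0, 40.0, 9.0)           # sfGFP-mCherry half-times

state = simulate(spec, grid, t_end=2.5 * 3600, dt_out=2.5 * 3600,
                 maturation=mat)[-1]
A, lam = fit_exponential(grid.positions, state.total_protein(),
                         (100.0, 400.0))
print(f"decay length at 2.5 h: {lam:.1f} um")

age = mean_age(spec, grid, t=2.5 * 3600)
sel = np.searchsorted(grid.positions, [100.0, 400.0])
print(f"mean age: {age.mean_age_min[sel[0]]:.1f} min at 100 um, "
      f"{age.mean_age_min[sel[1]]:.1f} min at 400 um")

tft = intensities_from_state(state, eps=1.0)
print(f"ratio: {tft.ratio[sel[0]]:.3f} at 100 um, "
      f"{tft.ratio[sel[1]]:.3f} at 400 um")
print(f"well-mixed steady-state ratio at t1/2=26 min: "
      f"{steady_state_ratio(26.0, mat):.3f}")
```

Output:

```
decay length at 2.5 h: 88.0 um
mean age: 37.8 min at 100 um, 89.0 min at 400 um
ratio: 0.577 at 100 um, 0.795 at 400 um
well-mixed steady-state ratio at t1/2=26 min: 0.597
```

The gradient's decay length matches the measured ~89 μm; the protein is
about 51 minutes older at 400 μm than at 100 μm, and the timer ratio rises
accordingly — the SDD signature.  The nuclear-shuttling model predicts an
even steeper age increase (nothing degrades), the static-RNA-gradient
model a flat age profile, and the RNA-diffusion model the inverse trend —
see `age_signature` and `docs/methods.md`.

A command-line interface mirrors the library:

```sh
tftgrad simulate --model SDD --out out/          # gradient + decay length
tftgrad age --model RNA-diff --out out/          # mean-age profile
tftgrad mc --model SDD --seed 7 --out out/       # particle Monte Carlo
tftgrad phase --model SDD --production-factor 0 --out out/
tftgrad recover --seed 3 --out out/              # synth -> correct -> fit
```

Configuration files are YAML (schema in `docs/config_schema.yaml`); every
stochastic command requires an explicit seed and writes a run manifest.

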