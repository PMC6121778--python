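# Run-configuration schema for tftgrad (YAML, one document per run).
# All lengths in micrometres (0 = anterior pole), diffusion in um^2/s,
# half-lives and half-times in minutes, rates in 1/s.  Command-line flags
# (--seed, --model, --out) override file values.  Stochastic commands
# (mc, synth, recover, and fit/scan restarts) require an explicit seed.

seed:           # int | null  — global random seed
out_dir:        # str         — output directory (default ".")
log_verbosity:  # "debug" | "info" | "warning" (default "info")

model:          # str (model name) or mapping with a name plus parameters
  name:         # "SDD" | "NucSh" | "RNA-grad" | "RNA-diff"
  D_protein:            # um^2/s      (default 3.6 for SDD)
  protein_half_life:    # min | null  (null for NucSh and RNA-diff)
  synthesis_rate:       # molecules/s injected at the source (default 1.0)
  source_decay_length:  # um; ~0 = point source at x=0 (default 0)
  D_rna:                # um^2/s      (RNA-diff only)
  rna_half_life:        # min         (RNA-diff only)
  rna_gradient_length:  # um          (RNA-grad only)
  translation_rate:     # protein per RNA per second (RNA-diff)
  k_on0:                # 1/s base nuclear trapping rate (NucSh)
  k_off:                # 1/s release rate (NucSh)
  nuclei_doubling_schedule:  # list of [start_min, duration_min|null]
  domain_length:        # um (default 500)
  rna_bolus_width:      # um, initial RNA extent (RNA-diff, default 20)
  rna_bolus_amount:     # molecules in the initial bolus (default 1000)
  D_time_dependence:    # [D0, D1, t0_min] for D(t) = D0 - D1*sqrt(t/t0)

grid:
  L:            # um (default 500)
  n_bins:       # int (default 250; dx = L / n_bins)

maturation:
  preset:           # "sfGFP-mCherry" (27/40/9 min) | "sfGFP-fmCherry" (27/6/6)
  green_half_time:  # min, overrides preset
  red_half_time_1:  # min
  red_half_time_2:  # min
  green_sd:         # min, Gaussian prior SD (fit restarts draw from these)
  red_sd_1:         # min
  red_sd_2:         # min

fitting:
  n_restarts:   # int (default 16)
  window:       # [lo_um, hi_um] fitting window (default [60, 450])

synthetic:
  eps:          # red/green intensity scaling of the generator
  n_embryos:    # batch size (default 4)

phase:
  t_switch_min:         # min, perturbation time
  production_factor:    # source multiplier after the switch
  degradation_factor:   # degradation multiplier after the switch
  t_end_min:            # min
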