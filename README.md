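# emuflux

**13C metabolic flux analysis with elementary metabolite units — stationary
and isotopically nonstationary.**

Intracellular metabolic fluxes cannot be measured directly.  13C-MFA infers
them by feeding a 13C-labeled carbon source, measuring the mass-isotopomer
distributions (MDVs) of intracellular metabolites or proteinogenic amino
acids by mass spectrometry, and fitting a labeling model to those spectra.
`emuflux` is a library (plus a thin CLI) for the whole workflow:

* **Automatic model construction** from a declarative worksheet: reactions in
  a `Rxns` column, atom transitions in a `Carbon_transitions` column
  (`ACCOA + OAA -> IsoCit`, `ab + cdef -> fedbac`).  Metabolite roles come
  from naming conventions (`Subs_` sources, `Ind_` unbalanced pools, `Sym_`
  symmetric molecules, `[...]` biomass sinks).
* **EMU decomposition**: the carbon-transition network is reduced to the
  minimal cascade of elementary metabolite units feeding the measured
  fragments; each EMU size `s` yields a linear system
  `A_s(v) Z_s = B_s(v) Y_s` whose rows are MDVs.
* **Labeling simulation** — algebraic at isotopic steady state, or
  integration of `dMDV_j/dt = (1/X_j)(Σ v_in MDV_in − Σ v_out MDV_j)` by
  fixed-step Euler with per-step renormalization for the isotopically
  nonstationary (INST) case, where `X_j` are metabolite pool sizes.
* **Flux estimation**: Levenberg–Marquardt minimization of the
  covariance-weighted SSD `Φ = Σ_k Σ_j Dᵀ C⁻¹ D` subject to `S v = 0`
  (held exactly via a null-space parameterization) and flux nonnegativity,
  from random feasible restarts.
* **Confidence intervals** by grid search: one flux is fixed at perturbed
  values, the rest reoptimized, and the interval is where the reoptimized
  SSD stays below `Φ_res (1 + F_α(1, n−p)/(n−p))`.
* **Natural-abundance correction** of raw spectra via per-fragment
  correction matrices and nonnegative least squares.
* **Synthetic experiments**: a fully specified 16-reaction TCA-cycle fixture
  (substrates, ground-truth fluxes, pool sizes, noise model) for
  end-to-end validation without any external data.

## Worked example

Fit fluxes to a simulated 17-point nonstationary time course of
oxaloacetate and succinate labeling (1% noise):

```bash
python examples/03_fit_fluxes.py
```

```
Phi_res = 124.1 with n = 136 data points, p = 3 free fluxes (converged: True)

  flux    fitted    true      sd     |z|
    R2    0.4992    0.50   0.00145   0.57
    R3    0.4992    0.50   0.00145   0.57
    R4    0.4992    0.50   0.00145   0.57
    R5    0.4984    0.50   0.00290   0.57
    R6    0.5704    0.58   0.01326   0.72
    R7    0.2441    0.25   0.00394   1.50
   R14    0.0992    0.10   0.00145   0.57
   R15    0.0720    0.08   0.01421   0.56
   R16    0.0433    0.05   0.00420   1.60
```

`Φ_res` is the weighted residual at the optimum (≈ the 136 data points for a
well-specified noise model); each free flux is recovered within two
standard errors of the value that generated the data.  The other examples
cover model construction and steady-state simulation (`01`), the
nonstationary time course (`02`), grid-search confidence intervals (`04`)
and natural-abundance correction (`05`).

The same workflow is available from the shell:

```bash
emuflux make-demo demo --mode inst          # write a simulated bundle
emuflux fit --mode inst --model demo --out result.csv
emuflux ci  --mode inst --model demo --flux R7 --flux R6 --out ci.csv
```

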