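# Methods

## Model and notation

A metabolic network at metabolic steady state satisfies `S v = 0`, where
`S` is the stoichiometric matrix over *balanced* metabolites and `v` the
flux vector.  Metabolites are excluded from balancing when they are
extracellular sources (`Subs_` prefix), explicitly unbalanced pools
(`Ind_`, e.g. CO2), or sink pseudo-metabolites (bracketed products such as
`[AKG_B]`, used for biomass drains).  Reaction atom maps are written as
parallel lowercase-letter strings (`ab + cdef -> fedbac`); the letter
multiset must balance between sides, which the parser enforces per
reaction.

Isotopic labeling of a fragment with `n` carbons is a mass distribution
vector (MDV) `[m+0, …, m+n]`, the fractions of molecules carrying
0…n tracer carbons, summing to 1.

### EMU decomposition

The labeling of any measured fragment depends only on specific atom
subsets (elementary metabolite units) of its precursors.  Tracing target
atoms backward through the atom maps yields, per EMU size `s`, a linear
balance `A_s(v) Z_s = B_s(v) Y_s`: diagonal entries of `A_s` are minus
the total consumption of the EMU's metabolite, off-diagonal entries the
same-size transfer fluxes, and `B_s` (with a minus sign) the inflows from
known EMUs — substrate EMUs and convolutions of already-solved smaller
EMUs (condensation reactions).  Sizes are solved in ascending order.
Condensations of two unknowns at the product's own size cannot occur
(two precursors of size ≥ 1 are each strictly smaller than their sum),
which the builder asserts.

Two conventions the worksheet dialect leaves implicit are resolved as
follows:

* **Symmetric metabolites** (`Sym_` prefix, e.g. succinate): every atom
  mapping touching a symmetric species is split into a forward and a
  fully reversed variant of half weight, on both production and
  consumption — the standard treatment of rotational scrambling.
  Identical variants are merged; weights per producing reaction sum to 1.
* **Unbalanced carbon donors** (`Ind_CO2` in the anaplerotic reaction):
  treated as source EMUs with a fixed unlabeled MDV unless the substrate
  file assigns them a labeling.  The intracellular CO2 pool is not
  tracked, consistent with its exclusion from mass balance.

Atom positions are 1-based in the letter order of the first atom string
in which a metabolite appears; conflicting carbon counts across
reactions are a configuration error.

### Nonstationary labeling

During the transient after a tracer switch each EMU's MDV obeys

    dMDV_j/dt = (1/X_j) [ Σ_i v_i_in MDV_i − Σ_l v_l_out MDV_j ]

with `X_j` the pool size (µmol gDCW⁻¹) of the EMU's metabolite and
condensation inflows convolved at the current state.  The reference
integrator is fixed-step explicit Euler without adaptive step-size
control; after every step each MDV is renormalized to sum 1.  Stiffness
is the user's responsibility via the step size: the integrator aborts
with a suggestion to reduce `h` if a state entry leaves `[-10, 10]` or a
sum becomes nonpositive (an oscillatory Euler instability can explode
while sums stay normalized, hence the magnitude guard).  Sampling times
are read off the Euler grid point landing on, or latest before, each
requested time — no interpolation.  At `t = 0` every intracellular MDV is
fully unlabeled; substrate labeling applies from the first step.

The integrator exists twice with identical semantics: a numba-compiled
kernel (default; the fitting and profiling workloads need it) and a pure
numpy loop kept as an executable reference; a test pins their agreement.

**Time to stationarity.**  The per-size dynamics are linear with system
matrix `diag(1/X) A_s`, so the slowest approach to isotopic stationarity
is governed by the smallest eigenvalue magnitude across sizes
(`relaxation_time`).  This exceeds the naive bound `max_j X_j /
throughput_j` (`slowest_turnover`) whenever label re-enters a pool; on
the bundled TCA fixture the two are ≈ 99 s vs ≈ 17 s.  Consistency tests
between the transient and stationary solvers use the eigenvalue-based
time scale, the one that actually controls convergence.

### Flux estimation

Fluxes minimize the covariance-weighted SSD
`Φ = Σ_k Σ_j Dᵀ C⁻¹ D` over sampling points `k` and fragments `j`,
`D = observed − simulated MDV`, with diagonal measurement covariance
(per-channel SDs).  `S v = 0` plus the predetermined fluxes form an
affine constraint set handled exactly by reparameterization:
`v = v_p + K u` with `K` an orthonormal null-space basis, so every
iterate is feasible by construction rather than by penalty.
Levenberg–Marquardt details:

* damping `λ` starts at 1e-3, ×10 on rejection, ÷10 on acceptance,
  with Marquardt diagonal scaling;
* Jacobian by forward finite differences, relative step 1e-6 with
  absolute floor 1e-8 (balancing Euler truncation noise in INST mode;
  the difference flips backward at the nonnegativity boundary);
* trial steps are shortened to remain in the flux box (nonnegativity,
  and an upper cap at twice the sampling bound) — a trial the simulator
  rejects as divergent counts as a rejected step;
* convergence when the relative Φ decrease falls below 1e-8 or the
  gradient norm below 1e-6; at most 200 iterations;
* the fit is repeated from `restarts` (default 10) random feasible
  starts — free fluxes drawn uniformly within bounds, dependent fluxes
  solved from the constraints, redrawn until nonnegative — and the best
  optimum kept.

Reported per-flux standard errors are linearized:
`cov(v) = K (JᵀJ)⁻¹ Kᵀ` with `J` the weighted-residual Jacobian at the
optimum (no residual-variance rescaling, since the measurement SDs are
taken as known).

**Counting.**  Independent data points `n` are Σ over fitted MDVs of
(length − 1), one degree per vector lost to normalization, times the
number of sampling points; degrees of freedom `p` is the null-space
dimension (number of free fluxes).  These enter the CI threshold below
and are reported with every fit.

### Confidence intervals

For flux `r`, the profile is obtained by adding the row `e_rᵀ` to the
constraint system (recomputing the null-space basis), fixing
`v_r = v_opt,r + d`, and reoptimizing from the neighboring grid point's
solution as warm start.  The 1−α interval is where the reoptimized SSD
stays below `Φ_res (1 + F_α(1, n−p)/(n−p))`.  The search grows `|d|`
geometrically (initial `d = max(1% |v_opt,r|, 1e-4)`, growth ×2) until
the threshold is crossed or a flux bound is reached (then flagged
one-sided/unbounded), and bisects the crossing to a relative tolerance of
1e-4.  A flux already implied by the constraints (adding `e_rᵀ` does not
reduce the null space) gets a width-0 interval.  The search is written
against a minimal "profile problem" interface, so the same code path is
validated on a linear-Gaussian problem whose interval is known in closed
form.

### Natural-abundance correction

The correction matrix's column `j` is the observable mass pattern of a
fragment carrying exactly `j` tracer carbons: a pure `m+j` shift
convolved with the natural isotope distributions of all non-skeleton
atoms and — by default — natural 13C over the remaining unlabeled
skeleton positions (a flag disables the skeleton term for comparison with
the simpler convention).  Abundance constants (13C 1.07%, 2H 0.0115%,
15N 0.364%, 18O 0.038/0.205%, 29/30Si, 33/34/36S) follow the IUPAC
representative isotopic compositions and live in a single versioned
table.  Correction solves `K m ≈ raw` by nonnegative least squares
(pseudo-inverse available as a diagnostic) and renormalizes.

## The synthetic TCA fixture

All validation runs on a 16-reaction TCA-cycle model fed by pyruvate and
glutamate, with a reversible succinate↔OAA pair and reversible
anaplerosis (PYR + CO2 ↔ OAA), succinate symmetric, CO2 unbalanced, six
biomass drains.  The substrate labeling is 50% [1-13C] + 50% [U-13C]
pyruvate and 100% [1-13C] glutamate.  One influx (R1) and the six drains
(R8–R13) are predetermined, leaving 3 free flux directions among the 9
remaining reactions.

Published flux values for this model exist only graphically, so the
fixture ground truth is a documented feasible point:
`v = (1.0, 0.5, 0.5, 0.5, 0.5, 0.58, 0.25, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1,
0.1, 0.08, 0.05)` µmol gDCW⁻¹ s⁻¹ for R1…R16 — moderate anaplerosis
(R7 = 0.25) and small exchange fluxes (R15 = 0.08, R16 = 0.05).  Pool
sizes (PYR 5, ACCOA 2, IsoCit 3, AKG 8, SUC 10, OAA 10 µmol gDCW⁻¹) give
labeling turnovers of 2–17 s and a system relaxation time of ≈ 99 s, so
the 17 × 5 s sampling window is genuinely mid-transient.  Recovery tests
are therefore *self-referential*: they assert that fitting data simulated
at this truth returns this truth, not any published flux map.

**Noise model.**  Measurement noise is additive Gaussian per mass
channel with SD 0.01 (an absolute fraction — "1%" on MDV data is
ambiguous between absolute and relative; absolute is chosen and the SDs
entering the fit covariance match it exactly), negative channels clipped
to zero, and the spectrum renormalized.  Real spectra differ in ways the
generator does not emulate: intensity-dependent (roughly multiplicative)
noise, natural-abundance contamination (available separately through the
correction module, but the bundled datasets are carbon-skeleton
fractions with skeleton-only `Components.csv` entries), drift between
replicates, and pool sizes that are themselves uncertain.  Passing
recovery tests therefore demonstrate correctness of the estimator under
its own assumptions, not field performance.

Measured fragments: the conventional-mode experiment reads the
proteinogenic readouts Val (= PYR{1–3} ⊗ PYR{2–3}), Lys (= OAA{1–4} ⊗
PYR{2–3}), Asp (= OAA{1–4}) and Suc (= SUC{1–4}); the nonstationary
experiment samples OAA and SUC directly.  Fragment declarations use a
`metabolite:atoms [+ metabolite:atoms]` syntax in `MSReac.csv`, with
multi-term fragments convolved.

## Problem sizes and defaults

Euler step 0.01 s for the TCA-scale model (0.001 s is appropriate at
~10× faster turnover); 17 sampling points at 5 s; LM restarts 10 by
default, 3 in the bundled comparisons (the stationary objective on this
model is well-behaved and restarts agree); CI profiling of four
representative reactions (R3, R6, R7, R15) spanning oxidative flux,
the net direction and both exchange back-fluxes.  The full
INST-vs-conventional comparison (two fits plus eight profiled intervals)
runs in well under a minute on one core.

## Known limitations

* Pool sizes are constants, never fitted; unreliable pool data bias INST
  estimates and nothing in the package detects that.
* The reference integrator is first-order; accuracy at a given cost is
  far below implicit or adaptive schemes, which are deliberately not on
  the contract path.
* EMU condensations with three or more carbon-bearing precursors in a
  single reaction are rejected (none occur in common central-metabolism
  maps; fold such reactions into steps).
* The F-threshold interval is exact only insofar as the local quadratic
  approximation and known-noise assumptions hold; profile asymmetry is
  reported, not corrected for.
* Only diagonal measurement covariance is supported.
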