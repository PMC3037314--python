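# Methods

## Model

A population of `N` identical, well-stirred cells shares one extracellular
pool.  The state of cell `i` is a telegraph mRNA indicator `M_i ∈ {0,1}` and
an autoinducer count `A_i`; the pool holds `A_ext`.  The reaction channels and
rates are listed in the README and in `qsnoise/ssa.py`.  Modeling choices
inherited from the regime the package targets (constitutive expression near,
but below, the QS activation threshold):

* **Single transcript.**  Transcription and mRNA degradation form a two-state
  Markov switch — at most one mRNA molecule per cell at a time.  This is the
  low-constitutive-expression regime; its parameter-space footprint is
  α > 2β, validated as a warning (not an error) since the analytics are
  mathematically valid outside it and the qualitative phenomenology does not
  depend on it.
* **No autoinduction feedback.**  Below threshold the positive feedback on
  the synthase gene is inactive; the model is linear given the mRNA states.
  Results do not transfer above the activation threshold.
* **One effective synthesis step.**  Translation and enzymatic synthesis are
  lumped into the single rate k₊ (substrate is not limiting); additional
  intermediate steps would raise the intrinsic noise floor.
* **Uniform dilution.**  Cell growth is compensated by an implied dilution
  protocol; its rate dominates chemical decay of the signal and acts equally
  inside and outside the cell, hence a single k₋.
* **Well-stirred.**  No spatial gradients; all cells see the same pool.

## Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| α | mRNA degradation (off-switch) rate | preset·k₋ (α̃ ∈ {8, 15}) | 1/min |
| β | transcription (on-switch) rate | preset·k₋ (β̃ ∈ {0.5, 2, 5}) | 1/min |
| k₋ | degradation/dilution | 0.02 | 1/min |
| D | membrane exchange | varied, D̃ = D/k₋ | 1/min |
| k₊ | synthesis per mRNA | calibrated (below) | molecules/min |
| N | cells | 100 | — |
| r | V/V_ext | 1e-5 | — |
| V | cell volume | 1.5 | μm³ |
| target ⟨c_A⟩ | mean signal level | 25 | nM |

k₋ = 0.02/min is the dilution rate of a ~50-min cell cycle; the measured
chemical decay of common AHLs is one to two orders of magnitude slower, so
dilution dominates.  N = 100 with r = 1e-5 puts the sensing potential
ν = 1/(rN) at 10³, in the experimentally estimated range for QS activation,
while keeping the population large enough to suppress small-system effects.
25 nM sits in the 10–50 nM band of reported activation thresholds; at
V = 1.5 μm³ it corresponds to n̄ ≈ 22.58 molecules per cell, which sets the
intrinsic noise floor 1/n̄ ≈ 0.0443.  The presets γ₁=(8,2), γ₂=(15,5),
γ₃=(8,0.5), γ₄=(15,0.5) are dimensionless (α̃, β̃) pairs spanning the
qualitative regimes of the stationary density; γ₂ is the reference set for
all noise experiments.

**Calibration.**  Given (α̃, β̃, D̃, Nr), k₊ is set from the closed-form mean
so that the stationary count equals the target: k₊ = n̄·k₋/⟨c̃_A⟩.  n̄ is kept
real (never rounded); the calibration is exact in rates, and recalibrated at
every grid point of a diffusion scan so that only the noise, not the mean,
changes with D̃.

## Analytics

All density arithmetic is in log-space via log-gamma.  The substituted
variable x = (1+D̃)c̃ − k₊_eff is Beta(β̃/(1+D̃), α̃/(1+D̃)); moments use the
exact Beta moment recursion plus a binomial shift — never quadrature — because
at large D̃ both exponents tend to 0 and the density has integrable endpoint
singularities that defeat adaptive rules (the test suite uses QUADPACK's
algebraic-weight rule for independent verification, restricted to D̃ ≤ 2000).
The mean-field self-consistency equation is solved by damped fixed-point
iteration (damping 0.5, relative tolerance 1e-12, max 10⁴ iterations); the
map is affine in the trial mean, hence a contraction, and the result agrees
with the explicit closed form to ~1e-12 relative.

Shape classification compares α̃ and β̃ with k_eff = 1+D̃; ties within 1e-12
absolute are reported DEGENERATE (the inequality is strict and ties are
measure-zero).  The NO_EXTREMUM class is not split in the return type; a
helper reports the density slope sign at the lower barrier, which
distinguishes the monotonically decreasing case (β̃ < k_eff < α̃, the one
reachable under low constitutive expression).

A numerical subtlety worth recording: at large D̃ an O(1) fraction of the
stationary mass lies within ~1e-20 of the support barriers.  In the
concentration variable this is below double-precision resolution of the
affine map, so (i) the PDF/CDF snap arguments within a few ulps onto the
barriers, and (ii) the reduced-process simulator evolves x itself, whose
relaxation toward a barrier is multiplicative and therefore resolves the
deep tails.  Distributional (KS) checks are done in x-space for the same
reason.

## Simulators

**SSA.**  Direct-method Gillespie over the exact master equation.  The N
influx channels are lumped into one channel of propensity N·r·D·A_ext with a
uniform destination draw (identical master equation, O(1) channels in N).
Stationary moments are exact time integrals of the piecewise-constant
trajectory — holding-time weighting between events — so the estimators carry
no discretization bias; trajectory thinning exists only as an output
convenience and is never used by estimators.  Pooling convention: per-cell
concentrations are pooled across cells and stationary time (cells are
exchangeable, so pooling equals the single-cell stationary law at lower
variance).  The dual-reporter variant duplicates the synthesis, degradation
and transport channels for two distinguishable products of the same mRNA,
each with its own pool.

**PDMP.**  The reduced equation is simulated by exact exponential relaxation
between telegraph switches with closed-form segment integrals of c̃ and c̃²;
there is no ODE error by construction.  The mean-field coupling inside
k₊_eff is a constant during a run (closed-form or fixed-point value, selected
by `mean_mode`), matching the stationary construction under which the
closed-form density is derived — not the running ensemble mean.

**Run protocol** (the model's source publications specify none; these are
this package's choices).  Initial states are drawn from the
`stationary_guess` distribution: M ~ Bernoulli(β/(α+β)), counts Poisson at
the predicted stationary mean, pool Poisson at its quasi-steady level —
which removes the mean transient entirely.  Generic runs default to a
burn-in of 20× the slowest relaxation scale max(1/k₋, τ_c, 1/(k₋+D));
scans use burn-in 300 min with a 2000 min stationary window and 8 replicates
(seeds base+index, recorded in outputs), sized so that the grid-averaged
intrinsic noise carries a standard error of ~0.002; the flatness regression
and the headline intrinsic-noise recomputation use a 4000 min window so the
slope SE and the grid average resolve well below the intrinsic level.  Uncertainty is always
the standard error across replicates.  The desk-scale scan grid is
D̃ ∈ {0, 1, 10, 10², 10³}; event rates grow linearly with D̃, so extending
to D̃ = 5·10⁴ is possible but costs ~50× the top grid point and is left to
explicit long runs.

## Noise decomposition

η²_total is the squared CV of the pooled per-cell concentration.  Two
independent intrinsic-noise estimators are implemented:

1. **Decomposition:** η²_int = η²_total(SSA) − η²_tran(closed form).
2. **Dual reporter:** η²_int = ⟨(c₁−c₂)²⟩ / (2⟨c₁⟩⟨c₂⟩), the standard
   operationalization of the perpendicular-to-diagonal spread of the joint
   reporter distribution (the common mRNA drive is common mode; only
   uncorrelated molecular events separate the reporters).

Without diffusion the two agree exactly with 1/n̄ by a conditional-Poisson
argument: given the mRNA trajectory the count is a linear birth–death
process, so the stationary law is a Poisson mixture and
η²_total = 1/n̄ + η²_tran identically.

**Known finite-N bias of the decomposition route.**  The closed-form
η²_tran assumes a quasi-steady, mean-field pool.  At finite N the pool
fluctuates and feeds a small extra correlated component back into every
cell, so the decomposition estimator inherits a positive excess that is not
molecular noise.  The exact size of the excess follows from the spectral
solution of the telegraph-driven linear network (the conditional-rate
system solved without the quasi-steady or mean-field closures, exposed as
`analytics.transcriptional_noise_exact`): at the
default geometry it is +1.1e-3 at D̃ = 10³, +2e-4 at D̃ = 10², and
negligible below — about 2% of the intrinsic level at its worst, vanishing
like 1/N.  The implied trend of η²_int across the desk-scale grid is a
slope of ~1e-6 per unit D̃, below the resolution of 8-replicate runs.  The
dual-reporter estimator does not carry this bias.  The scan's reported
slope SE is propagated from the replicate SEs through the OLS weights
rather than from the 3-degree-of-freedom fit residuals, whose own sampling
error would otherwise dominate the test of flatness.

## What the simulations do and do not show

All experiments are generated in-house by the simulator under the default
geometry; there is no external data.  Passing tests establish internal
consistency of simulators and closed forms and the qualitative phenomenology
(shape progression, non-monotonic noise, flat intrinsic floor) under the
stated idealizations.  They do not validate the idealizations themselves
against real colonies: cell-to-cell parameter variability, growth and
division, spatial structure, multi-step synthesis, receptor binding and
feedback above threshold are all outside the model.  The active-transport
mapping (D = D_out when r ≈ D_in/D_out) is a plausibility bridge, checked
only as a rate-ratio criterion.

## Numerical edge cases

* β = 0 with empty initial state is absorbing: runs terminate early and are
  flagged; noise is reported as undefined (error), never NaN.
* Density evaluation exactly on a barrier with a negative local exponent
  returns +inf (the singularity is integrable), never NaN.
* k₋ = 0 is rejected: every stationary quantity scales on 1/k₋.
* Degenerate shape ties are classified explicitly rather than resolved by
  floating-point accident.
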