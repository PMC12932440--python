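# Methods

## Model scope and assumptions

The model describes one basic multicellular unit (BMU) as a well-mixed
compartment. Seven scaled state variables evolve by ODEs: preosteoblasts
(PB), preosteoclasts (PC), osteoclasts (C), osteoblasts (B), osteocytes
(S), sclerostin (Sc), and bone density (B_d, equal to 1 at the
premenopausal reference; BMD = BMC₀·B_d with BMC₀ = 0.8). Precursor pools
are replenished at a scaled basal rate of one per day. Estrogen is an
algebraic input normalized to its premenopausal level, not a state
variable. Sclerostin stands in for the osteocyte-derived signaling it
dominates: its activation of osteoclastogenesis absorbs the RANKL pathway
and its repression of osteoblastogenesis absorbs Wnt inhibition; neither
pathway is modeled explicitly. Mechanical strain, pharmacological
treatment, and site-to-site (lumbar vs femoral) differences are outside
scope.

Surgical menopause enters through three parameters fit to data: fold
increases of osteocyte apoptosis (η_surg) and preosteoclast→osteoclast
differentiation (ω_surg) at onset, both relaxing back to baseline at a
shared rate τ (day⁻¹); τ = 0 means the effects are permanent. The two
fold-increases model the inflammatory/metabolic response to surgery, the
mechanisms most consistently reported in ovariectomy experiments.

## Parameters and units

Everything internal is in days and scaled species units. The packaged
YAML sets are:

* `natural.yaml` — baseline rates and Hill thresholds (differentiation
  rates ω_PC = 0.93, ω_PB = 0.32, ω_B = 6.4×10⁻⁴ day⁻¹; apoptosis rates
  η_B = 8.678×10⁻³, η_C = 1.096×10⁻⁴, η_S = 1.1×10⁻⁴ day⁻¹; formation/
  resorption rates λ_B = 1.29×10⁻⁶, λ_C = 3.82×10⁻⁶ day⁻¹; sclerostin
  turnover κ_Sc = 0.05 day⁻¹; estrogen thresholds e_PC = 0.2556,
  e_Sc = 10.59; sclerostin thresholds sc_PC = 8.6×10⁶, sc_PB = 163,
  sc_Ω = 3.04×10³; resorption coupling r_Ω = 1.02×10³, ν_Ω = 1.08×10³).
  The estrogen decline time τ_E is stated in years in config (2.6 y, the
  clinical convention) and converted to days on ingestion. Menopause onset
  sits at t_m = 10 950 days so the default simulation starts at day 0,
  thirty years earlier.
* `surgical_short_term.yaml` / `surgical_long_term.yaml` — estrogen
  kinetics plus the surgery effects calibrated against ≤15-year and
  30-year series respectively: {η_surg, τ, ω_surg} = {5, 9.7×10⁻³, 1.86}
  (short) and {0.4174, 0, 0.2155} (long). The estrogen clearance rate
  κ_E = ln 2 / t₁/₂ = 6.1996 day⁻¹ follows from the 161-minute circulating
  half-life measured in postmenopausal women, and the synthesis rate
  k_syn = κ_E·(15/156) = 0.596 day⁻¹ from serum levels of 156 pg/mL before
  surgery and ~15 pg/mL at the 30-day plateau.

These shipped fitted values depend on aggregated clinical series that are
not redistributable; they are defaults, not reproduction targets. The
package validates calibration by parameter recovery on synthetic cohorts
instead.

## Steady-state initialization

With density held fixed (it feeds back into nothing), the equilibrium of
the six-species subsystem at fixed estrogen E is triangular and solved in
closed form: B* = 1/(η_B + ω_B), S* = ω_B B*/η_S, Sc* = α f⁻(E, e_Sc)
S*/κ_Sc, then PB*, PC* from their production balances and C* = 1/η_C (the
steady osteoclast influx equals the scaled basal production of one). The
multiplier α (nominal 1) scales sclerostin production for the sensitivity
sweep. A numerical root solve cross-checks the cascade to 10⁻¹⁰ relative
on every call; the test suite additionally roots from perturbed starts so
the two routes stay genuinely independent.

Two inconsistencies in the published constants deserve note, and the
package resolves both in favor of the equations:

* The reference initial-condition table quotes C = 42, but the printed
  apoptosis rate gives C* = 1/η_C ≈ 9.1×10³. The equations win; a warning
  is logged whenever the packaged defaults are loaded.
* At the equilibrium the density equation does not balance: with the
  printed rates dB_d/dt ≈ −6.5×10⁻³ day⁻¹ (about −240 %/yr of the
  reference density), versus the sub-percent-per-year drifts the source
  analyses report. No reading of the resorption coupling we tried
  (activating vs repressive, either osteoclast level) closes the ~10³
  gap, so the equation is implemented exactly as written and density-level
  results are treated as qualitative. Concretely: density crosses zero
  during the 30-year premenopausal spin-up, so onset-normalized BMD
  curves have an inverted sign convention under the shipped defaults, and
  all trajectory-level claims in the tests (surgical loses faster than
  natural early; the no-new-effects model overshoots late loss; the
  long-term parameter set slows late loss) are asserted on absolute
  density differences, which are insensitive to the normalization. The
  calibration and recovery machinery is unaffected — it compares model to
  data generated by the same observable and is exercised end to end.
  A `resorption_inhibition` flag exposes the alternative repressive
  coupling f⁻(R, r_Ω) for exploration; it is off by default.

The sclerostin sensitivity sweep re-solves the equilibrium for
α ∈ [0.7, 1.2] at the post-surgical estrogen plateau E = k_syn/κ_E,
evaluates the density equation there, and reports %/yr against sclerostin
production relative to premenopause (α·f⁻(E_post, e_Sc)/f⁻(1, e_Sc)). The
curve is strictly decreasing with a single zero crossing: production below
the crossing implies net formation, above it net loss.

## Numerical integration

Simulations run by adaptive explicit Runge–Kutta (RK45) at absolute and
relative tolerances of 10⁻⁸ from 30 years before onset to up to 30 years
after, initialized at the equilibrium (recomputed whenever parameters
change, so calibration trial points are always self-consistent). The onset
t_m is a discontinuity of the surgical rates, so the window is integrated
as [t_start, t_m] and [t_m, t_end] with t_m a segment boundary; at exactly
t_m the pre-menopause branch applies, and the second segment evaluates the
surgery terms on their right-hand limit. The right-hand side evaluates the
six cell/signal components at max(value, 0): adaptive solvers probe
internal stages outside the admissible region — most aggressively when the
trajectory sits on the equilibrium and the step size grows far past the
stiffness limit — and the RHS must stay defined there; accepted solution
values are unaffected. Output lands on a monthly grid (always containing
t_m, so onset normalization is exact); values between grid points come
from monotone-cubic (PCHIP) interpolation. Verification: the adaptive
solution matches an independent fixed-step RK4 integration (0.25-day
steps) to better than 10⁻⁵ relative over a 5-year post-onset window,
halving the tolerances moves the 30-year endpoint by less than 10⁻⁶, and
a constant-estrogen run holds the six-species equilibrium for 60 years.

## Calibration

The objective is the unweighted sum of squared differences between
onset-normalized model BMD and observed normalized means at the
observation times within the horizon (15 years for the short-term
protocol, 30 for the long-term). Minimization uses
`scipy.optimize.least_squares` with method `"trf"` — the bound-constrained
trust-region variant of Levenberg–Marquardt — with ftol = xtol = gtol =
10⁻⁸ and at most 10 000 evaluations. The natural protocol frees the two
estrogen thresholds {e_PC, e_Sc}; the surgical protocol freezes those and
frees {η_surg, τ, ω_surg} in [0, 5] × [0, τ_max] × [0, 5]. The published
bound τ ≤ 1/365 day⁻¹ contradicts both its own gloss ("effects last a
minimum of one day", i.e. τ ≤ 1 day⁻¹) and the published short-term
estimate τ = 9.7×10⁻³ day⁻¹; the package defaults to τ_max = 1 day⁻¹ and
exposes the literal 1/365 as an option. Starting points default to the
bound midpoints (surgical) or the configured thresholds (natural), with
optional seeded Latin-hypercube multi-start; integration failures at wild
trial points return a constant large-penalty residual with a logged
warning so the optimizer retreats rather than aborting. Estimates within
10⁻⁸ of a bound (relative to the bound range) are flagged at-bound.

### Identifiability of the surgery parameters

With the published observation design — roughly yearly sampling — the
short-term surgery transient (1/τ ≈ 103 days) is essentially over before
the first post-onset observation. The data then constrain the *integrated*
excess effect (∝ fold/τ) tightly but the peak-versus-duration split only
weakly: the objective has a near-flat ridge along which all three
parameters scale together, and under observation noise the minimum travels
tens of percent along it (restarting at the truth converges to the same
displaced minimum, so this is the landscape, not the optimizer). Noise-free
data recover all three parameters to better than 0.01%; under noise the
recovery experiment therefore conditions τ on its known value and frees
the two folds, which are then recovered to a few percent at noise SD 0.02.
Fits to real data should either fix τ from external (e.g. inflammation
timescale) evidence, report fold/τ, or use sub-annual early sampling.

## Synthetic cohorts

The generator emulates the statistical structure of the published
cross-sectional series: six studies (cohort sizes 67, 20, 53, 210, 102,
141 women, cycling, matching the published surgical lumbar-spine series),
observation times (0, 1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30) years after
onset, and per-point study means drawn as truth + N(0, σ/√n) with
σ = 0.05 on normalized BMD (the scale of published error bars; the
recorded per-point SD is σ, one woman's spread). Each study carries its
own raw baseline BMD drawn uniformly from 0.9–1.25 g/cm², so the curation
pipeline's normalization step is genuinely exercised. Draws are
independent across time points (cross-sectional design); the generator
does not model within-woman longitudinal correlation, DXA measurement
physics, skeletal-site differences, or age-at-surgery covariates.
Passing recovery tests therefore demonstrate that the estimation machinery
is correct and that the parameters are identifiable under the assumed
noise model — not that the model is correct for real cohorts, where
between-study heterogeneity is structured rather than Gaussian.

## Curation pipeline

Study tables (mean BMD, SD, cohort size vs years since onset) are
normalized by the observation nearest onset (required within 1 year; SDs
scale by the same factor), then pooled within 1-year bins using
cohort-size-weighted means and a pooled SD combining within- and
between-study components; an unweighted mean is available by flag. The
windowed OLS loss rate (%/yr over the first 15 years) is a diagnostic
only and feeds nothing downstream. Aggregation is order-invariant and the
pipeline is idempotent on already-normalized input.

## Problem sizes

Default simulations cover 60 model-years at monthly output (~720 points,
tens of milliseconds each). Calibration examples and recovery experiments
use 9 aggregated observations (0–15 years) from six synthetic studies and
five-start optimization; a full recovery experiment runs in a few seconds,
and the entire test suite in well under a minute.

## Known limitations

* The printed rate constants leave the density equation far from balance
  (see above); absolute BMD levels are not interpretable under the shipped
  defaults, only differences and orderings.
* Sclerostin lumps RANKL/Wnt signaling; interventions targeting those
  pathways separately cannot be represented.
* The surgery response shares one timescale τ between apoptosis and
  differentiation effects by construction.
* The estrogen laws are deterministic population averages; perimenopausal
  variability is not modeled.
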