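# Methods

## The model

Each intracellular metabolite pool is treated as an independent
second-order linear process responding to a sustained step of magnitude
M (mM) in an extracellular substrate at t = 0. In deviation form
(y′ = pool − pre-step steady state), the transfer function is

    overdamped:    y′(s) = K·M·(τₐs + 1) / ((τ₁s + 1)(τ₂s + 1))
    underdamped:   y′(s) = K·M·(τₐs + 1) / (τ²s² + 2ζτs + 1),  0 < ζ < 1

The numerator zero (τₐ, minutes, any sign) lets the model express
inertia, overshoot and inverse response; without it a second-order lag
cannot. The model assumes linearity around the operating point,
time-invariance over the 2-hour window, and independence between pools —
it is a descriptive reduction of a metabolic network, not a mechanistic
one, chosen because the sampling density (8 points) cannot support more
parameters.

Closed-form step responses (inverse Laplace with a step input) are used
everywhere:

* overdamped, distinct roots:
  y′(t) = K·M·[1 + (τ₁−τₐ)/(τ₂−τ₁)·e^(−t/τ₁) + (τ₂−τₐ)/(τ₁−τ₂)·e^(−t/τ₂)]
* overdamped, repeated root (|τ₁−τ₂| < 10⁻⁶·τ₁): the analytic confluent
  limit y′ = K·M·[1 − e^(−t/τ)(1 + (1 − τₐ/τ)·t/τ)] rather than a
  numerical perturbation;
* underdamped:
  y′(t) = K·M·[1 − e^(−ζt/τ)(cos ω_d t + (ζ − τₐ/τ)/√(1−ζ²)·sin ω_d t)],
  ω_d = √(1−ζ²)/τ.

All three are validated in the test suite against an independent ODE
integration of the state-space realization (tolerance 10⁻⁶ relative over
randomized parameter sets, both branches, including the ζ → 1 limit
where the branches must agree). y′(0) = 0 is enforced exactly at the
step time; the final-value theorem gives y′(∞) = K·M.

Overdamped parameters are stored with τ₁ ≥ τ₂ (the model is symmetric
under swapping; the convention removes the identifiability ambiguity).

## Fitting

The baseline y₀ is the pre-step mean and is held fixed (a fitted-offset
variant is a config option elsewhere deemed unnecessary: the pre-step
sample measures it directly). Fitting is two-stage, mirroring common
practice of seeding a weighted fit with an unweighted one:

1. multi-start (default 8 seeded starts) unweighted least squares in a
   transformed parameter space — log time constants for positivity,
   logit damping for ζ ∈ (0,1), τₐ and K unconstrained;
2. SD-weighted refinement initialized from the stage-1 optimum.

Because replicate SDs at n = 3 have only 2 degrees of freedom, inverting
them raw lets a lucky small SD dominate; the weights therefore use SDs
shrunk halfway toward a relative-noise model sd ≈ ĉv·|y| (ĉv = median
observed relative SD). This variance-stabilized weighting is a design
choice of this package.

Both branches are fit; the lower weighted residual wins, with ties
(< 1% relative) resolved toward the overdamped branch (a robustness
prior: damped responses are the common case and the underdamped branch
should have to earn its extra oscillatory structure).

**Mean fitting error** is 100·mean_t|fit − obs| / mean_t(obs): the
denominator is the time-averaged observed level, not the dynamic range,
so the metric stays defined for flat profiles. Individual fits are
accepted at ≤ 5%, shared fits at ≤ 4%; both thresholds are configurable.

**Control descriptors.** Settling time is the last time the fitted pool
leaves the ±5% band around its final level y(∞), found by dense
evaluation plus bisection on the continuous curve; near-flat responses
never leave the band and report 0. The band is referenced to the final
pool level, so a fit with y(∞) ≤ 0 has no settling time. The damping
coefficient is the stored ζ (underdamped) or (τ₁+τ₂)/(2√(τ₁τ₂)) ≥ 1
(overdamped).

## Preprocessing decisions

* **Outlier rule.** A replicate sample is flagged when, for at least
  half the metabolites at its time point (breadth 0.5; 1.0 gives the
  literal "across all metabolites" reading), the replicate RSD exceeds
  10% with the sample and falls to ≤ 10% without it. Leave-one-out
  repair is the operationalization of "a sample that caused the high
  RSD"; two mutually discordant replicates repair nothing and are
  surfaced as a QC warning instead of a flag.
* **CV filter.** The 15% rule is applied to the mean over time points of
  the replicate RSD. The alternative reading — RSD of the time-point
  means across time — is selectable (`cv_across_time=True`) but not the
  default, since it deletes genuinely dynamic metabolites.
* **LOD rule.** A metabolite is excluded per line when ≥ ceil(0.625·n_T)
  time points (5 of 8) are below the LOD or missing; a time point counts
  as censored when more than half its replicates are. Below-LOD values
  are never imputed; they are excluded from averages and propagate as
  missing points.
* Units: analysis runs on conc × extract_volume / protein (relative mol
  per µg protein). The µM→mol constant is configurable (default 1) and
  cancels in every ratio and shape quantity.

## Steady-state statistics

Initial = pre-step replicates, final = 2-h replicates. The t-test is the
pooled-variance two-sided Student test; degenerate zero-variance inputs
follow the convention p = 1 (equal means) / p = 0 (different). BH is
applied per cell line across its retained metabolites (a pooled family
is a config option). A volcano call requires BH rejection *and*
|fc − 1| ≥ 0.3 — the margin reads "30% difference from the initial
steady state" literally, so down-calls need fc ≤ 0.7 (the symmetric
fc ≤ 1/1.3 variant is a config option). Both raw and adjusted p-value
columns are emitted.

## Shared dynamics

All 11 line groups of size ≥ 2 are fit jointly: one shape set
(scenario, τₐ, τ₁/τ₂ or τ/ζ) plus one gain per line, initialized from
the best individual fit, scenario chosen by the joint residual.
Acceptance demands *every* member line under the 4% error. The Venn
"specific" region is the unique accepted group of maximal size;
equal-size ties leave the metabolite ambiguous (a convention — the
alternative of listing both is preserved in `accepted_regions`).
Glutamine, driven directly by the step, is fit shared across all four
lines first; configured lines (default: the hNSC lines, which carry the
larger sample-wise quantification variability) are then renormalized by
simulated/observed glutamine per time point, which exactly cancels any
multiplicative per-sample artifact shared by co-measured metabolites.

## Cell-type discrimination

The pair-level classifier is this package's operationalization (the
distance is not uniquely determined by the problem statement): for every
unordered line pair and co-retained metabolite, the score is
|log₂(feature_a/feature_b)| for feature ∈ {initial, final, fold-change}
(absolute difference selectable). Different-type pairs are positives;
the ROC is a threshold sweep and the AUC equals the Mann–Whitney
probability with half credit for ties. All (metabolite, pair) instances
are pooled.

## Synthetic data generator

The generator emulates the study design: four cell lines (two hiPSC,
two hNSC), a glutamine step from 2.5 to 15 mM (M = 12.5 mM, a six-fold
increase), time grid −10 (pre-pulse), 0, 5, 10, 15, 30, 60, 120 min,
3 replicates, and 201 metabolites across seven targeted-assay classes.
Choices, fixed once:

* Replicate noise is multiplicative log-normal, CV 5% by default
  (concentrations are positive; targeted-assay RSDs are relative); the
  per-metabolite noise magnitude is a fixture choice, not a measured
  value. Protein per pellet is log-normal (mean 100 µg, CV 10%).
* Time constants lie in 2–40 min so dynamics play out inside the 2-h
  window, consistent with pools settling within 2 h.
* Planted structure: per metabolite a sharing label — all-shared,
  hiPSC-only, hNSC-only, line-specific, or flat (zero gain, labelled
  all-shared since any shape fits it) — plus a known number of "bad"
  metabolites (fully below-LOD, or replicate CV 35%) that the quality
  filters must remove exactly.
* Relative steady-state responses are drawn per cell *type* (identical
  within a type), so fold-changes are type-structured while absolute
  baselines get independent per-line jitter — the regime in which the
  fold-change feature should outperform raw levels.
* Lines whose dynamics are planted to differ receive shapes from
  qualitatively distinct archetypes (fast-settling, slow-settling,
  inverse-response, oscillatory), and each candidate set is verified by
  a noiseless cross-fit: if any pair of distinct-by-design lines can be
  jointly fit below a 7% mean error, the set is redrawn. Without this
  calibration, a shared fit with free gains is flexible enough to absorb
  moderate shape differences at 8 coarse time points, and the planted
  structure would not be decodable even in principle. Metabolites with
  distinguishable dynamics are also planted as strong responders
  (|ΔSS|/y₀ ≥ 0.4): a shape difference is only visible when the
  transient is a sizable fraction of the pool level.

What the generator does **not** emulate: metabolic-network coupling
between pools (no stoichiometry, no flux balance — pools are independent
surge-tank responses, which is exactly the fitted model class, so
generator round-trips test the pipeline, not the model's adequacy for
real cells), assay-specific biases, drift or batch structure, and
heavy-tailed outliers beyond the injected multiplicative ones. Passing
tests therefore demonstrate correctness of the algorithms under the
stated noise model, not biological validity on real bioreactor data.

## Problem sizes and numerics

Test-suite simulations use 12–120-metabolite panels; the acceptance
script uses the full 201-metabolite panel for the filter/fit/ROC
quantities and a 40-metabolite panel for the shared-dynamics recovery
rate (11 joint fits per metabolite dominate the cost). All randomness
flows from explicit seeds; reruns are byte-identical. Optimizer
failures are caught per start; a trajectory where every start fails is
reported as a failed fit, never an exception. Time constants decoded
from the optimizer are clamped to [10⁻³, 10⁶] min to keep the closed
forms finite during line searches.

## Known limitations

* The overdamped distinct-root formula loses precision as τ₁ → τ₂
  faster than the 10⁻⁶ switchover; the confluent branch covers the gap,
  but gradients near the boundary are computed numerically by the
  optimizer and can be noisy.
* With 7 informative post-step points, τₐ and the smaller time constant
  are weakly identified for near-first-order responses; the gain K and
  the dominant time constant are the robust quantities (reflected in the
  acceptance criteria: exact recovery is only claimed at zero noise).
* The Venn specific-region tie convention and the pair-distance
  definition in the ROC stage are package conventions; both alternatives
  are exposed as options or preserved in the outputs.
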