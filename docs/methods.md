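# Methods

## Model

`latstep` implements a once-per-step ("lag-1") template of lateral
stepping regulation. The walker's state between steps is the pair of
lateral foot positions `[z_L, z_R]`; task coordinates are the body
position `z_B = (z_L + z_R)/2` (a proxy for the lateral center of mass
at heel strike) and step width `w = z_R − z_L`. The model deliberately
abstracts away within-step dynamics, continuous-time trajectories, and
fore–aft variables: it is a template for testing hypotheses about
high-level regulation, not a biomechanical simulator.

Each regulated variable follows the stochastic update

    q' = q + g (1 + σ_m v_m) u(q) + σ_a v_a,
    u(q) = −k (q − q*),   k = 1 / (1 + σ_m² + γ/α),

the optimal single-step controller for the quadratic cost
`C = α e'² + γ u²` with multiplicative control noise. `v_m, v_a` are
i.i.d. standard normal.

**Foot-placement realization.** Only one foot moves per step, so the
two regulators' predictions cannot in general both be realized. Each
prediction implies a placement for the moving foot (stance foot fixed):
the width expert `z_stance ± w_pred` and the position expert
`2 z_B,pred − z_stance`. The realized placement is the convex mixture
weighted by the control proportion ρ. Consequences worth knowing:

* The realized `(z_B, w)` are recomputed from the feet; they equal the
  regulator predictions only when the two experts coincide (which
  happens exactly when the stance foot sits at the placement goal
  implied by the step's `(z_B*, w*)` pair).
* Error decay is **not** `(1−k)` per variable. At ρ = 0.9 the position
  error contracts at ≈ 0.84 per step (at ρ = 1 it is not corrected at
  all): a width-prioritizing step cannot serve the position goal. A
  noiseless 0.6 m lane change therefore retains a ≈ 2.6 mm position
  residual 20 steps after the transition and reaches 1 µm only near 60
  steps. This slow mode is the quantitative face of the
  stability–maneuverability trade-off, and it also means a
  position-controlled step (ρ ≤ 0.5) can transiently *increase* the
  width error.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| γ/α | effort vs. error weight | 0.10 | standard steady-state value for this model family |
| g | overall gain | 1 | the optimal gain is already in k; g is exposed for sensitivity studies |
| σ_a (w) | additive noise, width | 0.02 m | plausible steady-state step-width SD on a treadmill; **placeholder**, not fitted |
| σ_a (z_B) | additive noise, position | 0.01 m | placeholder, as above |
| σ_m | multiplicative noise | 0.1·σ_a (dimensionless) | stated convention; at these σ_a its effect on k is negligible (< 10⁻⁵) |
| ρ steady | control proportion | 0.9 | steady walking strongly prioritizes width regulation |
| ρ prep/recovery | | 0.7 | intermediate weighting at the flanking maneuver steps |
| ρ transition | | 0.5 | equal weighting maximizes placement accuracy at the crossing step |
| σ_a multiplier | | 2 at preparatory and transition steps | emulates the increased variability observed mid-maneuver |
| ε | medial offset at prep/recovery | 0.25·w* (0.03 m for w* = 0.12 m) | no published value; estimable from data via `dataio.estimate_epsilon` |

Where experimental steady-state SDs are available,
`dataio.estimate_steady_goals` returns them (`sd_w`, `sd_zB`) precisely
so they can replace the σ_a placeholders.

Per simulated step, four standard-normal draws are consumed in a fixed
order (position v_m, v_a; width v_m, v_a), so trajectories are
bit-reproducible under a seed independent of which noise terms are
active. Regulator parameter objects carry no RNG state; seeding is the
simulation layer's job.

## Maneuver schedules

The four-step lane-change schedule indexes steps 0 (preparatory,
trailing foot medially in by ε), 1 (transition, large ipsilateral
crossing step), 2 (recovery), 3 (arrival), with steady entries extending
constantly at both ends. The transition goals follow from the
closed-form intermediate-goal algebra applied between the preparatory
and recovery goal pairs; a brute-force construction in the
foot-placement plane (`verify_two_step_completion`) confirms the closed
form on random inputs at machine precision. A generic nonzero goal
change moves both feet's placement goals, hence needs ≥ 2 steps; on the
degenerate lines `Δz_B* = ±Δw*/2` one foot's goal is unchanged and
`minimum_steps` honestly reports 1.

## Prediction-ellipse statistics

Covariances use the unbiased (n−1) estimator. Semi-axes are
`√(5.991 λ_i)` and the area `5.991 π √(λ₁λ₂)`, with
`5.991 = χ²₀.₉₅(2 df)` computed from scipy at import, giving 95%
coverage under bivariate normality (verified by Monte Carlo to ±0.5
percentage points at 10⁵ draws). Aspect ratio is the eigenvalue ratio
`λ₁/λ₂` (not the axis-length ratio). Orientation is reported in two
conventions: `orientation_verbatim` applies the published two-argument
arctangent formula with its axis-aligned special cases exactly as
written (it yields π/2 for a cloud aligned with the constant-w* GEM),
while `orientation_w_gem` reports the major axis' angular deviation from
that GEM directly (θ_major − π/4 wrapped to (−π/2, π/2]), so a
GEM-aligned cloud reads 0; analysis summaries use the latter.
Isotropic covariances (relative eigenvalue gap < 10⁻¹²) have undefined
orientation and return NaN; degenerate clouds report infinite aspect
ratio and zero area. Bootstrap CIs are percentile intervals (default
1000 resamples) resampling at the maneuver level.

## Batch experiments and the constant-ρ sweep

`run_batch` summarizes many independent simulations per step index;
`rho_sweep` holds ρ constant at every step (noise multipliers reset
to 1, goals kept — without goal changes no lane change happens at all),
aggregates two-level (per-batch means/SDs, then the across-batch mean of
each), and passes a ρ only if every banded statistic lies inside its
reference interval at every step. Reference bands may be experimental
or generated from the model itself (`make_model_bands`, percentile range
of per-batch statistics); model-generated bands support two built-in
checks: bands from ρ = 0.9 steady-state output admit 0.9 (parameter
recovery), and bands from the adaptive maneuver model admit *no*
constant ρ (the negative result motivating per-step adaptation).
The default sweep scale is reduced (100 batches × 100 simulations);
the full 1000 × 1000 scale is behind the CLI `--full-scale` flag.

## Synthetic experiment generator

`dataio.generate_synthetic_experiment` emulates the lane-change study
design: 20 participants × 4 maneuvers between paths 0.6 m apart,
alternating direction (leftward maneuvers mirrored), step indices
−13…+18 so that 8 steps per side fall outside the [−5, +10] exclusion
window (16 steady steps per maneuver, 1280 pooled), a nominal cue
marked 0–3 steps before initiation, and 30 discarded burn-in steps so
the pre-maneuver distribution is stationary. It is model output, not
synthetic humans: it contains no inter-participant heterogeneity by
default (a per-participant goal perturbation is available), no cue
reaction process, no drift, no missing steps. A green end-to-end test
therefore establishes that the analysis pipeline recovers what the
model put in — not that the model fits any particular dataset.

Estimator caveat: the steady-goal and ε estimators reproduce the
experimental averaging procedures, which presume placements realize
their goals on average. On model data with γ/α = 0.1 (k ≈ 0.91),
realized maneuver placements undershoot their scheduled goals and the
post-transition steady window retains a ≈ 0.01 m healing transient, so
recovery is exact only for k ≈ 1 generators; the default-parameter
biases are of that order and documented in the tests. ε is estimated
from *signed* medial differences (preparatory left foot vs. its
pre-transition mean; recovery-step right foot vs. its post-transition
mean), which is unbiased under symmetric placement noise where an
absolute-value version would fold the noise distribution.

Strategy classification calls a maneuver `multi_step` when more than
one step's body position lies in the middle half of the gap between
path centers (a staircase needed extra partial steps); `crossover` when
the first foot to cross the midline is contralateral to the travel
direction; `ipsilateral_single_step` otherwise. Midline ties count as
the new path. A maneuver whose net displacement is below 0.1 m is
excluded (logged) as having no detectable crossing.

## Numerical choices

* Coordinates are meters; z increases to the walker's right; the origin
  is arbitrary and everything is translation covariant.
* `w = z_R − z_L` always, including mid-crossover (negative widths are
  legal data).
* Schedule lookups clamp to the stored index range (constant extension).
* Covariance symmetry is enforced to 1e−8 relative tolerance; PSD-ness
  to a small negative eigenvalue tolerance.
* Point-in-ellipse tests project onto the covariance eigenbasis so that
  rank-deficient ellipses contain only their affine support.

## Known limitations

* No within-step control, double-support dynamics, or continuous CoM
  trajectory; one sample per step.
* The regulator is linear with Gaussian noise; heavy-tailed or
  asymmetric placement errors are out of scope.
* σ_a defaults are placeholders, not fitted values; quantitative
  comparisons to data should set them from measured steady-state SDs.
* The constant-ρ sweep's pass/fail criterion inherits whatever the
  reference bands mean (middle-90% range vs. bootstrap CI); the band
  type is data, not logic.
* Analyses of archived experimental deposits are supported only through
  the documented CSV schema plus a column-mapping option; raw marker
  trajectories and heel-strike detection are out of scope.
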