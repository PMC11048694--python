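# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Scoring

A trial is an ordered stream of key presses scored against a looped
four-element target sequence. The scorer keeps a pointer `p` into the
sequence (starting at 0): a press equal to `seq[p]` is *correct* and
advances `p` (mod 4); a press of a key not in the sequence is a
*wrong key* error and leaves `p` unchanged; a press of an in-sequence
key other than `seq[p]` is a *wrong order* error, after which `p`
resynchronises to the position *after* the pressed key. The
resynchronisation rule treats an out-of-turn press as a skip, so a
single slip cannot cascade into a run of spurious errors; it is a
design choice (alternatives such as "hold position" would classify
subsequent presses differently) and is pinned down by an independent
brute-force oracle test. Error rate is errors/total; for an empty
trial it is undefined and propagated as missing rather than 0, which
would otherwise bias trial-level averages. Ties in timestamps keep
file order, so scoring is deterministic.

## Measurement model

Fifteen battery indicators load on four correlated latent abilities
(working memory: digit spans + Corsi reversed; processing speed:
coding, symbol search, number connection, trail-making A, plus a
cross-loading of the sequential digit span; psychomotor speed: three
clicking-speed conditions; dexterity: four Purdue Pegboard
conditions). Timed scores are negated before z-standardisation (so
higher = better while preserving linearity; reciprocals would not),
and standardisation uses the sample (n−1) SD, the convention of
covariance-based SEM.

With complete data the model minimises the ML discrepancy
`F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p` with `Σ = ΛΦΛᵀ + Θ`,
standardised factors (unit diagonal of Φ) and `χ² = (n−1)F`. With
missing indicators (the Corsi task is absent for a fraction of the
sample) the casewise full-information likelihood is maximised, grouped
by missingness pattern, with the saturated covariance for the χ²
baseline estimated by EM; the mean structure is saturated by the prior
standardisation. Residual variances are parameterised as
`1e−4 + exp(u)`, so Heywood cases are bounded at a small floor and
flagged. Free factor correlations are optimised directly in
(−0.999, 0.999) with a positive-definiteness guard; all factor
covariances are estimated freely by default (a `fixed_zero_corr`
pattern is available) because reporting a non-significant correlation
is not the same as constraining it to zero. Optimisation is L-BFGS-B
from scale-adapted starting values; non-convergence is reported with
the best iterate and gradient norm.

Fit indices use the standard formulas (CFI, TLI, IFI from the
independence baseline, which has the closed form `F_B = −log|R|`;
RMSEA; SRMR as the RMS of standardised residual moments over the
p(p+1)/2 unique elements). Factor scores use the regression method
`F̂ = ΦΛᵀΣ⁻¹x` on each participant's available indicators; a factor
with no observed indicator yields a missing score. Standard errors for
the factor correlations come from the inverse numerical Hessian of the
negative log-likelihood (delta method on the direct parameterisation).

## Learning curves

Performance (correct presses) follows
`y_it ~ Normal(η_it, σ)` with
`η_it = β_i + (α_i − β_i)·exp(−exp(γ_i)(t − 1))`. The trial index is
1-based and the exponent uses `t − 1`, so α is exactly the expected
trial-1 performance; the rate enters as `exp(γ)`, leaving γ
unconstrained with negative values meaning slow learning. A Gaussian
likelihood is used because the counts are large (≈10–60 per 20-s
trial); β < α is admissible and simply signals absence of learning.

Individual triples are exchangeable,
`(α_i, β_i, γ_i) ~ MVN(μ, Σ)`. The prior on `(μ, Σ)` is a weakly
informative, scale-adapted Normal-Inverse-Wishart — location at the
empirical trial-1 and last-trial means (γ location −1), κ₀ = 0.01,
ν₀ = 7, scale matrix set so the prior mean of Σ is diagonal with SDs of
twice the empirical trial-1/last-trial SDs (1.5 for γ) — chosen
conjugate so the population block is a single exact Gibbs draw.
`σ²` has a conjugate inverse-gamma prior (shape 2, scale matched to a
rough residual variance).

Sampling is blocked Gibbs. The individual triples, whose likelihood is
nonlinear in γ, take adaptive random-walk Metropolis steps vectorised
across participants (their full conditionals are independent): during
the first part of warm-up the proposal is shaped by the current
population covariance, after which each participant gets an empirical
proposal covariance accumulated from their own warm-up draws (scaled
2.38²/d), which aligns proposals with the β–γ ridge of slow learners;
a per-participant scalar scale adapts toward 30% acceptance by
Robbins-Monro and all adaptation stops at the end of warm-up. Six
Metropolis sub-steps per Gibbs sweep give split-R̂ ≤ 1.01 for the
population parameters at the reduced profile. Random-walk samplers
have no divergent transitions; the divergence count is reported as 0
for interface parity. The study sampling profile is 4 chains × 5000
iterations (2000 warm-up); the reduced profile used by tests and the
default pipeline is 2 × 1500 (500 warm-up), which keeps a full
pipeline run in minutes on one CPU while leaving diagnostics clean.
Chains are seeded by spawned, independent RNG streams, so runs are
bit-reproducible for a fixed configuration.

The polynomial comparison families (linear/quadratic/cubic) keep the
same random-effects structure — per-participant coefficient vectors
`c_i ~ MVN(μ, Σ)` on a centred/scaled trial axis — and are fully
conjugate, so they are sampled exactly. Families are compared by
PSIS-LOO elpd from the pointwise log-likelihood (draws thinned to keep
the likelihood matrix small); pairwise elpd differences carry an SE
from the pointwise contributions, and a comparison is flagged
unreliable when more than 10% of points have Pareto k > 0.7.

## Trial-wise associations

The analysis follows a two-stage design: the posterior-mean fitted
performance η̂_it (not the raw counts — the fitted value is the model's
estimate of a participant's ability-relevant performance level, and
raw-count standardisation is available behind the input contract for
sensitivity checks) is standardised within each task × trial so that
coefficients are in SD-per-SD units and comparable across the learning
phase. The regression

`z_it = δ_t + b_t x_i + c_t g_i + u_i + ε_it`

treats trials as factors: every coefficient is trial-indexed. The
learning-rate control g_i is the posterior-mean γ_i with its own
trial-wise coefficient c_t by default (a single global c is available —
the functional form of "controlling for learning rate" is genuinely
open); a participant random intercept u_i is included because 20
repeated measures per participant would otherwise make the credible
intervals anti-conservative. All coefficients have Normal(0, 2²)
priors and the two variance components inverse-gamma(2, 0.5).

The model is linear-Gaussian and is sampled by exact Gibbs. With
complete data the participant intercept is *collapsed out* of the
coefficient update: the per-participant marginal covariance
`σ²I + σ_u²11ᵀ` is inverted by Woodbury and all 3T coefficients are
drawn jointly. This matters because fitted curves are smooth — the
residual variance is tiny and an uncollapsed sampler crawls along the
intercept/coefficient ridge (R̂ ≈ 1.1), while the collapsed sampler
mixes essentially perfectly (R̂ ≈ 1.000). With missing cells the
sampler falls back to per-trial blocked updates.

Factor scores are treated as observed covariates; their estimation
uncertainty is not propagated. This mirrors the two-stage design and
is a known limitation (coefficients are attenuated relative to a joint
model).

The shape summary of an association trajectory reports the trial-1
coefficient, the argmin trial, the plateau (mean of the last three
trials) and a dip-rebound flag (interior minimum below both the
initial value and the plateau).

## Gaze change points

Per-trial gaze-change counts follow a two-segment hinge on the count
scale: a linear decline from a_i at trial 1 to zero at the individual
change point τ_i, exactly zero afterwards, with truncated-Gaussian
noise (`Normal⁺`) because counts are nonnegative. The piecewise linear
hinge is the minimal shape with an interpretable τ; τ_i is continuous
in [1, T] via a logit transform (printed change points are
non-integer), a_i positive via a log transform, and both have
hierarchical normal priors whose means/variances get conjugate
normal/inverse-gamma updates. Individual pairs `(log a_i, logit τ_i)`
take adaptive Metropolis steps; the noise scale σ_g takes a scalar
Metropolis step on the log scale under a Half-Normal prior. The
population change point is reported as the inverse-transformed
population location (the population-typical τ). All-zero participants
are retained — their τ posterior collapses to the lower boundary — and
flagged; participants with missing gaze video are dropped from this
module only, never from the performance analyses.

## Synthetic-data generator

The generator emulates the study conditions and is the ground truth
for every recovery test: 86 participants × 2 tasks × 20 trials;
battery scores from the four-factor measurement model (primary
loadings 0.7, DSP_S cross-loading, factor correlations with WM–PS at
0.44 and the motor factors intercorrelated 0.55–0.60, Corsi missing
for 22/86); performance counts from the exponential model with
population (α, β, γ) = (22, 45, −1.98) for the piano task and
(30, 55, −1.10) for the pad task, within-task parameter correlations
(α–β 0.4, β–γ 0.3), residual SD 2.5, counts rounded and floored at 0
(consistent with the Gaussian likelihood); cross-task parameter
correlations (0.6, 0.8, 0.5) realised through shared standardised
components, which slightly attenuates within-task correlations; error
counts per trial drawn on the odds scale from an exponentially
declining error-rate schedule (trial 1 ≈ 15% piano / 10.5% pad falling
to ≈ 6.5% / 2.5%), split evenly into wrong-key and wrong-order; gaze
counts from the hinge model with population change points 7.06 and
4.92 and 12 participants dropped; Gold-MSI and piano-hours covariates
drawn independent of performance (the study's musicality null);
key-press logs constructed by walking the scorer's own pointer rules,
so scoring a generated log reproduces the target counts exactly.

Abilities couple to the curves through shifts of (α, β, γ) by
(0.50, 0.55, 0.10) parameter-SDs per SD of the psychomotor factor.
With the study's slow learning rates this produces the qualitative
association shape of interest — strong at trial 1, weaker shortly
after, rising to a plateau — with the minimum in the early-to-middle
trials. A dedicated scenario (`dip_scenario_config`) places the
minimum at exactly trial 2: strong direct α coupling makes trial 1
clean (trial 1 is pure α), a fast mean rate with large *uncoupled*
rate heterogeneity injects maximal dilution immediately after trial 1,
and β coupling restores the plateau. The implied true per-trial
association has no closed form (η is nonlinear in γ), so a seeded
large-n Monte-Carlo oracle (`true_association_profile`) defines the
configured truth that recovery tests compare against.

What the generator does **not** emulate: within-trial timing and
inter-keystroke intervals, fatigue or consolidation across the
session, non-Gaussian count dispersion, systematic missingness
mechanisms, or floor/ceiling artefacts in the battery. Passing
recovery tests therefore demonstrates that the pipeline estimates what
it models under the study's design and effect sizes — not that the
model family is correct for any particular real dataset.

## Problem sizes and profiles

Unit tests run the samplers at 2 chains × 400–600 iterations; the
recovery and calibration studies use the reduced profile (2 × 1500,
500 warm-up): 20 replications for learning-curve interval coverage and
50 replications (10 generated studies × 5 independent null abilities)
for the association null calibration, sizes at which the Monte-Carlo
error of the checked quantities is well inside the asserted bands.
The association-shape study runs at n = 200 (see
`dip_scenario_config`): the dip location is an argmin over adjacent
trials ~0.15 correlation units apart, and at the study's own n = 86 a
single replication flips it too often to make a sharp check of the
method rather than of sampling noise. The
acceptance script runs the same studies from scratch in a few minutes
on one CPU; the full study profile (4 × 5000/2000) remains available
via `--full` flags.

## Known limitations

- The exponential-curve γ scale is tied to this package's declared
  parameterisation; published estimates from a differently
  parameterised nonlinear model are comparable only approximately.
- FIML assumes missingness at random given the observed indicators.
- PSIS-LOO on hierarchical models treats each observation as the
  leave-one-out unit (not each participant).
- The association stage ignores factor-score and learning-rate
  estimation uncertainty (two-stage design).
- The gaze model's hinge-plus-truncated-Gaussian family is one of
  several plausible "piecewise nonlinear" choices; an exponential
  decline variant would shift τ estimates slightly.
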