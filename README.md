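# skillcurve

Analysis pipeline for cognito-motor sequence learning in older adults:
what does it take to learn a new four-key motor sequence — on a piano
or on a response pad — and how do latent cognitive and motor abilities
relate to performance as learning unfolds?

The package reimplements, as tested and reusable code, a complete
analysis chain for a study design in which 86 older adults practise two
looped four-element key sequences (20 trials of 20 s each) while a
15-test battery measures working memory, processing speed, psychomotor
speed and dexterity:

1. **Scoring** (`skillcurve.scoring`) — raw key-press logs are scored
   against the looped target sequence: each press is *correct*,
   *wrong key* (not part of the sequence) or *wrong order* (in-sequence
   but out of turn). Correct presses per trial are the performance
   variable; errors / total presses is the error rate.
2. **Measurement** (`skillcurve.measurement`) — a confirmatory factor
   analysis of the battery,
   `Σ = ΛΦΛᵀ + Θ`, fitted by maximum likelihood (full-information when
   the Corsi block task is partly missing), with CFI / TLI / IFI /
   RMSEA / SRMR and regression-method factor scores
   `F̂ = ΦΛᵀΣ⁻¹x`.
3. **Learning curves** (`skillcurve.curves`) — a hierarchical Bayesian
   exponential model per task,

       y_it ~ Normal(η_it, σ),  η_it = β_i + (α_i − β_i)·exp(−exp(γ_i)·(t−1)),

   with correlated individual baselines α, asymptotes β and log
   learning rates γ, `(α_i, β_i, γ_i) ~ MVN(μ, Σ)`; split-R̂
   diagnostics and PSIS-LOO elpd comparison against hierarchical
   linear/quadratic/cubic alternatives.
4. **Associations** (`skillcurve.association`) — model-fitted
   performance standardised per task × trial (1 unit = 1 SD), then
   regressed on one predictor at a time with trials as factors,

       z_it = δ_t + b_t·x_i + c_t·g_i + u_i + ε_it,

   controlling for individual learning rates g and a participant random
   intercept u; `b_t` traces how strongly an ability predicts
   performance at every point of the learning phase.
5. **Gaze** (`skillcurve.gaze`) — a piecewise hinge change-point model
   for per-trial gaze changes between display and keys,
   `μ_it = a_i·max(0, (τ_i − t)/(τ_i − 1))`, estimating the trial τ at
   which visual control becomes negligible.
6. **Synthetic study** (`skillcurve.synth`) — a seeded generator
   producing battery scores, key logs, trial scores, gaze counts and
   musicality covariates with the full statistical structure above, so
   every stage is testable end to end without any data download.

## Worked example

Run the numbered analysis drivers (each is a thin script over the
library):

```bash
python analysis/01_simulate.py --seed 1     # synthetic study -> data/synth/
python analysis/02_score.py                 # key logs -> per-trial scores
python analysis/03_factors.py               # CFA + factor scores
python analysis/04_learning_curves.py --compare
python analysis/05_associations.py
python analysis/06_gaze.py
```

On the default synthetic study (seed 1) this prints, among other lines:

```
piano: error rate 15.0% (trial 1) -> 6.2% (trial 20)
CFA (fiml, n=86, converged=True)
  CFI=0.982 TLI=0.977 IFI=0.982 RMSEA=0.037 SRMR=0.060
piano: gamma = -1.94 [-2.15, -1.75], max Rhat 1.0045
pad: gamma = -1.07 [-1.23, -0.92], max Rhat 1.007
cross-task beta: r = 0.83 (p = 6.2e-23)
piano: visual control negligible around trial 6.71 [6.30, 7.14]
pad: visual control negligible around trial 4.79 [4.48, 5.12]
pad/PM: b1 = 0.55, min at trial 4, plateau 0.46 (dip-rebound: True)
```

Reading the numbers: the piano task has the more negative population
log learning rate (γ = −1.94 vs −1.07), i.e. slower convergence to its
asymptote; gaze changes reach zero around trial 6.7 (piano) vs 4.8
(pad), so the pad task is released from visual control earlier; and the
trial-wise coefficient of psychomotor speed starts high, dips early,
and climbs to a plateau — abilities matter most at the very start and
again late in learning. The generating values behind this study were
γ = −1.98 / −1.10 and change points 7.06 / 4.92, so the pipeline
recovers its inputs.

`analysis/07_reproduce_osf.py` runs the identical pipeline on the
study's deposited human dataset once it has been downloaded into
`data/osf/` with a column mapping (`skillcurve.pipeline.ingest_osf`).

There is also a CLI mirroring the drivers
(`skillcurve simulate | score | fit-curves | associations | gaze | run`).

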