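# Methods

## Model

Antisaccade behavior is modeled as a race between three single-boundary
Wald accumulators with unit diffusion coefficient (the diffusion scale is
not identifiable jointly with drift and threshold, so it is fixed by
convention).  Finishing times are inverse-Gaussian: for drift `v` and
threshold `a`, mean `a/v` and shape `a^2`.  Parameters, with units and
defaults used throughout the examples:

| parameter | meaning                               | typical value |
|-----------|---------------------------------------|---------------|
| `v_pre`   | prepotent drift (evidence/s)          | ~5            |
| `v_inhib` | inhibitory drift                      | ~6            |
| `v_exec`  | executive drift                       | ~7            |
| `a_mean`  | mean threshold (evidence units)       | ~1            |
| `a_diff`  | anti-minus-pro threshold difference   | 0             |
| `t`       | non-decision time (s)                 | ~0.15         |
| `t_exec`  | executive onset delay (s)             | ~0.05         |

Race logic: on an antisaccade trial draw `T_pre`, `T_inhib` and
`T_exec = t_exec + FPT(v_exec, a_anti)`.  An error occurs only when
`T_pre < T_inhib` **and** `T_pre < T_exec`; otherwise the trial is correct
with `rt = t + T_exec`.  The second comparison is required so that very
slow inhibition cannot produce errors later than the already-executed
correct response; ties (measure zero) resolve toward the correct response.
Effective thresholds split symmetrically, `a_pro = a_mean - a_diff/2`,
`a_anti = a_mean + a_diff/2`; `a_diff = 0` recovers the single-threshold
variant exactly.

Consequences used as exact tests: raising `v_inhib` right-censors the error
RT distribution while leaving every correct-trial RT untouched, and raising
`t_exec` shifts every correct RT by exactly the increment.  Both are
verified under common random numbers — inverse-Gaussian draws use the
Michael–Schucany–Haas transformation consuming exactly two uniforms per
draw (the normal variate comes from the quantile function, not rejection),
so counterfactual parameter settings can share one fixed uniform block.
One caveat: the transformation's acceptance branch can flip for a small
fraction (~2%) of draws when a drift changes, so error-rate monotonicity in
a drift holds at the count level, not for every individual draw.

## Likelihood

Prosaccade trials involve only the prepotent accumulator and are scored by
the closed-form shifted Wald density.  The antisaccade likelihood is
approximated by probability density approximation: simulate `n_sims`
trials at the candidate parameters (default 10,000; 2,000 in the fast
profile used by the tests), fit one Gaussian KDE per response channel with
Silverman's rule-of-thumb bandwidth `sd * (3n/4)^(-1/5)` on the RT scale,
and weight each channel by its simulated response probability so the
defective densities integrate to one jointly.  Densities are floored at
1e-10 before the log so the objective stays finite for RTs outside the
simulated support; a channel with fewer than two simulated trials
evaluates to the floor.  KDE kernels are truncated at eight bandwidths
(relative error < 1e-13, far below the floor).  The simulation uniform
block depends only on (seed, n_sims) and is reused across parameter
settings, which makes the objective deterministic within a fitting run —
without this, residual simulation noise destabilizes the optimizer.

At 10^5 simulations the single-accumulator PDA agrees with the closed-form
log-likelihood to ~0.02 nats/trial on typical data (the acceptance script
measures this), and the error shrinks monotonically in `n_sims`.

## Fitting

Per-subject maximum likelihood maximizes (closed-form pro) + (PDA anti)
with Powell local searches inside basin-hopping restarts (default 5 hops;
2 in the fast profile), hop proposals uniform within 25% of each bound
range.  Bounds: drifts (0.1, 40], `a_mean` (0.3, 5], |`a_diff`| <=
`a_mean`/2, `t` in [0.05, 0.6] s, `t_exec` in [0, 0.6] s — generous for
saccadic RTs.  Initialization moment-matches the prosaccade marginal
(`t0 = 0.9 min RT`; drift and threshold from the mean and variance of the
decision-time component, since a Wald has mean `a/v` and variance `a/v^3`),
with the inhibitory and executive drifts started at the prepotent value.
The best *valid* objective evaluation is returned, which also enforces the
relative `a_diff` constraint that the box bounds cannot express.  Loose
Powell tolerances (1e-3) suit the KDE-rough surface.  Subjects with fewer
than 20 trials in a condition are fit but flagged.

Model variants (e.g. `a_diff` free vs fixed, `t_exec` free vs 0) are
compared by AIC = 2k − 2 loglik.

Known estimation behavior: `t` trades off against the drifts along a ridge
(a later non-decision onset can be compensated by faster accumulation), so
individual estimates carry a modest common bias while the *ranking* across
subjects — what the downstream analyses use — is preserved; recovery
correlations for the drifts are ~0.8–0.9 at 200+200 trials.

## Behavioral analysis

Summary statistics are per-cell means/SDs (sample SD, n−1) and antisaccade
accuracy.  Delta plots use six quantile ranges (0–10, 10–30, 30–50, 50–70,
70–90, 90–100%); the sorted i-th of n RTs occupies quantile position
(i − 0.5)/n and ranges are half-open except the last.  Only correct
antisaccades enter; x is the across-condition mean of matching range
means, y the anti-minus-pro difference.  Ranges are computed per subject
and averaged across subjects pointwise (with standard errors), skipping
missing points.  Group comparisons default to the pooled-variance t test
(df = n1 + n2 − 2) with Welch available behind a flag.

## Downstream statistics

Stage is coded linearly 0–4 (controls, two pre-manifest bands, two
early-manifest bands) and regressed on all fitted parameters by OLS
(statsmodels; listwise deletion; rank-deficiency is an error).  Clinical
regressions use the same direction — score on parameters — with the motor
score entered as log(TMS + 1) because controls legitimately score zero.

Breakpoint detection is a deliberately minimal MARS variant: one
predictor, basis {1, x, max(0, x − k)} with up to two hinges, knots chosen
greedily from observed values (thinned to a 50-point quantile grid for
continuous predictors), model size selected by GCV with the conventional
penalty of 3 per knot and ties resolved toward the smaller model, so an
exactly linear response retains no hinge.  This is all the staging question
needs — *where* does a parameter start declining — and avoids carrying a
full MARS implementation.

## Classification

Binary: L2 logistic regression; the outer loop is a stratified shuffle
split (default 200 repeats, 20% held out), the inner loop 10-fold
stratified CV selecting the regularization strength from 13 log-spaced
values in [1e-3, 1e3] by classification accuracy; features are z-scored
with training-split statistics only.  Performance is the mean ± SD of the
held-out AUC.  Multiclass uses a random forest (500 trees, sqrt-features)
under the same outer protocol, reporting accuracy and the pooled confusion
matrix.  Feature sets are compared on *identical* outer splits with a
paired two-sided t test on per-split AUCs.  Calibration checks: permuted
labels give AUC ~0.5; a planted one-dimensional Gaussian gap d has optimum
AUC Phi(d/sqrt 2); an uninformative three-class problem recovers the
majority-class baseline.

## Synthetic cohorts

No oculomotor staging dataset of this kind is publicly deposited, so the
generator is a first-class module.  Subject parameters are drawn from
stage-specific Gaussians truncated to the fitting bounds.  The planted
structure: `v_exec` declines linearly by 0.35 per stage from 7.10 (a
stage-0 versus pooled stages-1+2 standardized difference of 0.35 at SD 1.5
— subtle, pre-manifest-like); `v_inhib` is flat (6.0) through stage 2 and
drops to 4.5 / 3.3 at the symptomatic stages; `v_pre`, `t` and `t_exec`
worsen only at stages 3–4.  Control-stage means were calibrated once so
simulated controls show the canonical healthy profile on this task:
prosaccade RT ~0.34 s, correct-antisaccade RT close to the prosaccade RT,
~68% antisaccade accuracy, errors faster than correct responses, and a
negative delta-plot slope.  That last property pins the regime
`v_exec > v_pre`: the correct-anti distribution is then tighter than the
prosaccade distribution and its slow tail is right-censored (slow
executive finishes tend to resolve as errors), which is what makes the
anti-minus-pro difference shrink across quantiles.  Stage-wise behavior at
the defaults: accuracy 0.68 / 0.67 / 0.66 / 0.56 / 0.49 and prosaccade RT
0.34→0.42 s — pre-manifest stages are nearly indistinguishable
behaviorally while the executive drift declines underneath, which is
exactly the dissociation the pipeline is meant to expose.

Clinical scores: log(TMS + 1) is linear in stage with Gaussian noise
(so TMS is generated as round(exp(·)) − 1, clipped at zero and the log
transform is well-posed); TFC declines from 13 mainly at symptomatic
stages; CAG is drawn independently of the parameters (non-expanded range
for controls, expanded for carriers).  Default counts mirror a large
staging study (123 / 61 / 61 / 63 / 62); trials default to 100 pro + 100
anti per subject.

What the generator does *not* emulate: measurement noise of the eye
tracker, anticipatory saccades, prosaccade errors, trial-history effects
and longitudinal visits.  Passing tests therefore demonstrate that the
pipeline recovers structure the model itself generated — internal
consistency and statistical power at realistic effect sizes — not that the
model is correct for any real population.

## Problem sizes and tolerances

The acceptance script and the end-to-end tests run at desk scale, chosen
as the smallest sizes at which each planted effect is reliably detectable:
parameter recovery uses 20 subjects × (200 pro + 200 anti) trials at
n_sims = 2,000 with 2 hops; the planted two-group executive-drift contrast
uses 6 subjects per group; the staged cohort uses (48, 24, 24, 24, 24)
subjects × (200 + 200) trials.  The classifier calibration uses 200 outer
repeats.  Smaller cohorts lose power for the two weakest downstream
signals (the partial regression coefficient of `v_exec` on stage, and the
inhibitory breakpoint under GCV), both of which depend on subject count
far more than on trials per subject because between-subject parameter
variance dominates estimation noise.

## Limitations

Across-trial parameter variability, sequential/trial-history effects and
hierarchical (shrinkage) estimation are out of scope; estimates are
per-subject maximum likelihood with no standard errors.  The `t`/drift
ridge biases absolute parameter values at small trial counts.  The hinge
regression handles one predictor only.  AUCs on the default cohort are
modest by construction (the planted pre-manifest effect is subtle); they
measure detectability, not clinical utility.

One consequence of simulating directly from the model deserves emphasis:
in the generator the correct-antisaccade mean RT is a clean readout of
`t + t_exec + a/v_exec`, so RT summary statistics carry nearly as much
pre-manifest executive signal as the fitted `v_exec` itself.  The
advantage of the model feature over summary features is therefore real
but small on synthetic cohorts, and can invert on an unlucky cohort draw;
on real recordings, noise sources the generator omits (tracker noise,
anticipatory saccades, session effects) degrade summary statistics while
model fitting pools information across the full distributions of both
trial types, which is where the larger published separation comes from.
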