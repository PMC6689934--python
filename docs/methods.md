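# Methods

## Task model

The environment is the standard two-stage decision task. Stage 1 offers
fractals A/B; A leads to state `s2` (fractals C/D) with probability
`p_common` = 0.7 and to `s3` (E/F) otherwise, B the reverse. Rewards are
binary. Reward probabilities of the four second-stage fractals follow
independent Gaussian random walks (per-trial sd 0.025) reflected at
[0.25, 0.75]; initial probabilities are drawn uniformly within the bounds
unless supplied. These walk parameters are the conventional design for this
task family and are configurable (`TaskConfig`); they are assumptions, not
estimates. On every trial and stage the two available fractals are assigned
to screen side independently with probability 0.5. Screen side and response
key are perfectly confounded by design, so the data model stores only the
key; trial records carry the full mapping so that key/choice/side
consistency is checkable (`validate_trials`).

Conventions: trial indices are 0-based; fractal A's common state is `s2`;
trial CSVs use the documented 11-column schema (UTF-8, header required,
unknown extra columns ignored with a warning).

## Agents

All five agents value second-stage fractals by SARSA temporal-difference
updates (learning rate `alpha1`) and the first stage additionally through an
eligibility trace `lambda1` that propagates the second-stage prediction
error backwards. Values start at zero. Model-based first-stage values
combine the known 70/30 transitions with the per-state maxima.

- **Model 1 (null)**: fractal values only;
  `Q_net = w1 Q_MB + (1 - w1) Q_Fractal` at stage 1, `Q_Fractal` at stage 2.
- **Model 2 (key values)**: adds a two-element `Q_Key` updated at stage 1 by
  `a2 l2 (r - Q_Key)` and at stage 2 by `a2 (1 - l2) (r - Q_Key)`, entering
  both stages' net values as `+ w2 Q_Key`. `lambda2` splits one reward's
  credit between the two key presses.
- **Model 3 (feature approximation)**: model-free values are a linear
  function of six fractal indicators and two key indicators; all active
  features share the prediction-error update (rate `alpha2`, trace
  `lambda1`). Both stages mix with `Q_MB` via `w1`.
- **Model 4 (conjunctive)**: 12 model-free values, one per (fractal, key)
  pair, SARSA-updated with rate `alpha2` and trace `lambda1`.
- **Model 5**: as Model 4, but the model-based system also distinguishes
  the four mapping-specific second-stage states; the common transition mass
  splits 0.35/0.35 over the two mappings of the common pair and 0.15/0.15
  over the rare pair. Because each mapping-specific state is defined by its
  key layout, its attainable value is taken as the max over the conjunctive
  values available under that mapping. At stage 2 the two systems coincide,
  so the net value is the conjunctive value itself.

Choice rule: `P(right) = logistic(beta (V_right - V_left) + bias terms)`,
with a single inverse temperature at both stages. The bias terms are signed
(right minus left): fractal perseveration (stage 1 only, indicator that an
option repeats the previous first-stage choice), key perseveration
(previous key press *within the same stage*), and a constant key bias. The
additive form with one beta is the minimal standard choice rule; `w1`/`w2`
already scale the value components. `w2` is left unbounded because it
scales an added component rather than a convex mixture; its scale trades
off with `beta`, an identifiability caveat shared with `beta` itself.

When the same container entry receives credit from both stages in one trial
(e.g. the same key pressed twice in Model 2), both increments are computed
from the pre-trial value and summed — the update equations all reference
time-`n` values on the right-hand side.

An optional variant replaces the spatial-motor-relevant learning rate
(`alpha1` in Model 1, `alpha2` in Model 2) with separate rates for mapping
repetitions vs. switches (`alpha_rep`/`alpha_flip`); equal rates reproduce
the base model exactly.

Two implementations of the likelihood exist: a readable per-trial API
(`init_values`/`update_values`/`net_values`/`choice_probability`) and a
fast flat-loop engine used by the fitter; the test-suite holds them to
agreement within 1e-12 per trial for all five models.

## Synthetic cohorts

Populations are Gaussian in the unconstrained fitting space (logit for
rates, traces and `w1`; log for `beta`; identity for `w2` and biases),
matching the hierarchical prior so recovery studies are internally
consistent. Desk-scale defaults: learning rates ~0.45, trace ~0.6,
`w1` ~0.5, `w2` = 0.3, `beta` ~4, mild perseveration (0.2/0.1), zero key
bias; unconstrained sds 0.7 for rates/traces/weights, 0.15 for `w2`, 0.35
for log-beta, 0.15-0.25 for biases. These are chosen once as plausible for
an adult cohort on this task; a 769/63/568-subject preset mirrors the
scale of a longitudinal study design. Default desk cohort: 100 subjects x
300 trials. Each subject receives a fresh reward schedule and simulation
seed derived from the cohort seed; outputs are byte-reproducible.

The generator emulates trial structure, drifting rewards, and parameter
heterogeneity. It does not emulate reaction times, missed/excluded trials,
session breaks, practice or age effects — so passing recovery tests show
the estimation machinery works under the model's own assumptions, not that
real data satisfy them.

## Sequential analyses

Consecutive trial pairs (lag 1 by default; lag 2 supported) are classified
within-subject by whether the second-stage pair repeats. Pair tables demand
exact index adjacency, so gaps (session breaks, dropped rows) never form
pairs. Mapping relation is defined by whether trial-n's chosen fractal
keeps its key side at n+lag.

Per-subject scores are raw stay-probability differences:
within-state interaction
`(stay|rew,same - stay|unrew,same) - (stay|rew,flip - stay|unrew,flip)`;
between-state and between-stage scores are rewarded-minus-unrewarded
key-stay differences. Cells with zero denominators make the subject missing
for that contrast (logged), never zero. Group inference is a one-sample t
test with 95% CI on the per-subject scores; a variational-Bayes
mixed-effects logistic regression (random intercepts) is available as an
alternative route (`method="mixed"`). Raw probability differences are the
primary report because they are in the same percent units across analyses;
regression coefficients are attached when requested.

A structural caveat found while validating the null model: outcome-blind
key perseveration shifts the logistic operating point differently for
same- vs flipped-mapping pairs, which induces a small *negative*
within-state interaction (~-0.03 at perseveration 0.1) even with no key
values at all. The between-state and between-stage effects are immune —
perseveration is outcome-independent — which is why the null checks rest on
those two. The clean within-state null (interaction = 0 without key values)
holds when key perseveration is zero.

## Hierarchical fitting

Per-subject MAP estimation runs in the unconstrained space under a diagonal
Gaussian prior (L-BFGS-B, box [-15, 15] as a numerical guard, 4 jittered
restarts on the first EM iteration, warm starts thereafter). The Laplace
evidence is `logpost(mode) + d/2 log(2 pi) - 1/2 log det H` with `H` the
numerical Hessian of the negative log posterior (symmetrised; ridged up
from 1e-8 if not positive definite, flagged). The M step sets the prior
mean to the mean of the modes and the prior variance to the spread of the
modes plus the mean posterior variance (diagonal of inverse Hessians),
floored at 1e-3. EM stops when the largest mean change drops below `tol`
(default 0.02, max 25 iterations). Because the E step is itself an
approximation, the evidence trace can dip by a fraction of a nat between
iterations; the invariant enforced in tests is monotonicity within a small
slack, not exact monotonicity.

`BIC_int = -2 sum_i log p(data_i | prior) + k log N` with `k` = two group
parameters per model parameter and `N` = total choices (two per trial).
The `N` convention is configurable via the results object; alternatives
(trials rather than choices) shift all models' scores nearly equally and
barely move the deltas.

Recovery behaviour at the default desk scale (100 subjects x 300 trials,
Model 2): subject-level correlations true-vs-MAP are high for `alpha1` and
`beta` (~0.9), good for `w2` (~0.7), moderate for `lambda1` (~0.6). Group
means recover well for most parameters; the eligibility trace is the
weakest — its group mean can land ~0.2 logit units low at this trial count,
a known soft-identifiability of trace parameters against `w1` in this task.

## Posterior-predictive checks

Each fitted subject is re-simulated (default 20 replicates x 1,000 trials,
fresh reward walks — the schedules actually experienced are not reused) and
the three effects are recomputed per replicate and averaged. Model-data
correspondence is the Pearson correlation across subjects between simulated
and empirical scores, with a bootstrap CI (2,000 resamples). The classic
first-stage outcome x transition interaction is computed here too, serving
as the behavioural model-based indicator; `mb_mf_association` correlates
the model-based block (`w1`, that interaction) with the spatial-motor block
(`w2`, the three sequential effects) using plain Pearson correlations with
Fisher-z CIs. A full latent-factor treatment is intentionally out of scope;
direct correlations keep the association interpretable at desk scale.

## Numerical and design choices

- Log-choice probabilities use a stable log-sigmoid; likelihoods are finite
  for any finite parameters and every choice probability is interior.
- All simulation seeds derive from user-supplied integers through
  `numpy.random.SeedSequence`; cohort CSVs are byte-identical across runs.
- Problem sizes in the test-suite (e.g. recovery at 100 x 300, model
  recovery at 30 x 250, EM restarts reduced to 2 where a fixture is
  re-fitted) are the package's chosen desk-scale defaults; study-scale
  presets exist but are not exercised by default.
- Ties never need breaking: choice probabilities are strictly interior.

## Known limitations

- MAP-based EM underestimates weakly identified group means (see the
  eligibility-trace note above); full posterior sampling is out of scope.
- `w2`/`beta` scale trade-off limits the interpretability of `w2`'s
  absolute magnitude; comparisons across subjects fitted with the same
  scheme remain meaningful.
- The variational mixed-effects route is approximate and used for
  direction/magnitude checks, not as the primary inference.
- Models 3-5 have fast likelihood kernels but only Models 1-2 have the fast
  simulator; large-scale forward simulation of Models 3-5 uses the readable
  path and is slower.
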