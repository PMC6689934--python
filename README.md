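# twostep-credit

Credit assignment to outcome-irrelevant, spatial-motor task features in the
two-step decision task: simulation, hierarchical model fitting, and
model-agnostic sequential analyses.

## The scientific problem

In the two-step task a first-stage choice between two fractal images leads,
with fixed probability 0.7/0.3, to one of two second-stage states, each
offering another pair of fractals; second-stage choices pay a binary reward
with slowly drifting probabilities. Crucially, fractals are re-assigned to
the left/right screen side (and hence to the left/right response key) at
random on every trial and stage, so *only fractal identity* predicts
reward — the response key is outcome-irrelevant. This package asks whether
model-free learning nevertheless assigns reward credit to the response key,
and how that tendency relates to model-based control.

Two complementary routes are implemented:

1. **Sequential (stay-probability) analyses** of raw choices:
   - *within-state*: the outcome x mapping interaction on fractal stay
     probability when the same second-stage pair repeats;
   - *between-states*: the effect of reward on repeating the response key
     when a different pair is offered next;
   - *between-stages*: the effect of second-stage reward on repeating that
     key at the next trial's first stage.
   A chooser that values only fractals shows no key-mediated reward effects;
   key-value learning makes all three positive.

2. **Computational modelling** with five reinforcement-learning agents. All
   share SARSA fractal learning with an eligibility trace

   `Q(f1) <- Q(f1) + a1 (Q(f2) - Q(f1)) + a1 l1 (r - Q(f2))`,
   `Q(f2) <- Q(f2) + a1 (r - Q(f2))`,

   and prospective model-based valuation
   `Q_MB(F) = P(s2|F) max Q(s2) + P(s3|F) max Q(s3)`.
   They differ in the spatial-motor component: none (Model 1); a separate
   key-value system `Q_Key` entering the net value as
   `Q_net = w1 Q_MB + (1 - w1) Q_Fractal + w2 Q_Key` (Model 2); linear
   function approximation over fractal and key features (Model 3);
   conjunctive fractal-key values (Model 4); conjunctive values in both
   systems with mapping-specific transition weights 0.35/0.15 (Model 5).
   Choices are logistic in beta times the net-value difference plus
   perseveration and key-bias terms.

Subjects are fitted hierarchically (EM with per-subject MAP estimation and
Laplace-approximated integrated likelihoods under a diagonal Gaussian group
prior) and models are compared by integrated BIC (a difference of 10+ counts
as strong evidence). Posterior-predictive checks simulate 20 sessions of
1,000 trials from each subject's fitted parameters and correlate simulated
with empirical effect scores. A synthetic-cohort generator with known ground
truth supports parameter- and model-recovery studies.

## Worked example

```python
import twostep_credit as tc

# a 20-subject key-value (Model 2) cohort, 300 trials each, with ground truth
spec = tc.default_population(2, n_subjects=20, n_trials=300, seed=3)
records, truth = tc.generate_cohort(spec, tc.TaskConfig())

# sequential analyses
pairs = tc.pairs_frame(records)
print(tc.between_stage_effect(pairs).summary())
# between_stage: effect = +0.0554 (95% CI [+0.0206, +0.0901]),
#   t(19) = 3.34, p = 0.00348, n = 20

# hierarchical fit and summary
result = tc.HierarchicalRLModel(tc.records_to_frame(records), model_id=2).fit(
    max_iter=10, n_starts=2, seed=1
)
print(result.summary())
# Hierarchical fit: Model 2
#   subjects: 20   choices: 12000
#   EM iterations: 4   converged: True
#   total log evidence: -6195.80
#   BIC_int: 12579.46
#   ... group-level means (w2 ~ 0.298, beta ~ 4.32, ...)
```

The between-stage effect (+5.5% here) says these simulated subjects were
more likely to repeat a rewarded second-stage key press at the next first
stage — the signature of state-independent key-value learning; the fitted
group-level `w2` quantifies the same tendency inside the model.

A thin CLI mirrors the library: `twostep-credit simulate|sequential|fit|compare|ppc`.

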