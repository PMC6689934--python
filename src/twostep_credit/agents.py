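"""The five reinforcement-learning agents for the two-step task.

All models learn fractal values with a SARSA temporal-difference rule with
an eligibility trace and value them prospectively through the known 70/30
transition structure (the model-based component). They differ in how — and
whether — credit is also assigned to the outcome-irrelevant response key:

* **Model 1** (null): fractal values only.
* **Model 2**: a separate model-free value per response key, updated at both
  stages with a shared learning rate ``alpha2`` and a stage-credit split
  ``lambda2``, added to the net value with weight ``w2``.
* **Model 3**: model-free values by linear function approximation over
  fractal and key features (weights ``w_1..w_8``).
* **Model 4**: conjunctive model-free values per (fractal, key) pair.
* **Model 5**: as Model 4, but the model-based system also distinguishes the
  four mapping-specific second-stage states (transition mass 0.35/0.35 for
  the common pair and 0.15/0.15 for the rare pair).

Choices follow a logistic rule on the net-value difference scaled by an
inverse temperature ``beta``, plus additive biases for fractal perseveration
(first stage only), key perseveration (within stage), and a constant key
preference.

This module exposes both a readable per-trial API (:func:`init_values`,
:func:`update_values`, :func:`net_values`, :func:`choice_probability`) and a
fast sequence-level likelihood/simulator backed by
:mod:`twostep_credit._engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from . import _engine
from .task import (
    COMMON_STATE,
    FIRST_STAGE_FRACTALS,
    FRACTAL_CODE,
    KEYS,
    STATE_FRACTALS,
    RewardSchedule,
    TaskConfig,
    TrialRecord,
    key_for,
)

__all__ = [
    "AgentParams",
    "ValueState",
    "ChoiceContext",
    "ParameterError",
    "init_values",
    "update_values",
    "model_based_values",
    "net_values",
    "choice_probability",
    "loglikelihood",
    "simulate_agent",
]

#: Transition weight per mapping-specific second-stage state in Model 5:
#: the 70% common mass splits evenly over the two mappings of the common
#: pair, the 30% rare mass over the two mappings of the rare pair.
MODEL5_COMMON_WEIGHT = 0.35
MODEL5_RARE_WEIGHT = 0.15


class ParameterError(ValueError):
    """Agent parameter outside its legal range."""


@dataclass
class AgentParams:
    """Free parameters of one model for one subject (natural space).

    Fields irrelevant to ``model_id`` are ignored. ``alpha_rep``/``alpha_flip``
    optionally replace the model's spatial-motor-relevant learning rate
    (``alpha1`` for Model 1, ``alpha2`` for Model 2) with separate rates for
    mapping repetitions vs. switches.
    """

    model_id: int
    alpha1: float = 0.0
    lambda1: float = 0.0
    alpha2: float = 0.0
    lambda2: float = 0.0
    w1: float = 0.0
    w2: float = 0.0
    beta: float = 1.0
    persev_fractal: float = 0.0
    persev_key: float = 0.0
    key_bias: float = 0.0
    alpha_rep: float | None = None
    alpha_flip: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3, 4, 5):
            raise ParameterError(f"unknown model_id {self.model_id}")
        for name in ("alpha1", "lambda1", "alpha2", "lambda2", "w1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ParameterError(f"beta={self.beta} must be nonnegative")
        for name in ("alpha_rep", "alpha_flip"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if (self.alpha_rep is None) != (self.alpha_flip is None):
            raise ParameterError("alpha_rep and alpha_flip must be set together")

    def as_dict(self) -> dict:
        d = {
            "alpha1": self.alpha1, "lambda1": self.lambda1,
            "alpha2": self.alpha2, "lambda2": self.lambda2,
            "w1": self.w1, "w2": self.w2, "beta": self.beta,
            "persev_fractal": self.persev_fractal,
            "persev_key": self.persev_key, "key_bias": self.key_bias,
        }
        if self.alpha_rep is not None:
            d["alpha_rep"] = self.alpha_rep
            d["alpha_flip"] = self.alpha_flip
        return d


@dataclass
class ValueState:
    """Learned quantities of one agent, all initialised to zero."""

    q_fractal: np.ndarray = field(default_factory=lambda: np.zeros(6))
    q_key: np.ndarray = field(default_factory=lambda: np.zeros(2))
    feat_weights: np.ndarray = field(default_factory=lambda: np.zeros(8))
    q_conj: np.ndarray = field(default_factory=lambda: np.zeros((6, 2)))
    last_s1_choice: str | None = None
    last_key: dict = field(default_factory=lambda: {1: None, 2: None})
    # mapping memory for the optional repetition/switch learning-rate variant
    last_s1_mapping: str | None = None
    last_s2_mapping: str | None = None


@dataclass
class ChoiceContext:
    """One binary choice: the two options in screen order."""

    stage: Literal[1, 2]
    state: str  # "s1" for the first stage, else "s2"/"s3"
    left: str  # fractal on the left
    right: str  # fractal on the right

    @property
    def options(self) -> tuple[str, str]:
        return (self.left, self.right)


def init_values(model_id: int) -> ValueState:
    """Fresh zero-initialised value containers for ``model_id``."""
    if model_id not in (1, 2, 3, 4, 5):
        raise ParameterError(f"unknown model_id {model_id}")
    return ValueState()


def _qmf_feature(values: ValueState, fractal: str, key: str) -> float:
    w = values.feat_weights
    return float(w[FRACTAL_CODE[fractal]] + w[6 + KEYS.index(key)])


def _stage_rates(params: AgentParams, trial: TrialRecord, values: ValueState):
    """Effective learning rate per stage, honouring the repetition/switch variant."""
    base = params.alpha2 if params.model_id == 2 else params.alpha1
    if params.alpha_rep is None:
        return base, base
    rep1 = values.last_s1_mapping == trial.s1_mapping
    rep2 = values.last_s2_mapping == trial.s2_mapping
    r1 = params.alpha_rep if rep1 else params.alpha_flip
    r2 = params.alpha_rep if rep2 else params.alpha_flip
    return r1, r2


def update_values(
    model_id: int, values: ValueState, trial: TrialRecord, params: AgentParams
) -> ValueState:
    """Apply one trial's end-of-trial updates in place (and return ``values``).

    All right-hand sides use the pre-trial values; when the same container
    entry receives credit from both stages (e.g. the same key pressed twice
    in Model 2) the two increments are computed from the old value and summed.
    """
    for arr in (values.q_fractal, values.q_key, values.feat_weights, values.q_conj):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite value state")
    f1, f2 = FRACTAL_CODE[trial.s1_choice], FRACTAL_CODE[trial.s2_choice]
    k1, k2 = KEYS.index(trial.s1_key), KEYS.index(trial.s2_key)
    r = float(trial.reward)
    a1s1, a1s2 = _stage_rates(params, trial, values)

    if model_id in (1, 2):
        q = values.q_fractal
        if model_id == 2:
            a1s1 = a1s2 = params.alpha1
        qf2 = float(q[f2])
        q[f1] += a1s1 * (qf2 - q[f1]) + a1s1 * params.lambda1 * (r - qf2)
        q[f2] += a1s2 * (r - qf2)
        if model_id == 2:
            a2s1, a2s2 = _stage_rates(params, trial, values)
            qk = values.q_key
            d1 = a2s1 * params.lambda2 * (r - float(qk[k1]))
            d2 = a2s2 * (1.0 - params.lambda2) * (r - float(qk[k2]))
            qk[k1] += d1
            qk[k2] += d2
    elif model_id == 3:
        w = values.feat_weights
        qmf1 = _qmf_feature(values, trial.s1_choice, trial.s1_key)
        qmf2 = _qmf_feature(values, trial.s2_choice, trial.s2_key)
        a2 = params.alpha2
        d11 = a2 * (qmf2 - qmf1) + a2 * params.lambda1 * (r - qmf2)
        d12 = a2 * (r - qmf2)
        w[f1] += d11
        w[6 + k1] += d11
        w[f2] += d12
        w[6 + k2] += d12
        q = values.q_fractal
        q[f2] += params.alpha1 * (r - q[f2])
    elif model_id in (4, 5):
        qc = values.q_conj
        a2 = params.alpha2
        q2 = float(qc[f2, k2])
        qc[f1, k1] += a2 * (q2 - qc[f1, k1]) + a2 * params.lambda1 * (r - q2)
        qc[f2, k2] += a2 * (r - q2)
        q = values.q_fractal
        q[f2] += params.alpha1 * (r - q[f2])
    else:
        raise ParameterError(f"unknown model_id {model_id}")

    values.last_s1_choice = trial.s1_choice
    values.last_key[1] = trial.s1_key
    values.last_key[2] = trial.s2_key
    values.last_s1_mapping = trial.s1_mapping
    values.last_s2_mapping = trial.s2_mapping
    return values


def _max_pair(values: np.ndarray, state: str) -> float:
    a, b = (FRACTAL_CODE[f] for f in STATE_FRACTALS[state])
    return float(max(values[a], values[b]))


def model_based_values(
    model_id: int,
    values: ValueState,
    params: AgentParams,
    s1_mapping: str | None = None,
    p_common: float = 0.7,
) -> dict[str, float]:
    """Model-based value of each first-stage fractal.

    Models 1-4 combine the 70/30 transition probabilities with the maximum
    second-stage fractal value of each state. Model 5 sums over the four
    mapping-specific states (0.35 per common mapping, 0.15 per rare one),
    maxing the conjunctive values available under each mapping.
    """
    out = {}
    if model_id == 5:
        qc = values.q_conj
        state_max = {}
        for state in ("s2", "s3"):
            fa, fb = (FRACTAL_CODE[f] for f in STATE_FRACTALS[state])
            # mapping 0: first fractal left; mapping 1: first fractal right
            state_max[state] = (
                max(float(qc[fa, 0]), float(qc[fb, 1])),
                max(float(qc[fa, 1]), float(qc[fb, 0])),
            )
        ph, pl = p_common / 2.0, (1.0 - p_common) / 2.0
        for f in FIRST_STAGE_FRACTALS:
            common = COMMON_STATE[f]
            rare = "s3" if common == "s2" else "s2"
            out[f] = ph * sum(state_max[common]) + pl * sum(state_max[rare])
        return out
    q = values.q_fractal
    for f in FIRST_STAGE_FRACTALS:
        common = COMMON_STATE[f]
        rare = "s3" if common == "s2" else "s2"
        out[f] = p_common * _max_pair(q, common) + (1 - p_common) * _max_pair(q, rare)
    return out


def net_values(
    model_id: int, values: ValueState, params: AgentParams, ctx: ChoiceContext
) -> tuple[float, float]:
    """Integrated (net) value of the left and right options in ``ctx``."""
    out = []
    if ctx.stage == 1:
        qmb = model_based_values(model_id, values, params)
        for fractal, key in ((ctx.left, "left"), (ctx.right, "right")):
            f = FRACTAL_CODE[fractal]
            if model_id in (1, 2):
                v = params.w1 * qmb[fractal] + (1 - params.w1) * float(values.q_fractal[f])
                if model_id == 2:
                    v += params.w2 * float(values.q_key[KEYS.index(key)])
            elif model_id == 3:
                v = params.w1 * qmb[fractal] + (1 - params.w1) * _qmf_feature(values, fractal, key)
            else:
                v = params.w1 * qmb[fractal] + (1 - params.w1) * float(
                    values.q_conj[f, KEYS.index(key)]
                )
            out.append(v)
    else:
        for fractal, key in ((ctx.left, "left"), (ctx.right, "right")):
            f, k = FRACTAL_CODE[fractal], KEYS.index(key)
            qf = float(values.q_fractal[f])
            if model_id == 1:
                v = qf
            elif model_id == 2:
                v = qf + params.w2 * float(values.q_key[k])
            elif model_id == 3:
                v = params.w1 * qf + (1 - params.w1) * _qmf_feature(values, fractal, key)
            elif model_id == 4:
                v = params.w1 * qf + (1 - params.w1) * float(values.q_conj[f, k])
            else:  # Model 5: the two systems coincide at the second stage
                v = float(values.q_conj[f, k])
            out.append(v)
    return out[0], out[1]


def choice_probability(
    net: tuple[float, float],
    params: AgentParams,
    ctx: ChoiceContext,
    history: ValueState,
) -> float:
    """Probability of choosing the right-hand option.

    Logistic in ``beta * (V_right - V_left)`` plus signed perseveration and
    key-bias terms; strictly inside (0, 1) for finite inputs.
    """
    if params.beta < 0:
        raise ParameterError("beta must be nonnegative")
    vl, vr = net
    z = params.beta * (vr - vl) + params.key_bias
    if ctx.stage == 1 and history.last_s1_choice is not None:
        z += params.persev_fractal * (
            (1.0 if ctx.right == history.last_s1_choice else 0.0)
            - (1.0 if ctx.left == history.last_s1_choice else 0.0)
        )
    prev_key = history.last_key.get(ctx.stage)
    if prev_key is not None:
        z += params.persev_key if prev_key == "right" else -params.persev_key
    return float(expit(z))


def _trial_contexts(trial: TrialRecord) -> tuple[ChoiceContext, ChoiceContext]:
    s1_left = trial.s1_mapping.split("-")[0]
    s1_right = "B" if s1_left == "A" else "A"
    pair = STATE_FRACTALS[trial.s2_state]
    s2_left = trial.s2_mapping.split("-")[0]
    s2_right = pair[1] if s2_left == pair[0] else pair[0]
    return (
        ChoiceContext(1, "s1", s1_left, s1_right),
        ChoiceContext(2, trial.s2_state, s2_left, s2_right),
    )


def _loglik_reference(model_id: int, params: AgentParams, records) -> np.ndarray:
    """Slow likelihood composed from the single-trial operations."""
    values = init_values(model_id)
    out = np.empty(len(records))
    for i, trial in enumerate(records):
        ctx1, ctx2 = _trial_contexts(trial)
        p1 = choice_probability(net_values(model_id, values, params, ctx1), params, ctx1, values)
        obs1 = p1 if trial.s1_key == "right" else 1 - p1
        p2 = choice_probability(net_values(model_id, values, params, ctx2), params, ctx2, values)
        obs2 = p2 if trial.s2_key == "right" else 1 - p2
        out[i] = np.log(obs1) + np.log(obs2)
        update_values(model_id, values, trial, params)
    return out


def loglikelihood(
    model_id: int,
    params: AgentParams,
    records: Sequence[TrialRecord],
    engine: Literal["fast", "reference"] = "fast",
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of observed choices (both stages).

    Records must be one subject's trials in order. The ``reference`` engine
    recomputes the same quantity through the single-trial API and exists for
    cross-checking.
    """
    if engine == "reference":
        per_trial = _loglik_reference(model_id, params, records)
    else:
        data = records if isinstance(records, _engine.EncodedSession) else _engine.encode_session(records)
        per_trial = np.asarray(loglik_from_encoded(model_id, params, data))
    total = float(per_trial.sum())
    if not np.isfinite(total):
        bad = int(np.flatnonzero(~np.isfinite(per_trial))[0])
        raise FloatingPointError(f"non-finite log-likelihood at trial {bad}")
    return total, per_trial


def loglik_from_encoded(model_id, params: AgentParams, data, p_common: float = 0.7):
    return _engine.loglik_encoded(model_id, params.as_dict(), data, p_common)


def _records_from_arrays(arrays: dict, subject_id: str, trial_offset: int = 0):
    from .task import SECOND_STAGE_FRACTALS, STATES

    f_names = FIRST_STAGE_FRACTALS + SECOND_STAGE_FRACTALS
    recs = []
    n = len(arrays["f1"])
    for t in range(n):
        f1 = int(arrays["f1"][t]); k1 = int(arrays["k1"][t])
        s1l = int(arrays["s1_left"][t]); st = int(arrays["state"][t])
        f2 = int(arrays["f2"][t]); k2 = int(arrays["k2"][t])
        s2l = int(arrays["s2_left"][t]); r = int(arrays["r"][t])
        recs.append(
            TrialRecord(
                subject_id=subject_id,
                trial=trial_offset + t,
                s1_choice=f_names[f1],
                s1_mapping=f"{f_names[s1l]}-left",
                s1_key=KEYS[k1],
                transition="common" if int(arrays["common"][t]) else "rare",
                s2_state=STATES[st],
                s2_choice=f_names[f2],
                s2_mapping=f"{f_names[s2l]}-left",
                s2_key=KEYS[k2],
                reward=r,
            )
        )
    return recs


def simulate_agent(
    model_id: int,
    params: AgentParams,
    config: TaskConfig,
    schedule: RewardSchedule,
    seed: int,
    subject_id: str = "sim",
) -> list[TrialRecord]:
    """Forward-simulate one agent for ``schedule.n_trials`` trials.

    Mappings are drawn independently per stage and trial (p=0.5 per side),
    transitions with ``config.p_common``, choices from the model's choice
    probabilities, rewards as Bernoulli draws from the schedule. Output is
    bit-reproducible given the seed and passes :func:`validate_trials`.
    """
    if model_id in (1, 2):
        arrays = _engine.simulate_encoded(
            model_id, params.as_dict(), schedule.probs, seed, config.p_common
        )
        return _records_from_arrays(arrays, subject_id)
    return _simulate_reference(model_id, params, config, schedule, seed, subject_id)


def _simulate_reference(model_id, params, config, schedule, seed, subject_id):
    from .task import SECOND_STAGE_FRACTALS, STATES, sample_transition

    rng = np.random.default_rng(seed)
    values = init_values(model_id)
    recs: list[TrialRecord] = []
    for t in range(schedule.n_trials):
        s1_left = "A" if rng.random() < 0.5 else "B"
        s1_right = "B" if s1_left == "A" else "A"
        ctx1 = ChoiceContext(1, "s1", s1_left, s1_right)
        p_right = choice_probability(net_values(model_id, values, params, ctx1), params, ctx1, values)
        k1 = "right" if rng.random() < p_right else "left"
        f1 = s1_right if k1 == "right" else s1_left
        state = sample_transition(f1, config, rng.random())
        transition = "common" if COMMON_STATE[f1] == state else "rare"
        pair = STATE_FRACTALS[state]
        s2_left = pair[0] if rng.random() < 0.5 else pair[1]
        s2_right = pair[1] if s2_left == pair[0] else pair[0]
        ctx2 = ChoiceContext(2, state, s2_left, s2_right)
        p_right = choice_probability(net_values(model_id, values, params, ctx2), params, ctx2, values)
        k2 = "right" if rng.random() < p_right else "left"
        f2 = s2_right if k2 == "right" else s2_left
        p_rew = schedule.probs[t, SECOND_STAGE_FRACTALS.index(f2)]
        r = int(rng.random() < p_rew)
        trial = TrialRecord(
            subject_id=subject_id, trial=t, s1_choice=f1,
            s1_mapping=f"{s1_left}-left", s1_key=k1, transition=transition,
            s2_state=state, s2_choice=f2, s2_mapping=f"{s2_left}-left",
            s2_key=k2, reward=r,
        )
        recs.append(trial)
        update_values(model_id, values, trial, params)
    return recs
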