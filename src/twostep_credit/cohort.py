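"""Synthetic cohorts: heterogeneous simulated subjects with ground truth.

The population distribution is Gaussian in the unconstrained parameter
space used by the hierarchical fitter (logit scale for rates/traces/``w1``,
log scale for ``beta``, identity for biases and ``w2``), so that
parameter-recovery studies are internally consistent with the fitting
prior. Each subject gets a fresh reward schedule and an independent
simulation seed, all derived from the cohort seed.

Default group-level moments are desk-scale stand-ins for a typical adult
two-step cohort: mid-range learning rates and traces, an inverse
temperature around 4, mild perseveration, and a key-value weight ``w2``
around 0.3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .agents import AgentParams, simulate_agent
from .task import TaskConfig, TrialRecord, make_reward_schedule, write_trials
from .transforms import PARAM_SPECS, from_unconstrained, param_names

__all__ = ["PopulationSpec", "default_population", "sample_population", "generate_cohort"]

#: default unconstrained-space group means per parameter
_DEFAULT_MEANS = {
    "alpha1": -0.2,  # learning rate ~0.45
    "lambda1": 0.4,  # eligibility trace ~0.6
    "alpha2": -0.2,
    "lambda2": 0.0,  # even credit split across stages
    "w1": 0.0,  # model-based weight ~0.5
    "w2": 0.3,
    "beta": 1.4,  # inverse temperature ~4
    "persev_fractal": 0.2,
    "persev_key": 0.1,
    "key_bias": 0.0,
}
#: default unconstrained-space group standard deviations
_DEFAULT_SDS = {
    "alpha1": 0.7,
    "lambda1": 0.7,
    "alpha2": 0.7,
    "lambda2": 0.7,
    "w1": 0.7,
    "w2": 0.15,
    "beta": 0.35,
    "persev_fractal": 0.25,
    "persev_key": 0.2,
    "key_bias": 0.15,
}


@dataclass
class PopulationSpec:
    """Group-level distribution of one model's parameters.

    ``means``/``sds`` are in the unconstrained space (one entry per free
    parameter of ``model_id``).
    """

    model_id: int
    means: dict[str, float]
    sds: dict[str, float]
    n_subjects: int = 100
    n_trials: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        names = set(param_names(self.model_id))
        if set(self.means) != names or set(self.sds) != names:
            raise ValueError(f"means/sds must cover exactly {sorted(names)}")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("population sds must be nonnegative")
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be positive")


def default_population(
    model_id: int,
    n_subjects: int = 100,
    n_trials: int = 300,
    seed: int = 0,
    mean_overrides: dict[str, float] | None = None,
    sd_overrides: dict[str, float] | None = None,
) -> PopulationSpec:
    """Desk-scale default population for ``model_id`` with optional overrides."""
    names = param_names(model_id)
    means = {k: _DEFAULT_MEANS[k] for k in names}
    sds = {k: _DEFAULT_SDS[k] for k in names}
    means.update(mean_overrides or {})
    sds.update(sd_overrides or {})
    return PopulationSpec(model_id, means, sds, n_subjects, n_trials, seed)


def study_scale_population(model_id: int, session: int = 1, seed: int = 0) -> PopulationSpec:
    """Cohort preset at the sample sizes of the three study sessions."""
    n = {1: 769, 2: 63, 3: 568}[session]
    return default_population(model_id, n_subjects=n, n_trials=200, seed=seed)


def sample_population(spec: PopulationSpec, rng: np.random.Generator | None = None) -> list[AgentParams]:
    """Draw ``n_subjects`` parameter sets from the group distribution."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    names = param_names(spec.model_id)
    mu = np.array([spec.means[k] for k in names])
    sd = np.array([spec.sds[k] for k in names])
    draws = mu + sd * rng.standard_normal((spec.n_subjects, len(names)))
    return [
        AgentParams(model_id=spec.model_id, **from_unconstrained(spec.model_id, x))
        for x in draws
    ]


def generate_cohort(
    spec: PopulationSpec,
    config: TaskConfig,
    trials_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[TrialRecord], dict]:
    """Simulate one cohort: per-subject fresh reward schedule and session.

    Returns the trial records of all subjects plus a ground-truth mapping
    ``{subject_id: {param: value, ..., "seed": int}}``; optionally writes a
    trial CSV and truth JSON. Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    param_seed, *rest = ss.spawn(1 + 2 * spec.n_subjects)
    params = sample_population(spec, np.random.default_rng(param_seed))
    config = TaskConfig(
        p_common=config.p_common,
        n_trials=spec.n_trials,
        reward_walk_sd=config.reward_walk_sd,
        reward_walk_bounds=config.reward_walk_bounds,
        reward_init=config.reward_init,
        seed=config.seed,
    )
    width = max(3, len(str(spec.n_subjects)))
    records: list[TrialRecord] = []
    truth: dict[str, dict] = {}
    for i, p in enumerate(params):
        sid = f"S{i + 1:0{width}d}"
        sched_seed, sim_seed = rest[2 * i], rest[2 * i + 1]
        schedule = make_reward_schedule(config, sched_seed)
        sim_seed_int = int(sim_seed.generate_state(1)[0] % (2**31))
        records.extend(simulate_agent(spec.model_id, p, config, schedule, sim_seed_int, sid))
        truth[sid] = {**p.as_dict(), "model_id": spec.model_id, "seed": sim_seed_int}
    if trials_path is not None:
        write_trials(records, trials_path)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=1))
    return records, truth
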