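"""Two-step task structure, trial records, reward dynamics and trial I/O.

The task has a first stage with two fractal options (``A``, ``B``) and two
second-stage states (``s2`` holding fractals ``C``/``D``, ``s3`` holding
``E``/``F``). A first-stage choice leads to its "common" state with
probability ``p_common`` (0.7 by default) and to the other state otherwise;
``A`` is commonly followed by ``s2`` and ``B`` by ``s3``. On every trial and
stage the two available fractals are independently assigned to the left and
right of the screen, so the same fractal may be selected with either response
key. Second-stage fractals pay a binary reward (0/1) with probabilities that
drift across trials as independent Gaussian random walks reflected at fixed
bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "RewardSchedule",
    "ConfigurationError",
    "SchemaError",
    "FIRST_STAGE_FRACTALS",
    "SECOND_STAGE_FRACTALS",
    "STATES",
    "STATE_FRACTALS",
    "COMMON_STATE",
    "KEYS",
    "key_for",
    "make_reward_schedule",
    "sample_transition",
    "validate_trials",
    "read_trials",
    "write_trials",
    "records_to_frame",
    "frame_to_records",
]

FIRST_STAGE_FRACTALS = ("A", "B")
SECOND_STAGE_FRACTALS = ("C", "D", "E", "F")
STATES = ("s2", "s3")
#: fractal pair offered in each second-stage state
STATE_FRACTALS = {"s2": ("C", "D"), "s3": ("E", "F")}
#: fixed action->state structure: the state each first-stage fractal commonly leads to
COMMON_STATE = {"A": "s2", "B": "s3"}
KEYS = ("left", "right")

#: fractal label -> integer code used by the numeric engine
FRACTAL_CODE = {f: i for i, f in enumerate(FIRST_STAGE_FRACTALS + SECOND_STAGE_FRACTALS)}

TRIAL_COLUMNS = [
    "subject_id",
    "trial",
    "s1_choice",
    "s1_mapping",
    "s1_key",
    "transition",
    "s2_state",
    "s2_choice",
    "s2_mapping",
    "s2_key",
    "reward",
]


class ConfigurationError(ValueError):
    """Invalid task configuration."""


class SchemaError(ValueError):
    """Trial table does not match the documented schema."""


@dataclass
class TaskConfig:
    """Parameters of the two-step task environment.

    Parameters
    ----------
    p_common
        Probability that a first-stage choice leads to its common
        second-stage state. Must lie in (0.5, 1].
    n_trials
        Number of trials per session.
    reward_walk_sd
        Standard deviation of the per-trial Gaussian increment of each
        fractal's reward probability.
    reward_walk_bounds
        ``(lo, hi)`` reflecting bounds of the reward-probability walks.
    reward_init
        Initial reward probabilities for fractals C, D, E, F. ``None`` means
        draw them uniformly within the bounds when a schedule is built.
    seed
        Default seed for schedule construction.
    """

    p_common: float = 0.7
    n_trials: int = 300
    reward_walk_sd: float = 0.025
    reward_walk_bounds: tuple[float, float] = (0.25, 0.75)
    reward_init: tuple[float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.reward_walk_bounds
        if not 0.5 < self.p_common <= 1.0:
            raise ConfigurationError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.reward_walk_sd < 0:
            raise ConfigurationError("reward_walk_sd must be nonnegative")
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(f"invalid reward bounds {self.reward_walk_bounds}")
        if self.reward_init is not None:
            if len(self.reward_init) != 4:
                raise ConfigurationError("reward_init needs one value per second-stage fractal")
            if not all(lo <= p <= hi for p in self.reward_init):
                raise ConfigurationError("reward_init values must lie within the walk bounds")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["reward_walk_bounds"] = list(self.reward_walk_bounds)
        if self.reward_init is not None:
            d["reward_init"] = list(self.reward_init)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["reward_walk_bounds"] = tuple(d["reward_walk_bounds"])
        if d.get("reward_init") is not None:
            d["reward_init"] = tuple(d["reward_init"])
        return cls(**d)


@dataclass
class TrialRecord:
    """One complete two-step trial."""

    subject_id: str
    trial: int
    s1_choice: str  # "A" or "B"
    s1_mapping: str  # "A-left" or "B-left": which fractal sat on the left
    s1_key: str  # "left" or "right"
    transition: str  # "common" or "rare"
    s2_state: str  # "s2" or "s3"
    s2_choice: str  # "C".."F", member of s2_state's pair
    s2_mapping: str  # e.g. "C-left": which second-stage fractal sat on the left
    s2_key: str
    reward: int  # 0 or 1


@dataclass
class RewardSchedule:
    """Reward probabilities per trial (rows) and second-stage fractal (columns C, D, E, F)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ConfigurationError("schedule must be (n_trials, 4)")

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]


def key_for(choice: str, mapping: str) -> str:
    """Response key that selects ``choice`` under ``mapping`` ("X-left")."""
    left_fractal = mapping.split("-")[0]
    return "left" if choice == left_fractal else "right"


def make_reward_schedule(config: TaskConfig, rng_seed: int | None = None) -> RewardSchedule:
    """Build drifting reward probabilities for the four second-stage fractals.

    Independent Gaussian random walks (sd ``reward_walk_sd``) reflected at
    ``reward_walk_bounds``. Row 0 equals ``reward_init`` (drawn uniformly in
    the bounds when unset); deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    lo, hi = config.reward_walk_bounds
    if config.reward_init is None:
        p = rng.uniform(lo, hi, size=4)
    else:
        p = np.asarray(config.reward_init, dtype=float)
    out = np.empty((config.n_trials, 4))
    out[0] = p
    steps = rng.normal(0.0, config.reward_walk_sd, size=(config.n_trials - 1, 4))
    for t in range(1, config.n_trials):
        p = _reflect(out[t - 1] + steps[t - 1], lo, hi)
        out[t] = p
    return RewardSchedule(out)


def _reflect(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    p = np.asarray(p, dtype=float).copy()
    # repeated reflection handles steps larger than the band width
    for _ in range(64):
        below, above = p < lo, p > hi
        if not (below.any() or above.any()):
            break
        p[below] = 2 * lo - p[below]
        p[above] = 2 * hi - p[above]
    return np.clip(p, lo, hi)


def sample_transition(s1_choice: str, config: TaskConfig, u: float) -> str:
    """Second-stage state reached from ``s1_choice`` given uniform deviate ``u``.

    Returns the choice's common state iff ``u < p_common``.
    """
    if s1_choice not in COMMON_STATE:
        raise ValueError(f"unknown first-stage fractal {s1_choice!r}")
    common = COMMON_STATE[s1_choice]
    rare = "s3" if common == "s2" else "s2"
    return common if u < config.p_common else rare


def validate_trials(
    records: Sequence[TrialRecord], config: TaskConfig | None = None
) -> list[dict]:
    """Check every record against the task's structural invariants.

    Returns a list of violations, each ``{"row": i, "field": ..., "message": ...}``;
    an empty list means the data are internally consistent.
    """
    report: list[dict] = []

    def flag(i: int, fieldname: str, message: str) -> None:
        report.append({"row": i, "field": fieldname, "message": message})

    last_trial: dict[str, int] = {}
    for i, r in enumerate(records):
        if r.s1_choice not in FIRST_STAGE_FRACTALS:
            flag(i, "s1_choice", f"unknown fractal {r.s1_choice!r}")
            continue
        if r.s2_state not in STATES:
            flag(i, "s2_state", f"unknown state {r.s2_state!r}")
            continue
        pair = STATE_FRACTALS[r.s2_state]
        if r.s2_choice not in pair:
            flag(i, "s2_choice", f"{r.s2_choice!r} not offered in {r.s2_state}")
        if r.s1_mapping not in ("A-left", "B-left"):
            flag(i, "s1_mapping", f"bad mapping {r.s1_mapping!r}")
        elif key_for(r.s1_choice, r.s1_mapping) != r.s1_key:
            flag(i, "s1_key", "key inconsistent with choice and mapping")
        valid_s2_maps = tuple(f"{f}-left" for f in pair)
        if r.s2_mapping not in valid_s2_maps:
            flag(i, "s2_mapping", f"bad mapping {r.s2_mapping!r} for {r.s2_state}")
        elif r.s2_choice in pair and key_for(r.s2_choice, r.s2_mapping) != r.s2_key:
            flag(i, "s2_key", "key inconsistent with choice and mapping")
        expected_state = (
            COMMON_STATE[r.s1_choice]
            if r.transition == "common"
            else ("s3" if COMMON_STATE[r.s1_choice] == "s2" else "s2")
        )
        if r.transition not in ("common", "rare"):
            flag(i, "transition", f"bad transition {r.transition!r}")
        elif expected_state != r.s2_state:
            flag(i, "s2_state", "state inconsistent with choice and transition label")
        if r.reward not in (0, 1):
            flag(i, "reward", f"reward must be 0/1, got {r.reward!r}")
        prev = last_trial.get(r.subject_id)
        if prev is not None and r.trial <= prev:
            flag(i, "trial", "trial index not strictly increasing within subject")
        last_trial[r.subject_id] = r.trial
    return report


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=TRIAL_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown columns: {', '.join(extra)}", stacklevel=2)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                TrialRecord(
                    subject_id=str(getattr(row, "subject_id")),
                    trial=int(getattr(row, "trial")),
                    s1_choice=str(getattr(row, "s1_choice")),
                    s1_mapping=str(getattr(row, "s1_mapping")),
                    s1_key=str(getattr(row, "s1_key")),
                    transition=str(getattr(row, "transition")),
                    s2_state=str(getattr(row, "s2_state")),
                    s2_choice=str(getattr(row, "s2_choice")),
                    s2_mapping=str(getattr(row, "s2_mapping")),
                    s2_key=str(getattr(row, "s2_key")),
                    reward=int(getattr(row, "reward")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"unparseable row {i}: {exc}") from exc
    return out


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read trial records from the documented CSV schema.

    Unknown extra columns are ignored with a warning; missing required
    columns raise :class:`SchemaError` naming them.
    """
    df = pd.read_csv(path)
    return frame_to_records(df)


def write_trials(records: Sequence[TrialRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
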