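"""Posterior-predictive checks and model-based/spatial-motor associations.

Simulates sessions from each subject's fitted (MAP) parameters, recomputes
the three sequential effects on the simulated data, and correlates the
simulated with the empirical per-subject effects. Also provides the classic
first-stage outcome x transition stay interaction (the model-based
signature) and a correlation summary between model-based indicators
(``w1``, the outcome x transition interaction) and spatial-motor indicators
(``w2`` and the three sequential effects).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .sequential import (
    _group_stats,
    between_stage_effect,
    between_state_effect,
    pairs_frame,
    within_state_effect,
)
from .task import TaskConfig, make_reward_schedule, records_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "PPCResult",
    "simulate_from_fit",
    "ppc_compare",
    "empirical_effects",
    "outcome_transition_interaction",
    "mb_mf_association",
]

EFFECT_NAMES = ("within_state", "between_state", "between_stage")


def _session_effects(a: dict) -> dict:
    """Sequential effect scores of one encoded session (numpy, no pandas)."""
    f2, k1, k2, st = a["f2"], a["k1"], a["k2"], a["state"]
    s2l, r = a["s2_left"], a["r"]
    rew = r[:-1] == 1
    within = st[1:] == st[:-1]
    stay_f = f2[1:] == f2[:-1]
    key_next_of_chosen = (f2[:-1] != s2l[1:]).astype(int)  # key selecting n's fractal at n+1
    same = key_next_of_chosen == k2[:-1]
    out = {}

    def cell(mask):
        return float(stay_f[mask].mean()) if mask.any() else np.nan

    rs, us = cell(within & same & rew), cell(within & same & ~rew)
    rf, uf = cell(within & ~same & rew), cell(within & ~same & ~rew)
    out["reward_effect_same"] = rs - us
    out["reward_effect_flipped"] = rf - uf
    out["within_state"] = (rs - us) - (rf - uf)
    stay_k = k2[1:] == k2[:-1]
    bs = ~within
    out["between_state"] = (
        (float(stay_k[bs & rew].mean()) if (bs & rew).any() else np.nan)
        - (float(stay_k[bs & ~rew].mean()) if (bs & ~rew).any() else np.nan)
    )
    stay_x = k1[1:] == k2[:-1]
    out["between_stage"] = (
        (float(stay_x[rew].mean()) if rew.any() else np.nan)
        - (float(stay_x[~rew].mean()) if (~rew).any() else np.nan)
    )
    return out


def simulate_from_fit(
    groupfit,
    config: TaskConfig | None = None,
    n_reps: int = 20,
    n_trials: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n_reps`` sessions of ``n_trials`` per fitted subject.

    Each replicate uses that subject's MAP parameters against a fresh
    drifting reward schedule. Returns the per-subject simulated effect
    scores (mean over replicates) for the three sequential analyses; the
    raw encoded replicates are attached as ``df.attrs["sessions"]``.
    """
    from .agents import AgentParams, simulate_agent
    from .task import RewardSchedule

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = config or TaskConfig()
    cfg = TaskConfig(
        p_common=base.p_common,
        n_trials=n_trials,
        reward_walk_sd=base.reward_walk_sd,
        reward_walk_bounds=base.reward_walk_bounds,
        reward_init=base.reward_init,
        seed=base.seed,
    )
    rows = []
    sessions: dict[str, list[dict]] = {}
    for si, sf in enumerate(groupfit.subject_fits):
        reps = []
        per_rep: list[dict] = []
        subj_ss = np.random.SeedSequence([seed, si])
        children = subj_ss.spawn(2 * n_reps)
        for rep in range(n_reps):
            sched = make_reward_schedule(cfg, children[2 * rep])
            sim_seed = int(children[2 * rep + 1].generate_state(1)[0] % (2**31))
            if groupfit.model_id in (1, 2):
                arrays = _engine.simulate_encoded(
                    groupfit.model_id, sf.params, sched.probs, sim_seed, cfg.p_common
                )
            else:
                params = AgentParams(model_id=groupfit.model_id, **sf.params)
                recs = simulate_agent(
                    groupfit.model_id, params, cfg, RewardSchedule(sched.probs), sim_seed, sf.subject_id
                )
                arrays = _records_arrays(recs)
            reps.append(arrays)
            per_rep.append(_session_effects(arrays))
        sessions[sf.subject_id] = reps
        agg = {k: float(np.nanmean([e[k] for e in per_rep])) for k in per_rep[0]}
        rows.append({"subject_id": sf.subject_id, **agg})
    df = pd.DataFrame(rows).set_index("subject_id")
    df.attrs["sessions"] = sessions
    df.attrs["n_reps"] = n_reps
    df.attrs["n_trials"] = n_trials
    return df


def _records_arrays(recs) -> dict:
    enc = _engine.encode_session(recs)
    return {
        "f1": np.array(enc.f1), "k1": np.array(enc.k1), "s1_left": np.array(enc.s1_left),
        "state": np.array(enc.state), "f2": np.array(enc.f2), "k2": np.array(enc.k2),
        "s2_left": np.array(enc.s2_left), "r": np.array(enc.r),
    }


def empirical_effects(records) -> pd.DataFrame:
    """Per-subject empirical effect scores for the three sequential analyses."""
    pf = pairs_frame(records, lag=1)
    within = within_state_effect(pf).per_subject
    between = between_state_effect(pf).per_subject
    stages = between_stage_effect(pf).per_subject
    return pd.DataFrame(
        {
            "within_state": within["effect"],
            "reward_effect_same": within["reward_effect_same"],
            "reward_effect_flipped": within["reward_effect_flipped"],
            "between_state": between["effect"],
            "between_stage": stages["effect"],
        }
    )


@dataclass
class PPCResult:
    """Model-data correspondence for the three sequential analyses."""

    correlations: dict  # analysis -> {r, ci_low, ci_high, n}
    per_subject: pd.DataFrame  # simulated and empirical scores, matched ids
    group: dict  # analysis -> {simulated, empirical, difference}
    n_reps: int
    n_trials: int

    def summary(self) -> str:
        lines = [f"Posterior-predictive check ({self.n_reps} reps x {self.n_trials} trials)"]
        for name in EFFECT_NAMES:
            c = self.correlations[name]
            g = self.group[name]
            if np.isnan(c["r"]):
                lines.append(f"  {name}: correlation undefined (n = {c['n']})")
                continue
            lines.append(
                f"  {name}: r = {c['r']:.3f} (95% CI [{c['ci_low']:.3f}, {c['ci_high']:.3f}], "
                f"n = {c['n']}); group effect simulated {g['simulated']:+.4f} "
                f"vs empirical {g['empirical']:+.4f}"
            )
        return "\n".join(lines)


def _boot_ci(x: np.ndarray, y: np.ndarray, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(x)
    rs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        xs, ys = x[idx], y[idx]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        rs.append(np.corrcoef(xs, ys)[0, 1])
    if not rs:
        return (np.nan, np.nan)
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def ppc_compare(
    simulated: pd.DataFrame,
    empirical: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> PPCResult:
    """Correlate simulated with empirical per-subject effect scores.

    Pearson r per analysis with a bootstrap CI over subjects; fewer than 3
    matched subjects yields an undefined (NaN) correlation.
    """
    joined = simulated.join(empirical, how="inner", lsuffix="_sim", rsuffix="_emp")
    correlations, group = {}, {}
    for name in EFFECT_NAMES:
        xs = joined[f"{name}_sim"].to_numpy(float)
        ys = joined[f"{name}_emp"].to_numpy(float)
        ok = np.isfinite(xs) & np.isfinite(ys)
        x, y = xs[ok], ys[ok]
        if len(x) < 3:
            logger.warning("%s: only %d matched subjects; correlation undefined", name, len(x))
            correlations[name] = {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": len(x)}
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            lo, hi = _boot_ci(x, y, n_boot=n_boot, seed=seed)
            correlations[name] = {"r": r, "ci_low": lo, "ci_high": hi, "n": len(x)}
        group[name] = {
            "simulated": float(np.nanmean(xs)),
            "empirical": float(np.nanmean(ys)),
            "difference": float(np.nanmean(xs) - np.nanmean(ys)),
        }
    return PPCResult(
        correlations=correlations,
        per_subject=joined,
        group=group,
        n_reps=simulated.attrs.get("n_reps", 0),
        n_trials=simulated.attrs.get("n_trials", 0),
    )


def outcome_transition_interaction(records) -> tuple[pd.DataFrame, dict]:
    """First-stage stay probability: outcome x transition interaction.

    The classic model-based signature: per subject, ``(stay|rew,common -
    stay|rew,rare) - (stay|unrew,common - stay|unrew,rare)`` for first-stage
    fractal repetition on consecutive trials.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.sort_values(["subject_id", "trial"], kind="stable")
    nxt = df.groupby("subject_id", sort=False).shift(-1)
    ok = nxt["trial"].notna() & (nxt["trial"] - df["trial"] == 1)
    cur, nxt = df[ok], nxt[ok]
    tbl = pd.DataFrame(
        {
            "subject_id": cur["subject_id"].to_numpy(),
            "stay": (nxt["s1_choice"].to_numpy() == cur["s1_choice"].to_numpy()).astype(float),
            "rewarded": (cur["reward"].to_numpy() == 1),
            "common": (cur["transition"].to_numpy() == "common"),
        }
    )
    cells = tbl.groupby(["subject_id", "rewarded", "common"])["stay"].mean().unstack(["rewarded", "common"])
    needed = [(True, True), (True, False), (False, True), (False, False)]
    cells = cells.reindex(columns=needed).dropna()
    inter = (cells[(True, True)] - cells[(True, False)]) - (
        cells[(False, True)] - cells[(False, False)]
    )
    per_subject = pd.DataFrame({"ot_interaction": inter})
    return per_subject, _group_stats(inter.to_numpy())


@dataclass
class AssociationResult:
    """Correlations between model-based and spatial-motor indicators."""

    r: pd.DataFrame  # cross-correlation matrix (MB rows x SM columns)
    ci: dict  # (row, col) -> (lo, hi), Fisher-z 95% intervals
    n: int

    def summary(self) -> str:
        lines = ["Model-based vs spatial-motor indicator correlations " f"(n = {self.n}):"]
        lines.append(self.r.to_string(float_format=lambda v: f"{v: .3f}"))
        return "\n".join(lines)


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n < 4 or not np.isfinite(r) or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se))


def mb_mf_association(groupfit, records) -> AssociationResult:
    """Correlate model-based indicators with spatial-motor indicators.

    Model-based block: the fitted ``w1`` and the first-stage outcome x
    transition interaction. Spatial-motor block: the fitted ``w2`` (when the
    fitted model has one) and the three sequential effects. All entries are
    plain Pearson correlations across subjects with Fisher-z CIs.
    """
    subj = groupfit.subject_table()
    emp = empirical_effects(records)
    ot, _ = outcome_transition_interaction(records)
    mb = pd.DataFrame({"w1": subj["w1"]}).join(ot, how="inner")
    sm_cols = {name: emp[name] for name in EFFECT_NAMES}
    if "w2" in subj.columns:
        sm_cols = {"w2": subj["w2"], **sm_cols}
    sm = pd.DataFrame(sm_cols)
    joined = mb.join(sm, how="inner").dropna()
    n = len(joined)
    r = pd.DataFrame(index=mb.columns, columns=sm.columns, dtype=float)
    ci = {}
    for a in mb.columns:
        for b in sm.columns:
            if n < 3 or joined[a].std() == 0 or joined[b].std() == 0:
                val = np.nan
            else:
                val = float(np.corrcoef(joined[a], joined[b])[0, 1])
            r.loc[a, b] = val
            ci[(a, b)] = _fisher_ci(val, n)
    if n < 3:
        logger.warning("mb_mf_association: %d subject(s); correlations undefined", n)
    return AssociationResult(r=r, ci=ci, n=n)
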