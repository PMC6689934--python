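"""Model-agnostic consecutive-trial (stay-probability) analyses.

Three analyses diagnose credit assignment to the outcome-irrelevant
response key from raw choice sequences:

* **within-state** — among trial pairs offering the same second-stage
  fractal pair, the effect of reward on *fractal* stay probability, split by
  whether the chosen fractal kept its key side (``same``) or switched it
  (``flipped``). Key-value learning predicts a positive outcome x mapping
  interaction.
* **between-states** — among pairs offering different fractal pairs, the
  effect of reward on repeating the second-stage *response key*.
* **between-stages** — over all consecutive pairs, the effect of reward at
  the second stage of trial *n* on repeating that key at the *first* stage
  of trial *n+1*.

Per-subject cell probabilities and difference scores are always computed;
group inference uses a one-sample t test on the per-subject scores, with a
mixed-effects logistic regression (random intercepts per subject) available
as an alternative route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import TrialRecord, key_for, records_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "TrialPair",
    "EffectResult",
    "classify_pairs",
    "pairs_frame",
    "within_state_effect",
    "between_state_effect",
    "between_stage_effect",
]


@dataclass
class TrialPair:
    """One consecutive (n, n+lag) trial pair within a subject."""

    subject_id: str
    trial: int  # trial index of trial n
    category: str  # "within_state" or "between_state"
    outcome: str  # "rewarded"/"unrewarded" at trial n
    mapping: str | None  # "same"/"flipped" (within_state only)
    stay_fractal: int | None  # within_state only
    stay_key_s2: int  # second-stage key repeated at n+lag
    stay_key_s2_to_s1: int  # second-stage key at n repeated at first stage of n+lag
    lag: int = 1


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def pairs_frame(records, lag: int = 1) -> pd.DataFrame:
    """Vectorised trial-pair table; one row per valid (n, n+lag) pair.

    Pairs must be ``lag`` apart in trial index within the same subject, so
    gaps (e.g. session breaks or dropped trials) never form pairs.
    """
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    df = _as_frame(records).sort_values(["subject_id", "trial"], kind="stable")
    nxt = df.groupby("subject_id", sort=False).shift(-lag)
    ok = nxt["trial"].notna() & (nxt["trial"] - df["trial"] == lag)
    cur, nxt = df[ok], nxt[ok]
    within = (nxt["s2_state"] == cur["s2_state"]).to_numpy()
    # does trial n's chosen second-stage fractal keep its key side at n+lag?
    left_next = nxt["s2_mapping"].str.split("-").str[0]
    key_of_chosen_next = np.where(cur["s2_choice"].to_numpy() == left_next.to_numpy(), "left", "right")
    same_mapping = key_of_chosen_next == cur["s2_key"].to_numpy()
    out = pd.DataFrame(
        {
            "subject_id": cur["subject_id"].to_numpy(),
            "trial": cur["trial"].to_numpy(),
            "category": np.where(within, "within_state", "between_state"),
            "outcome": np.where(cur["reward"].to_numpy() == 1, "rewarded", "unrewarded"),
            "mapping": np.where(within, np.where(same_mapping, "same", "flipped"), None),
            "stay_fractal": np.where(
                within, (nxt["s2_choice"].to_numpy() == cur["s2_choice"].to_numpy()).astype(float), np.nan
            ),
            "stay_key_s2": (nxt["s2_key"].to_numpy() == cur["s2_key"].to_numpy()).astype(int),
            "stay_key_s2_to_s1": (nxt["s1_key"].to_numpy() == cur["s2_key"].to_numpy()).astype(int),
            "lag": lag,
        }
    )
    return out.reset_index(drop=True)


def classify_pairs(records, lag: int = 1) -> list[TrialPair]:
    """Classify consecutive trial pairs (see :func:`pairs_frame`)."""
    pf = pairs_frame(records, lag)
    pairs = []
    for row in pf.itertuples(index=False):
        pairs.append(
            TrialPair(
                subject_id=row.subject_id,
                trial=int(row.trial),
                category=row.category,
                outcome=row.outcome,
                mapping=row.mapping,
                stay_fractal=None if np.isnan(row.stay_fractal) else int(row.stay_fractal),
                stay_key_s2=int(row.stay_key_s2),
                stay_key_s2_to_s1=int(row.stay_key_s2_to_s1),
                lag=int(row.lag),
            )
        )
    return pairs


@dataclass
class EffectResult:
    """Per-subject and group-level summary of one sequential analysis."""

    analysis: str
    per_subject: pd.DataFrame  # cell probabilities and the effect score
    group: dict  # mean effect, CI, t statistic, p, n
    mixed: dict | None = None  # mixed-effects logistic coefficients, if fitted

    def summary(self) -> str:
        g = self.group
        lines = [
            f"{self.analysis}: effect = {g['effect']:+.4f} "
            f"(95% CI [{g['ci_low']:+.4f}, {g['ci_high']:+.4f}]), "
            f"t({g['n'] - 1}) = {g['t']:.2f}, p = {g['p']:.3g}, n = {g['n']}"
        ]
        if self.mixed is not None:
            lines.append(
                f"  mixed-effects logistic: coef = {self.mixed['coef']:+.4f} "
                f"(sd {self.mixed['sd']:.4f})"
            )
        return "\n".join(lines)


def _group_stats(scores: np.ndarray) -> dict:
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    n = len(scores)
    mean = float(scores.mean()) if n else float("nan")
    if n < 2:
        return {"effect": mean, "ci_low": np.nan, "ci_high": np.nan, "t": np.nan, "p": np.nan, "n": n}
    sem = scores.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    if sem == 0:
        t = np.inf if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
    else:
        t, p = stats.ttest_1samp(scores, 0.0)
    return {
        "effect": mean,
        "ci_low": mean - tcrit * sem,
        "ci_high": mean + tcrit * sem,
        "t": float(t),
        "p": float(p),
        "n": n,
    }


def _mixed_logistic(df: pd.DataFrame, response: str, fixed: list[str]) -> dict | None:
    """Random-intercept logistic regression via variational Bayes (statsmodels)."""
    try:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        exog = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in fixed])
        subj = pd.Categorical(df["subject_id"])
        exog_vc = pd.get_dummies(subj).to_numpy(float)
        ident = np.zeros(exog_vc.shape[1], dtype=int)
        model = BinomialBayesMixedGLM(
            df[response].to_numpy(float), exog, exog_vc, ident, vcp_p=2.0, fe_p=2.0
        )
        fit = model.fit_vb()
        # last fixed-effect column is the effect of interest
        j = len(fixed)
        return {"coef": float(fit.fe_mean[j]), "sd": float(fit.fe_sd[j]),
                "all_coefs": fit.fe_mean.tolist()}
    except Exception as exc:  # pragma: no cover - diagnostic path
        logger.warning("mixed-effects fit failed: %s", exc)
        return None


def within_state_effect(pairs, method: str = "ttest") -> EffectResult:
    """Outcome x mapping interaction on fractal stay probability.

    Per subject: ``(stay|rew,same - stay|unrew,same) - (stay|rew,flipped -
    stay|unrew,flipped)`` from the four cell probabilities; subjects missing
    a cell are excluded from the group contrast (logged). ``method="mixed"``
    additionally fits the mixed-effects logistic regression.
    """
    pf = pairs if isinstance(pairs, pd.DataFrame) else pd.DataFrame([vars(p) for p in pairs])
    pf = pf[pf["category"] == "within_state"]
    cells = (
        pf.groupby(["subject_id", "outcome", "mapping"], observed=True)["stay_fractal"]
        .agg(["mean", "count"])
        .reset_index()
    )
    wide = cells.pivot_table(index="subject_id", columns=["outcome", "mapping"], values="mean")
    needed = [("rewarded", "same"), ("unrewarded", "same"), ("rewarded", "flipped"), ("unrewarded", "flipped")]
    have = [c for c in needed if c in wide.columns]
    if len(have) < 4:
        wide = wide.reindex(columns=needed)
    complete = wide.dropna(subset=[c for c in needed if c in wide.columns])
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("within-state: %d subject(s) missing a cell, excluded", dropped)
    eff_same = complete.get(("rewarded", "same")) - complete.get(("unrewarded", "same"))
    eff_flip = complete.get(("rewarded", "flipped")) - complete.get(("unrewarded", "flipped"))
    per_subject = pd.DataFrame(
        {
            "stay_rew_same": complete.get(("rewarded", "same")),
            "stay_unrew_same": complete.get(("unrewarded", "same")),
            "stay_rew_flipped": complete.get(("rewarded", "flipped")),
            "stay_unrew_flipped": complete.get(("unrewarded", "flipped")),
            "reward_effect_same": eff_same,
            "reward_effect_flipped": eff_flip,
            "effect": eff_same - eff_flip,
        }
    )
    group = _group_stats(per_subject["effect"].to_numpy())
    group["reward_effect_same"] = float(np.nanmean(eff_same)) if len(eff_same) else np.nan
    group["reward_effect_flipped"] = float(np.nanmean(eff_flip)) if len(eff_flip) else np.nan
    mixed = None
    if method == "mixed":
        mdf = pf.dropna(subset=["stay_fractal"]).copy()
        mdf["outcome_c"] = (mdf["outcome"] == "rewarded").astype(float)
        mdf["mapping_c"] = (mdf["mapping"] == "same").astype(float)
        mdf["interaction"] = mdf["outcome_c"] * mdf["mapping_c"]
        mixed = _mixed_logistic(mdf, "stay_fractal", ["outcome_c", "mapping_c", "interaction"])
    return EffectResult("within_state", per_subject, group, mixed)


def _two_cell_effect(pf: pd.DataFrame, response: str, analysis: str, method: str) -> EffectResult:
    cells = pf.pivot_table(index="subject_id", columns="outcome", values=response)
    for col in ("rewarded", "unrewarded"):
        if col not in cells.columns:
            cells[col] = np.nan
    complete = cells.dropna(subset=["rewarded", "unrewarded"])
    dropped = len(cells) - len(complete)
    if dropped:
        logger.info("%s: %d subject(s) missing a cell, excluded", analysis, dropped)
    per_subject = pd.DataFrame(
        {
            "stay_rewarded": complete["rewarded"],
            "stay_unrewarded": complete["unrewarded"],
            "effect": complete["rewarded"] - complete["unrewarded"],
        }
    )
    group = _group_stats(per_subject["effect"].to_numpy())
    mixed = None
    if method == "mixed":
        mdf = pf.copy()
        mdf["outcome_c"] = (mdf["outcome"] == "rewarded").astype(float)
        mixed = _mixed_logistic(mdf, response, ["outcome_c"])
    return EffectResult(analysis, per_subject, group, mixed)


def between_state_effect(pairs, method: str = "ttest") -> EffectResult:
    """Reward effect on key stay probability across different fractal pairs."""
    pf = pairs if isinstance(pairs, pd.DataFrame) else pd.DataFrame([vars(p) for p in pairs])
    pf = pf[pf["category"] == "between_state"]
    return _two_cell_effect(pf, "stay_key_s2", "between_state", method)


def between_stage_effect(records, method: str = "ttest", lag: int = 1) -> EffectResult:
    """Reward effect on repeating the second-stage key at the next first stage.

    Defined for every consecutive pair regardless of state repetition, so
    this accepts trial records (or a precomputed pair table).
    """
    if isinstance(records, pd.DataFrame) and "stay_key_s2_to_s1" in records.columns:
        pf = records
    else:
        pf = pairs_frame(records, lag=lag)
    return _two_cell_effect(pf, "stay_key_s2_to_s1", "between_stage", method)
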