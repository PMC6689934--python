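"""Hierarchical model fitting: EM with per-subject Laplace approximation.

Subject-level free parameters are estimated by MAP optimisation in an
unconstrained space under a diagonal Gaussian group prior; the group prior
moments are re-estimated by expectation maximization. The E step maximises

    log p(data_i | theta_i) + log N(theta_i | mu, diag(sigma^2))

per subject and Laplace-approximates each subject's integrated likelihood

    log p(data_i | mu, sigma^2) ~ logpost(theta_i*) + (d/2) log(2 pi)
                                   - (1/2) log det H_i,

with ``H_i`` the Hessian of the negative log posterior at the mode. The M
step sets ``mu`` to the mean of the subject modes and ``sigma^2`` to the
spread of the modes plus the mean posterior variance (diagonal of the
inverse Hessians). Models are compared by an integrated BIC,

    BIC_int = -2 sum_i log p(data_i | mu, sigma^2) + k log N,

where ``k`` counts group-level prior parameters (two per model parameter)
and ``N`` counts choices (two per complete trial); a difference of 10 or
more is treated as strong evidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from . import _engine
from .agents import AgentParams
from .task import TrialRecord, records_to_frame
from .transforms import from_unconstrained, param_names

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectFit",
    "GroupFitResults",
    "HierarchicalRLModel",
    "fit_subject_map",
    "em_fit",
    "integrated_bic",
    "compare_models",
]

_LN2PI = float(np.log(2 * np.pi))


@dataclass
class SubjectFit:
    """MAP estimate and Laplace evidence for one subject."""

    subject_id: str
    model_id: int
    x_map: np.ndarray  # unconstrained-space mode
    params: dict  # natural-space parameters at the mode
    log_post: float
    log_lik: float
    hessian: np.ndarray  # of the negative log posterior at the mode
    log_evidence: float
    n_trials: int
    converged: bool = True
    ridged: bool = False


def _neg_log_post(x, model_id, data, mu, var):
    p = from_unconstrained(model_id, x)
    ll = sum(_engine.loglik_encoded(model_id, p, data))
    lp = -0.5 * float(np.sum((x - mu) ** 2 / var)) - 0.5 * float(np.sum(np.log(2 * np.pi * var)))
    return -(ll + lp)


def _safe_chol_logdet(h: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """log det of ``h`` via Cholesky, ridging the diagonal if needed."""
    ridge, ridged = 0.0, False
    eye = np.eye(h.shape[0])
    for _ in range(40):
        try:
            c = np.linalg.cholesky(h + ridge * eye)
            return 2.0 * float(np.sum(np.log(np.diag(c)))), h + ridge * eye, ridged
        except np.linalg.LinAlgError:
            ridged = True
            ridge = max(ridge * 10.0, 1e-8)
    raise np.linalg.LinAlgError("Hessian could not be regularised")


def laplace_evidence(log_post_max: float, hessian: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Gaussian (Laplace) approximation of a log integrated likelihood.

    ``hessian`` is the curvature of the *negative* log posterior at its mode.
    Returns the evidence, the (possibly ridge-regularised) Hessian actually
    used, and whether regularisation was needed.
    """
    h = np.atleast_2d(np.asarray(hessian, dtype=float))
    h = 0.5 * (h + h.T)
    d = h.shape[0]
    logdet, h_reg, ridged = _safe_chol_logdet(h)
    return float(log_post_max + 0.5 * d * _LN2PI - 0.5 * logdet), h_reg, ridged


def fit_subject_map(
    model_id: int,
    records,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    start: np.ndarray | None = None,
    n_starts: int = 4,
    seed: int = 0,
    jitter: float = 1.0,
    subject_id: str | None = None,
) -> SubjectFit:
    """MAP + Laplace fit of one subject under a Gaussian prior.

    Runs ``n_starts`` L-BFGS-B optimisations (prior mean, supplied start,
    and seeded jittered starts) and keeps the best posterior. A singular
    Hessian at the mode is ridge-regularised with a warning flag.
    """
    data = records if isinstance(records, _engine.EncodedSession) else _engine.encode_session(records)
    if data.n_trials < 1:
        raise ValueError("at least one trial required")
    mu = np.asarray(prior_mean, dtype=float)
    var = np.asarray(prior_var, dtype=float)
    d = len(mu)
    rng = np.random.default_rng(seed)
    starts = [mu.copy()]
    if start is not None:
        starts.insert(0, np.asarray(start, dtype=float))
    while len(starts) < max(1, n_starts):
        starts.append(mu + jitter * np.sqrt(var) * rng.standard_normal(d))
    best = None
    converged = False
    bounds = [(-15.0, 15.0)] * d
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_post,
            np.clip(x0, -14.0, 14.0),
            args=(model_id, data, mu, var),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    x = np.asarray(best.x, dtype=float)
    hess = numdiff.approx_hess(x, _neg_log_post, args=(model_id, data, mu, var))
    log_post = -float(best.fun)
    evidence, hess_reg, ridged = laplace_evidence(log_post, hess)
    if ridged:
        logger.warning("subject %s: singular Hessian ridge-regularised", subject_id)
    p = from_unconstrained(model_id, x)
    ll = float(sum(_engine.loglik_encoded(model_id, p, data)))
    return SubjectFit(
        subject_id=subject_id or data.subject_id,
        model_id=model_id,
        x_map=x,
        params=p,
        log_post=log_post,
        log_lik=ll,
        hessian=hess_reg,
        log_evidence=float(evidence),
        n_trials=data.n_trials,
        converged=converged,
        ridged=ridged,
    )


@dataclass
class GroupFitResults:
    """Hierarchical fit of one model to a cohort (the Results object).

    Carries the group prior moments, the per-subject MAP fits with Laplace
    evidences, the EM iteration trace, and the integrated BIC.
    """

    model_id: int
    param_names: list[str]
    prior_mean: np.ndarray
    prior_var: np.ndarray
    subject_fits: list[SubjectFit]
    total_evidence: float
    bic_int: float
    n_choices: int
    trace: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def n_subjects(self) -> int:
        return len(self.subject_fits)

    def subject_table(self) -> pd.DataFrame:
        """Per-subject natural-space MAP parameters and evidences."""
        rows = []
        for sf in self.subject_fits:
            row = {"subject_id": sf.subject_id, **sf.params,
                   "log_lik": sf.log_lik, "log_evidence": sf.log_evidence,
                   "n_trials": sf.n_trials, "converged": sf.converged}
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")

    def group_table(self) -> pd.DataFrame:
        """Group prior moments, unconstrained and (mean) natural space."""
        nat = from_unconstrained(self.model_id, self.prior_mean)
        return pd.DataFrame(
            {
                "mean_unconstrained": self.prior_mean,
                "sd_unconstrained": np.sqrt(self.prior_var),
                "mean_natural": [nat[k] for k in self.param_names],
            },
            index=self.param_names,
        )

    def summary(self) -> str:
        lines = [
            f"Hierarchical fit: Model {self.model_id}",
            f"  subjects: {self.n_subjects}   choices: {self.n_choices}",
            f"  EM iterations: {len(self.trace)}   converged: {self.converged}",
            f"  total log evidence: {self.total_evidence:.2f}",
            f"  BIC_int: {self.bic_int:.2f}",
            "",
            self.group_table().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def simulate(self, config=None, n_reps: int = 20, n_trials: int = 1000, seed: int = 0):
        """Posterior-predictive simulation from the per-subject MAPs."""
        from .ppc import simulate_from_fit

        return simulate_from_fit(self, config=config, n_reps=n_reps, n_trials=n_trials, seed=seed)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_id": self.model_id,
            "param_names": self.param_names,
            "prior_mean": self.prior_mean.tolist(),
            "prior_var": self.prior_var.tolist(),
            "total_evidence": self.total_evidence,
            "bic_int": self.bic_int,
            "n_choices": self.n_choices,
            "trace": self.trace,
            "converged": self.converged,
            "subjects": {
                sf.subject_id: {
                    "x_map": sf.x_map.tolist(),
                    "params": sf.params,
                    "log_lik": sf.log_lik,
                    "log_evidence": sf.log_evidence,
                    "n_trials": sf.n_trials,
                    "converged": sf.converged,
                }
                for sf in self.subject_fits
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _group_sessions(records) -> list[_engine.EncodedSession]:
    if isinstance(records, list) and records and isinstance(records[0], _engine.EncodedSession):
        return records
    if isinstance(records, pd.DataFrame):
        from .task import frame_to_records

        records = frame_to_records(records)
    by_subject: dict[str, list[TrialRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    return [_engine.encode_session(recs) for recs in by_subject.values()]


def em_fit(
    model_id: int,
    records,
    init_mean: np.ndarray | None = None,
    init_var: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 0.02,
    n_starts: int = 4,
    seed: int = 0,
    var_floor: float = 1e-3,
) -> GroupFitResults:
    """Fit the group prior and all subjects by EM (see module docstring).

    Multi-start MAP optimisation is used on the first EM iteration; later
    iterations warm-start each subject from the previous mode. Stops when
    the largest group-mean change drops below ``tol``.
    """
    sessions = _group_sessions(records)
    if len(sessions) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    names = param_names(model_id)
    d = len(names)
    mu = np.zeros(d) if init_mean is None else np.asarray(init_mean, dtype=float).copy()
    var = np.full(d, 2.25) if init_var is None else np.asarray(init_var, dtype=float).copy()
    warm: dict[str, np.ndarray] = {}
    trace: list[dict] = []
    fits: list[SubjectFit] = []
    converged = False
    rng = np.random.default_rng(seed)
    for it in range(max_iter):
        fits = []
        for s in sessions:
            fit = fit_subject_map(
                model_id,
                s,
                mu,
                var,
                start=warm.get(s.subject_id),
                n_starts=n_starts if it == 0 else 1,
                seed=int(rng.integers(2**31)),
                subject_id=s.subject_id,
            )
            warm[s.subject_id] = fit.x_map
            fits.append(fit)
        X = np.vstack([f.x_map for f in fits])
        post_var = np.vstack([np.diag(np.linalg.inv(f.hessian)) for f in fits])
        new_mu = X.mean(axis=0)
        new_var = np.maximum(
            X.var(axis=0) + np.maximum(post_var, 0.0).mean(axis=0), var_floor
        )
        total_ev = float(sum(f.log_evidence for f in fits))
        delta = float(np.max(np.abs(new_mu - mu)))
        trace.append({"iteration": it, "total_evidence": total_ev, "mean_change": delta})
        mu, var = new_mu, new_var
        if delta < tol:
            converged = True
            break
    n_choices = 2 * sum(s.n_trials for s in sessions)
    fits.sort(key=lambda f: f.subject_id)
    result = GroupFitResults(
        model_id=model_id,
        param_names=names,
        prior_mean=mu,
        prior_var=var,
        subject_fits=fits,
        total_evidence=float(sum(f.log_evidence for f in fits)),
        bic_int=0.0,
        n_choices=n_choices,
        trace=trace,
        converged=converged,
    )
    result.bic_int = integrated_bic(result, n_choices)
    return result


def integrated_bic(groupfit: GroupFitResults, n_choices: int | None = None) -> float:
    """Integrated BIC: ``-2 * total evidence + k_group * log(N_choices)``.

    ``k_group`` is two per model parameter (group mean and variance).
    """
    n = groupfit.n_choices if n_choices is None else n_choices
    k_group = 2 * len(groupfit.param_names)
    return float(-2.0 * groupfit.total_evidence + k_group * np.log(n))


def compare_models(records, model_ids: Sequence[int] = (1, 2, 3, 4, 5), **em_kwargs) -> pd.DataFrame:
    """Fit each model and tabulate BIC_int and ΔBIC against Model 1.

    Failed fits appear as rows with NaN scores and the error message.
    """
    rows = []
    fits = {}
    for m in model_ids:
        try:
            gf = em_fit(m, records, **em_kwargs)
            fits[m] = gf
            rows.append({"model_id": m, "bic_int": gf.bic_int, "total_evidence": gf.total_evidence,
                         "n_params": len(gf.param_names), "error": ""})
        except Exception as exc:
            logger.warning("model %d fit failed: %s", m, exc)
            rows.append({"model_id": m, "bic_int": np.nan, "total_evidence": np.nan,
                         "n_params": len(param_names(m)), "error": str(exc)})
    df = pd.DataFrame(rows).set_index("model_id")
    ref = 1 if 1 in df.index and np.isfinite(df.loc[1, "bic_int"]) else df["bic_int"].idxmin()
    df["delta_bic_vs_model1"] = df["bic_int"] - df.loc[ref, "bic_int"]
    df["winner"] = df["bic_int"] == df["bic_int"].min()
    df.attrs["fits"] = fits
    return df


class HierarchicalRLModel:
    """Hierarchical two-step RL model bound to a cohort of trial data.

    Parameters
    ----------
    data
        Trial records (list of :class:`TrialRecord`) or a DataFrame in the
        documented trial schema, covering >= 2 subjects.
    model_id
        Which of the five agents to fit (default 2, the key-value model).

    ``fit()`` returns a :class:`GroupFitResults`.
    """

    def __init__(self, data, model_id: int = 2):
        self.model_id = model_id
        self.data = data
        self.sessions = _group_sessions(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model_id: int = 2) -> "HierarchicalRLModel":
        return cls(df, model_id=model_id)

    @classmethod
    def from_csv(cls, path, model_id: int = 2) -> "HierarchicalRLModel":
        return cls(pd.read_csv(path), model_id=model_id)

    def fit(self, **em_kwargs) -> GroupFitResults:
        return em_fit(self.model_id, self.sessions_records(), **em_kwargs)

    def sessions_records(self):
        return self.sessions

    def loglike_at(self, params: AgentParams) -> float:
        """Total log-likelihood of the whole cohort at one parameter set."""
        total = 0.0
        for s in self.sessions:
            total += sum(_engine.loglik_encoded(self.model_id, params.as_dict(), s))
        return float(total)
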