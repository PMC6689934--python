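"""Parameter vectors and unconstrained transforms for the five agents.

Hierarchical fitting and the population generator both work in an
unconstrained space where every parameter is real-valued: rates, traces and
the model-based weight live on a logit scale, the inverse temperature on a
log scale, and the additive bias terms (and the key-value weight ``w2``,
which scales an added component rather than a convex mixture) on the
identity scale.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = ["PARAM_SPECS", "param_names", "to_unconstrained", "from_unconstrained", "TRANSFORMS"]

_EPS = 1e-9


def _sigmoid(x: float) -> float:
    return float(expit(x))


def _logit(p: float) -> float:
    return float(logit(np.clip(p, _EPS, 1 - _EPS)))


def _log(x: float) -> float:
    return float(np.log(max(x, _EPS)))


TRANSFORMS = {
    "logit": (_sigmoid, _logit),  # (unconstrained -> natural, natural -> unconstrained)
    "log": (lambda x: float(np.exp(x)), _log),
    "identity": (float, float),
}

#: ordered (name, transform) pairs of the free parameters of each model
PARAM_SPECS: dict[int, tuple[tuple[str, str], ...]] = {
    1: (
        ("alpha1", "logit"),
        ("lambda1", "logit"),
        ("w1", "logit"),
        ("beta", "log"),
        ("persev_fractal", "identity"),
        ("persev_key", "identity"),
        ("key_bias", "identity"),
    ),
    2: (
        ("alpha1", "logit"),
        ("lambda1", "logit"),
        ("alpha2", "logit"),
        ("lambda2", "logit"),
        ("w1", "logit"),
        ("w2", "identity"),
        ("beta", "log"),
        ("persev_fractal", "identity"),
        ("persev_key", "identity"),
        ("key_bias", "identity"),
    ),
    3: (
        ("alpha1", "logit"),
        ("alpha2", "logit"),
        ("lambda1", "logit"),
        ("w1", "logit"),
        ("beta", "log"),
        ("persev_fractal", "identity"),
        ("persev_key", "identity"),
        ("key_bias", "identity"),
    ),
}
PARAM_SPECS[4] = PARAM_SPECS[3]
PARAM_SPECS[5] = PARAM_SPECS[3]


def param_names(model_id: int) -> list[str]:
    return [name for name, _ in PARAM_SPECS[model_id]]


def to_unconstrained(model_id: int, natural: dict[str, float]) -> np.ndarray:
    """Map a dict of natural-space parameter values to the fitting vector."""
    out = []
    for name, tr in PARAM_SPECS[model_id]:
        _, inv = TRANSFORMS[tr]
        out.append(inv(natural[name]))
    return np.asarray(out, dtype=float)


def from_unconstrained(model_id: int, x: np.ndarray) -> dict[str, float]:
    """Map a fitting vector back to natural-space parameter values."""
    spec = PARAM_SPECS[model_id]
    if len(x) != len(spec):
        raise ValueError(f"model {model_id} expects {len(spec)} parameters, got {len(x)}")
    out = {}
    for (name, tr), xi in zip(spec, x):
        fwd, _ = TRANSFORMS[tr]
        out[name] = fwd(float(xi))
    return out
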