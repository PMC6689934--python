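"""Fast numeric kernels for trial-sequence likelihoods and simulation.

Trial sequences are encoded once into flat integer lists (fractals 0-5,
keys 0=left/1=right, states 0=s2/1=s3) and the per-model likelihood loops
run on plain Python floats, which keeps a single likelihood evaluation for
a few-hundred-trial session well under a millisecond — the hierarchical
fitter evaluates these kernels hundreds of thousands of times.

The readable single-trial operations in :mod:`twostep_credit.agents` are the
reference implementation of the same equations; the test-suite checks the
two routes agree to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, log1p
from typing import Sequence

import numpy as np

from .task import FRACTAL_CODE, KEYS, STATES, TrialRecord


def _ll_choice(z: float, chose_right: int) -> float:
    """Stable log probability of the observed key under logit ``z`` for right."""
    zz = z if chose_right == 1 else -z
    if zz > 0.0:
        return -log1p(exp(-zz))
    return zz - log1p(exp(zz))


def _sigmoid(z: float) -> float:
    if z > 40.0:
        return 1.0
    if z < -40.0:
        return 0.0
    return 1.0 / (1.0 + exp(-z))

__all__ = ["EncodedSession", "encode_session", "loglik_encoded", "simulate_encoded"]


@dataclass
class EncodedSession:
    """One subject's trial sequence as parallel integer lists."""

    subject_id: str
    f1: list  # first-stage chosen fractal, 0/1
    k1: list  # first-stage key, 0=left/1=right
    s1_left: list  # fractal shown on the left at stage 1
    state: list  # second-stage state, 0=s2/1=s3
    f2: list  # second-stage chosen fractal, 2..5
    k2: list
    s2_left: list  # fractal shown on the left at stage 2
    r: list  # reward, 0/1

    @property
    def n_trials(self) -> int:
        return len(self.f1)


def encode_session(records: Sequence[TrialRecord]) -> EncodedSession:
    """Encode one subject's (sorted) records for the numeric kernels."""
    f1, k1, s1l, st, f2, k2, s2l, r = [], [], [], [], [], [], [], []
    sid = records[0].subject_id if records else ""
    for rec in records:
        f1.append(FRACTAL_CODE[rec.s1_choice])
        k1.append(KEYS.index(rec.s1_key))
        s1l.append(FRACTAL_CODE[rec.s1_mapping.split("-")[0]])
        st.append(STATES.index(rec.s2_state))
        f2.append(FRACTAL_CODE[rec.s2_choice])
        k2.append(KEYS.index(rec.s2_key))
        s2l.append(FRACTAL_CODE[rec.s2_mapping.split("-")[0]])
        r.append(int(rec.reward))
    return EncodedSession(sid, f1, k1, s1l, st, f2, k2, s2l, r)


def _rate(base: float, rep: bool, alpha_rep, alpha_flip) -> float:
    if alpha_rep is None:
        return base
    return alpha_rep if rep else alpha_flip


def loglik_encoded(model_id: int, p: dict, data: EncodedSession, p_common: float = 0.7):
    """Per-trial log-likelihood (both stages summed) for one session.

    ``p`` holds natural-space parameters; missing bias terms default to 0.
    Returns a list of length ``n_trials``.
    """
    if model_id in (1, 2):
        return _ll_m12(p, data, p_common, use_key=model_id == 2)
    if model_id == 3:
        return _ll_m3(p, data, p_common)
    if model_id in (4, 5):
        return _ll_m45(p, data, p_common, model5=model_id == 5)
    raise ValueError(f"unknown model_id {model_id}")


def _ll_m12(p: dict, d: EncodedSession, pc: float, use_key: bool):
    a1 = p["alpha1"]
    l1 = p["lambda1"]
    w1 = p["w1"]
    beta = p["beta"]
    pf = p.get("persev_fractal", 0.0)
    pk = p.get("persev_key", 0.0)
    kb = p.get("key_bias", 0.0)
    a2 = p.get("alpha2", 0.0)
    l2 = p.get("lambda2", 0.0)
    w2 = p.get("w2", 0.0)
    a_rep, a_flip = p.get("alpha_rep"), p.get("alpha_flip")
    q = [0.0] * 6
    qk = [0.0, 0.0]
    prev_f1 = prev_k1 = prev_k2 = -1
    prev_s1l = prev_state = prev_s2l = -1
    out = []
    F1, K1, S1L, ST, F2, K2, S2L, R = d.f1, d.k1, d.s1_left, d.state, d.f2, d.k2, d.s2_left, d.r
    for t in range(len(F1)):
        f1 = F1[t]; k1 = K1[t]; s1l = S1L[t]; st = ST[t]
        f2 = F2[t]; k2 = K2[t]; s2l = S2L[t]; r = R[t]
        # stage 1: model-based values from the known 70/30 transitions
        m2 = q[2] if q[2] > q[3] else q[3]
        m3 = q[4] if q[4] > q[5] else q[5]
        qmb_a = pc * m2 + (1.0 - pc) * m3
        qmb_b = pc * m3 + (1.0 - pc) * m2
        net_a = w1 * qmb_a + (1.0 - w1) * q[0]
        net_b = w1 * qmb_b + (1.0 - w1) * q[1]
        if use_key:
            key_a = 0 if s1l == 0 else 1  # key currently mapped to fractal A
            net_a += w2 * qk[key_a]
            net_b += w2 * qk[1 - key_a]
        vl, vr = (net_a, net_b) if s1l == 0 else (net_b, net_a)
        z = beta * (vr - vl) + kb
        if prev_f1 >= 0:
            rf = 1 - s1l
            z += pf * ((1.0 if rf == prev_f1 else 0.0) - (1.0 if s1l == prev_f1 else 0.0))
        if prev_k1 >= 0:
            z += pk if prev_k1 == 1 else -pk
        ll = _ll_choice(z, k1)
        # stage 2
        base = 2 + 2 * st
        fr = base + 1 if s2l == base else base
        nl = q[s2l]
        nr = q[fr]
        if use_key:
            nl += w2 * qk[0]
            nr += w2 * qk[1]
        z = beta * (nr - nl) + kb
        if prev_k2 >= 0:
            z += pk if prev_k2 == 1 else -pk
        ll += _ll_choice(z, k2)
        out.append(ll)
        # end-of-trial SARSA updates
        rep1 = s1l == prev_s1l
        rep2 = st == prev_state and s2l == prev_s2l
        if use_key:
            a1_s1 = a1_s2 = a1
            a2_s1 = _rate(a2, rep1, a_rep, a_flip)
            a2_s2 = _rate(a2, rep2, a_rep, a_flip)
        else:
            a1_s1 = _rate(a1, rep1, a_rep, a_flip)
            a1_s2 = _rate(a1, rep2, a_rep, a_flip)
        qf2 = q[f2]
        q[f1] += a1_s1 * (qf2 - q[f1]) + a1_s1 * l1 * (r - qf2)
        q[f2] += a1_s2 * (r - qf2)
        if use_key:
            d1 = a2_s1 * l2 * (r - qk[k1])
            d2 = a2_s2 * (1.0 - l2) * (r - qk[k2])
            qk[k1] += d1
            qk[k2] += d2
        prev_f1, prev_k1, prev_k2 = f1, k1, k2
        prev_s1l, prev_state, prev_s2l = s1l, st, s2l
    return out


def _ll_m3(p: dict, d: EncodedSession, pc: float):
    a1 = p["alpha1"]; a2 = p["alpha2"]; l1 = p["lambda1"]
    w1 = p["w1"]; beta = p["beta"]
    pf = p.get("persev_fractal", 0.0)
    pk = p.get("persev_key", 0.0)
    kb = p.get("key_bias", 0.0)
    q = [0.0] * 6  # fractal values for the model-based system (second stage only)
    w = [0.0] * 8  # feature weights: fractals 0..5, keys left/right at 6/7
    prev_f1 = prev_k1 = prev_k2 = -1
    out = []
    for t in range(len(d.f1)):
        f1 = d.f1[t]; k1 = d.k1[t]; s1l = d.s1_left[t]; st = d.state[t]
        f2 = d.f2[t]; k2 = d.k2[t]; s2l = d.s2_left[t]; r = d.r[t]
        m2 = q[2] if q[2] > q[3] else q[3]
        m3 = q[4] if q[4] > q[5] else q[5]
        qmb_a = pc * m2 + (1.0 - pc) * m3
        qmb_b = pc * m3 + (1.0 - pc) * m2
        key_a = 0 if s1l == 0 else 1
        net_a = w1 * qmb_a + (1.0 - w1) * (w[0] + w[6 + key_a])
        net_b = w1 * qmb_b + (1.0 - w1) * (w[1] + w[7 - key_a])
        vl, vr = (net_a, net_b) if s1l == 0 else (net_b, net_a)
        z = beta * (vr - vl) + kb
        if prev_f1 >= 0:
            rf = 1 - s1l
            z += pf * ((1.0 if rf == prev_f1 else 0.0) - (1.0 if s1l == prev_f1 else 0.0))
        if prev_k1 >= 0:
            z += pk if prev_k1 == 1 else -pk
        ll = _ll_choice(z, k1)
        base = 2 + 2 * st
        fr = base + 1 if s2l == base else base
        nl = w1 * q[s2l] + (1.0 - w1) * (w[s2l] + w[6])
        nr = w1 * q[fr] + (1.0 - w1) * (w[fr] + w[7])
        z = beta * (nr - nl) + kb
        if prev_k2 >= 0:
            z += pk if prev_k2 == 1 else -pk
        ll += _ll_choice(z, k2)
        out.append(ll)
        # feature-weight updates with active-feature indicators
        qmf1 = w[f1] + w[6 + k1]
        qmf2 = w[f2] + w[6 + k2]
        d11 = a2 * (qmf2 - qmf1) + a2 * l1 * (r - qmf2)
        d12 = a2 * (r - qmf2)
        w[f1] += d11
        w[6 + k1] += d11
        w[f2] += d12
        w[6 + k2] += d12
        q[f2] += a1 * (r - q[f2])
        prev_f1, prev_k1, prev_k2 = f1, k1, k2
    return out


def _ll_m45(p: dict, d: EncodedSession, pc: float, model5: bool):
    a1 = p["alpha1"]; a2 = p["alpha2"]; l1 = p["lambda1"]
    w1 = p["w1"]; beta = p["beta"]
    pf = p.get("persev_fractal", 0.0)
    pk = p.get("persev_key", 0.0)
    kb = p.get("key_bias", 0.0)
    ph = pc / 2.0  # common transition mass per mapping-specific state
    pl = (1.0 - pc) / 2.0
    q = [0.0] * 6
    qc = [0.0] * 12  # conjunctive fractal-key values, index fractal*2 + key
    prev_f1 = prev_k1 = prev_k2 = -1
    out = []
    for t in range(len(d.f1)):
        f1 = d.f1[t]; k1 = d.k1[t]; s1l = d.s1_left[t]; st = d.state[t]
        f2 = d.f2[t]; k2 = d.k2[t]; s2l = d.s2_left[t]; r = d.r[t]
        if model5:
            # four mapping-specific second-stage states; max over the
            # conjunctive values available under each mapping
            s2m0 = max(qc[4], qc[7])   # C-left: (C,left), (D,right)
            s2m1 = max(qc[5], qc[6])   # C-right
            s3m0 = max(qc[8], qc[11])  # E-left
            s3m1 = max(qc[9], qc[10])
            qmb_a = ph * (s2m0 + s2m1) + pl * (s3m0 + s3m1)
            qmb_b = ph * (s3m0 + s3m1) + pl * (s2m0 + s2m1)
        else:
            m2 = q[2] if q[2] > q[3] else q[3]
            m3 = q[4] if q[4] > q[5] else q[5]
            qmb_a = pc * m2 + (1.0 - pc) * m3
            qmb_b = pc * m3 + (1.0 - pc) * m2
        key_a = 0 if s1l == 0 else 1
        net_a = w1 * qmb_a + (1.0 - w1) * qc[key_a]
        net_b = w1 * qmb_b + (1.0 - w1) * qc[2 + 1 - key_a]
        vl, vr = (net_a, net_b) if s1l == 0 else (net_b, net_a)
        z = beta * (vr - vl) + kb
        if prev_f1 >= 0:
            rf = 1 - s1l
            z += pf * ((1.0 if rf == prev_f1 else 0.0) - (1.0 if s1l == prev_f1 else 0.0))
        if prev_k1 >= 0:
            z += pk if prev_k1 == 1 else -pk
        ll = _ll_choice(z, k1)
        base = 2 + 2 * st
        fr = base + 1 if s2l == base else base
        if model5:
            nl = qc[s2l * 2 + 0]
            nr = qc[fr * 2 + 1]
        else:
            nl = w1 * q[s2l] + (1.0 - w1) * qc[s2l * 2 + 0]
            nr = w1 * q[fr] + (1.0 - w1) * qc[fr * 2 + 1]
        z = beta * (nr - nl) + kb
        if prev_k2 >= 0:
            z += pk if prev_k2 == 1 else -pk
        ll += _ll_choice(z, k2)
        out.append(ll)
        # conjunctive SARSA updates
        i1 = f1 * 2 + k1
        i2 = f2 * 2 + k2
        q2 = qc[i2]
        qc[i1] += a2 * (q2 - qc[i1]) + a2 * l1 * (r - q2)
        qc[i2] += a2 * (r - q2)
        q[f2] += a1 * (r - q[f2])
        prev_f1, prev_k1, prev_k2 = f1, k1, k2
    return out


def simulate_encoded(
    model_id: int,
    p: dict,
    schedule: np.ndarray,
    seed: int,
    p_common: float = 0.7,
) -> dict[str, np.ndarray]:
    """Forward-simulate one agent (Models 1 and 2) against a reward schedule.

    Returns the encoded arrays of the realised session. Mappings are drawn
    with probability 0.5 per side, transitions with ``p_common``, rewards
    as Bernoulli draws from the schedule row of the chosen fractal.
    """
    if model_id not in (1, 2):
        raise ValueError("fast simulation implemented for Models 1 and 2")
    use_key = model_id == 2
    a1 = p["alpha1"]; l1 = p["lambda1"]; w1 = p["w1"]; beta = p["beta"]
    pf = p.get("persev_fractal", 0.0)
    pk = p.get("persev_key", 0.0)
    kb = p.get("key_bias", 0.0)
    a2 = p.get("alpha2", 0.0); l2 = p.get("lambda2", 0.0); w2 = p.get("w2", 0.0)
    a_rep, a_flip = p.get("alpha_rep"), p.get("alpha_flip")
    sched = np.asarray(schedule, dtype=float)
    n = sched.shape[0]
    rng = np.random.default_rng(seed)
    U = rng.random((n, 6)).tolist()
    rows = sched.tolist()
    q = [0.0] * 6
    qk = [0.0, 0.0]
    prev_f1 = prev_k1 = prev_k2 = -1
    prev_s1l = prev_state = prev_s2l = -1
    F1 = []; K1 = []; S1L = []; ST = []; F2 = []; K2 = []; S2L = []; R = []; TR = []
    for t in range(n):
        u = U[t]
        s1l = 0 if u[0] < 0.5 else 1
        m2 = q[2] if q[2] > q[3] else q[3]
        m3 = q[4] if q[4] > q[5] else q[5]
        qmb_a = p_common * m2 + (1.0 - p_common) * m3
        qmb_b = p_common * m3 + (1.0 - p_common) * m2
        net_a = w1 * qmb_a + (1.0 - w1) * q[0]
        net_b = w1 * qmb_b + (1.0 - w1) * q[1]
        if use_key:
            key_a = 0 if s1l == 0 else 1
            net_a += w2 * qk[key_a]
            net_b += w2 * qk[1 - key_a]
        vl, vr = (net_a, net_b) if s1l == 0 else (net_b, net_a)
        z = beta * (vr - vl) + kb
        if prev_f1 >= 0:
            rf = 1 - s1l
            z += pf * ((1.0 if rf == prev_f1 else 0.0) - (1.0 if s1l == prev_f1 else 0.0))
        if prev_k1 >= 0:
            z += pk if prev_k1 == 1 else -pk
        pr = _sigmoid(z)
        k1 = 1 if u[1] < pr else 0
        f1 = (1 - s1l) if k1 == 1 else s1l
        common = u[2] < p_common
        st = f1 if common else 1 - f1  # fractal A's common state is s2 (=0)
        base = 2 + 2 * st
        s2l = base if u[3] < 0.5 else base + 1
        fr = base + 1 if s2l == base else base
        nl = q[s2l]; nr = q[fr]
        if use_key:
            nl += w2 * qk[0]
            nr += w2 * qk[1]
        z = beta * (nr - nl) + kb
        if prev_k2 >= 0:
            z += pk if prev_k2 == 1 else -pk
        pr = _sigmoid(z)
        k2 = 1 if u[4] < pr else 0
        f2 = fr if k2 == 1 else s2l
        r = 1 if u[5] < rows[t][f2 - 2] else 0
        F1.append(f1); K1.append(k1); S1L.append(s1l); ST.append(st)
        F2.append(f2); K2.append(k2); S2L.append(s2l); R.append(r)
        TR.append(1 if common else 0)
        rep1 = s1l == prev_s1l
        rep2 = st == prev_state and s2l == prev_s2l
        if use_key:
            a1_s1 = a1_s2 = a1
            a2_s1 = _rate(a2, rep1, a_rep, a_flip)
            a2_s2 = _rate(a2, rep2, a_rep, a_flip)
        else:
            a1_s1 = _rate(a1, rep1, a_rep, a_flip)
            a1_s2 = _rate(a1, rep2, a_rep, a_flip)
        qf2 = q[f2]
        q[f1] += a1_s1 * (qf2 - q[f1]) + a1_s1 * l1 * (r - qf2)
        q[f2] += a1_s2 * (r - qf2)
        if use_key:
            d1 = a2_s1 * l2 * (r - qk[k1])
            d2 = a2_s2 * (1.0 - l2) * (r - qk[k2])
            qk[k1] += d1
            qk[k2] += d2
        prev_f1, prev_k1, prev_k2 = f1, k1, k2
        prev_s1l, prev_state, prev_s2l = s1l, st, s2l
    return {
        "f1": np.array(F1), "k1": np.array(K1), "s1_left": np.array(S1L),
        "state": np.array(ST), "f2": np.array(F2), "k2": np.array(K2),
        "s2_left": np.array(S2L), "r": np.array(R), "common": np.array(TR),
    }
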