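"""Compiled inner loops: fused ensemble RHS + adaptive Dormand-Prince 5(4).

The ensemble ODE (two shared modifiers plus six measured species per cell)
is the inner loop of every distribution-matching cost evaluation, so the
right-hand side and the adaptive integrator are fused and JIT-compiled.
The integrator mirrors the classic explicit Dormand-Prince 5(4) pair with
FSAL, an RMS error norm against ``atol + rtol * |y|``, and a standard
step-size controller; output states are produced by stepping exactly onto
each requested time.  :mod:`emtsig.model` falls back to SciPy's solvers when
this path reports failure (e.g. stiff parameter regimes).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B = _A[6].copy()  # 5th-order solution weights (FSAL)
_E = np.array(  # embedded 4th-order error weights
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)


@njit(cache=True, inline="always")
def _p(x, g):
    if g == 1.0:
        return x
    return x**g


@njit(cache=True)
def _rhs(t, y, out, p, T, gam, stim):
    # p holds the 38 population parameters in emtsig.params.PARAM_NAMES order
    u1 = 1.0
    u2 = 1.0
    if stim:
        if t >= p[1]:
            u1 = 1.0 + (p[0] - 1.0) * math.exp(-p[2] * (t - p[1]))
        if t >= p[4]:
            u2 = 1.0 + (p[3] - 1.0) * math.exp(-p[5] * (t - p[4]))
    xR = y[0] if y[0] > 0.0 else 0.0
    xP = y[1] if y[1] > 0.0 else 0.0
    out[0] = p[6] * _p(u1, p[7]) * _p(xP, p[8]) * (p[11] - y[0]) - p[10] * _p(xR, p[9])
    out[1] = p[12] * _p(u2, p[13]) - p[15] * _p(xP, p[14])
    k1, g1, h1 = p[16], p[17], p[18]
    k2, g2, h2 = p[19], p[20], p[21]
    k3, g3, h3 = p[22], p[23], p[24]
    k4, g4, h4 = p[25], p[26], p[27]
    k5, g5, h5 = p[28], p[29], p[30]
    k12, g12 = p[31], p[32]
    k6, g6, h6 = p[33], p[34], p[35]
    k13, g13 = p[36], p[37]
    aR = k1 * _p(xR, g1)
    aP = k4 * _p(xP, g4)
    n = T.shape[0]
    for c in range(n):
        b = 2 + 6 * c
        m = y[b] if y[b] > 0.0 else 0.0
        e = y[b + 1] if y[b + 1] > 0.0 else 0.0
        r = y[b + 2] if y[b + 2] > 0.0 else 0.0
        a = y[b + 3] if y[b + 3] > 0.0 else 0.0
        g = y[b + 4] if y[b + 4] > 0.0 else 0.0
        s = y[b + 5] if y[b + 5] > 0.0 else 0.0
        out[b] = aR * (T[c, 0] - y[b]) - gam[c, 0] * _p(m, h1)
        out[b + 1] = k2 * _p(m, g2) * (T[c, 1] - y[b + 1]) - gam[c, 1] * _p(e, h2)
        out[b + 2] = k3 * _p(e, g3) * (T[c, 2] - y[b + 2]) - gam[c, 2] * _p(r, h3)
        out[b + 3] = aP * (T[c, 3] - y[b + 3]) - gam[c, 3] * _p(a, h4)
        out[b + 4] = (k5 * _p(a, g5) + k12 * _p(r, g12)) * (T[c, 4] - y[b + 4]) - gam[
            c, 4
        ] * _p(g, h5)
        out[b + 5] = (k6 * _p(r, g6) + k13 * _p(a, g13)) * (T[c, 5] - y[b + 5]) - gam[
            c, 5
        ] * _p(s, h6)


@njit(cache=True)
def integrate_ensemble(y0, t_stops, record, p, T, gam, stim, rtol, atol, max_steps,
                       A, B, C, E):
    """Adaptive DOPRI5 from t=0 over the sorted positive ``t_stops``.

    The integrator steps exactly onto every stop; a state row is emitted for
    stops flagged in ``record`` (the others are break points, e.g. the input
    onset delays, where the RHS has a kink).  Returns (states, status, n_rhs);
    status 0 = success, 1 = step-count/step-size failure (caller falls back).
    """
    ny = y0.size
    n_rec = int(record.sum())
    states = np.empty((n_rec, ny))
    K = np.empty((7, ny))
    y = y0.copy()
    ynew = np.empty(ny)
    t = 0.0
    h = 1e-2
    n_rhs = 1
    _rhs(t, y, K[0], p, T, gam, stim)  # FSAL seed
    i_eval = 0
    i_rec = 0
    n_eval = t_stops.size
    t_end = t_stops[n_eval - 1]
    steps = 0
    while i_eval < n_eval:
        if steps >= max_steps:
            return states, 1, n_rhs
        t_target = t_stops[i_eval]
        if h > t_target - t:
            h = t_target - t
        if h < 1e-12 * max(t_end, 1.0):
            return states, 1, n_rhs
        # stages 1..6 (stage 0 is FSAL from the previous step)
        for s in range(1, 7):
            for j in range(ny):
                acc = 0.0
                for q in range(s):
                    aq = A[s, q]
                    if aq != 0.0:
                        acc += aq * K[q, j]
                ynew[j] = y[j] + h * acc
            _rhs(t + C[s] * h, ynew, K[s], p, T, gam, stim)
            n_rhs += 1
        # 5th-order solution is the last stage evaluation point (FSAL):
        # ynew currently holds y + h * sum(B*K) from stage 6 construction
        # error estimate
        err = 0.0
        ok = True
        for j in range(ny):
            e_j = 0.0
            for q in range(7):
                eq = E[q]
                if eq != 0.0:
                    e_j += eq * K[q, j]
            e_j *= h
            ay = abs(y[j])
            ayn = abs(ynew[j])
            sc = atol[j] + rtol * (ay if ay > ayn else ayn)
            w = e_j / sc
            err += w * w
            if not np.isfinite(ynew[j]):
                ok = False
        err = math.sqrt(err / ny)
        steps += 1
        if ok and np.isfinite(err) and err <= 1.0:
            t = t + h
            for j in range(ny):
                y[j] = ynew[j]
                K[0, j] = K[6, j]  # FSAL
            if t >= t_target - 1e-14 * max(t_target, 1.0):
                if record[i_eval]:
                    states[i_rec] = y
                    i_rec += 1
                i_eval += 1
                # restart the FSAL derivative after a potential RHS kink
                _rhs(t, y, K[0], p, T, gam, stim)
                n_rhs += 1
            # grow step
            if err == 0.0:
                fac = 10.0
            else:
                fac = 0.9 * err ** (-0.2)
                if fac > 10.0:
                    fac = 10.0
            h = h * fac
        else:
            if ok and np.isfinite(err):
                fac = 0.9 * err ** (-0.2)
                if fac < 0.2:
                    fac = 0.2
            else:
                fac = 0.2
            h = h * fac
    return states, 0, n_rhs


def simulate_compiled(y0, t_eval, p, T, gam, stim, rtol, atol, max_steps=20000):
    """Python-facing wrapper: adds input-onset break points, passes tableau."""
    t_eval = np.ascontiguousarray(t_eval, dtype=np.float64)
    t_end = float(t_eval[-1])
    stops = list(t_eval)
    if stim:
        # step exactly onto the delay onsets so the RHS is smooth per segment
        for tau in (p[1], p[4]):
            if 0.0 < tau < t_end and not np.any(np.isclose(np.array(stops), tau)):
                stops.append(float(tau))
    order = np.argsort(stops, kind="stable")
    t_stops = np.array(stops, dtype=np.float64)[order]
    record = np.array([i < len(t_eval) for i in order], dtype=np.bool_)
    states, status, n_rhs = integrate_ensemble(
        np.ascontiguousarray(y0, dtype=np.float64),
        t_stops,
        record,
        np.ascontiguousarray(p, dtype=np.float64),
        np.ascontiguousarray(T, dtype=np.float64),
        np.ascontiguousarray(gam, dtype=np.float64),
        bool(stim),
        float(rtol),
        np.ascontiguousarray(atol, dtype=np.float64),
        int(max_steps),
        _A, _B, _C, _E,
    )
    return states, status, n_rhs
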