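"""Compiled numerical kernels (forward Euler integration + sensitivities).

All kernels operate on pre-assembled per-step tracks:

  psi    (T, n, n)  total excitatory connectivity, diagonal included
  psim   (T, n)     diagonal of the inhibitory->excitatory matrix (negative)
  cgain  (T, n)     diagonal of the inhibitory-gain matrix (positive)
  drive  (T, n)     C @ U_d(t), the injected driving input per region

State layout is a (6, n) array ordered (x_E, x_I, a, f, v, q); the
resting point is x_E = x_I = a = 0, f = v = q = 1.  At each step all six
states are advanced synchronously from time-t values; the BOLD signal at
a sample is computed from (v, q) at that sample.

The gradient kernel propagates forward sensitivities of every state with
respect to a set of free parameters.  Each parameter j perturbs either a
single entry of psi (kind 0: row/col = target/source, time weight
``w[j, t]``, so w == 1 for a baseline strength and w == u_m(t) for a
modulatory weight) or a single row of the drive (kind 1).

Status convention: kernels return a status integer, -1 for success or
the offending step index when the trajectory leaves the valid domain
(non-finite, |x| exploding, or f/v/q <= 0).
"""

import numpy as np
from numba import njit

_BIG = 1e8

P_KIND_PSI = 0
P_KIND_DRIVE = 1


@njit(cache=True)
def simulate_core(psi, psim, cgain, drive, dt,
                  phi_d, phi_g, chi, tmtt, tau, alpha, e0,
                  v0, k1, k2, k3, init):
    """Integrate T Euler steps; return (states (T+1,6,n), y (T+1,n), status)."""
    T = psi.shape[0]
    n = psi.shape[1]
    states = np.empty((T + 1, 6, n))
    y = np.empty((T + 1, n))
    s = init.copy()
    status = -1
    for t in range(T + 1):
        for i in range(n):
            v = s[4, i]
            q = s[5, i]
            f = s[3, i]
            if not (np.isfinite(v) and np.isfinite(q) and np.isfinite(f)):
                status = t
                break
            if v <= 0.0 or q <= 0.0 or f <= 0.0 or abs(s[0, i]) > _BIG:
                status = t
                break
            y[t, i] = v0[i] * (k1[i] * (1.0 - q) + k2[i] * (1.0 - q / v)
                               + k3[i] * (1.0 - v))
        if status >= 0:
            break
        states[t] = s
        if t == T:
            break
        new = np.empty((6, n))
        for i in range(n):
            acc = 0.0
            for j in range(n):
                acc += psi[t, i, j] * s[0, j]
            new[0, i] = s[0, i] + dt * acc + dt * psim[t, i] * s[1, i] + dt * drive[t, i]
            new[1, i] = dt * cgain[t, i] * s[0, i] + (1.0 - dt * cgain[t, i]) * s[1, i]
            new[2, i] = (1.0 - phi_d[i] * dt) * s[2, i] + dt * s[0, i]
            new[3, i] = phi_g[i] * dt * s[2, i] + (1.0 - chi[i] * dt) * s[3, i] + chi[i] * dt
            f = s[3, i]
            v = s[4, i]
            q = s[5, i]
            fout = (tmtt[i] * v ** (1.0 / alpha[i]) + tau[i] * f) / (tau[i] + tmtt[i])
            E = 1.0 - (1.0 - e0[i]) ** (1.0 / f)
            new[4, i] = v + dt * (f - fout) / tmtt[i]
            new[5, i] = q * (1.0 - dt * fout / (tmtt[i] * v)) + dt * f * E / (tmtt[i] * e0[i])
        s = new
    return states, y, status


@njit(cache=True)
def loss_core(psi0, psim, cgain, drive0, p, p_kind, p_row, p_col, p_w, dt,
              phi_d, phi_g, chi, tmtt, tau, alpha, e0,
              v0, k1, k2, k3, init, obs):
    """Sum-of-squares BOLD loss over a window of len(obs) samples.

    psi0/drive0 are the fixed parts; free parameters p are added at use
    time via (p_kind, p_row, p_col, p_w).  Divergence returns inf.
    """
    T = obs.shape[0]
    n = psi0.shape[1]
    P = p.shape[0]
    s = init.copy()
    loss = 0.0
    for t in range(T):
        for i in range(n):
            v = s[4, i]
            q = s[5, i]
            if not (np.isfinite(v) and np.isfinite(q)):
                return np.inf
            if v <= 0.0 or q <= 0.0 or s[3, i] <= 0.0 or abs(s[0, i]) > _BIG:
                return np.inf
            yy = v0[i] * (k1[i] * (1.0 - q) + k2[i] * (1.0 - q / v) + k3[i] * (1.0 - v))
            r = yy - obs[t, i]
            loss += r * r
        if t == T - 1:
            break
        new = np.empty((6, n))
        for i in range(n):
            acc = drive0[t, i]
            for j in range(n):
                acc_psi = psi0[t, i, j]
                acc += acc_psi * s[0, j]
            new[0, i] = s[0, i] + dt * acc + dt * psim[t, i] * s[1, i]
        for jp in range(P):
            w = p_w[jp, t]
            if w != 0.0:
                if p_kind[jp] == 0:
                    new[0, p_row[jp]] += dt * p[jp] * w * s[0, p_col[jp]]
                else:
                    new[0, p_row[jp]] += dt * p[jp] * w
        for i in range(n):
            new[1, i] = dt * cgain[t, i] * s[0, i] + (1.0 - dt * cgain[t, i]) * s[1, i]
            new[2, i] = (1.0 - phi_d[i] * dt) * s[2, i] + dt * s[0, i]
            new[3, i] = phi_g[i] * dt * s[2, i] + (1.0 - chi[i] * dt) * s[3, i] + chi[i] * dt
            f = s[3, i]
            v = s[4, i]
            q = s[5, i]
            fout = (tmtt[i] * v ** (1.0 / alpha[i]) + tau[i] * f) / (tau[i] + tmtt[i])
            E = 1.0 - (1.0 - e0[i]) ** (1.0 / f)
            new[4, i] = v + dt * (f - fout) / tmtt[i]
            new[5, i] = q * (1.0 - dt * fout / (tmtt[i] * v)) + dt * f * E / (tmtt[i] * e0[i])
        s = new
    return loss


@njit(cache=True)
def loss_grad_core(psi0, psim, cgain, drive0, p, p_kind, p_row, p_col, p_w, dt,
                   phi_d, phi_g, chi, tmtt, tau, alpha, e0,
                   v0, k1, k2, k3, init, obs):
    """Loss and its gradient w.r.t. p by forward sensitivity propagation.

    Returns (loss, grad, status); on divergence loss is inf, grad zeros
    and status the offending step.
    """
    T = obs.shape[0]
    n = psi0.shape[1]
    P = p.shape[0]
    s = init.copy()
    # sensitivities d(state)/d(p_j): (P, 6, n), zero at window start (the
    # initial state is a datum handed over from the previous window).
    sens = np.zeros((P, 6, n))
    grad = np.zeros(P)
    loss = 0.0
    for t in range(T):
        for i in range(n):
            v = s[4, i]
            q = s[5, i]
            if not (np.isfinite(v) and np.isfinite(q)):
                return np.inf, np.zeros(P), t
            if v <= 0.0 or q <= 0.0 or s[3, i] <= 0.0 or abs(s[0, i]) > _BIG:
                return np.inf, np.zeros(P), t
            yy = v0[i] * (k1[i] * (1.0 - q) + k2[i] * (1.0 - q / v) + k3[i] * (1.0 - v))
            r = yy - obs[t, i]
            loss += r * r
            for jp in range(P):
                sv = sens[jp, 4, i]
                sq = sens[jp, 5, i]
                sy = v0[i] * (-k1[i] * sq - k2[i] * (sq / v - q * sv / (v * v))
                              - k3[i] * sv)
                grad[jp] += 2.0 * r * sy
        if t == T - 1:
            break
        new = np.empty((6, n))
        new_sens = np.empty((P, 6, n))
        # state update (identical to loss_core)
        for i in range(n):
            acc = drive0[t, i]
            for j in range(n):
                acc += psi0[t, i, j] * s[0, j]
            new[0, i] = s[0, i] + dt * acc + dt * psim[t, i] * s[1, i]
        for jp in range(P):
            w = p_w[jp, t]
            if w != 0.0:
                if p_kind[jp] == 0:
                    new[0, p_row[jp]] += dt * p[jp] * w * s[0, p_col[jp]]
                else:
                    new[0, p_row[jp]] += dt * p[jp] * w
        for i in range(n):
            new[1, i] = dt * cgain[t, i] * s[0, i] + (1.0 - dt * cgain[t, i]) * s[1, i]
            new[2, i] = (1.0 - phi_d[i] * dt) * s[2, i] + dt * s[0, i]
            new[3, i] = phi_g[i] * dt * s[2, i] + (1.0 - chi[i] * dt) * s[3, i] + chi[i] * dt
        # sensitivity update: x_E depends on psi (incl. free entries), x_I, drive
        for jp in range(P):
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += psi0[t, i, j] * sens[jp, 0, j]
                new_sens[jp, 0, i] = (sens[jp, 0, i] + dt * acc
                                      + dt * psim[t, i] * sens[jp, 1, i])
            # free-parameter contributions to d(x_E')/dp: both the direct
            # d(psi)/dp term and the p * d(x_E)/dp term of the free entry
            w = p_w[jp, t]
            for jq in range(P):
                wq = p_w[jq, t]
                if wq != 0.0 and p_kind[jq] == 0:
                    new_sens[jp, 0, p_row[jq]] += dt * p[jq] * wq * sens[jp, 0, p_col[jq]]
            if w != 0.0 and p_kind[jp] == 0:
                new_sens[jp, 0, p_row[jp]] += dt * w * s[0, p_col[jp]]
            elif w != 0.0 and p_kind[jp] == 1:
                new_sens[jp, 0, p_row[jp]] += dt * w
            for i in range(n):
                new_sens[jp, 1, i] = (dt * cgain[t, i] * sens[jp, 0, i]
                                      + (1.0 - dt * cgain[t, i]) * sens[jp, 1, i])
                new_sens[jp, 2, i] = (1.0 - phi_d[i] * dt) * sens[jp, 2, i] + dt * sens[jp, 0, i]
                new_sens[jp, 3, i] = (phi_g[i] * dt * sens[jp, 2, i]
                                      + (1.0 - chi[i] * dt) * sens[jp, 3, i])
        # hemodynamics (state + sensitivities share the partials)
        for i in range(n):
            f = s[3, i]
            v = s[4, i]
            q = s[5, i]
            ia = 1.0 / alpha[i]
            via = v ** ia
            fout = (tmtt[i] * via + tau[i] * f) / (tau[i] + tmtt[i])
            dfo_dv = tmtt[i] * ia * v ** (ia - 1.0) / (tau[i] + tmtt[i])
            dfo_df = tau[i] / (tau[i] + tmtt[i])
            one_me0 = 1.0 - e0[i]
            E = 1.0 - one_me0 ** (1.0 / f)
            dE_df = one_me0 ** (1.0 / f) * np.log(one_me0) / (f * f)
            new[4, i] = v + dt * (f - fout) / tmtt[i]
            new[5, i] = (q * (1.0 - dt * fout / (tmtt[i] * v))
                         + dt * f * E / (tmtt[i] * e0[i]))
            for jp in range(P):
                sf = sens[jp, 3, i]
                sv = sens[jp, 4, i]
                sq = sens[jp, 5, i]
                new_sens[jp, 4, i] = sv + dt * (sf - dfo_dv * sv - dfo_df * sf) / tmtt[i]
                new_sens[jp, 5, i] = (
                    (1.0 - dt * fout / (tmtt[i] * v)) * sq
                    - q * dt / tmtt[i] * ((dfo_dv / v - fout / (v * v)) * sv
                                          + dfo_df / v * sf)
                    + dt * (E + f * dE_df) / (tmtt[i] * e0[i]) * sf)
        s = new
        sens = new_sens
    return loss, grad, -1


@njit(cache=True)
def window_predict_core(psi0, psim, cgain, drive0, p, p_kind, p_row, p_col, p_w, dt,
                        phi_d, phi_g, chi, tmtt, tau, alpha, e0,
                        v0, k1, k2, k3, init, T):
    """Simulate a fitted window: states (T,6,n) and BOLD y (T,n)."""
    n = psi0.shape[1]
    P = p.shape[0]
    states = np.empty((T, 6, n))
    y = np.empty((T, n))
    s = init.copy()
    status = -1
    for t in range(T):
        for i in range(n):
            v = s[4, i]
            q = s[5, i]
            if not (np.isfinite(v) and np.isfinite(q)) or v <= 0.0 or q <= 0.0 \
                    or s[3, i] <= 0.0 or abs(s[0, i]) > _BIG:
                status = t
                return states, y, status
            y[t, i] = v0[i] * (k1[i] * (1.0 - q) + k2[i] * (1.0 - q / v)
                               + k3[i] * (1.0 - v))
        states[t] = s
        if t == T - 1:
            break
        new = np.empty((6, n))
        for i in range(n):
            acc = drive0[t, i]
            for j in range(n):
                acc += psi0[t, i, j] * s[0, j]
            new[0, i] = s[0, i] + dt * acc + dt * psim[t, i] * s[1, i]
        for jp in range(P):
            w = p_w[jp, t]
            if w != 0.0:
                if p_kind[jp] == 0:
                    new[0, p_row[jp]] += dt * p[jp] * w * s[0, p_col[jp]]
                else:
                    new[0, p_row[jp]] += dt * p[jp] * w
        for i in range(n):
            new[1, i] = dt * cgain[t, i] * s[0, i] + (1.0 - dt * cgain[t, i]) * s[1, i]
            new[2, i] = (1.0 - phi_d[i] * dt) * s[2, i] + dt * s[0, i]
            new[3, i] = phi_g[i] * dt * s[2, i] + (1.0 - chi[i] * dt) * s[3, i] + chi[i] * dt
            f = s[3, i]
            v = s[4, i]
            q = s[5, i]
            fout = (tmtt[i] * v ** (1.0 / alpha[i]) + tau[i] * f) / (tau[i] + tmtt[i])
            E = 1.0 - (1.0 - e0[i]) ** (1.0 / f)
            new[4, i] = v + dt * (f - fout) / tmtt[i]
            new[5, i] = q * (1.0 - dt * fout / (tmtt[i] * v)) + dt * f * E / (tmtt[i] * e0[i])
        s = new
    return states, y, status
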