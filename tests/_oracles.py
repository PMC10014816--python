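"""Independent oracles used by the test suite.

These implementations deliberately avoid the package's compiled kernels:
the continuous-time reference integrates the (non-discretized) system of
differential equations with an adaptive high-order Runge-Kutta solver,
and the grid search minimizes the window loss by brute force.
"""

import numpy as np
from scipy.integrate import solve_ivp


def continuous_bold_oracle(model, profiles, u_fn, t_eval, rtol=1e-10, atol=1e-12):
    """High-accuracy BOLD trajectory of the continuous-time system.

    ``profiles`` maps (source, target) edges to callables A_ij(t);
    ``u_fn`` maps t to the vector of driving inputs.  Returns y with
    shape (len(t_eval), n_regions).
    """
    n = model.n_regions
    pa = model.physio_arrays()
    k1, k2, k3 = model.bold_constants()
    C = np.zeros((n, model.stimuli.driving.shape[0]))
    for (r, j), c in model.graph.driving_map.items():
        C[r, j] = c
    sig, mu, lam = pa["sigma"], pa["mu"], pa["lambda_"]
    phi_d, phi_g, chi = pa["phi_decay"], pa["phi_gain"], pa["chi"]
    tm, tau, al, e0 = pa["t_mtt"], pa["tau"], pa["alpha"], pa["e0"]

    def a_mat(t):
        A = np.zeros((n, n))
        for (s, tt), fn in profiles.items():
            A[tt, s] = float(np.asarray(fn(t)))
        for (s, tt), a0 in model.graph.edges.items():
            if (s, tt) not in profiles:
                A[tt, s] = a0
        return A

    def rhs(t, z):
        x_e, x_i, a, f, v, q = z.reshape(6, n)
        f = np.maximum(f, 1e-9)
        v = np.maximum(v, 1e-9)
        psi = a_mat(t) - np.diag(sig)
        dxe = psi @ x_e - mu * x_i + C @ u_fn(t)
        dxi = lam * (x_e - x_i)
        da = -phi_d * a + x_e
        df = phi_g * a - chi * (f - 1.0)
        fout = (tm * v ** (1.0 / al) + tau * f) / (tau + tm)
        E = 1.0 - (1.0 - e0) ** (1.0 / f)
        dv = (f - fout) / tm
        dq = (f * E / e0 - fout * q / v) / tm
        return np.concatenate([dxe, dxi, da, df, dv, dq])

    z0 = np.concatenate([np.zeros(3 * n), np.ones(3 * n)])
    sol = solve_ivp(rhs, (float(t_eval[0]), float(t_eval[-1])), z0,
                    method="DOP853", rtol=rtol, atol=atol, dense_output=True)
    assert sol.success, sol.message
    out = np.empty((len(t_eval), n))
    v0 = pa["v0"]
    for i, t in enumerate(t_eval):
        z = sol.sol(t).reshape(6, n)
        v, q = z[4], z[5]
        out[i] = v0 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
    return out


def grid_search_edge(loss_fn, lo=-1.0, hi=1.0, num=4001):
    """Brute-force 1-D minimizer of a single-edge window loss."""
    grid = np.linspace(lo, hi, num)
    losses = np.array([loss_fn(np.array([g])) for g in grid])
    k = int(np.argmin(losses))
    return grid[k], losses[k], (hi - lo) / (num - 1)
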