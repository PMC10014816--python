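"""Forward simulation of the discretized generative model.

The generative chain per region is

  neuronal (two-state excitatory/inhibitory populations)
    -> neurovascular coupling (vasoactive signal a, inflow f)
    -> viscoelastic venous balloon (volume v, deoxyhemoglobin q)
    -> BOLD signal y(v, q)

integrated with the forward Euler scheme on a uniform dt grid.  The
scalar single-region update functions here are the readable reference
forms; :func:`simulate` delegates the full multi-region integration to
the compiled kernels in :mod:`dpdcm._core`.  Matrix-assembled update
forms (`neuronal_transition_matrix`, `hemo_matrix_step`,
`bold_affine`) are provided so the two routes can be cross-checked.

BOLD output is kept as a *fraction* of baseline signal throughout;
multiply by 100 for percent signal change (the metadata of every
trajectory states this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _core
from .model import ModelSpec, PhysioParams, StimulusSet

__all__ = [
    "ConnectivityMatrices",
    "TrajectoryBundle",
    "SimulationDivergence",
    "assemble_connectivity",
    "assemble_tracks",
    "step_neuronal",
    "step_nvc",
    "oxygen_extraction",
    "blood_outflow",
    "step_hemodynamics",
    "hemo_matrix_step",
    "bold_signal",
    "bold_affine",
    "neuronal_transition_matrix",
    "simulate",
    "sample_observations",
]


class SimulationDivergence(RuntimeError):
    """The trajectory left the valid state domain; carries the step index."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"trajectory diverged at step {step}")


@dataclass(frozen=True)
class ConnectivityMatrices:
    """Instantaneous connectivity assembly.

    psi   (n, n): total excitatory coupling, strictly negative diagonal
    psim  (n, n): inhibitory->excitatory coupling, diagonal (negative)
    cgain (n, n): inhibitory gain, diagonal (positive)
    input_weights (n, n_driving): effective C matrix
    """

    psi: np.ndarray
    psi_minus: np.ndarray
    c_mat: np.ndarray
    input_weights: np.ndarray


def assemble_connectivity(
    model: ModelSpec,
    a_now: Mapping[tuple[int, int], float],
    inputs_at_t: Mapping[str, np.ndarray] | None = None,
) -> ConnectivityMatrices:
    """Assemble the connectivity matrices at one instant.

    ``a_now`` assigns a strength to every edge of the graph (0-based
    (source, target) keys).  ``inputs_at_t`` optionally gives the
    instantaneous modulatory / context input values under keys
    "modulatory", "mu", "lambda" (vectors over input indices; absent
    keys mean all-zero inputs).
    """
    g = model.graph
    n = g.n_regions
    inputs_at_t = inputs_at_t or {}
    u_mod = np.asarray(inputs_at_t.get("modulatory", np.zeros(0)), dtype=float)
    u_mu = np.asarray(inputs_at_t.get("mu", np.zeros(0)), dtype=float)
    u_lam = np.asarray(inputs_at_t.get("lambda", np.zeros(0)), dtype=float)

    psi = np.zeros((n, n))
    for (s, t) in g.edge_list:
        if (s, t) not in a_now:
            raise KeyError(f"no strength assigned to edge ({s + 1},{t + 1})")
        psi[t, s] = a_now[(s, t)]
    for (s, t, m), b in g.modulatory_edges.items():
        psi[t, s] += b * u_mod[m]

    psim = np.zeros((n, n))
    cgain = np.zeros((n, n))
    for i, p in enumerate(model.params):
        sm = sum(b * u_mod[m] for (r, m), b in g.self_mod.items() if r == i)
        mm = sum(b * u_mu[k] for (r, k), b in g.inhibitory_mu_mod.items() if r == i)
        lm = sum(b * u_lam[l] for (r, l), b in g.inhibitory_lambda_mod.items() if r == i)
        psi[i, i] = -p.sigma * np.exp(p.sigma_tilde + sm)
        psim[i, i] = -p.mu * np.exp(p.mu_tilde + mm)
        cgain[i, i] = p.lambda_ * np.exp(p.lambda_tilde + lm)

    n_drv = model.stimuli.driving.shape[0]
    C = np.zeros((n, n_drv))
    for (r, j), c in g.driving_map.items():
        C[r, j] = c
    out = ConnectivityMatrices(psi=psi, psi_minus=psim, c_mat=cgain, input_weights=C)
    if not (np.all(np.isfinite(psi)) and np.all(np.isfinite(psim))):
        raise FloatingPointError("non-finite connectivity assembly")
    return out


# ---------------------------------------------------------------------------
# Scalar / single-step reference forms


def step_neuronal(x_e: np.ndarray, x_i: np.ndarray, mats: ConnectivityMatrices,
                  u_d: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of the two-state neuronal subsystem (affine update)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    psi, psim, cg = mats.psi, mats.psi_minus, mats.c_mat
    x_e_new = x_e + dt * (psi @ x_e) + dt * (psim @ x_i) + dt * (mats.input_weights @ u_d)
    x_i_new = dt * (cg @ x_e) + x_i - dt * (cg @ x_i)
    if not np.all(np.isfinite(x_e_new)):
        raise SimulationDivergence(0, "non-finite neuronal update")
    return x_e_new, x_i_new


def neuronal_transition_matrix(mats: ConnectivityMatrices, dt: float) -> np.ndarray:
    """The (2n x 2n) one-step update matrix of the stacked neuronal state."""
    n = mats.psi.shape[0]
    eye = np.eye(n)
    top = np.hstack([eye + dt * mats.psi, dt * mats.psi_minus])
    bot = np.hstack([dt * mats.c_mat, eye - dt * mats.c_mat])
    return np.vstack([top, bot])


def step_nvc(a: np.ndarray, f: np.ndarray, x_e: np.ndarray,
             params: PhysioParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Vasoactive signal and inflow update (feed-forward coupling)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a_new = (1.0 - params.phi_decay * dt) * a + dt * x_e
    f_new = params.phi_gain * dt * a + (1.0 - params.chi * dt) * f + params.chi * dt
    return a_new, f_new


def oxygen_extraction(f, e0: float):
    """Flow-dependent oxygen extraction fraction E(f) = 1 - (1-E0)^(1/f)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("inflow f must be > 0")
    if not 0 < e0 < 1:
        raise ValueError("e0 must be in (0, 1)")
    return 1.0 - (1.0 - e0) ** (1.0 / f)


def blood_outflow(v, f, params: PhysioParams):
    """Venous outflow of the viscoelastic balloon.

    f_out = (t_mtt * v^(1/alpha) + tau * f) / (tau + t_mtt); with tau = 0
    this collapses to the steady-state power law v^(1/alpha).
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume v must be > 0")
    return (params.t_mtt * v ** (1.0 / params.alpha) + params.tau * np.asarray(f)) \
        / (params.tau + params.t_mtt)


def step_hemodynamics(f: np.ndarray, v: np.ndarray, q: np.ndarray,
                      params: PhysioParams, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Volume and deoxyhemoglobin update (mass balance of the balloon)."""
    fout = blood_outflow(v, f, params)
    E = oxygen_extraction(f, params.e0)
    v_new = v + dt * (f - fout) / params.t_mtt
    q_new = q * (1.0 - dt * fout / (params.t_mtt * v)) \
        + dt * f * E / (params.t_mtt * params.e0)
    return v_new, q_new


def hemo_matrix_step(a, f, v, q, x_e, params: PhysioParams, dt: float):
    """Matrix form of the joint (a, f, v, q) update: W_H @ theta_H + W_HX x_E + omega_H.

    theta_H stacks [a, f, v, q, v^(1/alpha), q v^(1/alpha)/v, q f / v,
    (1 - (1-E0)^(1/f))/E0 * f]; equivalent to step_nvc + step_hemodynamics.
    """
    tm, tau, al, e0 = params.t_mtt, params.tau, params.alpha, params.e0
    theta = np.array([
        a, f, v, q,
        v ** (1.0 / al),
        q * v ** (1.0 / al) / v,
        q * f / v,
        (1.0 - (1.0 - e0) ** (1.0 / f)) / e0 * f,
    ])
    W = np.array([
        [1 - params.phi_decay * dt, 0, 0, 0, 0, 0, 0, 0],
        [params.phi_gain * dt, 1 - params.chi * dt, 0, 0, 0, 0, 0, 0],
        [0, dt / tm - tau * dt / ((tau + tm) * tm), 1, 0,
         -dt / (tau + tm), 0, 0, 0],
        [0, 0, 0, 1, 0, -tm * dt / (tm * (tau + tm)),
         -tau * dt / (tm * (tau + tm)), dt / tm],
    ])
    w_hx = np.array([dt, 0.0, 0.0, 0.0])
    omega = np.array([0.0, params.chi * dt, 0.0, 0.0])
    return W @ theta + w_hx * x_e + omega


def bold_signal(v, q, k, v0: float):
    """BOLD signal y = V0 [k1 (1-q) + k2 (1 - q/v) + k3 (1-v)] (fractional)."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume v must be > 0")
    return v0 * (k.k1 * (1.0 - q) + k.k2 * (1.0 - q / v) + k.k3 * (1.0 - v))


def bold_affine(v, q, k, v0: float):
    """Affine form: W_BOLD @ [q, q/v, v] + V0 (k1 + k2 + k3)."""
    w = np.array([-v0 * k.k1, -v0 * k.k2, -v0 * k.k3])
    theta = np.array([q, q / v, v])
    return w @ theta + v0 * (k.k1 + k.k2 + k.k3)


# ---------------------------------------------------------------------------
# Full trajectory integration


@dataclass(frozen=True)
class TrajectoryBundle:
    """Latent state and BOLD time courses on a uniform dt grid.

    All state arrays have shape (n_samples, n_regions).  ``y`` is the
    fractional BOLD signal (metadata key "bold_units").
    """

    dt: float
    x_e: np.ndarray
    x_i: np.ndarray
    a: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.y.shape[0]) * self.dt

    @property
    def n_regions(self) -> int:
        return self.y.shape[1]

    def to_frame(self):
        """Wide DataFrame: time, then y.Rk and state columns per region."""
        import pandas as pd

        data = {"time": self.time}
        for name, arr in (("y", self.y), ("xE", self.x_e), ("xI", self.x_i),
                          ("a", self.a), ("f", self.f), ("v", self.v), ("q", self.q)):
            for r in range(self.n_regions):
                data[f"{name}.R{r + 1}"] = arr[:, r]
        return pd.DataFrame(data)


def _diag_tracks(model: ModelSpec, stimuli: StimulusSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time tracks of the three diagonal terms, shape (n_samples, n)."""
    g = model.graph
    n = g.n_regions
    L = stimuli.n_samples
    sm = np.zeros((L, n))
    mm = np.zeros((L, n))
    lm = np.zeros((L, n))
    for (r, m), b in g.self_mod.items():
        sm[:, r] += b * stimuli.modulatory[m]
    for (r, k), b in g.inhibitory_mu_mod.items():
        mm[:, r] += b * stimuli.mu_context[k]
    for (r, l), b in g.inhibitory_lambda_mod.items():
        lm[:, r] += b * stimuli.lambda_context[l]
    pa = model.physio_arrays()
    psi_d = -pa["sigma"] * np.exp(pa["sigma_tilde"] + sm)
    psim_d = -pa["mu"] * np.exp(pa["mu_tilde"] + mm)
    cg_d = pa["lambda_"] * np.exp(pa["lambda_tilde"] + lm)
    return psi_d, psim_d, cg_d


def assemble_tracks(
    model: ModelSpec,
    stimuli: StimulusSet,
    conn_track: Mapping[tuple[int, int], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample connectivity and drive tracks for the compiled kernels.

    Returns (psi (L,n,n), psim (L,n), cgain (L,n), drive (L,n)).  Edge
    strengths come from ``conn_track`` (arrays of length L) where given,
    else from the static baseline A; modulatory B*u(t) terms are always
    added on top.
    """
    g = model.graph
    n = g.n_regions
    L = stimuli.n_samples
    psi_d, psim_d, cg_d = _diag_tracks(model, stimuli)
    psi = np.zeros((L, n, n))
    for (s, t) in g.edge_list:
        base = g.edges.get((s, t), 0.0)
        if conn_track and (s, t) in conn_track:
            track = np.asarray(conn_track[(s, t)], dtype=float)
            if track.shape != (L,):
                raise ValueError(
                    f"connectivity track for edge ({s + 1},{t + 1}) has length "
                    f"{track.shape[0]}; grid has {L} samples")
            psi[:, t, s] = track
        else:
            psi[:, t, s] = base
    for (s, t, m), b in g.modulatory_edges.items():
        psi[:, t, s] += b * stimuli.modulatory[m]
    idx = np.arange(n)
    psi[:, idx, idx] = psi_d

    C = np.zeros((n, stimuli.driving.shape[0]))
    for (r, j), c in g.driving_map.items():
        C[r, j] = c
    drive = stimuli.driving.T @ C.T  # (L, n)
    return psi, psim_d, cg_d, drive


def _rest_state(n: int) -> np.ndarray:
    init = np.zeros((6, n))
    init[3:6] = 1.0
    return init


def simulate(
    model: ModelSpec,
    stimuli: StimulusSet | None = None,
    conn_track: Mapping[tuple[int, int], np.ndarray] | None = None,
    init_state: np.ndarray | None = None,
) -> TrajectoryBundle:
    """Integrate the full generative model from rest.

    ``conn_track`` optionally supplies time-varying strengths per edge on
    the stimulus grid.  Raises :class:`SimulationDivergence` with the
    offending step index if the state leaves its valid domain; states are
    never clipped silently.
    """
    stimuli = stimuli if stimuli is not None else model.stimuli
    stimuli.check()
    n = model.n_regions
    psi, psim, cg, drive = assemble_tracks(model, stimuli, conn_track)
    pa = model.physio_arrays()
    k1, k2, k3 = model.bold_constants()
    init = _rest_state(n) if init_state is None else np.asarray(init_state, dtype=float)
    states, y, status = _core.simulate_core(
        psi[:-1], psim[:-1], cg[:-1], drive[:-1], stimuli.dt,
        pa["phi_decay"], pa["phi_gain"], pa["chi"], pa["t_mtt"], pa["tau"],
        pa["alpha"], pa["e0"], pa["v0"], k1, k2, k3, init)
    if status >= 0:
        raise SimulationDivergence(
            status, f"trajectory diverged at step {status} "
                    f"(t = {status * stimuli.dt:.4f} s)")
    return TrajectoryBundle(
        dt=stimuli.dt,
        x_e=states[:, 0], x_i=states[:, 1], a=states[:, 2],
        f=states[:, 3], v=states[:, 4], q=states[:, 5], y=y,
        meta={"bold_units": "fraction", "dt": stimuli.dt},
    )


def sample_observations(traj: TrajectoryBundle, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the BOLD output at the acquisition repetition time.

    Samples at t = 0, TR, 2 TR, ...; when TR is an integer multiple of dt
    this is exact index selection, otherwise the nearest grid point is
    taken (round-half-up via floor(x + 0.5)).
    Returns (sample times on the acquisition clock, y at those samples).
    """
    if tr < traj.dt:
        raise ValueError(f"TR ({tr} s) must be >= the simulation step ({traj.dt} s)")
    L = traj.y.shape[0]
    t_end = (L - 1) * traj.dt
    times = np.arange(0.0, t_end + 1e-12, tr)
    idx = np.floor(times / traj.dt + 0.5).astype(int)
    idx = np.minimum(idx, L - 1)
    return times, traj.y[idx]
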