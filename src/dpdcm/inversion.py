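"""Sliding-window (recurrent-unit) inversion of the generative model.

The observed BOLD run is padded by half a window at each end and covered
by overlapping windows (see :mod:`dpdcm.windows`).  Each window is one
recurrent unit: the generative model is simulated over the window from a
latent-state snapshot and the free parameters (edge strengths, and any
declared modulatory/driving weights) are fitted to the window's BOLD
samples by plain gradient descent with backtracking line search.  The
fitted parameters of window i initialize window i+1 (initialization
only — every window's inversion is an independent optimization), and the
latent snapshot handed over is read one stride into the fitted window's
simulation.  Window 0 starts from zero-mean connectivity and rest.

The per-window estimates, assembled at the window centers, form the
dynamic effective-connectivity tracks eff_conn(t); the fitted BOLD
output is stitched from each window's central stride segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _core
from .forward import _diag_tracks
from .model import ModelSpec, StimulusSet
from .windows import WindowPlan, plan_windows

__all__ = [
    "InversionConfig",
    "RecurrentState",
    "DynamicConnectivityEstimate",
    "window_loss",
    "invert_window",
    "run_recurrent_inversion",
]

FREE_CHOICES = ("edges", "modulatory", "driving")


@dataclass(frozen=True)
class InversionConfig:
    """Settings of the per-window gradient-descent inversion.

    ``learning_rate`` is the initial step size; on a loss increase the
    step is halved (backtracking), on acceptance it is doubled for the
    next iteration, so the exact initial value is uncritical.
    ``free_parameters`` declares which groups are estimated per window;
    everything else stays at its configured value.
    """

    max_iterations: int = 200
    tolerance: float = 1e-6
    learning_rate: float = 1.0
    free_parameters: tuple[str, ...] = ("edges", "modulatory")
    gradient_method: str = "forward"  # "forward" (sensitivities) or "fd"
    max_backtracks: int = 50
    seed: int = 0
    # BOLD lags its neuronal causes; the data slice fitted for the
    # estimate at time t is delayed by this much so the window is
    # centered on the neuronal epoch it estimates.  "auto" derives the
    # latency from the model's own hemodynamic impulse response.
    latency_s: float | str = "auto"

    def check(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not self.free_parameters:
            raise ValueError("free_parameters must be non-empty")
        for f in self.free_parameters:
            if f not in FREE_CHOICES:
                raise ValueError(f"unknown free parameter group '{f}'")
        if self.gradient_method not in ("forward", "fd"):
            raise ValueError("gradient_method must be 'forward' or 'fd'")
        if not (self.latency_s == "auto"
                or (isinstance(self.latency_s, (int, float)) and self.latency_s >= 0)):
            raise ValueError("latency_s must be 'auto' or a non-negative number")


@dataclass
class RecurrentState:
    """Hand-off set between consecutive windows.

    ``params`` are the free-parameter values after the window's fit,
    ``state`` the (6, n) latent snapshot at the next window's start, and
    ``diagnostics`` the window's convergence record.
    """

    params: np.ndarray
    state: np.ndarray
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DynamicConnectivityEstimate:
    """Assembled inversion result.

    eff_conn has shape (n_windows, n_edges): the total inter-regional
    coupling of each graph edge evaluated at each window center
    (baseline estimate plus any modulatory term at the center).
    fitted_bold is on the dt grid of the run.
    """

    centers: np.ndarray
    edge_labels: tuple[str, ...]
    eff_conn: np.ndarray
    fitted_bold: np.ndarray
    per_window: tuple[dict, ...]
    params_per_window: np.ndarray
    plan: WindowPlan

    @property
    def converged_fraction(self) -> float:
        if not self.per_window:
            return 1.0
        return float(np.mean([w["converged"] for w in self.per_window]))

    def eff_conn_frame(self):
        import pandas as pd

        return pd.DataFrame(self.eff_conn, columns=list(self.edge_labels),
                            index=pd.Index(self.centers, name="time"))


# ---------------------------------------------------------------------------
# Problem assembly


class _Problem:
    """Fixed tracks + free-parameter structure over a (padded) run."""

    def __init__(self, model: ModelSpec, stimuli: StimulusSet,
                 observed: np.ndarray, free: Sequence[str]):
        g = model.graph
        n = g.n_regions
        L = stimuli.n_samples
        if observed.shape != (L, n):
            raise ValueError(
                f"observed series has shape {observed.shape}; expected ({L}, {n})")
        self.model = model
        self.n = n
        self.L = L
        self.dt = stimuli.dt
        self.obs = np.ascontiguousarray(observed, dtype=float)

        free_edges = "edges" in free
        free_mod = "modulatory" in free
        free_drv = "driving" in free

        psi_d, psim_d, cg_d = _diag_tracks(model, stimuli)
        psi0 = np.zeros((L, n, n))
        for (s, t) in g.edge_list:
            if not free_edges:
                psi0[:, t, s] = g.edges.get((s, t), 0.0)
        if not free_mod:
            for (s, t, m), b in g.modulatory_edges.items():
                psi0[:, t, s] += b * stimuli.modulatory[m]
        idx = np.arange(n)
        psi0[:, idx, idx] = psi_d

        C = np.zeros((n, stimuli.driving.shape[0]))
        for (r, j), c in g.driving_map.items():
            C[r, j] = c
        drive0 = (stimuli.driving.T @ C.T) if not free_drv else np.zeros((L, n))

        kinds, rows, cols, ws, labels, truth = [], [], [], [], [], []
        ones = np.ones(L)
        if free_edges:
            for (s, t) in g.edge_list:
                kinds.append(_core.P_KIND_PSI)
                rows.append(t)
                cols.append(s)
                ws.append(ones)
                labels.append(f"A[R{s + 1}->R{t + 1}]")
                truth.append(g.edges.get((s, t), 0.0))
        if free_mod:
            for (s, t, m), b in g.modulatory_edges.items():
                kinds.append(_core.P_KIND_PSI)
                rows.append(t)
                cols.append(s)
                ws.append(stimuli.modulatory[m])
                labels.append(f"B[R{s + 1}->R{t + 1},u{m + 1}]")
                truth.append(b)
        if free_drv:
            for (r, j), c in g.driving_map.items():
                kinds.append(_core.P_KIND_DRIVE)
                rows.append(r)
                cols.append(0)
                ws.append(stimuli.driving[j])
                labels.append(f"C[R{r + 1},u{j + 1}]")
                truth.append(c)

        self.psi0 = psi0
        self.psim = psim_d
        self.cgain = cg_d
        self.drive0 = drive0
        self.p_kind = np.array(kinds, dtype=np.int64)
        self.p_row = np.array(rows, dtype=np.int64)
        self.p_col = np.array(cols, dtype=np.int64)
        self.p_w = np.ascontiguousarray(np.array(ws)) if ws else np.zeros((0, L))
        self.param_labels = tuple(labels)
        self.true_values = np.array(truth)
        self.n_params = len(labels)

        pa = model.physio_arrays()
        k1, k2, k3 = model.bold_constants()
        self._physio = (pa["phi_decay"], pa["phi_gain"], pa["chi"], pa["t_mtt"],
                        pa["tau"], pa["alpha"], pa["e0"], pa["v0"], k1, k2, k3)

    def _window_args(self, t0: int, T: int):
        sl = slice(t0, t0 + T)
        return (self.psi0[sl], self.psim[sl], self.cgain[sl], self.drive0[sl])

    def loss(self, p: np.ndarray, t0: int, T: int, init: np.ndarray) -> float:
        return float(_core.loss_core(
            *self._window_args(t0, T), np.asarray(p, dtype=float),
            self.p_kind, self.p_row, self.p_col, self.p_w[:, t0:t0 + T], self.dt,
            *self._physio, init, self.obs[t0:t0 + T]))

    def loss_grad(self, p: np.ndarray, t0: int, T: int,
                  init: np.ndarray) -> tuple[float, np.ndarray]:
        loss, grad, _status = _core.loss_grad_core(
            *self._window_args(t0, T), np.asarray(p, dtype=float),
            self.p_kind, self.p_row, self.p_col, self.p_w[:, t0:t0 + T], self.dt,
            *self._physio, init, self.obs[t0:t0 + T])
        return float(loss), grad

    def loss_grad_fd(self, p: np.ndarray, t0: int, T: int,
                     init: np.ndarray) -> tuple[float, np.ndarray]:
        """Central finite differences; the non-compiled gradient route."""
        p = np.asarray(p, dtype=float)
        base = self.loss(p, t0, T, init)
        grad = np.zeros_like(p)
        for j in range(len(p)):
            h = 1e-6 * max(1.0, abs(p[j]))
            pp = p.copy()
            pp[j] = p[j] + h
            lp = self.loss(pp, t0, T, init)
            pp[j] = p[j] - h
            lm = self.loss(pp, t0, T, init)
            grad[j] = (lp - lm) / (2 * h)
        return base, grad

    def predict(self, p: np.ndarray, t0: int, T: int,
                init: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        return _core.window_predict_core(
            *self._window_args(t0, T), np.asarray(p, dtype=float),
            self.p_kind, self.p_row, self.p_col, self.p_w[:, t0:t0 + T], self.dt,
            *self._physio, init, T)


def _rest(n: int) -> np.ndarray:
    s = np.zeros((6, n))
    s[3:6] = 1.0
    return s


def _descend(problem: _Problem, p0: np.ndarray, t0: int, T: int,
             init: np.ndarray, cfg: InversionConfig) -> tuple[np.ndarray, dict]:
    """Gradient descent with backtracking halving / doubling on success."""
    grad_fn = problem.loss_grad if cfg.gradient_method == "forward" \
        else problem.loss_grad_fd
    p = np.asarray(p0, dtype=float).copy()
    loss, grad = grad_fn(p, t0, T, init)
    lr = cfg.learning_rate
    lr_max = cfg.learning_rate * 2.0 ** 20  # bound the adaptive growth
    converged = False
    stalled = False
    iterations = 0
    trace = [loss]
    for _ in range(cfg.max_iterations):
        iterations += 1
        accepted = False
        for _bt in range(cfg.max_backtracks + 1):
            p_new = p - lr * grad
            loss_new = problem.loss(p_new, t0, T, init)
            if np.isfinite(loss_new) and loss_new <= loss:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            stalled = True
            break
        rel = abs(loss - loss_new) / max(loss, 1e-30)
        p = p_new
        loss = loss_new
        trace.append(loss)
        if rel < cfg.tolerance:
            converged = True
            break
        lr = min(lr * 2.0, lr_max)
        if iterations < cfg.max_iterations:
            loss, grad = grad_fn(p, t0, T, init)
    diag = {
        "iterations": iterations,
        "final_loss": float(loss),
        "converged": bool(converged),
        "stalled": bool(stalled),
        "loss_trace": tuple(trace),
    }
    return p, diag


def bold_latency(model: ModelSpec, dt: float | None = None) -> float:
    """Effective attribution latency of the model's BOLD cascade (s).

    Simulates the single-region BOLD response to a neuronal impulse with
    the model's (region-averaged) hemodynamic parameters and returns the
    centroid of the early positive lobe up to the response peak.  A
    window of BOLD data is maximally informative about neuronal events
    this long before each sample, so the inversion shifts each window's
    data slice by this latency.
    """
    from .model import derive_bold_constants

    dt = dt or model.stimuli.dt
    pa = model.physio_arrays()
    mean = {k: float(np.mean(v)) for k, v in pa.items()}
    p = model.params[0].with_overrides(**mean)
    k = derive_bold_constants(p)
    T = int(round(20.0 / dt))
    a, f, v, q = 0.0, 1.0, 1.0, 1.0
    ys = np.empty(T)
    for t in range(T):
        ys[t] = p.v0 * (k.k1 * (1 - q) + k.k2 * (1 - q / v) + k.k3 * (1 - v))
        x = 1.0 / dt if t == 0 else 0.0
        a, f = (1 - p.phi_decay * dt) * a + dt * x, \
            p.phi_gain * dt * a + (1 - p.chi * dt) * f + p.chi * dt
        fout = (p.t_mtt * v ** (1 / p.alpha) + p.tau * f) / (p.tau + p.t_mtt)
        E = 1 - (1 - p.e0) ** (1 / f)
        v, q = v + dt * (f - fout) / p.t_mtt, \
            q * (1 - dt * fout / (p.t_mtt * v)) + dt * f * E / (p.t_mtt * p.e0)
    pk = int(np.argmax(ys))
    w = np.clip(ys[:pk + 1], 0.0, None)
    if w.sum() <= 0:
        return 0.0
    tgrid = np.arange(pk + 1) * dt
    return float((tgrid * w).sum() / w.sum())


# ---------------------------------------------------------------------------
# Public operations


def window_loss(candidate_params: np.ndarray, window_data: np.ndarray,
                model: ModelSpec, init_state: np.ndarray | None = None,
                stimuli: StimulusSet | None = None,
                free_parameters: Sequence[str] = ("edges", "modulatory")) -> float:
    """Sum of squared BOLD residuals of one forward-simulated window.

    ``window_data`` is a (T, n) observed slice aligned with the first T
    samples of ``stimuli`` (default: the model's own stimuli);
    ``init_state`` is the latent snapshot at the window start (default
    rest).  Divergent candidates return ``inf``.
    """
    stimuli = stimuli if stimuli is not None else model.stimuli
    window_data = np.asarray(window_data, dtype=float)
    T = window_data.shape[0]
    obs_full = np.zeros((stimuli.n_samples, model.n_regions))
    obs_full[:T] = window_data
    problem = _Problem(model, stimuli, obs_full, free_parameters)
    if len(candidate_params) != problem.n_params:
        raise ValueError(
            f"candidate has {len(candidate_params)} values; problem declares "
            f"{problem.n_params} free parameters ({problem.param_labels})")
    init = _rest(model.n_regions) if init_state is None else init_state
    return problem.loss(np.asarray(candidate_params, dtype=float), 0, T, init)


def invert_window(init: RecurrentState, window_data: np.ndarray, model: ModelSpec,
                  cfg: InversionConfig | None = None,
                  stimuli: StimulusSet | None = None,
                  free_parameters: Sequence[str] | None = None,
                  stride_samples: int | None = None) -> RecurrentState:
    """Fit one window by gradient descent and produce the next hand-off.

    The returned state's ``params`` minimize :func:`window_loss`; its
    ``state`` is the latent snapshot one stride into the fitted window's
    simulation (or the final sample when no stride is given).
    """
    cfg = cfg or InversionConfig()
    cfg.check()
    if free_parameters is not None:
        cfg = replace(cfg, free_parameters=tuple(free_parameters))
    stimuli = stimuli if stimuli is not None else model.stimuli
    window_data = np.asarray(window_data, dtype=float)
    T = window_data.shape[0]
    obs_full = np.zeros((stimuli.n_samples, model.n_regions))
    obs_full[:T] = window_data
    problem = _Problem(model, stimuli, obs_full, cfg.free_parameters)
    p0 = np.asarray(init.params, dtype=float)
    if p0.shape != (problem.n_params,):
        raise ValueError(f"init.params must have shape ({problem.n_params},)")
    state0 = init.state if init.state is not None else _rest(model.n_regions)
    p, diag = _descend(problem, p0, 0, T, state0, cfg)
    states, _y, status = problem.predict(p, 0, T, state0)
    hand = stride_samples if stride_samples is not None else T - 1
    next_state = states[min(hand, T - 1)].copy() if status < 0 else state0
    return RecurrentState(params=p, state=next_state, diagnostics=diag)


def run_recurrent_inversion(
    model: ModelSpec,
    observed: np.ndarray,
    stimuli: StimulusSet | None = None,
    plan: WindowPlan | None = None,
    cfg: InversionConfig | None = None,
) -> DynamicConnectivityEstimate:
    """Invert a full run window by window and assemble eff_conn(t).

    ``observed`` is the (n_samples, n_regions) BOLD series on the dt
    grid of ``stimuli`` (resample first if acquired at a coarser TR).
    Windows are processed left to right; window i+1 is initialized from
    window i's estimates and latent snapshot.  A non-converged window is
    flagged in ``per_window`` but never aborts the run.
    """
    cfg = cfg or InversionConfig()
    cfg.check()
    stimuli = stimuli if stimuli is not None else model.stimuli
    observed = np.asarray(observed, dtype=float)
    if plan is None:
        plan = plan_windows(stimuli.duration, 5.0, 1.0, stimuli.dt)
    if abs(plan.dt - stimuli.dt) > 1e-12:
        raise ValueError("window plan and stimuli use different dt grids")
    n = model.n_regions
    if observed.shape != (plan.n_run_samples, n):
        raise ValueError(
            f"observed shape {observed.shape} does not match the plan "
            f"({plan.n_run_samples} samples x {n} regions)")

    # data-window latency: each window fits BOLD delayed by the
    # hemodynamic lag so the estimate is centered on its neuronal epoch
    latency = bold_latency(model) if cfg.latency_s == "auto" else float(cfg.latency_s)
    off = int(round(latency / plan.dt))
    T = plan.samples_per_window
    half = T // 2
    ss = plan.stride_samples
    off = min(off, half)  # keep the stitched stride segment inside the window

    # pad data and every input track by half a window of zeros (plus the
    # latency shift at the right edge)
    def _pad(arr):
        w = [(plan.pad_samples, plan.pad_samples + off)] + [(0, 0)] * (arr.ndim - 1)
        if arr.shape[0] != plan.n_run_samples:
            raise ValueError("series length does not match the window plan")
        return np.pad(arr, w)

    obs_pad = _pad(observed)
    pad_s = plan.pad_samples * plan.dt
    padded_stimuli = StimulusSet(
        dt=stimuli.dt,
        duration=stimuli.duration + 2 * pad_s + off * plan.dt,
        driving=_pad(stimuli.driving.T).T,
        modulatory=_pad(stimuli.modulatory.T).T,
        mu_context=_pad(stimuli.mu_context.T).T,
        lambda_context=_pad(stimuli.lambda_context.T).T,
    )
    problem = _Problem(model, padded_stimuli, obs_pad, cfg.free_parameters)

    N = plan.n_windows
    P = problem.n_params

    params = np.zeros(P)  # zero-mean initialization of window 0
    state = _rest(n)
    fitted = np.zeros((plan.n_run_samples, n))
    eff = np.zeros((N, len(model.graph.edge_list)))
    params_all = np.zeros((N, P))
    per_window = []

    for i in range(N):
        t0 = plan.window_start(i) + off
        p_init = params
        reinit = not np.isfinite(problem.loss(p_init, t0, T, state))
        if reinit:
            # warm start diverges from this window's snapshot (a wrong
            # hypothesis graph can drive estimates unstable): fall back
            # to the zero-mean initialization used for window 0
            p_init = np.zeros(P)
        p_fit, diag = _descend(problem, p_init, t0, T, state, cfg)
        states_w, y_w, status = problem.predict(p_fit, t0, T, state)
        if status >= 0:
            p_fit = np.zeros(P)
            diag["converged"] = False
            states_w, y_w, status = problem.predict(p_fit, t0, T, state)
        diag["reinitialized"] = bool(reinit)
        diag["init_params"] = p_init.copy()  # hand-off continuity record
        diag["center_s"] = float(plan.centers[i])
        diag["predict_status"] = int(status)
        per_window.append(diag)
        params_all[i] = p_fit

        if status < 0:
            # hand-off: latent snapshot one stride into the fitted window
            state = states_w[min(ss, T - 1)].copy()
            # stitched prediction: the stride segment centered on this window
            run_lo = i * ss
            lo = half - off
            seg = y_w[lo:lo + ss]
            fitted[run_lo:run_lo + ss] = seg[:plan.n_run_samples - run_lo]
            if i == N - 1 and lo + ss < T:
                fitted[run_lo + ss:run_lo + ss + 1] = y_w[lo + ss]
        # eff_conn attributed to the window center time
        center_idx = plan.window_start(i) + plan.pad_samples
        eff[i] = _eff_conn_at(problem, model, p_fit, padded_stimuli, center_idx)

        params = p_fit  # initialization of the next window

    labels = tuple(f"R{s + 1}->R{t + 1}" for (s, t) in model.graph.edge_list)
    return DynamicConnectivityEstimate(
        centers=plan.centers.copy(),
        edge_labels=labels,
        eff_conn=eff,
        fitted_bold=fitted,
        per_window=tuple(per_window),
        params_per_window=params_all,
        plan=plan,
    )


def _eff_conn_at(problem: _Problem, model: ModelSpec, p: np.ndarray,
                 stimuli: StimulusSet, idx: int) -> np.ndarray:
    """Total coupling of each graph edge at one padded-grid sample."""
    g = model.graph
    edge_index = {e: k for k, e in enumerate(g.edge_list)}
    out = np.zeros(len(edge_index))
    # fixed contributions present in psi0
    for e, k in edge_index.items():
        s, t = e
        out[k] = problem.psi0[idx, t, s]
    # free contributions
    for j in range(problem.n_params):
        if problem.p_kind[j] != _core.P_KIND_PSI:
            continue
        e = (int(problem.p_col[j]), int(problem.p_row[j]))
        if e in edge_index:
            out[edge_index[e]] += p[j] * problem.p_w[j, idx]
    return out
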