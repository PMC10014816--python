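"""Synthetic validation experiments: noise, acquisition grids, sweeps.

The pipeline emulated here is a full fMRI acquisition chain: the
noiseless generative trajectory is sampled at the scanner repetition
time, zero-mean Gaussian measurement noise is added on the acquired
samples at a declared contrast-to-noise ratio (CNR = sd(signal) /
sd(noise), per region), and the noisy series is linearly resampled back
to the 32 Hz integration grid before inversion.  Noise is injected
*before* resampling because that is the order of a real acquisition.

Sweep results collect per-cell NRMSE means and standard deviations over
repeated noise realizations.  Seeds follow base_seed + 1000 * cell_index
+ run_index so every (cell, run) draw is independent, and are recorded
in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inversion import InversionConfig, run_recurrent_inversion
from .metrics import nrmse_mean
from .presets import Preset, preset_models, simulate_preset, true_eff_conn
from .forward import sample_observations, simulate
from .model import StimulusSet
from .windows import plan_windows

__all__ = [
    "NoiseSpec",
    "ExperimentResult",
    "add_measurement_noise",
    "resample_linear",
    "invert_run",
    "cnr_tr_sweep",
    "stepsize_window_sweep",
]

TARGET_HZ = 32


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise / acquisition settings for one synthetic run."""

    cnr: float
    seed: int
    tr: float = 1.0

    def check(self, dt: float) -> None:
        if not self.cnr > 0:
            raise ValueError("cnr must be > 0")
        if self.tr < dt:
            raise ValueError(f"tr ({self.tr}) must be >= dt ({dt})")


@dataclass(frozen=True)
class ExperimentResult:
    """Grid of NRMSE summaries: one row per cell with mean/sd over runs."""

    axes: dict[str, tuple]
    table: pd.DataFrame  # per-(cell, run) rows
    summary: pd.DataFrame  # per-cell mean/sd
    seeds: tuple[int, ...] = field(default_factory=tuple)


def add_measurement_noise(y: np.ndarray, spec: NoiseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Add zero-mean Gaussian noise at the declared CNR.

    Noise sd is sd(y)/CNR per region (column).  Returns (noisy series,
    realized noise sd per region).  Seeded and reproducible.
    """
    y = np.asarray(y, dtype=float)
    y2 = np.atleast_2d(y.T).T
    sd_sig = y2.std(axis=0, ddof=0)
    if np.any(sd_sig == 0):
        raise ValueError("constant signal: CNR-scaled noise is undefined")
    rng = np.random.default_rng(spec.seed)
    sd_noise = sd_sig / spec.cnr
    noise = rng.standard_normal(y2.shape) * sd_noise
    noisy = y2 + noise
    return noisy.reshape(y.shape), sd_noise


def resample_linear(y_tr: np.ndarray, tr: float, target_hz: float = TARGET_HZ
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a TR-sampled series onto the target grid.

    The output grid spans the original time range with inclusive
    endpoints (length floor(range * hz) + 1); original sample times on
    the grid reproduce their values exactly.  Returns (grid times, y).
    """
    y_tr = np.asarray(y_tr, dtype=float)
    y2 = np.atleast_2d(y_tr.T).T
    m = y2.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples to resample")
    t_src = np.arange(m) * tr
    n_out = int(np.floor(t_src[-1] * target_hz + 1e-9)) + 1
    t_out = np.arange(n_out) / target_hz
    out = np.column_stack([np.interp(t_out, t_src, y2[:, j]) for j in range(y2.shape[1])])
    if y_tr.ndim == 1:
        out = out[:, 0]
    return t_out, out


def _fit_grid(y32: np.ndarray, n_needed: int) -> np.ndarray:
    """Pad (by holding the last value) or trim to the run's sample count."""
    if y32.shape[0] >= n_needed:
        return y32[:n_needed]
    reps = np.repeat(y32[-1:], n_needed - y32.shape[0], axis=0)
    return np.vstack([y32, reps])


def invert_run(preset: Preset, observed: np.ndarray, window_s: float = 5.0,
               cfg: InversionConfig | None = None, dt: float | None = None,
               stimuli: StimulusSet | None = None):
    """Invert an observed run with the preset's (true) graph.

    Returns (estimate, connectivity NRMSE %, BOLD NRMSE % vs observed).
    """
    stimuli = stimuli if stimuli is not None else preset.stimuli
    plan = plan_windows(stimuli.duration, window_s, 1.0, dt or stimuli.dt)
    est = run_recurrent_inversion(preset.model, observed, stimuli, plan, cfg)
    truth = true_eff_conn(preset, est.centers)
    conn_nrmse, _ = nrmse_mean(est.eff_conn, truth)
    bold_nrmse, _ = nrmse_mean(est.fitted_bold, observed)
    return est, conn_nrmse, bold_nrmse


def cnr_tr_sweep(preset_name: str, cnrs=(1, 3, 5, 10, 20),
                 trs=(4.0, 2.0, 1.0, 0.25, 0.1), runs: int = 10,
                 base_seed: int = 0, window_s: float = 5.0,
                 cfg: InversionConfig | None = None) -> ExperimentResult:
    """Noise/acquisition sweep: NRMSE of recovered connectivity per cell.

    For each (CNR, TR, run): simulate -> sample at TR -> add noise ->
    resample to 32 Hz -> invert with the true graph -> NRMSE of the
    eff_conn tracks (headline) and of the BOLD fit.  Failures are
    recorded per cell; the sweep continues.
    """
    preset = preset_models(preset_name)
    traj = simulate_preset(preset)
    rows = []
    seeds = []
    cell = 0
    for cnr in cnrs:
        for tr in trs:
            t_s, y_s = sample_observations(traj, tr)
            for run in range(runs):
                seed = base_seed + 1000 * cell + run
                seeds.append(seed)
                spec = NoiseSpec(cnr=float(cnr), seed=seed, tr=float(tr))
                spec.check(traj.dt)
                try:
                    noisy, _sd = add_measurement_noise(y_s, spec)
                    _t32, y32 = resample_linear(noisy, tr)
                    y32 = _fit_grid(y32, preset.stimuli.n_samples)
                    _est, conn, bold = invert_run(preset, y32, window_s, cfg)
                    rows.append(dict(cnr=float(cnr), tr=float(tr), run=run,
                                     seed=seed, nrmse_conn_pct=conn,
                                     nrmse_bold_pct=bold, ok=True))
                except Exception as exc:  # noqa: BLE001 — cell-level isolation
                    rows.append(dict(cnr=float(cnr), tr=float(tr), run=run,
                                     seed=seed, nrmse_conn_pct=np.nan,
                                     nrmse_bold_pct=np.nan, ok=False,
                                     error=str(exc)))
            cell += 1
    table = pd.DataFrame(rows)
    summary = (table[table["ok"]]
               .groupby(["cnr", "tr"], as_index=False)
               .agg(nrmse_mean=("nrmse_conn_pct", "mean"),
                    nrmse_sd=("nrmse_conn_pct", "std"),
                    bold_mean=("nrmse_bold_pct", "mean"),
                    n=("run", "count")))
    return ExperimentResult(axes={"cnr": tuple(cnrs), "tr": tuple(trs)},
                            table=table, summary=summary, seeds=tuple(seeds))


def stepsize_window_sweep(preset_name: str = "three_region_case_a",
                          dts=(1 / 32, 1 / 16, 1 / 8, 1 / 4),
                          windows=(5.0, 11.0),
                          cfg: InversionConfig | None = None) -> ExperimentResult:
    """Noiseless integration-step and window-length sensitivity sweep.

    Step-size axis: the ground truth is generated at the reference step
    (1/32 s); the inversion integrates at each coarser step on the
    index-decimated series.  Window axis: fixed reference step, varying
    window length.  Reports eff_conn NRMSE (headline) and BOLD NRMSE.
    """
    preset = preset_models(preset_name)
    traj = simulate_preset(preset)
    ref_dt = preset.stimuli.dt
    rows = []
    for dt in dts:
        k = dt / ref_dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"step {dt} is not a multiple of the reference {ref_dt}")
        k = int(round(k))
        stim = preset.stimuli
        coarse = StimulusSet(dt=dt, duration=stim.duration,
                             driving=stim.driving[:, ::k],
                             modulatory=stim.modulatory[:, ::k],
                             mu_context=stim.mu_context[:, ::k],
                             lambda_context=stim.lambda_context[:, ::k])
        y = traj.y[::k]
        _est, conn, bold = invert_run(preset, y, windows[0], cfg, dt=dt,
                                      stimuli=coarse)
        rows.append(dict(axis="dt", value=dt, window_s=windows[0],
                         nrmse_conn_pct=conn, nrmse_bold_pct=bold))
    for w in windows:
        _est, conn, bold = invert_run(preset, traj.y, w, cfg)
        rows.append(dict(axis="window", value=w, window_s=w,
                         nrmse_conn_pct=conn, nrmse_bold_pct=bold))
    table = pd.DataFrame(rows)
    return ExperimentResult(axes={"dt": tuple(dts), "window": tuple(windows)},
                            table=table, summary=table)
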