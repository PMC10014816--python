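"""Overlapping-window geometry for the recurrent inversion.

A run of ``duration`` seconds on a dt grid is zero-padded by half a
window at each end and covered by windows of length M seconds (T = M/dt
samples) advancing with a fixed stride (default 1 s).  Window i is
centered at t = i * stride; with the padding, every stride step of the
run has a window centered on it, so the estimated connectivity exists
for the entire extent of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WindowPlan", "plan_windows", "pad_series", "unpad_series"]


@dataclass(frozen=True)
class WindowPlan:
    window_length_s: float
    stride_s: float
    dt: float
    samples_per_window: int   # T = M / dt
    stride_samples: int
    pad_samples: int          # half a window at each end
    centers: np.ndarray       # window center times (s)
    n_run_samples: int        # unpadded series length

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    def window_start(self, i: int) -> int:
        """Start index of window i in the padded series."""
        return i * self.stride_samples

    def window_slice(self, i: int) -> slice:
        s = self.window_start(i)
        return slice(s, s + self.samples_per_window)


def _int_ratio(num: float, den: float, what: str) -> int:
    r = num / den
    k = round(r)
    if abs(r - k) > 1e-9 or k < 1:
        raise ValueError(f"{what}: {num} is not a positive integer multiple of {den}")
    return int(k)


def plan_windows(duration_s: float, m_s: float, stride_s: float = 1.0,
                 dt: float = 1.0 / 32) -> WindowPlan:
    """Plan the overlapping-window cover of a run.

    Requires M/dt and stride/dt to be integers and M <= duration.
    Centers sit at 0, stride, 2*stride, ... covering the run.
    """
    T = _int_ratio(m_s, dt, "window length / dt")
    stride_samples = _int_ratio(stride_s, dt, "stride / dt")
    if m_s > duration_s:
        raise ValueError(f"window ({m_s} s) longer than the run ({duration_s} s)")
    n_run = int(round(duration_s / dt)) + 1
    n_windows = int(round(duration_s / stride_s))
    centers = np.arange(n_windows) * stride_s
    pad = T // 2
    return WindowPlan(
        window_length_s=m_s,
        stride_s=stride_s,
        dt=dt,
        samples_per_window=T,
        stride_samples=stride_samples,
        pad_samples=pad,
        centers=centers,
        n_run_samples=n_run,
    )


def pad_series(arr: np.ndarray, plan: WindowPlan) -> np.ndarray:
    """Zero-pad a (n_samples, ...) series by half a window at each end."""
    arr = np.asarray(arr)
    if arr.shape[0] != plan.n_run_samples:
        raise ValueError(
            f"series has {arr.shape[0]} samples; plan expects {plan.n_run_samples}")
    width = [(plan.pad_samples, plan.pad_samples)] + [(0, 0)] * (arr.ndim - 1)
    return np.pad(arr, width)


def unpad_series(arr: np.ndarray, plan: WindowPlan) -> np.ndarray:
    """Inverse of :func:`pad_series` (bit-exact round trip)."""
    return arr[plan.pad_samples:arr.shape[0] - plan.pad_samples]
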