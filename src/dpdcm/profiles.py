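"""Connectivity profile and stimulus waveform generators.

Ground-truth effective connectivity in the validation experiments is
decomposed into a static plateau plus a sinusoidal (or piecewise-linear)
dynamic component, active over a declared interval.  The active epoch is
gated by a trapezoidal envelope with linear ramps so the coupling rises
piecewise-continuously from the resting value and returns to it — before
and after the epoch the track equals ``baseline`` exactly:

    track(t) = baseline + env(t) * (static + amplitude * shape(t))

with env = 0 outside [onset, offset], ramping 0 -> 1 over ``ramp_s``.
With ramp_s = 0 and static = 0 this reduces to the plain
baseline + amplitude * sin(2 pi (t - onset) / period) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConnectivityProfileSpec", "make_connectivity_profile", "make_stimulus"]


@dataclass(frozen=True)
class ConnectivityProfileSpec:
    """One edge's ground-truth strength profile."""

    baseline: float = 0.0
    static: float = 0.0
    amplitude: float = 0.0
    period_s: float = 1.0
    onset_s: float = 0.0
    offset_s: float = 0.0
    ramp_s: float = 0.0
    shape: str = "sinusoid"  # sinusoid | piecewise | constant
    knots: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    phase: float = 0.0

    def check(self) -> None:
        if self.offset_s < self.onset_s:
            raise ValueError("offset must be >= onset")
        if self.shape == "sinusoid" and not self.period_s > 0:
            raise ValueError("sinusoid needs period > 0")
        if self.shape == "piecewise" and len(self.knots) < 2:
            raise ValueError("piecewise shape needs at least 2 knots")
        if self.shape not in ("sinusoid", "piecewise", "constant"):
            raise ValueError(f"unknown shape '{self.shape}'")

    def __call__(self, t) -> np.ndarray:
        """Evaluate the profile at arbitrary times (vectorized)."""
        self.check()
        t = np.asarray(t, dtype=float)
        active = (t >= self.onset_s) & (t <= self.offset_s)
        env = np.zeros_like(t)
        if self.ramp_s > 0:
            rise = np.clip((t - self.onset_s) / self.ramp_s, 0.0, 1.0)
            fall = np.clip((self.offset_s - t) / self.ramp_s, 0.0, 1.0)
            env = np.where(active, np.minimum(rise, fall), 0.0)
        else:
            env = active.astype(float)
        if self.shape == "sinusoid":
            dyn = self.amplitude * np.sin(
                2 * np.pi * (t - self.onset_s) / self.period_s + self.phase)
        elif self.shape == "piecewise":
            xs = np.array([k[0] for k in self.knots])
            ys = np.array([k[1] for k in self.knots])
            dyn = self.amplitude * np.interp(t - self.onset_s, xs, ys)
        else:  # constant
            dyn = np.full_like(t, self.amplitude)
        return self.baseline + env * (self.static + dyn)


def make_connectivity_profile(spec: ConnectivityProfileSpec,
                              grid: np.ndarray) -> np.ndarray:
    """Evaluate a profile spec on a time grid (seconds)."""
    return spec(np.asarray(grid, dtype=float))


def make_stimulus(kind: str, grid: np.ndarray, amplitude: float = 1.0,
                  onset_s: float = 0.0, offset_s: float | None = None,
                  period_s: float = 1.0) -> np.ndarray:
    """Input waveform on a time grid, zero outside [onset, offset].

    kind "sinusoid": amplitude * sin(2 pi (t - onset) / period), so the
    value a quarter period after onset equals the amplitude.
    kind "block": constant amplitude inside the interval.
    """
    t = np.asarray(grid, dtype=float)
    offset_s = offset_s if offset_s is not None else float(t[-1])
    active = (t >= onset_s) & (t <= offset_s)
    if kind == "sinusoid":
        u = amplitude * np.sin(2 * np.pi * (t - onset_s) / period_s)
    elif kind == "block":
        u = np.full_like(t, amplitude)
    else:
        raise ValueError(f"unknown stimulus kind '{kind}'")
    return np.where(active, u, 0.0)
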