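"""Preset validation models: 3-region and 10-region synthetic studies.

These presets define the stated world of the package's validation
experiments.  Ground-truth effective connectivity decomposes into a
static plateau (0.4) plus a sinusoidal dynamic component (amplitude
0.3) gated to the stimulation epoch with 8 s linear ramps, so coupling
rises piecewise-continuously from zero and returns to zero.  The
driving input is a positive sinusoid (1 + 0.5 sin, 20 s period) over
the same epoch: stimulation intensity fluctuates around a nonzero mean,
which keeps neuronal activity — and hence connectivity identifiability —
alive throughout the epoch.

* ``three_region_case_a`` — R1 drives R2 and R3 over a 120 s run
  (stimulation 10-100 s); a fast (30 s period) coupling R1->R2 and a
  slow (60 s) coupling R1->R3.
* ``three_region_m1`` / ``three_region_m2`` — competing hypothesis
  graphs for model comparison.  m1 (the generating model) adds a
  feedback connection R2->R1 modulated by a block input u2; m2 is the
  chain R1->R2->R3 with feedback R3->R2 and u2 modulating R2->R3.
* ``ten_region_m1`` — the nine-edge, ten-region graph driven by two
  inputs 20 s apart; every edge carries a plateau + sinusoid profile.
* ``ten_region_m2`` — a deliberately wrong ten-region graph (same
  region and edge count, same inputs, scrambled wiring) used as the
  comparison hypothesis; a synthetic stand-in, not a published graph.

All presets use dt = 1/32 s.  Driving weights are C = 0.1, which keeps
blood-inflow excursions in the physiological range for the default
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import TrajectoryBundle, simulate
from .model import DEFAULT_PHYSIO, ModelSpec, RegionGraphSpec, StimulusSet, validate_model
from .profiles import ConnectivityProfileSpec, make_stimulus

__all__ = ["Preset", "preset_models", "simulate_preset", "true_eff_conn",
           "conn_tracks", "PRESET_NAMES"]

DT = 1.0 / 32
DRIVE_WEIGHT = 0.1

PRESET_NAMES = ("three_region_case_a", "three_region_m1", "three_region_m2",
                "ten_region_m1", "ten_region_m2")


@dataclass(frozen=True)
class Preset:
    name: str
    model: ModelSpec
    profiles: dict[tuple[int, int], ConnectivityProfileSpec]

    @property
    def stimuli(self) -> StimulusSet:
        return self.model.stimuli


def _drive_input(grid, onset, offset, period=20.0, mean=1.0, amplitude=0.5):
    """Stimulation intensity fluctuating sinusoidally about a positive mean."""
    return (make_stimulus("block", grid, mean, onset, offset)
            + make_stimulus("sinusoid", grid, amplitude, onset, offset, period))


def _profile(period: float, onset: float, offset: float,
             static: float = 0.4, amplitude: float = 0.3,
             ramp: float = 8.0) -> ConnectivityProfileSpec:
    return ConnectivityProfileSpec(
        baseline=0.0, static=static, amplitude=amplitude, period_s=period,
        onset_s=onset, offset_s=offset, ramp_s=ramp, shape="sinusoid")


def _three_region_case_a() -> Preset:
    duration, onset, offset = 120.0, 10.0, 100.0
    n = int(round(duration / DT)) + 1
    grid = np.arange(n) * DT
    u1 = _drive_input(grid, onset, offset)
    stimuli = StimulusSet(dt=DT, duration=duration, driving=u1[None, :],
                          modulatory=np.zeros((0, n)), mu_context=np.zeros((0, n)),
                          lambda_context=np.zeros((0, n)))
    graph = RegionGraphSpec(
        n_regions=3,
        edges={(0, 1): 0.0, (0, 2): 0.0},
        driving_map={(0, 0): DRIVE_WEIGHT},
    )
    model = validate_model(graph, DEFAULT_PHYSIO, stimuli)
    profiles = {
        (0, 1): _profile(30.0, onset, offset),   # fast R1->R2
        (0, 2): _profile(60.0, onset, offset),   # slow R1->R3
    }
    return Preset("three_region_case_a", model, profiles)


def _three_region_comparison(m2: bool) -> Preset:
    duration, onset, offset = 80.0, 10.0, 60.0
    n = int(round(duration / DT)) + 1
    grid = np.arange(n) * DT
    u1 = _drive_input(grid, onset, offset)
    u2 = make_stimulus("block", grid, amplitude=1.0, onset_s=25.0, offset_s=50.0)
    stimuli = StimulusSet(dt=DT, duration=duration, driving=u1[None, :],
                          modulatory=u2[None, :], mu_context=np.zeros((0, n)),
                          lambda_context=np.zeros((0, n)))
    # the task-modulated feedback loop amplifies activity, so the
    # comparison scenario uses a smaller driving weight to keep blood
    # inflow in the physiological range
    c = 0.05
    if not m2:
        # feedback R2->R1 modulated by u2 (generating model)
        graph = RegionGraphSpec(
            n_regions=3,
            edges={(0, 1): 0.4, (0, 2): 0.4, (1, 0): 0.2},
            modulatory_edges={(1, 0, 0): 0.75},
            driving_map={(0, 0): c},
        )
        name = "three_region_m1"
    else:
        # chain R1->R2->R3 with feedback R3->R2, u2 modulating R2->R3
        graph = RegionGraphSpec(
            n_regions=3,
            edges={(0, 1): 0.4, (1, 2): 0.4, (2, 1): 0.2},
            modulatory_edges={(1, 2, 0): 0.75},
            driving_map={(0, 0): c},
        )
        name = "three_region_m2"
    model = validate_model(graph, DEFAULT_PHYSIO, stimuli)
    return Preset(name, model, {})


_TEN_EDGES_M1 = ((0, 2), (2, 7), (0, 4), (0, 5), (0, 6), (1, 5), (1, 3),
                 (3, 8), (3, 9))
# wrong-hypothesis wiring: same size, same inputs, scrambled targets (synthetic)
_TEN_EDGES_M2 = ((0, 3), (3, 7), (1, 2), (2, 4), (1, 6), (4, 8), (6, 9),
                 (0, 5), (5, 1))


def _ten_region(edges: tuple, name: str, with_profiles: bool) -> Preset:
    duration = 120.0
    n = int(round(duration / DT)) + 1
    grid = np.arange(n) * DT
    u1 = _drive_input(grid, 10.0, 90.0)
    u2 = _drive_input(grid, 30.0, 110.0)  # 20 s delay between the two inputs
    stimuli = StimulusSet(dt=DT, duration=duration,
                          driving=np.vstack([u1, u2]),
                          modulatory=np.zeros((0, n)), mu_context=np.zeros((0, n)),
                          lambda_context=np.zeros((0, n)))
    graph = RegionGraphSpec(
        n_regions=10,
        edges={e: 0.0 for e in edges},
        driving_map={(0, 0): DRIVE_WEIGHT, (1, 1): DRIVE_WEIGHT},
    )
    model = validate_model(graph, DEFAULT_PHYSIO, stimuli)
    profiles = {}
    if with_profiles:
        periods = (30.0, 60.0, 45.0)
        for k, (s, t) in enumerate(edges):
            # the R2/R4 subtree follows the delayed input's epoch
            if s in (1, 3):
                onset, offset = 30.0, 110.0
            else:
                onset, offset = 10.0, 90.0
            profiles[(s, t)] = _profile(periods[k % 3], onset, offset)
    return Preset(name, model, profiles)


_BUILDERS = {
    "three_region_case_a": _three_region_case_a,
    "three_region_m1": lambda: _three_region_comparison(False),
    "three_region_m2": lambda: _three_region_comparison(True),
    "ten_region_m1": lambda: _ten_region(_TEN_EDGES_M1, "ten_region_m1", True),
    "ten_region_m2": lambda: _ten_region(_TEN_EDGES_M2, "ten_region_m2", False),
}


def preset_models(name: str) -> Preset:
    """Return a named preset (model, connectivity profiles, stimuli)."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset '{name}'; choose from {PRESET_NAMES}") from None


def conn_tracks(preset: Preset, grid: np.ndarray | None = None
                ) -> dict[tuple[int, int], np.ndarray]:
    """Evaluate the preset's ground-truth profiles on the dt grid."""
    grid = grid if grid is not None else preset.stimuli.time
    return {e: prof(grid) for e, prof in preset.profiles.items()}


def simulate_preset(preset: Preset) -> TrajectoryBundle:
    """Noiseless ground-truth trajectory of a preset."""
    tracks = conn_tracks(preset) or None
    return simulate(preset.model, conn_track=tracks)


def true_eff_conn(preset: Preset, times: np.ndarray) -> np.ndarray:
    """Ground-truth effective connectivity of each graph edge at given times.

    Profile edges are evaluated analytically; other edges take their
    static baseline plus modulatory input terms at those times.
    """
    times = np.asarray(times, dtype=float)
    g = preset.model.graph
    stim = preset.stimuli
    idx = np.floor(times / stim.dt + 0.5).astype(int)
    out = np.zeros((len(times), len(g.edge_list)))
    for k, (s, t) in enumerate(g.edge_list):
        if (s, t) in preset.profiles:
            out[:, k] = preset.profiles[(s, t)](times)
        else:
            out[:, k] = g.edges.get((s, t), 0.0)
            for (ss, tt, m), b in g.modulatory_edges.items():
                if (ss, tt) == (s, t):
                    out[:, k] += b * stim.modulatory[m][idx]
    return out
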