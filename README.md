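# dpdcm

Dynamic effective connectivity from fMRI BOLD signals: a discretized
physiological DCM forward simulator with a recurrent sliding-window
inversion.

fMRI measures neuronal activity only indirectly, through the
hemodynamic response. Generative models of that chain — neuronal
dynamics → neurovascular coupling → venous balloon → BOLD signal — let
one estimate *effective connectivity*: directed causal coupling between
brain regions at the neuronal level. Classical causal models assume the
coupling is constant across an experimental run, but under naturalistic
stimulation (movie watching, music) coupling strengths plausibly change
with time. This package simulates BOLD responses of region networks
with *time-varying* coupling, and recovers the coupling time courses
`eff_conn(t)` from observed BOLD runs at one-second resolution — without
prior knowledge of the coupling profiles.

It is aimed at methods researchers who want a fast, fully inspectable
sandbox for dynamic-connectivity estimation: every physiological
equation exists in a readable scalar form, the integration and gradient
kernels are compiled (numba), and the whole synthetic validation suite
(3- and 10-region models, model comparison, noise/TR sweeps, step-size
and window-size sensitivity) is reproducible from seeds.

## The model in brief

Per region, a two-state neuronal population (excitatory `x_E`,
inhibitory `x_I`), integrated with forward Euler at Δt = 1/32 s:

    X_E(t+Δt) = (I + Δt ψ) X_E + (Δt ψ⁻) X_I + (Δt C) U_d(t)
    X_I(t+Δt) = (Δt ℭ) X_E + (I − Δt ℭ) X_I

with inter-regional coupling `ψ_ij = A_ij + Σ_m B_ij^(m) u_m(t)` and
sign-constrained self-connections `ψ_ii = −σ e^(σ̃ + …)`. Excitatory
activity drives a vasoactive signal and blood inflow, which feed a
viscoelastic venous balloon for blood volume `v` and deoxyhemoglobin
`q`; the BOLD signal is `y = V₀[k₁(1−q) + k₂(1−q/v) + k₃(1−v)]`.

The inversion covers the run with overlapping windows (default 5 s,
stride 1 s, half-window zero padding), fits each window's coupling
parameters to its BOLD slice by gradient descent, and hands both the
estimates and the latent states forward to initialize the next window.
See `docs/methods.md` for the full treatment, including the
hemodynamic-latency alignment of window data.

## Worked example

```python
import dpdcm

# the 3-region validation model: R1 drives R2 (fast-varying coupling,
# 30 s period) and R3 (slow, 60 s) during a 90 s stimulation epoch
preset = dpdcm.preset_models("three_region_case_a")
truth = dpdcm.simulate_preset(preset)          # noiseless BOLD, 120 s at 32 Hz

from dpdcm.experiments import invert_run
est, conn_nrmse, bold_nrmse = invert_run(preset, truth.y, window_s=5.0)
print(f"connectivity NRMSE {conn_nrmse:.2f}%  BOLD NRMSE {bold_nrmse:.2f}%")
print(est.eff_conn_frame().loc[38:42].round(3))
```

prints

```
connectivity NRMSE 2.93%  BOLD NRMSE 0.69%
      R1->R2  R1->R3
time
38.0   0.288   0.456
39.0   0.345   0.426
40.0   0.406   0.396
41.0   0.468   0.364
42.0   0.529   0.333
```

The recovered tracks sit within a few percent of the generating
profiles: at t = 40 s both sinusoids pass through their 0.4 plateau
(the fast one rising, the slow one falling) and the estimates read
0.406 and 0.396. The same
pipeline distinguishes hypothesis graphs — inverting data generated
from a model with task-modulated feedback (m1) under a wrong chain
graph (m2) raises the region-averaged BOLD NRMSE from 0.03% to 17.82%:

```bash
dpdcm simulate --preset three_region_m1 --out sim/
dpdcm compare --presets three_region_m1 --presets three_region_m2 \
      --bold sim/bold.csv --out cmp/
```

Other entry points: `dpdcm invert` (recover eff_conn from a BOLD CSV),
`dpdcm sweep` (CNR × TR noise study), `dpdcm profile` (export
ground-truth coupling tracks). Each writes full-precision CSVs plus an
append-only JSON manifest.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main pipeline from scratch — the noiseless 3-region
recovery, the m1/m2 hypothesis comparison, and one seeded noisy
acquisition (CNR 5, TR 1 s) — printing the resulting error metrics and
writing the results JSON to `--out`.
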