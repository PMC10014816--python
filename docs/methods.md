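# Methods

## The generative model

Each brain region hosts a two-state neuronal population: an excitatory
state `x_E` and an inhibitory state `x_I`. Stacked over regions, the
discretized (forward-Euler) neuronal update is

    X_E(t+Δt) = (I + Δt ψ) X_E + (Δt ψ⁻) X_I + (Δt C) U_d(t)
    X_I(t+Δt) = (Δt ℭ) X_E + (I − Δt ℭ) X_I

where the total connectivity matrix ψ carries inter-regional coupling on
the off-diagonal, `ψ_ij = A_ij + Σ_m B_ij^(m) u_m(t)`, and a
sign-constrained exponential self-connection on the diagonal,
`ψ_ii = −σ exp(σ̃ + Σ_m b_ii^(m) u_m(t))`. The inhibitory–excitatory
coupling `ψ⁻` and the inhibitory gain `ℭ` are diagonal with analogous
exponential parameterizations (scales μ and λ). Self-connections are
therefore never graph edges; they cannot change sign.

Excitatory activity drives a feed-forward neurovascular cascade per
region — a vasoactive signal `a` (decay φ, gain ϕ) low-passes `x_E` into
normalized blood inflow `f` (decay χ) — which feeds a viscoelastic
venous balloon:

    f_out(v, f) = (t_MTT v^(1/α) + τ f) / (τ + t_MTT)
    v' = v + Δt (f − f_out)/t_MTT
    q' = q [1 − Δt f_out/(t_MTT v)] + Δt f E(f)/(t_MTT E₀),
    E(f) = 1 − (1 − E₀)^(1/f)

with mean transit time `t_MTT`, Grubb exponent α, viscoelastic constant
τ (τ > 0 uncouples flow and volume transients, producing the
post-stimulus undershoot), and flow-dependent oxygen extraction `E`.
The BOLD observable is

    y = V₀ [k₁(1−q) + k₂(1−q/v) + k₃(1−v)],
    k₁ = 4.3 ϑ₀ E₀ TE,  k₂ = ε r₀ E₀ TE,  k₃ = 1 − ε.

All six states advance synchronously from time-t values. `y` is kept
fractional internally; presentation multiplies by 100.

Every update exists in two algebraically identical forms — elementwise
scalar and matrix-assembled — and the test suite checks them against
each other to machine precision, so the compiled kernels are pinned to
the readable reference implementations.

## Default parameters

One documented default set, overridable per region (units: rates s⁻¹,
times s, fractions dimensionless):

| parameter | default | meaning |
|---|---|---|
| σ, μ, λ | 0.5, 0.4, 0.2 | self-connectivity, inhibitory–excitatory scale, inhibitory gain |
| σ̃, μ̃, λ̃ | 0 | log-scale deviations |
| φ, ϕ, χ | 0.6, 1.5, 0.6 | vasoactive decay/gain, inflow decay |
| t_MTT, τ, α | 2, 4, 0.32 | transit time, viscoelastic constant, Grubb exponent |
| E₀, V₀ | 0.4, 0.04 | resting O₂ extraction, venous volume fraction |
| ε, ϑ₀, r₀, TE | 0.4, 40.3, 25, 0.035 | BOLD-equation constants (gradient echo) |

These follow the two-state neural-mass / balloon literature and give a
BOLD impulse response peaking ≈3.2 s after a neuronal impulse with a
1–3% signal-change scale — ordinary task-fMRI territory. Δt defaults to
1/32 s; the Euler scheme's neuronal update matrix then has spectral
radius < 1 for all shipped configurations.

## Sliding-window inversion

A run is zero-padded by half a window per side and covered by windows of
length M (default 5 s) advancing at a 1 s stride, one estimate per
window center over the whole run. Each window is one recurrent unit:
the generative model is simulated across the window from a latent-state
snapshot and the free parameters (per-window edge strengths A, declared
modulatory weights B, optionally driving weights C; physiology stays
fixed) are fitted to the window's BOLD samples by gradient descent on
the sum of squared residuals. Window 0 starts from zero-mean
connectivity and rest; window i+1 is initialized from window i's
estimates (initialization only — each window's optimization is
independent) and from the latent snapshot read one stride into window
i's fitted simulation.

**Hemodynamic-latency alignment.** BOLD lags its neuronal causes, so a
window of BOLD data centered at time c is informative about coupling
roughly 2 s *before* c. The window's fitted data slice is therefore
delayed by the model's own hemodynamic latency — the centroid of the
early positive lobe of the BOLD impulse response (≈2.1 s at defaults,
recomputed from whatever parameters the model carries) — while the
estimate remains attributed to the window center. With `latency_s = 0`
the estimator is the literal centered-window scheme; its estimates then
systematically trail the true connectivity by the same ~2 s, which is
measurable with a step-profile probe.

**Optimizer.** Plain gradient descent with a backtracking line search:
the step is halved on any loss increase (up to 50 times; an all-rejected
iteration is reported as non-convergence, never silently) and doubled
after acceptance, bounded at 2²⁰× the initial rate — unbounded growth
lets parameters random-walk in near-zero-information windows (e.g.,
after the stimulus ends) where the loss surface is almost flat.
Iterations stop at `max_iterations` (200) or when the relative loss
change drops below `tolerance` (10⁻⁶). Gradients come from forward-mode
sensitivity propagation through the Euler recursion (compiled alongside
the states); central finite differences are available as a second route
and the two agree to 10⁻⁴ relative on random instances.

**Divergence policy.** Trajectories are never clipped: a forward
simulation that leaves the valid domain raises with the offending step
index, and a divergent candidate inside the line search scores infinite
loss and is rejected. If a window's warm start itself diverges (wrong
hypothesis graphs can drive estimates unstable), the window re-starts
from the zero-mean initialization and the run continues with the window
flagged.

**Outputs.** `eff_conn(t)` is the total inter-regional coupling of each
graph edge (estimated baseline plus modulatory term) at each window
center, at stride resolution; the fitted BOLD series is stitched from
each window's central stride segment.

## The synthetic world

The validation presets emulate a task run in which stimulation
intensity fluctuates sinusoidally about a positive mean
(`u = 1 + 0.5 sin(2πt/20)` during the epoch) while coupling strengths
carry a static plateau (0.4) plus a sinusoidal dynamic component
(amplitude 0.3) gated to the epoch by 8 s linear ramps. The positive
input mean matters: a zero-mean sinusoidal input crosses zero, and at
those instants upstream activity vanishes and connectivity is simply
unidentifiable — estimates freeze while the truth moves on. Likewise the
coupling returns to zero outside the epoch because connectivity during
silence is unidentifiable in principle; a nonzero resting coupling could
never be recovered and would only inflate error metrics with a term no
estimator can reduce.

Measurement noise is zero-mean Gaussian added per region on the
TR-sampled series at a declared contrast-to-noise ratio
(CNR = sd(signal)/sd(noise)), *before* linear resampling back to the
32 Hz grid — the order of a real acquisition. Sweeps repeat each cell
with seeds `base_seed + 1000·cell + run`.

What a green test does establish: the discretization converges
first-order to the continuous system; the inversion recovers the stated
world's connectivity tracks to a few percent without noise and degrades
monotonically with noise, coarser sampling, coarser integration steps
and longer windows; wrong hypothesis graphs fit distinguishably worse.
What it does not: the synthetic world has no physiological noise,
scanner drift, regional hemodynamic variability, or neuronal
stochasticity, and coupling dynamics slower than ~half the window
length; accuracy numbers do not transfer to empirical data.

## Numerical and design choices

- NRMSE = 100·RMSE/(max−min) of the reference series; range
  normalization is the stable choice for near-zero-mean signals and is
  isolated in one function. Model comparison averages per-region BOLD
  NRMSE of the stitched fit and ranks ascending, ties broken by
  declaration order.
- Window-length sensitivity is judged on the BOLD-fit NRMSE (the
  quantity that collapses, ~7× here, when an 11 s window can no longer
  track within-window dynamics); connectivity NRMSE degrades
  monotonically as well but less sharply.
- TR sampling uses exact index selection when TR is a grid multiple and
  the nearest grid point otherwise (round-half-up); resampled grids have
  inclusive endpoints (duration·32 + 1 samples).
- Time series are inclusive-endpoint (duration/Δt + 1 samples); window
  padding is ⌊T/2⌋ samples per side.
- Config files use 1-based region/input indices (R1…Rn); the loaders are
  the only place this mapping occurs. Unknown keys are rejected.
- Degenerate inputs fail loudly: constant references in NRMSE, constant
  signals in CNR scaling, non-uniform time grids, TR below Δt,
  non-integer window/stride ratios.

## Known limitations

- Per-window estimates are maximum-likelihood point estimates with no
  posterior uncertainty; weakly identified windows inherit the previous
  window's value rather than widening an error bar.
- The attribution latency is a single per-model scalar; strongly
  heterogeneous regional hemodynamics would warrant per-region
  alignment.
- Coupling dynamics faster than roughly half the window length are
  smoothed regardless of acquisition rate — a property of BOLD itself,
  not of the estimator.
- The number of free parameters grows with the edge count; the
  per-window problems stay well-posed for the graph sizes exercised
  here (≤ 10 regions, ≤ 9 edges) but no sparsity device is provided for
  dense graphs.
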