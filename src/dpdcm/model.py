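"""Model specification: region graph, physiological parameters, stimuli.

A model is a directed graph of brain regions.  Each region hosts a
two-state (excitatory/inhibitory) neuronal population coupled to a
neurovascular/hemodynamic cascade that produces the BOLD observable.
Off-diagonal connectivity ``A`` couples excitatory populations between
regions; modulatory weights ``B`` scale with experimental inputs;
driving weights ``C`` inject inputs into excitatory populations.
Self-connections are not graph edges: they live in the sign-constrained
exponential diagonal of the total connectivity matrix.

Region indices are 1-based in configuration files and documentation
(R1..Rn) and 0-based internally; the dataclass constructors here are the
only place that mapping happens (see :mod:`dpdcm.io` for file loading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RegionGraphSpec",
    "PhysioParams",
    "StimulusSet",
    "BoldConstants",
    "ModelSpec",
    "ModelValidationError",
    "DEFAULT_PHYSIO",
    "validate_model",
    "derive_bold_constants",
]


class ModelValidationError(ValueError):
    """A structural invariant of the model specification is violated."""


@dataclass(frozen=True)
class RegionGraphSpec:
    """Directed connectivity structure of the hypothesis graph.

    All indices are 0-based.  ``edges`` maps (source, target) -> baseline
    strength A[target, source] in s^-1.  ``modulatory_edges`` maps
    (source, target, input_index) -> modulatory weight B.  An entry of
    ``modulatory_edges`` whose (source, target) pair is absent from
    ``edges`` must be listed in ``modulation_only`` (a modulated
    connection with zero baseline).
    """

    n_regions: int
    edges: dict[tuple[int, int], float] = field(default_factory=dict)
    modulatory_edges: dict[tuple[int, int, int], float] = field(default_factory=dict)
    driving_map: dict[tuple[int, int], float] = field(default_factory=dict)  # (region, input) -> C
    self_mod: dict[tuple[int, int], float] = field(default_factory=dict)  # (region, input) -> b_ii
    inhibitory_mu_mod: dict[tuple[int, int], float] = field(default_factory=dict)
    inhibitory_lambda_mod: dict[tuple[int, int], float] = field(default_factory=dict)
    modulation_only: frozenset[tuple[int, int]] = frozenset()

    @property
    def edge_list(self) -> list[tuple[int, int]]:
        """Ordered (source, target) pairs: baseline edges then pure-modulation edges."""
        out = list(self.edges)
        out.extend(p for p in sorted(self.modulation_only) if p not in self.edges)
        return out


# Default per-region physiological parameter set.  Neuronal and vascular
# values follow the two-state neural-mass / viscoelastic balloon
# literature; the BOLD-equation constants correspond to a gradient-echo
# acquisition (TE 35 ms).  All rates in s^-1, times in s, fractions
# dimensionless.
_DEFAULTS = dict(
    sigma=0.5,
    mu=0.4,
    lambda_=0.2,
    sigma_tilde=0.0,
    mu_tilde=0.0,
    lambda_tilde=0.0,
    phi_decay=0.6,
    phi_gain=1.5,
    chi=0.6,
    t_mtt=2.0,
    tau=4.0,
    alpha=0.32,
    e0=0.4,
    v0=0.04,
    eps=0.4,
    theta0=40.3,
    r0=25.0,
    te=0.035,
)


@dataclass(frozen=True)
class PhysioParams:
    """Per-region physiological parameters.

    sigma/mu/lambda_ scale the self-, inhibitory-excitatory and
    inhibitory-gain connections; the tilde terms are log-scale
    deviations.  phi_decay/phi_gain/chi govern neurovascular coupling,
    (t_mtt, tau, alpha, e0, v0) the venous balloon, and
    (eps, theta0, r0, te) the BOLD signal equation.
    """

    sigma: float = _DEFAULTS["sigma"]
    mu: float = _DEFAULTS["mu"]
    lambda_: float = _DEFAULTS["lambda_"]
    sigma_tilde: float = _DEFAULTS["sigma_tilde"]
    mu_tilde: float = _DEFAULTS["mu_tilde"]
    lambda_tilde: float = _DEFAULTS["lambda_tilde"]
    phi_decay: float = _DEFAULTS["phi_decay"]
    phi_gain: float = _DEFAULTS["phi_gain"]
    chi: float = _DEFAULTS["chi"]
    t_mtt: float = _DEFAULTS["t_mtt"]
    tau: float = _DEFAULTS["tau"]
    alpha: float = _DEFAULTS["alpha"]
    e0: float = _DEFAULTS["e0"]
    v0: float = _DEFAULTS["v0"]
    eps: float = _DEFAULTS["eps"]
    theta0: float = _DEFAULTS["theta0"]
    r0: float = _DEFAULTS["r0"]
    te: float = _DEFAULTS["te"]

    def check(self) -> None:
        if not self.t_mtt > 0:
            raise ModelValidationError("t_mtt must be > 0")
        if self.tau < 0:
            raise ModelValidationError("tau must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ModelValidationError("alpha must be in (0, 1]")
        if not 0 < self.e0 < 1:
            raise ModelValidationError("e0 must be in (0, 1)")
        if not 0 < self.v0 < 1:
            raise ModelValidationError("v0 must be in (0, 1)")
        if not self.te > 0:
            raise ModelValidationError("te must be > 0")
        for name in ("sigma", "mu", "lambda_", "phi_decay", "phi_gain", "chi"):
            if not getattr(self, name) > 0:
                raise ModelValidationError(f"{name} must be > 0")

    def with_overrides(self, **kwargs: float) -> "PhysioParams":
        return replace(self, **kwargs)


DEFAULT_PHYSIO = PhysioParams()


@dataclass(frozen=True)
class StimulusSet:
    """Experimental input time courses on a uniform dt grid.

    Each array has shape (n_inputs, n_samples) where
    n_samples = round(duration / dt) + 1 (inclusive endpoints).
    ``driving`` feeds the C matrix, ``modulatory`` the B weights,
    ``mu_context`` / ``lambda_context`` the inhibitory modulations.
    """

    dt: float
    duration: float
    driving: np.ndarray
    modulatory: np.ndarray
    mu_context: np.ndarray
    lambda_context: np.ndarray

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def check(self) -> None:
        if not self.dt > 0:
            raise ModelValidationError("dt must be > 0")
        n = self.n_samples
        for name in ("driving", "modulatory", "mu_context", "lambda_context"):
            arr = getattr(self, name)
            if arr.ndim != 2:
                raise ModelValidationError(f"stimulus '{name}' must be 2-D (inputs x samples)")
            if arr.shape[1] != n:
                raise ModelValidationError(
                    f"stimulus '{name}' has {arr.shape[1]} samples; grid requires {n} "
                    f"(duration {self.duration} s at dt {self.dt} s)"
                )
            if not np.all(np.isfinite(arr)):
                raise ModelValidationError(f"stimulus '{name}' contains non-finite values")

    @staticmethod
    def zeros(dt: float, duration: float, n_driving: int = 1, n_modulatory: int = 0,
              n_mu: int = 0, n_lambda: int = 0) -> "StimulusSet":
        n = int(round(duration / dt)) + 1
        return StimulusSet(
            dt=dt,
            duration=duration,
            driving=np.zeros((n_driving, n)),
            modulatory=np.zeros((n_modulatory, n)),
            mu_context=np.zeros((n_mu, n)),
            lambda_context=np.zeros((n_lambda, n)),
        )


@dataclass(frozen=True)
class BoldConstants:
    """Dimensionless coefficients of the BOLD signal equation."""

    k1: float
    k2: float
    k3: float


def derive_bold_constants(params: PhysioParams) -> BoldConstants:
    """Coefficients of the gradient-echo BOLD equation.

    k1 = 4.3 * theta0 * E0 * TE   (extravascular term)
    k2 = eps * r0  * E0 * TE      (intravascular term)
    k3 = 1 - eps                  (volume-weighted balance)
    """
    params.check()
    return BoldConstants(
        k1=4.3 * params.theta0 * params.e0 * params.te,
        k2=params.eps * params.r0 * params.e0 * params.te,
        k3=1.0 - params.eps,
    )


@dataclass(frozen=True)
class ModelSpec:
    """A validated (graph, parameters, stimuli) triple.

    Construct via :func:`validate_model`; ``params`` holds one
    PhysioParams per region.
    """

    graph: RegionGraphSpec
    params: tuple[PhysioParams, ...]
    stimuli: StimulusSet

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions

    def physio_arrays(self) -> dict[str, np.ndarray]:
        """Stack per-region scalars into (n,) float arrays for the engine."""
        names = list(_DEFAULTS)
        return {name: np.array([getattr(p, name) for p in self.params], dtype=float)
                for name in names}

    def bold_constants(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ks = [derive_bold_constants(p) for p in self.params]
        return (np.array([k.k1 for k in ks]), np.array([k.k2 for k in ks]),
                np.array([k.k3 for k in ks]))


def _check_region(i: int, n: int, what: str) -> None:
    if not (0 <= i < n):
        raise ModelValidationError(f"{what}: region index {i} out of range for {n} regions")


def _check_input(j: int, n: int, what: str) -> None:
    if not (0 <= j < n):
        raise ModelValidationError(
            f"{what}: dangling input index {j} (stimuli define {n} inputs)")


def validate_model(
    graph: RegionGraphSpec,
    params: PhysioParams | Sequence[PhysioParams],
    stimuli: StimulusSet,
) -> ModelSpec:
    """Validate every structural invariant and bundle a ModelSpec.

    Raises :class:`ModelValidationError` naming the first violated
    invariant (self-edge, out-of-range region, dangling input index,
    non-uniform grid, invalid physiology).  Idempotent: revalidating the
    components of a returned ModelSpec yields an equal ModelSpec.
    """
    n = graph.n_regions
    if n < 1:
        raise ModelValidationError("n_regions must be a positive integer")

    if isinstance(params, PhysioParams):
        params = tuple([params] * n)
    else:
        params = tuple(params)
    if len(params) != n:
        raise ModelValidationError(f"expected {n} per-region parameter sets, got {len(params)}")
    for p in params:
        p.check()

    stimuli.check()
    n_mod = stimuli.modulatory.shape[0]
    n_drv = stimuli.driving.shape[0]
    n_mu = stimuli.mu_context.shape[0]
    n_lam = stimuli.lambda_context.shape[0]

    for (s, t), a in graph.edges.items():
        if s == t:
            raise ModelValidationError(
                f"self-edge ({s + 1},{t + 1}): self-connections live in the exponential "
                "diagonal, not in the edge list")
        _check_region(s, n, "edge source")
        _check_region(t, n, "edge target")
        if not math.isfinite(a):
            raise ModelValidationError(f"edge ({s + 1},{t + 1}) strength is not finite")
    for (s, t, m), b in graph.modulatory_edges.items():
        if s == t:
            raise ModelValidationError(f"self-edge ({s + 1},{t + 1}) in modulatory_edges")
        _check_region(s, n, "modulatory edge source")
        _check_region(t, n, "modulatory edge target")
        _check_input(m, n_mod, f"modulatory edge ({s + 1},{t + 1})")
        if (s, t) not in graph.edges and (s, t) not in graph.modulation_only:
            raise ModelValidationError(
                f"modulatory edge ({s + 1},{t + 1}) has no baseline edge and is not "
                "flagged modulation-only")
        if not math.isfinite(b):
            raise ModelValidationError(f"modulatory edge ({s + 1},{t + 1}) weight not finite")
    for (r, j) in graph.driving_map:
        _check_region(r, n, "driving map")
        _check_input(j, n_drv, f"driving map region {r + 1}")
    for (r, j) in graph.self_mod:
        _check_region(r, n, "self modulation")
        _check_input(j, n_mod, f"self modulation region {r + 1}")
    for (r, j) in graph.inhibitory_mu_mod:
        _check_region(r, n, "inhibitory mu modulation")
        _check_input(j, n_mu, f"mu modulation region {r + 1}")
    for (r, j) in graph.inhibitory_lambda_mod:
        _check_region(r, n, "inhibitory lambda modulation")
        _check_input(j, n_lam, f"lambda modulation region {r + 1}")

    return ModelSpec(graph=graph, params=params, stimuli=stimuli)
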