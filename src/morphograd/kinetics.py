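"""Sampling of per-cell kinetic parameters and source boundary draws.

Each cell carries its own morphogen production rate ``p``, decay rate
``d`` and diffusivity ``D``, drawn independently from log-normal
distributions — a coarse-grained representation of molecular noise that
is static in time but uncorrelated between cells. The decay exponent
``n`` and the reference concentration ``C_ref`` (which keeps the units
of the decay term independent of ``n``) are global.

Default parameter scales follow measurements of Hedgehog gradients:
mean diffusivity ``mu_D = 0.033 µm²/s`` and mean exponential decay
length ``mu_lambda = 20 µm``, which pin ``mu_d = mu_D / mu_lambda²``
and ``mu_p = mu_d * C_ref``. Physiological noise levels are around
``CV ≈ 0.3`` for the kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from morphograd.tissue_domain import CellularDomain, lognormal_shape_params

__all__ = [
    "DEFAULT_DIFFUSIVITY",
    "DEFAULT_DECAY_LENGTH",
    "KineticSpec",
    "KineticField",
    "SourceBoundarySpec",
    "default_kinetics",
    "sample_kinetic_field",
    "sample_source_boundary",
]

DEFAULT_DIFFUSIVITY = 0.033  # µm²/s
DEFAULT_DECAY_LENGTH = 20.0  # µm


@dataclass(frozen=True)
class KineticSpec:
    """Means and CVs of the log-normal kinetic parameter distributions.

    Attributes
    ----------
    mu_p
        Mean production rate (conc/s), active only in source cells.
    mu_d
        Mean decay rate (1/s). For linear decay the gradient length is
        ``sqrt(mu_D / mu_d)``.
    mu_D
        Mean diffusivity (µm²/s).
    cv_p, cv_d, cv_D
        Coefficients of variation of the three parameters.
    n
        Decay exponent; 1 is linear decay, larger values model
        self-enhanced degradation.
    C_ref
        Reference concentration normalizing the non-linear decay term
        ``d * C**n / C_ref**(n-1)`` (arb. units).
    """

    mu_p: float
    mu_d: float
    mu_D: float
    cv_p: float = 0.3
    cv_d: float = 0.3
    cv_D: float = 0.3
    n: float = 1.0
    C_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_p", "mu_d", "mu_D", "C_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("cv_p", "cv_d", "cv_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.n < 1:
            raise ValueError(f"decay exponent n must be >= 1, got {self.n}")

    @property
    def decay_length(self) -> float:
        """Linear-decay gradient length sqrt(mu_D / mu_d) in µm."""
        return float(np.sqrt(self.mu_D / self.mu_d))

    def with_(self, **kwargs) -> "KineticSpec":
        return replace(self, **kwargs)


def default_kinetics(**overrides) -> KineticSpec:
    """Default kinetic parameters.

    ``mu_D = 0.033 µm²/s``, ``mu_lambda = 20 µm`` so that
    ``mu_d = mu_D / mu_lambda² = 8.25e-5 /s``, ``mu_p = mu_d * C_ref``
    with ``C_ref = 1``, and all kinetic CVs at 0.3. Keyword overrides
    are applied on top (e.g. ``default_kinetics(n=2)``).
    """
    mu_D = DEFAULT_DIFFUSIVITY
    mu_d = mu_D / DEFAULT_DECAY_LENGTH**2
    c_ref = float(overrides.get("C_ref", 1.0))
    spec = KineticSpec(mu_p=mu_d * c_ref, mu_d=mu_d, mu_D=mu_D, C_ref=c_ref)
    if overrides:
        spec = replace(spec, **overrides)
    return spec


@dataclass(frozen=True)
class KineticField:
    """One realization of per-cell kinetic parameters.

    ``p``, ``d`` and ``D`` are aligned with the cells of a
    ``CellularDomain``; production only contributes in source cells
    (the solver applies the Heaviside factor)."""

    p: np.ndarray
    d: np.ndarray
    D: np.ndarray
    n: float
    C_ref: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        d = np.asarray(self.d, dtype=float)
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "D", D)
        if not (p.size == d.size == D.size):
            raise ValueError("p, d, D must have one value per cell")
        if np.any(p <= 0) or np.any(d <= 0) or np.any(D <= 0):
            raise ValueError("kinetic parameters must be strictly positive")

    @property
    def n_cells(self) -> int:
        return self.p.size


def _lognormal_draws(mean: float, cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    if cv == 0.0:
        return np.full(size, mean)
    mu_ln, sigma_ln = lognormal_shape_params(mean, cv)
    return rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=size)


def sample_kinetic_field(
    spec: KineticSpec, domain: CellularDomain, rng: np.random.Generator
) -> KineticField:
    """Draw independent (p, d, D) values for every cell of ``domain``."""
    n_cells = domain.n_cells
    return KineticField(
        p=_lognormal_draws(spec.mu_p, spec.cv_p, n_cells, rng),
        d=_lognormal_draws(spec.mu_d, spec.cv_d, n_cells, rng),
        D=_lognormal_draws(spec.mu_D, spec.cv_D, n_cells, rng),
        n=spec.n,
        C_ref=spec.C_ref,
    )


@dataclass(frozen=True)
class SourceBoundarySpec:
    """How the morphogen source is represented.

    ``source-domain``: morphogen is produced at rate ``p`` in explicit
    source cells on [-Ls, 0); the outer boundary at -Ls is no-flux.
    ``flux``: no source cells; an influx ``-D C'(0) = j0`` is imposed
    at x = 0, with ``j0`` drawn log-normally (mean ``mu_j0``).
    ``dirichlet``: no source cells; a fixed amplitude ``C(0) = C0`` is
    imposed, with ``C0`` drawn log-normally (mean ``mu_C0``).

    Default means place the three modes on equal footing for the
    default kinetics: ``mu_j0 = mu_D * C_ref / mu_lambda`` and
    ``mu_C0 = C_ref``.
    """

    mode: str = "source-domain"
    mu_j0: float = DEFAULT_DIFFUSIVITY * 1.0 / DEFAULT_DECAY_LENGTH
    mu_C0: float = 1.0
    cv_j0: float = 0.3
    cv_C0: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("source-domain", "flux", "dirichlet"):
            raise ValueError(f"unknown source mode {self.mode!r}")
        if self.mode == "flux" and self.mu_j0 <= 0:
            raise ValueError("mu_j0 must be positive in flux mode")
        if self.mode == "dirichlet" and self.mu_C0 <= 0:
            raise ValueError("mu_C0 must be positive in dirichlet mode")
        if self.cv_j0 < 0 or self.cv_C0 < 0:
            raise ValueError("boundary CVs must be non-negative")

    @property
    def mean_boundary_value(self) -> float:
        if self.mode == "flux":
            return self.mu_j0
        if self.mode == "dirichlet":
            return self.mu_C0
        raise ValueError("source-domain mode has no boundary value")


def sample_source_boundary(spec: SourceBoundarySpec, rng: np.random.Generator) -> float:
    """Draw one j0 (flux mode) or C0 (dirichlet mode) value.

    Raises
    ------
    ValueError
        In ``source-domain`` mode, where production is part of the
        per-cell kinetic field and no boundary draw exists.
    """
    if spec.mode == "source-domain":
        raise ValueError("no source boundary draw in source-domain mode")
    if spec.mode == "flux":
        return float(_lognormal_draws(spec.mu_j0, spec.cv_j0, 1, rng)[0])
    return float(_lognormal_draws(spec.mu_C0, spec.cv_C0, 1, rng)[0])
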