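"""Threshold readout, positional error and ensemble simulation.

Under the French flag paradigm a cell compares its sensed (diameter-
averaged) morphogen concentration to a threshold ``C_theta`` and
switches fate when the concentration falls below it. For each noisy
gradient realization j the position ``x_theta_j`` of the first
patterning cell whose average concentration subceeds the threshold is
recorded (at the cell border facing the source, where the fate
boundary forms). The positional error is the standard deviation of
these readout positions across realizations,

    sigma_x = stddev_j[x_theta_j],

with a bootstrap standard error. Realizations in which no cell
subceeds the threshold are censored and excluded (not imputed), and
ensembles with more than 20% censoring or solver failures are flagged
unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from morphograd.gradient_solver import (
    GradientRealization,
    SolverFailure,
    deterministic_reference,
    solve_steady_state,
)
from morphograd.kinetics import (
    KineticSpec,
    SourceBoundarySpec,
    sample_kinetic_field,
    sample_source_boundary,
)
from morphograd.tissue_domain import AreaDistributionSpec, CellularDomain, sample_domain

__all__ = [
    "EnsembleConfig",
    "ReadoutEnsemble",
    "PrecisionSummary",
    "threshold_from_reference",
    "read_position",
    "run_ensemble",
    "simulate_realizations",
    "positional_error",
    "eq_noise_to_position_error",
]

UNRELIABLE_FRACTION = 0.2  # censoring/failure fraction above which an ensemble is flagged


def threshold_from_reference(reference: GradientRealization, x_target: float) -> float:
    """Threshold concentration whose nominal readout position is
    ``x_target``: the cell-averaged concentration of the reference cell
    containing that position.

    The reference is typically the noise-free mean-parameter gradient,
    so the map from position to threshold is deterministic and strictly
    decreasing.
    """
    dom = reference.domain
    if not (0.0 <= x_target <= dom.Lp):
        raise ValueError(f"x_target {x_target} outside the patterning domain [0, {dom.Lp}]")
    idx = int(dom.cell_index(x_target)) - dom.n_source_cells
    return float(reference.cell_averages[idx])


def read_position(
    realization: GradientRealization,
    domain: CellularDomain,
    C_theta: float,
) -> float:
    """Readout position for one gradient: the source-facing border of
    the first patterning cell (scanning from x = 0) whose average
    concentration lies strictly below ``C_theta``.

    Returns ``nan`` (censored) if no cell subceeds the threshold.
    """
    if C_theta <= 0:
        return math.nan
    below = realization.cell_averages < C_theta
    idx = np.nonzero(below)[0]
    if idx.size == 0:
        return math.nan
    return float(domain.patterning_boundaries[idx[0]])


@dataclass(frozen=True)
class ReadoutEnsemble:
    """Readout positions over replicate gradients for one threshold.

    ``positions`` has one entry per *solved* replicate, with ``nan``
    marking censored readouts; ``n_failed`` counts replicates whose
    steady-state solve did not converge (excluded entirely).
    """

    positions: np.ndarray
    threshold: float
    target_position: float
    n_replicates: int
    n_censored: int
    n_failed: int = 0
    mu_delta: float = math.nan
    failed_seeds: tuple = ()

    @property
    def uncensored(self) -> np.ndarray:
        return self.positions[~np.isnan(self.positions)]

    @property
    def unreliable(self) -> bool:
        bad = self.n_censored + self.n_failed
        return bad > UNRELIABLE_FRACTION * self.n_replicates


@dataclass(frozen=True)
class PrecisionSummary:
    """Mean readout position, positional error and its bootstrap SE."""

    mu_x: float
    sigma_x: float
    sigma_x_se: float
    n_used: int
    n_censored: int
    n_failed: int = 0
    mu_delta: float = math.nan
    sigma_C_local: float = math.nan

    @property
    def sigma_x_cell_units(self) -> float:
        return self.sigma_x / self.mu_delta


@dataclass(frozen=True)
class EnsembleConfig:
    """Everything needed to simulate one ensemble of noisy gradients."""

    kinetics: KineticSpec
    area: AreaDistributionSpec = AreaDistributionSpec()
    source: SourceBoundarySpec = SourceBoundarySpec()
    Ls_over_delta: float = 5.0
    Lp_over_delta: float = 200.0

    @property
    def mu_delta(self) -> float:
        return self.area.mu_delta

    @property
    def Ls(self) -> float:
        if self.source.mode != "source-domain":
            return 0.0
        return self.Ls_over_delta * self.mu_delta

    @property
    def Lp(self) -> float:
        return self.Lp_over_delta * self.mu_delta

    def reference(self, tol: float = 1e-6) -> GradientRealization:
        return deterministic_reference(
            self.kinetics, self.source, Ls=self.Ls, Lp=self.Lp, mu_delta=self.mu_delta, tol=tol
        )


def simulate_realizations(
    config: EnsembleConfig, n_replicates: int, seed: int = 0
) -> list[tuple[CellularDomain, GradientRealization]]:
    """Solve ``n_replicates`` independent noisy gradients and return
    the (domain, realization) pairs, skipping failed solves. Useful for
    inspecting concentration statistics directly (e.g. local sigma_C)."""
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    out = []
    for child in children:
        try:
            out.append(_simulate_replicate(config, child))
        except SolverFailure:
            continue
    return out


def _simulate_replicate(config: EnsembleConfig, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    domain = sample_domain(config.area, config.Ls, config.Lp, rng)
    field = sample_kinetic_field(config.kinetics, domain, rng)
    bval = None
    if config.source.mode != "source-domain":
        bval = sample_source_boundary(config.source, rng)
    realization = solve_steady_state(domain, field, config.source, boundary_value=bval)
    return domain, realization


def run_ensemble(
    config: EnsembleConfig,
    x_targets,
    n_replicates: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
) -> dict[float, ReadoutEnsemble]:
    """Simulate ``n_replicates`` independent noisy gradients and read
    them out at one or more target positions.

    Thresholds are mapped from the noise-free mean-parameter reference
    gradient: ``C_theta(x_target)`` is the averaged concentration of
    the reference cell containing ``x_target``. Each replicate draws
    its own cellular domain, kinetic field and (in flux/dirichlet
    modes) source boundary value from an independent substream of the
    master seed, so any replicate can be reproduced in isolation.

    Returns a dict mapping each target position to a
    ``ReadoutEnsemble``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    x_targets = [float(x) for x in np.atleast_1d(x_targets)]
    reference = config.reference()
    thresholds = {x: threshold_from_reference(reference, x) for x in x_targets}

    children = np.random.SeedSequence(seed).spawn(n_replicates)
    results: list[tuple[CellularDomain, GradientRealization] | None] = []
    failed_seeds: list[int] = []

    def one(i: int):
        try:
            return _simulate_replicate(config, children[i])
        except SolverFailure:
            return None

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n_replicates))
    else:
        results = [one(i) for i in range(n_replicates)]

    failed_seeds = [i for i, r in enumerate(results) if r is None]
    solved = [r for r in results if r is not None]

    out: dict[float, ReadoutEnsemble] = {}
    for x_t in x_targets:
        c_theta = thresholds[x_t]
        positions = np.array(
            [read_position(real, dom, c_theta) for dom, real in solved], dtype=float
        )
        out[x_t] = ReadoutEnsemble(
            positions=positions,
            threshold=c_theta,
            target_position=x_t,
            n_replicates=n_replicates,
            n_censored=int(np.isnan(positions).sum()),
            n_failed=len(failed_seeds),
            mu_delta=config.mu_delta,
            failed_seeds=tuple(failed_seeds),
        )
    return out


def positional_error(
    ensemble: ReadoutEnsemble,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> PrecisionSummary:
    """Positional error (sample SD of uncensored readout positions)
    with a bootstrap standard error.

    Censored replicates carry no position and are excluded; at least
    two uncensored positions are required.
    """
    x = ensemble.uncensored
    if x.size < 2:
        raise ValueError("positional error undefined with fewer than 2 uncensored readouts")
    if rng is None:
        rng = np.random.default_rng(0)
    mu_x = float(np.mean(x))
    sigma_x = float(np.std(x, ddof=1))
    resamples = rng.choice(x, size=(n_bootstrap, x.size), replace=True)
    sigma_boot = np.std(resamples, axis=1, ddof=1)
    return PrecisionSummary(
        mu_x=mu_x,
        sigma_x=sigma_x,
        sigma_x_se=float(np.std(sigma_boot, ddof=1)),
        n_used=int(x.size),
        n_censored=ensemble.n_censored,
        n_failed=ensemble.n_failed,
        mu_delta=ensemble.mu_delta,
    )


def eq_noise_to_position_error(sigma_C: float, slope: float) -> float:
    """First-order estimate of the positional error from local
    concentration noise: ``sigma_x ≈ |dC/dx|^-1 sigma_C``.

    A vanishing slope (e.g. at the distal zero-flux boundary) makes
    the prediction diverge — the mechanism behind the loss of
    precision near an impermeable tissue end.
    """
    if sigma_C < 0:
        raise ValueError("sigma_C must be non-negative")
    if slope == 0:
        return math.inf
    return sigma_C / abs(slope)
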