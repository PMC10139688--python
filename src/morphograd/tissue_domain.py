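"""Construction of 1D cellular tissue domains.

The tissue is a line of cells spanning a morphogen source region on
``[-Ls, 0)`` and a patterning region on ``[0, Lp]``. Cell cross-sectional
areas ``A_i`` are drawn from a log-normal distribution and converted to
diameters ``delta_i = 2 * sqrt(A_i / pi)``; cells are appended one by one
until each region is filled. The log-normal mean area is chosen as

    mu_A = pi * (mu_delta / 2)**2 * (1 + CV_A**2)**(1/4)

which makes the mean of the resulting *diameters* exactly ``mu_delta``
(the quarter-power corrects for the concavity of the square root under
the log-normal law). No cell straddles ``x = 0``, so morphogen
production can switch off exactly at the source boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AreaDistributionSpec",
    "CellularDomain",
    "mean_area_from_diameter",
    "lognormal_shape_params",
    "sample_areas",
    "sample_domain",
    "uniform_domain",
]


def mean_area_from_diameter(mu_delta: float, cv_A: float) -> float:
    """Mean cell area giving a mean cell *diameter* of ``mu_delta``.

    Parameters
    ----------
    mu_delta
        Target mean cell diameter in µm. Must be positive.
    cv_A
        Coefficient of variation of the cell areas (dimensionless,
        non-negative).

    Returns
    -------
    float
        Mean area µm² of the log-normal area distribution. For
        ``cv_A = 0`` this is the area of a circle of diameter
        ``mu_delta``.
    """
    if mu_delta <= 0:
        raise ValueError(f"mu_delta must be positive, got {mu_delta}")
    if cv_A < 0:
        raise ValueError(f"cv_A must be non-negative, got {cv_A}")
    return np.pi * (mu_delta / 2.0) ** 2 * (1.0 + cv_A**2) ** 0.25


def lognormal_shape_params(mean: float, cv: float) -> tuple[float, float]:
    """Underlying normal parameters (mu_ln, sigma_ln) for a log-normal
    with the given arithmetic mean and coefficient of variation.

    Moment matching: ``sigma_ln**2 = ln(1 + cv**2)`` and
    ``mu_ln = ln(mean) - sigma_ln**2 / 2``.
    """
    if mean <= 0:
        raise ValueError(f"log-normal mean must be positive, got {mean}")
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    sigma_ln2 = np.log1p(cv**2)
    mu_ln = np.log(mean) - sigma_ln2 / 2.0
    return mu_ln, float(np.sqrt(sigma_ln2))


@dataclass(frozen=True)
class AreaDistributionSpec:
    """Log-normal cell-area distribution, parameterized by the target
    mean cell diameter ``mu_delta`` (µm) and the area CV ``cv_A``."""

    mu_delta: float = 5.0
    cv_A: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_delta <= 0:
            raise ValueError(f"mu_delta must be positive, got {self.mu_delta}")
        if self.cv_A < 0:
            raise ValueError(f"cv_A must be non-negative, got {self.cv_A}")

    @property
    def mu_A(self) -> float:
        """Mean cell area µm²."""
        return mean_area_from_diameter(self.mu_delta, self.cv_A)


def sample_areas(spec: AreaDistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. cell areas (µm²) from the specified log-normal."""
    if spec.cv_A == 0.0:
        return np.full(n, spec.mu_A)
    mu_ln, sigma_ln = lognormal_shape_params(spec.mu_A, spec.cv_A)
    return rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=n)


@dataclass(frozen=True)
class CellularDomain:
    """An ordered 1D cellular domain with source on [-Ls, 0) and
    patterning region on [0, Lp].

    Attributes
    ----------
    boundaries
        Cell border positions in µm, strictly increasing from ``-Ls``
        to ``Lp``; ``len(boundaries) == n_cells + 1``.
    diameters
        Per-cell widths in µm, all positive.
    is_source
        Boolean flag per cell, True iff the cell lies at x < 0.
    Ls, Lp
        Source and patterning region lengths in µm.
    """

    boundaries: np.ndarray
    diameters: np.ndarray
    is_source: np.ndarray
    Ls: float
    Lp: float

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        s = np.asarray(self.is_source, dtype=bool)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "is_source", s)
        if b.ndim != 1 or b.size != d.size + 1 or d.size != s.size:
            raise ValueError("inconsistent boundary/diameter/flag lengths")
        if np.any(d <= 0):
            raise ValueError("all cell diameters must be positive")
        if np.any(np.diff(b) <= 0):
            raise ValueError("cell boundaries must be strictly increasing")
        if not (np.isclose(b[0], -self.Ls) and np.isclose(b[-1], self.Lp)):
            raise ValueError("boundaries must span [-Ls, Lp]")

    @property
    def n_cells(self) -> int:
        return self.diameters.size

    @property
    def n_source_cells(self) -> int:
        return int(np.count_nonzero(self.is_source))

    @property
    def patterning_boundaries(self) -> np.ndarray:
        """Borders of the patterning cells only (from 0 to Lp)."""
        return self.boundaries[self.n_source_cells:]

    def cell_index(self, x: float | np.ndarray) -> np.ndarray:
        """Index of the cell containing position ``x`` (border positions
        belong to the cell on their right, except at ``x = Lp``)."""
        idx = np.searchsorted(self.boundaries, x, side="right") - 1
        return np.clip(idx, 0, self.n_cells - 1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "boundaries": self.boundaries.tolist(),
                "diameters": self.diameters.tolist(),
                "is_source": self.is_source.astype(int).tolist(),
                "Ls": self.Ls,
                "Lp": self.Lp,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "CellularDomain":
        rec = json.loads(payload)
        return cls(
            boundaries=np.asarray(rec["boundaries"], dtype=float),
            diameters=np.asarray(rec["diameters"], dtype=float),
            is_source=np.asarray(rec["is_source"], dtype=bool),
            Ls=float(rec["Ls"]),
            Lp=float(rec["Lp"]),
        )


def _fill_region(spec: AreaDistributionSpec, length: float, rng: np.random.Generator) -> np.ndarray:
    """Append cells until their cumulative width reaches ``length``; the
    final cell is truncated so the region length is met exactly."""
    if length == 0:
        return np.empty(0)
    diameters: list[float] = []
    total = 0.0
    # draw in blocks to amortize RNG calls
    block = max(8, int(np.ceil(length / spec.mu_delta)) + 4)
    while total < length:
        areas = sample_areas(spec, block, rng)
        for a in areas:
            delta = 2.0 * np.sqrt(a / np.pi)
            diameters.append(delta)
            total += delta
            if total >= length:
                break
    # truncate the last cell so the cumulative sum is exact
    overshoot = total - length
    diameters[-1] -= overshoot
    if diameters[-1] <= 1e-9 * spec.mu_delta and len(diameters) > 1:
        # degenerate sliver from float accumulation: absorb into neighbour
        sliver = diameters.pop()
        diameters[-1] += sliver
    return np.asarray(diameters)


def sample_domain(
    spec: AreaDistributionSpec,
    Ls: float,
    Lp: float,
    rng: np.random.Generator,
) -> CellularDomain:
    """Sample one cellular domain with log-normal cell areas.

    Source ([-Ls, 0)) and patterning ([0, Lp]) regions are filled
    independently, cell by cell; the last cell of each region is
    truncated so region lengths are exact for every draw.

    Parameters
    ----------
    spec
        Area distribution (mean diameter and area CV).
    Ls
        Source region length µm (``>= 0``; 0 means no explicit source,
        as used with flux or Dirichlet source boundary conditions).
    Lp
        Patterning region length µm (positive).
    rng
        NumPy random generator.
    """
    if Ls < 0:
        raise ValueError(f"Ls must be non-negative, got {Ls}")
    if Lp <= 0:
        raise ValueError(f"Lp must be positive, got {Lp}")
    d_src = _fill_region(spec, Ls, rng)
    d_pat = _fill_region(spec, Lp, rng)
    diameters = np.concatenate([d_src, d_pat])
    boundaries = np.concatenate([[-Ls], -Ls + np.cumsum(diameters)])
    boundaries[d_src.size] = 0.0  # exact source/patterning junction
    boundaries[-1] = Lp
    is_source = np.zeros(diameters.size, dtype=bool)
    is_source[: d_src.size] = True
    return CellularDomain(boundaries, diameters, is_source, Ls=Ls, Lp=Lp)


def uniform_domain(mu_delta: float, Ls: float, Lp: float) -> CellularDomain:
    """Deterministic domain of uniform cells of width ``mu_delta``.

    Used for noise-free reference gradients. If a region length is not
    an integer multiple of ``mu_delta``, the last cell is truncated.
    """
    if mu_delta <= 0:
        raise ValueError(f"mu_delta must be positive, got {mu_delta}")

    def region(length: float) -> np.ndarray:
        if length == 0:
            return np.empty(0)
        n_full = int(np.floor(length / mu_delta - 1e-12))
        d = [mu_delta] * n_full
        rest = length - n_full * mu_delta
        if rest > 1e-12 * mu_delta:
            d.append(rest)
        return np.asarray(d)

    d_src, d_pat = region(Ls), region(Lp)
    diameters = np.concatenate([d_src, d_pat])
    boundaries = np.concatenate([[-Ls], -Ls + np.cumsum(diameters)])
    boundaries[d_src.size] = 0.0
    boundaries[-1] = Lp
    is_source = np.zeros(diameters.size, dtype=bool)
    is_source[: d_src.size] = True
    return CellularDomain(boundaries, diameters, is_source, Ls=Ls, Lp=Lp)
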