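"""Synthetic (length, true thermal age) datasets for the validation pipeline.

Emulates the statistical structure the calibration formula assumes:
individual body lengths on a half-millimetre grid, concentrated near the
population mean, and individual true thermal ages scattered around a linear
conditional mean with negative slope.  Two ready-made specifications mirror
the in-house beetle rearing datasets used to validate the calibration:
173 Creophilus maxillosus records over 15-24 mm and 954 Necrodes littoralis
records over 12-22 mm.

Lengths are drawn from a truncated normal centred at the range midpoint
(sd parameter sqrt(3)*(l_max - l_min)/6), discretized to the grid by exact
bin probabilities; a uniform-grid mode exists to exercise the
arithmetic-sequence moment approximations.  The residual sd around the
generating line is chosen by variance decomposition so the marginal sd of
true k matches the analytic target ``s_e * sqrt(m) / 2``:

    sd_residual^2 = max(0, sd_total^2 - slope^2 * sd_length^2)

where ``sd_length`` is the *exact* sd of the discretized length
distribution (smaller than the analytic sqrt(3)w/6 because of truncation —
which is what leaves room for a positive residual term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .calibration import (
    CorrelationSign,
    SizeRange,
    ThermalSummationParams,
    Unit,
    calibration_line,
    sd_length_approx,
    sd_true_k,
)
from .registry import get_species
from .validation import InsectRecord

__all__ = ["LengthDistribution", "GeneratorSpec", "default_spec", "generate",
           "length_grid", "length_pmf"]

# Dataset sizes and length ranges of the two source rearing datasets.
DATASET_SHAPES = {
    "Creophilus maxillosus": (173, SizeRange(15.0, 24.0, source="dataset")),
    "Necrodes littoralis": (954, SizeRange(12.0, 22.0, source="dataset")),
}


class LengthDistribution(str, Enum):
    TRUNCNORM = "discretized-truncated-normal"
    UNIFORM_GRID = "uniform-grid"


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to generate one synthetic dataset reproducibly."""

    species: str
    n: int
    size_range: SizeRange
    intercept: float
    slope: float
    residual_sd: float
    seed: int = 0
    grid_step: float = 0.5
    length_distribution: LengthDistribution = LengthDistribution.TRUNCNORM
    unit: Unit = Unit.ADD

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual sd must be non-negative")
        if not np.isfinite([self.intercept, self.slope]).all():
            raise ValueError("generating line must be finite")

    def line(self, l):
        return self.intercept + self.slope * np.asarray(l, dtype=float)


def length_grid(size_range: SizeRange, step: float = 0.5) -> np.ndarray:
    """Grid of admissible lengths from l_min to l_max inclusive."""
    n = int(round(size_range.width / step)) + 1
    return size_range.l_min + step * np.arange(n)


def length_pmf(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Grid points and their exact sampling probabilities.

    Truncated-normal mode integrates the normal density (mean = midpoint,
    sd = sqrt(3)w/6) over each half-step bin and renormalizes over the
    range; uniform-grid mode weights every grid point equally.
    """
    grid = length_grid(spec.size_range, spec.grid_step)
    if spec.length_distribution is LengthDistribution.UNIFORM_GRID:
        p = np.full(grid.size, 1.0 / grid.size)
        return grid, p
    mu = spec.size_range.midpoint
    sigma = sd_length_approx(spec.size_range)
    half = spec.grid_step / 2.0
    upper = stats.norm.cdf(grid + half, loc=mu, scale=sigma)
    lower = stats.norm.cdf(grid - half, loc=mu, scale=sigma)
    p = upper - lower
    return grid, p / p.sum()


def _pmf_sd(grid: np.ndarray, p: np.ndarray) -> float:
    mean = float(np.dot(p, grid))
    return float(np.sqrt(np.dot(p, (grid - mean) ** 2)))


def default_spec(species: str, seed: int = 0) -> GeneratorSpec:
    """Generator specification emulating one of the two source datasets.

    The generating line is the species' calibration line recomputed on the
    dataset's own length range; the residual sd comes from the variance
    decomposition against the target marginal sd ``s_e * sqrt(m) / 2``.
    """
    entry = get_species(species)
    if entry.species not in DATASET_SHAPES:
        raise ValueError(
            f"no dataset emulation defined for {entry.species!r}; "
            f"choose one of {sorted(DATASET_SHAPES)}"
        )
    n, size_range = DATASET_SHAPES[entry.species]
    line = calibration_line(entry.params, size_range, entry.correlation_sign)
    sd_total = sd_true_k(entry.params.s_e, entry.params.m)
    probe = GeneratorSpec(
        species=entry.species, n=n, size_range=size_range,
        intercept=line.intercept, slope=line.slope, residual_sd=0.0, seed=seed,
        unit=entry.params.unit,
    )
    grid, p = length_pmf(probe)
    sd_len = _pmf_sd(grid, p)
    resid_var = sd_total**2 - line.slope**2 * sd_len**2
    if resid_var < 0:
        warnings.warn(
            "length spread alone exceeds the target marginal sd of true k; "
            "residual sd clipped to 0",
            UserWarning,
            stacklevel=2,
        )
        resid_var = 0.0
    return GeneratorSpec(
        species=entry.species, n=n, size_range=size_range,
        intercept=line.intercept, slope=line.slope,
        residual_sd=float(np.sqrt(resid_var)), seed=seed, unit=entry.params.unit,
    )


def generate(spec: GeneratorSpec) -> list[InsectRecord]:
    """Draw ``spec.n`` records; reproducible for a fixed seed.

    A single generator seeded with ``spec.seed`` governs both the length
    draws and the Gaussian residuals around the generating line.
    """
    rng = np.random.default_rng(spec.seed)
    grid, p = length_pmf(spec)
    lengths = rng.choice(grid, size=spec.n, p=p)
    resid = rng.normal(0.0, spec.residual_sd, size=spec.n) if spec.residual_sd > 0 \
        else np.zeros(spec.n)
    true_ks = spec.line(lengths) + resid
    return [
        InsectRecord(
            species=spec.species, length_mm=float(l), true_k=float(k), unit=spec.unit
        )
        for l, k in zip(lengths, true_ks)
    ]
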