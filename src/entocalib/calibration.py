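"""Closed-form calibration of thermal summation constants by insect body size.

The thermal summation constant *k* of an insect species is the physiological
age at adult emergence, expressed in accumulated degree-days (ADD) or
degree-hours (ADH) above the lower developmental threshold.  *k* is a
species-level average: individuals near the size extremes of a population
systematically deviate from it, because development time (and hence thermal
age) correlates with adult body size.

This module implements a calibration line that adjusts *k* for an
individual's body length *l* without requiring a fitted "k versus size"
regression.  Only quantities routinely published with thermal summation
models are needed: *k* itself, its standard error ``s_e``, the number of
experimental temperatures ``m`` used to derive it, and the species' adult
size range ``[l_min, l_max]`` from the entomological literature.  The
calibrated value is

    K_c(l) = k -+ s_e * sqrt(3 m) / (l_max - l_min) * (l - (l_max + l_min) / 2)

with ``-`` for the (usual) negative size/thermal-age correlation of
necrophagous and predatory species and ``+`` for the positive correlation of
parasitoids.  The line always passes through ``k`` at the midpoint of the
size range, and its total spread across the range is ``s_e * sqrt(3 m)``.

The construction rests on three moment approximations for a population whose
lengths span ``[l_min, l_max]``:

* ``sd(true k) ~= s_e * sqrt(m) / 2``    (:func:`sd_true_k`)
* ``sd(l) ~= sqrt(3) * (l_max - l_min) / 6``  (:func:`sd_length_approx`)
* ``mean(l) ~= (l_max + l_min) / 2``     (:func:`mean_length_approx`)

which, plugged into the reduced-major-axis slope ``sign(r) * sd(y)/sd(x)``
(see :mod:`entocalib.rma`), yield the line above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "Unit",
    "CorrelationSign",
    "ThermalSummationParams",
    "SizeRange",
    "CalibrationLine",
    "calibrate_k",
    "calibration_line",
    "sd_true_k",
    "sd_length_approx",
    "mean_length_approx",
]

HOURS_PER_DAY = 24.0


class Unit(str, Enum):
    """Thermal accumulation unit: degree-days or degree-hours (ADH = 24 x ADD)."""

    ADD = "ADD"
    ADH = "ADH"


class CorrelationSign(str, Enum):
    """Assumed sign of the correlation between body length and true thermal age.

    Negative for necrophagous and predatory carrion insects (larger adults
    emerge at a lower thermal age), positive for parasitoids.
    """

    NEGATIVE = "negative"
    POSITIVE = "positive"

    @property
    def value_sign(self) -> int:
        return -1 if self is CorrelationSign.NEGATIVE else 1


def _as_unit(unit: Unit | str) -> Unit:
    return Unit(unit) if not isinstance(unit, Unit) else unit


def _as_sign(sign: CorrelationSign | str) -> CorrelationSign:
    return CorrelationSign(sign) if not isinstance(sign, CorrelationSign) else sign


@dataclass(frozen=True)
class ThermalSummationParams:
    """Published constants of a species' linear thermal summation model.

    Parameters
    ----------
    k : float
        Thermal summation constant (thermal age at adult emergence), in `unit`.
    s_e : float
        Standard error of ``k``, same unit.
    m : int
        Number of constant experimental temperatures used to derive the model
        (at least 2; a thermal summation regression needs two temperatures).
    unit : Unit
        ADD (degree-days) or ADH (degree-hours).
    d0 : float, optional
        Lower developmental threshold (base temperature), deg C.
    """

    k: float
    s_e: float
    m: int
    unit: Unit = Unit.ADD
    d0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _as_unit(self.unit))
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.s_e < 0:
            raise ValueError(f"s_e must be non-negative, got {self.s_e}")
        if int(self.m) != self.m or self.m < 2:
            raise ValueError(f"m must be an integer >= 2, got {self.m}")
        object.__setattr__(self, "m", int(self.m))

    def to_unit(self, unit: Unit | str) -> "ThermalSummationParams":
        """Convert to the requested unit (ADH = 24 x ADD); d0 and m unchanged."""
        unit = _as_unit(unit)
        if unit is self.unit:
            return self
        factor = HOURS_PER_DAY if unit is Unit.ADH else 1.0 / HOURS_PER_DAY
        return replace(self, k=self.k * factor, s_e=self.s_e * factor, unit=unit)


@dataclass(frozen=True)
class SizeRange:
    """Adult body-length range of a species or population, in millimetres."""

    l_min: float
    l_max: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.l_min:
            raise ValueError(f"l_min must be positive, got {self.l_min}")
        if not self.l_min < self.l_max:
            raise ValueError(
                f"degenerate size range: require l_min < l_max, got "
                f"[{self.l_min}, {self.l_max}]"
            )

    @property
    def width(self) -> float:
        return self.l_max - self.l_min

    @property
    def midpoint(self) -> float:
        return (self.l_min + self.l_max) / 2.0

    def contains(self, l: float) -> bool:
        return self.l_min <= l <= self.l_max


@dataclass(frozen=True)
class CalibrationLine:
    """The calibration line K_c(l) = intercept + slope * l.

    ``slope`` is signed (negative for the usual negative size correlation).
    The line returns ``k`` of its generating parameters at the midpoint of
    ``valid_range`` and spans a total of ``s_e * sqrt(3 m)`` across it.
    """

    intercept: float
    slope: float
    unit: Unit
    valid_range: SizeRange
    correlation_sign: CorrelationSign

    @property
    def slope_magnitude(self) -> float:
        return abs(self.slope)

    def predict(self, l):
        """Evaluate K_c at length(s) ``l`` (mm); vectorized over arrays."""
        return self.intercept + self.slope * l

    __call__ = predict

    def __str__(self) -> str:  # e.g. "Kc(l) = 710.82 - 12.05*l [ADD]"
        op = "-" if self.slope < 0 else "+"
        return (
            f"Kc(l) = {self.intercept:.2f} {op} {abs(self.slope):.2f}*l "
            f"[{self.unit.value}]"
        )


def _slope_magnitude(params: ThermalSummationParams, size_range: SizeRange) -> float:
    return params.s_e * math.sqrt(3.0 * params.m) / size_range.width


def calibration_line(
    params: ThermalSummationParams,
    size_range: SizeRange,
    correlation_sign: CorrelationSign | str = CorrelationSign.NEGATIVE,
) -> CalibrationLine:
    """Construct the calibration line K_c(l) for a species.

    The signed slope is ``sign * s_e * sqrt(3 m) / (l_max - l_min)`` and the
    intercept is chosen so the line passes through ``k`` at the range
    midpoint.  With ``s_e = 0`` the line is the horizontal ``y = k`` (no
    calibration possible); a note is emitted.
    """
    correlation_sign = _as_sign(correlation_sign)
    if params.s_e == 0:
        warnings.warn(
            "s_e = 0: no calibration possible, line degenerates to constant k",
            UserWarning,
            stacklevel=2,
        )
    mag = _slope_magnitude(params, size_range)
    slope = correlation_sign.value_sign * mag
    intercept = params.k - slope * size_range.midpoint
    return CalibrationLine(
        intercept=intercept,
        slope=slope,
        unit=params.unit,
        valid_range=size_range,
        correlation_sign=correlation_sign,
    )


def calibrate_k(
    params: ThermalSummationParams,
    size_range: SizeRange,
    l: float,
    correlation_sign: CorrelationSign | str = CorrelationSign.NEGATIVE,
) -> float:
    """Calibrated thermal summation value K_c for an individual of length ``l``.

    Returns ``k`` exactly at the range midpoint; strictly decreasing in ``l``
    for negative correlation, strictly increasing for positive.  Lengths
    outside ``[l_min, l_max]`` are permitted (casework insects may slightly
    exceed literature ranges) but draw an extrapolation warning.
    """
    if not size_range.contains(l):
        warnings.warn(
            f"length {l} mm outside the calibration range "
            f"[{size_range.l_min}, {size_range.l_max}] mm: value is extrapolated",
            UserWarning,
            stacklevel=2,
        )
    line = calibration_line(params, size_range, correlation_sign)
    return float(line.predict(l))


def sd_true_k(s_e: float, m: int) -> float:
    """Approximate standard deviation of individual true thermal ages.

    ``sd(k_t) ~= s_e * sqrt(m) / 2`` — recovers the population spread of
    individual thermal ages from the standard error of the species mean and
    the number of experimental temperatures behind it.
    """
    if s_e < 0:
        raise ValueError("s_e must be non-negative")
    if m < 2:
        raise ValueError("m must be >= 2")
    return s_e * math.sqrt(m) / 2.0


def sd_length_approx(size_range: SizeRange) -> float:
    """Approximate sd of lengths spanning the range as an arithmetic sequence.

    ``sd(l) ~= sqrt(3) * (l_max - l_min) / 6`` — the large-n limit of the
    (population) sd of evenly spaced points over the range, identical to the
    sd of a continuous uniform distribution on it.
    """
    return math.sqrt(3.0) * size_range.width / 6.0


def mean_length_approx(size_range: SizeRange) -> float:
    """Approximate mean length: the midpoint of the size range."""
    return size_range.midpoint
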