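"""Thermal-time arithmetic for insect development.

Insect development under the linear degree-day model proceeds at a rate
proportional to temperature above the lower developmental threshold D0.
Physiological age is the accumulated thermal time: degree-days (ADD) or
degree-hours (ADH = 24 x ADD).  This module provides:

* true thermal age of an individual reared at constant temperature,
* conversion of thermal time back to clock time at a constant temperature,
* rectangular degree-day accumulation over a temperature log (clamped at D0),
* age at collection (calibrated age minus thermal time accrued during
  laboratory rearing),
* a minimal thermal-summation fitter (rate = 1/time regressed on
  temperature; k = 1/slope, D0 = -intercept/slope) for species lacking
  published constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import HOURS_PER_DAY, ThermalSummationParams, Unit, _as_unit

__all__ = [
    "TemperatureLog",
    "DevelopmentObservation",
    "true_k",
    "dd_to_days",
    "accumulate_dd",
    "age_at_collection",
    "fit_thermal_summation",
]


@dataclass(frozen=True)
class DevelopmentObservation:
    """One individual's constant-temperature rearing outcome."""

    temperature_c: float
    time_days: float
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if not self.time_days > 0:
            raise ValueError("development time must be positive")


class TemperatureLog:
    """An ordered temperature series with a declared sampling step (hours).

    Each sample represents the temperature over the following ``step_hours``
    interval (rectangular convention).
    """

    def __init__(self, timestamps, temps_c, step_hours: float):
        ts = pd.DatetimeIndex(timestamps)
        temps = np.asarray(temps_c, dtype=float)
        if len(ts) != temps.size:
            raise ValueError("timestamps and temperatures must have equal length")
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(ts) > 1 and ts.has_duplicates:
            raise ValueError("timestamps must be strictly increasing (duplicates found)")
        if not step_hours > 0:
            raise ValueError("sampling step must be positive")
        self.timestamps = ts
        self.temps_c = temps
        self.step_hours = float(step_hours)

    def __len__(self) -> int:
        return self.temps_c.size

    @classmethod
    def from_csv(cls, path, step_hours: float | None = None) -> "TemperatureLog":
        """Read a log CSV with columns ``timestamp`` (ISO-8601) and ``temp_c``.

        If ``step_hours`` is omitted it is inferred from the spacing of the
        first two timestamps.
        """
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if step_hours is None:
            if len(df) < 2:
                raise ValueError("cannot infer sampling step from fewer than 2 rows")
            step_hours = (
                (df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds()
                / 3600.0
            )
        return cls(df["timestamp"], df["temp_c"].to_numpy(), step_hours)

    @classmethod
    def constant(
        cls, temp_c: float, hours: float, step_hours: float = 1.0, start="2000-01-01"
    ) -> "TemperatureLog":
        """Convenience constructor: constant temperature for ``hours`` hours."""
        n = int(round(hours / step_hours))
        ts = pd.date_range(start=start, periods=n, freq=pd.Timedelta(hours=step_hours))
        return cls(ts, np.full(n, float(temp_c)), step_hours)


def true_k(
    obs: DevelopmentObservation, d0: float, unit: Unit | str = Unit.ADD
) -> float:
    """True thermal age at emergence of one individual.

    ``time * (temperature - D0)`` in ADD for time in days; x24 for ADH.
    """
    unit = _as_unit(unit)
    if obs.temperature_c <= d0:
        raise ValueError(
            f"no development at {obs.temperature_c} degC <= D0 = {d0} degC"
        )
    add = obs.time_days * (obs.temperature_c - d0)
    return add * HOURS_PER_DAY if unit is Unit.ADH else add


def dd_to_days(add: float, temperature_c: float, d0: float) -> float:
    """Clock days equivalent to ``add`` degree-days at a constant temperature."""
    if temperature_c <= d0:
        raise ValueError(
            f"no development at {temperature_c} degC <= D0 = {d0} degC"
        )
    return add / (temperature_c - d0)


def accumulate_dd(log: TemperatureLog, d0: float) -> float:
    """Degree-days accumulated over a temperature log (rectangular, clamped).

    ``sum max(T_i - D0, 0) * step/24``; never negative, additive over
    concatenated logs.
    """
    if len(log) == 0:
        warnings.warn("empty temperature log: 0 ADD accumulated", UserWarning,
                      stacklevel=2)
        return 0.0
    excess = np.clip(log.temps_c - d0, 0.0, None)
    return float(np.sum(excess) * log.step_hours / HOURS_PER_DAY)


def age_at_collection(
    k_c: float,
    rearing_accumulated: float,
    unit: Unit | str = Unit.ADD,
    rearing_unit: Unit | str | None = None,
) -> float:
    """Physiological age at collection: calibrated age minus rearing thermal time.

    Both quantities must be in the same unit.  A negative result is returned
    but flagged with a warning — collection age cannot be negative, so it
    signals inconsistent inputs.
    """
    unit = _as_unit(unit)
    if rearing_unit is not None and _as_unit(rearing_unit) is not unit:
        raise ValueError(
            f"unit mismatch: calibrated age in {unit.value}, rearing in "
            f"{_as_unit(rearing_unit).value}"
        )
    age = k_c - rearing_accumulated
    if age < 0:
        warnings.warn(
            f"negative age at collection ({age:g} {unit.value}): rearing "
            "accumulation exceeds the calibrated age — inputs are inconsistent",
            UserWarning,
            stacklevel=2,
        )
    return age


def fit_thermal_summation(
    observations: list[DevelopmentObservation], unit: Unit | str = Unit.ADD
) -> ThermalSummationParams:
    """Fit the linear thermal summation model to constant-temperature data.

    Regresses development rate 1/time on temperature; then ``k = 1/slope``
    and ``D0 = -intercept/slope``.  The standard error of ``k`` follows from
    the slope's standard error by first-order propagation,
    ``s_e(k) = se(slope) / slope**2``.  ``m`` is the number of distinct
    temperatures.
    """
    unit = _as_unit(unit)
    temps = np.array([o.temperature_c for o in observations], dtype=float)
    times = np.array([o.time_days for o in observations], dtype=float)
    m = int(np.unique(temps).size)
    if m < 3:
        raise ValueError(f"need >= 3 distinct temperatures, got {m}")
    rates = 1.0 / times
    res = stats.linregress(temps, rates)
    if res.slope <= 0:
        raise ValueError(
            "estimated slope of rate vs temperature is non-positive: "
            "no thermal response"
        )
    k = 1.0 / res.slope
    d0 = -res.intercept / res.slope
    s_e = res.stderr / res.slope**2
    if unit is Unit.ADH:
        k *= HOURS_PER_DAY
        s_e *= HOURS_PER_DAY
    return ThermalSummationParams(k=k, s_e=float(s_e), m=m, unit=unit, d0=float(d0))
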