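"""Reduced major axis (model II) regression.

RMA regression treats both variables as subject to variation — appropriate
when neither body length nor thermal age is a controlled predictor.  Its
loss is the summed product of vertical and horizontal residuals,

    L = sum_i (y_i - yhat_i) * (x_i - xhat_i),

minimized by slope ``sign(cor(x, y)) * sd(y) / sd(x)`` and intercept
``mean(y) - slope * mean(x)``.  Standard deviations use the population
(divide-by-n) convention; the slope is invariant to that choice but the
convention is fixed for exact reproducibility of the moment identities.

The model object follows the statsmodels pattern: ``RMA(endog, exog).fit()``
returns an :class:`RMAResults` carrying the estimates and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RMA", "RMAResults", "rma_fit", "rma_loss"]


@dataclass(frozen=True)
class RMAResults:
    """Fitted RMA line with sample moments.

    Attributes
    ----------
    slope, intercept : float
        Coefficients of y = slope * x + intercept.
    n : int
        Sample size.
    correlation : float
        Pearson correlation of x and y (its sign is the slope's sign).
    sd_x, sd_y : float
        Population (divide-by-n) standard deviations.
    """

    slope: float
    intercept: float
    n: int
    correlation: float
    sd_x: float
    sd_y: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        lines = [
            "Reduced Major Axis Regression Results",
            "=" * 45,
            f"{'No. observations:':<25}{self.n:>20d}",
            f"{'Slope:':<25}{self.slope:>20.6g}",
            f"{'Intercept:':<25}{self.intercept:>20.6g}",
            f"{'Pearson r:':<25}{self.correlation:>20.4f}",
            f"{'sd(x) (pop.):':<25}{self.sd_x:>20.6g}",
            f"{'sd(y) (pop.):':<25}{self.sd_y:>20.6g}",
            "=" * 45,
        ]
        return "\n".join(lines)


class RMA:
    """Reduced major axis regression model, ``endog`` (y) on ``exog`` (x)."""

    def __init__(self, endog, exog):
        y = np.asarray(endog, dtype=float).ravel()
        x = np.asarray(exog, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("endog and exog must have the same length")
        if x.size < 3:
            raise ValueError(f"RMA requires n >= 3 observations, got {x.size}")
        self.endog = y
        self.exog = x

    def fit(self) -> RMAResults:
        x, y = self.exog, self.endog
        n = x.size
        sd_x = float(np.std(x))  # population convention
        sd_y = float(np.std(y))
        if sd_x == 0:
            raise ValueError("sd(x) = 0: vertical degeneracy, RMA slope undefined")
        if sd_y == 0:
            raise ValueError("sd(y) = 0: horizontal degeneracy, RMA slope undefined")
        cov = float(np.mean((x - x.mean()) * (y - y.mean())))
        r = cov / (sd_x * sd_y)
        if r == 0:
            raise ValueError(
                "cor(x, y) = 0: slope sign is indeterminate for RMA regression"
            )
        slope = float(np.sign(r)) * sd_y / sd_x
        intercept = float(y.mean()) - slope * float(x.mean())
        return RMAResults(
            slope=slope,
            intercept=intercept,
            n=n,
            correlation=r,
            sd_x=sd_x,
            sd_y=sd_y,
        )


def rma_fit(x, y) -> RMAResults:
    """Functional shorthand for ``RMA(y, x).fit()`` (note the x, y order)."""
    return RMA(y, x).fit()


def rma_loss(x, y, line: RMAResults) -> float:
    """Product-of-residuals loss of ``line`` on the sample.

    ``L = |sum (y_i - yhat_i)(x_i - xhat_i)|`` with ``yhat = slope*x + b``
    and ``xhat = (y - b)/slope``.  Because each pointwise product equals
    ``-(1/slope) * (y_i - yhat_i)**2``, all products share one sign, so the
    magnitude of the sum equals the summed magnitudes — twice the total area
    of the residual triangles, the quantity RMA regression minimizes.  It is
    non-negative, zero for perfectly collinear data, and minimal at the RMA
    fit among lines of the same slope sign.
    """
    if line.slope == 0:
        raise ValueError("loss undefined for slope = 0 (horizontal residuals blow up)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    y_hat = line.slope * x + line.intercept
    x_hat = (y - line.intercept) / line.slope
    return float(abs(np.sum((y - y_hat) * (x - x_hat))))
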