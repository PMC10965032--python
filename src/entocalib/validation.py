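"""Validation pipeline: compare calibrated, fitted and constant thermal-age models.

The pipeline mirrors how a size calibration is judged against real rearing
data.  Individual (length, true thermal age) records — lengths measured on a
half-millimetre grid — are grouped into length classes and each class is
summarized by its median true k; medians remove the bias from heavily
unequal class sizes (most insects cluster near the mean length).  Three
models are then compared on the class medians by mean squared error:

* **RMA** — a reduced major axis line fitted to the medians themselves,
* **K_c** — the calibration line built only from the species constants
  (k, s_e, m) and the dataset's own minimal/maximal length,
* **constant k** — the horizontal line y = k (no calibration).

A second analysis restricts to unusually small and large individuals
(outside the ~33rd/~66th length percentiles), where calibration matters
most, and tests the per-class squared errors with a one-way ANOVA followed
by Fisher's LSD post hoc comparisons under Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calibration import (
    CalibrationLine,
    CorrelationSign,
    SizeRange,
    ThermalSummationParams,
    Unit,
    calibration_line,
)
from .rma import RMA, RMAResults

__all__ = [
    "InsectRecord",
    "LengthClass",
    "ConstantLine",
    "ThreeModels",
    "ExtremeSubset",
    "PairwiseComparison",
    "ModelComparison",
    "snap_half_mm",
    "bin_by_length",
    "fit_three_models",
    "mse",
    "extreme_subset",
    "compare_models_anova",
    "compare_models",
    "read_records",
    "write_records",
]

MODEL_NAMES = ("RMA", "K_c", "constant_k")


@dataclass(frozen=True)
class InsectRecord:
    """One individual: body length and (optionally) observed true thermal age."""

    species: str
    length_mm: float
    true_k: float | None = None
    unit: Unit = Unit.ADD
    sex: str | None = None
    temp_c: float | None = None
    dev_days: float | None = None


@dataclass(frozen=True)
class LengthClass:
    """All individuals sharing one half-millimetre length value."""

    length_mm: float
    members: tuple[float, ...]

    @property
    def median(self) -> float:
        return float(np.median(self.members))

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConstantLine:
    """The no-calibration model: y = k at every length."""

    value: float

    def predict(self, l):
        return np.broadcast_to(self.value, np.shape(l)).astype(float) \
            if np.ndim(l) else self.value

    __call__ = predict


class ThreeModels(NamedTuple):
    rma: RMAResults
    k_c: CalibrationLine
    constant: ConstantLine


class ExtremeSubset(NamedTuple):
    records: list
    low_threshold: float
    high_threshold: float


def snap_half_mm(length_mm):
    """Snap lengths to the nearest 0.5 mm; ties at .25 round half up."""
    return np.floor(np.asarray(length_mm, dtype=float) * 2.0 + 0.5) / 2.0


def bin_by_length(
    records: Sequence[InsectRecord], snap: bool = True
) -> list[LengthClass]:
    """Group records into length classes, one per distinct (snapped) length.

    Records without a true-k observation are excluded with a warning.
    Classes are returned sorted by ascending length.
    """
    usable = [r for r in records if r.true_k is not None]
    dropped = len(records) - len(usable)
    if dropped:
        warnings.warn(
            f"excluding {dropped} record(s) without a true-k observation",
            UserWarning,
            stacklevel=2,
        )
    groups: dict[float, list[float]] = {}
    for r in usable:
        length = float(snap_half_mm(r.length_mm)) if snap else r.length_mm
        groups.setdefault(length, []).append(float(r.true_k))
    return [
        LengthClass(length_mm=length, members=tuple(groups[length]))
        for length in sorted(groups)
    ]


def fit_three_models(
    classes: Sequence[LengthClass],
    params: ThermalSummationParams,
    size_range: SizeRange | None = None,
    correlation_sign: CorrelationSign | str = CorrelationSign.NEGATIVE,
) -> ThreeModels:
    """Fit/construct the RMA, K_c and constant-k models on class medians.

    When ``size_range`` is omitted the calibration uses the dataset's own
    minimal and maximal class lengths.
    """
    if len(classes) < 3:
        raise ValueError(f"need >= 3 length classes, got {len(classes)}")
    lengths = np.array([c.length_mm for c in classes])
    medians = np.array([c.median for c in classes])
    if size_range is None:
        size_range = SizeRange(float(lengths.min()), float(lengths.max()),
                               source="dataset")
    rma = RMA(medians, lengths).fit()
    k_c = calibration_line(params, size_range, correlation_sign)
    return ThreeModels(rma=rma, k_c=k_c, constant=ConstantLine(params.k))


def mse(classes: Sequence[LengthClass], line) -> float:
    """Mean squared error of a line against class medians (unweighted)."""
    if not classes:
        raise ValueError("no length classes")
    errs = np.array([c.median - float(line.predict(c.length_mm)) for c in classes])
    return float(np.mean(errs**2))


def _squared_errors(classes: Sequence[LengthClass], line) -> np.ndarray:
    return np.array(
        [(c.median - float(line.predict(c.length_mm))) ** 2 for c in classes]
    )


def extreme_subset(
    records: Sequence[InsectRecord],
    low_percentile: float = 33.0,
    high_percentile: float = 66.0,
) -> ExtremeSubset:
    """Keep only unusually small and large individuals.

    Retains records strictly below the low-percentile length or strictly
    above the high-percentile length (linear-interpolation percentiles),
    reporting the realized thresholds.
    """
    if not 0 < low_percentile < high_percentile < 100:
        raise ValueError("require 0 < low < high < 100")
    lengths = np.array([r.length_mm for r in records], dtype=float)
    low_thr = float(np.percentile(lengths, low_percentile))
    high_thr = float(np.percentile(lengths, high_percentile))
    kept = [r for r in records if r.length_mm < low_thr or r.length_mm > high_thr]
    if not kept:
        raise ValueError(
            f"extreme subset is empty (thresholds {low_thr:g}/{high_thr:g} mm)"
        )
    return ExtremeSubset(records=kept, low_threshold=low_thr, high_threshold=high_thr)


@dataclass(frozen=True)
class PairwiseComparison:
    """Fisher-LSD pairwise contrast between two models' squared errors."""

    model_a: str
    model_b: str
    mean_difference: float
    t_statistic: float
    p_raw: float
    p_adjusted: float = float("nan")


@dataclass(frozen=True)
class ModelComparison:
    """Results of the three-model comparison on per-class squared errors."""

    squared_errors: dict[str, np.ndarray]
    mse_: dict[str, float]
    anova_f: float
    anova_p: float
    pairwise: tuple[PairwiseComparison, ...]
    low_threshold: float | None = None
    high_threshold: float | None = None

    def summary(self) -> str:
        width = 62
        lines = ["Model comparison (squared errors over length classes)",
                 "=" * width]
        if self.low_threshold is not None:
            lines.append(
                f"Extreme subset: length < {self.low_threshold:g} mm or "
                f"> {self.high_threshold:g} mm"
            )
        lines.append(f"{'Model':<14}{'MSE':>16}{'n classes':>12}")
        lines.append("-" * width)
        for name in MODEL_NAMES:
            lines.append(
                f"{name:<14}{self.mse_[name]:>16.4f}"
                f"{len(self.squared_errors[name]):>12d}"
            )
        lines.append("-" * width)
        lines.append(f"One-way ANOVA: F = {self.anova_f:.4g}, P = {self.anova_p:.4g}")
        lines.append("LSD post hoc (Benjamini-Hochberg adjusted):")
        lines.append(f"{'contrast':<26}{'t':>10}{'P raw':>12}{'P adj':>12}")
        for pc in self.pairwise:
            lines.append(
                f"{pc.model_a + ' vs ' + pc.model_b:<26}{pc.t_statistic:>10.3f}"
                f"{pc.p_raw:>12.4g}{pc.p_adjusted:>12.4g}"
            )
        lines.append("=" * width)
        return "\n".join(lines)


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, float, int]:
    """Textbook one-way ANOVA: returns (F, p, pooled within MS, within df).

    Degenerate cases are resolved explicitly: zero between-group variation
    gives F = 0, p = 1; zero within-group variation with real between-group
    differences gives F = inf, p = 0.
    """
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n_total = all_vals.size
    g = len(groups)
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in groups)
    ss_within = sum(float(np.sum((arr - arr.mean()) ** 2)) for arr in groups)
    df_between = g - 1
    df_within = n_total - g
    msw = ss_within / df_within
    if ss_between == 0:
        return 0.0, 1.0, msw, df_within
    if ss_within == 0:
        return float("inf"), 0.0, msw, df_within
    f = (ss_between / df_between) / msw
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p, msw, df_within


def compare_models_anova(
    squared_errors: dict[str, np.ndarray] | dict[str, Sequence[float]],
    low_threshold: float | None = None,
    high_threshold: float | None = None,
) -> ModelComparison:
    """ANOVA + LSD + BH on per-class squared errors of the three models.

    The models form the groups of an unpaired one-way design; Fisher's LSD
    uses the pooled within-group variance from the ANOVA; the three pairwise
    p-values are Benjamini-Hochberg adjusted.
    """
    names = list(squared_errors)
    groups = {k: np.asarray(v, dtype=float) for k, v in squared_errors.items()}
    for name, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 classes")
    f, p, msw, df_within = _one_way_anova([groups[n] for n in names])

    raw: list[PairwiseComparison] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            diff = float(a.mean() - b.mean())
            se = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size))
            if se == 0:
                t = 0.0 if diff == 0 else np.sign(diff) * float("inf")
                p_raw = 1.0 if diff == 0 else 0.0
            else:
                t = diff / se
                p_raw = float(2.0 * stats.t.sf(abs(t), df_within))
            raw.append(
                PairwiseComparison(
                    model_a=names[i], model_b=names[j],
                    mean_difference=diff, t_statistic=float(t), p_raw=p_raw,
                )
            )
    adjusted = multipletests([pc.p_raw for pc in raw], method="fdr_bh")[1]
    pairwise = tuple(
        PairwiseComparison(
            model_a=pc.model_a, model_b=pc.model_b,
            mean_difference=pc.mean_difference, t_statistic=pc.t_statistic,
            p_raw=pc.p_raw, p_adjusted=float(adj),
        )
        for pc, adj in zip(raw, adjusted)
    )
    mse_ = {name: float(arr.mean()) for name, arr in groups.items()}
    return ModelComparison(
        squared_errors=groups, mse_=mse_, anova_f=f, anova_p=p, pairwise=pairwise,
        low_threshold=low_threshold, high_threshold=high_threshold,
    )


def compare_models(
    records: Sequence[InsectRecord],
    params: ThermalSummationParams,
    size_range: SizeRange | None = None,
    correlation_sign: CorrelationSign | str = CorrelationSign.NEGATIVE,
    extremes: bool = False,
    low_percentile: float = 33.0,
    high_percentile: float = 66.0,
) -> ModelComparison:
    """Full pipeline from individual records to a :class:`ModelComparison`.

    Bins records into half-mm length classes, optionally restricts to the
    extreme-size subset, fits the three models to class medians, and runs
    the squared-error ANOVA/LSD/BH comparison.  Deterministic: identical
    inputs give identical output.
    """
    low_thr = high_thr = None
    if extremes:
        records, low_thr, high_thr = extreme_subset(
            records, low_percentile, high_percentile
        )
    classes = bin_by_length(records)
    models = fit_three_models(classes, params, size_range, correlation_sign)
    sq = {
        "RMA": _squared_errors(classes, models.rma),
        "K_c": _squared_errors(classes, models.k_c),
        "constant_k": _squared_errors(classes, models.constant),
    }
    return compare_models_anova(sq, low_threshold=low_thr, high_threshold=high_thr)


RECORD_COLUMNS = ["species", "length_mm", "true_k", "unit", "sex", "temp_c", "dev_days"]


def read_records(path) -> list[InsectRecord]:
    """Read an insect-record CSV (columns species,length_mm,true_k,unit[,...])."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples():
        records.append(
            InsectRecord(
                species=row.species,
                length_mm=float(row.length_mm),
                true_k=None if pd.isna(row.true_k) else float(row.true_k),
                unit=Unit(getattr(row, "unit", "ADD")),
                sex=getattr(row, "sex", None),
                temp_c=getattr(row, "temp_c", None),
                dev_days=getattr(row, "dev_days", None),
            )
        )
    return records


def write_records(records: Sequence[InsectRecord], path) -> None:
    """Write insect records to CSV in the shared column layout."""
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "length_mm": [r.length_mm for r in records],
            "true_k": [r.true_k for r in records],
            "unit": [r.unit.value for r in records],
            "sex": [r.sex for r in records],
            "temp_c": [r.temp_c for r in records],
            "dev_days": [r.dev_days for r in records],
        }
    )
    df.to_csv(path, index=False)
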