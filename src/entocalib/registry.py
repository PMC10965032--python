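"""Packaged registry of forensically important carrion insects.

Ships per-species thermal summation constants (k, its standard error, unit,
number of experimental temperatures m), literature body-length ranges from
multiple sources, an ecology label, and the correlation-sign convention
(negative for necrophagous/predatory species, positive for parasitoids).
Eleven species of Central-European carrion entomofauna are pre-filled; the
registry is a plain CSV (with a mirrored JSON) so users can substitute size
ranges for the geographic population closest to their casework.

Also provides:

* :func:`infer_m` — brute-force inversion recovering the unpublished
  temperature count m from a published calibration-line slope, via
  ``slope = s_e * sqrt(3 m) / (l_max - l_min)``;
* :func:`choose_size_range` — the broadest-range rule (widest single source
  represents natural size variation best; ties broken toward larger l_max);
* :func:`species_formula` — the calibration line for a registry entry.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import pandas as pd

from .calibration import (
    CalibrationLine,
    CorrelationSign,
    SizeRange,
    ThermalSummationParams,
    calibration_line,
)

__all__ = [
    "SpeciesEntry",
    "PUBLISHED_LINES",
    "load_registry",
    "get_species",
    "load_size_ranges",
    "infer_m",
    "species_formula",
    "choose_size_range",
    "registry_path",
]

# Calibration-line coefficients as published in the source literature
# (intercept, signed slope), kept out of the user-editable CSV because they
# are fixed cross-check values, not per-population inputs.  The Nasonia
# vitripennis intercept is internally inconsistent with its own positive
# slope (the line never passes through k on the species' size range); it is
# retained verbatim for the record but excluded from agreement checks.
PUBLISHED_LINES: dict[str, tuple[float, float]] = {
    "Chrysomya albiceps": (174.74, -3.67),
    "Lucilia sericata": (7676.99, -194.56),
    "Phormia regina": (308.89, -3.49),
    "Fannia canicularis": (554.41, -13.84),
    "Necrobia rufipes": (842.57, -47.92),
    "Omosita colon": (578.69, -23.07),
    "Necrodes littoralis": (710.82, -12.05),
    "Thanatophilus sinuatus": (532.88, -16.42),
    "Thanatophilus rugosus": (415.47, -5.27),
    "Creophilus maxillosus": (548.5, -7.17),
    "Nasonia vitripennis": (8328.49, 2034.1),
}

INCONSISTENT_PUBLISHED_INTERCEPTS = frozenset({"Nasonia vitripennis"})


@dataclass(frozen=True)
class SpeciesEntry:
    """One registry row: a species with its constants and size data."""

    species: str
    family: str
    params: ThermalSummationParams
    ranges: tuple[SizeRange, ...]
    selected_range: SizeRange
    ecology: str
    correlation_sign: CorrelationSign
    published_line: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        expected = (
            CorrelationSign.POSITIVE
            if self.ecology == "parasitoid"
            else CorrelationSign.NEGATIVE
        )
        if self.correlation_sign is not expected:
            warnings.warn(
                f"{self.species}: correlation sign {self.correlation_sign.value} "
                f"overrides the ecology convention ({self.ecology} -> "
                f"{expected.value})",
                UserWarning,
                stacklevel=2,
            )


class InferredM(NamedTuple):
    m: int
    residual: float
    relative_residual: float


def registry_path() -> str:
    """Filesystem path of the packaged registry CSV."""
    return str(resources.files("entocalib").joinpath("data/species_registry.csv"))


def load_size_ranges(path=None) -> dict[str, tuple[SizeRange, ...]]:
    """Literature size ranges per species (multiple sources each)."""
    if path is None:
        path = resources.files("entocalib").joinpath("data/size_ranges.csv")
    df = pd.read_csv(path)
    out: dict[str, tuple[SizeRange, ...]] = {}
    for sp, grp in df.groupby("species", sort=False):
        out[sp] = tuple(
            SizeRange(r.l_min, r.l_max, source=r.source) for r in grp.itertuples()
        )
    return out


def load_registry(path=None) -> dict[str, SpeciesEntry]:
    """Load the species registry, keyed by binomial name."""
    if path is None:
        path = registry_path()
    df = pd.read_csv(path)
    surveys = load_size_ranges()
    entries: dict[str, SpeciesEntry] = {}
    for row in df.itertuples():
        d0 = None if pd.isna(row.d0) else float(row.d0)
        params = ThermalSummationParams(
            k=float(row.k), s_e=float(row.se), m=int(row.m), unit=row.unit, d0=d0
        )
        selected = SizeRange(float(row.l_min), float(row.l_max), source=row.range_source)
        ranges = surveys.get(row.species, (selected,))
        entries[row.species] = SpeciesEntry(
            species=row.species,
            family=row.family,
            params=params,
            ranges=ranges,
            selected_range=selected,
            ecology=row.ecology,
            correlation_sign=CorrelationSign(row.corr_sign),
            published_line=PUBLISHED_LINES.get(row.species),
        )
    return entries


def get_species(name: str, registry: dict[str, SpeciesEntry] | None = None) -> SpeciesEntry:
    """Look up a species, tolerating underscores and abbreviated genus.

    Accepts e.g. "Necrodes littoralis", "N_littoralis" or "N. littoralis".
    """
    if registry is None:
        registry = load_registry()
    if name in registry:
        return registry[name]
    norm = name.replace("_", " ").replace(".", "").strip().lower()
    for full, entry in registry.items():
        genus, _, epithet = full.partition(" ")
        candidates = {
            full.lower(),
            f"{genus[0]} {epithet}".lower(),
        }
        if norm in candidates:
            return entry
    raise KeyError(f"species {name!r} not in the registry")


def infer_m(
    printed_slope_magnitude: float,
    s_e: float,
    size_range: SizeRange,
    search_max: int = 30,
) -> InferredM:
    """Recover the temperature count m from a published slope magnitude.

    Searches integer m in [2, search_max] for the best match of
    ``s_e * sqrt(3 m) / width`` to the printed slope.  Returns the residual
    so callers can reject poor inversions; a residual above 0.5% of the
    printed slope draws a warning.  An exact tie between two m values is an
    error — no silent choice.
    """
    if printed_slope_magnitude <= 0:
        raise ValueError("printed slope magnitude must be positive")
    if s_e <= 0:
        raise ValueError("s_e must be positive to invert the slope")
    best: list[tuple[float, int]] = []
    for m in range(2, search_max + 1):
        resid = abs(printed_slope_magnitude - s_e * math.sqrt(3 * m) / size_range.width)
        best.append((resid, m))
    best.sort()
    if len(best) > 1 and best[0][0] == best[1][0]:
        raise ValueError(
            f"ambiguous inversion: m = {best[0][1]} and m = {best[1][1]} fit the "
            f"printed slope equally well"
        )
    resid, m = best[0]
    rel = resid / printed_slope_magnitude
    if rel > 0.005:
        warnings.warn(
            f"inverted m = {m} reproduces the printed slope only to "
            f"{100 * rel:.2f}% — check s_e and the size range",
            UserWarning,
            stacklevel=2,
        )
    return InferredM(m=m, residual=resid, relative_residual=rel)


def species_formula(entry: SpeciesEntry) -> CalibrationLine:
    """Calibration line for a registry entry (its params, range and sign)."""
    return calibration_line(entry.params, entry.selected_range, entry.correlation_sign)


def choose_size_range(ranges: list[SizeRange] | tuple[SizeRange, ...]) -> SizeRange:
    """The broadest-range rule: pick the widest single-source range.

    The widest range best represents natural size variation in the reference
    population.  Equal widths are broken toward the larger ``l_max`` (a
    convention, flagged with a warning).
    """
    if not ranges:
        raise ValueError("no size ranges to choose from")
    max_width = max(r.width for r in ranges)
    widest = [r for r in ranges if r.width == max_width]
    chosen = max(widest, key=lambda r: r.l_max)
    distinct = {(r.l_min, r.l_max) for r in widest}
    if len(distinct) > 1:
        warnings.warn(
            f"width tie among {sorted(distinct)}: choosing the range with the "
            f"larger l_max ({chosen.l_min}-{chosen.l_max}) by convention",
            UserWarning,
            stacklevel=2,
        )
    return chosen


def export_registry_json(path) -> None:
    """Write the registry CSV content as JSON (the mirrored format)."""
    df = pd.read_csv(registry_path())
    records = json.loads(df.to_json(orient="records"))
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
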