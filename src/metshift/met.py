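"""MET intensity assignments per sector and occupational energy expenditure.

Each sector carries a median (and range) physical-activity intensity in METs
(1 MET = 1 kcal per kg body weight per hour) taken from a published
occupational classification scheme. Sectors are bucketed into intensity
categories by their median MET — sedentary (<2), light (2.0–2.9), moderate
(3.0–5.9) — and a year's employment-weighted mean MET converts to daily
occupational energy expenditure as

    EE (kcal/workday) = hours worked x mean MET x body weight (kg)

with an assumed 8 h workday and fixed gender-specific reference weights
(the 1960–62 survey means: 76.9 kg men, 64.9 kg women).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Sequence

from .employment import EmploymentSeries, sector_prevalence
from .errors import ConfigurationError, DomainError
from .sectors import Sector


class Intensity(str, Enum):
    SEDENTARY = "sedentary"
    LIGHT = "light"
    MODERATE = "moderate"


class Gender(str, Enum):
    MEN = "men"
    WOMEN = "women"


@dataclass(frozen=True)
class IntensityScheme:
    """Half-open MET cut points: [0, s) sedentary, [s, l) light, [l, m) moderate."""

    sedentary_upper: float = 2.0
    light_upper: float = 3.0
    moderate_upper: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sedentary_upper < self.light_upper < self.moderate_upper:
            raise ConfigurationError("intensity cut points must be increasing and positive")


def classify_intensity(
    met: float, scheme: IntensityScheme = IntensityScheme()
) -> Intensity:
    """Bucket a median MET value into its intensity category.

    The scheme has no vigorous category: METs at or above the moderate upper
    bound are rejected rather than silently bucketed.
    """
    if met <= 0:
        raise DomainError(f"MET must be positive, got {met}")
    if met < scheme.sedentary_upper:
        return Intensity.SEDENTARY
    if met < scheme.light_upper:
        return Intensity.LIGHT
    if met < scheme.moderate_upper:
        return Intensity.MODERATE
    raise DomainError(
        f"MET {met} >= {scheme.moderate_upper}: no category above moderate"
    )


@dataclass(frozen=True)
class OccupationMET:
    """Median and range of physical-activity intensity for one sector."""

    sector: Sector
    met_median: float
    met_min: float
    met_max: float
    category: Intensity

    def __post_init__(self) -> None:
        if not self.met_min <= self.met_median <= self.met_max:
            raise ConfigurationError(
                f"{self.sector.value}: MET median outside [min, max]"
            )


def load_met_table(path) -> list[OccupationMET]:
    """Read a MET table CSV (``sector,met_median,met_min,met_max,category``)."""
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_met_rows(csv.DictReader(fh))


def _parse_met_rows(rows) -> list[OccupationMET]:
    table = [
        OccupationMET(
            sector=Sector(r["sector"]),
            met_median=float(r["met_median"]),
            met_min=float(r["met_min"]),
            met_max=float(r["met_max"]),
            category=Intensity(r["category"]),
        )
        for r in rows
    ]
    for e in table:
        if e.category is not classify_intensity(e.met_median):
            raise ConfigurationError(
                f"{e.sector.value}: category inconsistent with median MET"
            )
    return table


def met_table_default() -> list[OccupationMET]:
    """The packaged per-sector MET assignments (one row per sector).

    Medians range from 1.5 (information, financial, professional/business)
    to 4.0 (construction); all goods-producing sectors and farm jobs are
    moderate intensity, all service sectors sedentary or light.
    """
    path = resources.files("metshift").joinpath("data/met_table.csv")
    with path.open("r", encoding="utf-8") as fh:
        table = _parse_met_rows(csv.DictReader(fh))
    if {e.sector for e in table} != set(Sector):
        raise ConfigurationError("packaged MET table must cover all 11 sectors")
    return table


@dataclass(frozen=True)
class EEAssumptions:
    """Fixed assumptions behind the expenditure formula.

    The reference weight is held at the 1960–62 means for every year — the
    expenditure trend isolates the occupational-mix shift and feeds no
    weight change back into itself. The workweek factor (5/7 by default)
    converts per-workday deltas into per-calendar-day deltas and is applied
    only downstream, in weight prediction.
    """

    hours_per_workday: float = 8.0
    reference_weight_kg: Mapping[Gender, float] = field(
        default_factory=lambda: {Gender.MEN: 76.9, Gender.WOMEN: 64.9}
    )
    workweek_factor: float = 5.0 / 7.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hours_per_workday <= 24.0:
            raise ConfigurationError("hours_per_workday must be in (0, 24]")
        if any(w <= 0 for w in self.reference_weight_kg.values()):
            raise ConfigurationError("reference weights must be positive")
        if not 0.0 < self.workweek_factor <= 1.0:
            raise ConfigurationError("workweek_factor must be in (0, 1]")


def mean_met(
    prevalence: Mapping[Sector, float], met_table: Sequence[OccupationMET]
) -> float:
    """Employment-weighted mean occupational MET for one year.

    The prevalence-weighted sum of median METs; the min/max columns never
    enter. Bounded by the smallest and largest medians in the table.
    """
    medians = {e.sector: e.met_median for e in met_table}
    missing = [s.value for s in prevalence if s not in medians]
    if missing:
        raise ConfigurationError(f"sectors missing from MET table: {missing}")
    return float(sum(p * medians[s] for s, p in prevalence.items()))


def daily_occupational_ee(
    mean_met_value: float,
    assumptions: EEAssumptions = EEAssumptions(),
    gender: Gender = Gender.MEN,
) -> float:
    """Daily occupational energy expenditure in kcal per workday."""
    if mean_met_value <= 0:
        raise DomainError("mean MET must be positive")
    gender = Gender(gender)
    return (
        assumptions.hours_per_workday
        * mean_met_value
        * assumptions.reference_weight_kg[gender]
    )


@dataclass(frozen=True)
class ActivityTrendRow:
    """One year of the occupational-activity trend."""

    year: int
    mean_met: float
    category_prevalence: Mapping[Intensity, float]
    daily_ee_kcal: Mapping[Gender, float]


def category_prevalence(
    prevalence: Mapping[Sector, float], met_table: Sequence[OccupationMET]
) -> dict[Intensity, float]:
    """Aggregate sector prevalences into intensity-category prevalences."""
    cats = {e.sector: e.category for e in met_table}
    out = {c: 0.0 for c in Intensity}
    for sector, p in prevalence.items():
        out[cats[sector]] += p
    return out


def activity_trend(
    series: EmploymentSeries,
    met_table: Sequence[OccupationMET] | None = None,
    scheme: IntensityScheme = IntensityScheme(),
    assumptions: EEAssumptions = EEAssumptions(),
) -> list[ActivityTrendRow]:
    """Per-year mean METs, intensity-category prevalences and daily EE.

    The scheme re-derives each table row's category from its median, so a
    custom scheme propagates consistently.
    """
    if met_table is None:
        met_table = met_table_default()
    table = [
        OccupationMET(
            sector=e.sector,
            met_median=e.met_median,
            met_min=e.met_min,
            met_max=e.met_max,
            category=classify_intensity(e.met_median, scheme),
        )
        for e in met_table
    ]
    rows = []
    for year in series.years:
        prev = sector_prevalence(series, year)
        mm = mean_met(prev, table)
        rows.append(
            ActivityTrendRow(
                year=year,
                mean_met=mm,
                category_prevalence=category_prevalence(prev, table),
                daily_ee_kcal={
                    g: daily_occupational_ee(mm, assumptions, g) for g in Gender
                },
            )
        )
    return rows


def write_trend_table(rows: Sequence[ActivityTrendRow], path) -> None:
    """CSV: ``year,mean_met,prev_sedentary,prev_light,prev_moderate,ee_kcal_men,ee_kcal_women``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["year", "mean_met", "prev_sedentary", "prev_light",
             "prev_moderate", "ee_kcal_men", "ee_kcal_women"]
        )
        for r in rows:
            writer.writerow(
                [r.year, repr(r.mean_met)]
                + [repr(r.category_prevalence[c]) for c in Intensity]
                + [repr(r.daily_ee_kcal[g]) for g in Gender]
            )
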