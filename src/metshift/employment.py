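"""Sector-level employment time series: IO, validation, prevalence, trends.

The raw input is a delimited text file with one record per (year, sector)
holding the number of employed persons in thousands, modelled on the BLS
Current Employment Statistics series pooled with Current Population Survey
agricultural employment. Sector shares ("prevalences") within a year are the
basic statistic everything downstream consumes.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .errors import DomainError, FormatError, ValidationError
from .sectors import Sector, resolve_sector

logger = logging.getLogger(__name__)

_YEAR_COLS = {"year"}
_SECTOR_COLS = {"sector", "industry"}
_EMPLOYED_COLS = {"employed_thousands", "employed", "employment"}


@dataclass(frozen=True)
class EmploymentSeries:
    """Employment counts (thousands of persons) by calendar year and sector.

    Missing (year, sector) cells mean zero employment; a year with no
    positive employment at all is invalid.
    """

    records: Mapping[tuple[int, Sector], float]
    year_range: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("employment series has no records")
        years = sorted({y for y, _ in self.records})
        if self.year_range is None:
            object.__setattr__(self, "year_range", (years[0], years[-1]))
        for (year, sector), count in self.records.items():
            if not math.isfinite(count):
                raise ValidationError(f"non-finite count for ({year}, {sector.value})")
            if count < 0:
                raise ValidationError(
                    f"negative employment count for ({year}, {sector.value})"
                )
        first, last = self.year_range
        for year in range(first, last + 1):
            if self.total(year) <= 0:
                raise ValidationError(f"no employment in year {year}")

    @property
    def years(self) -> list[int]:
        first, last = self.year_range
        return list(range(first, last + 1))

    def employed(self, year: int, sector: Sector) -> float:
        return float(self.records.get((year, sector), 0.0))

    def total(self, year: int) -> float:
        return float(sum(c for (y, _), c in self.records.items() if y == year))


def load_employment_series(
    path: str | Path, delimiter: str | None = None
) -> EmploymentSeries:
    """Read a delimited employment file into a validated series.

    The header must name a year column, a sector column and an employed
    column (``year,sector,employed_thousands`` is the canonical dialect; TSV
    is accepted). Sector labels are resolved case-insensitively through the
    packaged alias table; unmappable labels are reported with their line
    numbers. Cells absent from the file are treated as zero employment.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        cols = {c.strip().lower(): c for c in reader.fieldnames}
        try:
            year_col = next(cols[c] for c in _YEAR_COLS if c in cols)
            sector_col = next(cols[c] for c in _SECTOR_COLS if c in cols)
            employed_col = next(cols[c] for c in _EMPLOYED_COLS if c in cols)
        except StopIteration:
            raise FormatError(
                f"{path}: header must name year, sector and employed columns; "
                f"got {reader.fieldnames}"
            ) from None

        records: dict[tuple[int, Sector], float] = {}
        bad_labels: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                year = int(row[year_col])
                count = float(row[employed_col])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row: {exc}") from None
            try:
                sector = resolve_sector(row[sector_col])
            except KeyError:
                bad_labels.append(f"line {lineno}: {row[sector_col]!r}")
                continue
            if count < 0:
                raise ValidationError(
                    f"negative employment count for ({year}, {sector.value})"
                )
            records[(year, sector)] = records.get((year, sector), 0.0) + count
        if bad_labels:
            raise ValidationError(
                f"{path}: unmappable sector labels: " + "; ".join(bad_labels)
            )
    series = EmploymentSeries(records)
    n_cells = len(series.years) * len(Sector)
    if len(records) < n_cells:
        logger.warning(
            "%s: %d of %d (year, sector) cells missing; treated as zero employment",
            path, n_cells - len(records), n_cells,
        )
    return series


def write_employment_series(series: EmploymentSeries, path: str | Path) -> None:
    """Write the canonical CSV dialect (``year,sector,employed_thousands``).

    Counts are written with ``repr`` so a load round-trips bit-for-bit.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "sector", "employed_thousands"])
        for (year, sector), count in sorted(
            series.records.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            writer.writerow([year, sector.value, repr(count)])


def sector_prevalence(series: EmploymentSeries, year: int) -> dict[Sector, float]:
    """Fraction of total employment in each sector for one year.

    Fractions are counts divided by the year's pooled total (private
    nonagricultural plus agricultural employment) and sum to one.
    """
    first, last = series.year_range
    if not first <= year <= last:
        raise DomainError(f"year {year} outside series range [{first}, {last}]")
    total = series.total(year)
    if total <= 0:
        raise DomainError(f"no employment in year {year}")
    return {s: series.employed(year, s) / total for s in Sector}


def write_prevalence_table(
    series: EmploymentSeries, path: str | Path
) -> None:
    """Tidy CSV ``year,sector,prevalence`` for every year in the series."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "sector", "prevalence"])
        for year in series.years:
            prev = sector_prevalence(series, year)
            for sector in Sector:
                writer.writerow([year, sector.value, repr(prev[sector])])


@dataclass(frozen=True)
class TrendResult:
    """OLS secular-trend summary: slope per calendar year and two-sided p."""

    slope: float
    p_value: float
    n_years: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.n_years < 2:
            raise ValueError("trend needs at least 2 years")


def trend_test(values_by_year: Mapping[int, float]) -> TrendResult:
    """Two-sided test for a linear secular trend.

    Ordinary least squares of the yearly statistic on calendar year with a t
    test on the slope. Degenerate exact fits are resolved by the limit of
    the t statistic: zero residual variance with a zero slope gives p = 1,
    with a nonzero slope p = 0.
    """
    if len(values_by_year) < 2 or len(set(values_by_year)) < 2:
        raise DomainError("trend test needs at least 2 distinct years")
    years = np.array(sorted(values_by_year), dtype=float)
    vals = np.array([values_by_year[int(y)] for y in years], dtype=float)
    n = len(years)
    x = years - years.mean()
    sxx = float(x @ x)
    slope = float(x @ (vals - vals.mean())) / sxx
    resid = vals - vals.mean() - slope * x
    ss_res = float(resid @ resid)
    scale = max(float(vals @ vals), 1.0)
    if ss_res <= 1e-24 * scale:
        p = 1.0 if abs(slope) <= 1e-15 else 0.0
        return TrendResult(slope=slope, p_value=p, n_years=n)
    se = math.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return TrendResult(slope=slope, p_value=p, n_years=n)


def prevalence_by_year(
    series: EmploymentSeries, sector: Sector
) -> dict[int, float]:
    """Convenience: one sector's prevalence as a year-indexed mapping."""
    return {y: sector_prevalence(series, y)[sector] for y in series.years}
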