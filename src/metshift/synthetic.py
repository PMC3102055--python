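"""Synthetic employment series anchored to the printed 1960/2008 shares.

The real analysis ran on five decades of BLS establishment-survey extracts
that are not redistributable here. This module generates employment series
with the same statistical structure: an 11-sector prevalence simplex
drifting between a 1960 and a 2008 anchor vector, with optional
multiplicative log-normal noise, renormalized to the simplex each year.
The anchors pin every share the source analysis prints — moderate-intensity
category mass 48% -> 20%, manufacturing 30% -> 12%, and
professional/business + education/health + leisure/hospitality 20% -> 43% —
while the unpinned sectors take fixed, documented values consistent with
the qualitative trends (construction roughly flat, information and farm
declining).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np

from .employment import EmploymentSeries
from .errors import DomainError, ValidationError
from .met import Gender, Intensity, met_table_default
from .sectors import Sector

#: Start/end sector shares. Pinned values (manufacturing, the moderate
#: category total, the three growing service sectors) come from the printed
#: 1960/2008 figures; the rest are round documented constants.
_PREVALENCE_1960: dict[Sector, float] = {
    Sector.FARM: 0.080,
    Sector.MINING_LOGGING: 0.020,
    Sector.CONSTRUCTION: 0.080,
    Sector.MANUFACTURING: 0.300,
    Sector.TRADE_TRANSPORT_UTILITIES: 0.220,
    Sector.INFORMATION: 0.035,
    Sector.FINANCIAL: 0.045,
    Sector.PROFESSIONAL_BUSINESS: 0.080,
    Sector.EDUCATION_HEALTH: 0.060,
    Sector.LEISURE_HOSPITALITY: 0.060,
    Sector.OTHER_SERVICES: 0.020,
}
_PREVALENCE_2008: dict[Sector, float] = {
    Sector.FARM: 0.015,
    Sector.MINING_LOGGING: 0.005,
    Sector.CONSTRUCTION: 0.060,
    Sector.MANUFACTURING: 0.120,
    Sector.TRADE_TRANSPORT_UTILITIES: 0.225,
    Sector.INFORMATION: 0.025,
    Sector.FINANCIAL: 0.070,
    Sector.PROFESSIONAL_BUSINESS: 0.160,
    Sector.EDUCATION_HEALTH: 0.170,
    Sector.LEISURE_HOSPITALITY: 0.100,
    Sector.OTHER_SERVICES: 0.050,
}

_GROWTH_SERVICE_SECTORS = (
    Sector.PROFESSIONAL_BUSINESS,
    Sector.EDUCATION_HEALTH,
    Sector.LEISURE_HOSPITALITY,
)

NHANES_PERIODS: dict[str, tuple[int, int]] = {
    "1960-62": (1960, 1962),
    "1971-74": (1971, 1974),
    "1976-80": (1976, 1980),
    "1988-94": (1988, 1994),
    "1999-2002": (1999, 2002),
    "2003-06": (2003, 2006),
}


@dataclass(frozen=True)
class AnchorSet:
    """Endpoint prevalence vectors and totals for the synthetic drift."""

    year_start: int = 1960
    year_end: int = 2008
    prevalence_start: Mapping[Sector, float] = field(
        default_factory=lambda: dict(_PREVALENCE_1960)
    )
    prevalence_end: Mapping[Sector, float] = field(
        default_factory=lambda: dict(_PREVALENCE_2008)
    )
    total_employment_start: float = 54_000.0  # thousands
    total_employment_end: float = 137_000.0

    def __post_init__(self) -> None:
        if self.year_end <= self.year_start:
            raise ValidationError("year_end must follow year_start")
        categories = {e.sector: e.category for e in met_table_default()}
        for name, vec in (("start", self.prevalence_start), ("end", self.prevalence_end)):
            if set(vec) != set(Sector):
                raise ValidationError(f"{name} vector must cover all 11 sectors")
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} vector sums to {total}, not 1")
            if any(p < 0 for p in vec.values()):
                raise ValidationError(f"{name} vector has negative shares")
        for vec, moderate, manuf, services, tol_services in (
            (self.prevalence_start, 0.48, 0.30, 0.20, 0.01),
            (self.prevalence_end, 0.20, 0.12, 0.43, 0.01),
        ):
            mod_mass = sum(
                p for s, p in vec.items() if categories[s] is Intensity.MODERATE
            )
            if abs(mod_mass - moderate) > 0.005:
                raise ValidationError(
                    f"moderate-category mass {mod_mass:.3f} != {moderate}"
                )
            if abs(vec[Sector.MANUFACTURING] - manuf) > 0.005:
                raise ValidationError("manufacturing share off its anchor")
            svc = sum(vec[s] for s in _GROWTH_SERVICE_SECTORS)
            if abs(svc - services) > tol_services:
                raise ValidationError("growing-service share off its anchor")


def default_anchor_set() -> AnchorSet:
    """The documented anchor set pinned to the printed 1960/2008 shares."""
    return AnchorSet()


def generate_employment_series(
    anchors: AnchorSet | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EmploymentSeries:
    """Draw a synthetic employment series between the anchor vectors.

    Each year's prevalence vector is the linear interpolation between the
    anchors, perturbed per (year, sector) by mean-one multiplicative
    log-normal noise with relative standard deviation ``noise_sd``, then
    renormalized to the simplex. Counts are prevalence times a linearly
    interpolated total employment. Deterministic given ``seed``.
    """
    if anchors is None:
        anchors = default_anchor_set()
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    sectors = list(Sector)
    p0 = np.array([anchors.prevalence_start[s] for s in sectors])
    p1 = np.array([anchors.prevalence_end[s] for s in sectors])
    span = anchors.year_end - anchors.year_start
    sigma = float(np.sqrt(np.log1p(noise_sd**2)))  # log-normal with sd ~ noise_sd
    records: dict[tuple[int, Sector], float] = {}
    for year in range(anchors.year_start, anchors.year_end + 1):
        w = (year - anchors.year_start) / span
        prev = (1.0 - w) * p0 + w * p1
        if noise_sd > 0:
            prev = prev * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(sectors))
        prev = prev / prev.sum()
        total = (
            (1.0 - w) * anchors.total_employment_start
            + w * anchors.total_employment_end
        )
        for s, p in zip(sectors, prev):
            records[(year, s)] = float(p * total)
    return EmploymentSeries(records)


@dataclass(frozen=True)
class NHANESWeightFixture:
    """Mean body weights (40–50 year olds) by survey period and gender.

    Only the three printed anchors are populated — (1960–62, men, 76.9 kg),
    (1960–62, women, 64.9 kg), (2003–06, men, 91.8 kg); every other cell is
    absent and flagged unreported. User-supplied cells can be merged in but
    remain marked non-printed.
    """

    rows: list[tuple[str, Gender, Optional[float], str]]

    def weight(self, period: str, gender: Gender) -> Optional[float]:
        for p, g, w, _ in self.rows:
            if p == period and g is Gender(gender):
                return w
        raise DomainError(f"unknown period/gender: {period}, {gender}")

    def source(self, period: str, gender: Gender) -> str:
        for p, g, _, src in self.rows:
            if p == period and g is Gender(gender):
                return src
        raise DomainError(f"unknown period/gender: {period}, {gender}")

    def observed(self, gender: Gender) -> dict[str, float]:
        """Period -> weight mapping for the populated cells of one gender."""
        return {
            p: w for p, g, w, _ in self.rows
            if g is Gender(gender) and w is not None
        }


def nhanes_weight_fixture() -> NHANESWeightFixture:
    """Load the packaged survey-weight fixture."""
    path = resources.files("metshift").joinpath("data/nhanes_weights.csv")
    rows: list[tuple[str, Gender, Optional[float], str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for r in csv.DictReader(fh):
            weight = float(r["mean_weight_kg"]) if r["mean_weight_kg"] else None
            rows.append((r["period"], Gender(r["gender"]), weight, r["source"]))
    periods = {p for p, *_ in rows}
    if periods != set(NHANES_PERIODS):
        raise ValidationError("fixture periods do not match the survey periods")
    return NHANESWeightFixture(rows=rows)
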