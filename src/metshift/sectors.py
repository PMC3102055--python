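"""Industry sector taxonomy.

Employment is tracked at the granularity of 11 broad industry sectors:
agricultural jobs (one sector), three goods-producing sectors, and seven
service-providing sectors. This matches the coarsest published breakdown of
the BLS Current Employment Statistics establishment survey, pooled with
agricultural employment from the Current Population Survey.
"""

from __future__ import annotations

import csv
from enum import Enum
from importlib import resources


class SuperCategory(str, Enum):
    AGRICULTURE = "agriculture"
    GOODS_PRODUCING = "goods_producing"
    SERVICE_PROVIDING = "service_providing"


class Sector(str, Enum):
    FARM = "farm"
    MINING_LOGGING = "mining_logging"
    CONSTRUCTION = "construction"
    MANUFACTURING = "manufacturing"
    TRADE_TRANSPORT_UTILITIES = "trade_transport_utilities"
    INFORMATION = "information"
    FINANCIAL = "financial"
    PROFESSIONAL_BUSINESS = "professional_business"
    EDUCATION_HEALTH = "education_health"
    LEISURE_HOSPITALITY = "leisure_hospitality"
    OTHER_SERVICES = "other_services"

    @property
    def super_category(self) -> SuperCategory:
        return SUPER_CATEGORY[self]


SUPER_CATEGORY: dict[Sector, SuperCategory] = {
    Sector.FARM: SuperCategory.AGRICULTURE,
    Sector.MINING_LOGGING: SuperCategory.GOODS_PRODUCING,
    Sector.CONSTRUCTION: SuperCategory.GOODS_PRODUCING,
    Sector.MANUFACTURING: SuperCategory.GOODS_PRODUCING,
    Sector.TRADE_TRANSPORT_UTILITIES: SuperCategory.SERVICE_PROVIDING,
    Sector.INFORMATION: SuperCategory.SERVICE_PROVIDING,
    Sector.FINANCIAL: SuperCategory.SERVICE_PROVIDING,
    Sector.PROFESSIONAL_BUSINESS: SuperCategory.SERVICE_PROVIDING,
    Sector.EDUCATION_HEALTH: SuperCategory.SERVICE_PROVIDING,
    Sector.LEISURE_HOSPITALITY: SuperCategory.SERVICE_PROVIDING,
    Sector.OTHER_SERVICES: SuperCategory.SERVICE_PROVIDING,
}


def _load_alias_table() -> dict[str, Sector]:
    """Packaged alias table mapping common free-text labels to sectors."""
    aliases: dict[str, Sector] = {}
    path = resources.files("metshift").joinpath("data/sector_aliases.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            aliases[row["alias"].strip().lower()] = Sector(row["sector"])
    return aliases


_ALIASES: dict[str, Sector] | None = None


def resolve_sector(label: str) -> Sector:
    """Map a free-text sector label to a :class:`Sector`.

    Matching is case-insensitive and tolerant of surrounding whitespace;
    the alias table ships with the package. Raises ``KeyError`` for labels
    that cannot be mapped.
    """
    global _ALIASES
    if _ALIASES is None:
        _ALIASES = _load_alias_table()
    key = label.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(f"unknown sector label: {label!r}")
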