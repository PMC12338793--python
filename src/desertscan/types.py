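"""Core domain records: tracts, blocks, pharmacies and classification outputs.

Coordinates are planar, in miles, on a synthetic study plane by default; a
haversine mode interprets ``(x, y)`` as ``(lon, lat)`` in decimal degrees for
real-world data. Tract identifiers are fixed-width 11-character strings,
mirroring the 11-digit census-tract GEOID (2-digit state + 3-digit county +
6-digit tract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import DataError

RACE_GROUPS = ("White", "Black", "Hispanic", "Asian", "AIAN")

GEOID_LENGTH = 11


def validate_geoid(tract_id: str) -> str:
    if not isinstance(tract_id, str) or len(tract_id) != GEOID_LENGTH:
        raise DataError(
            f"tract_id must be a {GEOID_LENGTH}-character string, got {tract_id!r}"
        )
    return tract_id


@dataclass(frozen=True)
class Block:
    """A census block centroid with its resident population."""

    block_id: str
    tract_id: str
    x: float
    y: float
    population: int

    def __post_init__(self) -> None:
        validate_geoid(self.tract_id)
        if self.population < 0:
            raise DataError(f"block {self.block_id}: population must be >= 0")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataError(f"block {self.block_id}: non-finite centroid")


@dataclass(frozen=True)
class Pharmacy:
    """A retail-pharmacy point location; ``open_flag=False`` models a closure."""

    pharmacy_id: str
    x: float
    y: float
    open_flag: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataError(f"pharmacy {self.pharmacy_id}: non-finite location")


@dataclass(frozen=True)
class Tract:
    """One census tract's population, covariates, indices and area.

    ``rri`` is the residential redlining index (odds ratio of mortgage
    denial relative to the MSA); ``None`` means missing, which is a retained
    analysis category. ``ddi`` is the 0-100 digital divide index with its
    infrastructure/adoption (``ddi_infa``) and socioeconomic (``ddi_se``)
    component scores.
    """

    tract_id: str
    population: int
    area: float  # square miles
    prop_poverty: float
    median_income: float | None
    msa_median_income: float | None
    race_props: Mapping[str, float]
    prop_age65: float
    prop_female: float
    prop_lt_hs: float
    prop_uninsured: float
    prop_amb_disability: float
    vehicles_owned: int
    ddi: float
    ddi_infa: float
    ddi_se: float
    rri: float | None = None
    msa_id: str = ""
    x: float = float("nan")  # tract representative point (centroid of its square)
    y: float = float("nan")

    def __post_init__(self) -> None:
        validate_geoid(self.tract_id)
        if self.population <= 0:
            raise DataError(f"tract {self.tract_id}: population must be > 0")
        if self.area <= 0:
            raise DataError(f"tract {self.tract_id}: area must be > 0")
        for name in ("prop_poverty", "prop_age65", "prop_female", "prop_lt_hs",
                     "prop_uninsured", "prop_amb_disability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"tract {self.tract_id}: {name}={v} outside [0, 1]")
        for name in ("ddi", "ddi_infa", "ddi_se"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DataError(f"tract {self.tract_id}: {name}={v} outside [0, 100]")
        total = 0.0
        for group, p in self.race_props.items():
            if group not in RACE_GROUPS:
                raise DataError(f"tract {self.tract_id}: unknown race group {group!r}")
            if not 0.0 <= p <= 1.0:
                raise DataError(f"tract {self.tract_id}: race proportion {group}={p}")
            total += p
        if total > 1.0 + 1e-9:
            raise DataError(
                f"tract {self.tract_id}: race proportions sum to {total:.6f} > 1"
            )
        if self.rri is not None and self.rri <= 0:
            raise DataError(f"tract {self.tract_id}: rri must be positive or missing")

    @property
    def density(self) -> float:
        """Population density in inhabitants per square mile."""
        return self.population / self.area


@dataclass(frozen=True)
class DesertAssessment:
    """Per-tract classification output.

    ``desert`` is the primary definition (low-income AND low-access);
    ``desert_distance_only`` drops the income requirement (secondary
    analysis). ``radius_used`` is the urbanicity radius in miles, or 0.5
    when the vehicle-ownership exception is what triggered the low-access
    flag. ``access_fraction_beyond`` is the population share living at or
    beyond ``radius_used`` from the nearest pharmacy.
    """

    tract_id: str
    urbanicity: str  # urban | suburban | rural
    low_income: bool
    low_access: bool
    desert: bool
    desert_distance_only: bool
    access_fraction_beyond: float
    radius_used: float
    segregation: str  # White | Black | Hispanic | Asian | AIAN | Integrated
    ddi_category: str  # low | moderate | high
    redlining_category: str  # low | neutral | high | missing


@dataclass
class SyntheticCohort:
    """A generated study cohort plus its ground truth.

    In geometry mode ``truth`` carries the per-tract oracle desert label
    computed by an exhaustive block-pharmacy distance scan; in label mode it
    carries the true coefficient vector of the generating logistic model.
    """

    tracts: list[Tract]
    blocks: list[Block]
    pharmacies: list[Pharmacy]
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.tract_id for t in self.tracts]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate tract_id in cohort")
        tract_ids = set(ids)
        seen = set()
        for b in self.blocks:
            if b.tract_id not in tract_ids:
                raise DataError(f"block {b.block_id} references unknown tract {b.tract_id}")
            seen.add(b.tract_id)
        if self.blocks and seen != tract_ids:
            missing = sorted(tract_ids - seen)[:5]
            raise DataError(f"tracts without blocks: {missing}")
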