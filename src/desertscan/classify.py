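"""Pharmacy-desert classification rules.

A tract is a pharmacy desert when it meets both a low-income and a
low-access criterion:

* low-income: >= 20% of the population below the Federal poverty level, or
  median household income < 80% of the median income of the tract's MSA;
* low-access: >= one third of the population living at or beyond the
  urbanicity-specific radius (1 mile urban, 5 suburban, 10 rural) from the
  nearest pharmacy; or, for tracts with fewer than 100 car-owning
  individuals, at or beyond 0.5 miles.

A secondary "distance-only" mode classifies on the access criterion alone.
Boundary conventions (all tested): density exactly 1,000 or 5,000 per square
mile is suburban; a racial/ethnic group at exactly 50% is not a majority
(tract is Integrated); the one-third access threshold is exact (1/3, not
0.33); redlining index exactly 1.3 is "high".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .access import AccessSummary, nearest_distances
from .exceptions import DataError, DegenerateTractError, MissingDataError
from .types import Block, DesertAssessment, Pharmacy, RACE_GROUPS, Tract

logger = logging.getLogger(__name__)

URBAN_DENSITY = 5000.0  # inhabitants / sq mi, exclusive lower bound for urban
RURAL_DENSITY = 1000.0  # exclusive upper bound for rural
RADIUS_BY_URBANICITY = {"urban": 1.0, "suburban": 5.0, "rural": 10.0}
VEHICLE_EXCEPTION_RADIUS = 0.5
VEHICLE_EXCEPTION_COUNT = 100
LOW_ACCESS_FRACTION = 1.0 / 3.0  # ">= 33%" means one third exactly
POVERTY_THRESHOLD = 0.20
INCOME_RATIO_THRESHOLD = 0.80
MAJORITY_THRESHOLD = 0.50
RRI_LOW_CUT = 0.7
RRI_HIGH_CUT = 1.3


def classify_urbanicity(population: int, area: float) -> str:
    """Urban / suburban / rural by population density.

    > 5,000 per sq mi is urban, < 1,000 rural, the inclusive band
    [1,000, 5,000] suburban.
    """
    if area <= 0:
        raise DataError(f"area must be positive, got {area}")
    density = population / area
    if density > URBAN_DENSITY:
        return "urban"
    if density < RURAL_DENSITY:
        return "rural"
    return "suburban"


def low_income_flag(tract: Tract) -> bool:
    """True when the tract meets either arm of the low-income criterion."""
    if tract.median_income is None or tract.msa_median_income is None:
        raise MissingDataError(
            f"tract {tract.tract_id}: income data missing, exclude from analysis"
        )
    if tract.prop_poverty >= POVERTY_THRESHOLD:
        return True
    return tract.median_income < INCOME_RATIO_THRESHOLD * tract.msa_median_income


def low_access_flag(tract: Tract, access: AccessSummary) -> tuple[bool, float]:
    """Evaluate the low-access criterion.

    Returns ``(flag, radius_used)``: the urbanicity radius in miles, or 0.5
    when only the vehicle-ownership exception fired.
    """
    if access.tract_id != tract.tract_id:
        raise DataError(
            f"access summary for {access.tract_id} does not match tract {tract.tract_id}"
        )
    urbanicity = classify_urbanicity(tract.population, tract.area)
    radius = RADIUS_BY_URBANICITY[urbanicity]
    if access.fraction_beyond(radius) >= LOW_ACCESS_FRACTION:
        return True, radius
    if (
        tract.vehicles_owned < VEHICLE_EXCEPTION_COUNT
        and access.fraction_beyond(VEHICLE_EXCEPTION_RADIUS) >= LOW_ACCESS_FRACTION
    ):
        return True, VEHICLE_EXCEPTION_RADIUS
    return False, radius


def classify_segregation(race_props: Mapping[str, float]) -> str:
    """The group holding a strict majority (> 50%), else "Integrated"."""
    total = 0.0
    for group, p in race_props.items():
        if group not in RACE_GROUPS:
            raise DataError(f"unknown race group {group!r}")
        if not 0.0 <= p <= 1.0:
            raise DataError(f"race proportion {group}={p} outside [0, 1]")
        total += p
    if total > 1.0 + 1e-9:
        raise DataError(f"race proportions sum to {total:.6f} > 1")
    for group, p in race_props.items():
        if p > MAJORITY_THRESHOLD:
            return group
    return "Integrated"


def ddi_quartile_cuts(ddi_values: Sequence[float]) -> tuple[float, float]:
    """Cohort (Q1, Q3) cut points for DDI categorisation.

    Quartiles are lower order statistics so categories are stable under any
    rank-preserving transformation of the scores.
    """
    arr = np.asarray(ddi_values, dtype=float)
    if arr.size < 4 or np.unique(arr).size < 4:
        raise DataError("DDI categorisation needs >= 4 distinct values")
    q1 = float(np.quantile(arr, 0.25, method="lower"))
    q3 = float(np.quantile(arr, 0.75, method="lower"))
    if q1 == q3:
        raise DataError("degenerate DDI distribution: Q1 == Q3")
    return q1, q3


def categorize_ddi(ddi_values: Sequence[float]) -> list[str]:
    """Low / moderate / high DDI by cohort quartiles.

    Bottom quartile (< Q1) is "low", the interquartile band "moderate", and
    the top quartile (>= Q3) "high".
    """
    q1, q3 = ddi_quartile_cuts(ddi_values)
    return [
        "low" if v < q1 else ("high" if v >= q3 else "moderate") for v in ddi_values
    ]


def categorize_redlining(rri: float | None) -> str:
    """Redlining index band: low (<0.7), neutral [0.7, 1.3), high (>=1.3).

    A missing index is a retained category, not a dropped observation.
    """
    if rri is None or (isinstance(rri, float) and math.isnan(rri)):
        return "missing"
    if rri <= 0:
        raise DataError(f"redlining index must be positive, got {rri}")
    if rri < RRI_LOW_CUT:
        return "low"
    if rri >= RRI_HIGH_CUT:
        return "high"
    return "neutral"


def classify_desert(
    tract: Tract,
    access: AccessSummary,
    mode: str = "primary",
    ddi_cuts: tuple[float, float] | None = None,
) -> DesertAssessment:
    """Full per-tract assessment.

    ``mode="primary"`` requires both criteria; ``mode="distance_only"``
    classifies on access alone (secondary analysis). ``ddi_cuts`` are the
    cohort (Q1, Q3) DDI cut points; without them the DDI category is left
    empty (it is a cohort-relative quantity).
    """
    if mode not in ("primary", "distance_only"):
        raise ValueError(f"mode must be 'primary' or 'distance_only', got {mode!r}")
    urbanicity = classify_urbanicity(tract.population, tract.area)
    income = low_income_flag(tract)
    access_flag, radius = low_access_flag(tract, access)
    if ddi_cuts is None:
        ddi_cat = ""
    else:
        q1, q3 = ddi_cuts
        ddi_cat = "low" if tract.ddi < q1 else ("high" if tract.ddi >= q3 else "moderate")
    return DesertAssessment(
        tract_id=tract.tract_id,
        urbanicity=urbanicity,
        low_income=income,
        low_access=access_flag,
        desert=(income and access_flag) if mode == "primary" else access_flag,
        desert_distance_only=access_flag,
        access_fraction_beyond=access.fraction_beyond(radius),
        radius_used=radius,
        segregation=classify_segregation(tract.race_props),
        ddi_category=ddi_cat,
        redlining_category=categorize_redlining(tract.rri),
    )


@dataclass
class CohortClassification:
    """Assessments for the analytic cohort plus the exclusion waterfall."""

    assessments: list[DesertAssessment]
    excluded: dict[str, str]  # tract_id -> reason
    ddi_cuts: tuple[float, float]


def classify_cohort(
    tracts: Iterable[Tract],
    blocks: Iterable[Block],
    pharmacies: Sequence[Pharmacy],
    mode: str = "primary",
    metric: str = "planar",
) -> CohortClassification:
    """Classify every tract in a cohort.

    Tracts without income data or without populated blocks are excluded with
    a logged reason (the analytic-cohort filter); DDI quartile cut points are
    computed once over the included tracts.
    """
    tracts = list(tracts)
    blocks_by_tract: dict[str, list[Block]] = {}
    for b in blocks:
        blocks_by_tract.setdefault(b.tract_id, []).append(b)

    # one global nearest-neighbour query over all block centroids
    all_blocks = [b for t in tracts for b in blocks_by_tract.get(t.tract_id, [])]
    if all_blocks:
        pts = np.array([[b.x, b.y] for b in all_blocks], dtype=float)
        dists = dict(
            zip(
                (id(b) for b in all_blocks),
                nearest_distances(pts, pharmacies, metric),
            )
        )

    included: list[tuple[Tract, AccessSummary]] = []
    excluded: dict[str, str] = {}
    for t in tracts:
        t_blocks = blocks_by_tract.get(t.tract_id, [])
        if not t_blocks:
            excluded[t.tract_id] = "no blocks"
            continue
        if t.median_income is None or t.msa_median_income is None:
            excluded[t.tract_id] = "missing income data"
            continue
        try:
            summary = AccessSummary(
                tract_id=t.tract_id,
                nearest_distance_by_block={
                    b.block_id: float(dists[id(b)]) for b in t_blocks
                },
                population_by_block={b.block_id: b.population for b in t_blocks},
            )
        except DegenerateTractError:
            excluded[t.tract_id] = "zero population"
            continue
        included.append((t, summary))

    if excluded:
        logger.info(
            "excluded %d of %d tracts from the analytic cohort (%s)",
            len(excluded),
            len(tracts),
            ", ".join(sorted(set(excluded.values()))),
        )
    if not included:
        raise DataError("no tracts remain after exclusions")

    cuts = ddi_quartile_cuts([t.ddi for t, _ in included])
    assessments = [
        classify_desert(t, summary, mode=mode, ddi_cuts=cuts)
        for t, summary in included
    ]
    return CohortClassification(assessments=assessments, excluded=excluded, ddi_cuts=cuts)
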