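"""Readers and writers for cohort files.

On disk a cohort is: ``tracts.csv``, ``blocks.csv``, ``pharmacies.geojson``
(an RFC 7946 point FeatureCollection) and ``truth.json``. Column names are
documented in ``docs/data_dictionary.md``; extra columns are accepted with a
warning for forward compatibility. The round trip through these functions is
lossless field-for-field.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import pandas as pd

from .exceptions import DataError
from .types import Block, Pharmacy, SyntheticCohort, Tract, RACE_GROUPS, validate_geoid

TRACT_COLUMNS = [
    "tract_id", "population", "area", "x", "y", "prop_poverty", "median_income",
    "msa_id", "msa_median_income",
    "prop_white", "prop_black", "prop_hispanic", "prop_asian", "prop_aian",
    "prop_age65", "prop_female", "prop_lt_hs", "prop_uninsured",
    "prop_amb_disability", "vehicles_owned", "ddi", "ddi_infa", "ddi_se", "rri",
]
BLOCK_COLUMNS = ["block_id", "tract_id", "x", "y", "population"]

_RACE_COL = {g: f"prop_{g.lower()}" for g in RACE_GROUPS}


def tracts_to_frame(tracts: list[Tract]) -> pd.DataFrame:
    rows = []
    for t in tracts:
        row = {
            "tract_id": t.tract_id, "population": t.population, "area": t.area,
            "x": t.x, "y": t.y, "prop_poverty": t.prop_poverty,
            "median_income": t.median_income, "msa_id": t.msa_id,
            "msa_median_income": t.msa_median_income,
            "prop_age65": t.prop_age65, "prop_female": t.prop_female,
            "prop_lt_hs": t.prop_lt_hs, "prop_uninsured": t.prop_uninsured,
            "prop_amb_disability": t.prop_amb_disability,
            "vehicles_owned": t.vehicles_owned,
            "ddi": t.ddi, "ddi_infa": t.ddi_infa, "ddi_se": t.ddi_se, "rri": t.rri,
        }
        for g, col in _RACE_COL.items():
            row[col] = t.race_props.get(g, 0.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=TRACT_COLUMNS)


def blocks_to_frame(blocks: list[Block]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"block_id": b.block_id, "tract_id": b.tract_id, "x": b.x, "y": b.y,
             "population": b.population}
            for b in blocks
        ],
        columns=BLOCK_COLUMNS,
    )


def pharmacies_to_geojson(pharmacies: list[Pharmacy]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": {"pharmacy_id": p.pharmacy_id, "open": p.open_flag},
            }
            for p in pharmacies
        ],
    }


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort to ``directory``; returns the paths written."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "tracts": directory / "tracts.csv",
            "blocks": directory / "blocks.csv",
            "pharmacies": directory / "pharmacies.geojson",
            "truth": directory / "truth.json",
        }
        tracts_to_frame(cohort.tracts).to_csv(paths["tracts"], index=False)
        blocks_to_frame(cohort.blocks).to_csv(paths["blocks"], index=False)
        with open(paths["pharmacies"], "w") as fh:
            json.dump(pharmacies_to_geojson(cohort.pharmacies), fh, indent=1, sort_keys=True)
        with open(paths["truth"], "w") as fh:
            json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        return paths
    except OSError as exc:
        raise DataError(f"failed writing cohort to {directory}: {exc}") from exc


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{what}: missing columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what}: ignoring extra columns {extra}", stacklevel=3)


def _opt(v) -> float | None:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)


def read_tracts(path: str | Path) -> list[Tract]:
    df = pd.read_csv(path, dtype={"tract_id": str, "msa_id": str},
                     float_precision="round_trip")
    _check_columns(df, TRACT_COLUMNS, f"tracts file {path}")
    if df["tract_id"].duplicated().any():
        dupes = df.loc[df["tract_id"].duplicated(), "tract_id"].tolist()[:5]
        raise DataError(f"duplicate tract_id in {path}: {dupes}")
    tracts = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            validate_geoid(row.tract_id)
            tracts.append(
                Tract(
                    tract_id=row.tract_id, population=int(row.population),
                    area=float(row.area), prop_poverty=float(row.prop_poverty),
                    median_income=_opt(row.median_income),
                    msa_median_income=_opt(row.msa_median_income),
                    race_props={g: float(getattr(row, _RACE_COL[g])) for g in RACE_GROUPS},
                    prop_age65=float(row.prop_age65), prop_female=float(row.prop_female),
                    prop_lt_hs=float(row.prop_lt_hs),
                    prop_uninsured=float(row.prop_uninsured),
                    prop_amb_disability=float(row.prop_amb_disability),
                    vehicles_owned=int(row.vehicles_owned),
                    ddi=float(row.ddi), ddi_infa=float(row.ddi_infa),
                    ddi_se=float(row.ddi_se), rri=_opt(row.rri),
                    msa_id=row.msa_id, x=float(row.x), y=float(row.y),
                )
            )
        except DataError as exc:
            raise DataError(f"{path} row {i + 2}: {exc}") from exc
    return tracts


def read_blocks(path: str | Path) -> list[Block]:
    df = pd.read_csv(path, dtype={"block_id": str, "tract_id": str},
                     float_precision="round_trip")
    _check_columns(df, BLOCK_COLUMNS, f"blocks file {path}")
    blocks = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            blocks.append(
                Block(block_id=row.block_id, tract_id=row.tract_id,
                      x=float(row.x), y=float(row.y), population=int(row.population))
            )
        except DataError as exc:
            raise DataError(f"{path} row {i + 2}: {exc}") from exc
    return blocks


def read_pharmacies(path: str | Path) -> list[Pharmacy]:
    """Read any RFC 7946 point FeatureCollection as pharmacies."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    pharmacies = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise DataError(f"{path} feature {i}: only Point geometries supported")
        x, y = geom["coordinates"][:2]
        props = feat.get("properties") or {}
        pharmacies.append(
            Pharmacy(
                pharmacy_id=str(props.get("pharmacy_id", f"P{i:06d}")),
                x=float(x), y=float(y),
                open_flag=bool(props.get("open", True)),
            )
        )
    return pharmacies


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Referential integrity (blocks pointing at unknown tracts, tracts without
    blocks, duplicate ids) is validated by the :class:`SyntheticCohort`
    constructor; offenders are named in the error.
    """
    directory = Path(directory)
    tracts = read_tracts(directory / "tracts.csv")
    blocks = read_blocks(directory / "blocks.csv")
    pharmacies = read_pharmacies(directory / "pharmacies.geojson")
    truth_path = directory / "truth.json"
    truth = {}
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return SyntheticCohort(tracts=tracts, blocks=blocks, pharmacies=pharmacies, truth=truth)
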