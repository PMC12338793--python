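"""Descriptive comparison of desert vs non-desert tracts and map export.

Continuous variables are summarized as median (IQR) and compared with the
Wilcoxon rank-sum test; categorical variables as n (%) with the chi-square
test, switching to Fisher's exact test for 2x2 tables with any expected cell
below 5. Percentages in formatted output follow a mixed-precision
convention (>=10% integer, otherwise one decimal, "<0.1%" below 0.1%); raw
values are always retained in machine-readable fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .types import DesertAssessment, Tract

ASSESSMENT_COLUMNS = [
    "tract_id", "urbanicity", "low_income", "low_access", "desert",
    "desert_distance_only", "access_fraction_beyond", "radius_used",
    "segregation", "ddi_category", "redlining_category",
]


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage of ``numerator`` in ``denominator``, rounded half-up."""
    if denominator <= 0:
        raise DataError("percentage denominator must be positive")
    value = 100.0 * numerator / denominator
    scale = 10**decimals
    return np.floor(value * scale + 0.5) / scale


def format_percent(value: float) -> str:
    """Mixed-precision display rule: 34%, 3.7%, or "<0.1%"."""
    if value >= 10.0:
        return f"{value:.0f}%"
    if value >= 0.1:
        return f"{value:.1f}%"
    return "<0.1%"


@dataclass
class TableOneRow:
    """One line of the descriptive table (a variable, or one of its levels)."""

    variable: str
    level: str | None
    overall: str
    non_desert: str
    desert: str
    test: str  # wilcoxon | chisq | fisher | none
    p_value: float
    raw: dict = field(default_factory=dict)
    note: str = ""


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.percentile(x.dropna(), [25, 50, 75])
    return f"{med:,.1f} ({q1:,.1f}, {q3:,.1f})"


def table_one(
    df: pd.DataFrame,
    group_col: str = "desert",
    variables: Sequence[str] | None = None,
) -> list[TableOneRow]:
    """Build the descriptive comparison of desert vs non-desert tracts.

    Numeric columns are treated as continuous, everything else (and
    booleans) as categorical. Output ordering is the column order of ``df``.
    """
    if group_col not in df.columns:
        raise DataError(f"group column {group_col!r} not in data")
    grp = df[group_col].astype(bool)
    if grp.all() or (~grp).all():
        raise DataError("both desert and non-desert groups must be non-empty")
    g0, g1 = df[~grp], df[grp]
    if variables is None:
        variables = [c for c in df.columns if c not in (group_col, "tract_id")]

    rows: list[TableOneRow] = []
    for var in variables:
        col = df[var]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            if col.nunique(dropna=True) <= 1:
                rows.append(
                    TableOneRow(var, None, _median_iqr(col), _median_iqr(g0[var]),
                                _median_iqr(g1[var]), "none", float("nan"),
                                note="zero variance; test skipped")
                )
                continue
            stat = stats.mannwhitneyu(
                g0[var].dropna(), g1[var].dropna(), alternative="two-sided"
            )
            rows.append(
                TableOneRow(
                    var, None, _median_iqr(col), _median_iqr(g0[var]),
                    _median_iqr(g1[var]), "wilcoxon", float(stat.pvalue),
                    raw={"medians": [float(g0[var].median()), float(g1[var].median())]},
                )
            )
        else:
            levels = sorted(col.astype(str).unique())
            counts = pd.crosstab(col.astype(str), grp)
            counts = counts.reindex(index=levels, columns=[False, True], fill_value=0)
            table = counts.to_numpy()
            test, p, note = "chisq", float("nan"), ""
            if table.shape[0] < 2:
                test, note = "none", "single level; test skipped"
            else:
                chi2, p_chi, _, expected = stats.chi2_contingency(table)
                if table.shape == (2, 2) and (expected < 5).any():
                    test = "fisher"
                    _, p = stats.fisher_exact(table)
                else:
                    p = float(p_chi)
                    if (expected < 5).any():
                        note = "expected cell < 5; chi-square retained (table > 2x2)"
            for level in levels:
                n0 = int(counts.loc[level, False])
                n1 = int(counts.loc[level, True])
                rows.append(
                    TableOneRow(
                        var, level,
                        f"{n0 + n1:,} ({format_percent(percentage(n0 + n1, len(df)))})",
                        f"{n0:,} ({format_percent(percentage(n0, len(g0)))})",
                        f"{n1:,} ({format_percent(percentage(n1, len(g1)))})",
                        test, float(p),
                        raw={"n_non_desert": n0, "n_desert": n1},
                        note=note,
                    )
                )
    return rows


def table_one_frame(rows: list[TableOneRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"variable": r.variable, "level": r.level, "overall": r.overall,
             "non_desert": r.non_desert, "desert": r.desert, "test": r.test,
             "p_value": r.p_value, "note": r.note}
            for r in rows
        ]
    )


def assessments_to_frame(assessments: Sequence[DesertAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(a, c) for c in ASSESSMENT_COLUMNS} for a in assessments],
        columns=ASSESSMENT_COLUMNS,
    )


def analysis_frame(
    tracts: Sequence[Tract], assessments: Sequence[DesertAssessment]
) -> pd.DataFrame:
    """Merge assessments with tract covariates into the regression table.

    Adds the upper-quartile binary flags for education, insurance and
    ambulatory disability (the dichotomization cut is cohort-relative).
    """
    by_id = {t.tract_id: t for t in tracts}
    adf = assessments_to_frame(assessments)
    missing = [tid for tid in adf["tract_id"] if tid not in by_id]
    if missing:
        raise DataError(f"assessments reference unknown tracts: {missing[:5]}")
    sel = [by_id[tid] for tid in adf["tract_id"]]
    for name, attr in (
        ("lt_hs_high", "prop_lt_hs"),
        ("uninsured_high", "prop_uninsured"),
        ("disability_high", "prop_amb_disability"),
    ):
        vals = np.array([getattr(t, attr) for t in sel])
        adf[name] = (vals >= np.quantile(vals, 0.75, method="lower")).astype(int)
    adf["desert"] = adf["desert"].astype(int)
    for col in ("population", "median_income", "prop_poverty", "ddi", "ddi_infa",
                "ddi_se", "prop_age65", "prop_female", "x", "y"):
        # None (missing income) becomes NaN so the column stays numeric
        adf[col] = pd.to_numeric(pd.Series([getattr(t, col) for t in sel]))
    return adf


def export_map(
    assessments: Sequence[DesertAssessment],
    tracts: Sequence[Tract],
    geojson_path,
    png_path=None,
) -> dict:
    """Choropleth-style export of desert status.

    Writes an RFC 7946 FeatureCollection of tract squares (side derived from
    the tract's area) carrying the assessment fields; optionally renders a
    simple PNG map. Returns the GeoJSON object.
    """
    import json

    by_id = {t.tract_id: t for t in tracts}
    features = []
    for a in assessments:
        t = by_id.get(a.tract_id)
        if t is None or not np.isfinite(t.x) or not np.isfinite(t.y):
            continue
        half = float(np.sqrt(t.area)) / 2.0
        ring = [
            [t.x - half, t.y - half], [t.x + half, t.y - half],
            [t.x + half, t.y + half], [t.x - half, t.y + half],
            [t.x - half, t.y - half],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {c: getattr(a, c) for c in ASSESSMENT_COLUMNS},
            }
        )
    if len(features) < len(assessments):
        import warnings

        warnings.warn(
            f"{len(assessments) - len(features)} tracts lack coordinates; "
            "GeoJSON-only export for the rest", stacklevel=2,
        )
    collection = {"type": "FeatureCollection", "features": features}
    with open(geojson_path, "w") as fh:
        json.dump(collection, fh, indent=1, sort_keys=True)

    if png_path is not None and features:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        classes = sorted({f["properties"]["desert"] for f in features})
        colors = {True: "#b2182b", False: "#f0f0f0"}
        for f in features:
            ring = f["geometry"]["coordinates"][0]
            xs = [p[0] for p in ring]
            ys = [p[1] for p in ring]
            ax.fill(xs, ys, color=colors[f["properties"]["desert"]],
                    edgecolor="#999999", linewidth=0.2)
        labels = {True: "pharmacy desert", False: "not a desert"}
        handles = [plt.Rectangle((0, 0), 1, 1, color=colors[c]) for c in classes]
        ax.legend(handles, [labels[c] for c in classes], loc="upper right", fontsize=8)
        ax.set_aspect("equal")
        ax.set_xlabel("miles")
        ax.set_ylabel("miles")
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return collection
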