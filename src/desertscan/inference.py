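"""Association inference: logistic ORs, VIF, E-values, Moran's I.

The desert indicator is modelled by ordinary maximum-likelihood logistic
regression; odds ratios carry Wald 95% confidence intervals (symmetric on
the log-odds scale). Multicollinearity is gauged with variance inflation
factors, robustness to unmeasured confounding with E-values, and residual
spatial structure with Moran's I on the model-predicted odds (a diagnostic,
not a correction — no spatially correlated error model is fitted).

E-values follow the approximate odds-ratio pathway for a non-rare outcome:
the OR is converted to a risk ratio by the square root (inverting protective
ORs first) and E = RR + sqrt(RR * (RR - 1)). Reported E-values are rounded
toward 1 at two decimals, a conservative convention that never overstates
how strong an unmeasured confounder would have to be.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DataError

__all__ = [
    "DesignSpec", "AssociationResult", "SpatialWeights", "DEFAULT_DESIGN",
    "build_design_matrix", "fit_logistic", "compute_vif", "evalue_for_or",
    "build_weights", "morans_i", "analyze_associations",
]


@dataclass(frozen=True)
class DesignSpec:
    """Model design: outcome column, predictors and reference levels.

    ``predictors`` maps a column name to its type: ``"binary"``,
    ``"categorical"`` (dummy-coded against the reference level) or
    ``"continuous"``.
    """

    outcome: str = "desert"
    predictors: tuple[tuple[str, str], ...] = ()
    reference_levels: Mapping[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, kind in self.predictors:
            if kind not in ("binary", "categorical", "continuous"):
                raise DataError(f"predictor {name}: unknown type {kind!r}")
            if name == self.outcome:
                raise DataError(f"predictor {name} duplicates the outcome")
            if kind == "categorical" and name not in self.reference_levels:
                raise DataError(f"categorical predictor {name} needs a reference level")


#: default design mirroring the named predictors of the desert model
DEFAULT_DESIGN = DesignSpec(
    outcome="desert",
    predictors=(
        ("ddi_category", "categorical"),
        ("redlining_category", "categorical"),
        ("segregation", "categorical"),
        ("urbanicity", "categorical"),
        ("lt_hs_high", "binary"),
        ("uninsured_high", "binary"),
        ("disability_high", "binary"),
    ),
    reference_levels={
        "ddi_category": "low",
        "redlining_category": "neutral",
        "segregation": "White",
        "urbanicity": "suburban",
    },
)


@dataclass
class SpatialWeights:
    """Neighbour lists with weights; optionally row-standardized."""

    n: int
    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    row_standardized: bool

    def __post_init__(self) -> None:
        if len(self.neighbors) != self.n or len(self.weights) != self.n:
            raise DataError("neighbor/weight lists must have length n")
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if len(nb) != len(w):
                raise DataError(f"row {i}: neighbor and weight lengths differ")
            if np.any(nb == i):
                raise DataError(f"row {i}: self-neighbor not allowed")
            if np.any(np.asarray(w) < 0):
                raise DataError(f"row {i}: negative weight")

    @property
    def total_weight(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag: weighted sum of each unit's neighbors' values."""
        out = np.zeros(self.n)
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            if len(nb):
                out[i] = float(np.dot(w, x[nb]))
        return out


@dataclass
class AssociationResult:
    """Fitted-model summary for the desert association analysis."""

    coefficients: dict[str, float]
    or_estimates: dict[str, tuple[float, float, float, float]]  # OR, lo, hi, p
    vif: dict[str, float]
    evalues: dict[str, tuple[float, float]]
    morans_i: tuple[float, float, float] | None  # I, expected, permutation p
    n_used: int
    convergence: bool
    diagnostic: str = ""

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            if isinstance(v, float) and not math.isfinite(v):
                return None  # strict-JSON representation of inf/nan
            return v

        return clean({
            "schema_version": 1,
            "coefficients": self.coefficients,
            "or_estimates": {
                k: {"or": v[0], "ci_low": v[1], "ci_high": v[2], "p": v[3]}
                for k, v in self.or_estimates.items()
            },
            "vif": self.vif,
            "evalues": {k: {"point": v[0], "ci": v[1]} for k, v in self.evalues.items()},
            "morans_i": (
                None
                if self.morans_i is None
                else {"I": self.morans_i[0], "expected_I": self.morans_i[1],
                      "permutation_p": self.morans_i[2]}
            ),
            "n_used": self.n_used,
            "convergence": self.convergence,
            "diagnostic": self.diagnostic,
        })


def build_design_matrix(
    df: pd.DataFrame, design: DesignSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and dummy-coded design matrix (with constant)."""
    if design.outcome not in df.columns:
        raise DataError(f"outcome column {design.outcome!r} not in data")
    y = df[design.outcome].astype(int)
    if set(y.unique()) - {0, 1}:
        raise DataError(f"outcome {design.outcome!r} must be binary 0/1")
    cols: dict[str, np.ndarray] = {}
    for name, kind in design.predictors:
        if name not in df.columns:
            raise DataError(f"predictor column {name!r} not in data")
        if kind == "continuous":
            cols[name] = df[name].astype(float).to_numpy()
        elif kind == "binary":
            cols[name] = df[name].astype(int).to_numpy()
        else:
            ref = design.reference_levels[name]
            levels = [str(v) for v in df[name].unique()]
            if ref not in levels:
                raise DataError(
                    f"reference level {ref!r} absent from predictor {name!r}"
                )
            for level in sorted(set(levels) - {ref}):
                col = (df[name].astype(str) == level).to_numpy().astype(int)
                if col.sum() == 0:
                    raise DataError(f"empty category {name}={level!r} after filtering")
                cols[f"{name}[{level}]"] = col
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "const", 1.0)
    return y, X


def fit_logistic(design: DesignSpec, df: pd.DataFrame) -> AssociationResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs on the OR scale.

    Perfect separation is flagged (``convergence=False`` with a diagnostic)
    rather than raised. Deterministic given input ordering.
    """
    y, X = build_design_matrix(df, design)
    if y.nunique() < 2:
        raise DataError("outcome has a single class; logistic fit undefined")
    if len(df) <= X.shape[1]:
        raise DataError(f"n={len(df)} too small for {X.shape[1]} parameters")
    model = sm.Logit(y.to_numpy(), X.to_numpy())
    diagnostic = ""
    converged = False
    res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged:
            diagnostic = "optimizer failed to converge"
        # near-separation shows up as exploding standard errors
        if converged and not np.all(np.isfinite(res.bse)):
            converged = False
            diagnostic = "non-finite standard errors (possible separation)"
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        diagnostic = f"perfect separation or singular design: {exc}"

    names = list(X.columns)
    if res is None:
        return AssociationResult(
            coefficients={}, or_estimates={}, vif={}, evalues={},
            morans_i=None, n_used=len(df), convergence=False, diagnostic=diagnostic,
        )
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    z = stats.norm.ppf(0.975)
    coefficients = dict(zip(names, map(float, params)))
    with np.errstate(over="ignore"):  # a near-separated level can overflow its CI bound
        or_estimates = {
            name: (
                float(np.exp(b)),
                float(np.exp(b - z * se)),
                float(np.exp(b + z * se)),
                float(p),
            )
            for name, b, se, p in zip(names, params, bse, pvals)
            if name != "const"
        }
    result = AssociationResult(
        coefficients=coefficients,
        or_estimates=or_estimates,
        vif={},
        evalues={},
        morans_i=None,
        n_used=len(df),
        convergence=converged,
        diagnostic=diagnostic,
    )
    result._fitted_probs = np.asarray(res.predict())  # type: ignore[attr-defined]
    return result


def compute_vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per predictor column.

    ``X`` is a design matrix without a constant (one is appended for the
    auxiliary regressions). Exact collinearity yields ``inf``, not an
    exception; a constant column is an error.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise DataError("VIF needs at least two predictors")
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise DataError(f"constant column {c!r}: VIF undefined")
    mat = np.column_stack([X.to_numpy(dtype=float), np.ones(len(X))])
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(X.columns):
            v = float(variance_inflation_factor(mat, j))
            out[name] = math.inf if (not math.isfinite(v) or v > 1e12) else v
    return out


def evalue_for_or(
    or_point: float, ci_bound_nearer_1: float | None = None, decimals: int = 2
) -> tuple[float, float]:
    """E-value for an odds ratio (non-rare outcome).

    The OR is converted to an approximate risk ratio via the square root
    (protective ORs are inverted first), then
    ``E = RR + sqrt(RR * (RR - 1))``. The CI E-value uses the bound nearer
    the null and is 1 when the interval crosses 1. Values are rounded toward
    1 at ``decimals`` places so robustness is never overstated.
    """
    def _one(orv: float) -> float:
        if orv <= 0:
            raise DataError(f"odds ratio must be positive, got {orv}")
        rr = math.sqrt(orv) if orv >= 1.0 else math.sqrt(1.0 / orv)
        e = rr + math.sqrt(rr * (rr - 1.0))
        return math.floor(e * 10**decimals + 1e-9) / 10**decimals

    e_point = _one(or_point)
    if ci_bound_nearer_1 is None:
        return e_point, float("nan")
    protective = or_point < 1.0
    crosses = (ci_bound_nearer_1 >= 1.0) if protective else (ci_bound_nearer_1 <= 1.0)
    e_ci = 1.0 if crosses else _one(ci_bound_nearer_1)
    return e_point, e_ci


def build_weights(
    coords: np.ndarray | None = None,
    grid_shape: tuple[int, int] | None = None,
    scheme: str = "knn",
    k: int = 8,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Spatial weights from point coordinates (knn) or a grid (rook/queen).

    knn neighbour sets are ordered by (distance, index) — ties break to the
    lower index — and are not symmetrized; contiguity schemes are symmetric
    by construction. Rows are standardized to sum to 1 by default (isolated
    units keep a zero row).
    """
    if scheme == "knn":
        if coords is None:
            raise DataError("knn weights need point coordinates")
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        if n < 2:
            raise DataError("need at least two units for spatial weights")
        if not 1 <= k < n:
            raise DataError(f"knn needs 1 <= k < n, got k={k}, n={n}")
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        neighbors = []
        for i in range(n):
            order = np.lexsort((np.arange(n), dist[i]))
            order = order[order != i][:k]
            neighbors.append(np.sort(order))
    elif scheme in ("rook", "queen"):
        if grid_shape is None:
            raise DataError(f"{scheme} weights need grid_shape")
        rows, cols = grid_shape
        n = rows * cols
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        neighbors = []
        for i in range(n):
            r, c = divmod(i, cols)
            nb = [
                (r + dr) * cols + (c + dc)
                for dr, dc in steps
                if 0 <= r + dr < rows and 0 <= c + dc < cols
            ]
            neighbors.append(np.array(sorted(nb), dtype=int))
    else:
        raise DataError(f"unknown weight scheme {scheme!r}")

    weights = []
    for nb in neighbors:
        if len(nb) == 0:
            weights.append(np.array([]))
        elif row_standardize:
            weights.append(np.full(len(nb), 1.0 / len(nb)))
        else:
            weights.append(np.ones(len(nb)))
    return SpatialWeights(
        n=n, neighbors=[np.asarray(nb, dtype=int) for nb in neighbors],
        weights=weights, row_standardized=row_standardize,
    )


def morans_i(
    values: Sequence[float],
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Global Moran's I with a two-sided permutation p-value.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    The permutation p uses the add-one rule over ``n_perm`` random
    relabelings, two-sided around the null expectation -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    if len(x) != weights.n:
        raise DataError(f"values length {len(x)} != weights.n {weights.n}")
    if np.ptp(x) == 0:
        raise DataError("Moran's I undefined for a constant vector")
    n = weights.n
    W = weights.total_weight
    if W <= 0:
        raise DataError("weights sum to zero")
    z = x - x.mean()
    denom = float(np.dot(z, z))

    def stat(zv: np.ndarray) -> float:
        return float(n / W * np.dot(zv, weights.lag(zv)) / denom)

    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    if n_perm <= 0:
        return i_obs, expected, float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    ref = abs(i_obs - expected)
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if abs(stat(zp) - expected) >= ref - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return i_obs, expected, p


def analyze_associations(
    df: pd.DataFrame,
    design: DesignSpec = DEFAULT_DESIGN,
    coords: np.ndarray | None = None,
    weights: SpatialWeights | None = None,
    scheme: str = "knn",
    k: int = 8,
    n_perm: int = 999,
    seed: int = 0,
    moran_scale: str = "odds",
) -> AssociationResult:
    """Full association analysis: logistic fit, VIF, E-values, Moran's I.

    Moran's I is evaluated on the model-predicted odds p/(1-p) (or on the
    predicted probabilities with ``moran_scale="probability"``) using the
    provided weights, or row-standardized knn weights built from ``coords``.
    """
    result = fit_logistic(design, df)
    if not result.or_estimates:
        return result
    _, X = build_design_matrix(df, design)
    predictors = X.drop(columns="const")
    if predictors.shape[1] >= 2:
        result.vif = compute_vif(predictors)
    result.evalues = {
        name: evalue_for_or(orv, lo if orv >= 1 else hi)
        for name, (orv, lo, hi, _p) in result.or_estimates.items()
    }
    if weights is None and coords is not None:
        weights = build_weights(coords=coords, scheme=scheme, k=k)
    if weights is not None and result.convergence:
        probs = np.clip(result._fitted_probs, 1e-12, 1 - 1e-12)  # type: ignore[attr-defined]
        vals = probs / (1 - probs) if moran_scale == "odds" else probs
        result.morans_i = morans_i(vals, weights, n_perm=n_perm, seed=seed)
    return result
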