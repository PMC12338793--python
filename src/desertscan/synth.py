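"""Seeded synthetic cohorts of tracts, blocks and pharmacies.

Two generation modes serve two validation purposes:

* **geometry mode** — desert status *emerges* from the spatial layout: tracts
  tile a planar grid (miles), blocks sit on a jittered sub-grid inside their
  tract, and pharmacies follow an inhomogeneous Poisson process whose
  intensity falls with the tract's digital-divide stratum, so induced desert
  status is associated with DDI and redlining. The cohort's ``truth`` holds
  desert labels computed by an exhaustive block-pharmacy distance scan that
  is deliberately independent of the access/classifier modules.
* **label mode** — desert status is *drawn* from a logistic model with known
  coefficients over the generated covariates, providing a known-truth target
  for parameter recovery by the inference stage. Covariates are spatially
  autocorrelated (neighbour-averaged noise) so spatial diagnostics are
  exercised.

Marginal distributions default to values typical of US census tracts (median
population ~3,700; median household income ~$62,600; DDI median ~19 with
IQR ~14-24; ~39% of tracts missing a redlining index); each logical
component (geometry, covariates, pharmacies, labels) draws from its own RNG
stream derived from the master seed, so changing one configuration block
does not perturb unrelated draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .exceptions import ConfigError
from .types import Block, Pharmacy, SyntheticCohort, Tract

RACE_GROUPS = ("White", "Black", "Hispanic", "Asian", "AIAN")

#: encodable covariate categories for label-mode coefficients
LABEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "ddi": ("moderate", "high"),                    # reference: low
    "redlining": ("low", "high", "missing"),        # reference: neutral
    "segregation": ("Black", "Hispanic", "Asian", "AIAN", "Integrated"),  # ref: White
    "urbanicity": ("urban", "rural"),               # reference: suburban
    "lt_hs_high": ("1",),                           # binary, upper-quartile cut
    "uninsured_high": ("1",),
    "disability_high": ("1",),
}

#: generator defaults mirroring the reported adjusted odds ratios where printed
DEFAULT_TRUE_LOG_ODDS: dict[str, float] = {
    "intercept": -4.3,
    "ddi:moderate": math.log(2.84),
    "ddi:high": math.log(6.94),
    "redlining:low": math.log(0.64),
    "redlining:high": math.log(2.18),
    "redlining:missing": math.log(1.5),
    "segregation:Black": math.log(2.09),
    "segregation:Hispanic": math.log(2.94),
    "segregation:AIAN": math.log(16.0),
    "segregation:Asian": 0.0,
    "segregation:Integrated": 0.0,
    "urbanicity:urban": math.log(2.0),
    "urbanicity:rural": math.log(2.0),
    "lt_hs_high:1": math.log(1.39),
    "uninsured_high:1": math.log(1.37),
    "disability_high:1": math.log(1.30),
}

DEFAULT_COVARIATE_SPEC: dict = {
    "population_median": 3743.0,
    "population_log_sd": 1.0,
    "population_min": 200,
    "income_median": 62557.0,
    "income_log_sd": 0.45,
    "poverty_median": 0.12,
    "ddi_median": 18.8,
    "ddi_scale": 7.4,
    "rri_log_median": 0.15,
    "rri_log_sd": 0.45,
    "majority_probs": {
        "White": 0.55, "Black": 0.09, "Hispanic": 0.11,
        "Asian": 0.012, "AIAN": 0.008, "Integrated": 0.23,
    },
    "low_vehicle_rate": 0.03,
    "missing_income_rate": 0.0,
    "smoothing_passes": 3,
}

DEFAULT_PHARMACY_INTENSITY: dict[str, float] = {
    "low": 1.0, "moderate": 0.5, "high": 0.12,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the synthetic cohort generator.

    ``pharmacy_intensity`` is the expected number of pharmacies per tract;
    either one number for every tract or a mapping keyed by the tract's DDI
    quartile category (low / moderate / high), which is how desert status is
    made to covary with the digital divide. ``true_log_odds`` is the
    label-mode coefficient vector keyed ``"covariate:category"`` plus
    ``"intercept"``.
    """

    n_tracts: int = 400
    grid_shape: tuple[int, int] = (20, 20)
    tract_side: float = 1.0  # miles
    blocks_per_tract: int = 9
    pharmacy_intensity: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHARMACY_INTENSITY)
    )
    covariate_spec: dict = field(default_factory=dict)
    true_log_odds: Mapping[str, float] | None = None
    missing_redlining_rate: float = 0.39
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracts < 1:
            raise ConfigError(f"n_tracts must be positive, got {self.n_tracts}")
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1 or rows * cols < self.n_tracts:
            raise ConfigError(
                f"grid_shape {self.grid_shape} cannot hold n_tracts={self.n_tracts}"
            )
        if self.tract_side <= 0:
            raise ConfigError(f"tract_side must be positive, got {self.tract_side}")
        if self.blocks_per_tract < 1:
            raise ConfigError(
                f"blocks_per_tract must be positive, got {self.blocks_per_tract}"
            )
        if isinstance(self.pharmacy_intensity, Mapping):
            for k, v in self.pharmacy_intensity.items():
                if k not in ("low", "moderate", "high"):
                    raise ConfigError(f"pharmacy_intensity: unknown stratum {k!r}")
                if v < 0:
                    raise ConfigError(f"pharmacy_intensity[{k!r}] must be nonnegative")
        elif self.pharmacy_intensity < 0:
            raise ConfigError("pharmacy_intensity must be nonnegative")
        if not 0.0 <= self.missing_redlining_rate <= 1.0:
            raise ConfigError(
                f"missing_redlining_rate must be in [0, 1], got {self.missing_redlining_rate}"
            )
        unknown = set(self.covariate_spec) - set(DEFAULT_COVARIATE_SPEC)
        if unknown:
            raise ConfigError(f"covariate_spec: unknown keys {sorted(unknown)}")
        if self.true_log_odds is not None:
            for key in self.true_log_odds:
                if key == "intercept":
                    continue
                cov, _, cat = key.partition(":")
                if cov not in LABEL_COVARIATES or cat not in LABEL_COVARIATES[cov]:
                    raise ConfigError(f"true_log_odds: unknown term {key!r}")

    @property
    def spec(self) -> dict:
        merged = dict(DEFAULT_COVARIATE_SPEC)
        merged.update(self.covariate_spec)
        return merged


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("geometry", "covariates", "pharmacies", "labels")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _smooth_field(rng: np.random.Generator, rows: int, cols: int, passes: int) -> np.ndarray:
    """Spatially autocorrelated standard field via neighbour-averaged noise."""
    f = rng.standard_normal((rows, cols))
    for _ in range(passes):
        acc = f.copy()
        cnt = np.ones_like(f)
        acc[1:, :] += f[:-1, :]; cnt[1:, :] += 1
        acc[:-1, :] += f[1:, :]; cnt[:-1, :] += 1
        acc[:, 1:] += f[:, :-1]; cnt[:, 1:] += 1
        acc[:, :-1] += f[:, 1:]; cnt[:, :-1] += 1
        f = acc / cnt
    f = (f - f.mean()) / f.std()
    return f


def _quartile_categories(values: np.ndarray) -> np.ndarray:
    q1 = np.quantile(values, 0.25, method="lower")
    q3 = np.quantile(values, 0.75, method="lower")
    return np.where(values < q1, "low", np.where(values >= q3, "high", "moderate"))


def _tract_id(i: int) -> str:
    return f"99{i:09d}"


def _generate_covariates(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Draw all tract-level covariates on the grid (first n_tracts cells)."""
    spec = config.spec
    rows, cols = config.grid_shape
    n = config.n_tracts
    rng = _streams(config.seed)["covariates"]
    passes = spec["smoothing_passes"]

    def smooth() -> np.ndarray:
        return _smooth_field(rng, rows, cols, passes).ravel()[:n]

    dep = smooth()                       # shared deprivation factor
    pop_z = smooth()
    u_ddi = 0.8 * dep + 0.6 * smooth()   # DDI latent, spatially smooth
    u_inc = 0.7 * dep + 0.714 * rng.standard_normal(n)
    u_rri = 0.7 * dep + 0.714 * smooth()

    population = np.maximum(
        spec["population_min"],
        np.rint(np.exp(np.log(spec["population_median"]) + spec["population_log_sd"] * pop_z)),
    ).astype(int)
    ddi = np.clip(spec["ddi_median"] + spec["ddi_scale"] * u_ddi, 0.0, 100.0)
    ddi_infa = np.clip(
        17.5 + 7.0 * (0.9 * u_ddi + 0.44 * rng.standard_normal(n)), 0.0, 100.0
    )
    ddi_se = np.clip(
        11.5 + 4.0 * (0.85 * u_ddi + 0.53 * rng.standard_normal(n)), 0.0, 100.0
    )
    median_income = np.exp(np.log(spec["income_median"]) - spec["income_log_sd"] * u_inc)
    prop_poverty = expit(
        logit(spec["poverty_median"]) + 0.75 * dep + 0.66 * rng.standard_normal(n)
    )
    rri = np.exp(spec["rri_log_median"] + spec["rri_log_sd"] * u_rri)
    rri_missing = rng.random(n) < config.missing_redlining_rate
    income_missing = rng.random(n) < spec["missing_income_rate"]

    # MSA = grid quadrant; MSA income drawn once per MSA
    r_idx, c_idx = np.divmod(np.arange(n), cols)
    msa_code = (r_idx >= rows // 2).astype(int) * 2 + (c_idx >= cols // 2).astype(int)
    msa_incomes = rng.normal(66000.0, 6000.0, 4)
    msa_id = np.array([f"M{m:02d}" for m in msa_code])
    msa_median_income = msa_incomes[msa_code]

    majority_probs = spec["majority_probs"]
    groups = list(majority_probs)
    p = np.array([majority_probs[g] for g in groups], dtype=float)
    p = p / p.sum()
    majority = rng.choice(len(groups), size=n, p=p)
    # Dirichlet over 5 groups + an other/multiracial remainder, drawn as
    # normalized gammas with a concentration spike on the majority group
    alpha = np.ones((n, 6))
    integrated_alpha = np.array([6.0, 2.0, 2.0, 0.5, 0.3, 2.0])
    for g_idx, group in enumerate(groups):
        mask = majority == g_idx
        if group == "Integrated":
            alpha[mask] = integrated_alpha
        else:
            alpha[mask, RACE_GROUPS.index(group)] = 14.0
    gam = rng.standard_gamma(alpha)
    race = (gam / gam.sum(axis=1, keepdims=True))[:, :5]

    prop_age65 = expit(logit(0.157) + 0.35 * rng.standard_normal(n))
    prop_female = np.clip(rng.normal(0.51, 0.017, n), 0.30, 0.70)
    prop_lt_hs = expit(logit(0.284) + 0.6 * (0.6 * dep + 0.8 * rng.standard_normal(n)))
    prop_uninsured = expit(logit(0.077) + 0.7 * (0.6 * dep + 0.8 * rng.standard_normal(n)))
    prop_amb_disability = expit(
        logit(0.077) + 0.5 * (0.5 * dep + 0.87 * rng.standard_normal(n))
    )

    own = expit(rng.normal(1.6, 0.8, n) - 0.6 * dep)
    vehicles = np.floor(population * 0.75 * own).astype(int)
    low_vehicle = rng.random(n) < spec["low_vehicle_rate"]
    vehicles[low_vehicle] = rng.integers(0, 100, low_vehicle.sum())

    return {
        "population": population, "ddi": ddi, "ddi_infa": ddi_infa, "ddi_se": ddi_se,
        "median_income": median_income, "income_missing": income_missing,
        "prop_poverty": prop_poverty, "rri": rri, "rri_missing": rri_missing,
        "msa_id": msa_id, "msa_median_income": msa_median_income, "race": race,
        "prop_age65": prop_age65, "prop_female": prop_female,
        "prop_lt_hs": prop_lt_hs, "prop_uninsured": prop_uninsured,
        "prop_amb_disability": prop_amb_disability, "vehicles": vehicles,
    }


def _build_tracts(config: GeneratorConfig, cov: dict[str, np.ndarray]) -> list[Tract]:
    side = config.tract_side
    area = side * side
    _, cols = config.grid_shape
    tracts = []
    for i in range(config.n_tracts):
        r, c = divmod(i, cols)
        tracts.append(
            Tract(
                tract_id=_tract_id(i),
                population=int(cov["population"][i]),
                area=area,
                prop_poverty=float(cov["prop_poverty"][i]),
                median_income=(
                    None if cov["income_missing"][i] else float(cov["median_income"][i])
                ),
                msa_median_income=float(cov["msa_median_income"][i]),
                race_props={g: float(cov["race"][i, j]) for j, g in enumerate(RACE_GROUPS)},
                prop_age65=float(cov["prop_age65"][i]),
                prop_female=float(cov["prop_female"][i]),
                prop_lt_hs=float(cov["prop_lt_hs"][i]),
                prop_uninsured=float(cov["prop_uninsured"][i]),
                prop_amb_disability=float(cov["prop_amb_disability"][i]),
                vehicles_owned=int(cov["vehicles"][i]),
                ddi=float(cov["ddi"][i]),
                ddi_infa=float(cov["ddi_infa"][i]),
                ddi_se=float(cov["ddi_se"][i]),
                rri=None if cov["rri_missing"][i] else float(cov["rri"][i]),
                msa_id=str(cov["msa_id"][i]),
                x=(c + 0.5) * side,
                y=(r + 0.5) * side,
            )
        )
    return tracts


def _build_blocks(config: GeneratorConfig, tracts: Sequence[Tract]) -> list[Block]:
    """Jittered sub-grid of block centroids; populations multinomial."""
    rng = _streams(config.seed)["geometry"]
    side = config.tract_side
    k = config.blocks_per_tract
    m = math.ceil(math.sqrt(k))
    sub = side / m
    pops = rng.multinomial(
        np.array([t.population for t in tracts]), np.full(k, 1.0 / k)
    )
    jitter = rng.uniform(0.1, 0.9, (len(tracts), k, 2))
    blocks: list[Block] = []
    for i, t in enumerate(tracts):
        x0, y0 = t.x - side / 2.0, t.y - side / 2.0
        for j in range(k):
            br, bc = divmod(j, m)
            blocks.append(
                Block(
                    block_id=f"{t.tract_id}B{j:03d}",
                    tract_id=t.tract_id,
                    x=x0 + (bc + jitter[i, j, 0]) * sub,
                    y=y0 + (br + jitter[i, j, 1]) * sub,
                    population=int(pops[i, j]),
                )
            )
    return blocks


def _intensity_per_tract(config: GeneratorConfig, tracts: Sequence[Tract]) -> np.ndarray:
    if not isinstance(config.pharmacy_intensity, Mapping):
        return np.full(len(tracts), float(config.pharmacy_intensity))
    ddi = np.array([t.ddi for t in tracts])
    cats = _quartile_categories(ddi)
    table = {**DEFAULT_PHARMACY_INTENSITY, **config.pharmacy_intensity}
    return np.array([table[c] for c in cats])


def _build_pharmacies(config: GeneratorConfig, tracts: Sequence[Tract]) -> list[Pharmacy]:
    rng = _streams(config.seed)["pharmacies"]
    side = config.tract_side
    lam = _intensity_per_tract(config, tracts)
    pharmacies: list[Pharmacy] = []
    for t, li in zip(tracts, lam):
        for _ in range(rng.poisson(li)):
            px = t.x - side / 2.0 + rng.uniform(0.0, side)
            py = t.y - side / 2.0 + rng.uniform(0.0, side)
            pharmacies.append(
                Pharmacy(pharmacy_id=f"P{len(pharmacies):06d}", x=px, y=py)
            )
    return pharmacies


# --- exhaustive-distance oracle (independent of the access/classify modules) ---

def _oracle_desert_labels(
    tracts: Sequence[Tract], blocks: Sequence[Block], pharmacies: Sequence[Pharmacy]
) -> dict[str, dict]:
    """Ground-truth desert labels by exhaustive pairwise distance scan.

    Re-states the classification rules in straight-line code on purpose: it
    is the independent check of the classifier pipeline, sharing none of it.
    """
    px = np.array([p.x for p in pharmacies if p.open_flag], dtype=float)
    py = np.array([p.y for p in pharmacies if p.open_flag], dtype=float)
    by_tract: dict[str, list[Block]] = {}
    for b in blocks:
        by_tract.setdefault(b.tract_id, []).append(b)

    out: dict[str, dict] = {}
    for t in tracts:
        if t.median_income is None or t.msa_median_income is None:
            out[t.tract_id] = {"excluded": "missing income data"}
            continue
        t_blocks = by_tract.get(t.tract_id, [])
        total = sum(b.population for b in t_blocks)
        if total <= 0:
            out[t.tract_id] = {"excluded": "zero population"}
            continue
        nearest = []
        for b in t_blocks:  # exhaustive scan, one block at a time
            if px.size == 0:
                nearest.append(math.inf)
            else:
                nearest.append(float(np.min(np.hypot(px - b.x, py - b.y))))

        density = t.population / t.area
        if density > 5000.0:
            radius = 1.0
        elif density < 1000.0:
            radius = 10.0
        else:
            radius = 5.0

        def beyond(r: float) -> float:
            far = sum(
                b.population for b, d in zip(t_blocks, nearest) if d >= r
            )
            return far / total

        low_access = beyond(radius) >= 1.0 / 3.0
        radius_used = radius
        if not low_access and t.vehicles_owned < 100 and beyond(0.5) >= 1.0 / 3.0:
            low_access = True
            radius_used = 0.5
        low_income = (
            t.prop_poverty >= 0.20 or t.median_income < 0.80 * t.msa_median_income
        )
        out[t.tract_id] = {
            "desert": bool(low_income and low_access),
            "desert_distance_only": bool(low_access),
            "low_income": bool(low_income),
            "low_access": bool(low_access),
            "radius_used": radius_used,
        }
    return out


def generate_geometry_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a cohort whose desert status emerges from the spatial layout."""
    cov = _generate_covariates(config)
    tracts = _build_tracts(config, cov)
    blocks = _build_blocks(config, tracts)
    pharmacies = _build_pharmacies(config, tracts)
    truth = {
        "mode": "geometry",
        "per_tract": _oracle_desert_labels(tracts, blocks, pharmacies),
    }
    return SyntheticCohort(tracts=tracts, blocks=blocks, pharmacies=pharmacies, truth=truth)


def _design_from_arrays(
    ddi: np.ndarray, rri: np.ndarray, race: np.ndarray, density: np.ndarray,
    lt_hs: np.ndarray, unins: np.ndarray, disab: np.ndarray,
) -> dict[str, np.ndarray]:
    """Encode label-mode covariate categories from raw arrays.

    ``rri`` uses NaN for missing; ``race`` is (n, 5) ordered as RACE_GROUPS.
    """
    def upper_quartile_flag(v: np.ndarray) -> np.ndarray:
        return (v >= np.quantile(v, 0.75, method="lower")).astype(int)

    best = race.argmax(axis=1)
    best_p = race[np.arange(len(race)), best]
    seg = np.where(best_p > 0.5, np.array(RACE_GROUPS)[best], "Integrated")
    urb = np.where(density > 5000.0, "urban", np.where(density < 1000.0, "rural", "suburban"))
    red = np.where(
        np.isnan(rri), "missing",
        np.where(rri < 0.7, "low", np.where(rri >= 1.3, "high", "neutral")),
    )
    return {
        "ddi": _quartile_categories(ddi),
        "redlining": red,
        "segregation": seg,
        "urbanicity": urb,
        "lt_hs_high": upper_quartile_flag(lt_hs).astype(str),
        "uninsured_high": upper_quartile_flag(unins).astype(str),
        "disability_high": upper_quartile_flag(disab).astype(str),
    }


def _label_design(tracts: Sequence[Tract]) -> dict[str, np.ndarray]:
    """Encoded label-mode covariates from tract records."""
    return _design_from_arrays(
        ddi=np.array([t.ddi for t in tracts]),
        rri=np.array([np.nan if t.rri is None else t.rri for t in tracts]),
        race=np.array([[t.race_props[g] for g in RACE_GROUPS] for t in tracts]),
        density=np.array([t.population / t.area for t in tracts]),
        lt_hs=np.array([t.prop_lt_hs for t in tracts]),
        unins=np.array([t.prop_uninsured for t in tracts]),
        disab=np.array([t.prop_amb_disability for t in tracts]),
    )


def _draw_labels(config: GeneratorConfig, design: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    beta = dict(config.true_log_odds)
    eta = np.full(n, beta.get("intercept", 0.0))
    for key, value in beta.items():
        if key == "intercept" or value == 0.0:
            continue
        covname, _, cat = key.partition(":")
        eta += value * (design[covname] == cat)
    rng = _streams(config.seed)["labels"]
    return rng.random(n) < expit(eta)


def generate_label_table(config: GeneratorConfig):
    """Label-mode analysis table without materializing tract/block records.

    Returns the same DataFrame as ``label_frame(generate_label_cohort(cfg))``
    (identical draws from the same RNG streams); intended for simulation
    studies with many large replicates where only the regression table is
    needed.
    """
    import pandas as pd

    if config.true_log_odds is None:
        raise ConfigError("true_log_odds must be supplied for label mode")
    cov = _generate_covariates(config)
    n = config.n_tracts
    area = config.tract_side**2
    rri = np.where(cov["rri_missing"], np.nan, cov["rri"])
    design = _design_from_arrays(
        ddi=cov["ddi"], rri=rri, race=cov["race"],
        density=cov["population"] / area,
        lt_hs=cov["prop_lt_hs"], unins=cov["prop_uninsured"],
        disab=cov["prop_amb_disability"],
    )
    labels = _draw_labels(config, design, n)
    return pd.DataFrame(
        {
            "tract_id": [_tract_id(i) for i in range(n)],
            "desert": labels.astype(int),
            "ddi_category": design["ddi"],
            "redlining_category": design["redlining"],
            "segregation": design["segregation"],
            "urbanicity": design["urbanicity"],
            "lt_hs_high": design["lt_hs_high"].astype(int),
            "uninsured_high": design["uninsured_high"].astype(int),
            "disability_high": design["disability_high"].astype(int),
        }
    )


def generate_label_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a cohort whose desert label is drawn from a known logistic model.

    ``truth`` stores the coefficient vector and the drawn labels; pharmacies
    are not generated (irrelevant to label-mode inference).
    """
    if config.true_log_odds is None:
        raise ConfigError("true_log_odds must be supplied for label mode")
    cov = _generate_covariates(config)
    tracts = _build_tracts(config, cov)
    blocks = _build_blocks(config, tracts)
    design = _label_design(tracts)
    labels = _draw_labels(config, design, len(tracts))

    truth = {
        "mode": "label",
        "true_log_odds": {k: float(v) for k, v in config.true_log_odds.items()},
        "desert": {t.tract_id: bool(y) for t, y in zip(tracts, labels)},
    }
    return SyntheticCohort(tracts=tracts, blocks=blocks, pharmacies=[], truth=truth)


def label_frame(cohort: SyntheticCohort):
    """Analysis table for a label-mode cohort: outcome + encoded covariates.

    Columns match :data:`desertscan.inference.DEFAULT_DESIGN`; binary flags
    are already 0/1 integers.
    """
    import pandas as pd

    if cohort.truth.get("mode") != "label":
        raise ConfigError("label_frame requires a label-mode cohort")
    design = _label_design(cohort.tracts)
    labels = cohort.truth["desert"]
    return pd.DataFrame(
        {
            "tract_id": [t.tract_id for t in cohort.tracts],
            "desert": [int(labels[t.tract_id]) for t in cohort.tracts],
            "ddi_category": design["ddi"],
            "redlining_category": design["redlining"],
            "segregation": design["segregation"],
            "urbanicity": design["urbanicity"],
            "lt_hs_high": design["lt_hs_high"].astype(int),
            "uninsured_high": design["uninsured_high"].astype(int),
            "disability_high": design["disability_high"].astype(int),
        }
    )


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
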