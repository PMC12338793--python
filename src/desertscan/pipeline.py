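"""End-to-end orchestration: generate -> classify -> describe -> associate.

Every run writes a manifest recording the configuration hash, the seed,
package versions and the tract counts at each filtering step (input cohort,
exclusions with reasons, analytic cohort, deserts), so the filtering
waterfall of any run is reproducible and auditable. Identical configuration
and seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_cohort
from .exceptions import ConfigError
from .inference import DEFAULT_DESIGN, analyze_associations, build_weights
from .io import read_cohort, write_cohort
from .report import analysis_frame, assessments_to_frame, export_map, table_one, table_one_frame
from .synth import GeneratorConfig, generate_geometry_cohort, generate_label_cohort, label_frame

logger = logging.getLogger(__name__)

DEFAULT_PIPELINE_CONFIG: dict = {
    "mode": "geometry",  # geometry | label | files
    "generator": {},
    "files": {},
    "classify": {"mode": "primary"},
    "associate": {"enabled": True, "scheme": "knn", "k": 8, "n_perm": 199, "seed": 7},
}


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_PIPELINE_CONFIG.items()}
    for key, value in (config or {}).items():
        if key not in cfg:
            raise ConfigError(f"unknown pipeline config key {key!r}")
        if isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run",
                 seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    cfg = _merged(config)
    if seed is not None:
        cfg["generator"]["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cfg["generator"].get("seed"),
        "versions": {
            "desertscan": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {},
    }

    mode = cfg["mode"]
    if mode == "files":
        paths = cfg["files"]
        for key in ("tracts", "blocks", "pharmacies"):
            if key not in paths:
                raise ConfigError(f"files mode requires files.{key}")
        from .io import read_blocks, read_pharmacies, read_tracts
        from .types import SyntheticCohort

        cohort = SyntheticCohort(
            tracts=read_tracts(paths["tracts"]),
            blocks=read_blocks(paths["blocks"]),
            pharmacies=read_pharmacies(paths["pharmacies"]),
        )
    elif mode in ("geometry", "label"):
        gen = GeneratorConfig(**cfg["generator"])
        cohort = (
            generate_geometry_cohort(gen) if mode == "geometry"
            else generate_label_cohort(gen)
        )
        write_cohort(cohort, out)
    else:
        raise ConfigError(f"unknown pipeline mode {mode!r}")
    manifest["counts"]["tracts_input"] = len(cohort.tracts)
    manifest["counts"]["blocks"] = len(cohort.blocks)
    manifest["counts"]["pharmacies"] = len(cohort.pharmacies)

    if mode == "label":
        frame = label_frame(cohort)
        frame.to_csv(out / "assessments.csv", index=False)
        manifest["counts"]["tracts_analytic"] = len(frame)
        manifest["counts"]["deserts"] = int(frame["desert"].sum())
        coords = np.array([[t.x, t.y] for t in cohort.tracts])
    else:
        classification = classify_cohort(
            cohort.tracts, cohort.blocks, cohort.pharmacies,
            mode=cfg["classify"]["mode"],
        )
        adf = assessments_to_frame(classification.assessments)
        adf.to_csv(out / "assessments.csv", index=False)
        manifest["counts"]["tracts_excluded"] = len(classification.excluded)
        manifest["counts"]["excluded_reasons"] = dict(
            pd.Series(list(classification.excluded.values())).value_counts()
        ) if classification.excluded else {}
        manifest["counts"]["tracts_analytic"] = len(classification.assessments)
        manifest["counts"]["deserts"] = int(adf["desert"].sum())

        included = set(adf["tract_id"])
        kept = [t for t in cohort.tracts if t.tract_id in included]
        frame = analysis_frame(kept, classification.assessments)
        frame = frame.rename(columns={})
        rows = table_one(
            frame.drop(columns=["tract_id", "x", "y"]), group_col="desert"
        ) if 0 < frame["desert"].sum() < len(frame) else []
        table_one_frame(rows).to_csv(out / "table_one.csv", index=False)
        export_map(classification.assessments, cohort.tracts,
                   out / "map.geojson", out / "map.png")
        coords = frame[["x", "y"]].to_numpy()

    assoc_cfg = cfg["associate"]
    if assoc_cfg.get("enabled", True):
        weights = build_weights(coords=coords, scheme=assoc_cfg["scheme"],
                                k=assoc_cfg["k"])
        result = analyze_associations(
            frame, DEFAULT_DESIGN, weights=weights,
            n_perm=assoc_cfg["n_perm"], seed=assoc_cfg["seed"],
        )
        with open(out / "association.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        manifest["counts"]["model_converged"] = result.convergence

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
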