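"""End-to-end orchestration: extract features, fit, evaluate, report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import collagen_disorder as cd
from . import til_architecture as ta
from .io_core import TileBundle, read_nuclei_csv, read_survival_csv, read_tile_bundle
from .risk_model import (CoxElasticNetRisk, c_index, compare_groups, hazard_ratio,
                         km_logrank, stratify)

logger = logging.getLogger(__name__)

ALL_FEATURE_NAMES: tuple[str, ...] = (
    ta.TIL_FEATURE_NAMES + cd.ENTROPY_FEATURE_NAMES
)


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one declarative object.

    Unknown keys in a config file are rejected; the resolved config is
    written alongside every run's outputs.
    """

    window_sizes: tuple[int, ...] = cd.DEFAULT_WINDOW_SIZES
    bins: int = 36
    sigma: float = 2.0
    response_quantile: float = 0.75
    n_orientations: int = 12
    grid_step: int = 4
    pair_radius: float = 50.0
    min_fibers: int = 10
    front_band_um: float = 100.0
    link_radius_um: float = 30.0
    epsilon_um: float = 20.0
    microns_per_pixel: float = 0.25
    alpha_ratio: float = 0.5
    cv_folds: int = 5
    threshold_mode: str = "train_mean"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window_sizes" in data:
            data["window_sizes"] = tuple(data["window_sizes"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["window_sizes"] = list(data["window_sizes"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# feature extraction


def extract_tile_features(tile: TileBundle, nuclei, config: RunConfig
                          ) -> tuple[list, dict[str, float]]:
    """(entropy maps at every window size, TIL feature dict) for one tile."""
    maps = cd.tile_entropy_maps(
        tile, window_sizes=config.window_sizes, sigma=config.sigma,
        response_quantile=config.response_quantile,
        n_orientations=config.n_orientations, grid_step=config.grid_step,
        bins=config.bins, pair_radius=config.pair_radius,
        min_fibers=config.min_fibers)
    til = ta.tile_til_features(tile, nuclei, front_band_um=config.front_band_um,
                               link_radius_um=config.link_radius_um,
                               epsilon_um=config.epsilon_um)
    return maps, til


def _discover_tiles(tiles_dir: Path, masks_dir: Path, nuclei_dir: Path
                    ) -> dict[str, list[tuple[str, Path, Path, Path, Path]]]:
    """Group tile stems by patient (stem = <patient>_<tileindex>)."""
    by_patient: dict[str, list] = {}
    for img in sorted(tiles_dir.glob("*.png")) + sorted(tiles_dir.glob("*.tif*")):
        stem = img.stem
        pid = stem.rsplit("_", 1)[0]
        epi = masks_dir / f"{stem}_epi{img.suffix}"
        stro = masks_dir / f"{stem}_str{img.suffix}"
        nuc = nuclei_dir / f"{stem}.csv"
        if not (epi.exists() and stro.exists() and nuc.exists()):
            logger.warning("tile %s missing masks or nuclei; skipped", stem)
            continue
        by_patient.setdefault(pid, []).append((stem, img, epi, stro, nuc))
    return by_patient


def run_extract(tiles_dir: str | Path, nuclei_dir: str | Path,
                config: RunConfig, masks_dir: str | Path | None = None
                ) -> pd.DataFrame:
    """Per-patient feature table (14 features + invasive-front TIL density).

    Expects tiles/<patient>_<t>.png with masks/<stem>_{epi,str}.png and
    nuclei/<stem>.csv; a patient with zero valid tiles is excluded with a
    logged reason.
    """
    tiles_dir = Path(tiles_dir)
    nuclei_dir = Path(nuclei_dir)
    masks_dir = Path(masks_dir) if masks_dir else tiles_dir.parent / "masks"
    rows = {}
    for pid, tiles in sorted(_discover_tiles(tiles_dir, masks_dir, nuclei_dir).items()):
        maps, til_rows = [], []
        for stem, img, epi, stro, nuc in tiles:
            tile = read_tile_bundle(img, epi, stro, config.microns_per_pixel,
                                    tile_id=stem, patient_id=pid)
            nuclei = read_nuclei_csv(nuc)
            tile_maps, til = extract_tile_features(tile, nuclei, config)
            maps.extend(tile_maps)
            til_rows.append(til)
        if not til_rows:
            logger.warning("patient %s has no valid tiles; excluded", pid)
            continue
        rows[pid] = {**cd.aggregate_entropy_features(maps),
                     **ta.patient_til_features(til_rows)}
    features = pd.DataFrame.from_dict(rows, orient="index")
    ordered = [c for c in ALL_FEATURE_NAMES if c in features.columns]
    extra = [c for c in features.columns if c not in ordered]
    return features[ordered + extra]


# ---------------------------------------------------------------------------
# modeling


def _align(features: pd.DataFrame, survival: pd.DataFrame
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    surv = survival.set_index("patient_id") if "patient_id" in survival.columns else survival
    shared = [p for p in features.index if p in surv.index]
    if not shared:
        raise ValueError("no patients shared between features and survival")
    return features.loc[shared], surv.loc[shared]


def evaluate_cohort(model: CoxElasticNetRisk, features: pd.DataFrame,
                    survival: pd.DataFrame) -> dict:
    """Stratify one cohort and compute its survival statistics and the
    high/low-risk comparisons of TIL density and mean collagen entropy."""
    X, surv = _align(features, survival)
    model_X = X[model.feature_names_]
    scores = model.predict(model_X)
    cohort = stratify(scores, model, survival=surv, patient_ids=list(X.index))
    report: dict = {
        "n": int(len(cohort)),
        "n_events": int(cohort["event"].sum()),
        "n_high": int((cohort["group"] == "high").sum()),
        "c_index": c_index(scores, surv),
    }
    if cohort["group"].nunique() == 2:
        km = km_logrank(cohort)
        report["logrank_p"] = km["logrank_p"]
        report.update({k: v for k, v in hazard_ratio(cohort).items()
                       if k in ("hr", "ci_low", "ci_high", "wald_p", "flag")})
        for col in ("til_density_front", "cfods_mean_w200"):
            if col in X.columns:
                vals = X[col].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                report[f"compare_{col}"] = compare_groups(
                    vals[ok], cohort["group"].to_numpy()[ok])
    else:
        report["degenerate_stratification"] = True
    return report, cohort


def run_full(train_features: pd.DataFrame, train_survival: pd.DataFrame,
             validations: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
             config: RunConfig) -> dict:
    """Fit on the training cohort and evaluate every cohort.

    Returns {"model": fitted model, "cohorts": per-cohort stats,
    "stratification": per-cohort frames}.
    """
    X, surv = _align(train_features, train_survival)
    model_cols = [c for c in ALL_FEATURE_NAMES if c in X.columns]
    model = CoxElasticNetRisk(alpha_ratio=config.alpha_ratio,
                              cv_folds=config.cv_folds,
                              random_state=config.seed,
                              threshold_mode=config.threshold_mode)
    model.fit(X[model_cols], surv)
    report: dict = {"model": model, "cohorts": {}, "stratification": {}}
    cohorts = {"train": (train_features, train_survival), **dict(validations)}
    for name, (feats, sv) in cohorts.items():
        stats, cohort = evaluate_cohort(model, feats, sv)
        report["cohorts"][name] = stats
        report["stratification"][name] = cohort
    return report


def run_full_from_dir(cohort_dir: str | Path, config: RunConfig,
                      validation_dirs: Mapping[str, str | Path] | None = None) -> dict:
    """Extract features from a cohort directory, fit, and evaluate."""
    cohort_dir = Path(cohort_dir)
    feats = run_extract(cohort_dir / "tiles", cohort_dir / "nuclei", config,
                        masks_dir=cohort_dir / "masks")
    surv = pd.read_csv(cohort_dir / "survival.csv")
    validations = {}
    for name, vdir in (validation_dirs or {}).items():
        vdir = Path(vdir)
        vfeats = run_extract(vdir / "tiles", vdir / "nuclei", config,
                             masks_dir=vdir / "masks")
        validations[name] = (vfeats, pd.read_csv(vdir / "survival.csv"))
    return run_full(feats, surv, validations, config)


def report_to_json(report: dict, path: str | Path) -> None:
    """Serialize a run_full report (model as nested JSON, frames dropped)."""
    out = {"cohorts": report["cohorts"],
           "model": json.loads(report["model"].to_json())}
    Path(path).write_text(json.dumps(out, indent=2, default=float))
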