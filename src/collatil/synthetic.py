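"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the pipeline's real inputs at desk scale: oriented
fiber textures inside stromal masks (axial von Mises orientations with
controllable concentration), clustered compartment-labeled nuclei point
processes with controllable TIL fractions, survival times from a known Cox
model on patient-level covariates, and boundary-spanning MAF / expression
fixtures.  Every generator is deterministic given the spec's master seed
and emits the truth needed to score downstream operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import line_aa

from .io_core import (ExpressionMatrix, GeneSet, NucleusRecord, TileBundle,
                      write_nuclei_csv)

__all__ = [
    "SyntheticCohortSpec",
    "patient_latents",
    "gen_fiber_tile",
    "gen_nuclei",
    "gen_survival",
    "gen_feature_cohort",
    "gen_cohort_dir",
    "gen_maf_fixture",
    "gen_expression_fixture",
    "sample_axial_von_mises",
]


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Tiles default to 600x600 px at 0.25 um/px (>= the largest entropy
    window) so a cohort is generated in seconds; per-patient collagen
    concentration kappa and stromal TIL fraction are the latent axes that
    drive both the rendered tiles and the survival model.
    """

    n_patients: int = 20
    tiles_per_patient: int = 2
    tile_size: int = 600
    microns_per_pixel: float = 0.25
    # fibers
    kappa_range: tuple[float, float] = (0.0, 16.0)     # per-patient concentration
    fiber_density_per_mm2: float = 15000.0             # segments per mm^2 stroma
    fiber_length_px: tuple[float, float] = (20.0, 40.0)
    # nuclei (Thomas cluster process per compartment)
    parent_rate_per_mm2: float = 2500.0
    mean_offspring: float = 7.0
    offspring_spread_px: float = 12.0
    til_fraction_epithelium: float = 0.15
    til_fraction_stroma_range: tuple[float, float] = (0.05, 0.65)
    # survival: hazard rises with collagen order (kappa), falls with TILs
    beta_kappa: float = 0.8
    beta_til: float = -0.8
    lambda0: float = 0.02                               # per month
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa_range[0] < 0:
            raise ValueError("kappa must be >= 0")
        if not 0 <= self.til_fraction_epithelium <= 1:
            raise ValueError("TIL fractions must lie in [0, 1]")
        for rate in (self.fiber_density_per_mm2, self.parent_rate_per_mm2,
                     self.mean_offspring, self.lambda0):
            if rate < 0:
                raise ValueError("rates must be >= 0")


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def sample_axial_von_mises(rng: np.random.Generator, mu_deg: float,
                           kappa: float, size: int) -> np.ndarray:
    """Orientations in degrees on [0, 180) ~ axial von Mises(mu, kappa).

    Sampled as von Mises on the doubled angle then halved; kappa = 0 is the
    uniform axial distribution.
    """
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size)
    doubled = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size)
    return np.rad2deg(doubled / 2.0) % 180.0


def patient_latents(spec: SyntheticCohortSpec, patient_index: int) -> dict[str, float]:
    """Per-patient latent parameters shared by tiles, nuclei and survival."""
    rng = _rng(spec.seed, 1000 + patient_index)
    lo_k, hi_k = spec.kappa_range
    lo_t, hi_t = spec.til_fraction_stroma_range
    return {
        "mu_deg": float(rng.uniform(0.0, 180.0)),
        "kappa": float(rng.uniform(lo_k, hi_k)),
        "til_fraction_stroma": float(rng.uniform(lo_t, hi_t)),
    }


# ---------------------------------------------------------------------------
# tiles


def _epithelium_blob(size: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth lobed blob covering roughly a quarter of the tile."""
    cy = size * rng.uniform(0.3, 0.7)
    cx = size * rng.uniform(0.3, 0.7)
    r0 = size * rng.uniform(0.22, 0.3)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    ang = np.arctan2(yy - cy, xx - cx)
    radius = r0 * (1.0 + 0.25 * np.sin(3 * ang + phase))
    return np.hypot(yy - cy, xx - cx) < radius


def gen_fiber_tile(spec: SyntheticCohortSpec, patient_index: int,
                   tile_index: int) -> dict:
    """Render one tile: epithelium blob, stromal fiber texture, truth angles.

    Fibers are anti-aliased bright line segments on a dark noisy background,
    centered at stroma pixels, with orientations drawn from the patient's
    axial von Mises distribution.
    """
    latents = patient_latents(spec, patient_index)
    rng = _rng(spec.seed, 1000 + patient_index, tile_index)
    size = spec.tile_size
    epi = _epithelium_blob(size, rng)
    stroma = ~epi

    image = rng.normal(60.0, 4.0, (size, size))
    image[epi] += 60.0

    mm2 = stroma.sum() * (spec.microns_per_pixel * 1e-3) ** 2
    n_fibers = int(rng.poisson(spec.fiber_density_per_mm2 * mm2))
    sy, sx = np.nonzero(stroma)
    centers = rng.integers(0, len(sy), n_fibers) if len(sy) else np.empty(0, int)
    thetas = sample_axial_von_mises(rng, latents["mu_deg"], latents["kappa"], n_fibers)
    lengths = rng.uniform(*spec.fiber_length_px, n_fibers)
    for k in range(n_fibers):
        cy, cx = sy[centers[k]], sx[centers[k]]
        t = np.deg2rad(thetas[k])
        dx, dy = np.cos(t) * lengths[k] / 2, -np.sin(t) * lengths[k] / 2
        r0, c0 = int(round(cy - dy)), int(round(cx - dx))
        r1, c1 = int(round(cy + dy)), int(round(cx + dx))
        rr, cc, val = line_aa(np.clip(r0, 0, size - 1), np.clip(c0, 0, size - 1),
                              np.clip(r1, 0, size - 1), np.clip(c1, 0, size - 1))
        image[rr, cc] += 90.0 * val
    image = np.clip(image, 0, 255).astype(np.uint8)
    return {
        "image": image,
        "epithelium_mask": epi,
        "stroma_mask": stroma,
        "true_orientations": thetas,
        "latents": latents,
    }


def gen_nuclei(spec: SyntheticCohortSpec, epithelium_mask: np.ndarray,
               stroma_mask: np.ndarray, patient_index: int, tile_index: int
               ) -> tuple[list[NucleusRecord], dict]:
    """Clustered nuclei per compartment (Thomas process) with TIL labels.

    Parents are Poisson over the compartment area; offspring are Gaussian
    around each parent, thinned to the compartment mask.  The returned
    truth maps each nucleus to (compartment, parent id).
    """
    latents = patient_latents(spec, patient_index)
    rng = _rng(spec.seed, 1000 + patient_index, tile_index, 7)
    px_to_mm2 = (spec.microns_per_pixel * 1e-3) ** 2
    nuclei: list[NucleusRecord] = []
    truth: list[tuple[str, int]] = []
    til_frac = {"epithelium": spec.til_fraction_epithelium,
                "stroma": latents["til_fraction_stroma"]}
    parent_id = 0
    for comp, mask in (("epithelium", np.asarray(epithelium_mask, bool)),
                       ("stroma", np.asarray(stroma_mask, bool))):
        my, mx = np.nonzero(mask)
        if len(my) == 0:
            continue
        n_parents = rng.poisson(spec.parent_rate_per_mm2 * mask.sum() * px_to_mm2)
        for _ in range(n_parents):
            j = rng.integers(0, len(my))
            py, px = float(my[j]), float(mx[j])
            for _ in range(rng.poisson(spec.mean_offspring)):
                x = px + rng.normal(0, spec.offspring_spread_px)
                y = py + rng.normal(0, spec.offspring_spread_px)
                r, c = int(y), int(x)
                if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
                    continue
                if not mask[r, c]:
                    continue
                nuclei.append(NucleusRecord(x=x, y=y,
                                            is_til=bool(rng.random() < til_frac[comp])))
                truth.append((comp, parent_id))
            parent_id += 1
    return nuclei, {"assignments": truth, "til_fractions": til_frac}


# ---------------------------------------------------------------------------
# survival


def gen_survival(features: pd.DataFrame, true_beta: Mapping[str, float],
                 lambda0: float, censor_rate: float, seed: int) -> pd.DataFrame:
    """Event times from a Cox-exponential model on z-scored features.

    T ~ Exponential(lambda0 * exp(sum beta_f z_f)); censoring is uniform on
    [0, tau] with tau chosen (bisection on the sampled times) so that the
    expected censored fraction is about ``censor_rate``.
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = _rng(seed, 99)
    z = (features - features.mean()) / features.std(ddof=0).replace(0, 1.0)
    risk = np.zeros(len(features))
    for f, b in true_beta.items():
        risk += b * z[f].to_numpy(dtype=float)
    rate = lambda0 * np.exp(risk)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate == 0:
        time, event = t_event, np.ones(len(t_event), dtype=bool)
    else:
        # P(event) under C ~ U(0, tau) is 1 - E[min(T, tau)] / tau, which
        # increases with tau; bisect for the target event fraction
        def event_frac(tau: float) -> float:
            return 1.0 - np.minimum(t_event, tau).mean() / tau
        target = 1.0 - censor_rate
        lo, hi = 1e-6, float(t_event.max()) * 50
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if event_frac(mid) > target:
                hi = mid
            else:
                lo = mid
        c = rng.uniform(0, 0.5 * (lo + hi), len(t_event))
        event = t_event <= c
        time = np.minimum(t_event, c)
    return pd.DataFrame({"patient_id": list(features.index),
                         "time": time, "event": event.astype(int)})


# ---------------------------------------------------------------------------
# feature-level cohort (model-scale tests without rendering images)


def gen_feature_cohort(spec: SyntheticCohortSpec, seed: int | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A cohort of 14-feature vectors + TIL density + survival, no images.

    Feature values are monotone functions of the per-patient latents (high
    kappa -> low entropy features; high stromal TIL fraction -> high TIL
    density, low non-TIL/TIL ratio) plus noise; survival risk rises with
    kappa and falls with the TIL fraction, matching the latent axes the
    rendered tiles share.  Returns (features, survival, latents).
    """
    spec = SyntheticCohortSpec(**{**asdict(spec), "seed": spec.seed if seed is None else seed})
    rng = _rng(spec.seed, 555)
    rows, lat_rows, ids = [], [], []
    for p in range(spec.n_patients):
        lat = patient_latents(spec, p)
        kappa, tf = lat["kappa"], lat["til_fraction_stroma"]
        noise = rng.normal(0, 0.15, 8)
        base = 9.0 - 1.3 * np.log1p(kappa)
        spread = abs(rng.normal(0.3, 0.1))
        feats = {
            "til_ratio_nontil_surr_til_epi": max(0.2, (1 - tf) / max(tf, 0.05)
                                                 + rng.normal(0, 0.5)),
            "til_nclusters_til_near_nontil_epi": max(0.0, 2 + 4 * tf + rng.normal(0, 0.5)),
            "til_presence_pct_nontil_str": float(np.clip(0.5 + rng.normal(0, 0.2), 0, 1)),
            "til_intersect_area_front": abs(rng.normal(500, 200)),
            "til_min_area_stril_front": abs(rng.normal(300, 100)),
            "til_range_area_epintl_front": abs(rng.normal(800, 300)),
            "cfods_mean_w200": base + noise[0],
            "cfods_min_w200": base - spread + noise[1],
            "cfods_max_w250": base + spread + noise[2],
            "cfods_min_w350": base - spread + noise[3],
            "cfods_min_w400": base - spread + noise[4],
            "cfods_min_w450": base - spread + noise[5],
            "cfods_max_w550": base + spread + noise[6],
            "cfods_max_w600": base + spread + noise[7],
            "til_density_front": float(np.clip(tf + rng.normal(0, 0.04), 0, 1)),
        }
        rows.append(feats)
        lat_rows.append(lat)
        ids.append(f"P{p:03d}")
    features = pd.DataFrame(rows, index=ids)
    latents = pd.DataFrame(lat_rows, index=ids)
    survival = gen_survival(
        latents.assign(log_kappa=np.log1p(latents["kappa"]))
               [["log_kappa", "til_fraction_stroma"]],
        {"log_kappa": spec.beta_kappa, "til_fraction_stroma": spec.beta_til},
        spec.lambda0, spec.censor_rate, spec.seed)
    survival.index = ids
    return features, survival, latents


# ---------------------------------------------------------------------------
# directory cohort


def gen_cohort_dir(spec: SyntheticCohortSpec, out_dir: str | Path) -> Path:
    """Write the full directory layout the CLI consumes.

    tiles/<patient>_<t>.png, masks/<patient>_<t>_{epi,str}.png,
    nuclei/<patient>_<t>.csv, survival.csv, truth/.
    """
    out = Path(out_dir)
    for sub in ("tiles", "masks", "nuclei", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    truth: dict[str, dict] = {"patients": {}}
    for p in range(spec.n_patients):
        pid = f"P{p:03d}"
        truth["patients"][pid] = patient_latents(spec, p)
        for t in range(spec.tiles_per_patient):
            tile = gen_fiber_tile(spec, p, t)
            stem = f"{pid}_{t}"
            iio.imwrite(out / "tiles" / f"{stem}.png", tile["image"])
            iio.imwrite(out / "masks" / f"{stem}_epi.png",
                        tile["epithelium_mask"].astype(np.uint8) * 255)
            iio.imwrite(out / "masks" / f"{stem}_str.png",
                        tile["stroma_mask"].astype(np.uint8) * 255)
            nuclei, _ = gen_nuclei(spec, tile["epithelium_mask"],
                                   tile["stroma_mask"], p, t)
            write_nuclei_csv(out / "nuclei" / f"{stem}.csv", nuclei)
    latents = pd.DataFrame([patient_latents(spec, p) for p in range(spec.n_patients)],
                           index=[f"P{p:03d}" for p in range(spec.n_patients)])
    survival = gen_survival(
        latents.assign(log_kappa=np.log1p(latents["kappa"]))
               [["log_kappa", "til_fraction_stroma"]],
        {"log_kappa": spec.beta_kappa, "til_fraction_stroma": spec.beta_til},
        spec.lambda0, spec.censor_rate, spec.seed)
    survival.to_csv(out / "survival.csv", index=False)
    (out / "truth" / "latents.json").write_text(json.dumps(truth, indent=2))
    return out


# ---------------------------------------------------------------------------
# genomics fixtures


def gen_maf_fixture(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """A MAF table spanning every depth/VAF filter boundary plus one planted
    hypermutated sample; truth carries per-row retention and the plant.

    Boundary rows probe depths 29/30/31, tumor VAF 0.09/0.10/0.11 and
    normal VAF 0.04/0.05/0.06 under the strict-inequality rules, and one
    locus carries two annotations (Silent + Missense) to exercise the
    any-non-synonymous classification.
    """
    rng = _rng(seed, 1234)
    rows: list[dict] = []
    retained: list[bool] = []
    position = [1]

    def add(sample, gene, vc, t_depth, t_alt, n_depth, n_alt, keep, pos=None):
        if pos is None:
            pos = position[0]
            position[0] += 1
        rows.append({"Hugo_Symbol": gene, "Variant_Classification": vc,
                     "Tumor_Sample_Barcode": sample, "Chromosome": "1",
                     "Start_Position": pos, "t_depth": t_depth,
                     "t_alt_count": t_alt, "n_depth": n_depth, "n_alt_count": n_alt})
        retained.append(keep)

    # depth boundaries (other fields safely passing)
    add("S1", "TP53", "Missense_Mutation", 29, 10, 60, 0, False)
    add("S1", "TP53", "Missense_Mutation", 30, 10, 60, 0, True)
    add("S1", "TP53", "Missense_Mutation", 31, 10, 60, 0, True)
    add("S2", "KRAS", "Nonsense_Mutation", 60, 20, 29, 0, False)
    add("S2", "KRAS", "Nonsense_Mutation", 60, 20, 30, 0, True)
    # tumor VAF boundaries at depth 100
    add("S3", "PIK3CA", "Missense_Mutation", 100, 9, 60, 0, False)   # 0.09
    add("S3", "PIK3CA", "Missense_Mutation", 100, 10, 60, 0, True)   # 0.10
    add("S3", "PIK3CA", "Missense_Mutation", 100, 11, 60, 0, True)   # 0.11
    # normal VAF boundaries at depth 100
    add("S4", "PTEN", "Silent", 80, 20, 100, 4, True)                # 0.04
    add("S4", "PTEN", "Silent", 80, 20, 100, 5, True)                # 0.05
    add("S4", "PTEN", "Silent", 80, 20, 100, 6, False)               # 0.06
    # zero tumor depth -> VAF 0 -> filtered
    add("S5", "EGFR", "Missense_Mutation", 0, 0, 60, 0, False)
    # one locus, two annotations (collapses to a single Mut record)
    shared = position[0]
    add("S6", "PIK3CA", "Silent", 90, 30, 90, 0, True, pos=shared)
    rows.append({"Hugo_Symbol": "PIK3CA", "Variant_Classification": "Missense_Mutation",
                 "Tumor_Sample_Barcode": "S6", "Chromosome": "1",
                 "Start_Position": shared, "t_depth": 90, "t_alt_count": 30,
                 "n_depth": 90, "n_alt_count": 0})
    position[0] += 1
    # background cohort for the hypermutation rule; counts are spread out so
    # the cohort IQR is wide enough that only the plant exceeds Q3 + 1.5*IQR
    for s in range(1, 9):
        for _ in range(4 + 2 * s + int(rng.integers(0, 3))):
            add(f"S{s}", f"G{int(rng.integers(0, 200))}", "Missense_Mutation",
                int(rng.integers(40, 120)), 30, int(rng.integers(40, 120)), 0, True)
    hyper = "S_HYPER"
    for _ in range(120):
        add(hyper, f"G{int(rng.integers(0, 200))}", "Missense_Mutation",
            int(rng.integers(40, 120)), 30, int(rng.integers(40, 120)), 0, True)
    df = pd.DataFrame(rows)
    truth = {"row_retained": retained, "hypermutated_sample": hyper,
             "multi_annotation_key": ("S6", "PIK3CA", shared)}
    return df, truth


def gen_expression_fixture(n_genes: int = 400, n_samples: int = 30,
                           set_size: int = 20, shift_sd: float = 2.0,
                           seed: int = 0) -> tuple[ExpressionMatrix, GeneSet]:
    """Standard-normal expression with one gene set up-shifted by shift_sd
    (in SD units) in every sample; returns the matrix and the planted set."""
    rng = _rng(seed, 4321)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    values = rng.normal(0.0, 1.0, (n_genes, n_samples))
    planted = sorted(rng.choice(n_genes, size=set_size, replace=False))
    values[planted, :] += shift_sd
    return (ExpressionMatrix(genes=genes, samples=samples, values=values),
            GeneSet(name="planted", genes=frozenset(genes[i] for i in planted)))
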