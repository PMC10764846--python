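"""Domain types, coordinate conventions, and readers/writers.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` = column (rightward), ``y`` = row (downward).  All distances are
computed in pixels; thresholds stated in microns are converted through
``microns_per_pixel`` (e.g. 20 um -> 80 px at 0.25 um/px).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("epithelium", "stroma", "neither")

__all__ = [
    "TileBundle",
    "NucleusRecord",
    "SurvivalRecord",
    "MafRecord",
    "GeneSet",
    "ExpressionMatrix",
    "read_tile_bundle",
    "read_nuclei_csv",
    "write_nuclei_csv",
    "read_maf",
    "read_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_survival_csv",
    "write_survival_csv",
    "binarize_mask",
]


@dataclass
class TileBundle:
    """One tile's grayscale image plus epithelium/stroma masks.

    Masks share the image dimensions and are pixelwise disjoint; the tile
    is the unit of feature extraction.
    """

    tile_id: str
    patient_id: str
    image: np.ndarray
    epithelium_mask: np.ndarray
    stroma_mask: np.ndarray
    microns_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D grayscale, got shape {self.image.shape}")
        self.epithelium_mask = np.asarray(self.epithelium_mask, dtype=bool)
        self.stroma_mask = np.asarray(self.stroma_mask, dtype=bool)
        for name, mask in (("epithelium_mask", self.epithelium_mask),
                           ("stroma_mask", self.stroma_mask)):
            if mask.shape != self.image.shape:
                raise ValueError(
                    f"{name} shape {mask.shape} does not match image shape {self.image.shape}"
                )
        overlap = int(np.count_nonzero(self.epithelium_mask & self.stroma_mask))
        if overlap:
            # Real segmentation exports can disagree at boundaries; epithelium wins.
            logger.warning("tile %s: %d overlapping epithelium/stroma pixels assigned "
                           "to epithelium", self.tile_id, overlap)
            self.stroma_mask = self.stroma_mask & ~self.epithelium_mask
        if not self.microns_per_pixel > 0:
            raise ValueError(f"microns_per_pixel must be > 0, got {self.microns_per_pixel}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def um_to_px(self, microns: float) -> float:
        return microns / self.microns_per_pixel


@dataclass
class NucleusRecord:
    """A nucleus centroid with TIL flag and (post-assignment) compartment label."""

    x: float
    y: float
    is_til: bool
    compartment: str = "neither"
    in_invasive_front: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time {self.time} for {self.patient_id}")


@dataclass
class MafRecord:
    """One unique somatic mutation (possibly carrying several annotations)."""

    sample_id: str
    gene: str
    variant_classifications: list[str]
    t_depth: int
    n_depth: int
    t_vaf: float
    n_vaf: float

    def __post_init__(self) -> None:
        if not self.variant_classifications:
            raise ValueError("a mutation record needs >=1 variant classification")
        if self.t_depth < 0 or self.n_depth < 0:
            raise ValueError("read depths must be >= 0")
        for name, v in (("t_vaf", self.t_vaf), ("n_vaf", self.n_vaf)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with unique gene symbols and no missing values."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.genes)} genes, {len(self.samples)} samples)"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def column(self, sample_id: str) -> pd.Series:
        return self.to_frame()[sample_id]


# ---------------------------------------------------------------------------
# raster I/O


def binarize_mask(raster: np.ndarray) -> np.ndarray:
    """Any nonzero pixel -> True.  Idempotent."""
    return np.asarray(raster) != 0


def _read_gray(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].astype(float).mean(axis=-1)
    return arr


def read_tile_bundle(
    image_path: str | Path,
    epi_mask_path: str | Path,
    stroma_mask_path: str | Path,
    microns_per_pixel: float = 0.25,
    tile_id: str | None = None,
    patient_id: str = "",
) -> TileBundle:
    """Load an image and its epithelium/stroma masks into a TileBundle.

    Masks are binarized (nonzero -> True); epithelium/stroma overlap is
    resolved in favor of epithelium with a logged warning.
    """
    image = _read_gray(image_path)
    epi = binarize_mask(_read_gray(epi_mask_path))
    stroma = binarize_mask(_read_gray(stroma_mask_path))
    if tile_id is None:
        tile_id = Path(image_path).stem
    bundle = TileBundle(tile_id=tile_id, patient_id=patient_id, image=image,
                        epithelium_mask=epi, stroma_mask=stroma,
                        microns_per_pixel=microns_per_pixel)
    logger.info("tile %s: %dx%d px, %d epithelium / %d stroma pixels",
                tile_id, *bundle.shape,
                int(bundle.epithelium_mask.sum()), int(bundle.stroma_mask.sum()))
    return bundle


# ---------------------------------------------------------------------------
# tabular I/O


def read_nuclei_csv(path: str | Path) -> list[NucleusRecord]:
    """Read a nuclei table (columns x, y, is_til) in file order."""
    df = pd.read_csv(path)
    missing = {"x", "y", "is_til"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing nuclei columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(NucleusRecord(x=float(row.x), y=float(row.y),
                                         is_til=bool(int(row.is_til))))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed nuclei row {i}: {exc}") from exc
    logger.info("%s: read %d nuclei", path, len(records))
    return records


def write_nuclei_csv(path: str | Path, nuclei: Sequence[NucleusRecord]) -> None:
    pd.DataFrame({
        "x": [n.x for n in nuclei],
        "y": [n.y for n in nuclei],
        "is_til": [int(n.is_til) for n in nuclei],
    }).to_csv(path, index=False)


_MAF_REQUIRED = ["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode",
                 "t_depth", "t_alt_count", "n_depth", "n_alt_count"]


def _vaf(alt: float, depth: float) -> float:
    return 0.0 if depth == 0 else float(alt) / float(depth)


def read_maf(path: str | Path) -> list[MafRecord]:
    """Read an MC3-style MAF; rows sharing sample+gene+position collapse into
    one record carrying all annotations.

    VAFs are computed as alt reads / depth, 0 when depth is 0.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing MAF columns {missing}")
    key_cols = ["Tumor_Sample_Barcode", "Hugo_Symbol"]
    for c in ("Chromosome", "Start_Position"):
        if c in df.columns:
            key_cols.append(c)
    records = []
    for _, grp in df.groupby(key_cols, sort=False):
        first = grp.iloc[0]
        records.append(MafRecord(
            sample_id=str(first["Tumor_Sample_Barcode"]),
            gene=str(first["Hugo_Symbol"]),
            variant_classifications=[str(v) for v in grp["Variant_Classification"]],
            t_depth=int(first["t_depth"]),
            n_depth=int(first["n_depth"]),
            t_vaf=_vaf(first["t_alt_count"], first["t_depth"]),
            n_vaf=_vaf(first["n_alt_count"], first["n_depth"]),
        ))
    logger.info("%s: read %d rows -> %d unique mutation records", path, len(df), len(records))
    return records


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line {lineno} has no genes")
        sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    logger.info("%s: read %d gene sets", path, len(sets))
    return sets


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes-as-rows TSV; duplicate genes or missing values are rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate gene rows {dups[:5]}")
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    logger.info("%s: read expression matrix %d genes x %d samples", path, *df.shape)
    return ExpressionMatrix(genes=[str(g) for g in df.index],
                            samples=[str(s) for s in df.columns],
                            values=df.to_numpy(dtype=float))


def write_expression_tsv(path: str | Path, expr: ExpressionMatrix) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_survival_csv(path: str | Path) -> list[SurvivalRecord]:
    """Read patient outcomes (columns patient_id, time, event); one row per patient."""
    df = pd.read_csv(path)
    missing = {"patient_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing survival columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient_id rows")
    records = [SurvivalRecord(patient_id=str(r.patient_id), time=float(r.time),
                              event=bool(int(r.event)))
               for r in df.itertuples(index=False)]
    logger.info("%s: read %d survival records (%d events)", path, len(records),
                sum(r.event for r in records))
    return records


def write_survival_csv(path: str | Path, records: Sequence[SurvivalRecord]) -> None:
    pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "time": [r.time for r in records],
        "event": [int(r.event) for r in records],
    }).to_csv(path, index=False)
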