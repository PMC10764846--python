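"""TIL spatial architecture: compartments, proximity clusters, features.

Nuclei are split into four classes (epithelial/stromal x TIL/non-TIL) by
mask membership of their centroid pixel.  Proximity clusters are connected
components of the graph joining same-class nuclei within a link radius;
their convex hulls support the area and intersection features.  The
invasive tumor front is the band of tissue within a configurable distance
(default 100 um) of the epithelium-stroma boundary, on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.spatial import cKDTree, ConvexHull, QhullError
from shapely.geometry import Polygon

from .io_core import NucleusRecord, TileBundle

logger = logging.getLogger(__name__)

NUCLEUS_CLASSES = ("epi_til", "epi_nontil", "str_til", "str_nontil")

TIL_FEATURE_NAMES: tuple[str, ...] = (
    "til_ratio_nontil_surr_til_epi",
    "til_nclusters_til_near_nontil_epi",
    "til_presence_pct_nontil_str",
    "til_intersect_area_front",
    "til_min_area_stril_front",
    "til_range_area_epintl_front",
)


@dataclass
class CellCluster:
    class_label: str
    member_indices: list[int]
    hull: np.ndarray          # (K, 2) vertex coordinates, px
    area: float               # px^2; 0 when < 3 non-collinear members
    in_invasive_front: bool = False

    def __post_init__(self) -> None:
        if self.class_label not in NUCLEUS_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not self.member_indices:
            raise ValueError("a cluster needs >= 1 member")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    def __len__(self) -> int:
        return len(self.member_indices)


@dataclass
class CompartmentGeometry:
    epithelium_mask: np.ndarray
    stroma_mask: np.ndarray
    invasive_front_mask: np.ndarray
    front_band_um: float = 100.0


def nucleus_class(n: NucleusRecord) -> str | None:
    """One of the four nuclei classes, or None outside both compartments."""
    if n.compartment == "epithelium":
        return "epi_til" if n.is_til else "epi_nontil"
    if n.compartment == "stroma":
        return "str_til" if n.is_til else "str_nontil"
    return None


# ---------------------------------------------------------------------------
# compartments and invasive front


def invasive_front_mask(epithelium_mask: np.ndarray, stroma_mask: np.ndarray,
                        front_band_um: float, microns_per_pixel: float) -> np.ndarray:
    """Pixels within ``front_band_um`` of the epithelium-stroma boundary.

    The boundary set is the pair of pixel layers where the two compartments
    touch; the band extends on both sides via a Euclidean distance
    transform, restricted to tissue (epithelium or stroma).
    """
    epi = np.asarray(epithelium_mask, dtype=bool)
    stroma = np.asarray(stroma_mask, dtype=bool)
    touch = (ndimage.binary_dilation(epi) & stroma) | (ndimage.binary_dilation(stroma) & epi)
    if not touch.any():
        return np.zeros_like(epi)
    dist = ndimage.distance_transform_edt(~touch)
    band_px = front_band_um / microns_per_pixel
    return (dist <= band_px) & (epi | stroma)


def make_geometry(tile: TileBundle, front_band_um: float = 100.0) -> CompartmentGeometry:
    return CompartmentGeometry(
        epithelium_mask=tile.epithelium_mask,
        stroma_mask=tile.stroma_mask,
        invasive_front_mask=invasive_front_mask(
            tile.epithelium_mask, tile.stroma_mask, front_band_um, tile.microns_per_pixel),
        front_band_um=front_band_um,
    )


def assign_compartments(nuclei: Sequence[NucleusRecord],
                        geometry: CompartmentGeometry) -> list[NucleusRecord]:
    """Label each nucleus by mask membership of its centroid pixel (in place)."""
    h, w = geometry.epithelium_mask.shape
    for i, n in enumerate(nuclei):
        r, c = int(n.y), int(n.x)
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"nucleus {i} at ({n.x}, {n.y}) outside {h}x{w} raster")
        if geometry.epithelium_mask[r, c]:
            n.compartment = "epithelium"
        elif geometry.stroma_mask[r, c]:
            n.compartment = "stroma"
        else:
            n.compartment = "neither"
        n.in_invasive_front = bool(geometry.invasive_front_mask[r, c])
    return list(nuclei)


def density_per_class(nuclei: Sequence[NucleusRecord],
                      geometry: CompartmentGeometry,
                      microns_per_pixel: float) -> dict[str, float]:
    """Count of each nuclei class per mm^2 of its compartment mask.

    NaN (logged) for a class whose compartment mask is empty.
    """
    px_to_mm2 = (microns_per_pixel * 1e-3) ** 2
    areas = {
        "epithelium": float(geometry.epithelium_mask.sum()) * px_to_mm2,
        "stroma": float(geometry.stroma_mask.sum()) * px_to_mm2,
    }
    densities: dict[str, float] = {}
    for label in NUCLEUS_CLASSES:
        comp = "epithelium" if label.startswith("epi") else "stroma"
        count = sum(1 for n in nuclei if nucleus_class(n) == label)
        if areas[comp] == 0:
            logger.warning("empty %s compartment: density of %s undefined", comp, label)
            densities[label] = float("nan")
        else:
            densities[label] = count / areas[comp]
    return densities


# ---------------------------------------------------------------------------
# clusters


def _hull_and_area(points: np.ndarray) -> tuple[np.ndarray, float]:
    if len(points) < 3:
        return points.copy(), 0.0
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear members
        return points.copy(), 0.0
    return points[hull.vertices], float(hull.volume)  # 2-D "volume" is area


def build_clusters(nuclei: Sequence[NucleusRecord],
                   indices: Sequence[int],
                   class_label: str,
                   link_radius_um: float,
                   microns_per_pixel: float) -> list[CellCluster]:
    """Proximity clusters of one nuclei class.

    Connected components of the graph joining nuclei whose centroid distance
    is <= the link radius; singletons are size-1 clusters with area 0.  A
    cluster is flagged in-front when at least half of its members are.
    """
    if not link_radius_um > 0:
        raise ValueError("link_radius_um must be > 0")
    if not indices:
        return []
    radius_px = link_radius_um / microns_per_pixel
    pts = np.array([(nuclei[i].x, nuclei[i].y) for i in indices], dtype=float)
    pairs = cKDTree(pts).query_pairs(radius_px, output_type="ndarray")
    n = len(indices)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])) if len(pairs)
        else ([], ([], [])), shape=(n, n))
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    clusters = []
    for comp in range(n_comp):
        member_pos = np.nonzero(labels == comp)[0]
        members = [indices[j] for j in member_pos]
        hull, area = _hull_and_area(pts[member_pos])
        n_front = sum(1 for i in members if nuclei[i].in_invasive_front)
        clusters.append(CellCluster(class_label=class_label,
                                    member_indices=members, hull=hull, area=area,
                                    in_invasive_front=n_front * 2 >= len(members)))
    return clusters


def build_all_clusters(nuclei: Sequence[NucleusRecord], link_radius_um: float,
                       microns_per_pixel: float) -> dict[str, list[CellCluster]]:
    by_class: dict[str, list[int]] = {c: [] for c in NUCLEUS_CLASSES}
    for i, n in enumerate(nuclei):
        label = nucleus_class(n)
        if label is not None:
            by_class[label].append(i)
    return {label: build_clusters(nuclei, idx, label, link_radius_um, microns_per_pixel)
            for label, idx in by_class.items()}


def _cluster_min_distance(a: CellCluster, b: CellCluster,
                          nuclei: Sequence[NucleusRecord]) -> float:
    """Minimum member-centroid distance between two clusters (px)."""
    pa = np.array([(nuclei[i].x, nuclei[i].y) for i in a.member_indices])
    pb = np.array([(nuclei[i].x, nuclei[i].y) for i in b.member_indices])
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


# ---------------------------------------------------------------------------
# per-tile features


def feature_ratio_nontil_to_surrounding_tils(
    nuclei: Sequence[NucleusRecord],
    epsilon_um: float = 20.0,
    microns_per_pixel: float = 0.25,
) -> float:
    """Epithelial non-TIL count over the count of TILs within epsilon of one.

    The denominator is guarded at 1 so isolated non-TIL populations still
    produce a finite ratio; 0 when there are no epithelial non-TILs.
    """
    eps_px = epsilon_um / microns_per_pixel
    nontil = [n for n in nuclei if nucleus_class(n) == "epi_nontil"]
    if not nontil:
        return 0.0
    tils = [n for n in nuclei if n.is_til]
    n_near = 0
    if tils and nontil:
        tree = cKDTree(np.array([(n.x, n.y) for n in nontil]))
        til_pts = np.array([(n.x, n.y) for n in tils])
        dist, _ = tree.query(til_pts, k=1)
        n_near = int((dist <= eps_px).sum())
    return len(nontil) / max(n_near, 1)


def feature_til_clusters_near_nontil_cluster(
    clusters_epi_til: Sequence[CellCluster],
    clusters_epi_nontil: Sequence[CellCluster],
    nuclei: Sequence[NucleusRecord],
    epsilon_um: float = 20.0,
    microns_per_pixel: float = 0.25,
) -> float:
    """Mean, over epithelial non-TIL clusters, of the number of epithelial
    TIL clusters within epsilon (minimum member-to-member distance)."""
    if not clusters_epi_nontil:
        return 0.0
    eps_px = epsilon_um / microns_per_pixel
    counts = [sum(1 for t in clusters_epi_til
                  if _cluster_min_distance(nt, t, nuclei) <= eps_px)
              for nt in clusters_epi_nontil]
    return float(np.mean(counts))


def feature_presence_pct_nontil_near_nontil(
    clusters_str_nontil: Sequence[CellCluster],
    nuclei: Sequence[NucleusRecord],
    epsilon_um: float = 20.0,
    microns_per_pixel: float = 0.25,
) -> float:
    """Fraction of stromal non-TIL clusters with another such cluster within
    epsilon; 0 when fewer than two clusters exist."""
    if len(clusters_str_nontil) < 2:
        return 0.0
    eps_px = epsilon_um / microns_per_pixel
    present = 0
    for i, a in enumerate(clusters_str_nontil):
        for j, b in enumerate(clusters_str_nontil):
            if i != j and _cluster_min_distance(a, b, nuclei) <= eps_px:
                present += 1
                break
    return present / len(clusters_str_nontil)


def _hull_polygon(cluster: CellCluster) -> Polygon | None:
    if len(cluster.hull) < 3 or cluster.area == 0:
        return None
    return Polygon(cluster.hull)


def feature_intersected_area(
    clusters_epi_til: Sequence[CellCluster],
    clusters_epi_nontil: Sequence[CellCluster],
    front_only: bool = True,
) -> float:
    """Total pairwise convex-hull intersection area (px^2) between epithelial
    TIL and non-TIL clusters, restricted to invasive-front clusters."""
    tils = [c for c in clusters_epi_til if c.in_invasive_front or not front_only]
    nontils = [c for c in clusters_epi_nontil if c.in_invasive_front or not front_only]
    total = 0.0
    for a in tils:
        pa = _hull_polygon(a)
        if pa is None:
            continue
        for b in nontils:
            pb = _hull_polygon(b)
            if pb is not None:
                total += pa.intersection(pb).area
    return total


def feature_cluster_area_stats(clusters: Sequence[CellCluster], stat: str) -> float:
    """min or range of areas over clusters of size >= 3; NaN when none qualify.

    Caller restricts ``clusters`` to the desired class and in-front flag.
    """
    if stat not in ("min", "range"):
        raise ValueError(f"stat must be 'min' or 'range', got {stat!r}")
    areas = [c.area for c in clusters if len(c) >= 3]
    if not areas:
        logger.warning("no qualifying clusters for area %s", stat)
        return float("nan")
    return float(min(areas)) if stat == "min" else float(max(areas) - min(areas))


def til_density(nuclei: Sequence[NucleusRecord]) -> float:
    """TILs as a fraction of all nuclei in stromal invasive-front regions.

    NaN when no stromal in-front nuclei exist.
    """
    denom = [n for n in nuclei if n.compartment == "stroma" and n.in_invasive_front]
    if not denom:
        return float("nan")
    return sum(1 for n in denom if n.is_til) / len(denom)


# ---------------------------------------------------------------------------
# per-tile and per-patient assembly


def tile_til_features(
    tile: TileBundle,
    nuclei: Sequence[NucleusRecord],
    front_band_um: float = 100.0,
    link_radius_um: float = 30.0,
    epsilon_um: float = 20.0,
) -> dict[str, float]:
    """Assign compartments, build clusters, and compute the six cluster
    features plus the invasive-front TIL density for one tile."""
    mpp = tile.microns_per_pixel
    geometry = make_geometry(tile, front_band_um)
    assign_compartments(nuclei, geometry)
    clusters = build_all_clusters(nuclei, link_radius_um, mpp)
    front = {label: [c for c in cl if c.in_invasive_front]
             for label, cl in clusters.items()}
    return {
        "til_ratio_nontil_surr_til_epi": feature_ratio_nontil_to_surrounding_tils(
            nuclei, epsilon_um, mpp),
        "til_nclusters_til_near_nontil_epi": feature_til_clusters_near_nontil_cluster(
            clusters["epi_til"], clusters["epi_nontil"], nuclei, epsilon_um, mpp),
        "til_presence_pct_nontil_str": feature_presence_pct_nontil_near_nontil(
            clusters["str_nontil"], nuclei, epsilon_um, mpp),
        "til_intersect_area_front": feature_intersected_area(
            clusters["epi_til"], clusters["epi_nontil"], front_only=True),
        "til_min_area_stril_front": feature_cluster_area_stats(front["str_til"], "min"),
        "til_range_area_epintl_front": feature_cluster_area_stats(front["epi_nontil"], "range"),
        "til_density_front": til_density(nuclei),
    }


def patient_til_features(per_tile: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Per-patient value = mean over tiles with non-missing values."""
    names = list(TIL_FEATURE_NAMES) + ["til_density_front"]
    out: dict[str, float] = {}
    for name in names:
        vals = [t[name] for t in per_tile if name in t and np.isfinite(t[name])]
        out[name] = float(np.mean(vals)) if vals else float("nan")
    return out
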