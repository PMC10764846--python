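"""Collagen fiber orientation disorder in stromal regions (CFOD-S).

Fiber orientations are estimated with an oriented first-derivative-of-Gaussian
filter bank restricted to the stroma mask.  Within each W x W neighborhood of
a tile, an orientation co-occurrence matrix is built over nearby fiber pairs
and summarized by its Shannon entropy (bits): 0 when every local pair shares
one orientation bin, up to 2*log2(B) when pairs spread uniformly over all
B x B bin combinations.  Eight per-patient statistics of these entropy maps
(mean/min/max at selected window sizes) form the collagen half of the
feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_core import TileBundle

logger = logging.getLogger(__name__)

#: the eight per-patient entropy features: (statistic, window size in px)
ENTROPY_FEATURE_SPECS: tuple[tuple[str, int], ...] = (
    ("mean", 200), ("min", 200), ("max", 250), ("min", 350),
    ("min", 400), ("min", 450), ("max", 550), ("max", 600),
)

ENTROPY_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"cfods_{stat}_w{w}" for stat, w in ENTROPY_FEATURE_SPECS
)

DEFAULT_WINDOW_SIZES: tuple[int, ...] = tuple(sorted({w for _, w in ENTROPY_FEATURE_SPECS}))


@dataclass(frozen=True)
class FiberPoint:
    """A stromal location carrying an estimated fiber orientation.

    ``theta`` is the fiber (not gradient) direction in degrees on [0, 180),
    measured counterclockwise from +x on the displayed image (y up);
    ``magnitude`` is the strength of the maximal filter response.
    """

    x: float
    y: float
    theta: float
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 180.0:
            raise ValueError(f"theta={self.theta} outside [0, 180)")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class OrientationCooccurrenceMatrix:
    bins: int
    counts: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bins < 2:
            raise ValueError("need >= 2 orientation bins")
        if self.counts.shape != (self.bins, self.bins):
            raise ValueError("counts shape does not match bins")


@dataclass
class EntropyFeatureMap:
    """Per-window entropies for one tile at one window size.

    ``entries`` holds ((origin_x, origin_y), entropy_bits, n_fibers) for each
    evaluated window; windows with too few fibers are tallied in
    ``skipped_windows``.
    """

    window_size: int
    entries: list[tuple[tuple[int, int], float, int]]
    skipped_windows: int = 0

    @property
    def entropies(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)


# ---------------------------------------------------------------------------
# fiber orientation detection


def _steerable_responses(image: np.ndarray, sigma: float, n_orientations: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Max |response| and argmax angle of an oriented Gaussian-derivative bank.

    The first derivative of a Gaussian is steerable: the response at angle a
    is cos(a)*Gx + sin(a)*Gy, so the K-filter bank needs only two
    convolutions.  Returns (max |response| HxW, gradient angle in degrees HxW,
    quantized to the bank's K steps on [0, 180)).
    """
    img = np.asarray(image, dtype=float)
    gx = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    angles = np.arange(n_orientations) * (180.0 / n_orientations)
    rad = np.deg2rad(angles)
    stack = np.abs(np.cos(rad)[:, None, None] * gx + np.sin(rad)[:, None, None] * gy)
    best = np.argmax(stack, axis=0)
    return np.take_along_axis(stack, best[None], axis=0)[0], angles[best]


def detect_fiber_orientations(
    tile: TileBundle,
    sigma: float = 2.0,
    response_quantile: float = 0.75,
    n_orientations: int = 12,
    grid_step: int = 4,
) -> list[FiberPoint]:
    """Estimate fiber orientations at stromal pixels of a tile.

    The fiber direction is the bank's maximal-response gradient direction
    rotated by 90 degrees (a linear structure's intensity gradient is
    perpendicular to its axis).  Only stromal pixels whose maximal response
    exceeds the ``response_quantile`` quantile of stromal responses are kept,
    subsampled on a ``grid_step``-px lattice to bound downstream pair counts.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not 0.0 < response_quantile < 1.0:
        raise ValueError("response_quantile must lie in (0, 1)")
    stroma = tile.stroma_mask
    if not stroma.any():
        logger.warning("tile %s: empty stroma mask, no fibers detected", tile.tile_id)
        return []
    magnitude, grad_angle = _steerable_responses(tile.image, sigma, n_orientations)
    threshold = np.quantile(magnitude[stroma], response_quantile)
    keep = stroma & (magnitude > threshold)
    keep[np.arange(keep.shape[0]) % grid_step != 0, :] = False
    keep[:, np.arange(keep.shape[1]) % grid_step != 0] = False
    ys, xs = np.nonzero(keep)
    # fiber axis is perpendicular to the gradient; the sign flip converts the
    # y-down gradient frame to the y-up math convention used for theta
    theta = (90.0 - grad_angle[ys, xs]) % 180.0
    return [FiberPoint(x=float(x), y=float(y), theta=float(t), magnitude=float(m))
            for x, y, t, m in zip(xs, ys, theta, magnitude[ys, xs])]


def fibers_to_arrays(fibers: Sequence[FiberPoint]) -> tuple[np.ndarray, np.ndarray]:
    """(N,2) xy coordinates and (N,) orientations for vectorized geometry."""
    if not fibers:
        return np.empty((0, 2)), np.empty(0)
    xy = np.array([(f.x, f.y) for f in fibers], dtype=float)
    theta = np.array([f.theta for f in fibers], dtype=float)
    return xy, theta


# ---------------------------------------------------------------------------
# co-occurrence and entropy


def orientation_bin(theta: float | np.ndarray, bins: int) -> np.ndarray:
    """Bin index floor(theta*B/180); theta=180 wraps to bin 0."""
    idx = np.floor(np.asarray(theta) * bins / 180.0).astype(int)
    return np.mod(idx, bins)


def build_cooccurrence(
    fibers: Sequence[FiberPoint],
    bins: int = 36,
    pair_radius: float = 50.0,
) -> OrientationCooccurrenceMatrix:
    """Orientation co-occurrence over fiber pairs within ``pair_radius`` px.

    Every unordered pair of distinct fibers at Euclidean distance
    <= pair_radius increments counts[bin_i, bin_j] and counts[bin_j, bin_i],
    so the matrix is symmetric and sums to 2 * n_pairs.  Same-orientation
    pairs fall on the diagonal.  Use ``pair_radius=np.inf`` for all pairs.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if not pair_radius > 0:
        raise ValueError("pair_radius must be > 0")
    counts = np.zeros((bins, bins), dtype=np.int64)
    if len(fibers) < 2:
        return OrientationCooccurrenceMatrix(bins=bins, counts=counts, n_pairs=0)
    xy, theta = fibers_to_arrays(fibers)
    b = orientation_bin(theta, bins)
    if np.isinf(pair_radius):
        ii, jj = np.triu_indices(len(fibers), k=1)
    else:
        pairs = cKDTree(xy).query_pairs(pair_radius, output_type="ndarray")
        if len(pairs) == 0:
            return OrientationCooccurrenceMatrix(bins=bins, counts=counts, n_pairs=0)
        ii, jj = pairs[:, 0], pairs[:, 1]
    np.add.at(counts, (b[ii], b[jj]), 1)
    np.add.at(counts, (b[jj], b[ii]), 1)
    return OrientationCooccurrenceMatrix(bins=bins, counts=counts, n_pairs=len(ii))


def cooccurrence_entropy(matrix: OrientationCooccurrenceMatrix) -> float:
    """Shannon entropy (bits) of the normalized co-occurrence matrix.

    0 for an empty or single-cell matrix; at most 2*log2(B) (uniform over
    all B*B cells).
    """
    total = matrix.counts.sum()
    if total == 0:
        return 0.0
    p = matrix.counts[matrix.counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_feature_map(
    tile: TileBundle,
    fibers: Sequence[FiberPoint],
    window_size: int,
    bins: int = 36,
    pair_radius: float = 50.0,
    min_fibers: int = 10,
) -> EntropyFeatureMap:
    """Entropy of the orientation co-occurrence matrix per W x W neighborhood.

    Windows tile the image on a non-overlapping grid anchored at (0, 0);
    partial windows at the right/bottom edges are discarded.  Windows holding
    fewer than ``min_fibers`` fibers are skipped (counted, not evaluated).
    """
    h, w = tile.shape
    if window_size > min(h, w):
        raise ValueError(f"window_size {window_size} exceeds tile shape {(h, w)}")
    if min_fibers < 2:
        raise ValueError("min_fibers must be >= 2")
    xy, theta = fibers_to_arrays(fibers)
    entries: list[tuple[tuple[int, int], float, int]] = []
    skipped = 0
    for oy in range(0, h - window_size + 1, window_size):
        for ox in range(0, w - window_size + 1, window_size):
            if len(xy):
                inside = ((xy[:, 0] >= ox) & (xy[:, 0] < ox + window_size)
                          & (xy[:, 1] >= oy) & (xy[:, 1] < oy + window_size))
                local = [fibers[i] for i in np.nonzero(inside)[0]]
            else:
                local = []
            if len(local) < min_fibers:
                skipped += 1
                continue
            ent = cooccurrence_entropy(build_cooccurrence(local, bins, pair_radius))
            entries.append(((ox, oy), ent, len(local)))
    return EntropyFeatureMap(window_size=window_size, entries=entries,
                             skipped_windows=skipped)


def aggregate_entropy_features(
    maps: Iterable[EntropyFeatureMap],
) -> dict[str, float]:
    """Pool windows across one patient's tiles and emit the 8 named features.

    Windows are pooled per window size across all tiles before taking
    mean/min/max (min and max are only meaningful over the pooled set).
    A size with zero evaluated windows yields NaN for its features and the
    patient should be excluded from model fitting by the caller.
    """
    pooled: dict[int, list[float]] = {}
    for m in maps:
        pooled.setdefault(m.window_size, []).extend(e[1] for e in m.entries)
    features: dict[str, float] = {}
    for (stat, w), name in zip(ENTROPY_FEATURE_SPECS, ENTROPY_FEATURE_NAMES):
        values = pooled.get(w, [])
        if not values:
            logger.warning("no evaluated %dx%d windows; feature %s missing", w, w, name)
            features[name] = float("nan")
        else:
            features[name] = float({"mean": np.mean, "min": np.min, "max": np.max}[stat](values))
    return features


def tile_entropy_maps(
    tile: TileBundle,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
    sigma: float = 2.0,
    response_quantile: float = 0.75,
    n_orientations: int = 12,
    grid_step: int = 4,
    bins: int = 36,
    pair_radius: float = 50.0,
    min_fibers: int = 10,
) -> list[EntropyFeatureMap]:
    """Detect fibers once and build entropy maps at every requested size."""
    fibers = detect_fiber_orientations(tile, sigma=sigma,
                                       response_quantile=response_quantile,
                                       n_orientations=n_orientations,
                                       grid_step=grid_step)
    return [entropy_feature_map(tile, fibers, w, bins=bins, pair_radius=pair_radius,
                                min_fibers=min_fibers)
            for w in window_sizes if w <= min(tile.shape)]
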