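import numpy as np
import pytest
from skimage.draw import line_aa

from collatil.io_core import TileBundle


def make_line_tile(angle_deg: float, size: int = 256, n_lines: int = 14,
                   seed: int = 0) -> TileBundle:
    """Parallel bright lines at a known orientation on a dark background,
    with a full-stroma mask."""
    rng = np.random.default_rng(seed)
    big = 2 * size  # draw on a larger canvas so no line end is visible
    img = rng.normal(40.0, 2.0, (big, big))
    t = np.deg2rad(angle_deg)
    dx, dy = np.cos(t), -np.sin(t)  # y grows downward
    for k in range(n_lines):
        cx = rng.uniform(0.25, 0.75) * big
        cy = rng.uniform(0.25, 0.75) * big
        half = float(big)
        r0, c0 = int(cy - dy * half), int(cx - dx * half)
        r1, c1 = int(cy + dy * half), int(cx + dx * half)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < big) & (cc >= 0) & (cc < big)
        img[rr[keep], cc[keep]] += 120.0 * val[keep]
    lo = size // 2
    img = np.clip(img[lo:lo + size, lo:lo + size], 0, 255).astype(np.uint8)
    return TileBundle(tile_id=f"lines{angle_deg}", patient_id="p", image=img,
                      epithelium_mask=np.zeros((size, size), bool),
                      stroma_mask=np.ones((size, size), bool))


def make_blank_tile(size: int = 256, stroma: bool = True) -> TileBundle:
    """Constant-intensity tile (optionally full-stroma) for degenerate cases."""
    mask = np.ones((size, size), bool) if stroma else np.zeros((size, size), bool)
    return TileBundle(tile_id="blank", patient_id="p",
                      image=np.full((size, size), 128, np.uint8),
                      epithelium_mask=np.zeros((size, size), bool),
                      stroma_mask=mask)


def axial_circular_mean(theta_deg: np.ndarray) -> float:
    """Mean orientation on the 180-degree-periodic circle (doubled angles)."""
    doubled = np.deg2rad(2.0 * np.asarray(theta_deg))
    return float(np.rad2deg(np.arctan2(np.sin(doubled).mean(),
                                       np.cos(doubled).mean())) / 2.0) % 180.0


def axial_distance(a: float, b: float) -> float:
    """Angular distance between two orientations modulo 180 degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@pytest.fixture
def blank_tile():
    return make_blank_tile()
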