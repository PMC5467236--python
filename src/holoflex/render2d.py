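"""Render synthetic holoenzymes as 2D images and detect them back.

Images emulate the appearance of negatively stained particles (bright
protein on dark background) on a 4.37 Å/px scale in a 128x128 box: the
hub as an annulus (outer radius 55 Å, pore radius 12.5 Å) and each kinase
domain as an isotropic Gaussian blob.  Detection recovers the hub centre
by intensity centroid and the kinase centres by local-maximum search
outside a 50 Å inner exclusion radius, mirroring the masking radii used
for focused classification of such particles.

Image convention: origin top-left, row-major, y increasing downward.
A particle coordinate (x, y) in Å maps to (col, row) = centre + (x, y)/px,
which makes decreasing mathematical polar angle appear clockwise on
screen — the same convention `particle_geometry` measures in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
import tifffile

__all__ = [
    "RenderConfig",
    "RenderError",
    "DetectionResult",
    "render_particle",
    "detect_particle",
    "write_tiff",
    "read_tiff",
]


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class RenderConfig:
    pixel_size: float = 4.37        # Å per pixel
    box: int = 128                  # square image side, px
    hub_outer_radius: float = 55.0  # Å
    hub_pore_radius: float = 12.5   # Å (pore diameter ~25 Å)
    kinase_blob_sigma: float = 10.0  # Å
    noise_sigma: float = 0.05       # additive, relative to unit intensity
    inner_exclusion: float = 50.0   # Å, detection mask around the hub
    merge_distance: float = 20.0    # Å, closer peaks may be fused
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hub_pore_radius >= self.hub_outer_radius:
            raise RenderError("pore must be smaller than the hub")
        if self.box * self.pixel_size < 2 * (self.hub_outer_radius + 20):
            raise RenderError("field of view too small")


@dataclass
class DetectionResult:
    hub_centre_px: tuple          # (row, col)
    coords: np.ndarray            # kinase centres, Å relative to hub centre
    n_peaks: int
    complete: bool                # False if fewer peaks than expected
    merged_flags: np.ndarray = field(default_factory=lambda: np.array([]))


def _grids(cfg: RenderConfig) -> tuple[np.ndarray, np.ndarray]:
    c = (cfg.box - 1) / 2.0
    rows, cols = np.mgrid[0:cfg.box, 0:cfg.box]
    x = (cols - c) * cfg.pixel_size
    y = (rows - c) * cfg.pixel_size
    return x, y


def render_particle(particle, cfg: RenderConfig = RenderConfig(),
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Single-channel float image of one particle (hub at image centre)."""
    if particle.coords is None:
        raise RenderError("particle has no coordinates (use angular mode)")
    coords = np.asarray(particle.coords, dtype=float)
    half = cfg.box * cfg.pixel_size / 2.0
    if (np.abs(coords) + 3 * cfg.kinase_blob_sigma > half).any():
        raise RenderError("particle exceeds the field of view")

    x, y = _grids(cfg)
    r = np.hypot(x, y)
    img = ((r >= cfg.hub_pore_radius) & (r <= cfg.hub_outer_radius)
           ).astype(float)
    for (cx, cy) in coords:
        img += np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                      / (2.0 * cfg.kinase_blob_sigma ** 2))
    img = np.clip(img, 0.0, 1.0)
    if cfg.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    return img


def _refine_peak(img: np.ndarray, row: int, col: int,
                 half: int = 2) -> tuple[float, float]:
    """Sub-pixel peak position by local intensity-weighted centroid."""
    r0, r1 = max(row - half, 0), min(row + half + 1, img.shape[0])
    c0, c1 = max(col - half, 0), min(col + half + 1, img.shape[1])
    patch = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
    total = patch.sum()
    if total == 0:
        return float(row), float(col)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return float((patch * rr).sum() / total), float((patch * cc).sum() / total)


def detect_particle(image: np.ndarray, cfg: RenderConfig = RenderConfig(),
                    n_expected: int | None = None) -> DetectionResult:
    """Hub centre + kinase-centre coordinates (Å, relative to hub centre).

    Fewer peaks than expected yields a flagged partial result, not an
    exception.  Peaks closer than ``merge_distance`` are fused by the
    local-maximum search and the surviving peak is flagged as merged.
    """
    px = cfg.pixel_size
    smooth = gaussian_filter(image.astype(float), sigma=1.0)

    # hub centre: intensity centroid of the central disc
    c = (cfg.box - 1) / 2.0
    x, y = _grids(cfg)
    disc = np.hypot(x, y) <= cfg.hub_outer_radius
    w = np.clip(smooth - np.median(smooth), 0.0, None) * disc
    if w.sum() == 0:
        hub_rc = (c, c)
    else:
        rows, cols = np.mgrid[0:cfg.box, 0:cfg.box]
        hub_rc = (float((w * rows).sum() / w.sum()),
                  float((w * cols).sum() / w.sum()))

    # subtract the known hub annulus (aligned to the detected centre) so
    # its flat plateau cannot masquerade as kinase peaks — the image-space
    # analogue of masking out the hub before classification
    rows, cols = np.mgrid[0:cfg.box, 0:cfg.box]
    xr = (cols - hub_rc[1]) * px
    yr = (rows - hub_rc[0]) * px
    rr_hub = np.hypot(xr, yr)
    template = ((rr_hub >= cfg.hub_pore_radius)
                & (rr_hub <= cfg.hub_outer_radius)).astype(float)
    residual = smooth - gaussian_filter(template, sigma=1.0)

    # suppression footprint kept small so genuinely paired kinases
    # (~35 Å apart) both survive; the 20 Å merge rule is applied below
    peaks = peak_local_max(residual, min_distance=2,
                           threshold_abs=0.25, exclude_border=False)
    coords = []
    for (pr, pc) in peaks:
        prr, prc = _refine_peak(residual, pr, pc)
        dx = (prc - hub_rc[1]) * px
        dy = (prr - hub_rc[0]) * px
        if np.hypot(dx, dy) < cfg.inner_exclusion:
            continue
        coords.append((dx, dy))
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)

    # fuse detections closer than merge_distance (paired kinases may blur
    # together at high noise); surviving peaks are flagged so affected
    # separations can be excluded downstream
    merged_coords: list[np.ndarray] = []
    merged_flags: list[bool] = []
    used = np.zeros(len(coords), dtype=bool)
    for i in range(len(coords)):
        if used[i]:
            continue
        group = [i]
        for j in range(i + 1, len(coords)):
            if not used[j] and np.linalg.norm(
                    coords[i] - coords[j]) < cfg.merge_distance:
                group.append(j)
        used[group] = True
        merged_coords.append(coords[group].mean(axis=0))
        merged_flags.append(len(group) > 1)
    coords = np.asarray(merged_coords, dtype=float).reshape(-1, 2)
    merged = np.asarray(merged_flags, dtype=bool)

    complete = n_expected is None or len(coords) >= n_expected
    return DetectionResult(hub_centre_px=hub_rc, coords=coords,
                           n_peaks=len(coords), complete=complete,
                           merged_flags=merged)


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write as 16-bit grayscale TIFF (intensities rescaled to the range)."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scale = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    tifffile.imwrite(str(path), (scale * 65535).astype(np.uint16))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float) / 65535.0
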