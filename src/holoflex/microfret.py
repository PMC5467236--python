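"""Three-filter ("micro-FRET") sensitized-emission correction.

Sensitized-emission FRET imaging acquires three registered single-plane
images: donor excitation/donor emission, acceptor excitation/acceptor
emission, and donor excitation/acceptor emission (raw, uncorrected FRET).
The raw FRET channel contains, besides true sensitized emission, donor
bleed-through and acceptor cross-excitation that mix in linearly.  The
correction subtracts fixed fractions of the background-subtracted donor
and acceptor images:

    FRETc = raw - 0.02093 * donor_image - 0.09484 * acceptor_image

The default coefficients are the GFP bleed-through and mCherry
cross-excitation fractions; they are deliberately rounded *up* from the
measured cross-bleed so that residual bleed-through can only depress, not
inflate, the corrected signal.  FRETc scales with fluorophore abundance,
so per-cell values are normalized by mean donor intensity; the
normalization is valid only with the acceptor in excess, enforced by a
closed [4, 11] window on the acceptor/donor abundance ratio.  Detected
GFP intensity is divided by a 4.8 channel detection-efficiency factor to
convert it to abundance-equivalent units before the ratio is formed.

Fluorophore-to-role assignment is configurable: formulas are written
against donor/acceptor roles, and the default role map takes mGFP as the
acceptor and mCherry as the donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FretCoefficients",
    "CellTruth",
    "FretScene",
    "FretSceneParams",
    "GatingError",
    "synth_fret_scene",
    "estimate_background",
    "background_subtract",
    "correct_fret",
    "normalized_fret",
    "acceptor_donor_ratio",
    "in_ratio_window",
]


class GatingError(ValueError):
    """Cell excluded by the gating rules (or invalid gating input)."""


@dataclass(frozen=True)
class FretCoefficients:
    donor_bleedthrough: float = 0.02093       # fraction of donor image
    acceptor_crossexcitation: float = 0.09484  # fraction of acceptor image
    gfp_detection_efficiency: float = 4.8      # GFP channel vs mCherry
    ratio_window: tuple = (4.0, 11.0)          # closed acceptor/donor window
    acceptor_fluorophore: str = "gfp"          # role map, configurable
    donor_fluorophore: str = "mcherry"

    def __post_init__(self) -> None:
        for f in (self.donor_bleedthrough, self.acceptor_crossexcitation):
            if not (0.0 <= f < 1.0):
                raise ValueError("bleed-through fractions must be in [0, 1)")
        lo, hi = self.ratio_window
        if not lo < hi:
            raise ValueError("ratio window low must be below high")
        if {self.acceptor_fluorophore, self.donor_fluorophore} != \
                {"gfp", "mcherry"}:
            raise ValueError("roles must map gfp and mcherry")


@dataclass
class CellTruth:
    centre: tuple
    radius: float
    donor_abundance: float
    acceptor_abundance: float
    efficiency: float


@dataclass
class FretScene:
    donor: np.ndarray        # donor ex / donor em
    acceptor: np.ndarray     # acceptor ex / acceptor em
    raw_fret: np.ndarray     # donor ex / acceptor em
    background: dict         # channel -> true background level
    rois: np.ndarray         # labelled mask, 0 = background
    cells: list              # CellTruth per label (label = index + 1)
    coeffs: FretCoefficients


@dataclass
class FretSceneParams:
    shape: tuple = (96, 96)
    n_cells: int = 6
    cell_radius: float = 9.0
    donor_range: tuple = (200.0, 1000.0)
    ratio_range: tuple = (2.0, 14.0)    # acceptor/donor abundance
    efficiencies: Sequence[float] | None = None  # per cell, else drawn
    efficiency_range: tuple = (0.0, 0.4)
    background: dict = field(default_factory=lambda: {
        "donor": 50.0, "acceptor": 50.0, "raw_fret": 50.0})
    noise_sigma: float = 2.0            # additive read noise, counts
    fret_gain: float = 0.5              # sensitized counts per donor*E


def synth_fret_scene(params: FretSceneParams = FretSceneParams(),
                     seed: int = 0,
                     coeffs: FretCoefficients = FretCoefficients()
                     ) -> FretScene:
    """Scene with the linear mixing model the correction assumes.

    Per cell with donor abundance D, acceptor abundance A and true
    efficiency E (uniform intensity discs on a flat background):
        donor channel    = detection_gain(donor) * D (1 - E)
        acceptor channel = detection_gain(acceptor) * A
        raw FRET         = fret_gain * D * E
                           + bleedthrough * donor channel
                           + crossexcitation * acceptor channel
    plus per-channel background and Gaussian read noise.  The channel of
    whichever fluorophore is GFP carries the 4.8x detection-efficiency
    gain, so gating on detected signals recovers true abundance ratios.
    """
    rng = np.random.default_rng(seed)
    if params.efficiencies is not None:
        effs = list(params.efficiencies)
        if len(effs) != params.n_cells:
            raise ValueError("one efficiency per cell required")
    else:
        effs = rng.uniform(*params.efficiency_range,
                           params.n_cells).tolist()
    if any(not (0.0 <= e < 1.0) for e in effs):
        raise ValueError("efficiencies must be in [0, 1)")

    donor_gain = coeffs.gfp_detection_efficiency \
        if coeffs.donor_fluorophore == "gfp" else 1.0
    acceptor_gain = coeffs.gfp_detection_efficiency \
        if coeffs.acceptor_fluorophore == "gfp" else 1.0

    h, w = params.shape
    rois = np.zeros(params.shape, dtype=int)
    yy, xx = np.mgrid[0:h, 0:w]

    # cells on a jittered grid so ROIs stay disjoint
    n_side = int(np.ceil(np.sqrt(params.n_cells)))
    pitch_y, pitch_x = h / n_side, w / n_side
    cells = []
    donor_img = np.zeros(params.shape)
    acceptor_img = np.zeros(params.shape)
    true_fret = np.zeros(params.shape)
    for i in range(params.n_cells):
        gy, gx = divmod(i, n_side)
        cy = (gy + 0.5) * pitch_y + rng.uniform(-2, 2)
        cx = (gx + 0.5) * pitch_x + rng.uniform(-2, 2)
        D = rng.uniform(*params.donor_range)
        A = D * rng.uniform(*params.ratio_range)
        E = effs[i]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= params.cell_radius ** 2
        rois[mask] = i + 1
        donor_img[mask] = donor_gain * D * (1.0 - E)
        acceptor_img[mask] = acceptor_gain * A
        true_fret[mask] = params.fret_gain * D * E
        cells.append(CellTruth((cy, cx), params.cell_radius, D, A, E))

    raw = (true_fret
           + coeffs.donor_bleedthrough * donor_img
           + coeffs.acceptor_crossexcitation * acceptor_img)

    bg = params.background
    ns = params.noise_sigma

    def finish(img, key):
        out = img + bg[key]
        if ns > 0:
            out = out + rng.normal(0.0, ns, img.shape)
        return out

    return FretScene(donor=finish(donor_img, "donor"),
                     acceptor=finish(acceptor_img, "acceptor"),
                     raw_fret=finish(raw, "raw_fret"),
                     background=dict(bg), rois=rois, cells=cells,
                     coeffs=coeffs)


def estimate_background(image: np.ndarray, blank_mask: np.ndarray) -> float:
    """Per-channel background: median over a user-supplied blank region."""
    if not blank_mask.any():
        raise ValueError("empty blank region")
    return float(np.median(image[blank_mask]))


def background_subtract(image: np.ndarray, background: float) -> np.ndarray:
    return np.asarray(image, dtype=float) - background


def correct_fret(raw: np.ndarray, donor_img: np.ndarray,
                 acceptor_img: np.ndarray,
                 coeffs: FretCoefficients = FretCoefficients()) -> np.ndarray:
    """Pixelwise FRETc on background-subtracted inputs.

    Negative pixels are retained — the correction is a pure subtraction.
    """
    raw = np.asarray(raw, dtype=float)
    donor_img = np.asarray(donor_img, dtype=float)
    acceptor_img = np.asarray(acceptor_img, dtype=float)
    if not (raw.shape == donor_img.shape == acceptor_img.shape):
        raise ValueError("channel shape mismatch")
    return (raw
            - coeffs.donor_bleedthrough * donor_img
            - coeffs.acceptor_crossexcitation * acceptor_img)


def normalized_fret(fretc: np.ndarray, donor_img: np.ndarray,
                    roi: np.ndarray) -> float:
    """Mean FRETc over the ROI divided by mean donor intensity there."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise GatingError("empty ROI")
    donor_mean = float(np.asarray(donor_img, dtype=float)[roi].mean())
    if donor_mean <= 0:
        raise GatingError("non-positive donor signal; cell excluded")
    return float(np.asarray(fretc, dtype=float)[roi].mean()) / donor_mean


def acceptor_donor_ratio(gfp_signal: float, mcherry_signal: float,
                         coeffs: FretCoefficients = FretCoefficients()
                         ) -> float:
    """Acceptor/donor abundance ratio from detected channel signals.

    The GFP-channel signal is divided by the detection-efficiency factor
    (4.8) to convert detected intensity into abundance-equivalent units;
    the ratio is then acceptor-role abundance over donor-role abundance
    under the configured role map.
    """
    if gfp_signal <= 0 or mcherry_signal <= 0:
        raise GatingError("non-positive signal; cell excluded")
    abundance = {"gfp": gfp_signal / coeffs.gfp_detection_efficiency,
                 "mcherry": float(mcherry_signal)}
    return (abundance[coeffs.acceptor_fluorophore]
            / abundance[coeffs.donor_fluorophore])


def in_ratio_window(ratio: float,
                    coeffs: FretCoefficients = FretCoefficients()) -> bool:
    """Closed-interval gate on the acceptor/donor abundance ratio."""
    lo, hi = coeffs.ratio_window
    return lo <= ratio <= hi
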