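"""Stimulus luminance measurement and the paired control comparison.

Mean luminance is the arithmetic mean of the 8-bit intensities of the
pixels whose centers fall inside the region (whole frame or the eye
AOI polygon, classified with the same ray-casting routine used for
gaze).  Color images are converted to grayscale with Rec. 601 luma
weights before measurement.  The control analyses are the paired
Wilcoxon between large- and small-pupil variants and the Spearman
correlation between per-image luminance differences and per-image
pupil-response differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aoi import EyeAOI, points_in_polygon
from .core import GeometryError
from .stats import CorrelationResult, WilcoxonResult, spearman, wilcoxon_signed_rank


@dataclass
class StimulusImage:
    image_id: str
    pixels: np.ndarray  # (h, w) uint8 grayscale

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:  # RGB -> Rec. 601 luma
            px = np.clip(
                0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2], 0, 255
            )
        self.pixels = px.astype(np.uint8)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def load(cls, path: str | Path) -> "StimulusImage":
        from PIL import Image

        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
        return cls(Path(path).stem, arr)


def mean_luminance(image: StimulusImage, region: EyeAOI | None = None) -> float:
    """Mean 8-bit intensity over the region (whole image if ``None``).

    Pixel (r, c) has its center at coordinates (c + 0.5, r + 0.5).
    """
    px = image.pixels.astype(float)
    if region is None:
        return float(px.mean())
    x0, y0, x1, y1 = region.bounds()
    c0 = max(int(np.floor(x0 - 0.5)), 0)
    r0 = max(int(np.floor(y0 - 0.5)), 0)
    c1 = min(int(np.ceil(x1)) + 1, image.width)
    r1 = min(int(np.ceil(y1)) + 1, image.height)
    if c1 <= c0 or r1 <= r0:
        raise GeometryError("region does not overlap the image")
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    centers = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])
    inside = points_in_polygon(centers, region)
    if not inside.any():
        raise GeometryError("no pixel centers inside the region")
    return float(px[r0:r1, c0:c1].ravel()[inside].mean())


def paired_luminance_test(pairs: list[tuple[float, float]]) -> WilcoxonResult:
    """Wilcoxon signed-rank on per-image (small - large) luminance."""
    if len(pairs) < 2:
        raise GeometryError("need at least 2 image pairs")
    diffs = [small - large for large, small in pairs]
    return wilcoxon_signed_rank(diffs)


def luminance_pupil_correlation(image_diffs, pupil_diffs) -> CorrelationResult:
    """Full Spearman between per-image luminance differences and
    per-image mean pupil-response differences."""
    return spearman(image_diffs, pupil_diffs)
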