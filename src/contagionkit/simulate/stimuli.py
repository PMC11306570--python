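"""Synthetic stimulus landmarks and face-like grayscale images.

These are schematic stand-ins for the face photographs: an oval face
on a uniform background with iris/pupil disks whose pupil radius
differs between the large- and small-pupil variants, plus eyebrow
arcs.  They exist so the AOI, gaze-classification and luminance stages
can run on pixel data with known geometry; no attempt is made to look
like a real photograph.
"""

from __future__ import annotations

import numpy as np

from ..aoi import Landmarks
from ..config import SimConfig


def stimulus_image_ids(config: SimConfig) -> list[str]:
    return [
        f"face{a:02d}_{size}"
        for a in range(config.n_stimulus_pairs)
        for size in ("large", "small")
    ]


def _face_geometry(config: SimConfig, actor: int) -> dict:
    """Deterministic per-actor geometry with small landmark jitter."""
    rng = np.random.default_rng(np.random.SeedSequence([0xFACE, actor]))
    w, h = config.stim_width, config.stim_height
    jitter = lambda s=3.0: rng.uniform(-s, s)  # noqa: E731
    eye_y = 0.42 * h + jitter()
    geo = {
        "eye_left": np.array([0.35 * w + jitter(), eye_y + jitter(1.5)]),
        "eye_right": np.array([0.65 * w + jitter(), eye_y + jitter(1.5)]),
        "cheek_left": np.array([0.22 * w + jitter(), 0.52 * h + jitter()]),
        "cheek_right": np.array([0.78 * w + jitter(), 0.52 * h + jitter()]),
        "iris_r": 0.045 * w * (1 + 0.08 * rng.standard_normal()),
        "mouth": np.array([0.5 * w, 0.72 * h]),
    }
    brow_y = 0.345 * h
    for side, x0 in (("left", 0.35 * w), ("right", 0.65 * w)):
        xs = x0 + np.linspace(-0.10 * w, 0.10 * w, 5)
        ys = brow_y - 8.0 * np.sin(np.linspace(0.2, np.pi - 0.2, 5)) + jitter(2.0)
        geo[f"eyebrow_{side}"] = np.column_stack([xs, ys + rng.uniform(-1, 1, 5)])
    return geo


def generate_landmarks(config: SimConfig, actor: int, image_id: str | None = None) -> Landmarks:
    geo = _face_geometry(config, actor)
    return Landmarks(
        image_id=image_id or f"face{actor:02d}",
        width=config.stim_width,
        height=config.stim_height,
        eyebrow_left=geo["eyebrow_left"],
        eyebrow_right=geo["eyebrow_right"],
        cheek_left=geo["cheek_left"],
        cheek_right=geo["cheek_right"],
        eye_left=geo["eye_left"],
        eye_right=geo["eye_right"],
    )


def _disk(grid_y: np.ndarray, grid_x: np.ndarray, center, radius: float) -> np.ndarray:
    return (grid_x - center[0]) ** 2 + (grid_y - center[1]) ** 2 <= radius**2


def render_stimulus(
    config: SimConfig, actor: int, pupil_size: str, cross: bool = False
) -> np.ndarray:
    """8-bit grayscale stimulus image for one actor/pupil-size variant.

    Pupil radius is ~50% of the iris radius in the large variant and
    ~30% in the small variant, so the eye region of the large variant
    is slightly darker — the residual luminance confound the paired
    control analysis is meant to detect.
    """
    if pupil_size not in ("large", "small"):
        raise ValueError(f"unknown pupil size {pupil_size!r}")
    geo = _face_geometry(config, actor)
    w, h = config.stim_width, config.stim_height
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), 185.0)

    # face oval
    cx, cy = 0.5 * w, 0.52 * h
    face = ((xx - cx) / (0.38 * w)) ** 2 + ((yy - cy) / (0.45 * h)) ** 2 <= 1.0
    img[face] = 150.0

    frac = 0.5 if pupil_size == "large" else 0.3
    for eye in (geo["eye_left"], geo["eye_right"]):
        img[_disk(yy, xx, eye, geo["iris_r"] * 1.6)] = 210.0  # sclera
        img[_disk(yy, xx, eye, geo["iris_r"])] = 110.0  # iris
        img[_disk(yy, xx, eye, geo["iris_r"] * frac)] = 25.0  # pupil

    for side in ("left", "right"):  # eyebrow strokes
        for x, y in geo[f"eyebrow_{side}"]:
            img[_disk(yy, xx, (x, y), 2.5)] = 70.0

    mx, my = geo["mouth"]
    mouth = ((xx - mx) / (0.10 * w)) ** 2 + ((yy - my) / (0.02 * h)) ** 2 <= 1.0
    img[mouth] = 90.0

    if cross:  # fixation cross between the eyes
        gx = 0.5 * (geo["eye_left"][0] + geo["eye_right"][0])
        gy = 0.5 * (geo["eye_left"][1] + geo["eye_right"][1])
        arm = 6
        img[int(gy) - 1 : int(gy) + 2, int(gx) - arm : int(gx) + arm + 1] = 0.0
        img[int(gy) - arm : int(gy) + arm + 1, int(gx) - 1 : int(gx) + 2] = 0.0

    return img.astype(np.uint8)
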