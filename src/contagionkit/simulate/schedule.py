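"""Blocked stimulus schedule.

Blocks are homogeneous in (emotion, stimulus pupil size); each gaze
condition contributes ``blocks_per_condition`` blocks cycling through
the four (emotion, size) cells.  Block order and within-block image
order are permuted by the seed.  Every trial is preceded by the 1 s
inter-stimulus fixation that doubles as its baseline window; the first
trial of a block follows the 10 s block fixation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..core import EVENT_COLUMNS, validate_events


def _actors_for_emotion(config: SimConfig, emotion: str) -> list[int]:
    half = config.n_stimulus_pairs // 2
    return list(range(0, half)) if emotion == "happy" else list(
        range(half, config.n_stimulus_pairs)
    )


def generate_schedule(config: SimConfig, seed: int) -> pd.DataFrame:
    """Generate one participant's trial schedule as an events table."""
    rng = np.random.default_rng(seed)
    cells = [("happy", "large"), ("happy", "small"), ("sad", "large"), ("sad", "small")]
    blocks = []
    for condition in ("CROSS", "NO_CROSS"):
        cycle = itertools.cycle(cells)
        for _ in range(config.blocks_per_condition):
            emotion, size = next(cycle)
            blocks.append((condition, emotion, size))
    order = rng.permutation(len(blocks))

    rows = []
    trial = 0
    for block_index, bi in enumerate(order):
        condition, emotion, size = blocks[bi]
        actors = _actors_for_emotion(config, emotion)
        images = [actors[i % len(actors)] for i in range(config.trials_per_block)]
        images = list(rng.permutation(images))
        block_start = block_index * config.block_duration_s
        for k, actor in enumerate(images):
            onset = (
                block_start
                + config.block_fixation_s
                + k * (config.stim_duration_s + config.isi_fixation_s)
            )
            rows.append(
                {
                    "trial": trial,
                    "onset_s": onset,
                    "duration_s": config.stim_duration_s,
                    "block": block_index,
                    "condition": condition,
                    "stim_pupil": size,
                    "emotion": emotion,
                    "image_id": f"face{actor:02d}_{size}",
                }
            )
            trial += 1
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return validate_events(events)
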