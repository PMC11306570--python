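"""Cohort assembly: orchestrated simulation and on-disk layout.

One seeded generator hierarchy drives everything: the cohort seed
spawns one child per participant, and each participant's child seeds
their schedule and streams, so a single participant can be regenerated
without re-simulating the rest of the cohort.

On-disk layout (all plain text)::

    cohort_dir/
      config.yaml
      participants.tsv
      landmarks/<image_id>.json
      stimuli/<image_id>.png          (optional)
      <participant_id>/
        events.tsv
        gaze.csv      t, lx, ly, rx, ry, valid_l, valid_r
        pupil.csv     t, dl, dr
        eda.csv       t, us
        rr.csv        t, rr_ms
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..aoi import EyeAOI, Landmarks, build_eye_aoi
from ..config import SimConfig, save_config
from ..core import SampledStream
from ..hr import RRSeries
from .cohort import Participant, cohort_frame, generate_cohort
from .schedule import generate_schedule
from .stimuli import generate_landmarks, render_stimulus
from .streams import simulate_eda, simulate_gaze, simulate_pupil, simulate_rr

ALL_MODALITIES = ("gaze", "pupil", "eda", "rr")


@dataclass
class CohortData:
    """In-memory synthetic cohort: everything the pipeline consumes."""

    config: SimConfig
    participants: list[Participant]
    landmarks: dict[str, Landmarks]
    aois: dict[str, EyeAOI]
    schedules: dict[str, pd.DataFrame]
    gaze: dict[str, tuple[SampledStream, SampledStream]] = field(default_factory=dict)
    pupil: dict[str, tuple[SampledStream, SampledStream]] = field(default_factory=dict)
    eda: dict[str, SampledStream] = field(default_factory=dict)
    rr: dict[str, RRSeries] = field(default_factory=dict)

    def participant_frame(self) -> pd.DataFrame:
        return cohort_frame(self.participants)


def simulate_cohort(
    config: SimConfig,
    modalities: tuple[str, ...] = ALL_MODALITIES,
    ellipse_height_ratio: float = 0.5,
    ellipse_vertices: int = 32,
) -> CohortData:
    """Simulate a full cohort for the configured study design."""
    cohort = generate_cohort(config)
    landmarks: dict[str, Landmarks] = {}
    aois: dict[str, EyeAOI] = {}
    for actor in range(config.n_stimulus_pairs):
        for size in ("large", "small"):
            image_id = f"face{actor:02d}_{size}"
            lm = generate_landmarks(config, actor, image_id)
            landmarks[image_id] = lm
            aois[image_id] = build_eye_aoi(lm, ellipse_height_ratio, ellipse_vertices)

    data = CohortData(config, cohort, landmarks, aois, {})
    root = np.random.SeedSequence([config.seed, 0x5EED])
    for participant, child in zip(cohort, root.spawn(len(cohort))):
        seeds = child.generate_state(5) % (2**31)
        sched = generate_schedule(config, int(seeds[0]))
        data.schedules[participant.id] = sched
        if "pupil" in modalities:
            data.pupil[participant.id] = simulate_pupil(
                participant, sched, config, int(seeds[1])
            )
        if "gaze" in modalities:
            data.gaze[participant.id] = simulate_gaze(
                participant, sched, aois, config, int(seeds[2])
            )
        if "eda" in modalities:
            data.eda[participant.id] = simulate_eda(sched, config, int(seeds[3]))
        if "rr" in modalities:
            data.rr[participant.id] = simulate_rr(sched, config, int(seeds[4]))
    return data


def _write_stream_csv(path: Path, columns: dict[str, np.ndarray]) -> None:
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.6f")


def write_cohort(data: CohortData, out_dir: str | Path, images: bool = False) -> Path:
    """Write a cohort to the plain-text layout; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(data.config, out / "config.yaml")
    data.participant_frame().to_csv(out / "participants.tsv", sep="\t", index=False)

    lm_dir = out / "landmarks"
    lm_dir.mkdir(exist_ok=True)
    for image_id, lm in data.landmarks.items():
        lm.save(lm_dir / f"{image_id}.json")

    if images:
        from PIL import Image

        stim_dir = out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        for actor in range(data.config.n_stimulus_pairs):
            for size in ("large", "small"):
                arr = render_stimulus(data.config, actor, size)
                Image.fromarray(arr).save(stim_dir / f"face{actor:02d}_{size}.png")

    for p in data.participants:
        pdir = out / p.id
        pdir.mkdir(exist_ok=True)
        data.schedules[p.id].to_csv(pdir / "events.tsv", sep="\t", index=False)
        if p.id in data.gaze:
            left, right = data.gaze[p.id]
            _write_stream_csv(
                pdir / "gaze.csv",
                {
                    "t": left.t,
                    "lx": left.values[:, 0],
                    "ly": left.values[:, 1],
                    "rx": right.values[:, 0],
                    "ry": right.values[:, 1],
                    "valid_l": left.mask.astype(int),
                    "valid_r": right.mask.astype(int),
                },
            )
        if p.id in data.pupil:
            left, right = data.pupil[p.id]
            _write_stream_csv(
                pdir / "pupil.csv", {"t": left.t, "dl": left.values, "dr": right.values}
            )
        if p.id in data.eda:
            eda = data.eda[p.id]
            _write_stream_csv(pdir / "eda.csv", {"t": eda.t, "us": eda.values})
        if p.id in data.rr:
            rr = data.rr[p.id]
            _write_stream_csv(pdir / "rr.csv", {"t": rr.t, "rr_ms": rr.rr})
    return out
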