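"""Core containers shared across the pipeline.

All signals are carried as :class:`SampledStream` objects: a timestamp
vector, a value array (1-D for scalar channels, ``(n, 2)`` for gaze
coordinates), and a boolean validity mask (``True`` = usable sample).
Trial metadata travels as a pandas ``DataFrame`` with the schema checked
by :func:`validate_events`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "trial",
    "onset_s",
    "duration_s",
    "block",
    "condition",
    "stim_pupil",
    "emotion",
    "image_id",
]

CONDITIONS = ("CROSS", "NO_CROSS")
PUPIL_SIZES = ("large", "small")
EMOTIONS = ("happy", "sad")


class ContagionError(Exception):
    """Base class for pipeline errors."""


class InvalidConfigError(ContagionError):
    pass


class GeometryError(ContagionError):
    pass


class DegenerateInputError(ContagionError):
    """Raised when a statistic is undefined for the given input."""


class SchemaError(ContagionError):
    """A table or stream violates its declared schema."""


@dataclass
class SampledStream:
    """A (possibly irregularly) sampled signal.

    Parameters
    ----------
    t
        Sample timestamps in seconds, strictly increasing.
    values
        Sample values; shape ``(n,)`` or ``(n, k)``.
    mask
        Per-sample validity; invalid samples hold undefined values
        (NaN on disk).
    """

    t: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(
                self.values if self.values.ndim == 1 else self.values.min(axis=1)
            )
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.t.ndim != 1:
            raise SchemaError("timestamps must be 1-D")
        if len(self.t) != len(self.values) or len(self.t) != len(self.mask):
            raise SchemaError("t, values and mask must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise SchemaError(f"timestamps not strictly increasing at row {bad}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "SampledStream":
        return SampledStream(self.t.copy(), self.values.copy(), self.mask.copy())

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        """Timestamps and values of valid samples only."""
        return self.t[self.mask], self.values[self.mask]


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an events table against the trial schema and invariants."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"events table missing columns: {missing}")
    ev = events.sort_values("onset_s").reset_index(drop=True)
    if (ev["duration_s"] <= 0).any():
        raise SchemaError("trial durations must be positive")
    ends = ev["onset_s"].to_numpy() + ev["duration_s"].to_numpy()
    if np.any(ev["onset_s"].to_numpy()[1:] < ends[:-1] - 1e-9):
        raise SchemaError("trials overlap in time")
    bad_cond = set(ev["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown conditions: {bad_cond}")
    bad_size = set(ev["stim_pupil"]) - set(PUPIL_SIZES)
    if bad_size:
        raise SchemaError(f"unknown stimulus pupil sizes: {bad_size}")
    return ev
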