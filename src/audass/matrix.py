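"""Facial matrix accumulation and windowing (layer 2).

Per-frame AU intensity levels are normalized to fixed reals and appended as
columns to a 31-row facial matrix (rows in catalog order, one column per
frame).  Whenever 30 new columns have accumulated — one second of video at
the default 30 fps — they are emitted as a non-overlapping (tumbling)
31x30 window for the prediction network; residual columns are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .levels import (
    AU_CATALOG,
    IntensityLevel,
    N_AUS,
    normalize_intensity,
)

WINDOW_COLUMNS = 30


@dataclass(frozen=True)
class AUFrame:
    """Intensity levels of all 31 catalog AUs for one video frame."""

    levels: Mapping[str, IntensityLevel]
    frame_index: int = 0
    fps: float = 30.0

    def __post_init__(self) -> None:
        missing = [au for au in AU_CATALOG if au not in self.levels]
        if missing:
            raise ValueError(f"frame is missing AUs: {missing[:5]}")
        unknown = [au for au in self.levels if au not in AU_CATALOG]
        if unknown:
            raise ValueError(f"unknown AUs in frame: {unknown[:5]}")

    @property
    def timestamp(self) -> float:
        return self.frame_index / self.fps

    def to_array(self) -> np.ndarray:
        """Levels as an int array in catalog order."""
        return np.array([int(self.levels[au]) for au in AU_CATALOG])

    def normalized(self) -> np.ndarray:
        """Normalized column vector in catalog order."""
        return np.array(
            [normalize_intensity(self.levels[au]) for au in AU_CATALOG]
        )

    @classmethod
    def from_levels(cls, levels: Iterable[IntensityLevel],
                    frame_index: int = 0, fps: float = 30.0) -> "AUFrame":
        vals = list(levels)
        if len(vals) != N_AUS:
            raise ValueError(f"expected {N_AUS} levels, got {len(vals)}")
        return cls(
            levels=dict(zip(AU_CATALOG, (IntensityLevel(v) for v in vals))),
            frame_index=frame_index,
            fps=fps,
        )


@dataclass(frozen=True)
class Window:
    """One 31x30 facial-matrix slice: a second of video at 30 fps."""

    values: np.ndarray
    start_frame: int = 0
    fps: float = 30.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_AUS, WINDOW_COLUMNS):
            raise ValueError(
                f"window must be {N_AUS}x{WINDOW_COLUMNS}, got {vals.shape}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def start_time(self) -> float:
        return self.start_frame / self.fps

    @property
    def duration(self) -> float:
        return WINDOW_COLUMNS / self.fps

    def flatten(self) -> np.ndarray:
        """Flatten column-major (frame by frame), length 930.

        Each frame's 31 AU values stay contiguous; this fixed ordering is
        the network's input contract.
        """
        return self.values.flatten(order="F")


class FacialMatrix:
    """Accumulates normalized AU columns and emits tumbling windows."""

    def __init__(self, fps: float = 30.0) -> None:
        if fps < 1:
            raise ValueError("fps must be >= 1")
        self.fps = float(fps)
        self._columns: list[np.ndarray] = []
        self._drained = 0  # frames already emitted as windows

    @property
    def n_columns(self) -> int:
        """Columns currently buffered (ingested since the last drain)."""
        return len(self._columns)

    @property
    def n_ingested(self) -> int:
        """Total frames ever ingested."""
        return self._drained + len(self._columns)

    def append_frame(self, frame: AUFrame) -> "FacialMatrix":
        """Append one frame as a new normalized column (catalog row order)."""
        self._columns.append(frame.normalized())
        return self

    def to_array(self) -> np.ndarray:
        """Buffered matrix, 31 rows x n_columns."""
        if not self._columns:
            return np.zeros((N_AUS, 0))
        return np.stack(self._columns, axis=1)

    def drain_windows(self) -> list[Window]:
        """Emit all complete 30-column windows; keep the residual buffered.

        Conservation: frames ingested = 30 x windows emitted + residual.
        """
        out: list[Window] = []
        while len(self._columns) >= WINDOW_COLUMNS:
            cols, self._columns = (
                self._columns[:WINDOW_COLUMNS],
                self._columns[WINDOW_COLUMNS:],
            )
            out.append(
                Window(
                    values=np.stack(cols, axis=1),
                    start_frame=self._drained,
                    fps=self.fps,
                )
            )
            self._drained += WINDOW_COLUMNS
        return out


def windows_from_frames(frames: Iterable[AUFrame], fps: float = 30.0) -> list[Window]:
    """Convenience: ingest a frame sequence and return its complete windows."""
    fm = FacialMatrix(fps=fps)
    for f in frames:
        fm.append_frame(f)
    return fm.drain_windows()
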