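"""Eye/mouth block localisation in a binary face mask.

Works on the row profile of a face mask: the row with the most face pixels
in the upper half of the mask is taken as the median row of the eye block,
and the corresponding row in the lower half as the median of the mouth
block.  Each candidate row is then validated against canonical face-height
ratios: eyes between 2/20 and 9/20 of face height, mouth between 11/20 and
15/20.  Invalid blocks are flagged rather than raised so that streaming
callers can skip frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_HEIGHT = 20


@dataclass(frozen=True)
class BlockDetectionConfig:
    """Validation bands as fraction intervals of face height (inclusive)."""

    eye_band: tuple[float, float] = (2 / 20, 9 / 20)
    mouth_band: tuple[float, float] = (11 / 20, 15 / 20)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("eye_band", self.eye_band),
                               ("mouth_band", self.mouth_band)):
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError(f"{name} must satisfy 0 <= lo < hi <= 1")


@dataclass(frozen=True)
class BlockResult:
    eye_median_row: int
    mouth_median_row: int
    eye_valid: bool
    mouth_valid: bool

    def to_dict(self) -> dict[str, object]:
        return {
            "eye_median_row": self.eye_median_row,
            "mouth_median_row": self.mouth_median_row,
            "eye_valid": self.eye_valid,
            "mouth_valid": self.mouth_valid,
        }


def _as_mask(mask, min_height: int = 1) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < min_height or arr.shape[1] < 1:
        raise ValueError(
            f"mask must be at least {min_height} rows by 1 column, "
            f"got {arr.shape}"
        )
    arr = (arr != 0).astype(np.int64)
    if arr.sum() == 0:
        raise ValueError("mask contains no face pixels")
    return arr


def row_white_profile(mask) -> np.ndarray:
    """Number of face (1) pixels in each row; length equals mask height."""
    return _as_mask(mask).sum(axis=1)


def detect_blocks(mask, cfg: BlockDetectionConfig | None = None) -> BlockResult:
    """Locate eye and mouth block median rows and validate them.

    The mask is split at half its height (rows with ``row / H < 1/2`` form
    the upper part).  Within each part the row with the highest face-pixel
    count is the block median; argmax ties break to the smallest row index.
    A block is valid iff its part is non-empty and ``row / H`` lies inside
    the configured band (inclusive).
    """
    cfg = cfg or BlockDetectionConfig()
    arr = _as_mask(mask, min_height=MIN_HEIGHT)
    H = arr.shape[0]
    profile = arr.sum(axis=1)
    split = (H + 1) // 2  # first row with row/H >= 1/2

    upper, lower = profile[:split], profile[split:]
    eye_row = int(np.argmax(upper))
    mouth_row = split + int(np.argmax(lower)) if lower.size else split

    def _valid(row: int, count: int, band: tuple[float, float]) -> bool:
        frac = row / H
        return count > 0 and band[0] <= frac <= band[1]

    return BlockResult(
        eye_median_row=eye_row,
        mouth_median_row=mouth_row,
        eye_valid=_valid(eye_row, int(profile[eye_row]), cfg.eye_band),
        mouth_valid=_valid(mouth_row, int(profile[mouth_row]) if mouth_row < H else 0,
                           cfg.mouth_band),
    )
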