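"""Core vocabulary shared by every layer of the pipeline.

Defines the FACS action-unit catalog used throughout (31 AUs coded with
intensity levels), the six-step intensity scale O..E, the fixed
normalization of those levels into [0, 1], and the five DASS severity
bands.
"""

from __future__ import annotations

import enum


class IntensityLevel(enum.IntEnum):
    """FACS action-unit intensity: O (absent) through E (maximum).

    The ordinal rank (0..5) follows the FACS convention: O < A < B < C < D < E.
    """

    O = 0
    A = 1
    B = 2
    C = 3
    D = 4
    E = 5

    @classmethod
    def from_letter(cls, letter: str) -> "IntensityLevel":
        try:
            return cls[letter.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown intensity level {letter!r}; expected one of O, A, B, C, D, E"
            ) from None


#: Normalized value of each intensity level.  Note the non-uniform top step
#: (D = 0.8, E = 0.9): the scale is kept exactly as defined, not rescaled.
NORMALIZED_INTENSITY: dict[IntensityLevel, float] = {
    IntensityLevel.O: 0.0,
    IntensityLevel.A: 0.2,
    IntensityLevel.B: 0.4,
    IntensityLevel.C: 0.6,
    IntensityLevel.D: 0.8,
    IntensityLevel.E: 0.9,
}

#: Allowed normalized values, in level order.
INTENSITY_VALUES: tuple[float, ...] = tuple(
    NORMALIZED_INTENSITY[lv] for lv in IntensityLevel
)


def normalize_intensity(level: IntensityLevel) -> float:
    """Map an intensity level to its normalized value in [0, 1]."""
    return NORMALIZED_INTENSITY[IntensityLevel(level)]


class SeverityBand(enum.IntEnum):
    """DASS severity band; ordinal rank 1 (Normal) .. 5 (Extremely Severe)."""

    NORMAL = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4
    EXTREMELY_SEVERE = 5

    @property
    def label(self) -> str:
        return _BAND_LABELS[self]


_BAND_LABELS = {
    SeverityBand.NORMAL: "Normal",
    SeverityBand.MILD: "Mild",
    SeverityBand.MODERATE: "Moderate",
    SeverityBand.SEVERE: "Severe",
    SeverityBand.EXTREMELY_SEVERE: "Extremely Severe",
}

#: The three DASS scales, in canonical order.
SCALES: tuple[str, str, str] = ("depression", "anxiety", "stress")

# The 31 AUs coded with intensity levels that the pipeline analyzes:
# upper face AU1, AU2, AU4, AU5, AU6, AU7, AU43, AU45; lower face AU8-AU20
# and AU22-AU28; cheeks AU33, AU34, AU35.  AU41, AU42 and AU46 are excluded
# (not coded with intensity levels); AUs are treated individually, as
# nonadditive.  Ordered by ascending AU number; every module shares this
# ordering.
_AU_NUMBERS = (
    1, 2, 4, 5, 6, 7,
    8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
    22, 23, 24, 25, 26, 27, 28,
    33, 34, 35,
    43, 45,
)

AU_CATALOG: tuple[str, ...] = tuple(f"AU{n}" for n in _AU_NUMBERS)
AU_INDEX: dict[str, int] = {au: i for i, au in enumerate(AU_CATALOG)}

N_AUS = len(AU_CATALOG)
assert N_AUS == 31
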