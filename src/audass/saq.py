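"""DASS-42 self-analysis questionnaire (SAQ) scoring and severity banding.

The DASS-42 has 42 items, 14 per scale (depression, anxiety, stress), each
self-rated 0..3.  A scale's raw score is the sum of its 14 item scores
(0..42) and maps to one of five severity bands via a per-scale cut-point
table.  The instrument's item-to-scale mapping is licensed material and is
therefore configuration, not code: callers supply a
:class:`ScaleAssignment`; the default (items 1-14 depression, 15-28
anxiety, 29-42 stress) is a synthetic placeholder used by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .levels import SCALES, SeverityBand

N_ITEMS = 42
ITEMS_PER_SCALE = 14
MAX_ITEM_SCORE = 3
MAX_RAW = ITEMS_PER_SCALE * MAX_ITEM_SCORE  # 42

#: Per-scale raw-score intervals for the five severity bands, inclusive.
#: The top band is open-ended ("28+", "20+", "34+") and capped at the
#: maximum possible raw score.
SCALE_BAND_TABLE: dict[str, tuple[tuple[int, int], ...]] = {
    "depression": ((0, 9), (10, 13), (14, 20), (21, 27), (28, MAX_RAW)),
    "anxiety": ((0, 7), (8, 9), (10, 14), (15, 19), (20, MAX_RAW)),
    "stress": ((0, 14), (15, 18), (19, 25), (26, 33), (34, MAX_RAW)),
}

#: Default synthetic item partition: 1-based item indices per scale.
DEFAULT_SCALE_ASSIGNMENT: dict[str, tuple[int, ...]] = {
    "depression": tuple(range(1, 15)),
    "anxiety": tuple(range(15, 29)),
    "stress": tuple(range(29, 43)),
}


def _validate_assignment(assignment: Mapping[str, Sequence[int]]) -> None:
    if set(assignment) != set(SCALES):
        raise ValueError(f"scale_assignment must cover exactly {SCALES}")
    seen: set[int] = set()
    for scale in SCALES:
        items = tuple(assignment[scale])
        if len(items) != ITEMS_PER_SCALE:
            raise ValueError(
                f"scale {scale!r} must have exactly {ITEMS_PER_SCALE} items, "
                f"got {len(items)}"
            )
        for it in items:
            if not 1 <= it <= N_ITEMS:
                raise ValueError(f"item index {it} out of range 1..{N_ITEMS}")
            if it in seen:
                raise ValueError(f"item {it} assigned to more than one scale")
            seen.add(it)


@dataclass(frozen=True)
class SAQResponse:
    """A complete DASS-42 self-report.

    Parameters
    ----------
    item_scores
        42 integer scores, item 1 first, each in 0..3.
    scale_assignment
        1-based item indices per scale; defaults to the synthetic partition.
    """

    item_scores: tuple[int, ...]
    scale_assignment: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_ASSIGNMENT)
    )

    def __post_init__(self) -> None:
        scores = tuple(int(s) for s in self.item_scores)
        if len(scores) != N_ITEMS:
            raise ValueError(
                f"expected {N_ITEMS} item scores, got {len(scores)}"
            )
        for i, s in enumerate(scores, start=1):
            if not 0 <= s <= MAX_ITEM_SCORE:
                raise ValueError(
                    f"item {i} has score {s}, outside 0..{MAX_ITEM_SCORE}"
                )
        object.__setattr__(self, "item_scores", scores)
        _validate_assignment(self.scale_assignment)


def score_scale(response: SAQResponse, scale: str) -> int:
    """Raw score of one scale: the sum of its 14 item scores (0..42)."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    items = response.scale_assignment[scale]
    return sum(response.item_scores[i - 1] for i in items)


def band_raw_score(scale: str, raw: int) -> SeverityBand:
    """Severity band containing a raw scale score.

    Raises
    ------
    ValueError
        If ``raw`` is outside 0..42.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    raw = int(raw)
    if not 0 <= raw <= MAX_RAW:
        raise ValueError(f"raw score {raw} outside 0..{MAX_RAW}")
    for band, (lo, hi) in zip(SeverityBand, SCALE_BAND_TABLE[scale]):
        if lo <= raw <= hi:
            return band
    raise AssertionError("band table does not cover 0..42")  # pragma: no cover


def score_saq(response: SAQResponse) -> dict[str, dict[str, object]]:
    """Score all three scales; returns {scale: {raw, band}}."""
    out: dict[str, dict[str, object]] = {}
    for scale in SCALES:
        raw = score_scale(response, scale)
        out[scale] = {"raw": raw, "band": band_raw_score(scale, raw)}
    return out
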