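"""Post-network decision logic: AU-signature shortcut and the rule-based
classifier (RBC).

Each DASS scale has a four-AU signature (depression: AU6, AU12, AU15,
AU26; anxiety: AU2, AU9, AU25, AU45; stress: AU1, AU6, AU12, AU15).  When
all four signature AUs of a scale reach intensity D or E within a window,
that scale is scored Extremely Severe directly, bypassing the network.

The RBC aggregates the per-second band triples: if the same triple occurs
for five consecutive seconds, it is the system's final output; otherwise
the output is Undefined (insufficient information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .levels import AU_INDEX, SCALES, SeverityBand
from .matrix import AUFrame, FacialMatrix, Window
from .network import FFNNParams, predict_window

#: Normalized intensity of level D; the shortcut requires >= this value.
SHORTCUT_THRESHOLD = 0.8

BandTriple = tuple[SeverityBand, SeverityBand, SeverityBand]


def _default_signatures() -> dict[str, tuple[str, ...]]:
    return {
        "depression": ("AU6", "AU12", "AU15", "AU26"),
        "anxiety": ("AU2", "AU9", "AU25", "AU45"),
        "stress": ("AU1", "AU6", "AU12", "AU15"),
    }


@dataclass(frozen=True)
class SignatureRules:
    """Per-scale signature AU sets with the D-level intensity threshold."""

    signatures: Mapping[str, tuple[str, ...]] = field(
        default_factory=_default_signatures
    )
    threshold: float = SHORTCUT_THRESHOLD
    same_frame: bool = False  # strict mode: co-occurrence in one column

    def __post_init__(self) -> None:
        if set(self.signatures) != set(SCALES):
            raise ValueError(f"signatures must cover exactly {SCALES}")
        for scale, aus in self.signatures.items():
            if len(set(aus)) != 4:
                raise ValueError(
                    f"signature for {scale!r} must contain 4 distinct AUs"
                )
            for au in aus:
                if au not in AU_INDEX:
                    raise ValueError(f"{au!r} is not in the AU catalog")


def signature_shortcut(
    window: Window, rules: SignatureRules | None = None
) -> dict[str, bool]:
    """Per-scale Extremely-Severe override flags for one window.

    Default mode fires a scale when each of its four signature AUs reaches
    the D-level threshold in at least one column of the window (not
    necessarily the same column); ``rules.same_frame`` requires a single
    column where all four reach it simultaneously.
    """
    rules = rules or SignatureRules()
    fired: dict[str, bool] = {}
    for scale in SCALES:
        rows = [AU_INDEX[au] for au in rules.signatures[scale]]
        sub = window.values[rows, :] >= rules.threshold
        if rules.same_frame:
            fired[scale] = bool(np.any(sub.all(axis=0)))
        else:
            fired[scale] = bool(sub.any(axis=1).all())
    return fired


@dataclass(frozen=True)
class AggregatorConfig:
    """RBC configuration.

    By default "same prediction" means the identical band triple.  With
    ``per_scale`` each scale's run is found independently and the final
    triple combines the three decisions (Undefined if any scale never
    stabilizes); this decides more often on streams whose scales
    stabilize at different times.
    """

    required_consecutive: int = 5
    per_scale: bool = False

    def __post_init__(self) -> None:
        if self.required_consecutive < 1:
            raise ValueError("required_consecutive must be a positive integer")


def _first_run(values: Sequence, k: int) -> int | None:
    """Index of the last element of the first run of >= k equal values."""
    run_val, run_len = None, 0
    for i, v in enumerate(values):
        run_len = run_len + 1 if v == run_val else 1
        run_val = v
        if run_len >= k:
            return i
    return None


def rbc_aggregate(
    per_second: Sequence[BandTriple], cfg: AggregatorConfig | None = None
) -> BandTriple | None:
    """Final output of the rule-based classifier.

    Scans the ordered per-second band triples for the first run of at
    least ``cfg.required_consecutive`` identical triples ("same
    prediction" compares the full triple) and returns that triple.
    Returns ``None`` (Undefined) if no qualifying run exists.
    """
    cfg = cfg or AggregatorConfig()
    if len(per_second) == 0:
        raise ValueError("per-second prediction sequence is empty")
    if cfg.per_scale:
        bands = []
        for k in range(3):
            seq = [t[k] for t in per_second]
            i = _first_run(seq, cfg.required_consecutive)
            if i is None:
                return None
            bands.append(seq[i])
        return tuple(bands)
    i = _first_run(per_second, cfg.required_consecutive)
    return None if i is None else per_second[i]


@dataclass(frozen=True)
class SecondRecord:
    """One per-second trace entry: time, band triple, producing path."""

    t: float
    bands: BandTriple
    paths: tuple[str, str, str]  # "network" | "shortcut" per scale
    activations: tuple[float, float, float]

    def to_dict(self) -> dict[str, object]:
        return {
            "t": self.t,
            "bands": [b.label for b in self.bands],
            "paths": list(self.paths),
            "activations": list(self.activations),
        }


@dataclass(frozen=True)
class StreamPrediction:
    final: BandTriple | None
    trace: tuple[SecondRecord, ...]
    decision_time: float | None  # seconds consumed when the RBC decided
    diagnostic: str | None = None

    @property
    def undefined(self) -> bool:
        return self.final is None


def predict_stream(
    frames: Sequence[AUFrame],
    params: FFNNParams,
    rules: SignatureRules | None = None,
    agg: AggregatorConfig | None = None,
    fps: float = 30.0,
) -> StreamPrediction:
    """Run the full per-second pipeline over an AU-frame stream.

    Frames are accumulated into 31x30 windows; each window is scored by the
    signature shortcut (per scale) or, where the shortcut does not fire, by
    the network's banded output.  The RBC then looks for five consecutive
    identical triples.  Streams shorter than one window yield Undefined
    with a diagnostic.
    """
    rules = rules or SignatureRules()
    agg = agg or AggregatorConfig()
    fm = FacialMatrix(fps=fps)
    for f in frames:
        fm.append_frame(f)
    windows = fm.drain_windows()
    if not windows:
        return StreamPrediction(
            final=None, trace=(), decision_time=None,
            diagnostic=f"stream has {len(frames)} frames; at least 30 needed",
        )

    trace: list[SecondRecord] = []
    triples: list[BandTriple] = []
    for w in windows:
        pred = predict_window(params, w)
        fired = signature_shortcut(w, rules)
        bands = []
        paths = []
        for scale, band in zip(SCALES, pred.bands):
            if fired[scale]:
                bands.append(SeverityBand.EXTREMELY_SEVERE)
                paths.append("shortcut")
            else:
                bands.append(band)
                paths.append("network")
        triple = tuple(bands)
        triples.append(triple)
        trace.append(
            SecondRecord(
                t=w.start_time + w.duration,
                bands=triple,
                paths=tuple(paths),
                activations=pred.activations,
            )
        )

    final = rbc_aggregate(triples, agg)
    decision_time = None
    if final is not None:
        if agg.per_scale:
            ends = [_first_run([t[k] for t in triples],
                               agg.required_consecutive) for k in range(3)]
            decision_time = trace[max(ends)].t
        else:
            decision_time = trace[_first_run(triples,
                                             agg.required_consecutive)].t
    return StreamPrediction(
        final=final, trace=tuple(trace), decision_time=decision_time,
    )
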