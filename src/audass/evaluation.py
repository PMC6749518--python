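"""Evaluation metrics and leave-one-out protocols.

Per-band performance is measured one-vs-rest: for a chosen severity band,
TP counts cases where the system correctly predicted that band, TN where
it correctly predicted a different band, FP/FN the two error directions;
then

    AC = (TP + TN) / (TP + TN + FP + FN)
    SE = TPR = TP / (TP + FN)
    SP = TNR = TN / (TN + FP)

Undefined stream predictions (no five-second consensus) are excluded from
the confusion counts and reported separately as an undecided rate.

Two leave-one-out methodologies are provided over a simulated cohort whose
samples are tagged DSC (emotion induced during recording) or DSR (no
emotion induced): intrasubject (folds over one subject's samples) and
intersubject (folds over subjects).  An optional training-emotion filter
restricts the training fold to recordings of the named induced emotions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .decision import AggregatorConfig, SignatureRules, predict_stream
from .levels import SCALES, SeverityBand
from .matrix import windows_from_frames
from .network import (
    TrainingConfig,
    encode_bands,
    train,
)
from .synth import EMOTIONS, CohortSample


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsTriple:
    """Accuracy, sensitivity and specificity; None marks an undefined ratio."""

    ac: float | None
    se: float | None
    sp: float | None


def confusion_for_level(
    predictions: Sequence[SeverityBand | None],
    truths: Sequence[SeverityBand],
    level: SeverityBand,
) -> ConfusionCounts:
    """One-vs-rest confusion counts for one severity band.

    ``None`` predictions (Undefined) are skipped; they do not enter any of
    the four counts.
    """
    if len(predictions) != len(truths):
        raise ValueError(
            f"predictions ({len(predictions)}) and truths ({len(truths)}) "
            "must be aligned"
        )
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truths):
        if p is None:
            continue
        if t == level:
            if p == level:
                tp += 1
            else:
                fn += 1
        else:
            if p == level:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> MetricsTriple:
    """AC/SE/SP from one-vs-rest counts; undefined ratios become None."""
    total = counts.total
    ac = (counts.tp + counts.tn) / total if total else None
    pos = counts.tp + counts.fn
    se = counts.tp / pos if pos else None
    neg = counts.tn + counts.fp
    sp = counts.tn / neg if neg else None
    return MetricsTriple(ac=ac, se=se, sp=sp)


# ---------------------------------------------------------------------------
# protocols

Split = Literal["DSC", "DSR", "both"]


@dataclass(frozen=True)
class ProtocolSpec:
    methodology: Literal["intrasubject", "intersubject"]
    train_split: Split = "DSC"
    test_split: Split = "DSR"
    emotion_filter: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.emotion_filter is not None:
            unknown = set(self.emotion_filter) - set(EMOTIONS)
            if unknown:
                raise ValueError(f"unknown emotions in filter: {unknown}")


@dataclass
class FoldRecord:
    fold: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class ProtocolResult:
    """Per-scale, per-band metrics table plus stream-level diagnostics."""

    per_scale_band: dict[str, dict[SeverityBand, MetricsTriple]]
    per_scale_accuracy: dict[str, float | None]
    undecided_rate: float
    mean_decision_seconds: float | None
    folds: list[FoldRecord]
    predictions: list[tuple[str, tuple | None, tuple]]  # (sample, pred, truth)

    def audit_no_leakage(self) -> bool:
        """True iff no fold shares a sample between train and test."""
        return all(
            not (set(f.train_ids) & set(f.test_ids)) for f in self.folds
        )


def _in_split(sample: CohortSample, split: Split) -> bool:
    return split == "both" or sample.dataset == split


def _train_pool(
    samples: Sequence[CohortSample], spec: ProtocolSpec
) -> list[CohortSample]:
    pool = [s for s in samples if _in_split(s, spec.train_split)]
    if spec.emotion_filter is not None:
        pool = [s for s in pool if s.emotion in spec.emotion_filter]
    return pool


def _folds(samples: Sequence[CohortSample], spec: ProtocolSpec):
    """Yield (fold name, train samples, test samples) leave-one-out folds."""
    if spec.methodology == "intersubject":
        subjects = sorted({s.subject_id for s in samples})
        if len(subjects) < 2:
            raise ValueError("intersubject protocol needs >= 2 subjects")
        for subj in subjects:
            train_s = _train_pool(
                [s for s in samples if s.subject_id != subj], spec)
            test_s = [s for s in samples
                      if s.subject_id == subj and _in_split(s, spec.test_split)]
            if train_s and test_s:
                yield f"leave-out-{subj}", train_s, test_s
    else:
        for subj in sorted({s.subject_id for s in samples}):
            own = [s for s in samples if s.subject_id == subj]
            if len(own) < 2:
                raise ValueError(
                    f"intrasubject protocol needs >= 2 samples per subject; "
                    f"{subj} has {len(own)}"
                )
            for held in own:
                if not _in_split(held, spec.test_split):
                    continue
                train_s = _train_pool(
                    [s for s in own if s.sample_id != held.sample_id], spec)
                if train_s:
                    yield f"{subj}-leave-out-{held.sample_id}", train_s, [held]


def _training_set(samples: Iterable[CohortSample]):
    windows, targets = [], []
    for s in samples:
        for w in windows_from_frames(s.frames):
            windows.append(w)
            targets.append(encode_bands(s.truth))
    return windows, np.asarray(targets)


def run_protocol(
    samples: Sequence[CohortSample],
    spec: ProtocolSpec,
    train_cfg: TrainingConfig | None = None,
    seed: int = 0,
    rules: SignatureRules | None = None,
    agg: AggregatorConfig | None = None,
    fps: float = 30.0,
) -> ProtocolResult:
    """Leave-one-out evaluation of the full pipeline over a cohort.

    In every fold a fresh network is trained on the fold's training
    windows (targets are the band midpoints of each sample's session
    truth) and the held-out streams are scored by the complete per-second
    pipeline (signature shortcut, network banding, RBC).  The per-sample
    final triples are compared with the session truths.
    """
    train_cfg = train_cfg or TrainingConfig()
    if not samples:
        raise ValueError("cohort is empty")

    folds: list[FoldRecord] = []
    preds: list[tuple[str, tuple | None, tuple]] = []
    decision_times: list[float] = []
    full_lengths: list[float] = []

    for k, (name, train_s, test_s) in enumerate(_folds(samples, spec)):
        windows, targets = _training_set(train_s)
        cfg_k = TrainingConfig(
            learning_rate=train_cfg.learning_rate,
            momentum=train_cfg.momentum,
            max_epochs=train_cfg.max_epochs,
            target_error=train_cfg.target_error,
            validation_fraction=train_cfg.validation_fraction,
            mode=train_cfg.mode,
            seed=int((seed * 100003 + k) % (2**31 - 1)),
        )
        params, _hist = train(windows, targets, cfg_k)
        folds.append(
            FoldRecord(
                fold=name,
                train_ids=tuple(s.sample_id for s in train_s),
                test_ids=tuple(s.sample_id for s in test_s),
            )
        )
        for s in test_s:
            result = predict_stream(s.frames, params, rules=rules, agg=agg,
                                    fps=fps)
            preds.append((s.sample_id, result.final, s.truth))
            if result.final is not None and result.decision_time is not None:
                decision_times.append(result.decision_time)
            else:
                full_lengths.append(len(s.frames) / fps)

    per_scale_band: dict[str, dict[SeverityBand, MetricsTriple]] = {}
    per_scale_accuracy: dict[str, float | None] = {}
    for i, scale in enumerate(SCALES):
        scale_preds = [p[1][i] if p[1] is not None else None for p in preds]
        scale_truths = [p[2][i] for p in preds]
        per_scale_band[scale] = {
            band: metrics(confusion_for_level(scale_preds, scale_truths, band))
            for band in SeverityBand
        }
        defined = [(p, t) for p, t in zip(scale_preds, scale_truths)
                   if p is not None]
        per_scale_accuracy[scale] = (
            sum(p == t for p, t in defined) / len(defined) if defined else None
        )

    n_streams = len(preds)
    n_undecided = sum(1 for p in preds if p[1] is None)
    all_durations = decision_times + full_lengths
    return ProtocolResult(
        per_scale_band=per_scale_band,
        per_scale_accuracy=per_scale_accuracy,
        undecided_rate=n_undecided / n_streams if n_streams else 0.0,
        mean_decision_seconds=(
            float(np.mean(all_durations)) if all_durations else None
        ),
        folds=folds,
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# emotion-conditioned training comparison

def per_window_scale_accuracy(
    params, samples: Sequence[CohortSample], scale: str
) -> float:
    """Fraction of test windows whose network band matches the truth band."""
    from .network import band_output, forward

    i = SCALES.index(scale)
    correct = total = 0
    for s in samples:
        for w in windows_from_frames(s.frames):
            band = band_output(float(forward(params, w.flatten())[i]))
            correct += band == s.truth[i]
            total += 1
    if total == 0:
        raise ValueError("no test windows")
    return correct / total


def stratified_cohort_samples(
    scale: str,
    cfg,
    seed: int = 0,
    n_dsr: int = 2,
    isolate: bool = True,
):
    """One subject per severity band of ``scale``.

    With ``isolate`` the other two scales are held at Normal so their
    signature bursts (which share AUs with ``scale``'s signature) do not
    interfere; otherwise they are drawn at random.  Returns the DSC
    samples for all six emotions plus ``n_dsr`` DSR recordings per
    subject.  Used by experiments that need every band of one scale
    represented regardless of cohort sampling luck.
    """
    from .synth import (
        CohortSample,
        SubjectProfile,
        generate_au_stream,
    )

    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for rank in range(5):
        if isolate:
            bands = {s: SeverityBand.NORMAL for s in SCALES}
        else:
            bands = {s: SeverityBand(int(rng.integers(1, 6))) for s in SCALES}
        bands[scale] = SeverityBand(rank + 1)
        profile = SubjectProfile(subject_id=f"B{seed}-{rank}", bands=bands)
        truth = tuple(bands[s] for s in SCALES)
        for emo in EMOTIONS:
            frames = generate_au_stream(
                profile, emotion=emo, cfg=cfg,
                seed=int(rng.integers(2**31 - 1)),
            )
            samples.append(CohortSample(
                sample_id=f"{profile.subject_id}-{emo}",
                subject_id=profile.subject_id, session=0, dataset="DSC",
                emotion=emo, frames=tuple(frames), truth=truth,
            ))
        for j in range(n_dsr):
            frames = generate_au_stream(
                profile, emotion=None, cfg=cfg,
                seed=int(rng.integers(2**31 - 1)),
            )
            samples.append(CohortSample(
                sample_id=f"{profile.subject_id}-dsr{j}",
                subject_id=profile.subject_id, session=0, dataset="DSR",
                emotion=None, frames=tuple(frames), truth=truth,
            ))
    return samples


def emotion_training_comparison(
    scale: str,
    emotion_filter: Sequence[str],
    seed: int = 0,
    generator_cfg=None,
    train_cfg: TrainingConfig | None = None,
    n_dsr: int = 2,
) -> dict[str, float]:
    """Does emotion-selective training help the matched scale?

    Builds two band-stratified cohorts (five subjects each, one per
    severity band of ``scale``): training and test.  Two networks are
    trained on the training cohort's DSC recordings — one restricted to
    the filtered emotions, one on all six — and both are scored on the
    test cohort's DSR windows by per-window band accuracy for ``scale``.
    Returns {"filtered": acc, "unfiltered": acc}.
    """
    from .synth import GeneratorConfig

    gcfg = generator_cfg or GeneratorConfig(duration=8.0)
    train_cfg = train_cfg or TrainingConfig(max_epochs=2000, seed=seed)
    train_samples = stratified_cohort_samples(scale, gcfg, seed=2 * seed,
                                              n_dsr=0)
    test_samples = [
        s for s in stratified_cohort_samples(scale, gcfg, seed=2 * seed + 1,
                                             n_dsr=n_dsr)
        if s.dataset == "DSR"
    ]
    out: dict[str, float] = {}
    for name, emos in (("filtered", tuple(emotion_filter)),
                       ("unfiltered", None)):
        pool = [s for s in train_samples if s.dataset == "DSC"]
        if emos is not None:
            pool = [s for s in pool if s.emotion in emos]
        windows, targets = _training_set(pool)
        params, _ = train(windows, targets, train_cfg)
        out[name] = per_window_scale_accuracy(params, test_samples, scale)
    return out
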