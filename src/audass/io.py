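"""File formats: AU-stream CSV, SAQ CSV/JSON, mask CSV, model artifacts,
cohort directories.

One canonical CSV dialect is used everywhere: comma-separated, UTF-8,
header required.  Model artifacts are a single versioned JSON document so
that identical training runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .levels import AU_CATALOG, IntensityLevel, SeverityBand
from .matrix import AUFrame
from .network import FFNNParams
from .saq import SAQResponse, score_saq

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# AU streams

def write_au_stream(path, frames, fps: float = 30.0) -> None:
    """Write frames as CSV: frame_index plus 31 letter-level AU columns."""
    rows = []
    for f in frames:
        row = {"frame_index": f.frame_index}
        row.update({au: f.levels[au].name for au in AU_CATALOG})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_au_stream(path, fps: float = 30.0) -> list[AUFrame]:
    """Read an AU-stream CSV; validates columns, levels and frame order."""
    df = pd.read_csv(path, dtype=str)
    expected = ["frame_index", *AU_CATALOG]
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"unknown columns in {path}: {unknown}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    frames: list[AUFrame] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        idx = int(row["frame_index"])
        if idx != pos:
            raise ValueError(
                f"{path}: frame_index {idx} at row {pos + 2} breaks the "
                f"0..n-1 sequence"
            )
        try:
            levels = {au: IntensityLevel.from_letter(row[au])
                      for au in AU_CATALOG}
        except ValueError as exc:
            raise ValueError(f"{path}: row {pos + 2}: {exc}") from None
        frames.append(AUFrame(levels=levels, frame_index=idx, fps=fps))
    return frames


# ---------------------------------------------------------------------------
# SAQ

def read_saq(path) -> SAQResponse:
    """Read a DASS-42 response from CSV (item_index, score) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return SAQResponse(item_scores=tuple(int(s) for s in data["items"]))
    df = pd.read_csv(path)
    if not {"item_index", "score"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns item_index, score")
    scores = [0] * 42
    seen = set()
    for _, row in df.iterrows():
        i = int(row["item_index"])
        if not 1 <= i <= 42 or i in seen:
            raise ValueError(f"{path}: bad or duplicate item_index {i}")
        seen.add(i)
        scores[i - 1] = int(row["score"])
    if len(seen) != 42:
        raise ValueError(f"{path}: expected 42 items, got {len(seen)}")
    return SAQResponse(item_scores=tuple(scores))


def saq_report(response: SAQResponse) -> dict:
    """JSON-ready scoring report for all three scales."""
    result = score_saq(response)
    return {
        scale: {"raw": v["raw"], "band": v["band"].label}
        for scale, v in result.items()
    }


# ---------------------------------------------------------------------------
# masks

def read_mask_csv(path) -> np.ndarray:
    arr = pd.read_csv(path, header=None).to_numpy()
    return (arr != 0).astype(int)


def write_mask_csv(path, mask) -> None:
    pd.DataFrame(np.asarray(mask, dtype=int)).to_csv(
        path, header=False, index=False
    )


# ---------------------------------------------------------------------------
# model artifacts

def save_model(path, params: FFNNParams, fps: float = 30.0,
               kind: str = "dass") -> None:
    """Serialize a trained network as versioned JSON (byte-reproducible)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": kind,
        "layer_sizes": list(params.layer_sizes),
        "activations": ["tanh", "sigmoid", "sigmoid"],
        "fps": fps,
        "catalog": list(AU_CATALOG),
        "weights": [w.tolist() for w in params.weights],
        "output_bias": params.output_bias.tolist(),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path) -> tuple[FFNNParams, dict]:
    """Load a model artifact; returns (params, metadata)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')}"
        )
    params = FFNNParams(
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        output_bias=np.asarray(doc["output_bias"], dtype=float),
    )
    meta = {k: doc[k] for k in ("kind", "layer_sizes", "fps", "catalog")}
    return params, meta


# ---------------------------------------------------------------------------
# cohort directories

def write_cohort(outdir, cohort, samples, config: dict) -> None:
    """Write a simulated cohort: streams/*.csv, saq.csv, profiles.json,
    manifest.json."""
    outdir = Path(outdir)
    (outdir / "streams").mkdir(parents=True, exist_ok=True)
    manifest = {"config": config, "samples": []}
    for s in samples:
        fname = f"streams/{s.sample_id}.csv"
        write_au_stream(outdir / fname, s.frames)
        manifest["samples"].append({
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "session": s.session,
            "dataset": s.dataset,
            "emotion": s.emotion,
            "file": fname,
            "truth": [b.label for b in s.truth],
        })
    profiles = [
        {
            "subject_id": p.subject_id,
            "bands": {k: v.label for k, v in p.bands.items()},
            "disorder": p.disorder,
            "demographic": p.demographic,
        }
        for p in cohort
    ]
    (outdir / "profiles.json").write_text(json.dumps(profiles, indent=1))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


_LABEL_TO_BAND = {b.label: b for b in SeverityBand}


def read_cohort(outdir):
    """Load a cohort directory written by :func:`write_cohort`."""
    from .synth import CohortSample

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    samples = []
    for rec in manifest["samples"]:
        frames = read_au_stream(outdir / rec["file"])
        samples.append(
            CohortSample(
                sample_id=rec["sample_id"],
                subject_id=rec["subject_id"],
                session=rec["session"],
                dataset=rec["dataset"],
                emotion=rec["emotion"],
                frames=tuple(frames),
                truth=tuple(_LABEL_TO_BAND[t] for t in rec["truth"]),
            )
        )
    return samples, manifest
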