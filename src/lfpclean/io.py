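"""Recording readers/writers and the self-describing result bundle.

Recordings arrive as delimited text (channels as rows; comma, tab or
whitespace separated), as a binary matrix in NumPy ``.npy`` format, or as a
MATLAB ``.mat`` matrix.  None of these carry a sampling rate, so ``fs`` is
always supplied by the caller, along with a multiplicative ``scale`` that
fixes wrong magnitude annotations (e.g. 1000 to turn volts into
millivolts).

The result bundle is a single versioned container (an uncompressed zip with
a JSON manifest plus lossless ``.npy`` payloads, written with fixed
timestamps so identical content gives identical bytes).  It stores the
labelling, the trained model, training history, evaluation numbers, the
cleaned recording and the replacement log -- everything needed to re-run
the evaluation with no external state.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import os
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io

from . import __version__
from .errors import BundleVersionError, ParseError
from .forecasters import (
    ForecastModelSpec,
    NeuralForecaster,
    TrainingHistory,
    build_cnn_lstm,
    build_lstm,
)
from .labelling import LabelArray, SegmentSet, ThresholdSpec
from .replacement import ChannelLog, ReplacementLog
from .signal_core import Recording, WindowGrid

__all__ = [
    "read_recording",
    "write_recording",
    "ResultBundle",
    "save_bundle",
    "load_bundle",
    "model_from_bundle",
]

SCHEMA_VERSION = 1
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)  # fixed so identical content -> identical bytes


# ---------------------------------------------------------------------------
# Recording formats
# ---------------------------------------------------------------------------
def _parse_delimited(text: str, path: str) -> np.ndarray:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    first = lines[0]
    if "," in first:
        split = lambda ln: [tok for tok in ln.split(",")]
    elif "\t" in first:
        split = lambda ln: ln.split("\t")
    else:
        split = lambda ln: ln.split()
    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines):
        toks = [t.strip() for t in split(ln) if t.strip()]
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise ParseError(f"{path}: row {i + 1} has {len(toks)} values, expected {width}")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 1}: non-numeric cell ({exc})") from exc
    return np.asarray(rows, dtype=np.float64)


def _load_mat(path: str) -> np.ndarray:
    mat = scipy.io.loadmat(path)
    arrays = {
        k: np.asarray(v)
        for k, v in mat.items()
        if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
        and np.issubdtype(np.asarray(v).dtype, np.number)
    }
    if not arrays:
        raise ParseError(f"{path}: no 2-D numeric matrix found")
    name = max(arrays, key=lambda k: arrays[k].size)
    return arrays[name].astype(np.float64)


def read_recording(
    path: str | Path,
    fs: float,
    format: str = "auto",
    scale: float = 1.0,
    channel_ids: tuple[str, ...] = (),
) -> Recording:
    """Load a channels x samples voltage matrix and apply the scale factor."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if format == "auto":
        format = {".npy": "binary_matrix", ".mat": "mat"}.get(path.suffix.lower(), "delimited")
    if format == "delimited":
        data = _parse_delimited(path.read_text(), str(path))
    elif format == "binary_matrix":
        data = np.load(path, allow_pickle=False).astype(np.float64)
    elif format == "mat":
        data = _load_mat(str(path))
    else:
        raise ParseError(f"unknown recording format {format!r}")
    return Recording(data * scale, fs=fs, scale=scale, channel_ids=channel_ids)


def write_recording(recording: Recording, path: str | Path, format: str = "auto") -> None:
    """Write a recording as delimited text (csv/tsv) or a binary matrix."""
    path = Path(path)
    if format == "auto":
        format = "binary_matrix" if path.suffix.lower() == ".npy" else "delimited"
    if format == "binary_matrix":
        np.save(path, recording.data)
    elif format == "delimited":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        with open(path, "w") as fh:
            for row in recording.data:
                fh.write(sep.join(repr(float(v)) for v in row) + "\n")
    else:
        raise ParseError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------
@dataclass
class ResultBundle:
    """Self-describing pipeline state; every field optional past the header."""

    source: str = ""
    seed: int = 0
    config_hash: str = ""
    tool_version: str = __version__
    fs: float = 0.0
    scale: float = 1.0
    window_seconds: float = 0.0
    recording: Recording | None = None
    threshold: ThresholdSpec | None = None
    labels: LabelArray | None = None
    segments: SegmentSet | None = None
    model_spec: dict | None = None
    model_weights: dict[str, np.ndarray] | None = None
    history: TrainingHistory | None = None
    evaluation: dict | None = None
    test_truth: np.ndarray | None = None
    test_forecasts: np.ndarray | None = None
    cleaned: Recording | None = None
    replacement_log: ReplacementLog | None = None
    extras: dict = field(default_factory=dict)


def _manifest_and_arrays(b: ResultBundle) -> tuple[dict, dict[str, np.ndarray]]:
    arrays: dict[str, np.ndarray] = {}
    man: dict = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": b.tool_version,
        "source": b.source,
        "seed": b.seed,
        "config_hash": b.config_hash,
        "fs": b.fs,
        "scale": b.scale,
        "window_seconds": b.window_seconds,
        "extras": b.extras,
    }
    if b.recording is not None:
        arrays["recording"] = b.recording.data
        man["recording"] = {"fs": b.recording.fs, "scale": b.recording.scale,
                            "channel_ids": list(b.recording.channel_ids)}
    if b.threshold is not None:
        arrays["thresholds"] = b.threshold.thresholds
        man["threshold_provenance"] = b.threshold.provenance
    if b.labels is not None:
        arrays["labels"] = b.labels.labels
        g = b.labels.grid
        man["grid"] = {"window_len": g.window_len, "n_windows": g.n_windows, "fs": g.fs}
    if b.segments is not None:
        s = b.segments
        if s.clean_segments:
            arrays["clean_segments"] = np.stack(s.clean_segments)
        if s.artefactual_segments:
            arrays["artefactual_samples"] = np.stack([a for a, _ in s.artefactual_segments])
            arrays["artefactual_labels"] = np.stack([l for _, l in s.artefactual_segments])
        man["segments"] = {
            "segment_len": s.segment_len, "clean_prefix_len": s.clean_prefix_len,
            "fs": s.fs, "split": list(s.split), "seed": s.seed,
            "clean_positions": [list(p) for p in s.clean_positions],
            "artefactual_positions": [list(p) for p in s.artefactual_positions],
        }
    if b.model_spec is not None:
        man["model_spec"] = b.model_spec
    if b.model_weights is not None:
        for k, v in b.model_weights.items():
            arrays[f"weights/{k}"] = v
        man["weight_keys"] = sorted(b.model_weights)
    if b.history is not None:
        man["history"] = dataclasses.asdict(b.history)
    if b.evaluation is not None:
        man["evaluation"] = b.evaluation
    if b.test_truth is not None:
        arrays["test_truth"] = b.test_truth
    if b.test_forecasts is not None:
        arrays["test_forecasts"] = b.test_forecasts
    if b.cleaned is not None:
        arrays["cleaned"] = b.cleaned.data
        man["cleaned"] = {"fs": b.cleaned.fs, "scale": b.cleaned.scale,
                          "channel_ids": list(b.cleaned.channel_ids)}
    if b.replacement_log is not None:
        man["replacement_log"] = {
            "context_len": b.replacement_log.context_len,
            "model_description": b.replacement_log.model_description,
            "channels": {
                str(ch): {"replaced": log.replaced,
                          "unreplaceable": [list(u) for u in log.unreplaceable]}
                for ch, log in b.replacement_log.channels.items()
            },
        }
    return man, arrays


def save_bundle(bundle: ResultBundle, path: str | Path) -> None:
    """Write the bundle atomically; identical content gives identical bytes."""
    man, arrays = _manifest_and_arrays(bundle)
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    try:
        with zipfile.ZipFile(tmp, "w", compression=zipfile.ZIP_STORED) as zf:
            info = zipfile.ZipInfo("manifest.json", date_time=_ZIP_DATE)
            zf.writestr(info, json.dumps(man, sort_keys=True, indent=1))
            for name in sorted(arrays):
                buf = _io.BytesIO()
                np.save(buf, np.ascontiguousarray(arrays[name]), allow_pickle=False)
                zf.writestr(zipfile.ZipInfo(f"arrays/{name}.npy", date_time=_ZIP_DATE),
                            buf.getvalue())
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def load_bundle(path: str | Path) -> ResultBundle:
    with zipfile.ZipFile(path) as zf:
        man = json.loads(zf.read("manifest.json"))
        if man.get("schema_version") != SCHEMA_VERSION:
            raise BundleVersionError(
                f"bundle schema {man.get('schema_version')} != supported {SCHEMA_VERSION}"
            )
        arrays: dict[str, np.ndarray] = {}
        for entry in zf.namelist():
            if entry.startswith("arrays/") and entry.endswith(".npy"):
                arrays[entry[len("arrays/"):-4]] = np.load(
                    _io.BytesIO(zf.read(entry)), allow_pickle=False
                )
    b = ResultBundle(
        source=man["source"], seed=man["seed"], config_hash=man["config_hash"],
        tool_version=man["tool_version"], fs=man["fs"], scale=man["scale"],
        window_seconds=man["window_seconds"], extras=man.get("extras", {}),
    )
    if "recording" in man:
        r = man["recording"]
        b.recording = Recording(arrays["recording"], fs=r["fs"], scale=r["scale"],
                                channel_ids=tuple(r["channel_ids"]))
    if "thresholds" in arrays:
        b.threshold = ThresholdSpec(arrays["thresholds"], provenance=man["threshold_provenance"])
    if "grid" in man:
        g = man["grid"]
        b.labels = LabelArray(arrays["labels"], WindowGrid(g["window_len"], g["n_windows"], g["fs"]))
    if "segments" in man:
        s = man["segments"]
        clean = list(arrays.get("clean_segments", np.empty((0, 0))))
        art_s = arrays.get("artefactual_samples")
        art_l = arrays.get("artefactual_labels")
        art = list(zip(art_s, art_l)) if art_s is not None else []
        b.segments = SegmentSet(
            clean_segments=clean, artefactual_segments=art,
            segment_len=s["segment_len"], clean_prefix_len=s["clean_prefix_len"],
            fs=s["fs"], split=list(s["split"]), seed=s["seed"],
            clean_positions=[tuple(p) for p in s["clean_positions"]],
            artefactual_positions=[tuple(p) for p in s["artefactual_positions"]],
        )
    b.model_spec = man.get("model_spec")
    if "weight_keys" in man:
        b.model_weights = {k: arrays[f"weights/{k}"] for k in man["weight_keys"]}
    if "history" in man:
        b.history = TrainingHistory(**man["history"])
    b.evaluation = man.get("evaluation")
    b.test_truth = arrays.get("test_truth")
    b.test_forecasts = arrays.get("test_forecasts")
    if "cleaned" in man:
        c = man["cleaned"]
        b.cleaned = Recording(arrays["cleaned"], fs=c["fs"], scale=c["scale"],
                              channel_ids=tuple(c["channel_ids"]))
    if "replacement_log" in man:
        rl = man["replacement_log"]
        log = ReplacementLog(context_len=rl["context_len"],
                             model_description=rl["model_description"])
        for ch, d in rl["channels"].items():
            log.channels[int(ch)] = ChannelLog(
                replaced=list(d["replaced"]),
                unreplaceable=[(u[0], u[1]) for u in d["unreplaceable"]],
            )
        b.replacement_log = log
    return b


def model_from_bundle(bundle: ResultBundle) -> NeuralForecaster:
    """Rebuild the trained network stored in a bundle."""
    if bundle.model_spec is None:
        raise ParseError("bundle has no model")
    ms = bundle.model_spec
    spec = ForecastModelSpec(ms["architecture"], ms["input_len"], ms["output_len"],
                             ms.get("hidden_size"))
    builder = build_lstm if spec.architecture == "lstm" else build_cnn_lstm
    model = builder(spec, seed=ms.get("build_seed", 0))
    if bundle.model_weights is not None:
        model.load_weights(bundle.model_weights)
        model.trained = True
    model.norm_mean = ms.get("norm_mean", 0.0)
    model.norm_std = ms.get("norm_std", 1.0)
    return model
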