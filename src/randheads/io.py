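"""Reading and writing the pipeline's on-disk formats.

Feature/target tables travel as CSV; image sets as directory-per-class
PNG folders (``pos/``, ``neg/``); cross-validation reports as CSV (one
row per fold plus Avr/Std rows) and JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .evaluation import METRIC_NAMES, AggregateReport, MetricsReport, round2
from .features import LabeledImageSet
from .heads import FeatureMatrix

__all__ = [
    "write_features_csv",
    "read_features_csv",
    "write_image_folder",
    "read_image_folder",
    "read_nifti_slices",
    "write_report_csv",
    "write_report_json",
    "write_roc_tsv",
    "write_manifest",
]

POS_DIR = "pos"
NEG_DIR = "neg"


def write_features_csv(X, path, labels=None, header: bool = True) -> None:
    """Write a feature matrix (optionally with a trailing ``label`` column)."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    cols = [f"f{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols)
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    df.to_csv(path, index=False, header=header)


def read_features_csv(path, header: bool = True):
    """Read a feature CSV; returns (FeatureMatrix, labels-or-None)."""
    df = pd.read_csv(path, header=0 if header else None)
    labels = None
    if header and "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return FeatureMatrix(df.to_numpy(dtype=float)), labels


def write_image_folder(data: LabeledImageSet, out_dir) -> None:
    """Write 8-bit grayscale PNGs under ``pos/`` and ``neg/`` subfolders."""
    out = Path(out_dir)
    for sub in (POS_DIR, NEG_DIR):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for img, label, sid in zip(data.images, data.labels, data.ids):
        sub = POS_DIR if label == 1 else NEG_DIR
        arr = (np.clip(np.asarray(img, dtype=float), 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / sub / f"{sid}.png")


def read_image_folder(in_dir) -> LabeledImageSet:
    """Read a ``pos/`` / ``neg/`` PNG or JPEG folder into a LabeledImageSet."""
    root = Path(in_dir)
    images, labels, ids = [], [], []
    for sub, label in ((POS_DIR, 1), (NEG_DIR, 0)):
        d = root / sub
        if not d.is_dir():
            continue
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            arr = np.asarray(Image.open(f).convert("L"), dtype=float) / 255.0
            images.append(arr)
            labels.append(label)
            ids.append(f"{sub}/{f.stem}")
    if not images:
        raise ValueError(f"no images found under {root} (expected pos/ and neg/ subfolders)")
    return LabeledImageSet(images=images, labels=np.array(labels), ids=ids)


def read_nifti_slices(path, axis: int = 2) -> list:
    """Optional NIfTI reader: axial (default) slices normalised to [0, 1]."""
    try:
        import nibabel as nib
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading NIfTI requires the optional 'nibabel' dependency") from e
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    vmin, vmax = vol.min(), vol.max()
    if vmax > vmin:
        vol = (vol - vmin) / (vmax - vmin)
    return [np.take(vol, i, axis=axis) for i in range(vol.shape[axis])]


def _report_rows(reports, agg: AggregateReport):
    rows = []
    for i, r in enumerate(reports, start=1):
        rows.append({"fold": f"F{i}", **{m: round2(getattr(r, m)) for m in METRIC_NAMES}})
    rows.append({"fold": "Avr", **{m: round2(agg.means[m]) for m in METRIC_NAMES}})
    rows.append({"fold": "Std", **{m: round2(agg.stds[m]) for m in METRIC_NAMES}})
    return rows


def write_report_csv(reports, agg: AggregateReport, path) -> None:
    """One row per fold plus Avr/Std rows; metrics displayed at 2 decimals."""
    pd.DataFrame(_report_rows(reports, agg)).to_csv(path, index=False)


def write_report_json(reports, agg: AggregateReport, path) -> None:
    """Full-precision fold metrics and aggregates as JSON."""
    payload = {
        "folds": [r.as_dict() for r in reports],
        "aggregate": agg.as_dict(),
        "display": {
            "folds": [r.as_dict(rounded=True) for r in reports],
            "aggregate": agg.as_dict(rounded=True),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_roc_tsv(scores, labels, path) -> None:
    """Export ROC points (FPR, TPR by descending score threshold) as TSV."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    tp = np.cumsum(y[order] == 1)
    fp = np.cumsum(y[order] == 0)
    n_pos, n_neg = max(tp[-1], 1), max(fp[-1], 1)
    pts = np.column_stack([np.concatenate([[0], fp / n_neg]),
                           np.concatenate([[0], tp / n_pos])])
    np.savetxt(path, pts, delimiter="\t", header="fpr\ttpr", comments="", fmt="%.6f")


def write_manifest(path, command: str, config: dict, seed: int) -> None:
    """Reproducibility manifest: config, its hash, seed and versions."""
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": int(seed),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
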