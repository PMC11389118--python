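"""Reading and writing of score tensors, labels, images and JSON reports.

Score tensors travel either as a long CSV (``sample_id, classifier, class,
score``) or as a NumPy ``.npz`` archive with arrays ``scores`` (N x samples
x L), ``classifier_names``, ``class_names`` and ``sample_ids``.  Labels are a
two-column CSV (``sample_id, label``).  Images are 8/16-bit grayscale
PNG or PGM via imageio.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .fusion import FusionResult, ScoreTensor

__all__ = [
    "read_scores",
    "write_scores_csv",
    "write_scores_npz",
    "read_labels",
    "write_labels",
    "read_image",
    "write_image",
    "fusion_report",
    "write_json",
]


def read_scores(path: str | Path) -> tuple[ScoreTensor, list]:
    """Load a score tensor plus sample ids from CSV or npz, by extension."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as arc:
            tensor = ScoreTensor(
                arc["scores"],
                [str(c) for c in arc["classifier_names"]],
                [str(c) for c in arc["class_names"]],
            )
            return tensor, list(arc["sample_ids"])
    df = pd.read_csv(path)
    required = {"sample_id", "classifier", "class", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score CSV missing columns: {sorted(missing)}")
    classifiers = sorted(df["classifier"].unique())
    classes = sorted(df["class"].unique())
    samples = list(dict.fromkeys(df["sample_id"]))  # first-appearance order
    wide = df.pivot_table(
        index=["classifier", "sample_id"], columns="class", values="score",
        sort=False,
    ).reindex(columns=classes)
    if wide.isna().any().any():
        raise ValueError("score CSV is not a complete classifier x sample x class grid")
    scores = np.stack(
        [wide.loc[c].reindex(samples).to_numpy() for c in classifiers]
    )
    return ScoreTensor(scores, [str(c) for c in classifiers], [str(c) for c in classes]), samples


def write_scores_csv(path: str | Path, tensor: ScoreTensor, sample_ids=None) -> None:
    n, s, l = tensor.scores.shape
    ids = list(sample_ids) if sample_ids is not None else list(range(s))
    rows = {
        "sample_id": np.repeat(np.tile(ids, n), l),
        "classifier": np.repeat(tensor.classifier_names, s * l),
        "class": np.tile(tensor.class_names, n * s),
        "score": tensor.scores.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scores_npz(path: str | Path, tensor: ScoreTensor, sample_ids=None) -> None:
    s = tensor.scores.shape[1]
    ids = np.asarray(sample_ids if sample_ids is not None else np.arange(s))
    np.savez(
        path,
        scores=tensor.scores,
        classifier_names=np.asarray(tensor.classifier_names),
        class_names=np.asarray(tensor.class_names),
        sample_ids=ids,
    )


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sample_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns: {sorted(missing)}")
    return df


def write_labels(path: str | Path, labels, sample_ids=None) -> None:
    labels = np.asarray(labels)
    ids = sample_ids if sample_ids is not None else np.arange(labels.size)
    pd.DataFrame({"sample_id": ids, "label": labels}).to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # collapse an RGB(A) read of a grayscale file
        img = img[..., 0]
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"{path}: expected an integer grayscale image")
    return img


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, img)


def fusion_report(result: FusionResult, config_echo: dict, sample_ids=None,
                  dump_intermediates: bool = False) -> dict:
    """JSON-serialisable report of one fusion run."""
    s = result.fused_class.shape[0]
    ids = list(sample_ids) if sample_ids is not None else list(range(s))
    report = {
        "method": result.method,
        "config": config_echo,
        "fused_class": {str(i): int(c) for i, c in zip(ids, result.fused_class)},
        "fused_score": {str(i): [float(v) for v in row]
                        for i, row in zip(ids, result.fused_score)},
    }
    if dump_intermediates:
        for name in ("frs", "ccfs", "ranks"):
            arr = getattr(result, name)
            if arr is not None:
                report[name] = arr.tolist()
    return report


def write_json(path: str | Path, obj: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
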