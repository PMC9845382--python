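"""On-disk formats: TIFF/NPY images and masks, CSV features/manifests,
JSON sidecars and reports, BED-like boundary files, trace plots.

Images are stored as single-channel float32 TIFF (or .npy), masks as uint8
TIFF/NPY with the label encoding AIR=0, SC=1, EPIDERMIS=2, DERMIS=3; a JSON
sidecar next to each image stores pixel spacings and generation parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InputError
from .phantom import OCTImage, SegmentationMask
from .boundary import ScoreTrace


def save_image(path, image: OCTImage, params: dict | None = None) -> None:
    """Write a float32 TIFF (or .npy) plus a JSON sidecar with spacings."""
    path = Path(path)
    px = np.asarray(image.pixels, dtype=np.float32)
    if path.suffix == ".npy":
        np.save(path, px)
    else:
        tifffile.imwrite(path, px)
    sidecar = {"axial_spacing_um": image.axial_spacing,
               "lateral_spacing_um": image.lateral_spacing,
               "lateral_offset": image.lateral_offset}
    if params:
        sidecar["generation_params"] = params
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_image(path) -> OCTImage:
    path = Path(path)
    if path.suffix == ".npy":
        px = np.load(path)
    else:
        px = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return OCTImage(pixels=np.asarray(px, dtype=np.float32),
                    axial_spacing=meta.get("axial_spacing_um", 5.0),
                    lateral_spacing=meta.get("lateral_spacing_um", 17.0),
                    lateral_offset=meta.get("lateral_offset", 0))


def save_mask(path, mask: SegmentationMask) -> None:
    path = Path(path)
    lab = np.asarray(mask.labels, dtype=np.uint8)
    if path.suffix == ".npy":
        np.save(path, lab)
    else:
        tifffile.imwrite(path, lab)


def load_mask(path) -> SegmentationMask:
    path = Path(path)
    lab = np.load(path) if path.suffix == ".npy" else tifffile.imread(path)
    return SegmentationMask(labels=np.asarray(lab, dtype=np.uint8))


def save_features_csv(path, matrix: np.ndarray, group: str,
                      patch_ids=None) -> None:
    """One row per patch: patch id, group, then the feature columns."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise InputError("feature matrix must be 2D")
    ids = patch_ids if patch_ids is not None else list(range(matrix.shape[0]))
    df = pd.DataFrame(matrix,
                      columns=[f"f{k}" for k in range(matrix.shape[1])])
    df.insert(0, "group", group)
    df.insert(0, "patch_id", ids)
    df.to_csv(path, index=False)


def load_features_csv(path):
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("f")]
    return df[cols].to_numpy(dtype=np.float64), df


def save_scores_csv(path, patch_ids, scores, labels=None) -> None:
    df = pd.DataFrame({"patch_id": patch_ids, "score": scores})
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)


def save_trace_csv(path, trace: ScoreTrace) -> None:
    df = pd.DataFrame({"position": trace.positions, "score": trace.scores})
    if trace.filtered is not None:
        df["filtered"] = trace.filtered
    df.to_csv(path, index=False)


def save_boundaries_bed(path, trace: ScoreTrace, name: str = "trace") -> None:
    """Boundaries as BED-like 0-based half-open single-A-scan intervals."""
    lines = []
    for b in trace.boundaries:
        start = int(np.floor(b.position))
        lines.append(f"{name}\t{start}\t{start + 1}\t{b.direction}"
                     f"\t{b.magnitude:.6g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def plot_trace(path, trace: ScoreTrace, title: str | None = None) -> None:
    """Raw + filtered score trace with its first difference and boundaries."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(trace.positions, trace.scores, "k-", lw=0.8, label="SVM score")
    if trace.filtered is not None:
        ax.plot(trace.positions, trace.filtered, "b-", lw=1.4,
                label="filtered")
        d = np.diff(trace.filtered)
        ax.plot(0.5 * (trace.positions[:-1] + trace.positions[1:]), d,
                "r-", lw=1.0, label="first difference")
    for b in trace.boundaries:
        ax.axvline(b.position, color="red", alpha=0.3)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("lateral position (A-scan)")
    ax.set_ylabel("prediction score")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
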