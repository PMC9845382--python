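"""Per-pixel U-Net activations pooled into patch-level feature vectors.

The trained segmentation network is reused as a feature extractor: a patch
is forward-propagated to the last ReLU of the last decoder stage, where the
network holds N = 16 activations per pixel.  Patch-level predictors are the
means of these activations over pixel groups chosen from the network's own
segmentation of the same patch:

* ``ALL`` — every pixel the network did not label air (air pixels are noise
  dominated and excluded; stratum corneum pixels are included here),
* ``EPIDERMIS`` / ``DERMIS`` — pixels of that layer only (stratum corneum
  excluded: too few pixels to pool reliably),
* ``EPIDERMIS_AND_DERMIS`` — the epidermis mean concatenated with the
  dermis mean, a 32-dimensional vector.

Pooling uses the mean, not the raw sum, so vectors are comparable between
patches with different layer thicknesses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import InputError, DegeneratePatchError
from .phantom import OCTImage, SegmentationMask, AIR, EPIDERMIS, DERMIS
from .segmentation import SegmenterModel

N_PIXEL_FEATURES = 16


class FeatureGroup(str, Enum):
    """Pixel group over which per-pixel activations are averaged."""

    ALL = "all"
    EPIDERMIS = "epidermis"
    DERMIS = "dermis"
    EPIDERMIS_AND_DERMIS = "epidermis_and_dermis"


@dataclass(frozen=True)
class PixelFeatureMap:
    """(depth, lateral, N) activations at the last decoder ReLU (N = 16)."""

    activations: np.ndarray
    source: OCTImage | None = None

    def __post_init__(self):
        act = np.asarray(self.activations)
        if act.ndim != 3:
            raise InputError("activations must be (depth, lateral, N)")
        object.__setattr__(self, "activations", act)

    @property
    def n_features(self) -> int:
        return self.activations.shape[2]


@dataclass(frozen=True)
class FeatureVector:
    """A pooled predictor: 16 values for single groups, 32 for the
    concatenated epidermis+dermis group."""

    values: np.ndarray
    group: FeatureGroup

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise InputError("feature vector must be finite")
        expected = (2 * N_PIXEL_FEATURES
                    if self.group == FeatureGroup.EPIDERMIS_AND_DERMIS
                    else N_PIXEL_FEATURES)
        if v.size != expected:
            raise InputError(
                f"group {self.group.value} expects length {expected}, got {v.size}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def extract_pixel_features(model: SegmenterModel,
                           patch: OCTImage) -> PixelFeatureMap:
    """Forward-propagate a patch to the last decoder ReLU.

    Deterministic; returns a (depth, lateral, 16) non-negative tensor.
    """
    _, feats, _ = model.forward(np.asarray(patch.pixels, dtype=np.float32))
    return PixelFeatureMap(activations=feats[0], source=patch)


_GROUP_SELECTORS = {
    FeatureGroup.ALL: lambda lab: lab != AIR,
    FeatureGroup.EPIDERMIS: lambda lab: lab == EPIDERMIS,
    FeatureGroup.DERMIS: lambda lab: lab == DERMIS,
}


def pool_features(fmap: PixelFeatureMap, mask: SegmentationMask,
                  group: FeatureGroup) -> FeatureVector:
    """Mean of per-pixel activations over one pixel group.

    ``mask`` must be the model's own segmentation of the same patch.  The
    ALL group is every non-air pixel (stratum corneum included); EPIDERMIS
    and DERMIS select only their layer.  An empty group raises
    :class:`DegeneratePatchError` so the caller decides whether to skip the
    patch or fall back to ALL.
    """
    if group == FeatureGroup.EPIDERMIS_AND_DERMIS:
        raise InputError(
            "pool_features pools a single group; use featurize_patch or "
            "concat_features for the concatenated predictor")
    lab = np.asarray(mask.labels)
    if lab.shape != fmap.activations.shape[:2]:
        raise InputError("mask shape does not match feature map")
    sel = _GROUP_SELECTORS[group](lab)
    if not sel.any():
        raise DegeneratePatchError(group.value)
    vals = fmap.activations[sel].mean(axis=0)
    return FeatureVector(values=vals, group=group)


def concat_features(x_e: FeatureVector, x_d: FeatureVector) -> FeatureVector:
    """[epidermis block; dermis block] -> 32-dimensional predictor."""
    if x_e.group != FeatureGroup.EPIDERMIS or x_d.group != FeatureGroup.DERMIS:
        raise InputError(
            f"expected (EPIDERMIS, DERMIS) inputs, got "
            f"({x_e.group.value}, {x_d.group.value})")
    return FeatureVector(values=np.concatenate([x_e.values, x_d.values]),
                         group=FeatureGroup.EPIDERMIS_AND_DERMIS)


def _pool_from_arrays(feats: np.ndarray, labels: np.ndarray,
                      group: FeatureGroup) -> FeatureVector:
    fmap = PixelFeatureMap(activations=feats)
    mask = SegmentationMask(labels=labels)
    if group == FeatureGroup.EPIDERMIS_AND_DERMIS:
        return concat_features(pool_features(fmap, mask, FeatureGroup.EPIDERMIS),
                               pool_features(fmap, mask, FeatureGroup.DERMIS))
    return pool_features(fmap, mask, group)


def featurize_patch(model: SegmenterModel, patch: OCTImage,
                    group: FeatureGroup) -> FeatureVector:
    """Segment, extract per-pixel activations and pool, in one forward pass.

    For ``EPIDERMIS_AND_DERMIS`` the epidermis and dermis means are pooled
    from the same forward pass and concatenated (epidermis block first).
    Propagates :class:`DegeneratePatchError` for empty groups.
    """
    logits, feats, _ = model.forward(np.asarray(patch.pixels, dtype=np.float32))
    labels = np.argmax(logits[0], axis=-1).astype(np.uint8)
    return _pool_from_arrays(feats[0], labels, group)


def featurize_patches(model: SegmenterModel, patches: list[OCTImage],
                      group: FeatureGroup, batch_size: int = 32,
                      on_degenerate: str = "skip"):
    """Featurize many patches with batched forward passes.

    Returns ``(matrix, kept_indices)`` where ``matrix`` has one row per
    successfully featurized patch.  ``on_degenerate``: "skip" drops patches
    with an empty group (with a warning), "raise" propagates the error.
    """
    if on_degenerate not in ("skip", "raise"):
        raise InputError("on_degenerate must be 'skip' or 'raise'")
    rows, kept = [], []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start:start + batch_size]
        X = np.stack([np.asarray(p.pixels, dtype=np.float32) for p in chunk])
        logits, feats, _ = model.forward(X)
        labels = np.argmax(logits, axis=-1).astype(np.uint8)
        for k in range(len(chunk)):
            try:
                fv = _pool_from_arrays(feats[k], labels[k], group)
            except DegeneratePatchError as err:
                if on_degenerate == "raise":
                    raise
                warnings.warn(
                    f"patch {start + k}: skipped ({err})", stacklevel=2)
                continue
            rows.append(fv.values)
            kept.append(start + k)
    if not rows:
        return np.empty((0, 0)), []
    return np.vstack(rows), kept


def featurize_patches_multigroup(model: SegmenterModel,
                                 patches: list[OCTImage],
                                 groups: list[FeatureGroup],
                                 batch_size: int = 32) -> dict:
    """Pool several feature groups from a single forward pass per patch.

    One U-Net forward dominates the cost of featurization, so pooling all
    requested groups from the same activations is far cheaper than separate
    passes.  Returns ``{group: (matrix, kept_indices)}``; a patch degenerate
    for one group is skipped for that group only (with a warning).
    """
    acc = {g: ([], []) for g in groups}
    for start in range(0, len(patches), batch_size):
        chunk = patches[start:start + batch_size]
        X = np.stack([np.asarray(p.pixels, dtype=np.float32) for p in chunk])
        logits, feats, _ = model.forward(X)
        labels = np.argmax(logits, axis=-1).astype(np.uint8)
        for k in range(len(chunk)):
            for g in groups:
                try:
                    fv = _pool_from_arrays(feats[k], labels[k], g)
                except DegeneratePatchError as err:
                    warnings.warn(
                        f"patch {start + k}: skipped for {g.value} ({err})",
                        stacklevel=2)
                    continue
                acc[g][0].append(fv.values)
                acc[g][1].append(start + k)
    return {g: (np.vstack(rows) if rows else np.empty((0, 0)), kept)
            for g, (rows, kept) in acc.items()}
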