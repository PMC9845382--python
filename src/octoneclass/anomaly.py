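"""Synthesized abnormal-tissue operators applied to normal OCT patches.

Three operators turn a normal image into an abnormal one, mimicking the OCT
appearance of the two main nonmelanoma skin cancers and of a disturbed
dermis-epidermis junction (DEJ):

* BCC-like — basal cell carcinoma shadows the signal below the upper
  dermis: every pixel at or below a random onset depth within the dermis is
  scaled to 75% of its original magnitude.
* SCC-like — squamous cell carcinoma shows discrete bright sub-surface
  regions: a random rectangle fully below the detected skin surface is
  scaled by +25%.
* DEJ disruption — the layer structure is erased by normalising every
  A-scan with the image's averaged depth profile (rescaled to preserve the
  overall mean magnitude, so the classifier must respond to structure, not
  global gain).

All operators act on linear magnitude, preserve shape and non-negativity,
and are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, InputError, DegenerateInputError
from .phantom import OCTImage, SegmentationMask, AIR, DERMIS


@dataclass(frozen=True)
class AnomalySpec:
    """Parameters of the three abnormality operators."""

    kind: str = "bcc"  # {"bcc", "scc", "dej"}
    bcc_factor: float = 0.75
    scc_factor: float = 1.25
    scc_region_height: tuple[int, int] = (20, 60)
    scc_region_width: tuple[int, int] = (8, 24)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.kind not in ("bcc", "scc", "dej"):
            raise ParameterError(f"unknown anomaly kind {self.kind!r}")
        # factor 1.0 is admitted as the structural identity (output == input)
        if not (0 < self.bcc_factor <= 1):
            raise ParameterError("bcc_factor must lie in (0, 1]")
        if self.scc_factor < 1:
            raise ParameterError("scc_factor must be >= 1")
        for lo, hi in (self.scc_region_height, self.scc_region_width):
            if lo < 1 or hi < lo:
                raise ParameterError("scc region bounds must satisfy 1 <= lo <= hi")


def _copy_like(image: OCTImage, pixels: np.ndarray) -> OCTImage:
    return OCTImage(pixels=pixels.astype(image.pixels.dtype),
                    axial_spacing=image.axial_spacing,
                    lateral_spacing=image.lateral_spacing,
                    lateral_offset=image.lateral_offset)


def synthesize_bcc(image: OCTImage, mask: SegmentationMask,
                   spec: AnomalySpec | None = None,
                   rng: np.random.Generator | None = None) -> OCTImage:
    """Scale every pixel at or below a random dermis onset row to 75%.

    The onset row is a single shared depth for the whole patch (nodular BCC
    shadows laterally coherently), drawn uniformly from the patch's dermis
    depth range.  Pixels above the onset are returned bitwise unchanged.
    """
    spec = spec or AnomalySpec(kind="bcc")
    spec.validate()
    lab = np.asarray(mask.labels)
    if lab.shape != image.pixels.shape:
        raise InputError("mask shape does not match image")
    dermis_cols = (lab == DERMIS).any(axis=0)
    if not dermis_cols.all():
        raise DegenerateInputError("mask must contain dermis pixels in every column")
    rng = rng or np.random.default_rng(spec.rng_seed)
    dermis_rows = np.nonzero((lab == DERMIS).any(axis=1))[0]
    z0 = int(rng.integers(dermis_rows.min(), dermis_rows.max() + 1))
    out = np.array(image.pixels, copy=True)
    out[z0:, :] = out[z0:, :] * spec.bcc_factor
    return _copy_like(image, out)


def synthesize_scc(image: OCTImage, mask: SegmentationMask,
                   spec: AnomalySpec | None = None,
                   rng: np.random.Generator | None = None) -> OCTImage:
    """Scale a random rectangle fully below the skin surface by +25%.

    The rectangle's height/width are drawn from ``spec`` bounds (clipped to
    what fits below the deepest surface row), its position uniform subject
    to lying below the detected surface in every column.
    """
    spec = spec or AnomalySpec(kind="scc")
    spec.validate()
    lab = np.asarray(mask.labels)
    if lab.shape != image.pixels.shape:
        raise InputError("mask shape does not match image")
    tissue = lab != AIR
    if not tissue.any(axis=0).all():
        raise DegenerateInputError("every column must contain non-air pixels")
    H, W = image.pixels.shape
    # first tissue row per column; the region must start below the deepest one
    surface = tissue.argmax(axis=0)
    top_min = int(surface.max()) + 1
    h_lo, h_hi = spec.scc_region_height
    w_lo, w_hi = spec.scc_region_width
    h_hi = min(h_hi, H - top_min)
    w_hi = min(w_hi, W)
    if h_hi < h_lo or w_hi < w_lo:
        raise ParameterError(
            f"scc region bounds infeasible: need height >= {h_lo} below row "
            f"{top_min} and width >= {w_lo} in a {H}x{W} image")
    rng = rng or np.random.default_rng(spec.rng_seed)
    h = int(rng.integers(h_lo, h_hi + 1))
    w = int(rng.integers(w_lo, w_hi + 1))
    top = int(rng.integers(top_min, H - h + 1))
    left = int(rng.integers(0, W - w + 1))
    out = np.array(image.pixels, copy=True)
    out[top:top + h, left:left + w] = out[top:top + h, left:left + w] * spec.scc_factor
    return _copy_like(image, out)


def synthesize_dej_disruption(image: OCTImage) -> OCTImage:
    """Flatten the layer structure by A-scan depth-profile normalisation.

    Every column is divided by the image's averaged depth profile A(z) and
    rescaled by mean_z(A) so the overall mean magnitude is preserved; a
    column-constant image therefore becomes constant.  eps guards
    zero rows of the profile.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    if px.shape[1] < 2:
        raise InputError("DEJ disruption needs >= 2 A-scans")
    if not px.any():
        raise DegenerateInputError("all-zero image")
    profile = px.mean(axis=1)
    eps = 1e-6 * px.max()
    out = px / np.maximum(profile, eps)[:, None] * profile.mean()
    return _copy_like(image, out)


@dataclass(frozen=True)
class LabeledPatch:
    """One patch of the 4-way dataset with its class and binary label."""

    image: OCTImage
    class_label: str          # {"normal", "bcc", "scc", "dej"}
    is_normal: bool
    source_index: int


def build_anomaly_dataset(normal_patches: list[tuple[OCTImage, SegmentationMask]],
                          specs: dict[str, AnomalySpec] | None = None,
                          seed: int = 0) -> list[LabeledPatch]:
    """Expand normal patches into the 4-way normal/BCC/SCC/DEJ dataset.

    Every input patch contributes itself (labelled normal) plus one BCC, one
    SCC and one DEJ-disrupted variant (labelled abnormal), so the output has
    exactly 4x the input size — e.g. 1116 normal patches expand to 4464.
    Operator randomness is drawn from a single child stream per patch, so
    the dataset is reproducible for a fixed ``seed``.
    """
    if len(normal_patches) == 0:
        raise InputError("need at least one normal patch")
    specs = specs or {"bcc": AnomalySpec(kind="bcc"),
                      "scc": AnomalySpec(kind="scc")}
    out: list[LabeledPatch] = []
    children = np.random.SeedSequence(seed).spawn(len(normal_patches))
    for idx, ((img, mask), child) in enumerate(zip(normal_patches, children)):
        rng = np.random.default_rng(child)
        out.append(LabeledPatch(img, "normal", True, idx))
        out.append(LabeledPatch(
            synthesize_bcc(img, mask, specs["bcc"], rng=rng), "bcc", False, idx))
        out.append(LabeledPatch(
            synthesize_scc(img, mask, specs["scc"], rng=rng), "scc", False, idx))
        out.append(LabeledPatch(
            synthesize_dej_disruption(img), "dej", False, idx))
    return out
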