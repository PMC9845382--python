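"""Synthetic skin OCT phantoms with ground-truth layer masks.

A phantom B-scan emulates the layered appearance of normal skin under OCT:
a signal-free air region above the surface, a thin bright stratum corneum,
an epidermis of reduced brightness with a clearly visible dermis-epidermis
junction (DEJ), and a dermis whose backscatter magnitude decays
exponentially with depth.  Speckle is modelled as i.i.d. multiplicative
unit-mean Rayleigh noise, so the expected image equals the noise-free layer
template.

Axis convention (shared by every module): axis 0 is depth (z), with row 0 on
the shallow/air side; axis 1 is the lateral scan direction (x), one column
per A-scan.  Magnitudes are linear (not log-compressed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ParameterError

# Layer label encoding, used by every module and by mask files on disk.
AIR = 0
STRATUM_CORNEUM = 1
EPIDERMIS = 2
DERMIS = 3

LABEL_NAMES = {AIR: "air", STRATUM_CORNEUM: "stratum_corneum",
               EPIDERMIS: "epidermis", DERMIS: "dermis"}


@dataclass(frozen=True)
class OCTImage:
    """A 2D OCT B-scan magnitude image.

    ``pixels[z, x]`` is a non-negative linear signal magnitude; z increases
    with depth, x with lateral position.  Spacings are in micrometres.
    """

    pixels: np.ndarray
    axial_spacing: float = 5.0
    lateral_spacing: float = 17.0
    lateral_offset: int = 0  # column offset in a parent image, for patches

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ParameterError("OCTImage.pixels must be 2D (depth x lateral)")
        if np.any(px < 0):
            raise ParameterError("OCTImage magnitudes must be >= 0")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def lateral_extent_mm(self) -> float:
        """Physical lateral span in millimetres (width x lateral spacing)."""
        return self.width * self.lateral_spacing / 1000.0


@dataclass(frozen=True)
class SegmentationMask:
    """Per-pixel layer labels for an :class:`OCTImage` (same shape)."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ParameterError("SegmentationMask.labels must be 2D")
        if lab.min() < AIR or lab.max() > DERMIS:
            raise ParameterError("mask labels must lie in {0..3}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of the normal-skin phantom.

    Depth quantities are in pixels (axial spacing ~5 um/px, so e.g. the
    default epidermis of 20 px is ~100 um).  Intensities are linear
    magnitudes on an arbitrary scale with the stratum corneum brightest.
    """

    image_height: int = 256
    image_width: int = 256
    axial_spacing: float = 5.0
    lateral_spacing: float = 17.0
    surface_depth_mean: float = 30.0
    surface_undulation_amp: float = 6.0
    sc_thickness: int = 3
    epidermis_thickness_mean: float = 20.0
    intensity_air: float = 0.04
    intensity_sc: float = 1.0
    intensity_epidermis: float = 0.55
    intensity_dermis_top: float = 0.80
    # ~0.6 mm at 5 um/px: at 1060 nm skin attenuates with mu_eff ~ 1-2/mm,
    # so dermis backscatter stays above the noise floor through the whole
    # 1.28 mm image, as in the normal-skin appearance being emulated
    dermis_decay_length: float = 120.0
    speckle_enabled: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.intensity_sc > self.intensity_epidermis > self.intensity_air >= 0):
            raise ParameterError(
                "intensity ordering violated: require "
                "intensity_sc > intensity_epidermis > intensity_air >= 0")
        if self.intensity_dermis_top <= 0:
            raise ParameterError("intensity_dermis_top must be > 0")
        if self.sc_thickness <= 0 or self.epidermis_thickness_mean <= 0:
            raise ParameterError("layer thicknesses must be > 0")
        if self.dermis_decay_length <= 0:
            raise ParameterError("dermis_decay_length must be > 0")
        if self.surface_undulation_amp < 0:
            raise ParameterError("surface_undulation_amp must be >= 0")
        deepest = (self.surface_depth_mean + self.surface_undulation_amp
                   + self.sc_thickness + self.epidermis_thickness_mean + 1)
        if deepest >= self.image_height:
            raise ParameterError(
                "surface_depth_mean + undulation + sc + epidermis thicknesses + 1 "
                f"({deepest:.0f}) must be < image_height ({self.image_height})")
        if self.image_height < 2 or self.image_width < 1:
            raise ParameterError("image dimensions must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# Rayleigh scale giving unit mean: E[Rayleigh(s)] = s * sqrt(pi/2).
_RAYLEIGH_UNIT_SCALE = float(np.sqrt(2.0 / np.pi))


def _smooth_curve(rng: np.random.Generator, n: int, amp: float) -> np.ndarray:
    """Smooth zero-mean lateral curve bounded by +/- amp, quantised later.

    Low-pass filtered white noise; rescaled so its max |value| equals amp
    (or all zeros when amp == 0 / the noise degenerates).
    """
    if amp == 0 or n == 1:
        return np.zeros(n)
    raw = rng.standard_normal(n + 64)
    smooth = gaussian_filter1d(raw, sigma=max(4.0, n / 16.0), mode="reflect")
    smooth = smooth[32:32 + n]
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros(n)
    return smooth / peak * amp


def generate_phantom(params: PhantomParams) -> tuple[OCTImage, SegmentationMask]:
    """Generate one phantom B-scan and its ground-truth layer mask.

    The noise-free template puts air rows at the noise floor, stratum corneum
    rows at ``intensity_sc``, epidermis rows at ``intensity_epidermis`` and
    dermis rows at ``intensity_dermis_top * exp(-d / dermis_decay_length)``
    where ``d`` is the number of pixels below the DEJ (the first dermis row
    has d = 0).  With ``speckle_enabled`` every pixel is multiplied by an
    i.i.d. unit-mean Rayleigh variate, so the expected image equals the
    template.  Deterministic for a fixed ``rng_seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    H, W = params.image_height, params.image_width

    surface = np.rint(
        params.surface_depth_mean
        + _smooth_curve(rng, W, params.surface_undulation_amp)
    ).astype(int)
    surface = np.clip(surface, 1, H - int(params.sc_thickness)
                      - int(round(params.epidermis_thickness_mean)) - 2)

    sc_bottom = surface + int(params.sc_thickness)
    dej = sc_bottom + int(round(params.epidermis_thickness_mean))

    rows = np.arange(H)[:, None]
    labels = np.full((H, W), AIR, dtype=np.uint8)
    labels[(rows >= surface) & (rows < sc_bottom)] = STRATUM_CORNEUM
    labels[(rows >= sc_bottom) & (rows < dej)] = EPIDERMIS
    labels[rows >= dej] = DERMIS

    template = np.full((H, W), params.intensity_air, dtype=np.float64)
    template[labels == STRATUM_CORNEUM] = params.intensity_sc
    template[labels == EPIDERMIS] = params.intensity_epidermis
    depth_below_dej = rows - dej[None, :]
    dermis_sel = labels == DERMIS
    template[dermis_sel] = (
        params.intensity_dermis_top
        * np.exp(-depth_below_dej / params.dermis_decay_length)
    )[dermis_sel]

    if params.speckle_enabled:
        speckle = rng.rayleigh(scale=_RAYLEIGH_UNIT_SCALE, size=(H, W))
        pixels = template * speckle
    else:
        pixels = template

    image = OCTImage(pixels=pixels.astype(np.float32),
                     axial_spacing=params.axial_spacing,
                     lateral_spacing=params.lateral_spacing)
    return image, SegmentationMask(labels=labels)


def _jitter_params(base: PhantomParams, rng: np.random.Generator,
                   seed: int) -> PhantomParams:
    """Per-image layer-thickness jitter creating inter-image variability.

    Geometry (layer thicknesses, surface depth) varies between images;
    layer intensities and the dermis decay stay at their nominal values —
    they characterise the tissue/instrument, not the anatomy, and the
    abnormality operators are defined as magnitude changes against that
    nominal appearance.
    """
    epi = base.epidermis_thickness_mean * rng.uniform(0.8, 1.2)
    sc = int(rng.integers(2, 6))  # thin, 2-5 px
    surf = base.surface_depth_mean * rng.uniform(0.8, 1.2)
    return replace(base,
                   epidermis_thickness_mean=epi,
                   sc_thickness=sc,
                   surface_depth_mean=surf,
                   rng_seed=seed)


def generate_dataset(params: PhantomParams, n_images: int,
                     seed: int) -> list[tuple[OCTImage, SegmentationMask]]:
    """Generate ``n_images`` phantoms with jittered per-image geometry.

    Each image uses an independent child seed derived deterministically from
    ``(seed, index)`` via :class:`numpy.random.SeedSequence`, so the dataset
    is reproducible and images are statistically independent.
    """
    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_images)
    out = []
    for child in children:
        child_rng = np.random.default_rng(child)
        img_seed = int(child_rng.integers(0, 2**31 - 1))
        p = _jitter_params(params, child_rng, img_seed)
        out.append(generate_phantom(p))
    return out
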