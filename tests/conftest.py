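"""Shared fixtures: phantom data and a trained fixture segmenter.

The expensive artifacts (a U-Net trained on phantom patches, a bank of
pooled feature vectors) are session-scoped: they are trained once at fixed
seeds and shared by the segmentation, feature, classifier, boundary and
acceptance tests.
"""

from __future__ import annotations

import pytest

from octoneclass.phantom import (PhantomParams, SegmentationMask,
                                 generate_dataset)
from octoneclass.segmentation import (TrainConfig, build_unet, train_unet,
                                      split_into_patches)
from octoneclass.features import FeatureGroup, featurize_patches

# seeds are fixed study conditions, not tunables
SEG_TRAIN_SEED = 11
SEG_TEST_SEED = 99
FEATURE_BANK_SEED = 21


def mask_for_patch(mask, patch, width: int = 32) -> SegmentationMask:
    """Ground-truth mask slice matching a patch's lateral offset."""
    sub = mask.labels[:, patch.lateral_offset:patch.lateral_offset + width]
    return SegmentationMask(labels=sub)


def patch_mask_pairs(images_with_masks):
    """Split images into 32-wide patches paired with ground-truth masks."""
    pairs = []
    for img, msk in images_with_masks:
        for p in split_into_patches(img):
            pairs.append((p, mask_for_patch(msk, p)))
    return pairs


@pytest.fixture(scope="session")
def phantom_params():
    return PhantomParams(image_width=256)


@pytest.fixture(scope="session")
def fixture_segmenter(phantom_params):
    """U-Net trained on 32 phantom patches (4 images), fixed seeds.

    Reaches ~0.99 held-out pixel accuracy on phantoms; training takes a
    couple of minutes once per session.
    """
    data = generate_dataset(phantom_params, 4, seed=SEG_TRAIN_SEED)
    pairs = patch_mask_pairs(data)
    model = build_unet(seed=0)
    train_unet(model, [p for p, _ in pairs], [m for _, m in pairs],
               TrainConfig(mini_batch=8, epochs=20, seed=0))
    return model


@pytest.fixture(scope="session")
def heldout_pairs(phantom_params):
    """Phantom patches with ground-truth masks, unseen during training."""
    data = generate_dataset(phantom_params, 2, seed=SEG_TEST_SEED)
    return patch_mask_pairs(data)


@pytest.fixture(scope="session")
def feature_bank(fixture_segmenter):
    """1000 pooled epidermis+dermis feature rows from normal phantoms."""
    params = PhantomParams(image_width=2048)
    data = generate_dataset(params, 16, seed=FEATURE_BANK_SEED)
    patches = [p for img, _ in data for p in split_into_patches(img)]
    X, kept = featurize_patches(fixture_segmenter, patches,
                                FeatureGroup.EPIDERMIS_AND_DERMIS)
    assert X.shape[0] >= 1000, "feature bank unexpectedly small"
    return X[:1000]
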