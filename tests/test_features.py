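"""Feature pooling: oracles, invariances, composition with the network."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octoneclass.exceptions import InputError, DegeneratePatchError
from octoneclass.phantom import (PhantomParams, OCTImage, SegmentationMask,
                                 generate_phantom, AIR, STRATUM_CORNEUM,
                                 EPIDERMIS, DERMIS)
from octoneclass.segmentation import build_unet
from octoneclass.features import (FeatureGroup, PixelFeatureMap,
                                  FeatureVector, extract_pixel_features,
                                  pool_features, concat_features,
                                  featurize_patch, featurize_patches,
                                  N_PIXEL_FEATURES)


def _fmap(values):
    return PixelFeatureMap(activations=np.asarray(values, dtype=np.float64))


def _mask(labels):
    return SegmentationMask(labels=np.asarray(labels, dtype=np.uint8))


class TestPooling:
    def test_constant_map_pools_to_constant(self):
        fmap = _fmap(np.full((4, 4, 16), 2.5))
        mask = _mask(np.full((4, 4), DERMIS))
        fv = pool_features(fmap, mask, FeatureGroup.DERMIS)
        np.testing.assert_allclose(fv.values, 2.5)

    def test_two_pixel_hand_mean(self):
        act = np.zeros((2, 1, 16))
        act[0, 0, :] = 1.0
        act[1, 0, :] = 3.0
        fv = pool_features(_fmap(act), _mask([[EPIDERMIS], [EPIDERMIS]]),
                           FeatureGroup.EPIDERMIS)
        np.testing.assert_allclose(fv.values, 2.0)

    def test_checkerboard_mask_matches_bruteforce_loop(self):
        rng = np.random.default_rng(7)
        act = rng.random((4, 4, 16))
        labels = np.indices((4, 4)).sum(axis=0) % 2 * DERMIS  # checkerboard
        fv = pool_features(_fmap(act), _mask(labels), FeatureGroup.DERMIS)
        # exhaustive loop oracle
        acc, count = np.zeros(16), 0
        for i in range(4):
            for j in range(4):
                if labels[i, j] == DERMIS:
                    acc += act[i, j]
                    count += 1
        np.testing.assert_allclose(fv.values, acc / count, rtol=1e-12)

    def test_all_group_excludes_air_but_keeps_stratum_corneum(self):
        act = np.zeros((3, 1, 16))
        act[0, 0, :] = 100.0   # air: must not contribute
        act[1, 0, :] = 1.0     # SC: included in ALL
        act[2, 0, :] = 3.0     # dermis
        fv = pool_features(_fmap(act),
                           _mask([[AIR], [STRATUM_CORNEUM], [DERMIS]]),
                           FeatureGroup.ALL)
        np.testing.assert_allclose(fv.values, 2.0)

    def test_empty_group_raises_with_group_name(self):
        fmap = _fmap(np.zeros((2, 2, 16)))
        with pytest.raises(DegeneratePatchError) as err:
            pool_features(fmap, _mask(np.full((2, 2), AIR)),
                          FeatureGroup.EPIDERMIS)
        assert err.value.group == "epidermis"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pooled_values_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        act = rng.random((6, 4, 16))
        labels = rng.integers(0, 4, (6, 4))
        labels[0, 0] = DERMIS  # ensure non-empty
        fv = pool_features(_fmap(act), _mask(labels), FeatureGroup.DERMIS)
        sel = labels == DERMIS
        assert np.all(fv.values >= act[sel].min(axis=0) - 1e-12)
        assert np.all(fv.values <= act[sel].max(axis=0) + 1e-12)
        # permuting pixel order within the group leaves the mean unchanged
        perm = rng.permutation(sel.sum())
        manual = act[sel][perm].mean(axis=0)
        np.testing.assert_allclose(fv.values, manual, rtol=1e-12)


class TestConcat:
    def test_order_and_length(self):
        x_e = FeatureVector(np.ones(16), FeatureGroup.EPIDERMIS)
        x_d = FeatureVector(np.full(16, 2.0), FeatureGroup.DERMIS)
        fv = concat_features(x_e, x_d)
        assert len(fv) == 32
        np.testing.assert_array_equal(fv.values[:16], 1.0)
        np.testing.assert_array_equal(fv.values[16:], 2.0)

    def test_wrong_groups_rejected(self):
        x_e = FeatureVector(np.ones(16), FeatureGroup.EPIDERMIS)
        x_d = FeatureVector(np.full(16, 2.0), FeatureGroup.DERMIS)
        with pytest.raises(InputError):
            concat_features(x_d, x_e)  # order sensitivity is type-checked
        with pytest.raises(InputError):
            FeatureVector(np.ones(20), FeatureGroup.EPIDERMIS)


class TestExtraction:
    def test_feature_dimension_is_16(self):
        model = build_unet(seed=0)
        img, _ = generate_phantom(PhantomParams(image_width=32))
        fmap = extract_pixel_features(model, img)
        assert fmap.n_features == N_PIXEL_FEATURES == 16
        assert np.all(fmap.activations >= 0)  # post-ReLU

    def test_zero_input_gives_zero_activations(self):
        # with a linear input transform and zero-initialised biases,
        # conv(0) = 0 and ReLU(0) = 0 propagate to the feature layer
        from octoneclass.segmentation import UNetConfig
        model = build_unet(UNetConfig(input_transform="linear"), seed=1)
        patch = OCTImage(pixels=np.zeros((256, 32), dtype=np.float32))
        fmap = extract_pixel_features(model, patch)
        assert np.all(fmap.activations == 0)

    def test_repeated_extraction_bitwise_equal(self):
        model = build_unet(seed=2)
        img, _ = generate_phantom(PhantomParams(image_width=32, rng_seed=3))
        a = extract_pixel_features(model, img)
        b = extract_pixel_features(model, img)
        assert np.array_equal(a.activations, b.activations)


class TestFeaturizePatch:
    def test_concatenated_group_has_length_32(self, fixture_segmenter):
        img, _ = generate_phantom(PhantomParams(image_width=32, rng_seed=9))
        fv = featurize_patch(fixture_segmenter, img,
                             FeatureGroup.EPIDERMIS_AND_DERMIS)
        assert len(fv) == 32

    def test_composition_equals_manual_pipeline(self, fixture_segmenter):
        from octoneclass.segmentation import segment
        img, _ = generate_phantom(PhantomParams(image_width=32, rng_seed=9))
        fv = featurize_patch(fixture_segmenter, img, FeatureGroup.ALL)
        fmap = extract_pixel_features(fixture_segmenter, img)
        mask = segment(fixture_segmenter, img)
        manual = pool_features(fmap, mask, FeatureGroup.ALL)
        np.testing.assert_allclose(fv.values, manual.values, rtol=1e-6)

    def test_all_air_patch_is_degenerate(self):
        # through a freshly initialised linear-input network (zero biases)
        # a zero patch yields all-zero logits; the argmax tie resolves to
        # AIR everywhere and the ALL group (non-air) is empty
        from octoneclass.segmentation import UNetConfig
        model = build_unet(UNetConfig(input_transform="linear"), seed=0)
        patch = OCTImage(pixels=np.zeros((256, 32), dtype=np.float32))
        with pytest.raises(DegeneratePatchError):
            featurize_patch(model, patch, FeatureGroup.ALL)

    def test_batched_featurization_matches_single(self, fixture_segmenter):
        imgs = [generate_phantom(PhantomParams(image_width=32, rng_seed=s))[0]
                for s in range(3)]
        X, kept = featurize_patches(fixture_segmenter, imgs,
                                    FeatureGroup.EPIDERMIS_AND_DERMIS)
        assert kept == [0, 1, 2]
        for k, img in enumerate(imgs):
            fv = featurize_patch(fixture_segmenter, img,
                                 FeatureGroup.EPIDERMIS_AND_DERMIS)
            np.testing.assert_allclose(X[k], fv.values, rtol=1e-5, atol=1e-6)
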