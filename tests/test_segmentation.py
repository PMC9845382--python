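"""U-Net architecture contracts, patch splitting, training behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from conftest import patch_mask_pairs, SEG_TEST_SEED, SEG_TRAIN_SEED

from octoneclass.exceptions import ParameterError, InputError, DataError
from octoneclass.phantom import (PhantomParams, OCTImage, generate_phantom,
                                 generate_dataset, AIR)
from octoneclass.segmentation import (UNetConfig, TrainConfig, SegmenterModel,
                                      build_unet, train_unet, segment,
                                      split_into_patches, pixel_accuracy)


def _phantom_patch(seed=0, **kw):
    img, mask = generate_phantom(PhantomParams(image_width=32, rng_seed=seed,
                                               **kw))
    return img, mask


class TestPatchSplitting:
    @pytest.mark.parametrize("width,expected", [(2048, 64), (256, 8), (70, 2)])
    def test_patch_counts(self, width, expected):
        img = OCTImage(pixels=np.zeros((256, width), dtype=np.float32))
        patches = split_into_patches(img)
        assert len(patches) == expected
        assert [p.lateral_offset for p in patches] == \
            [32 * k for k in range(expected)]
        assert all(p.width == 32 for p in patches)

    def test_remainder_columns_discarded(self):
        px = np.arange(256 * 70, dtype=np.float32).reshape(256, 70)
        img = OCTImage(pixels=px)
        patches = split_into_patches(img)
        np.testing.assert_array_equal(patches[1].pixels, px[:, 32:64])

    def test_too_narrow_image_rejected(self):
        img = OCTImage(pixels=np.zeros((256, 20), dtype=np.float32))
        with pytest.raises(InputError):
            split_into_patches(img)


class TestArchitecture:
    def test_channel_widths_double_per_stage(self):
        assert UNetConfig().channel_widths == (16, 32, 64, 128, 256)

    def test_forward_shapes_and_feature_channels(self):
        m = build_unet(seed=0)
        x = np.random.default_rng(0).random((256, 32), dtype=np.float32)
        logits, feats, _ = m.forward(x)
        assert logits.shape == (1, 256, 32, 4)
        assert feats.shape == (1, 256, 32, 16)

    def test_indivisible_input_rejected_at_build_time(self):
        with pytest.raises(ParameterError, match="divisible"):
            build_unet(UNetConfig(input_width=24))

    def test_same_seed_gives_identical_initial_weights(self):
        a, b = build_unet(seed=3), build_unet(seed=3)
        for name in a.params:
            assert np.array_equal(a.params[name][0].value,
                                  b.params[name][0].value)

    def test_zero_weights_give_uniform_scores_and_air_tie(self):
        m = build_unet(seed=0)
        for wp, bp in m.params.values():
            wp.value[...] = 0
            bp.value[...] = 0
        img, _ = _phantom_patch()
        logits, _, _ = m.forward(np.asarray(img.pixels))
        assert np.all(logits == logits[..., :1])  # symmetric scores
        # documented tie rule: argmax resolves to the lowest class index
        assert np.all(segment(m, img).labels == AIR)

    def test_checkpoint_roundtrip_preserves_forward_bitwise(self, tmp_path):
        m = build_unet(seed=4)
        img, _ = _phantom_patch(seed=5)
        ref, ref_feats, _ = m.forward(np.asarray(img.pixels))
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = SegmenterModel.load(path)
        out, feats, _ = m2.forward(np.asarray(img.pixels))
        assert np.array_equal(ref, out)
        assert np.array_equal(ref_feats, feats)


class TestTraining:
    def test_memorizes_a_single_patch(self):
        img, mask = _phantom_patch(seed=1)
        m = build_unet(seed=0)
        train_unet(m, [img], [mask],
                   TrainConfig(mini_batch=1, epochs=100, seed=0))
        assert m.train_log[-1] < m.train_log[0]
        assert pixel_accuracy(segment(m, img), mask) > 0.99

    def test_training_is_deterministic(self):
        img, mask = _phantom_patch(seed=2)
        final = []
        for _ in range(2):
            m = build_unet(seed=1)
            train_unet(m, [img], [mask],
                       TrainConfig(mini_batch=1, epochs=2, seed=7))
            final.append({k: v[0].value.copy() for k, v in m.params.items()})
        for name in final[0]:
            assert np.array_equal(final[0][name], final[1][name])

    def test_bad_labels_identify_offending_patch(self):
        img, mask = _phantom_patch(seed=3)

        class RawMask:
            labels = np.asarray(mask.labels).astype(np.int64) + 7

        with pytest.raises(DataError, match="patch 1"):
            train_unet(build_unet(seed=0), [img, img],
                       [mask, RawMask()], TrainConfig(epochs=1))


class TestTrainedFixtureModel:
    def test_heldout_pixel_accuracy(self, fixture_segmenter, heldout_pairs):
        accs = [pixel_accuracy(segment(fixture_segmenter, p), m)
                for p, m in heldout_pairs]
        assert np.mean(accs) >= 0.90

    def test_training_loss_decreased(self, fixture_segmenter):
        log = fixture_segmenter.train_log
        assert log[-1] < log[0]
        # smoothed over epochs the curve trends downward
        smooth = np.convolve(log, np.ones(3) / 3, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_noise_floor_patch_air_region_is_majority_air(self,
                                                          fixture_segmenter):
        # the depth range where air occurs in training (above the deepest
        # surface) must be recognised as air on a pure noise-floor patch;
        # deeper rows are dominated by the learned positional layer prior
        rng = np.random.default_rng(0)
        px = (0.04 * rng.rayleigh(np.sqrt(2 / np.pi), (256, 32))
              ).astype(np.float32)
        mask = segment(fixture_segmenter, OCTImage(pixels=px))
        assert np.mean(mask.labels[:24] == AIR) > 0.5

    def test_speckle_degrades_accuracy_of_clean_trained_model(self,
                                                              phantom_params):
        # train on noise-free phantoms: speckle is then genuine noise and
        # must strictly lower accuracy on the same geometries
        clean_params = replace(phantom_params, speckle_enabled=False)
        train_pairs = patch_mask_pairs(
            generate_dataset(clean_params, 1, seed=SEG_TRAIN_SEED))
        model = build_unet(seed=0)
        train_unet(model, [p for p, _ in train_pairs],
                   [m for _, m in train_pairs],
                   TrainConfig(mini_batch=8, epochs=12, seed=0))
        accs = {}
        for tag, params in (("clean", clean_params),
                            ("speckled", phantom_params)):
            pairs = patch_mask_pairs(
                generate_dataset(params, 2, seed=SEG_TEST_SEED))
            accs[tag] = np.mean([pixel_accuracy(segment(model, p), m)
                                 for p, m in pairs])
        assert accs["clean"] > accs["speckled"]
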