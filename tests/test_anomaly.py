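"""Synthesized abnormality operators: exact scalings and dataset counts."""

import numpy as np
import pytest

from octoneclass.exceptions import (ParameterError, InputError,
                                    DegenerateInputError)
from octoneclass.phantom import (PhantomParams, OCTImage, SegmentationMask,
                                 generate_phantom, DERMIS)
from octoneclass.anomaly import (AnomalySpec, synthesize_bcc, synthesize_scc,
                                 synthesize_dej_disruption,
                                 build_anomaly_dataset)


@pytest.fixture()
def phantom_pair():
    return generate_phantom(PhantomParams(image_width=32, rng_seed=4))


class TestBCC:
    def test_exact_75_percent_below_onset_and_untouched_above(self,
                                                              phantom_pair):
        img, mask = phantom_pair
        out = synthesize_bcc(img, mask, AnomalySpec(kind="bcc", rng_seed=1))
        ratio = out.pixels / img.pixels
        changed_rows = np.nonzero(~np.isclose(ratio, 1.0).all(axis=1))[0]
        z0 = changed_rows.min()
        assert np.allclose(out.pixels[z0:] / img.pixels[z0:], 0.75)
        assert np.array_equal(out.pixels[:z0], img.pixels[:z0])  # bitwise
        # onset lies within the dermis depth range
        dermis_rows = np.nonzero((mask.labels == DERMIS).any(axis=1))[0]
        assert dermis_rows.min() <= z0 <= dermis_rows.max()

    def test_onset_at_first_dermis_row_scales_every_dermis_pixel(self,
                                                                 phantom_pair):
        img, mask = phantom_pair

        class FirstRowRng:
            def integers(self, lo, hi):
                return lo

        out = synthesize_bcc(img, mask, AnomalySpec(kind="bcc"),
                             rng=FirstRowRng())
        # brute-force pixel loop oracle
        z0 = np.nonzero((mask.labels == DERMIS).any(axis=1))[0].min()
        for i in range(img.height):
            for j in range(0, img.width, 7):
                expected = (img.pixels[i, j] * np.float32(0.75)
                            if i >= z0 else img.pixels[i, j])
                assert out.pixels[i, j] == expected

    def test_factor_one_returns_input_bitwise(self, phantom_pair):
        img, mask = phantom_pair
        out = synthesize_bcc(img, mask,
                             AnomalySpec(kind="bcc", bcc_factor=1.0,
                                         rng_seed=0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_missing_dermis_rejected(self, phantom_pair):
        img, mask = phantom_pair
        no_dermis = SegmentationMask(
            labels=np.where(mask.labels == DERMIS, 2, mask.labels))
        with pytest.raises(DegenerateInputError):
            synthesize_bcc(img, no_dermis, AnomalySpec(kind="bcc"))

    def test_mean_dermis_magnitude_strictly_decreases(self, phantom_pair):
        img, mask = phantom_pair
        out = synthesize_bcc(img, mask, AnomalySpec(kind="bcc", rng_seed=2))
        sel = mask.labels == DERMIS
        assert out.pixels[sel].mean() < img.pixels[sel].mean()


class TestSCC:
    def test_exact_125_percent_inside_region_untouched_outside(self,
                                                               phantom_pair):
        img, mask = phantom_pair
        out = synthesize_scc(img, mask, AnomalySpec(kind="scc", rng_seed=3))
        ratio = out.pixels / np.maximum(img.pixels, 1e-30)
        inside = ~np.isclose(ratio, 1.0)
        assert inside.any()
        assert np.allclose(ratio[inside], 1.25)
        assert np.array_equal(out.pixels[~inside], img.pixels[~inside])
        # the changed pixels form a solid rectangle below the surface
        rows = np.nonzero(inside.any(axis=1))[0]
        cols = np.nonzero(inside.any(axis=0))[0]
        assert inside[rows.min():rows.max() + 1,
                      cols.min():cols.max() + 1].all()
        surface = (mask.labels != 0).argmax(axis=0)
        assert rows.min() > surface.max()

    def test_fixed_seed_replays_identical_region(self, phantom_pair):
        img, mask = phantom_pair
        spec = AnomalySpec(kind="scc", rng_seed=11)
        a = synthesize_scc(img, mask, spec)
        b = synthesize_scc(img, mask, spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_infeasible_region_bounds_rejected(self, phantom_pair):
        img, mask = phantom_pair
        with pytest.raises(ParameterError, match="infeasible"):
            synthesize_scc(img, mask,
                           AnomalySpec(kind="scc",
                                       scc_region_width=(64, 64)))

    def test_mean_region_magnitude_strictly_increases(self, phantom_pair):
        img, mask = phantom_pair
        out = synthesize_scc(img, mask, AnomalySpec(kind="scc", rng_seed=5))
        changed = out.pixels != img.pixels
        assert out.pixels[changed].mean() > img.pixels[changed].mean()


class TestDEJDisruption:
    def test_column_constant_image_becomes_constant(self):
        profile = np.linspace(1.0, 0.1, 64, dtype=np.float32)
        img = OCTImage(pixels=np.tile(profile[:, None], (1, 8)))
        out = synthesize_dej_disruption(img)
        np.testing.assert_allclose(out.pixels, profile.mean(), rtol=1e-5)

    def test_overall_mean_magnitude_preserved(self):
        img, _ = generate_phantom(PhantomParams(image_width=32, rng_seed=6))
        out = synthesize_dej_disruption(img)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(),
                                                  rel=1e-5)

    def test_hand_computed_3x3_case(self):
        px = np.array([[2.0, 2.0, 4.0],
                       [1.0, 1.0, 2.0],
                       [0.5, 0.5, 1.0]])
        img = OCTImage(pixels=px)
        out = synthesize_dej_disruption(img)
        profile = px.mean(axis=1)                        # [8/3, 4/3, 2/3]
        expected = px / profile[:, None] * profile.mean()
        np.testing.assert_allclose(out.pixels, expected, rtol=1e-6)
        # the bright third column keeps its contrast; layer profile is gone
        np.testing.assert_allclose(out.pixels[:, 0], out.pixels[0, 0])
        assert np.all(out.pixels[:, 2] > out.pixels[:, 0])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            synthesize_dej_disruption(
                OCTImage(pixels=np.ones((8, 1), dtype=np.float32)))
        with pytest.raises(DegenerateInputError):
            synthesize_dej_disruption(
                OCTImage(pixels=np.zeros((8, 4), dtype=np.float32)))


class TestDatasetBuilder:
    def test_counts_and_labels(self):
        pairs = [generate_phantom(PhantomParams(image_width=32, rng_seed=s))
                 for s in range(3)]
        out = build_anomaly_dataset(pairs, seed=1)
        assert len(out) == 4 * 3
        normal = [lp for lp in out if lp.is_normal]
        abnormal = [lp for lp in out if not lp.is_normal]
        assert len(abnormal) == 3 * len(normal)
        assert sorted({lp.class_label for lp in out}) == \
            ["bcc", "dej", "normal", "scc"]

    def test_1116_patches_expand_to_4464(self):
        # counting logic only; no need to materialise real patches
        img, mask = generate_phantom(PhantomParams(image_width=32, rng_seed=0))
        out = build_anomaly_dataset([(img, mask)] * 1116, seed=2)
        assert len(out) == 4464

    def test_reproducible_and_shape_preserving(self):
        pairs = [generate_phantom(PhantomParams(image_width=32, rng_seed=8))]
        a = build_anomaly_dataset(pairs, seed=5)
        b = build_anomaly_dataset(pairs, seed=5)
        for la, lb in zip(a, b):
            assert np.array_equal(la.image.pixels, lb.image.pixels)
            assert la.image.pixels.shape == (256, 32)
            assert np.all(la.image.pixels >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_anomaly_dataset([], seed=0)
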