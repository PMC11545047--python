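"""Segmentation, pixel exclusion and mean-spectrum extraction on scenes
with known ground truth."""

import numpy as np
import pytest

import berryvis as bv
from berryvis.extraction import (
    InvalidFruitError,
    NoFruitError,
    exclude_defect_edges,
    exclude_glare,
    mean_spectrum,
    pixelwise_classify,
    segment_fruit,
)
from berryvis.preprocess import PipelineSpec, Step, fit_pipeline
from berryvis.chemometrics import dummy_matrix, fit_plsda
from berryvis.types import MASK_BACKGROUND, MASK_GLARE


def jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentation:
    def test_recovers_truth_masks(self, small_cube):
        masks = segment_fruit(small_cube)
        assert len(masks) == 5
        for k, m in enumerate(masks, start=1):
            # masks come back row-major by centroid; match by best overlap
            best = max(
                jaccard(m.all_pixels, small_cube.fruit_ids == j)
                for j in range(1, 6)
            )
            assert best >= 0.95

    def test_deterministic_row_major_order(self, small_cube):
        masks = segment_fruit(small_cube)
        cents = [m.centroid for m in masks]
        assert cents == sorted(cents)

    def test_uniform_dark_cube_raises(self):
        cube = bv.Hypercube(
            np.full((20, 20, 121), 0.02), bv.DEFAULT_GRID
        )
        with pytest.raises(NoFruitError):
            segment_fruit(cube)

    def test_zero_threshold_flags_oversized_component(self, small_cube):
        masks = segment_fruit(small_cube, background_threshold=0.0)
        assert len(masks) == 1
        assert masks[0].oversized
        assert masks[0].all_pixels.all()

    def test_reference_band_must_be_on_grid(self, small_cube):
        with pytest.raises(bv.BerryvisError, match="not on the cube grid"):
            segment_fruit(small_cube, reference_band=803.0)


class TestGlareExclusion:
    def test_matches_generator_glare_mask_exactly(self, small_cube):
        masks = segment_fruit(small_cube)
        truth_glare = small_cube.truth_masks == MASK_GLARE
        for m in masks:
            out = exclude_glare(small_cube, m, 0.98)
            assert np.array_equal(out.excluded_glare, m.all_pixels & truth_glare)

    def test_glare_free_cube_excludes_nothing(self):
        layout = bv.SceneLayout(n_fruit=3, glare_fraction=0.0)
        cube = bv.generate_hypercube(bv.SimulationConfig(seed=4), layout)
        for m in segment_fruit(cube):
            out = exclude_glare(cube, m, 1.05)
            assert not out.excluded_glare.any()

    def test_level_below_fruit_reflectance_invalid(self, small_cube):
        m = segment_fruit(small_cube)[0]
        with pytest.raises(InvalidFruitError):
            exclude_glare(small_cube, m, 0.01)


class TestDefectEdgeExclusion:
    def test_spatially_constant_fruit_no_exclusions(self):
        cube_arr = np.full((30, 30, 121), 0.02)
        cube_arr[5:25, 5:25, :] = 0.5
        cube = bv.Hypercube(cube_arr, bv.DEFAULT_GRID)
        m = segment_fruit(cube)[0]
        out = exclude_defect_edges(cube, m, gradient_threshold=0.05)
        inner = np.zeros((30, 30), dtype=bool)
        inner[7:23, 7:23] = True  # away from the object border itself
        assert not (out.excluded_defect_edge & inner).any()

    def test_sharp_defect_patch_boundary_excluded(self):
        layout = bv.SceneLayout(
            n_fruit=1, classes=(4,), defect_fraction=0.3, glare_fraction=0.0,
            rows=64, cols=64,
        )
        cube = bv.generate_hypercube(bv.SimulationConfig(seed=6), layout)
        m = segment_fruit(cube)[0]
        out = exclude_defect_edges(cube, m, gradient_threshold=0.04)
        defect = cube.truth_masks == bv.types.MASK_DEFECT_TISSUE
        from scipy import ndimage

        boundary = defect ^ ndimage.binary_erosion(defect)
        frac = (out.excluded_defect_edge & boundary).sum() / boundary.sum()
        assert frac >= 0.9

    def test_infinite_threshold_is_identity(self, small_cube):
        m = segment_fruit(small_cube)[0]
        out = exclude_defect_edges(small_cube, m, gradient_threshold=np.inf)
        assert np.array_equal(out.retained, m.retained)


class TestMeanSpectrum:
    def test_identical_pixels_return_that_spectrum(self):
        arr = np.full((10, 10, 121), 0.02)
        arr[2:8, 2:8, :] = 0.4
        cube = bv.Hypercube(arr, bv.DEFAULT_GRID)
        m = segment_fruit(cube)[0]
        assert np.allclose(mean_spectrum(cube, m), 0.4)

    def test_two_pixel_average(self):
        arr = np.full((5, 5, 121), 0.0)
        arr[1, 1, :] = 0.2
        arr[1, 2, :] = 0.4
        cube = bv.Hypercube(arr, bv.DEFAULT_GRID)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[1, 2] = True
        fm = bv.FruitMask(all_pixels=mask, retained=mask.copy())
        assert np.allclose(mean_spectrum(cube, fm), 0.3)

    def test_matches_bruteforce_sum(self, small_cube, rng):
        m = segment_fruit(small_cube)[1]
        got = mean_spectrum(small_cube, m)
        rr, cc = np.nonzero(m.retained)
        brute = sum(small_cube.cube[r, c] for r, c in zip(rr, cc)) / rr.size
        assert np.allclose(got, brute)

    def test_permutation_invariant_linear(self, small_cube):
        m = segment_fruit(small_cube)[0]
        a = mean_spectrum(small_cube, m)
        doubled = bv.Hypercube(
            2.0 * small_cube.cube, small_cube.grid
        )
        assert np.allclose(mean_spectrum(doubled, m), 2.0 * a)


class TestPartitionProperty:
    def test_retained_plus_excluded_equals_all(self, small_cube):
        for m in segment_fruit(small_cube):
            m = exclude_glare(small_cube, m, 0.98)
            m = exclude_defect_edges(small_cube, m, 0.04)
            union = m.retained | m.excluded_glare | m.excluded_defect_edge
            assert np.array_equal(union, m.all_pixels)
            assert not (m.retained & m.excluded_glare).any()
            assert not (m.retained & m.excluded_defect_edge).any()
            assert not (m.excluded_glare & m.excluded_defect_edge).any()


@pytest.fixture(scope="module")
def strong_model():
    from berryvis.simulate import with_effect_scale

    cfg = with_effect_scale(
        bv.SimulationConfig(seed=31, severity_sd=0.2, class_counts=(80, 80, 80, 80)),
        2.0,
    )
    data = bv.generate_spectra(cfg).to_two_class()
    spec = PipelineSpec((Step("msc"), Step("mean_center")))
    fitted, Xt = fit_pipeline(spec, data.reflectance, data.grid)
    Y, cls = dummy_matrix(data.labels)
    model = fit_plsda(Xt, Y, 3, classes=cls)
    model.pipeline = fitted
    return cfg, model


class TestPixelwiseClassification:
    def test_sound_fruit_pixels_mostly_sound(self, strong_model):
        cfg, model = strong_model
        layout = bv.SceneLayout(n_fruit=1, classes=(1,), glare_fraction=0.0,
                                rows=48, cols=48)
        cube = bv.generate_hypercube(cfg, layout)
        m = segment_fruit(cube)
        labels = pixelwise_classify(cube, m[0], model)
        on_fruit = labels[m[0].retained]
        assert (on_fruit == 1).mean() >= 0.9

    def test_background_is_null_label(self, strong_model, small_cube):
        cfg, model = strong_model
        m = exclude_glare(small_cube, segment_fruit(small_cube)[0], 0.98)
        labels = pixelwise_classify(small_cube, m, model)
        assert np.all(labels[small_cube.truth_masks == MASK_BACKGROUND] == 0)
        assert np.all(labels[m.excluded_glare] == 0)

    def test_single_pixel_mask_consistent_with_predict(self, strong_model, small_cube):
        cfg, model = strong_model
        full = exclude_glare(small_cube, segment_fruit(small_cube)[0], 0.98)
        rr, cc = np.nonzero(full.retained)
        one = np.zeros_like(full.retained)
        one[rr[0], cc[0]] = True
        fm = bv.FruitMask(all_pixels=one, retained=one.copy())
        img = pixelwise_classify(small_cube, fm, model)
        spec = small_cube.cube[rr[0], cc[0]][None, :]
        _, lab, _ = model.predict(model.pipeline.transform(spec))
        assert img[rr[0], cc[0]] == lab[0]

    def test_grid_mismatch_rejected(self, strong_model):
        cfg, model = strong_model
        cube = bv.Hypercube(np.full((8, 8, 50), 0.5), np.linspace(400, 890, 50))
        fm_mask = np.ones((8, 8), dtype=bool)
        fm = bv.FruitMask(all_pixels=fm_mask, retained=fm_mask.copy())
        with pytest.raises(bv.BerryvisError, match="grid"):
            pixelwise_classify(cube, fm, model)


def test_extraction_recovers_fruit_level_labels():
    """Extraction + a two-class model on strong effects reproduces the
    fruit-level label for nearly all fruit in fresh scenes."""
    from berryvis.simulate import with_effect_scale

    cfg = with_effect_scale(
        bv.SimulationConfig(seed=77, severity_sd=0.2, class_counts=(60, 60, 60, 60)),
        2.0,
    )
    data = bv.generate_spectra(cfg).to_two_class()
    spec = PipelineSpec((Step("msc"), Step("mean_center")))
    fitted, Xt = fit_pipeline(spec, data.reflectance, data.grid)
    Y, cls = dummy_matrix(data.labels)
    model = fit_plsda(Xt, Y, 3, classes=cls)

    hits = 0
    total = 0
    for seed in (1, 2, 3):
        layout = bv.SceneLayout(n_fruit=6, classes=(1, 2, 3, 4, 1, 3))
        cube = bv.generate_hypercube(
            bv.SimulationConfig(
                seed=seed, severity_sd=0.2,
                effect_carotenoid=cfg.effect_carotenoid,
                effect_water=cfg.effect_water, effect_sugar=cfg.effect_sugar,
            ),
            layout,
        )
        spectra, masks = bv.extract_spectra(cube)
        Xp = fitted.transform(spectra)
        _, pred, _ = model.predict(Xp)
        want = np.where(np.array(layout.classes) > 1, 2, 1)
        # masks are centroid-ordered; map back to fruit ids by overlap
        for m, p in zip(masks, pred):
            ids, counts = np.unique(
                cube.fruit_ids[m.all_pixels], return_counts=True
            )
            fruit_id = int(ids[np.argmax(counts)])
            total += 1
            hits += int(p == want[fruit_id - 1])
    assert hits / total >= 0.95
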