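"""Stitching, region grid, pixel features and the trainable classifier."""

import numpy as np
import pytest

from sourmon.segmentation import (
    FEATURE_NAMES,
    StitchCalibration,
    TileImage,
    build_grid,
    deselect_regions,
    extract_features,
    segment,
    stitch,
    train_classifier,
)
from sourmon.simulate import render_frame


class TestStitch:
    def test_single_tile_identity(self, rendered_frames, tile_geometry):
        fr = rendered_frames[0.3]
        out = stitch([TileImage(**fr.tiles[0])], StitchCalibration())
        assert np.allclose(out, fr.tiles[0]["pixels"], atol=1e-12)

    def test_exact_stage_metadata_reconstructs_canvas(self, rendered_frames, tile_geometry):
        fr = rendered_frames[0.3]
        out = stitch([TileImage(**t) for t in fr.tiles], StitchCalibration())
        assert out.shape == fr.image.shape
        assert np.nanmax(np.abs(out - fr.image)) < 1e-9

    def test_jittered_tiles_refined_within_one_px(self, tile_geometry, cho_config):
        worst = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            fr = render_frame(0.3, tile_geometry, cho_config, rng)
            true = [
                (int(round(t["stage_y_um"])), int(round(t["stage_x_um"]))) for t in fr.tiles
            ]
            jittered = [
                TileImage(
                    t["pixels"],
                    t["stage_x_um"] + int(rng.integers(-3, 4)),
                    t["stage_y_um"] + int(rng.integers(-3, 4)),
                    t["t_h"],
                )
                for t in fr.tiles
            ]
            _, offs = stitch(
                jittered, StitchCalibration(), refine=True, search_radius_px=5, return_offsets=True
            )
            rel_true = [(r - true[0][0], c - true[0][1]) for r, c in true]
            rel_est = [(r - offs[0][0], c - offs[0][1]) for r, c in offs]
            worst = max(
                worst,
                max(
                    max(abs(a - c), abs(b - d))
                    for (a, b), (c, d) in zip(rel_true, rel_est)
                ),
            )
        assert worst <= 1

    def test_mixed_timepoints_rejected(self, rendered_frames):
        fr = rendered_frames[0.3]
        tiles = [TileImage(**fr.tiles[0]), TileImage(fr.tiles[1]["pixels"], 0.0, 0.0, t_h=99.0)]
        with pytest.raises(ValueError, match="acquisition time"):
            stitch(tiles, StitchCalibration())


class TestRegionGrid:
    def test_chamber_grid_region_count(self):
        grid = build_grid((4700, 1500), rows=47, cols=15)
        assert grid.n_regions == 705

    def test_single_region_grid(self):
        grid = build_grid((100, 100), rows=1, cols=1)
        sl = grid.region_slices(0)
        assert sl == (slice(0, 100), slice(0, 100))

    def test_even_partition(self):
        grid = build_grid((100, 100), rows=2, cols=2)
        for i in range(4):
            rs, cs = grid.region_slices(i)
            assert rs.stop - rs.start == 50 and cs.stop - cs.start == 50

    def test_partition_is_disjoint_cover(self):
        grid = build_grid((103, 57), rows=7, cols=5)
        seen = np.zeros((103, 57), dtype=int)
        for i in range(grid.n_regions):
            seen[grid.region_slices(i)] += 1
        assert np.all(seen == 1)

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_grid((10, 10), rows=20, cols=20)

    def test_deselect_bookkeeping(self):
        grid = build_grid((470, 150), rows=47, cols=15)
        out = deselect_regions(grid, border=1, blocks=[(17, 30, 4, 10)])
        assert out.n_regions == 705
        assert out.n_discarded == 198
        assert out.n_retained == 507

    def test_deselect_none_and_nearly_all(self):
        grid = build_grid((90, 90), rows=3, cols=3)
        assert deselect_regions(grid, indices=[]).n_retained == 9
        one = deselect_regions(grid, indices=list(range(8)))
        assert one.n_retained == 1
        with pytest.raises(ValueError, match="no retained"):
            deselect_regions(grid, indices=list(range(9)))


class TestFeatures:
    def test_constant_image_zero_contrast(self):
        stack = extract_features(np.full((32, 32), 0.7))
        names = dict(zip(FEATURE_NAMES, np.moveaxis(stack, -1, 0)))
        for key in ("sd_s3", "sd_s9", "gradient", "log_s2"):
            assert np.allclose(names[key], 0.0, atol=1e-8)

    def test_step_edge_peaks_gradient_on_edge(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        stack = extract_features(img)
        grad = stack[..., FEATURE_NAMES.index("gradient")]
        assert np.argmax(grad[16, :]) in (15, 16)

    def test_halo_rim_has_high_log_response(self, rendered_frames):
        fr = rendered_frames[0.3]
        stack = extract_features(fr.image)
        log = np.abs(stack[..., FEATURE_NAMES.index("log_s2")])
        from skimage.morphology import dilation, disk

        rim = dilation(fr.mask, disk(2)) & ~fr.mask
        assert np.median(log[rim]) > np.median(log[~fr.mask & ~rim])


class TestClassifier:
    def test_separable_toy_problem(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.uniform(size=(64, 64)) > 0.5, 1.0, 0.0)
        clf = train_classifier(img, img > 0.5, seed=0)
        assert clf.holdout_accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self, rendered_frames):
        fr = rendered_frames[0.3]
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(fr.mask.ravel()).reshape(fr.mask.shape)
            clf = train_classifier(fr.image, perm, seed=seed, max_pixels_per_class=4000)
            accs.append(clf.holdout_accuracy)
        assert abs(float(np.mean(accs)) - 0.5) < 0.05

    def test_single_class_labels_rejected(self, rendered_frames):
        fr = rendered_frames[0.3]
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(fr.image, np.zeros_like(fr.mask), seed=0)

    def test_accuracy_on_generated_fixtures(self, trained_classifier):
        assert trained_classifier.holdout_accuracy >= 0.9

    def test_training_deterministic(self, rendered_frames):
        fr = rendered_frames[0.3]
        a = train_classifier(fr.image, fr.mask, seed=3)
        b = train_classifier(fr.image, fr.mask, seed=3)
        assert np.array_equal(a.coef, b.coef)
        assert a.holdout_accuracy == b.holdout_accuracy

    def test_classifier_json_round_trip(self, trained_classifier, tmp_path):
        from sourmon.segmentation import TrainedPixelClassifier

        p = tmp_path / "clf.json"
        trained_classifier.save(p)
        loaded = TrainedPixelClassifier.load(p)
        assert np.array_equal(loaded.coef, trained_classifier.coef)
        assert loaded.feature_names == trained_classifier.feature_names


class TestSegment:
    def test_blank_background_empty_mask(self, trained_classifier, small_geometry, cho_config):
        fr = render_frame(0.0, small_geometry, cho_config, np.random.default_rng(11))
        out = segment(fr.image, trained_classifier)
        assert out.mask.sum() == 0

    def test_confluency_recovered_within_5pct(self, trained_classifier, tile_geometry, cho_config):
        fr = render_frame(0.3, tile_geometry, cho_config, np.random.default_rng(12))
        out = segment(fr.image, trained_classifier)
        assert abs(out.confluency - fr.realized_confluency) <= 0.05

    def test_segmentation_deterministic(self, trained_classifier, rendered_frames):
        fr = rendered_frames[0.5]
        a = segment(fr.image, trained_classifier)
        b = segment(fr.image, trained_classifier)
        assert np.array_equal(a.mask, b.mask)

    def test_sweep_sparse_to_packed(self, trained_classifier, small_geometry, cho_config):
        # detection works from isolated round cells to packed layers
        for c in (0.05, 0.2, 0.4, 0.6, 0.8):
            fr = render_frame(c, small_geometry, cho_config, np.random.default_rng(int(c * 100)))
            out = segment(fr.image, trained_classifier)
            assert abs(out.confluency - fr.realized_confluency) <= 0.05
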