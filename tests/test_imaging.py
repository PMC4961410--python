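"""Image pipeline: stitching, background, segmentation, measurement."""

import numpy as np
import pytest

from ctcgate.core import LayoutError, ValidationError
from ctcgate.imaging import (
    StitchedImage,
    TileGrid,
    extract_features,
    run_image_pipeline,
    segment_nuclei,
    segmentation_scores,
    stitch_tiles,
    subtract_background,
)
from ctcgate.synthetic import (
    ImageParams,
    SampleScenario,
    make_scenario,
    render_sample,
    sample_events,
)

from conftest import make_population

CH1 = ("ch1",)


def one_channel_grid(tiles, offsets):
    return TileGrid(tiles=[t[None].astype(np.uint16) for t in tiles],
                    offsets=offsets, channel_names=CH1)


class TestStitching:
    def test_horizontal_concatenation_without_overlap(self):
        a = np.full((8, 10), 100)
        b = np.full((8, 10), 200)
        out = stitch_tiles(one_channel_grid([a, b], [(0, 0), (0, 10)]))
        assert out.pixels.shape == (1, 8, 20)
        assert (out.pixels[0, :, :10] == 100).all()
        assert (out.pixels[0, :, 10:] == 200).all()

    def test_overlap_averaged(self):
        a = np.full((8, 20), 100)
        b = np.full((8, 20), 200)
        out = stitch_tiles(one_channel_grid([a, b], [(0, 0), (0, 10)]))
        assert (out.pixels[0, :, 10:20] == 150).all()
        assert (out.pixels[0, :, :10] == 100).all()
        assert (out.pixels[0, :, 20:] == 200).all()

    def test_stitched_field_matches_pretiling_oracle(self):
        # noise-free rendering retains the un-tiled field as the oracle
        pops = (make_population("CTC", 1.0, "CTC"),)
        sc = SampleScenario("stitch", "EpCAM", pops, n_cells=30, seed=4)
        events, truth = sample_events(sc)
        params = ImageParams(field_shape=(256, 256), noise_sd=0.0)
        grid, truth = render_sample(events, truth, params)
        out = stitch_tiles(grid)
        np.testing.assert_allclose(out.pixels, np.round(truth.clean_field),
                                   atol=1e-6)

    def test_inconsistent_tiles_rejected(self):
        with pytest.raises(ValidationError):
            one_channel_grid([np.zeros((4, 4)), np.zeros((4, 5))],
                             [(0, 0), (0, 4)])
        with pytest.raises(LayoutError):
            one_channel_grid([np.zeros((4, 4))], [(0, 0), (0, 4)])
        with pytest.raises(LayoutError):
            one_channel_grid([np.zeros((4, 4))], [(-1, 0)])


class TestBackground:
    def test_constant_plus_bright_pixel(self):
        img = np.full((1, 20, 20), 500.0)
        img[0, 3, 3] = 2500.0
        out = subtract_background(StitchedImage(img, CH1))
        assert out.pixels[0, 3, 3] == 2000.0
        assert out.pixels[0, 0, 0] == 0.0
        assert out.provenance["background_estimates"]["ch1"] == 500.0

    def test_offset_invariance(self, rng):
        img = rng.uniform(100, 200, size=(1, 30, 30))
        out1 = subtract_background(StitchedImage(img.copy(), CH1))
        out2 = subtract_background(StitchedImage(img + 77.0, CH1))
        np.testing.assert_allclose(out1.pixels, out2.pixels, atol=1e-3)

    def test_idempotent_on_subtracted_image(self, rng):
        img = np.zeros((1, 40, 40))
        img[0, :5, :5] = rng.uniform(500, 600, size=(5, 5))  # sparse signal
        once = subtract_background(StitchedImage(img, CH1))
        twice = subtract_background(once)
        np.testing.assert_allclose(once.pixels, twice.pixels, atol=1e-9)

    def test_planted_background_recovered(self, rendered_sample):
        _, _, _, grid, params = rendered_sample
        out = subtract_background(stitch_tiles(grid))
        est = out.provenance["background_estimates"]["pck"]
        assert est == pytest.approx(params.background, abs=2 * params.noise_sd)


def _disc_image(centers, radius, shape=(64, 64), value=1000.0):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 < radius ** 2] = value
    return img


def _bfs_components(binary):
    """Independent 8-connected component oracle (BFS flood fill)."""
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for sy in range(h):
        for sx in range(w):
            if binary[sy, sx] and labels[sy, sx] == 0:
                current += 1
                stack = [(sy, sx)]
                labels[sy, sx] = current
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and binary[ny, nx] and labels[ny, nx] == 0):
                                labels[ny, nx] = current
                                stack.append((ny, nx))
    return labels, current


class TestSegmentation:
    def test_two_separated_discs(self):
        img = _disc_image([(16, 16), (48, 48)], radius=6)
        mask = segment_nuclei(img, threshold=500)
        assert mask.max() == 2

    def test_dumbbell_is_split_into_two(self):
        # two discs overlapping by less than a radius
        img = _disc_image([(32, 24), (32, 42)], radius=7, shape=(64, 72))
        mask = segment_nuclei(img, threshold=500, split_min_distance=5)
        assert mask.max() == 2
        # both halves keep roughly a disc's area
        sizes = np.bincount(mask.ravel())[1:]
        assert (sizes > 80).all()

    def test_matches_component_oracle_when_splitting_disabled(self, rng):
        for _ in range(10):
            img = (rng.random((28, 28)) < 0.25) * 1000.0
            mask = segment_nuclei(img, threshold=500, min_area=1,
                                  split_touching=False)
            oracle, n = _bfs_components(img > 0)
            assert mask.max() == n
            # identical membership up to label permutation
            for k in range(1, n + 1):
                ours = np.unique(mask[oracle == k])
                assert len(ours) == 1 and ours[0] > 0

    def test_min_area_filter(self):
        img = _disc_image([(16, 16)], radius=6)
        img[40, 40] = 1000.0  # single-pixel speck
        mask = segment_nuclei(img, threshold=500, min_area=5)
        assert mask.max() == 1

    def test_threshold_above_max_warns_and_returns_empty(self):
        img = _disc_image([(16, 16)], radius=6)
        with pytest.warns(UserWarning):
            mask = segment_nuclei(img, threshold=5000)
        assert mask.max() == 0

    def test_raising_threshold_never_increases_count(self):
        # each nucleus has a uniform amplitude, so a higher cutoff can only
        # drop whole nuclei, never split them
        sc = make_scenario("fig2d_capture", seed=21, n_cells=60,
                           capture_antibody="MUC1")[0]
        events, truth = sample_events(sc)
        params = ImageParams(field_shape=(768, 768), touching_rate=0.0,
                             noise_sd=0.0, background=0.0)
        grid, _ = render_sample(events, truth, params)
        img = stitch_tiles(grid).channel("hoechst")
        counts = [segment_nuclei(img, threshold=t, split_touching=False).max()
                  for t in (500, 1500, 3000, 5000)]
        assert counts[0] == 60
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recall_precision_on_rendered_field(self):
        # non-touching cells at default noise
        sc = make_scenario("fig2d_capture", seed=13, n_cells=150,
                           capture_antibody="EpCAM")[0]
        events, truth = sample_events(sc)
        params = ImageParams(field_shape=(1024, 1024), touching_rate=0.0)
        grid, truth = render_sample(events, truth, params)
        corrected = subtract_background(stitch_tiles(grid))
        mask = segment_nuclei(corrected.channel("hoechst"), threshold=800)
        scores = segmentation_scores(mask, truth.mask)
        assert scores["recall"] >= 0.95
        assert scores["precision"] >= 0.95


class TestFeatureExtraction:
    def test_four_pixel_label_mean(self):
        mask = np.zeros((4, 4), dtype=np.int32)
        mask[0, 0] = mask[0, 1] = mask[1, 0] = mask[1, 1] = 1
        img = np.zeros((1, 4, 4))
        img[0, 0, 0], img[0, 0, 1], img[0, 1, 0], img[0, 1, 1] = 10, 10, 20, 20
        events = extract_features(mask, StitchedImage(img, CH1),
                                  cytoplasm_dilation=0)
        assert len(events) == 1
        assert events.data.loc[0, "ch1"] == pytest.approx(15.0)
        assert events.data.loc[0, "area"] == 4

    def test_matches_brute_force_mean_oracle(self, rng):
        for _ in range(10):
            mask = (rng.random((20, 20)) < 0.3).astype(np.int32)
            from scipy import ndimage
            mask, n = ndimage.label(mask)
            img = rng.uniform(0, 100, size=(1, 20, 20))
            events = extract_features(mask, StitchedImage(img, CH1),
                                      cytoplasm_dilation=0)
            assert len(events) == n
            for k in range(1, n + 1):
                pix = [img[0, y, x] for y in range(20) for x in range(20)
                       if mask[y, x] == k]
                expected = sum(pix) / len(pix)
                got = events.data.loc[events.data.event_id == k, "ch1"].iloc[0]
                assert got == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            extract_features(np.zeros((5, 5), dtype=np.int32),
                             StitchedImage(np.zeros((1, 6, 6)), CH1))

    def test_event_count_equals_label_count(self, rendered_sample):
        _, events, truth, grid, _ = rendered_sample
        out = run_image_pipeline(grid)
        assert len(out) == out.provenance["n_labels"]


class TestPipeline:
    def test_noiseless_single_cell_recovers_planted_mfi(self):
        pops = (make_population("CTC", 1.0, "CTC", radius=(7.0, 1.0),
                                pck=(400.0, 1.0), cd45=(50.0, 1.0)),)
        sc = SampleScenario("clean", "EpCAM", pops, n_cells=1, seed=6)
        events, truth = sample_events(sc)
        params = ImageParams(field_shape=(160, 160), noise_sd=0.0)
        grid, truth = render_sample(events, truth, params)
        out = run_image_pipeline(grid)
        assert len(out) == 1
        # median background estimate is exact here, signal uniform on disc
        assert out.data.loc[0, "pck"] == pytest.approx(400.0, abs=1.0)
        assert out.data.loc[0, "cd45"] == pytest.approx(50.0, abs=1.0)
        # hoechst is diluted by the cytoplasm ring (nuclear-only signal
        # measured over the dilated region)
        nucleus_px = (truth.mask == 1).sum()
        assert 0 < out.data.loc[0, "hoechst"] < 3000.0
        assert out.data.loc[0, "area"] == nucleus_px

    def test_pipeline_deterministic(self, rendered_sample):
        _, _, _, grid, _ = rendered_sample
        a = run_image_pipeline(grid)
        b = run_image_pipeline(grid)
        cols = [c for c in a.data.columns]
        assert a.data[cols].equals(b.data[cols])

    def test_event_and_image_mode_agree_on_bright_channels(self, rendered_sample):
        sc, events, truth, grid, _ = rendered_sample
        from ctcgate.imaging import match_to_truth
        measured = match_to_truth(run_image_pipeline(grid), truth)
        for cls in ("WBC", "MYELOID", "CTC"):
            ev = events.data[events.data.truth_class == cls]
            im = measured.data[measured.data.truth_class == cls]
            if len(ev) < 5 or len(im) < 5:
                continue
            for pop in sc.populations:
                if pop.truth_class != cls:
                    continue
                for ch in ("cd45", "cd11b", "pck", "pdl1"):
                    if pop.channel_params[ch].median < 250:
                        continue  # near noise floor: zero-clipping biases
                    ratio = im[ch].median() / ev[ch].median()
                    assert ratio == pytest.approx(1.0, abs=0.10), (cls, ch)
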