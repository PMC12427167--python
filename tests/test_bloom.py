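"""Bloom-occurrence compositing, lake rasterization and per-lake summaries."""

import numpy as np
import pytest
from shapely.geometry import box

from lakebloom import (
    BloomMask,
    GridTransform,
    Lake,
    apply_threshold,
    bloom_occurrence,
    classify_lake,
    compute_fai,
    lake_mask,
    max_bloom_extent,
)
from lakebloom.bloom import BoRaster


def _mask(values, valid=None, tag="2021-06"):
    values = np.asarray(values, dtype=bool)
    valid = np.ones_like(values, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return BloomMask(values=values, valid=valid, threshold_used=0.02, date_tag=tag)


def test_bo_is_percentage_of_valid_scenes():
    series = [[[1]], [[0]], [[1]], [[1]]]
    bo = bloom_occurrence([_mask(s, tag=f"2021-0{i}") for i, s in enumerate(series, 3)])
    assert bo.values[0, 0] == 75.0
    assert bo.n_scenes_used[0, 0] == 4


def test_bo_zero_when_never_bloomed():
    bo = bloom_occurrence([_mask([[0]], tag=f"2021-0{i}") for i in range(3, 7)])
    assert bo.values[0, 0] == 0.0


def test_bo_denominator_excludes_missing_scenes():
    masks = [
        _mask([[1]], tag="2021-03"),
        _mask([[0]], tag="2021-04"),
        _mask([[0]], valid=[[0]], tag="2021-05"),
        _mask([[0]], valid=[[0]], tag="2021-06"),
    ]
    bo = bloom_occurrence(masks)
    assert bo.values[0, 0] == 50.0
    assert bo.n_scenes_used[0, 0] == 2


def test_bo_missing_everywhere_is_nan():
    bo = bloom_occurrence([_mask([[0]], valid=[[0]])])
    assert np.isnan(bo.values[0, 0])


def test_bo_requires_masks():
    with pytest.raises(ValueError):
        bloom_occurrence([])


GRID = GridTransform.from_origin(0.0, 2000.0, 20.0)  # 100x100 pixels


def test_lake_mask_center_rule_square():
    # 100 m x 100 m square aligned to the 20-m grid -> exactly 5x5 pixels
    lake = Lake("sq", box(200, 200, 300, 300), surface_area_km2=0.01)
    lm = lake_mask(lake, GRID, (100, 100))
    assert lm.sum() == 25


def test_lake_mask_subpixel_pond_centered_on_center():
    # 10 m pond centered on a pixel center claims exactly that pixel
    lake = Lake("pond", box(205, 205, 215, 215), surface_area_km2=1e-4)
    lm = lake_mask(lake, GRID, (100, 100))
    assert lm.sum() == 1


def test_lake_mask_outside_grid_warns(caplog):
    lake = Lake("far", box(5000, 5000, 5100, 5100), surface_area_km2=0.01)
    with caplog.at_level("WARNING"):
        lm = lake_mask(lake, GRID, (100, 100))
    assert lm.sum() == 0
    assert "does not overlap" in caplog.text


def _bo_raster(values):
    vals = np.asarray(values, dtype=float)
    return BoRaster(values=vals, n_scenes_used=np.full(vals.shape, 8), transform=GRID)


def test_mbe_counts_ever_bloomed_pixels():
    vals = np.zeros((100, 100))
    lake = Lake("sq", box(200, 200, 300, 300), surface_area_km2=0.01)
    # 5 of the 25 lake pixels ever bloomed
    vals[86:87, 10:15] = 25.0
    s = max_bloom_extent(_bo_raster(vals), lake, GRID)
    assert s.mbe_km2 == pytest.approx(5 * 400 / 1e6)
    assert s.n_bloom_pixels == 5


def test_mbe_zero_when_no_bloom():
    lake = Lake("sq", box(200, 200, 300, 300), surface_area_km2=0.01)
    s = max_bloom_extent(_bo_raster(np.zeros((100, 100))), lake, GRID)
    assert s.mbe_km2 == 0.0 and s.mean_bo_pct == 0.0 and s.n_bloom_pixels == 0


def test_mean_bo_over_bloomed_pixels_only():
    vals = np.zeros((100, 100))
    lake = Lake("sq", box(200, 200, 300, 300), surface_area_km2=0.01)
    vals[85:86, 10:14] = 50.0  # 4 bloomed pixels at 50%, 21 at 0%
    s = max_bloom_extent(_bo_raster(vals), lake, GRID)
    assert s.mbe_km2 == pytest.approx(0.0016)
    assert s.mean_bo_pct == 50.0


@pytest.mark.parametrize(
    "area,depth,expected",
    [
        (0.5, 2.0, ("small", "shallow")),
        (1.0, 3.0, ("medium", "deep")),
        (100.0, 5.0, ("medium", "deep")),
        (150.0, None, ("large", "unknown")),
    ],
)
def test_size_and_depth_classes(area, depth, expected):
    lake = Lake("x", box(0, 0, 100, 100), surface_area_km2=area, mean_depth_m=depth)
    assert classify_lake(lake) == expected


def _pipeline_masks(bundle, threshold=0.02):
    return [apply_threshold(compute_fai(s, bundle.stack.bands), threshold)
            for s in bundle.stack.scenes]


def test_scene_permutation_invariance(noiseless_region):
    masks = _pipeline_masks(noiseless_region)
    bo_fwd = bloom_occurrence(masks)
    bo_rev = bloom_occurrence(masks[::-1])
    assert np.array_equal(bo_fwd.values, bo_rev.values, equal_nan=True)


def test_pipeline_matches_brute_force_recomputation(noiseless_region):
    """BO and MBE from the vectorized pipeline equal an independent
    per-pixel, per-scene recount on the noiseless fixture."""
    bundle = noiseless_region
    stack = bundle.stack
    wl = {b.role: b.center_wavelength for b in stack.bands}
    idx = {b.role: b.band_index for b in stack.bands}
    frac = (wl["nir"] - wl["red"]) / (wl["swir"] - wl["red"])

    masks = _pipeline_masks(bundle)
    bo = bloom_occurrence(masks)
    bo.transform = stack.transform

    for lake in bundle.lakes:
        lm = lake_mask(lake, stack.transform, stack.shape)
        n_bloom_pixels = 0
        for r, c in np.argwhere(lm):
            hits = 0
            for scene in stack.scenes:
                rr = scene.reflectance
                f = rr[idx["nir"], r, c] - (
                    rr[idx["red"], r, c]
                    + (rr[idx["swir"], r, c] - rr[idx["red"], r, c]) * frac
                )
                hits += f >= 0.02
            expected_bo = 100.0 * hits / len(stack.scenes)
            assert bo.values[r, c] == pytest.approx(expected_bo, abs=0)
            n_bloom_pixels += hits > 0
        s = max_bloom_extent(bo, lake, stack.transform)
        assert s.n_bloom_pixels == n_bloom_pixels
        assert s.mbe_km2 == pytest.approx(n_bloom_pixels * 400 / 1e6, abs=0)


def test_mbe_never_exceeds_rasterized_lake_area(noisy_region):
    bundle = noisy_region
    masks = _pipeline_masks(bundle)
    bo = bloom_occurrence(masks)
    bo.transform = bundle.stack.transform
    for lake in bundle.lakes:
        lm = lake_mask(lake, bundle.stack.transform, bundle.stack.shape)
        s = max_bloom_extent(bo, lake, bundle.stack.transform)
        assert s.n_bloom_pixels <= lm.sum()
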