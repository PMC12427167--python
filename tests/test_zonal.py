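"""Buffer-ring geometry and zonal covariate summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from lakebloom import (
    CovariateRaster,
    GridTransform,
    Lake,
    LakeSet,
    assemble_table,
    build_buffers,
    summarize_covariates,
)
from lakebloom.bloom import LakeBloomSummary
from lakebloom.zonal import BufferRing


def _lakeset(*lakes):
    return LakeSet(lakes=list(lakes), region_tag="t")


CIRCLE = Lake("circle", Point(5000, 5000).buffer(500, quad_segs=64), surface_area_km2=math.pi * 0.25)
SQUARE = Lake("square", box(4000, 4000, 5000, 5000), surface_area_km2=1.0)


def test_circle_ring_area_matches_annulus():
    rings = build_buffers(_lakeset(CIRCLE), [100.0])
    expected = math.pi * (600**2 - 500**2)
    assert rings[0].geometry.area == pytest.approx(expected, rel=0.02)


def test_square_ring_area_matches_minkowski_sum():
    rings = build_buffers(_lakeset(SQUARE), [100.0])
    expected = 4 * (1000 * 100) + math.pi * 100**2
    assert rings[0].geometry.area == pytest.approx(expected, rel=0.02)


def test_rings_exclude_lake_and_nest():
    rings = build_buffers(_lakeset(SQUARE), [100.0, 200.0, 500.0])
    for ring in rings:
        assert ring.geometry.intersection(SQUARE.geometry).area < 1e-6
    r100, r200, r500 = (r.geometry for r in rings)
    assert r200.contains(r100.buffer(-1e-6))
    assert r500.contains(r200.buffer(-1e-6))


def test_annular_mode_rings_are_disjoint():
    rings = build_buffers(_lakeset(SQUARE), [100.0, 200.0], mode="annular")
    assert rings[0].geometry.intersection(rings[1].geometry).area < 1.0
    cumulative = build_buffers(_lakeset(SQUARE), [100.0, 200.0])[1]
    union_area = rings[0].geometry.area + rings[1].geometry.area
    assert union_area == pytest.approx(cumulative.geometry.area, rel=1e-6)


def test_nonpositive_distance_rejected():
    with pytest.raises(ValueError):
        build_buffers(_lakeset(SQUARE), [0.0])


GRID = GridTransform.from_origin(0.0, 10000.0, 50.0)  # 200x200 at 50 m


def _raster(values, name="slope"):
    return CovariateRaster(name=name, values=np.asarray(values, dtype=float), transform=GRID)


def test_constant_raster_mean_is_exact():
    ring = build_buffers(_lakeset(SQUARE), [200.0])[0]
    assert summarize_covariates(ring, _raster(np.full((200, 200), 2.0))) == 2.0


def test_erosion_sum_counts_cells():
    ring = BufferRing("square", 100.0, box(1000, 1000, 1500, 1250))  # 10x5 cells
    val = summarize_covariates(ring, _raster(np.full((200, 200), 2.0), name="erosion"))
    assert val == pytest.approx(2.0 * 50)


def test_nodata_cells_excluded_from_mean():
    vals = np.full((200, 200), np.nan)
    # ring covers one 50-m row of 4 cells: values 1, 2, 3, nodata
    vals[100, 20:23] = [1.0, 2.0, 3.0]
    ring = BufferRing("x", 100.0, box(1000, 4950, 1200, 5000))
    assert summarize_covariates(ring, _raster(vals)) == pytest.approx(2.0)


def test_no_overlap_returns_missing(caplog):
    ring = BufferRing("x", 100.0, box(50000, 50000, 51000, 51000))
    with caplog.at_level("WARNING"):
        assert np.isnan(summarize_covariates(ring, _raster(np.ones((200, 200)))))


def test_cumulative_sum_monotone_in_distance():
    rng = np.random.default_rng(5)
    rast = _raster(rng.uniform(0, 3, size=(200, 200)), name="erosion")
    rings = build_buffers(_lakeset(SQUARE), [100.0, 200.0, 500.0, 1000.0])
    sums = [summarize_covariates(r, rast) for r in rings]
    assert all(b >= a for a, b in zip(sums, sums[1:]))


def _summaries(lake_ids, mbe=0.01):
    return [
        LakeBloomSummary(lake_id=lid, mbe_km2=mbe, mean_bo_pct=50.0, n_bloom_pixels=25,
                         size_class="small", depth_class="shallow", year_tag="all")
        for lid in lake_ids
    ]


def _covariate_stack(shape=(200, 200)):
    rng = np.random.default_rng(7)
    from lakebloom.types import COVARIATE_NAMES

    return [
        CovariateRaster(name=n, values=rng.uniform(1, 2, size=shape), transform=GRID)
        for n in COVARIATE_NAMES
    ]


def test_assemble_table_one_row_per_lake_distance():
    lakes = _lakeset(
        Lake("a", box(2000, 2000, 2600, 2600), 0.36),
        Lake("b", box(5000, 5000, 5600, 5600), 0.36),
        Lake("c", box(8000, 2000, 8600, 2600), 0.36),
    )
    rings = build_buffers(lakes, [100.0, 200.0, 500.0, 1000.0])
    df = assemble_table(lakes, rings, _covariate_stack(), _summaries(["a", "b", "c"]))
    assert len(df) == 12
    assert set(df.columns) >= {"lake_id", "distance_m", "erosion_sum", "slope_mean", "mbe_km2"}


def test_lake_outside_rasters_dropped_with_log(caplog):
    lakes = _lakeset(
        Lake("in", box(2000, 2000, 2600, 2600), 0.36),
        Lake("out", box(60000, 60000, 60600, 60600), 0.36),
    )
    rings = build_buffers(lakes, [100.0, 200.0])
    with caplog.at_level("WARNING"):
        df = assemble_table(lakes, rings, _covariate_stack(), _summaries(["in", "out"]))
    assert sorted(df["lake_id"].unique()) == ["in"]
    assert "dropped 2 row(s)" in caplog.text


def test_missing_bloom_summary_names_the_orphan():
    lakes = _lakeset(Lake("a", box(2000, 2000, 2600, 2600), 0.36))
    rings = build_buffers(lakes, [100.0])
    with pytest.raises(KeyError, match="a"):
        assemble_table(lakes, rings, _covariate_stack(), _summaries(["b"]))


def test_zonal_mean_constant_across_resolutions():
    ring = build_buffers(_lakeset(SQUARE), [300.0])[0]
    for px in (25.0, 50.0, 100.0):
        n = int(10000 / px)
        t = GridTransform.from_origin(0.0, 10000.0, px)
        rast = CovariateRaster(name="slope", values=np.full((n, n), 7.25), transform=t)
        assert summarize_covariates(ring, rast) == 7.25
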