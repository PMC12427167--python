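"""Welch t-tests, compact letter displays and the land-cover table."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from shapely.geometry import box

from lakebloom import (
    CategoricalRaster,
    GridTransform,
    Lake,
    LakeSet,
    letter_display,
    lulc_mbe_table,
    pairwise_letters,
    welch_ttest,
)
from lakebloom.bloom import LakeBloomSummary
from lakebloom.zonal import build_buffers


def test_identical_samples_give_t0_p1():
    c = welch_ttest([1, 2, 3], [1, 2, 3])
    assert c.t_statistic == 0.0
    assert c.p_value == pytest.approx(1.0)
    assert not c.significant


def test_matches_scipy_reference_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(2, 40))
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(2, 40))
        ours = welch_ttest(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert ours.t_statistic == pytest.approx(t, abs=1e-10)
        assert ours.p_value == pytest.approx(p, abs=1e-10)


def test_students_variant_matches_scipy():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=12), rng.normal(1.0, size=9)
    ours = welch_ttest(a, b, equal_var=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    assert ours.t_statistic == pytest.approx(t, abs=1e-12)
    assert ours.p_value == pytest.approx(p, abs=1e-12)


def test_symmetry_and_scale_invariance():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=10), rng.normal(0.5, 2.0, size=14)
    ab, ba = welch_ttest(a, b), welch_ttest(b, a)
    assert ab.p_value == ba.p_value
    assert ab.t_statistic == -ba.t_statistic
    scaled = welch_ttest(3.0 * a, 3.0 * b)
    assert scaled.t_statistic == pytest.approx(ab.t_statistic, rel=1e-12)
    assert scaled.p_value == pytest.approx(ab.p_value, rel=1e-12)


def test_degenerate_samples_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        welch_ttest([0, 0, 0], [0, 0, 0])
    with pytest.raises(ValueError, match="at least 2"):
        welch_ttest([1], [1, 2])


@pytest.mark.parametrize(
    "sig_pairs,expected",
    [
        ([], ["a", "a", "a"]),                       # nothing differs
        ([(0, 1), (0, 2), (1, 2)], ["a", "b", "c"]),  # everything differs
        ([(0, 2), (1, 2)], ["a", "a", "b"]),          # only group 3 differs
    ],
)
def test_letter_display_examples(sig_pairs, expected):
    sig = np.zeros((3, 3), dtype=bool)
    for i, j in sig_pairs:
        sig[i, j] = sig[j, i] = True
    assert letter_display(sig) == expected


def test_letter_display_invariant_exhaustive_up_to_4_groups():
    """Groups share a letter iff their pairwise test is non-significant,
    for every significance pattern on 2-4 groups."""
    for k in (2, 3, 4):
        pairs = list(itertools.combinations(range(k), 2))
        for bits in itertools.product([False, True], repeat=len(pairs)):
            sig = np.zeros((k, k), dtype=bool)
            for (i, j), b in zip(pairs, bits):
                sig[i, j] = sig[j, i] = b
            letters = letter_display(sig)
            for i, j in pairs:
                shares = bool(set(letters[i]) & set(letters[j]))
                assert shares == (not sig[i, j]), (k, bits, letters)


def test_highest_mean_group_gets_earliest_letter():
    sig = np.zeros((3, 3), dtype=bool)
    sig[0, 2] = sig[2, 0] = True
    letters = letter_display(sig, means=[1.0, 5.0, 10.0])
    assert letters[2].startswith("a")


def test_pairwise_letters_end_to_end():
    rng = np.random.default_rng(3)
    samples = {
        "x": rng.normal(0, 1, 30),
        "y": rng.normal(0.1, 1, 30),
        "z": rng.normal(5, 1, 30),
    }
    pairs, letters = pairwise_letters(samples)
    assert len(pairs) == 3
    assert set(letters["x"]) & set(letters["y"])       # x ~ y
    assert not set(letters["x"]) & set(letters["z"])   # z differs


GRID = GridTransform.from_origin(0.0, 10000.0, 50.0)
CLASSES = {1: "forest", 2: "agriculture", 3: "builtup"}


def _summary(lake_id, mbe):
    return LakeBloomSummary(lake_id=lake_id, mbe_km2=mbe, mean_bo_pct=50.0, n_bloom_pixels=1,
                            size_class="small", depth_class="shallow", year_tag="all")


def test_lulc_percentages_and_log10_ha():
    lakes = LakeSet(lakes=[Lake("a", box(4000, 4000, 5000, 5000), 1.0)], region_tag="t")
    rings = build_buffers(lakes, [100.0])
    codes = np.full((200, 200), 2, dtype=float)
    codes[:, :90] = 1  # forest west of x = 4500
    lulc = CategoricalRaster(values=codes, transform=GRID, class_names=CLASSES)
    # MBE of 0.01 km2 = 1 ha -> log10 = 0
    df = lulc_mbe_table(lakes, rings, lulc, [_summary("a", 0.01)])
    assert len(df) == 1
    row = df.iloc[0]
    assert row["log10_mbe_ha"] == pytest.approx(0.0)
    assert row["forest_pct"] + row["agriculture_pct"] + row["builtup_pct"] == pytest.approx(100.0)
    assert 30.0 < row["forest_pct"] < 70.0  # ring straddles the forest boundary


def test_lulc_unknown_codes_ignored_and_zero_mbe_dropped(caplog):
    lakes = LakeSet(
        lakes=[Lake("a", box(4000, 4000, 5000, 5000), 1.0),
               Lake("b", box(7000, 7000, 7500, 7500), 0.25)],
        region_tag="t",
    )
    rings = build_buffers(lakes, [100.0])
    codes = np.full((200, 200), 1, dtype=float)
    codes[::2, :] = 99  # unknown class on alternating rows
    lulc = CategoricalRaster(values=codes, transform=GRID, class_names=CLASSES)
    with caplog.at_level("INFO"):
        df = lulc_mbe_table(lakes, rings, lulc, [_summary("a", 0.04), _summary("b", 0.0)])
    assert df["lake_id"].tolist() == ["a"]           # b dropped: log10(0) undefined
    assert df.iloc[0]["forest_pct"] == pytest.approx(100.0)  # of known-class cells
    assert "unknown LULC code" in caplog.text
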