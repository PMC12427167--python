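"""Group comparisons and the land-cover / bloom-extent table.

Differences in bloom metrics between years, regions and lake classes are
assessed with two-sided independent t-tests.  The unequal-variance (Welch)
variant is the default, matching R's ``t.test``; Student's pooled-variance
variant is available by flag.  Pairwise outcomes are summarized as a
compact letter display: groups sharing a letter are not significantly
different.  No multiple-testing correction is applied across pairwise
comparisons (raw letters are reported); this is recorded in output
metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bloom import LakeBloomSummary
from .types import CategoricalRaster, LakeSet
from .zonal import BufferRing

logger = logging.getLogger(__name__)

__all__ = ["GroupComparison", "welch_ttest", "letter_display", "lulc_mbe_table", "pairwise_letters"]

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    sample_sizes: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    p_value: float
    alpha: float
    significant: bool


def welch_ttest(sample_a, sample_b, alpha: float = DEFAULT_ALPHA, equal_var: bool = False,
                labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided independent t-test (Welch by default).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with
    Welch-Satterthwaite degrees of freedom; ``equal_var=True`` switches to
    Student's pooled-variance form.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise ValueError("both samples have zero variance")
    ma, mb = a.mean(), b.mean()
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        sea2, seb2 = va / na, vb / nb
        se = math.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (sea2**2 / (na - 1) + seb2**2 / (nb - 1))
    t = (ma - mb) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        group_labels=labels,
        sample_sizes=(na, nb),
        means=(float(ma), float(mb)),
        t_statistic=float(t),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
    )


def letter_display(significant: np.ndarray, means=None) -> list[str]:
    """Compact letter display from a pairwise significance matrix.

    ``significant[i, j]`` is True when groups i and j differ significantly.
    Returns one letter string per group such that two groups share a letter
    iff their pairwise test is non-significant (insert-and-absorb).  When
    ``means`` is given, groups are lettered so the highest-mean group gets
    the earliest letter.
    """
    sig = np.asarray(significant, dtype=bool)
    k = sig.shape[0]
    if sig.shape != (k, k) or not np.array_equal(sig, sig.T) or sig.diagonal().any():
        raise ValueError("significance matrix must be symmetric with a False diagonal")

    letters: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            for letter in [L for L in letters if i in L and j in L]:
                letters.remove(letter)
                for new in (letter - {i}, letter - {j}):
                    if not any(new <= L for L in letters):
                        letters.append(new)
    letters = [L for L in letters if L]

    order = np.argsort(-np.asarray(means, dtype=float), kind="stable") if means is not None else np.arange(k)
    rank = {int(g): r for r, g in enumerate(order)}
    letters.sort(key=lambda L: min(rank[g] for g in L))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(k)]
    for idx, L in enumerate(letters):
        for g in L:
            out[g] += alphabet[idx]
    return out


def pairwise_letters(samples: dict[str, np.ndarray], alpha: float = DEFAULT_ALPHA,
                     equal_var: bool = False) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise t-tests between named groups plus their letter display.

    Groups with fewer than 2 observations or zero variance against every
    partner are compared as non-significant (no evidence of difference) and
    logged.
    """
    names = list(samples)
    k = len(names)
    sig = np.zeros((k, k), dtype=bool)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            try:
                cmp_ = welch_ttest(samples[names[i]], samples[names[j]], alpha=alpha,
                                   equal_var=equal_var, labels=(names[i], names[j]))
                sig[i, j] = sig[j, i] = cmp_.significant
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "n_a": cmp_.sample_sizes[0], "n_b": cmp_.sample_sizes[1],
                    "mean_a": cmp_.means[0], "mean_b": cmp_.means[1],
                    "t": cmp_.t_statistic, "p": cmp_.p_value,
                    "significant": cmp_.significant,
                })
            except ValueError as exc:
                logger.warning("pair (%s, %s) untestable: %s", names[i], names[j], exc)
                rows.append({
                    "group_a": names[i], "group_b": names[j],
                    "n_a": len(samples[names[i]]), "n_b": len(samples[names[j]]),
                    "mean_a": float(np.mean(samples[names[i]])) if len(samples[names[i]]) else float("nan"),
                    "mean_b": float(np.mean(samples[names[j]])) if len(samples[names[j]]) else float("nan"),
                    "t": float("nan"), "p": float("nan"), "significant": False,
                })
    means = [float(np.mean(samples[n])) if len(samples[n]) else float("nan") for n in names]
    lets = letter_display(sig, means=means)
    return pd.DataFrame(rows), dict(zip(names, lets))


def lulc_mbe_table(
    lakes: LakeSet,
    rings: list[BufferRing],
    lulc: CategoricalRaster,
    bloom_summaries: list[LakeBloomSummary],
    year_tag: str = "all",
) -> pd.DataFrame:
    """Per-lake land-cover percentages in the 100 m zone vs log10(MBE in ha).

    Percentages are of ring cells with a known class code; unknown codes
    are ignored with a log entry.  Lakes with MBE = 0 are dropped (log10
    undefined) and logged.
    """
    import shapely

    mbe_by_lake = {s.lake_id: s.mbe_km2 for s in bloom_summaries if s.year_tag == year_tag}
    class_names = lulc.class_names or {}
    t = lulc.transform
    rows_out = []
    n_dropped = 0
    for ring in rings:
        mbe = mbe_by_lake.get(ring.lake_id)
        if mbe is None:
            raise KeyError(f"no bloom summary for lake {ring.lake_id!r}")
        if mbe <= 0:
            n_dropped += 1
            continue
        minx, miny, maxx, maxy = ring.geometry.bounds
        r0, c0 = t.rowcol(minx, maxy)
        r1, c1 = t.rowcol(maxx, miny)
        r_lo = max(int(np.floor(min(r0, r1))) - 1, 0)
        r_hi = min(int(np.ceil(max(r0, r1))) + 1, lulc.values.shape[0])
        c_lo = max(int(np.floor(min(c0, c1))) - 1, 0)
        c_hi = min(int(np.ceil(max(c0, c1))) + 1, lulc.values.shape[1])
        xs = t.c + t.a * (np.arange(c_lo, c_hi) + 0.5)
        ys = t.f + t.e * (np.arange(r_lo, r_hi) + 0.5)
        xg, yg = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(ring.geometry, xg.ravel(), yg.ravel()).reshape(xg.shape)
        codes = lulc.values[r_lo:r_hi, c_lo:c_hi][inside].astype(int)
        codes = codes[codes >= 0]
        known = np.isin(codes, list(class_names))
        if (~known).any():
            logger.warning("ring %s: %d cell(s) with unknown LULC code ignored",
                           ring.lake_id, int((~known).sum()))
        codes = codes[known]
        row = {"lake_id": ring.lake_id, "distance_m": ring.distance_m}
        denom = codes.size
        for code, cname in sorted(class_names.items()):
            row[f"{cname}_pct"] = 100.0 * float((codes == code).sum()) / denom if denom else float("nan")
        row["log10_mbe_ha"] = math.log10(mbe * 100.0)  # km^2 -> ha
        rows_out.append(row)
    if n_dropped:
        logger.info("lulc_mbe_table: dropped %d ring(s) with MBE = 0", n_dropped)
    return pd.DataFrame(rows_out)
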