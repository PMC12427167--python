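"""End-to-end orchestration: scenes -> FAI -> BO/MBE -> buffers -> ranking -> stats.

A run is driven by one :class:`RunConfig` and produces a deterministic
directory of artifacts: per-lake bloom summaries per threshold, the
covariate table per buffer distance, importance tables per threshold x
distance x drop-set, group-comparison tables, and a metadata echo of the
configuration.  Identical config + seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bloom import summarize_lakes
from .fai import apply_threshold, compute_fai
from .importance import ForestConfig, fit_importance, sensitivity_rerun
from .io import read_covariate, read_lakes, read_scene_stack, write_table
from .stats import pairwise_letters
from .synthetic import RegionBundle, SimConfig, generate_region
from .types import CovariateRaster, LakeSet, SceneStack
from .zonal import DEFAULT_DISTANCES, assemble_table, build_buffers

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    region_tag: str = "region"
    out_dir: str | Path = "lakebloom_run"
    seed: int = 0
    # synthetic input (used when no paths are given)
    sim: SimConfig | None = None
    # file inputs
    scene_paths: list | None = None
    lakes_path: str | Path | None = None
    covariate_paths: dict[str, str] | None = None
    band_map: dict[str, int] | None = None
    wavelengths: dict[str, float] | None = None
    # analysis settings
    thresholds: tuple[float, ...] = (0.02,)
    buffer_distances: tuple[float, ...] = DEFAULT_DISTANCES
    forest: ForestConfig = field(default_factory=ForestConfig)
    drop_sets: tuple[tuple[str, ...], ...] = ()
    fit_min_rows: int | None = None


def _load_inputs(cfg: RunConfig) -> tuple[SceneStack, LakeSet, list[CovariateRaster]]:
    if cfg.scene_paths is None:
        sim = cfg.sim or SimConfig(seed=cfg.seed, region_tag=cfg.region_tag)
        bundle: RegionBundle = generate_region(sim)
        return bundle.stack, bundle.lakes, bundle.covariates
    if cfg.lakes_path is None or cfg.covariate_paths is None:
        raise ValueError("file-based runs need scene_paths, lakes_path and covariate_paths")
    # validate all covariate paths up front so a run aborts before any heavy work
    for name, path in sorted(cfg.covariate_paths.items()):
        if not Path(path).exists():
            raise FileNotFoundError(f"zonal stage: covariate raster {name!r} not found at {path}")
    stack = read_scene_stack(cfg.scene_paths, cfg.band_map, cfg.wavelengths)
    lakes = read_lakes(cfg.lakes_path, region_tag=cfg.region_tag)
    covs = [read_covariate(path, name=name) for name, path in sorted(cfg.covariate_paths.items())]
    return stack, lakes, covs


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the products and their paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, lakes, covariates = _load_inputs(cfg)
    logger.info("run %s: %d scenes, %d lakes, %d covariates",
                cfg.region_tag, len(stack.scenes), len(lakes), len(covariates))

    if any(t <= 0 for t in cfg.thresholds):
        raise ValueError("thresholds must be positive")
    if list(cfg.buffer_distances) != sorted(set(cfg.buffer_distances)):
        raise ValueError("buffer distances must be strictly increasing")

    fai_rasters = [compute_fai(scene, stack.bands) for scene in stack.scenes]

    products: dict = {"out_dir": out, "summaries": {}, "importance": {}, "comparisons": None}
    summary_frames = []
    for thr in cfg.thresholds:
        masks = [apply_threshold(f, thr) for f in fai_rasters]
        summaries = summarize_lakes(masks, lakes, stack.transform)
        rows = pd.DataFrame(
            [
                {
                    "lake_id": s.lake_id, "year": s.year_tag, "threshold": thr,
                    "n_scenes": s.n_scenes, "mbe_km2": s.mbe_km2,
                    "mean_bo_pct": s.mean_bo_pct, "n_bloom_pixels": s.n_bloom_pixels,
                    "size_class": s.size_class, "depth_class": s.depth_class,
                }
                for s in summaries
            ]
        ).sort_values(["year", "lake_id"], kind="stable").reset_index(drop=True)
        summary_frames.append(rows)
        products["summaries"][thr] = summaries
    summary_df = pd.concat(summary_frames, ignore_index=True)
    write_table(summary_df, out / "lake_bloom_summary.csv")

    rings = build_buffers(lakes, cfg.buffer_distances)
    importance_rows = []
    tables = {}
    for thr in cfg.thresholds:
        table = assemble_table(lakes, rings, covariates, products["summaries"][thr])
        tables[thr] = table
        write_table(table, out / f"covariate_table_thr{thr:g}.csv")
        drop_variants: list[tuple[str, tuple[str, ...]]] = [("full", ())]
        drop_variants += [("drop_" + "_".join(ds), ds) for ds in cfg.drop_sets]
        forest = cfg.forest
        if cfg.fit_min_rows is not None:
            forest = ForestConfig(n_trees=forest.n_trees, mtry=forest.mtry, seed=forest.seed,
                                  min_leaf=forest.min_leaf, min_rows=cfg.fit_min_rows)
        for d in cfg.buffer_distances:
            for variant, drop in drop_variants:
                try:
                    if drop:
                        res = sensitivity_rerun(table, forest, set(drop), distance_m=d)
                    else:
                        res = fit_importance(table, forest, distance_m=d)
                except ValueError as exc:
                    logger.warning("importance fit skipped (thr=%g, d=%g, %s): %s", thr, d, variant, exc)
                    continue
                products["importance"][(thr, d, variant)] = res
                for rank, cov in enumerate(res.ranking, start=1):
                    importance_rows.append({
                        "threshold": thr, "distance_m": d, "variant": variant,
                        "covariate": cov, "raw_importance": res.raw_importance[cov],
                        "relative_pct": res.relative_importance[cov], "rank": rank,
                        "n_rows": res.n_rows, "seed": res.seed,
                    })
    if importance_rows:
        write_table(pd.DataFrame(importance_rows), out / "importance.csv")

    # group comparisons at the primary threshold
    base = summary_frames[0]
    comparison_frames = []
    letter_rows = []
    pooled = base[base["year"] == "all"]
    years = sorted(y for y in base["year"].unique() if y != "all")
    groupings = {"size_class": pooled, "depth_class": pooled}
    if len(years) > 1:
        groupings["year"] = base[base["year"] != "all"]
    for grouping, frame in groupings.items():
        for metric in ("mbe_km2", "mean_bo_pct"):
            samples = {
                str(g): sub[metric].to_numpy()
                for g, sub in frame.groupby(grouping)
                if len(sub) >= 2 and g != "unknown"
            }
            if len(samples) < 2:
                continue
            pairs, letters = pairwise_letters(samples)
            pairs.insert(0, "metric", metric)
            pairs.insert(0, "grouping", grouping)
            comparison_frames.append(pairs)
            for g, letter in letters.items():
                letter_rows.append({"grouping": grouping, "metric": metric, "group": g,
                                    "n": len(samples[g]), "mean": float(np.mean(samples[g])),
                                    "letters": letter})
    if comparison_frames:
        comparisons = pd.concat(comparison_frames, ignore_index=True)
        write_table(comparisons, out / "comparisons.csv")
        write_table(pd.DataFrame(letter_rows), out / "comparison_letters.csv")
        products["comparisons"] = comparisons

    meta = {
        "lakebloom_version": __version__,
        "region_tag": cfg.region_tag,
        "seed": cfg.seed,
        "thresholds": list(cfg.thresholds),
        "buffer_distances": list(cfg.buffer_distances),
        "forest": {"n_trees": cfg.forest.n_trees, "mtry": cfg.forest.mtry,
                   "min_leaf": cfg.forest.min_leaf, "seed": cfg.forest.seed},
        "drop_sets": [list(d) for d in cfg.drop_sets],
        "n_scenes": len(stack.scenes),
        "n_lakes": len(lakes),
        "synthetic": cfg.scene_paths is None,
        "sim": asdict(cfg.sim) if cfg.sim is not None else None,
        "notes": [
            "FAI follows the baseline-subtraction form; threshold comparison is inclusive (>=)",
            "BO denominator = scenes with valid data at the pixel",
            "mean BO averaged over pixels with BO > 0",
            "buffer zones cumulative from the shoreline; lake surface excluded",
            "no multiple-testing correction across pairwise comparisons",
        ],
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    products["tables"] = tables
    products["summary_df"] = summary_df
    return products
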