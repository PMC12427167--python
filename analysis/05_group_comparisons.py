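"""Compare bloom metrics between years and lake classes with t-tests.

Welch t-tests with compact letter displays on MBE and mean BO, grouped by
year, size class and depth class, from the per-lake summary of script 02.
Writes results/05_comparisons.csv and 05_comparison_letters.csv.
"""

from pathlib import Path

import pandas as pd

from lakebloom import pairwise_letters, write_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "02_lake_bloom_summary.csv")
    df = df[df["threshold"] == 0.02]
    pooled = df[df["year"] == "all"]
    per_year = df[df["year"] != "all"].assign(year=lambda d: d["year"].astype(str))

    frames, letter_rows = [], []
    groupings = {"size_class": pooled, "depth_class": pooled, "year": per_year}
    for grouping, frame in groupings.items():
        for metric in ("mbe_km2", "mean_bo_pct"):
            samples = {str(g): s[metric].to_numpy() for g, s in frame.groupby(grouping) if len(s) >= 2}
            if len(samples) < 2:
                continue
            pairs, letters = pairwise_letters(samples)
            pairs.insert(0, "metric", metric)
            pairs.insert(0, "grouping", grouping)
            frames.append(pairs)
            for g, letter in letters.items():
                letter_rows.append({"grouping": grouping, "metric": metric, "group": g,
                                    "n": len(samples[g]), "mean": float(samples[g].mean()),
                                    "letters": letter})
            for row in pairs.itertuples():
                verdict = "differs" if row.significant else "similar"
                print(f"{grouping}/{metric}: {row.group_a} vs {row.group_b} -> "
                      f"t={row.t:.2f}, p={row.p:.3g} ({verdict})")
    write_table(pd.concat(frames, ignore_index=True), RESULTS / "05_comparisons.csv")
    write_table(pd.DataFrame(letter_rows), RESULTS / "05_comparison_letters.csv")
    print(f"wrote -> {RESULTS / '05_comparisons.csv'} and 05_comparison_letters.csv")


if __name__ == "__main__":
    main()
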