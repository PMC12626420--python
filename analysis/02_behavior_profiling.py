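#!/usr/bin/env python
"""Behavioral profiling of the simulated mutant line.

Reads the traces written by 01_simulate_cohorts.py, extracts the named
measure matrix (baseline frequency/magnitude/location measures plus
stimulus-response measures per subset), compares homozygotes to wild-type
siblings per measure (Kruskal-Wallis + SSMD), and rolls the results up into
the replicate-wise category bubble summary.

Expected outcome for the planted effects: an increased-sign frequency
bubble (bout-rate x1.5) and a decreased-sign frequency bubble from the
dark-flash response deficit, reproducible across both replicates.
"""

from pathlib import Path

import pandas as pd

from mescreen import io
from mescreen.behavior_features import build_measure_matrix
from mescreen.behavior_stats import compare_all_measures, summarize_categories
from mescreen.pipeline import default_epochs, default_subsets

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results"
DURATION_S = 1800.0


def main() -> None:
    schedule = io.read_schedule(DATA / "schedule.yaml")
    bubble_rows = []
    for rep in ("1", "2"):
        traces = io.read_traces(DATA / f"traces_rep{rep}.tsv", DATA / f"bursts_rep{rep}.tsv")
        gmap = io.read_genotypes(DATA / f"genotypes_rep{rep}.tsv")
        matrix, metadata = build_measure_matrix(
            traces, default_epochs(DURATION_S), default_subsets(schedule)
        )
        io.write_measure_matrix(matrix, metadata, OUT / f"measures_rep{rep}.tsv")
        results = compare_all_measures(matrix, gmap, group_pair=("-/-", "+/+"))
        results.to_csv(OUT / f"comparisons_rep{rep}.tsv", sep="\t", index=False)
        bubbles = summarize_categories(results)
        bubbles.insert(0, "replicate", rep)
        bubble_rows.append(bubbles)
        n_sig = int(results["significant"].sum())
        print(f"replicate {rep}: {len(results)} measures, {n_sig} significant "
              f"(-/- vs +/+ at alpha 0.05)")
        for _, row in bubbles.iterrows():
            print(f"  {row['category']:<10} {row['sign']:<9} "
                  f"{row['percent_significant']:5.1f}% significant, "
                  f"mean SSMD {row['mean_ssmd']:+.2f}")
    summary = pd.concat(bubble_rows, ignore_index=True)
    summary.to_csv(OUT / "bubble_summary.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'bubble_summary.tsv'}")


if __name__ == "__main__":
    main()
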