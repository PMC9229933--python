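#!/usr/bin/env python
"""Per-bin differential-abundance statistics.

Fits the per-week treatment model on log2-transformed bin values for
every retained bin, adjusts p-values by Benjamini–Hochberg within each
week, and writes results/results_bins.csv. Prints the per-week counts of
significant bins at the two FDR tiers.

Run after 02:  python analysis/03_differential_stats.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from nmrbin import io as nio
from nmrbin.stats import auto_pseudocount, fit_bin_model, tier_counts
from nmrbin.types import results_frame


def main() -> None:
    thresholded = nio.read_bin_matrix(
        ROOT / "scratch" / "bin_matrix_thresholded.csv", stage_tag="thresholded"
    )
    raw = nio.read_bin_matrix(ROOT / "scratch" / "bin_matrix_raw.csv")
    meta = nio.read_metadata(ROOT / "results" / "metadata.csv")
    results = fit_bin_model(thresholded, meta, pseudocount=auto_pseudocount(raw))
    results_frame(results).to_csv(ROOT / "results" / "results_bins.csv", index=False)
    for row in tier_counts(results).itertuples(index=False):
        week, n_bins, n05, n10, n_ns = row
        print(
            f"week {week}: {n_bins} bins tested, {n05} at q<0.05, "
            f"{n10} more at q<0.1, {n_ns} not significant"
        )
    print(f"per-bin results -> {ROOT / 'results' / 'results_bins.csv'}")


if __name__ == "__main__":
    main()
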