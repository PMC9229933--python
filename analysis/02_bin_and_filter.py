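#!/usr/bin/env python
"""Bin the cohort spectra and run the two-stage filter cascade.

Buckets every spectrum onto the 0.01-ppm grid (1000 bins over 0–10 ppm),
removes the 20 water-region interference bins, then drops bins whose
maximum intensity across samples falls below 100,000. Writes the staged
matrices to scratch/ and the cascade trace to results/filter_trace.json.

Run after 01:  python analysis/02_bin_and_filter.py
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from nmrbin import io as nio
from nmrbin.binning import BinSpec, bin_cohort
from nmrbin.filtering import exclude_bins, threshold_filter


def main() -> None:
    cohort = ROOT / "scratch" / "cohort"
    spectra = [nio.read_spectrum(p) for p in sorted((cohort / "spectra").glob("*.csv"))]
    matrix = bin_cohort(spectra, BinSpec())
    excluded, trace = exclude_bins(matrix)
    thresholded, trace = threshold_filter(excluded, trace=trace)

    nio.write_bin_matrix(matrix, ROOT / "scratch" / "bin_matrix_raw.csv")
    nio.write_bin_matrix(thresholded, ROOT / "scratch" / "bin_matrix_thresholded.csv")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "filter_trace.json").write_text(
        json.dumps(trace.to_dict(), indent=2) + "\n"
    )
    print(
        f"cascade: {trace.n_initial} bins -> {trace.n_after_exclusion} after "
        f"water-region exclusion -> {trace.n_after_threshold} above the "
        f"{trace.threshold:,.0f} intensity threshold ({trace.statistic})"
    )


if __name__ == "__main__":
    main()
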