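"""The two-stage bin-filter cascade: interference exclusion, then intensity
thresholding.

Stage 1 removes a fixed list of interference bins (default: the 20 bins of
the suppressed-water region [4.70, 4.90) ppm). Stage 2 keeps a bin iff a
per-bin summary statistic across samples (default: the maximum) is at or
above an intensity threshold (default 100,000). On the study's data this
cascade traces 1000 → 980 → 768 bins. Exclusion always precedes
thresholding; filtering only drops columns, never modifies retained values.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .types import BinMatrix, ConfigurationError, FilterTrace, ValidationError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 100_000.0
THRESHOLD_STATISTICS = ("max", "mean", "median")

#: the suppressed-water interference region, spanning 20 bins at 0.01 ppm
WATER_REGION = (4.70, 4.90)


def default_water_exclusion() -> list[str]:
    """The packaged default exclusion list: the 20 bins of [4.70, 4.90)."""
    text = resources.files("nmrbin.data").joinpath("water_exclusion.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return labels


def load_exclusion_list(path) -> list[str]:
    """Read an exclusion list: one bin label per line, '#' comments allowed."""
    text = Path(path).read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def exclude_bins(
    matrix: BinMatrix,
    excluded: Optional[Sequence[str]] = None,
    strict: bool = True,
) -> tuple[BinMatrix, FilterTrace]:
    """Drop the listed interference bins from the matrix.

    ``excluded`` defaults to the packaged water-region list. In strict
    mode (default) unknown labels are an error naming the offenders; in
    lenient mode they are warned and skipped. The returned trace records
    the n_initial → n_after_exclusion counts.
    """
    if excluded is None:
        excluded = default_water_exclusion()
    excluded = list(excluded)
    present = set(matrix.bin_labels)
    unknown = [lab for lab in excluded if lab not in present]
    if unknown:
        if strict:
            raise ValidationError(
                f"exclusion list contains unknown bin labels: {sorted(unknown)}"
            )
        log.warning("skipping %d unknown exclusion labels: %s", len(unknown), sorted(unknown))
    to_drop = [lab for lab in excluded if lab in present]
    out = BinMatrix(data=matrix.data.drop(columns=to_drop), stage_tag="excluded")
    trace = FilterTrace(
        n_initial=matrix.n_bins,
        excluded_labels=to_drop,
        n_after_exclusion=out.n_bins,
    )
    trace.validate()
    return out, trace


def threshold_filter(
    matrix: BinMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    statistic: str = "max",
    trace: Optional[FilterTrace] = None,
) -> tuple[BinMatrix, FilterTrace]:
    """Keep a bin iff statistic(column across samples) >= threshold (inclusive).

    The default statistic is the per-bin maximum: a bin survives if ANY
    sample shows signal at or above the threshold, the most permissive
    reading, which keeps bins present in only one condition. Expects a
    stage_tag="excluded" matrix (a raw matrix is accepted with a warning).
    Updates and returns the cascade ``trace``.
    """
    if statistic not in THRESHOLD_STATISTICS:
        raise ConfigurationError(
            f"unknown threshold statistic {statistic!r}; choose from {THRESHOLD_STATISTICS}"
        )
    if threshold < 0:
        raise ConfigurationError("threshold must be non-negative")
    if matrix.stage_tag == "raw":
        log.warning("threshold filter applied to a raw (pre-exclusion) matrix")
    stat = getattr(matrix.data, statistic)(axis=0)
    keep = stat >= threshold
    out = BinMatrix(data=matrix.data.loc[:, keep.to_numpy()], stage_tag="thresholded")
    if trace is None:
        trace = FilterTrace(
            n_initial=matrix.n_bins, excluded_labels=[], n_after_exclusion=matrix.n_bins
        )
    trace.threshold = float(threshold)
    trace.statistic = statistic
    trace.n_after_threshold = out.n_bins
    trace.validate()
    return out, trace
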