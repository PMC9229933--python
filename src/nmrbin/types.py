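"""Core domain types for the fecal ¹H-NMR binning/differential-abundance pipeline.

The pipeline's in-memory contract is small: a :class:`Spectrum` per sample,
a cohort-level :class:`BinMatrix` (samples × ppm bins), sample metadata for
the 2 (sanitary condition) × 2 (age) design, a bin→metabolite
:class:`AnnotationTable`, and result records (:class:`BinTestResult`,
:class:`MetaboliteSummary`) plus the :class:`FilterTrace` audit record for
the two-stage bin-filter cascade.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("HSC", "LSC")
WEEKS = (14, 22)
ORIGINS = ("diet", "microbiome", "endogenous")

#: significance tiers used in the result tables
TIER_STRICT = "lt_0.05"
TIER_LOOSE = "lt_0.1"
TIER_NS = "ns"


class ValidationError(ValueError):
    """Raised when an input table or domain object violates its contract."""


class FormatError(ValueError):
    """Raised when an on-disk file does not conform to the expected format."""


class ConfigurationError(ValueError):
    """Raised for inconsistent pipeline/bin-grid configuration."""


@dataclass
class Spectrum:
    """One sample's 1D ¹H-NMR spectrum: chemical shift (ppm) vs intensity.

    The ppm axis is normalized to strictly ascending order on construction;
    instrument exports in descending ppm are accepted and flipped together
    with their intensities, so the multiset of (ppm, intensity) pairs is
    never altered.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D sequences")
        if self.ppm.size != self.intensity.size:
            raise ValidationError(
                f"ppm ({self.ppm.size}) and intensity ({self.intensity.size}) "
                "lengths differ"
            )
        if self.ppm.size < 2:
            raise ValidationError("a spectrum needs at least 2 data points")
        d = np.diff(self.ppm)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        else:
            raise ValidationError(
                f"ppm axis of sample {self.sample_id!r} is not strictly monotone"
            )
        if not (np.all(np.isfinite(self.ppm)) and np.all(np.isfinite(self.intensity))):
            raise ValidationError(f"non-finite values in spectrum {self.sample_id!r}")

    def __len__(self) -> int:
        return int(self.ppm.size)


@dataclass(frozen=True)
class SampleMetadata:
    """Design factors for one fecal sample: animal, pen, treatment, age."""

    sample_id: str
    animal_id: str
    pen_id: str
    treatment: str  # "HSC" | "LSC"
    week: int  # 14 | 22

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: treatment {self.treatment!r} "
                f"not in {TREATMENTS}"
            )
        if self.week not in WEEKS:
            raise ValidationError(
                f"sample {self.sample_id!r}: week {self.week!r} not in {WEEKS}"
            )


def metadata_frame(meta: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by sample_id."""
    df = pd.DataFrame([dataclasses.asdict(m) for m in meta])
    if df.empty:
        df = pd.DataFrame(
            columns=["sample_id", "animal_id", "pen_id", "treatment", "week"]
        )
    return df.set_index("sample_id")


#: stage tags a BinMatrix moves through in the filter cascade
STAGE_TAGS = ("raw", "excluded", "thresholded")


@dataclass
class BinMatrix:
    """Samples × ppm-bins intensity table with cascade provenance.

    ``data`` is a DataFrame whose index is the ordered sample_ids and whose
    columns are 2-decimal left-edge bin labels, unique and sorted by ppm.
    """

    data: pd.DataFrame
    stage_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.stage_tag not in STAGE_TAGS:
            raise ValidationError(f"unknown stage_tag {self.stage_tag!r}")
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValidationError(f"duplicate bin labels: {dupes}")
        ppm = [float(c) for c in cols]
        if any(b <= a for a, b in zip(ppm, ppm[1:])):
            raise ValidationError("bin labels must be sorted ascending by ppm")
        idx = list(self.data.index)
        if len(set(idx)) != len(idx):
            raise ValidationError("duplicate sample_ids in bin matrix")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValidationError("bin matrix contains non-finite values")

    @property
    def bin_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass
class AnnotationTable:
    """Bin → metabolite map (published-table style).

    One metabolite may own several bins; a bin belongs to at most one
    metabolite unless every one of its rows is flagged ``shared`` (the
    butyrate/propionate bin at 2.18 ppm is the canonical case).
    """

    data: pd.DataFrame  # columns: bin_label, metabolite, origin, tentative, shared

    REQUIRED = ("bin_label", "metabolite", "origin", "tentative", "shared")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        bad = self.data.loc[~self.data["origin"].isin(ORIGINS)]
        if len(bad):
            raise ValidationError(
                "unknown origin values: "
                + ", ".join(f"{r.bin_label}->{r.origin!r}" for r in bad.itertuples())
            )
        dup = self.data["bin_label"].duplicated(keep=False)
        if dup.any():
            offenders = self.data.loc[dup]
            not_shared = offenders.loc[~offenders["shared"].astype(bool)]
            if len(not_shared):
                raise ValidationError(
                    "bins mapped to multiple metabolites without shared flag: "
                    + ", ".join(sorted(set(not_shared["bin_label"])))
                )

    @property
    def metabolites(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.data["metabolite"]))

    def bins_for(self, metabolite: str) -> list[str]:
        sel = self.data.loc[self.data["metabolite"] == metabolite, "bin_label"]
        return list(sel)


@dataclass
class FilterTrace:
    """Audit record of the two-stage bin-filter cascade.

    Counts must be monotone: ``n_initial >= n_after_exclusion >=
    n_after_threshold`` (the 1000 → 980 → 768 trajectory of the study).
    """

    n_initial: int
    excluded_labels: list[str] = field(default_factory=list)
    n_after_exclusion: Optional[int] = None
    threshold: Optional[float] = None
    statistic: Optional[str] = None
    n_after_threshold: Optional[int] = None

    def validate(self) -> None:
        if self.n_after_exclusion is not None:
            if self.n_after_exclusion != self.n_initial - len(self.excluded_labels):
                raise ValidationError("exclusion count inconsistent with label list")
            if self.n_after_exclusion > self.n_initial:
                raise ValidationError("cascade counts must be non-increasing")
        if self.n_after_threshold is not None:
            if self.n_after_exclusion is None:
                raise ValidationError("threshold stage recorded before exclusion")
            if not (0 <= self.n_after_threshold <= self.n_after_exclusion):
                raise ValidationError("cascade counts must be non-increasing")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BinTestResult:
    """Differential-abundance result for one bin at one week (or pooled)."""

    bin_label: str
    week: str  # "14" | "22" | "pooled"
    ratio_hsc_lsc: float  # NaN when the LSC group mean is <= 0
    log2_effect: float
    t_stat: float
    df: float
    p_raw: float
    q_fdr: float = np.nan
    tier: str = TIER_NS
    degenerate: bool = False


def results_frame(results: Sequence[BinTestResult]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(BinTestResult)]
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=cols)


@dataclass
class MetaboliteSummary:
    """Summary-table row: a metabolite's bins aggregated per week.

    Ratios are unweighted means of the constituent bins' HSC/LSC ratios;
    the tier derives from the mean FDR q over the bins (the study's stated
    aggregation), at full precision — rounding happens only at rendering.
    """

    metabolite: str
    origin: str
    tentative: bool
    bins: list[str]
    week14_ratio: float
    week14_q: float
    week14_tier: str
    week22_ratio: float
    week22_q: float
    week22_tier: str
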