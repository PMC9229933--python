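"""Bin→metabolite annotation and summary-table aggregation.

Multi-bin metabolites are aggregated per week as the unweighted
arithmetic mean of their bins' HSC/LSC ratios, and their significance
tier derives from the unweighted mean of the bins' FDR q-values — the
mean-of-bins / mean-FDR-over-bins rules used in the source study's
reporting.
Mean-of-q is statistically unconventional; a documented alternative
(``fdr_agg="min"``) uses the minimum q instead. Single-bin metabolites
pass their bin's values through unchanged.

A bin flagged ``shared`` contributes to every metabolite it is annotated
with (the 2.18-ppm bin feeds both the butyrate and the propionate mean,
which is what reproduces the printed mean propionate of 0.77 from bins
0.73 and 0.81 at week 14).

All arithmetic is at full precision; half-up rounding to 2 decimals
happens only when rendering the report.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as nio
from .stats import assign_tier
from .types import (
    TIER_LOOSE,
    TIER_NS,
    TIER_STRICT,
    AnnotationTable,
    BinTestResult,
    MetaboliteSummary,
    ValidationError,
)

log = logging.getLogger(__name__)

FDR_AGGS = ("mean", "min")

_TIER_RENDER = {TIER_STRICT: "<0.05", TIER_LOOSE: "<0.1", TIER_NS: "ns"}
_ORIGIN_RENDER = {
    "diet": "Diet",
    "microbiome": "Microbiome",
    "endogenous": "Endogenous (host)",
}


def load_annotation(path=None) -> AnnotationTable:
    """Load an annotation CSV; default is the packaged metabolite-table map."""
    if path is None:
        ref = resources.files("nmrbin.data").joinpath("table1_annotation.csv")
        with resources.as_file(ref) as p:
            return nio.read_annotation(p)
    return nio.read_annotation(path)


def _week_lookup(results: Sequence[BinTestResult], week: str) -> dict[str, BinTestResult]:
    return {r.bin_label: r for r in results if r.week == week}


def summarize_metabolites(
    results: Sequence[BinTestResult],
    annot: AnnotationTable,
    fdr_agg: str = "mean",
) -> list[MetaboliteSummary]:
    """Aggregate per-bin results into per-metabolite summary rows.

    Requires per-week results (weeks "14" and "22"). Annotated bins
    absent from the results (filtered out) are warned and skipped; a
    metabolite with no surviving bin is excluded with a warning.
    Aggregation is permutation-invariant in bin order.
    """
    if fdr_agg not in FDR_AGGS:
        raise ValidationError(f"unknown fdr_agg {fdr_agg!r}; choose from {FDR_AGGS}")
    by_week = {w: _week_lookup(results, w) for w in ("14", "22")}
    if not by_week["14"] or not by_week["22"]:
        raise ValidationError(
            "metabolite aggregation needs per-week results for weeks 14 and 22"
        )
    agg_fn = np.mean if fdr_agg == "mean" else np.min
    summaries: list[MetaboliteSummary] = []
    for met in annot.metabolites:
        rows = annot.data.loc[annot.data["metabolite"] == met]
        bins = list(rows["bin_label"])
        surviving = [b for b in bins if b in by_week["14"] and b in by_week["22"]]
        dropped = [b for b in bins if b not in surviving]
        if dropped:
            log.warning("%s: bins %s missing from results; skipped", met, dropped)
        if not surviving:
            log.warning("%s: no surviving bins; metabolite excluded", met)
            continue
        per_week: dict[str, tuple[float, float, str]] = {}
        for w in ("14", "22"):
            res = [by_week[w][b] for b in surviving]
            ratio = float(np.mean([r.ratio_hsc_lsc for r in res]))
            q = float(agg_fn([r.q_fdr for r in res]))
            per_week[w] = (ratio, q, assign_tier(q))
        summaries.append(
            MetaboliteSummary(
                metabolite=met,
                origin=str(rows["origin"].iloc[0]),
                tentative=bool(rows["tentative"].iloc[0]),
                bins=surviving,
                week14_ratio=per_week["14"][0],
                week14_q=per_week["14"][1],
                week14_tier=per_week["14"][2],
                week22_ratio=per_week["22"][0],
                week22_q=per_week["22"][1],
                week22_tier=per_week["22"][2],
            )
        )
    return summaries


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Presentation rounding (half away from zero), e.g. 0.775 -> 0.78."""
    if np.isnan(x):
        return float("nan")
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def _fmt_ratio(x: float) -> str:
    if np.isnan(x):
        return "undef"
    return f"{round_half_up(x):.2f}"


def summaries_frame(summaries: Sequence[MetaboliteSummary]) -> pd.DataFrame:
    """Full-precision per-metabolite results as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "metabolite": s.metabolite,
                "origin": s.origin,
                "tentative": s.tentative,
                "bins": ";".join(s.bins),
                "week14_ratio": s.week14_ratio,
                "week14_q": s.week14_q,
                "week14_tier": s.week14_tier,
                "week22_ratio": s.week22_ratio,
                "week22_q": s.week22_q,
                "week22_tier": s.week22_tier,
            }
            for s in summaries
        ]
    )


def render_table1(
    summaries: Sequence[MetaboliteSummary],
    bin_results: Sequence[BinTestResult],
    annot: Optional[AnnotationTable] = None,
) -> pd.DataFrame:
    """Render the report table: per-bin rows plus "Mean …" rows.

    Columns: Expected Origin | Bins | Metabolite | Ratio HSC/LSC (wk 14) |
    FDR (wk 14) | Ratio HSC/LSC (wk 22) | FDR (wk 22). Multi-bin
    metabolites list each bin's row followed by an aggregate row;
    single-bin metabolites get one row. Ratios rendered at 2 decimals
    (half-up), FDR as "<0.05" / "<0.1" / "ns".
    """
    by_week = {w: _week_lookup(bin_results, w) for w in ("14", "22")}
    rows = []
    for s in summaries:
        met_name = s.metabolite + (" (tentative)" if s.tentative else "")
        if len(s.bins) > 1:
            for b in s.bins:
                r14, r22 = by_week["14"].get(b), by_week["22"].get(b)
                rows.append(
                    {
                        "Expected Origin": _ORIGIN_RENDER[s.origin],
                        "Bins": b,
                        "Metabolite": met_name,
                        "Ratio HSC/LSC (wk 14)": _fmt_ratio(r14.ratio_hsc_lsc) if r14 else "",
                        "FDR (wk 14)": _TIER_RENDER[r14.tier] if r14 else "",
                        "Ratio HSC/LSC (wk 22)": _fmt_ratio(r22.ratio_hsc_lsc) if r22 else "",
                        "FDR (wk 22)": _TIER_RENDER[r22.tier] if r22 else "",
                    }
                )
            label = f"Mean {s.metabolite.lower()}"
        else:
            label = met_name
        rows.append(
            {
                "Expected Origin": _ORIGIN_RENDER[s.origin],
                "Bins": s.bins[0] if len(s.bins) == 1 else "",
                "Metabolite": label,
                "Ratio HSC/LSC (wk 14)": _fmt_ratio(s.week14_ratio),
                "FDR (wk 14)": _TIER_RENDER[s.week14_tier],
                "Ratio HSC/LSC (wk 22)": _fmt_ratio(s.week22_ratio),
                "FDR (wk 22)": _TIER_RENDER[s.week22_tier],
            }
        )
    cols = [
        "Expected Origin",
        "Bins",
        "Metabolite",
        "Ratio HSC/LSC (wk 14)",
        "FDR (wk 14)",
        "Ratio HSC/LSC (wk 22)",
        "FDR (wk 22)",
    ]
    return pd.DataFrame(rows, columns=cols)


def table_to_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of the report table (header-only when empty)."""
    header = "| " + " | ".join(table.columns) + " |"
    sep = "|" + "|".join(["---"] * len(table.columns)) + "|"
    lines = [header, sep]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
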