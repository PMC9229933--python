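#!/usr/bin/env python
"""Aggregate significant bins into the metabolite ratio table and compare
recovered ratios with the planted truth.

Maps retained bins to metabolites via the packaged annotation, averages
multi-bin metabolites (mean ratio, mean FDR q), renders the report table,
and joins the per-metabolite ratios against the generator's truth table
to quantify recovery error.

Run after 03:  python analysis/04_metabolite_table.py
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from nmrbin.annotate import (
    load_annotation,
    render_table1,
    summaries_frame,
    summarize_metabolites,
    table_to_markdown,
)
from nmrbin.types import BinTestResult


def main() -> None:
    rdf = pd.read_csv(ROOT / "results" / "results_bins.csv", dtype={"bin_label": str, "week": str})
    results = [BinTestResult(**row) for row in rdf.to_dict(orient="records")]
    annot = load_annotation()
    summaries = summarize_metabolites(results, annot)
    sdf = summaries_frame(summaries)
    sdf.to_csv(ROOT / "results" / "results_metabolites.csv", index=False)
    table = render_table1(summaries, results, annot)
    (ROOT / "results" / "table1_report.md").write_text(table_to_markdown(table))

    truth = pd.read_csv(ROOT / "results" / "truth.csv")
    rows = []
    for week in (14, 22):
        t = truth.loc[truth["week"] == week].set_index("metabolite")["true_ratio"]
        for s in summaries:
            if s.metabolite in t.index:
                est = s.week14_ratio if week == 14 else s.week22_ratio
                rows.append(
                    {
                        "metabolite": s.metabolite,
                        "week": week,
                        "planted_ratio": t[s.metabolite],
                        "recovered_ratio": est,
                        "rel_error": est / t[s.metabolite] - 1,
                    }
                )
    rec = pd.DataFrame(rows)
    rec.to_csv(ROOT / "results" / "recovery_vs_truth.csv", index=False)
    print(table_to_markdown(table))
    worst = rec.loc[rec["rel_error"].abs().idxmax()]
    print(
        f"recovered vs planted ratios: median |rel err| = "
        f"{rec['rel_error'].abs().median():.3f}, worst = {worst['rel_error']:+.3f} "
        f"({worst['metabolite']}, week {worst['week']:.0f})"
    )


if __name__ == "__main__":
    main()
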