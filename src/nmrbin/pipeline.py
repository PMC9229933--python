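"""End-to-end orchestration: simulate a cohort to disk, or run the full
bin → exclude → threshold → fit → FDR → annotate → render analysis.

Both entry points are plain functions so scripts and tests drive them
directly; the CLI is a thin wrapper. ``run_analyze`` logs the filter
cascade counts (the study's 1000 → 980 → 768 checkpoints) and writes a
JSON run report alongside the result tables.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from . import annotate as ann
from . import io as nio
from .binning import BinSpec, bin_cohort
from .config import PipelineConfig
from .filtering import default_water_exclusion, exclude_bins, load_exclusion_list, threshold_filter
from .simulate import CohortDesign, null_cohort, simulate_cohort
from .stats import fit_bin_model, tier_counts
from .types import BinMatrix, FilterTrace, Spectrum, results_frame

log = logging.getLogger(__name__)


def run_simulate(config: PipelineConfig, out_dir) -> dict:
    """Generate a synthetic cohort and write spectra, metadata and truth table.

    Layout: ``out/spectra/<sample_id>.csv`` (2-column ppm,intensity),
    ``out/metadata.csv``, ``out/truth.csv``. Deterministic given the seed.
    """
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    sc = config.simulate
    design = CohortDesign(
        n_per_cell=sc.n_per_cell,
        animal_cv=sc.animal_cv,
        noise_sd=sc.noise_sd,
        baseline_amplitude=sc.baseline_amplitude,
        points_per_bin=sc.points_per_bin,
        seed=sc.seed,
    )
    gen = null_cohort if sc.null else simulate_cohort
    spectra, meta, truth = gen(design)
    for s in spectra:
        nio.write_spectrum(s, out / "spectra" / f"{s.sample_id}.csv")
    nio.write_metadata(meta, out / "metadata.csv")
    truth.to_csv(out / "truth.csv", index=False)
    log.info("wrote %d spectra to %s", len(spectra), out / "spectra")
    return {"n_spectra": len(spectra), "out_dir": str(out)}


def _load_spectra(spectra_dir) -> list[Spectrum]:
    paths = sorted(Path(spectra_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no spectrum files (*.csv) under {spectra_dir}")
    return [nio.read_spectrum(p) for p in paths]


def run_analyze(
    config: PipelineConfig,
    out_dir,
    spectra_dir=None,
    bin_matrix_path=None,
    metadata_path=None,
) -> dict:
    """Run the full analysis and write all result artefacts to ``out_dir``.

    Input is either a directory of spectrum files (binned here) or a
    pre-binned samples×bins CSV (binning skipped; downstream identical).
    Outputs: staged bin matrices, per-bin results CSV, per-metabolite
    results CSV, a publication-style markdown report and run_report.json.
    """
    if (spectra_dir is None) == (bin_matrix_path is None):
        raise ValueError("provide exactly one of spectra_dir or bin_matrix_path")
    if metadata_path is None:
        raise ValueError("metadata_path is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ac = config.analyze
    started = datetime.datetime.now().isoformat(timespec="seconds")

    meta = nio.read_metadata(metadata_path)

    if spectra_dir is not None:
        spec = BinSpec(
            window_lo=ac.window_lo,
            window_hi=ac.window_hi,
            width=ac.bin_width,
            aggregation=ac.bin_aggregation,
        )
        raw = bin_cohort(_load_spectra(spectra_dir), spec)
    else:
        raw = nio.read_bin_matrix(bin_matrix_path, stage_tag="raw")
    nio.write_bin_matrix(raw, out / "bin_matrix_raw.csv")
    log.info("binning: %d samples x %d bins", raw.n_samples, raw.n_bins)

    excl_list = (
        load_exclusion_list(ac.exclude_bins_path)
        if ac.exclude_bins_path
        else default_water_exclusion()
    )
    excluded, trace = exclude_bins(raw, excl_list)
    log.info("exclusion: %d -> %d bins", trace.n_initial, trace.n_after_exclusion)
    thresholded, trace = threshold_filter(
        excluded, threshold=ac.threshold, statistic=ac.threshold_statistic, trace=trace
    )
    log.info(
        "threshold %g (%s): %d -> %d bins",
        ac.threshold, ac.threshold_statistic, trace.n_after_exclusion, trace.n_after_threshold,
    )
    nio.write_bin_matrix(excluded, out / "bin_matrix_excluded.csv")
    nio.write_bin_matrix(thresholded, out / "bin_matrix_thresholded.csv")

    # auto pseudocount is derived from the pre-threshold matrix so the log2
    # offset sits below the noise floor rather than at the retained-signal scale
    from .stats import auto_pseudocount

    pc = ac.pseudocount if ac.pseudocount is not None else auto_pseudocount(excluded)
    results = fit_bin_model(
        thresholded, meta, mode=ac.model_mode, transform=ac.transform, pseudocount=pc
    )
    rdf = results_frame(results)
    rdf.to_csv(out / "results_bins.csv", index=False)
    counts = tier_counts(results)
    for row in counts.itertuples(index=False):
        log.info(
            "week %s: %d bins, %d at q<0.05, %d at q<0.1", row.week, row.n_bins,
            getattr(row, "_2"), getattr(row, "_3"),
        )

    annot = ann.load_annotation(ac.annotation_path)
    summaries: list = []
    table = None
    if ac.model_mode == "per_week":
        summaries = ann.summarize_metabolites(results, annot, fdr_agg=ac.fdr_aggregation)
        ann.summaries_frame(summaries).to_csv(out / "results_metabolites.csv", index=False)
        table = ann.render_table1(summaries, results, annot)
        (out / "table1_report.md").write_text(ann.table_to_markdown(table), encoding="utf-8")

    report = {
        "version": __version__,
        "started": started,
        "filter_trace": trace.to_dict(),
        "tier_counts": counts.to_dict(orient="records"),
        "n_metabolites": len(summaries),
        "config": {
            "analyze": dataclasses.asdict(ac),
        },
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
    return {
        "trace": trace,
        "results": results,
        "summaries": summaries,
        "table": table,
        "tier_counts": counts,
        "report": report,
        "matrices": {"raw": raw, "excluded": excluded, "thresholded": thresholded},
    }
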