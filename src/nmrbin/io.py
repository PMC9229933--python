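"""Readers and writers for the pipeline's on-disk formats.

All files are plain text: 2-column delimited spectra (ppm, intensity;
comma or tab autodetected), CSV bin matrices (first column ``sample_id``,
remaining headers the bin labels), CSV sample metadata and CSV annotation
tables. One CSV dialect throughout: comma separator, ``.`` decimal mark,
UTF-8, mandatory header row for matrices/metadata/annotation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    AnnotationTable,
    BinMatrix,
    FormatError,
    SampleMetadata,
    Spectrum,
    ValidationError,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_METADATA_COLUMNS = ["sample_id", "animal_id", "pen_id", "treatment", "week"]


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def read_spectrum(path: PathLike, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) text file into a :class:`Spectrum`.

    A single non-numeric header line is tolerated. Malformed rows raise a
    :class:`FormatError` naming the 1-based line number. ``sample_id``
    defaults to the file's stem.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    lines = path.read_text(encoding="utf-8").splitlines()
    rows: list[tuple[float, float]] = []
    delim: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p for p in line.split(delim) if p != ""] if delim != " " else line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1 and not rows:
                continue  # header line
            raise FormatError(
                f"{path}: line {lineno}: non-numeric field in {line!r}"
            ) from None
    if len(rows) < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    arr = np.asarray(rows, dtype=float)
    try:
        return Spectrum(sample_id=sample_id, ppm=arr[:, 0], intensity=arr[:, 1])
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


def write_spectrum(spectrum: Spectrum, path: PathLike) -> None:
    """Write a spectrum as CSV with a ``ppm,intensity`` header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ppm,intensity\n")
        for p, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{float(p)!r},{float(y)!r}\n")


def read_metadata(path: PathLike) -> list[SampleMetadata]:
    """Read and validate the sample-metadata CSV.

    Enforces the 2×2 factor structure: treatment in {HSC, LSC}, week in
    {14, 22}; sample_id unique. An empty (header-only) table yields an
    empty list with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    if df.empty:
        log.warning("%s: metadata table is empty", path)
        return []
    dup = df["sample_id"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate sample_id rows: "
            + ", ".join(sorted(set(df.loc[dup, "sample_id"])))
        )
    records = []
    errors = []
    for row in df.itertuples(index=True):
        try:
            week = int(row.week)
        except (TypeError, ValueError):
            errors.append(f"row {row.Index + 2}: non-integer week {row.week!r}")
            continue
        try:
            records.append(
                SampleMetadata(
                    sample_id=str(row.sample_id),
                    animal_id=str(row.animal_id),
                    pen_id=str(row.pen_id),
                    treatment=str(row.treatment),
                    week=week,
                )
            )
        except ValidationError as e:
            errors.append(f"row {row.Index + 2}: {e}")
    if errors:
        raise ValidationError(f"{path}: invalid metadata rows:\n  " + "\n  ".join(errors))
    return records


def write_metadata(meta: list[SampleMetadata], path: PathLike) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.animal_id, m.pen_id, m.treatment, m.week) for m in meta],
        columns=_METADATA_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_bin_matrix(matrix: BinMatrix, path: PathLike) -> None:
    """Write a bin matrix as CSV at full stored precision (lossless round-trip)."""
    df = matrix.data.copy()
    df.index.name = "sample_id"
    # repr-based formatting keeps 17 significant digits -> lossless round trip
    df.to_csv(path)


def read_bin_matrix(path: PathLike, stage_tag: str = "raw") -> BinMatrix:
    """Read a samples×bins CSV (column 1 = sample_id, headers = bin labels)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    labels = header[1:]
    if len(set(labels)) != len(labels):
        dupes = sorted({c for c in labels if labels.count(c) > 1})
        raise FormatError(f"{path}: duplicated bin columns: {dupes}")
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise FormatError(f"{path}: {e}") from e
    df.columns = labels  # keep 2-decimal labels verbatim (pandas would keep str anyway)
    df.index = df.index.astype(str)
    try:
        return BinMatrix(data=df, stage_tag=stage_tag)
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


def read_annotation(path: PathLike) -> AnnotationTable:
    """Read a bin→metabolite annotation CSV.

    Columns: ``bin_label, metabolite, origin, tentative[, shared]``;
    ``shared`` defaults to false and marks bins deliberately assigned to
    more than one metabolite.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"bin_label": str, "metabolite": str, "origin": str})
    required = ["bin_label", "metabolite", "origin", "tentative"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    if "shared" not in df.columns:
        df["shared"] = False
    for col in ("tentative", "shared"):
        df[col] = (
            df[col]
            .map(lambda v: str(v).strip().lower() in ("true", "1", "yes"))
            .astype(bool)
        )
    return AnnotationTable(data=df[["bin_label", "metabolite", "origin", "tentative", "shared"]])


def write_annotation(annot: AnnotationTable, path: PathLike) -> None:
    annot.data.to_csv(path, index=False)
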