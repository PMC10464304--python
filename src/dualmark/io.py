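"""Readers and writers for the text formats the pipeline exchanges.

BED (3/4/6 column), 4-column bedGraph, two-column chrom.sizes and the
delimited titration tables. All genomic formats are 0-based half-open;
malformed lines raise with the offending line number. chrom.sizes is the
single source of truth for chromosome names and lengths — every genomic
reader validates against it.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationCurve
from .intervals import IntervalSet
from .tracks import CoverageTrack

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_titrations",
    "write_fit_table",
]


class FormatError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise FormatError(path, lineno, "expected <chrom> <length>")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise FormatError(path, lineno, f"bad length {fields[1]!r}") from None
        if length <= 0:
            raise FormatError(path, lineno, "length must be > 0")
        if name in sizes:
            raise FormatError(path, lineno, f"duplicate chromosome {name!r}")
        sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path, chrom_sizes: dict[str, int] | None = None, role: str = "") -> IntervalSet:
    """Read BED3/BED4/BED6; comment/track lines skipped; output sorted."""
    recs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(path, lineno, "fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(path, lineno, "non-integer coordinates") from None
        if start < 0:
            raise FormatError(path, lineno, "negative start coordinate")
        if start >= end:
            raise FormatError(path, lineno, f"start {start} >= end {end}")
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise FormatError(path, lineno, "interval beyond chromosome end")
        if len(fields) >= 4:
            recs.append((chrom, start, end, fields[3]))
        else:
            recs.append((chrom, start, end))
    out = IntervalSet.from_records(recs) if recs else IntervalSet.empty()
    out.role = role
    return out


def write_bed(intervals: IntervalSet, path) -> None:
    has_name = "name" in intervals.df.columns
    with open(path, "w") as fh:
        for row in intervals.df.itertuples(index=False):
            if has_name and not pd.isna(row.name):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph into a coverage track.

    Gaps mean signal 0; overlapping records or coordinates outside the
    chromosome are rejected with a line number.
    """
    recs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise FormatError(path, lineno, "fewer than 4 bedGraph columns")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise FormatError(path, lineno, "malformed coordinates or value") from None
        if chrom not in chrom_sizes:
            raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")
        if start < 0 or start >= end or end > chrom_sizes[chrom]:
            raise FormatError(path, lineno, f"bad interval [{start}, {end})")
        if not np.isfinite(value):
            raise FormatError(path, lineno, "non-finite value")
        recs.append((chrom, start, end, value))
    try:
        return CoverageTrack.from_records(recs, chrom_sizes)
    except ValueError as exc:  # overlap detected during assembly
        raise FormatError(path, 0, str(exc)) from exc


def write_bedgraph(track: CoverageTrack, path, include_zero: bool = False) -> None:
    """Write runs as bedGraph; adjacent equal-value runs are merged."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.to_records(include_zero=include_zero):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


TITRATION_COLUMNS = [
    "replicate_id",
    "peptide_id",
    "variant_id",
    "peptide_conc_nM",
    "protein_conc_nM",
    "anisotropy",
]


def read_titrations(path) -> list[TitrationCurve]:
    """Read a delimited titration table into one curve per replicate.

    Expects columns replicate_id, peptide_id, variant_id, peptide_conc_nM,
    protein_conc_nM, anisotropy (TSV or CSV, sniffed from the header).
    """
    with open(path) as fh:
        sample = fh.readline()
    sep = "\t" if "\t" in sample else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(TITRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    curves = []
    for (rep, pep, var), sub in df.groupby(
        ["replicate_id", "peptide_id", "variant_id"], sort=True
    ):
        sub = sub.sort_values("protein_conc_nM")
        curves.append(
            TitrationCurve(
                peptide_id=str(pep),
                variant_id=str(var),
                peptide_conc=float(sub["peptide_conc_nM"].iloc[0]),
                protein_conc=sub["protein_conc_nM"].to_numpy(),
                anisotropy=sub["anisotropy"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return curves


def write_titrations(curves: list[TitrationCurve], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TITRATION_COLUMNS)
        for c in curves:
            for conc, y in zip(c.protein_conc, c.anisotropy):
                w.writerow(
                    [c.replicate_id, c.peptide_id, c.variant_id, c.peptide_conc, conc, y]
                )


def write_fit_table(fits, path) -> None:
    """Per-replicate fit results as TSV (one row per fit)."""
    rows = [
        {
            "replicate_id": f.replicate_id,
            "peptide_id": getattr(f, "peptide_id", ""),
            "variant_id": getattr(f, "variant_id", ""),
            "model": f.model,
            "KD_nM": f.params.KD,
            "BL": f.params.BL,
            "F": f.params.F,
            "rss": f.rss,
            "converged": f.converged,
            "n_points": f.n_points,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
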