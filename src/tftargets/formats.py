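"""Readers and writers for the plain-text formats the pipeline speaks.

BED3/BED6 for peaks and fragments (tab-separated, ``#`` comment lines
skipped, no track lines), a GTF-lite gene reader (1-based inclusive,
converted to 0-based half-open on read), a simple gene TSV dialect, TSV count
matrices, GMT gene sets, survival tables and Kaplan-Meier step curves.
Malformed lines raise errors naming the file and line number.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, Peak, PeakSet

__all__ = [
    "read_bed_intervals",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_genes_gtf",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_survival_tsv",
    "write_survival_tsv",
    "write_km_curve",
]


class FormatError(ValueError):
    """A malformed line in an input file."""


def _bed_rows(path: str | Path):
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if not 0 <= start < end:
                raise FormatError(
                    f"{path}: line {lineno}: require 0 <= start < end, "
                    f"got {start}..{end}"
                )
            yield lineno, fields, start, end


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read fragments/regions from BED3+ as bare intervals."""
    out = []
    for _, fields, start, end in _bed_rows(path):
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def read_peaks_bed(
    path: str | Path, condition: str, replicate_ids: Sequence[str] = ()
) -> PeakSet:
    """Read a peak set from BED: name in column 4, RPKM in column 5.

    Extra columns beyond 6 are preserved only if they encode per-replicate
    counts as a comma-separated column 7.
    """
    peaks = []
    for lineno, fields, start, end in _bed_rows(path):
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else f"peak_{lineno}"
        rpkm = float(fields[4]) if len(fields) >= 5 and fields[4] != "." else 0.0
        counts: tuple[int, ...] = ()
        source_ids: tuple[str, ...] = ()
        if len(fields) >= 7 and fields[6]:
            try:
                counts = tuple(int(x) for x in fields[6].split(","))
            except ValueError:
                source_ids = tuple(fields[6].split(";"))
        peaks.append(
            Peak(GenomicInterval(fields[0], start, end), name, rpkm=rpkm,
                 counts=counts, source_ids=source_ids)
        )
    return PeakSet(condition=condition, peaks=peaks, replicate_ids=tuple(replicate_ids))


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in peaks:
            cols = [
                p.interval.chrom,
                str(p.interval.start),
                str(p.interval.end),
                p.peak_id,
                f"{p.rpkm:.6g}",
                p.interval.strand,
            ]
            if p.counts:
                cols.append(",".join(str(c) for c in p.counts))
            elif p.source_ids:
                cols.append(";".join(p.source_ids))
            fh.write("\t".join(cols) + "\n")


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Gene TSV dialect: gene_id, chrom, start, end, strand (0-based half-open)."""
    path = Path(path)
    genes = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("gene_id")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 fields")
            gid, chrom, start, end, strand = fields[:5]
            try:
                interval = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            genes.append(GeneModel(gid, interval, strand))
    _check_unique([g.gene_id for g in genes], path)
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.interval.chrom}\t{g.interval.start}\t"
                f"{g.interval.end}\t{g.strand}\n"
            )


_GTF_GENE_ID = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """GTF-lite: keep ``gene`` features; 1-based inclusive converted to
    0-based half-open; gene_id parsed from the attribute column."""
    path = Path(path)
    genes = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GTF fields")
            if fields[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(fields[8])
            if not m:
                raise FormatError(f"{path}: line {lineno}: missing gene_id attribute")
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            strand = fields[6]
            interval = GenomicInterval(fields[0], start1 - 1, end1, strand)
            genes.append(GeneModel(m.group(1), interval, strand))
    _check_unique([g.gene_id for g in genes], path)
    return genes


def _check_unique(ids: list[str], path: Path) -> None:
    seen = set()
    for gid in ids:
        if gid in seen:
            raise FormatError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """TSV count matrix: first column feature id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name, description, then member genes (tab-separated)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs name, description and >= 1 gene"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    """Survival table: sample_id, time, event (1 event / 0 censored)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if (df["time"] < 0).any():
        raise FormatError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event must be 0 or 1")
    return df.set_index("sample_id")


def write_survival_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)


def write_km_curve(
    times: np.ndarray, events: np.ndarray, path: str | Path
) -> pd.DataFrame:
    """Kaplan-Meier survival step function, written as two-column TSV."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    curve = km.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    curve.to_csv(path, sep="\t", index=False)
    return curve
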