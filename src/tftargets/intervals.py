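"""Genomic interval data model and peak-level operations.

Coordinates are 0-based half-open (BED convention) throughout the package;
1-based inputs (GTF) are converted on read by :mod:`tftargets.formats`.

The atoms here are :class:`GenomicInterval`, :class:`Peak`, :class:`PeakSet`
and :class:`GeneModel`.  Operations cover the occupancy preprocessing steps of
a CUT&Tag/ATAC-style workflow: RPKM filtering of called peaks, consensus
merging of peak sets, fragment recounting in consensus intervals, and
TSS-distance / genomic-context classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "compute_rpkm",
    "filter_peaks_by_rpkm",
    "merge_consensus",
    "count_fragments_in_intervals",
    "classify_tss_context",
]

DEFAULT_RPKM_THRESHOLD = 10.0
DEFAULT_CONTEXT_BINS = (0.0, 10_000.0, 100_000.0, np.inf)


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Any-overlap (>= 1 bp) test."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak with signal statistics.

    ``rpkm`` is reads per kilobase of peak per million mapped fragments,
    averaged over the replicates of the peak set's condition.  ``counts``
    holds per-replicate fragment counts aligned with the owning
    :class:`PeakSet`'s ``replicate_ids``.
    """

    interval: GenomicInterval
    peak_id: str
    rpkm: float = 0.0
    counts: tuple[int, ...] = ()
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"peak {self.peak_id}: negative rpkm {self.rpkm}")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"peak {self.peak_id}: negative count")


@dataclass
class PeakSet:
    """An ordered collection of peaks for one condition.

    Peaks are kept sorted by (chrom, start); peak ids must be unique.
    """

    condition: str
    peaks: list[Peak] = field(default_factory=list)
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate peak ids in peak set {self.condition!r}")
        if self.replicate_ids:
            for p in self.peaks:
                if p.counts and len(p.counts) != len(self.replicate_ids):
                    raise ValueError(
                        f"peak {p.peak_id}: {len(p.counts)} counts for "
                        f"{len(self.replicate_ids)} replicates"
                    )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def counts_frame(self) -> pd.DataFrame:
        """Peak x replicate fragment counts as a DataFrame."""
        data = np.array([p.counts for p in self.peaks], dtype=np.int64)
        if data.size == 0:
            data = data.reshape(0, len(self.replicate_ids))
        return pd.DataFrame(
            data, index=[p.peak_id for p in self.peaks], columns=list(self.replicate_ids)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-aware transcription start site.

    The TSS is ``interval.start`` on the + strand and ``interval.end - 1``
    (the last covered base) on the - strand, so it always lies inside the
    half-open body interval.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


def compute_rpkm(
    counts: np.ndarray | Sequence[Sequence[int]],
    lengths: np.ndarray | Sequence[int],
    library_sizes: np.ndarray | Sequence[int] | None = None,
) -> np.ndarray:
    """Per-peak RPKM averaged over replicates.

    rpkm_ij = count_ij * 1e9 / (length_i * library_size_j), then averaged over
    the replicate axis.  ``library_sizes`` defaults to the column sums of the
    count matrix (total mapped fragments per replicate).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a peak x replicate matrix")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    per_rep = counts * 1e9 / (lengths[:, None] * library_sizes[None, :])
    return per_rep.mean(axis=1)


def filter_peaks_by_rpkm(
    peaks: PeakSet, threshold: float = DEFAULT_RPKM_THRESHOLD
) -> PeakSet:
    """Drop peaks with RPKM strictly below ``threshold``.

    Keep-if->=-threshold boundary; the input is not modified.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    for p in peaks:
        if p.rpkm < 0:  # defensive: Peak forbids this at construction
            raise ValueError(f"peak {p.peak_id}: negative rpkm")
    kept = [p for p in peaks if p.rpkm >= threshold]
    return PeakSet(
        condition=peaks.condition, peaks=kept, replicate_ids=peaks.replicate_ids
    )


def merge_consensus(
    peak_sets: Sequence[PeakSet], condition: str | None = None
) -> PeakSet:
    """Union-merge peaks from several sets into disjoint consensus intervals.

    Overlapping or book-ended (end == next start) intervals on the same
    chromosome are merged, matching the default behaviour of ``bedtools
    merge``.  Each consensus peak records the contributing peak ids in
    ``source_ids``.  Output peaks are named ``consensus_<k>`` in sorted order.
    """
    records: list[tuple[str, int, int, str]] = []
    for ps in peak_sets:
        for p in ps:
            records.append((p.interval.chrom, p.interval.start, p.interval.end, p.peak_id))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    merged: list[Peak] = []
    cur: list | None = None  # [chrom, start, end, ids]
    for chrom, start, end, pid in records:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].append(pid)
        else:
            if cur is not None:
                merged.append(_consensus_peak(cur, len(merged)))
            cur = [chrom, start, end, [pid]]
    if cur is not None:
        merged.append(_consensus_peak(cur, len(merged)))

    if condition is None:
        condition = "+".join(dict.fromkeys(ps.condition for ps in peak_sets)) or "consensus"
    return PeakSet(condition=condition, peaks=merged)


def _consensus_peak(cur: list, k: int) -> Peak:
    chrom, start, end, ids = cur
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        peak_id=f"consensus_{k + 1}",
        source_ids=tuple(ids),
    )


def _chrom_arrays(consensus: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, row indices) for sorted disjoint peaks."""
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    chroms = np.array([p.interval.chrom for p in consensus])
    starts = np.array([p.interval.start for p in consensus], dtype=np.int64)
    ends = np.array([p.interval.end for p in consensus], dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        mask = chroms == chrom
        s, e = starts[mask], ends[mask]
        if np.any(np.diff(s) < 0) or np.any(s[1:] < e[:-1]):
            raise ValueError(
                f"consensus peaks on {chrom} must be sorted and disjoint"
            )
        out[chrom] = (s, e, np.flatnonzero(mask))
    return out


def count_fragments_in_intervals(
    fragments: Mapping[str, Iterable[GenomicInterval]] | Sequence[Iterable[GenomicInterval]],
    consensus: PeakSet,
) -> pd.DataFrame:
    """Count fragments overlapping each consensus interval, per replicate.

    Entry (i, j) is the number of replicate-j fragments overlapping consensus
    interval i by at least 1 bp; a fragment contributes to every interval it
    overlaps.  ``fragments`` maps replicate id to its fragment intervals (a
    plain sequence of fragment lists gets numeric replicate ids).
    """
    if not isinstance(fragments, Mapping):
        fragments = {str(j): frags for j, frags in enumerate(fragments)}
    by_chrom = _chrom_arrays(consensus)
    n = len(consensus)
    mat = np.zeros((n, len(fragments)), dtype=np.int64)
    for j, (rep, frags) in enumerate(fragments.items()):
        frag_list = list(frags)
        if not frag_list:
            continue
        fchrom = np.array([f.chrom for f in frag_list])
        fstart = np.array([f.start for f in frag_list], dtype=np.int64)
        fend = np.array([f.end for f in frag_list], dtype=np.int64)
        for chrom, (s, e, rows) in by_chrom.items():
            sel = fchrom == chrom
            if not np.any(sel):
                continue
            fs, fe = fstart[sel], fend[sel]
            # fragment overlaps intervals lo..hi-1 (disjoint + sorted)
            lo = np.searchsorted(e, fs, side="right")
            hi = np.searchsorted(s, fe, side="left")
            delta = np.zeros(len(s) + 1, dtype=np.int64)
            valid = hi > lo
            np.add.at(delta, lo[valid], 1)
            np.add.at(delta, hi[valid], -1)
            mat[rows, j] += np.cumsum(delta[:-1])
    return pd.DataFrame(
        mat, index=[p.peak_id for p in consensus], columns=list(fragments.keys())
    )


def classify_tss_context(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    bins: Sequence[float] = DEFAULT_CONTEXT_BINS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Label peaks genic/intergenic and bin their nearest-TSS distances.

    A peak is *genic* when its midpoint lies inside any gene body, else
    *intergenic*.  Distance is |midpoint - nearest strand-aware TSS| over all
    genes on the peak's chromosome (infinite when the chromosome has no gene).
    Returns a per-peak table (peak_id, context, tss_distance, distance_bin)
    and a histogram over ``bins`` whose counts sum to the number of peaks.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    bins = np.asarray(bins, dtype=float)

    tss_by_chrom: dict[str, np.ndarray] = {}
    bodies_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(g.interval.chrom for g in genes):
        sub = [g for g in genes if g.interval.chrom == chrom]
        tss_by_chrom[chrom] = np.sort(np.array([g.tss for g in sub], dtype=np.int64))
        starts = np.array([g.interval.start for g in sub], dtype=np.int64)
        ends = np.array([g.interval.end for g in sub], dtype=np.int64)
        bodies_by_chrom[chrom] = (starts, ends)

    rows = []
    for p in peaks:
        mid = p.interval.midpoint
        chrom = p.interval.chrom
        if chrom in tss_by_chrom:
            tss = tss_by_chrom[chrom]
            k = np.searchsorted(tss, mid)
            cand = tss[max(k - 1, 0): k + 1]
            dist = float(np.min(np.abs(cand - mid)))
            starts, ends = bodies_by_chrom[chrom]
            genic = bool(np.any((starts <= mid) & (mid < ends)))
        else:
            dist, genic = np.inf, False
        rows.append((p.peak_id, "genic" if genic else "intergenic", dist))

    table = pd.DataFrame(rows, columns=["peak_id", "context", "tss_distance"])
    labels = [_bin_label(bins[i], bins[i + 1]) for i in range(len(bins) - 1)]
    idx = np.clip(np.searchsorted(bins, table["tss_distance"].to_numpy(), side="right") - 1,
                  0, len(labels) - 1)
    table["distance_bin"] = [labels[i] for i in idx]
    hist = table["distance_bin"].value_counts().reindex(labels, fill_value=0)
    hist.name = "n_peaks"
    return table, hist


def _bin_label(lo: float, hi: float) -> str:
    fmt = lambda x: "inf" if np.isinf(x) else f"{x / 1000:g}kb"
    return f"{fmt(lo)}-{fmt(hi)}"
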