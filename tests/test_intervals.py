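"""Interval algebra: RPKM filter, consensus merge, fragment counting,
TSS-context classification — checked against brute-force oracles."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tftargets import (
    GenomicInterval,
    Peak,
    PeakSet,
    classify_tss_context,
    compute_rpkm,
    count_fragments_in_intervals,
    filter_peaks_by_rpkm,
    merge_consensus,
)
from conftest import make_gene, make_peaks


# ---------------------------------------------------------------- data model

def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 50)
    iv = GenomicInterval("chr1", 10, 20)
    assert iv.length == 10
    assert iv.midpoint == 15


def test_peak_rejects_negative_signal():
    iv = GenomicInterval("chr1", 0, 100)
    with pytest.raises(ValueError):
        Peak(iv, "p1", rpkm=-1.0)
    with pytest.raises(ValueError):
        Peak(iv, "p1", counts=(3, -2))


def test_peakset_sorts_and_rejects_duplicate_ids():
    ps = make_peaks([("chr2", 5, 10), ("chr1", 50, 60), ("chr1", 5, 10)])
    assert [(p.interval.chrom, p.interval.start) for p in ps] == [
        ("chr1", 5), ("chr1", 50), ("chr2", 5)
    ]
    with pytest.raises(ValueError, match="duplicate"):
        PeakSet("N", peaks=[
            Peak(GenomicInterval("chr1", 0, 5), "x"),
            Peak(GenomicInterval("chr1", 9, 12), "x"),
        ])


def test_strand_aware_tss():
    assert make_gene("a", "chr1", 100, 200, "+").tss == 100
    assert make_gene("b", "chr1", 100, 200, "-").tss == 199


# --------------------------------------------------------------- rpkm filter

def test_rpkm_filter_boundary_keeps_at_threshold():
    ps = make_peaks(
        [("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500)],
        rpkms=[9.99, 10.0, 250.3],
    )
    kept = filter_peaks_by_rpkm(ps, 10.0)
    assert [p.rpkm for p in kept] == [10.0, 250.3]
    assert len(ps) == 3  # input untouched


def test_rpkm_filter_empty_and_zero_threshold():
    empty = PeakSet("N")
    assert len(filter_peaks_by_rpkm(empty, 10.0)) == 0
    ps = make_peaks([("chr1", 0, 100), ("chr1", 200, 300)], rpkms=[0.0, 3.0])
    assert len(filter_peaks_by_rpkm(ps, 0.0)) == len(ps)


def test_rpkm_filter_matches_elementwise_loop():
    rng = np.random.default_rng(7)
    rpkms = rng.exponential(20.0, size=1000)
    ps = make_peaks([("chr1", 1000 * i, 1000 * i + 500) for i in range(1000)],
                    rpkms=list(rpkms))
    kept = filter_peaks_by_rpkm(ps, 10.0)
    survivors = sum(1 for r in rpkms if r >= 10.0)  # brute-force loop
    assert len(kept) == survivors


def test_compute_rpkm_formula():
    counts = np.array([[10, 20], [30, 40]])
    lengths = np.array([1000, 2000])
    lib = np.array([1_000_000, 2_000_000])
    rpkm = compute_rpkm(counts, lengths, lib)
    # count * 1e9 / (len * lib), replicate-averaged
    expected0 = (10 * 1e9 / (1000 * 1e6) + 20 * 1e9 / (1000 * 2e6)) / 2
    assert rpkm[0] == pytest.approx(expected0)


# ------------------------------------------------------------ consensus merge

def sweep_union(intervals):
    """Independent sweep-line union (book-ended intervals merge)."""
    out = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return [tuple(x) for x in out]


def test_merge_overlapping_and_cross_chromosome():
    merged = merge_consensus([make_peaks([("chr1", 100, 200), ("chr1", 150, 250)])])
    assert [(p.interval.start, p.interval.end) for p in merged] == [(100, 250)]
    assert merged.peaks[0].source_ids == ("p1", "p2")

    merged = merge_consensus([make_peaks([("chr1", 100, 200), ("chr2", 100, 200)])])
    assert len(merged) == 2


def test_merge_bookended_intervals():
    merged = merge_consensus([make_peaks([("chr1", 100, 200), ("chr1", 200, 300)])])
    assert [(p.interval.start, p.interval.end) for p in merged] == [(100, 300)]


def test_merge_matches_sweepline_oracle():
    rng = np.random.default_rng(11)
    triples = []
    for i in range(500):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, 100_000))
        triples.append((chrom, start, start + int(rng.integers(1, 2000))))
    sets = [make_peaks(triples[:250], "N"),
            make_peaks([(c, s, e) for c, s, e in triples[250:]], "EY")]
    merged = merge_consensus(sets)
    got = [(p.interval.chrom, p.interval.start, p.interval.end) for p in merged]
    assert got == sweep_union(triples)


def test_merge_matches_bedtools(tmp_path):
    """Independent cross-check against the reference merging tool."""
    rng = np.random.default_rng(3)
    triples = sorted(
        ("chr1", int(s), int(s) + int(rng.integers(1, 800)))
        for s in rng.integers(0, 50_000, size=200)
    )
    bed = tmp_path / "in.bed"
    bed.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in triples))
    out = subprocess.run(
        ["bedtools", "merge", "-i", str(bed)], capture_output=True, text=True, check=True
    ).stdout
    expected = [tuple(line.split("\t")) for line in out.strip().split("\n")]
    merged = merge_consensus([make_peaks(triples)])
    got = [(p.interval.chrom, str(p.interval.start), str(p.interval.end)) for p in merged]
    assert got == expected


interval_lists = st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 5000), st.integers(1, 300)),
    min_size=1, max_size=40,
)


@settings(max_examples=50, derandomize=True)
@given(interval_lists)
def test_merge_disjoint_sorted_idempotent(raw):
    triples = [(c, s, s + l) for c, s, l in raw]
    merged = merge_consensus([make_peaks(triples)])
    ivs = merged.intervals()
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom:
            assert a.end < b.start  # disjoint, not even book-ended
        assert (a.chrom, a.start) <= (b.chrom, b.start)
    assert sum(iv.length for iv in ivs) <= sum(e - s for _, s, e in triples)
    again = merge_consensus([merged])
    assert [(i.start, i.end) for i in again.intervals()] == [
        (i.start, i.end) for i in ivs
    ]


# ---------------------------------------------------------- fragment counting

def test_count_fragments_containment_and_one_bp_overlap():
    consensus = merge_consensus([make_peaks([("chr1", 100, 200)])])
    counts = count_fragments_in_intervals(
        {"r1": [GenomicInterval("chr1", 150, 160)],
         "r2": [GenomicInterval("chr1", 199, 210)],
         "r3": [GenomicInterval("chr1", 200, 210)]},
        consensus,
    )
    assert counts.loc["consensus_1", "r1"] == 1
    assert counts.loc["consensus_1", "r2"] == 1  # 1-bp overlap counts
    assert counts.loc["consensus_1", "r3"] == 0  # book-ended fragment does not


def test_count_fragments_rejects_unsorted_consensus():
    bad = PeakSet("N", peaks=[
        Peak(GenomicInterval("chr1", 0, 100), "a"),
        Peak(GenomicInterval("chr1", 50, 160), "b"),
    ])
    with pytest.raises(ValueError, match="disjoint"):
        count_fragments_in_intervals({"r": []}, bad)


def test_count_fragments_matches_allpairs_oracle():
    rng = np.random.default_rng(3)
    consensus = merge_consensus([make_peaks(
        [("chr1", 1000 * i, 1000 * i + int(rng.integers(100, 900))) for i in range(200)]
    )])
    frags = {
        rep: [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 400)))
            for s in rng.integers(0, 200_000, size=5000)
        ]
        for rep in ("r1", "r2")
    }
    got = count_fragments_in_intervals(frags, consensus)
    for j, rep in enumerate(("r1", "r2")):
        for i, peak in enumerate(consensus):
            expected = sum(f.overlaps(peak.interval) for f in frags[rep])
            assert got.iloc[i, j] == expected


# --------------------------------------------------------- TSS context

def test_context_zero_distance_and_genic_binning():
    genes = [make_gene("a", "chr1", 100_000, 200_000, "+")]
    peaks = make_peaks([
        (("chr1"), 99_750, 100_250),      # midpoint exactly at the TSS
        (("chr1"), 149_750, 150_250),     # inside body, 50 kb from TSS
    ])
    table, hist = classify_tss_context(peaks, genes)
    assert table.loc[0, "tss_distance"] == 0
    assert table.loc[0, "distance_bin"] == "0kb-10kb"
    assert table.loc[1, "context"] == "genic"
    assert table.loc[1, "distance_bin"] == "10kb-100kb"
    assert hist.sum() == len(peaks)


def test_context_requires_genes():
    with pytest.raises(ValueError):
        classify_tss_context(make_peaks([("chr1", 0, 10)]), [])


def test_context_matches_exhaustive_nearest_tss_scan():
    rng = np.random.default_rng(5)
    genes = [
        make_gene(f"g{i}", "chr1", int(s), int(s) + 5000, "+-"[int(rng.integers(2))])
        for i, s in enumerate(sorted(rng.choice(2_000_000 // 6000, 100, replace=False) * 6000))
    ]
    peaks = make_peaks([
        ("chr1", int(s), int(s) + 400) for s in rng.integers(0, 2_000_000, size=1000)
    ])
    table, hist = classify_tss_context(peaks, genes)
    # oracle: exhaustive scan over all genes per peak
    edges = [0, 10_000, 100_000, np.inf]
    oracle_bins = {lab: 0 for lab in hist.index}
    for p in peaks:
        mid = p.interval.midpoint
        d = min(abs(g.tss - mid) for g in genes)
        genic = any(g.interval.start <= mid < g.interval.end for g in genes)
        row = table[table["peak_id"] == p.peak_id].iloc[0]
        assert row["tss_distance"] == d
        assert (row["context"] == "genic") == genic
        k = max(i for i in range(3) if edges[i] <= d)
        oracle_bins[hist.index[k]] += 1
    assert hist.to_dict() == oracle_bins
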