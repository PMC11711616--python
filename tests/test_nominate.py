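"""Peak annotation, regulatory potential, BETA KS test, evidence intersection."""

import math

import numpy as np
import pandas as pd
import pytest

from tftargets import (
    PeakSet,
    annotate_peaks,
    beta_test,
    intersect_evidence,
    regulatory_potential,
)
from conftest import make_gene, make_peaks


def peak_at(mid, chrom="chr1", width=200, pid="p1"):
    return make_peaks([(chrom, mid - width // 2, mid + width // 2)])


# ------------------------------------------------------------- annotation

def test_annotate_tss_window_strict_boundary():
    gene = make_gene("gA", "chr1", 1_000_000, 1_010_000, "+")  # TSS at 1,000,000
    near = peak_at(1_000_000 - 9_999)
    at_limit = peak_at(1_000_000 - 10_000)
    links_near = annotate_peaks(near, [gene])
    links_limit = annotate_peaks(at_limit, [gene])
    assert links_near.iloc[0]["relation"] == "near_tss"
    assert links_near.iloc[0]["tss_distance"] == 9_999
    assert links_limit.empty  # "closer than 10 kb" excludes the boundary


def test_annotate_in_body_and_multi_gene_links():
    genes = [
        make_gene("gA", "chr1", 0, 50_000, "+"),
        make_gene("gB", "chr1", 52_000, 80_000, "+"),
    ]
    ps = peak_at(49_000)  # inside gA body, 3 kb before gB TSS
    links = annotate_peaks(ps, genes).set_index("gene_id")
    assert links.loc["gA", "relation"] == "in_body"
    assert links.loc["gB", "relation"] == "near_tss"


def test_annotate_requires_genes_and_positive_window():
    ps = peak_at(100)
    with pytest.raises(ValueError):
        annotate_peaks(ps, [])
    with pytest.raises(ValueError):
        annotate_peaks(ps, [make_gene("g", "chr1", 0, 10)], tss_window=0)


def test_annotate_matches_allpairs_oracle_and_window_monotone():
    rng = np.random.default_rng(23)
    genes = [
        make_gene(f"g{i}", "chr1", int(s), int(s) + 8_000, "+-"[int(rng.integers(2))])
        for i, s in enumerate(sorted(rng.choice(3_000_000 // 10_000, 150, replace=False) * 10_000))
    ]
    ps = make_peaks([
        ("chr1", int(s), int(s) + 500) for s in rng.integers(0, 3_000_000, size=2000)
    ])
    links = annotate_peaks(ps, genes, tss_window=10_000)
    got = {(r.peak_id, r.gene_id) for r in links.itertuples()}
    oracle = set()
    for p in ps:
        mid = p.interval.midpoint
        for g in genes:
            if (g.interval.start <= mid < g.interval.end) or abs(g.tss - mid) < 10_000:
                oracle.add((p.peak_id, g.gene_id))
    assert got == oracle
    wider = annotate_peaks(ps, genes, tss_window=25_000)
    assert got <= {(r.peak_id, r.gene_id) for r in wider.itertuples()}


# ------------------------------------------------------- regulatory potential

def test_rp_closed_form_values():
    gene = make_gene("gA", "chr1", 1_000_000, 1_005_000, "+")
    at_tss = peak_at(1_000_000)
    at_edge = peak_at(1_000_000 + 100_000)
    none_near = peak_at(1_000_000 + 100_001 + 100)  # midpoint just past the window
    assert regulatory_potential([gene], at_tss).loc["gA", "rp"] == pytest.approx(
        math.exp(-0.5)
    )
    assert regulatory_potential([gene], at_edge).loc["gA", "rp"] == pytest.approx(
        math.exp(-4.5)
    )
    assert regulatory_potential([gene], none_near).loc["gA", "rp"] == 0.0


def test_rp_additive_and_decreasing_in_distance():
    gene = make_gene("gA", "chr1", 500_000, 505_000, "+")
    singles = [
        regulatory_potential([gene], peak_at(500_000 + d)).loc["gA", "rp"]
        for d in (0, 10_000, 50_000, 99_000)
    ]
    assert all(a > b for a, b in zip(singles, singles[1:]))
    both = make_peaks([
        ("chr1", 500_000 - 100, 500_000 + 100),
        ("chr1", 510_000 - 100, 510_000 + 100),
    ])
    combined = regulatory_potential([gene], both).loc["gA", "rp"]
    assert combined == pytest.approx(singles[0] + singles[1])


def test_rp_rank_is_permutation_with_deterministic_ties():
    genes = [make_gene(f"g{i}", "chr2", 10_000 * i + 1_000, 10_000 * i + 3_000, "+")
             for i in range(5)]
    rp = regulatory_potential(genes, PeakSet("tf"))  # no peaks: all rp 0, tie on id
    assert sorted(rp["rp_rank"]) == [1, 2, 3, 4, 5]
    assert list(rp.sort_values("rp_rank").index) == [g.gene_id for g in genes]


# --------------------------------------------------------------- BETA test

def _rp_frame(ranks):
    return pd.DataFrame(
        {"rp": 0.0, "rp_rank": list(ranks)},
        index=pd.Index([f"g{i}" for i in range(len(ranks))], name="gene_id"),
    )


def _degs(classes, lfcs=None):
    idx = pd.Index([f"g{i}" for i in range(len(classes))], name="gene_id")
    return pd.DataFrame(
        {"log2fc": lfcs if lfcs is not None else 0.0, "klass": list(classes)},
        index=idx,
    )


def test_beta_identical_rank_multisets_give_null():
    # up and static classes carry exactly the same rank multiset
    rp = pd.concat([_rp_frame(range(1, 11)),
                    _rp_frame(range(1, 11)).set_index(pd.Index([f"h{i}" for i in range(10)], name="gene_id"))])
    degs = pd.DataFrame(
        {"log2fc": 2.0, "klass": ["up"] * 10 + ["static"] * 10}, index=rp.index
    )
    res = beta_test(rp, degs)
    assert res.ks_up[0] == 0.0
    assert res.ks_up[1] == pytest.approx(1.0)


def test_beta_concentrated_up_ranks_highly_significant():
    n = 1000
    rp = _rp_frame(range(1, n + 1))
    classes = ["up" if r <= 50 else "static" for r in range(1, n + 1)]
    res = beta_test(rp, _degs(classes, lfcs=2.0))
    assert res.ks_up[1] < 1e-3
    assert res.ks_down is None  # empty down class flagged undefined, not zero
    for curve in res.curves.values():
        frac = curve["cumulative_fraction"].to_numpy()
        assert (np.diff(frac) >= 0).all()
        assert frac[-1] == pytest.approx(1.0)


def test_beta_ks_matches_bruteforce_ecdf_enumeration():
    rng = np.random.default_rng(31)
    ranks = rng.permutation(np.arange(1, 201)) + 0.0
    classes = ["up"] * 40 + ["static"] * 160
    rp = _rp_frame(ranks)
    res = beta_test(rp, _degs(classes, lfcs=1.5))
    up = np.sort(ranks[:40])
    static = np.sort(ranks[40:])
    grid = np.concatenate([up, static])
    d_oracle = max(
        abs((up <= x).mean() - (static <= x).mean()) for x in grid
    )
    assert res.ks_up[0] == pytest.approx(d_oracle)


def test_beta_activated_ranking_is_rank_product_ascending():
    rp = _rp_frame([3, 1, 2, 4])
    degs = _degs(["up", "up", "static", "up"], lfcs=[1.5, 3.0, 0.0, 2.0])
    res = beta_test(rp, degs)
    # up-regulation ranks: g1 (lfc 3.0) -> 1, g3 (2.0) -> 2, g0 (1.5) -> 3
    # rank products: g1: 1*1=1, g3: 4*2=8, g0: 3*3=9
    assert list(res.activated_ranking.index) == ["g1", "g3", "g0"]
    assert list(res.activated_ranking["rank_product"]) == [1, 8, 9]


def test_beta_missing_rp_gene_rejected():
    rp = _rp_frame([1, 2])
    degs = _degs(["up", "static", "up"])
    with pytest.raises(ValueError, match="missing"):
        beta_test(rp, degs)


# ------------------------------------------------------- evidence intersection

def test_directional_overlap_percentage():
    b = {f"id{i}" for i in range(38_020)}
    a = {f"id{i}" for i in range(28_986)}
    _, summary = intersect_evidence(b, a, set(), set())
    pct = summary["overlap_pct"]["gained_acetyl"]["gained_tf"]
    assert round(pct) == 76


def test_identical_sets_all_nominated():
    s = {"g1", "g2", "g3"}
    table, summary = intersect_evidence(s, set(s), set(s), set(s))
    assert table["nominated"].all()
    assert summary["n_nominated"] == 3
    assert summary["venn_regions"] == {
        "gained_tf&gained_acetyl&gained_access&upregulated": 3
    }
    for a in summary["overlap_pct"]:
        for b in summary["overlap_pct"][a]:
            assert summary["overlap_pct"][a][b] == pytest.approx(100.0)


def test_intersection_matches_membership_oracle_and_order_invariance():
    rng = np.random.default_rng(29)
    universe = [f"g{i}" for i in range(2000)]
    sets = [set(rng.choice(universe, size=500, replace=False).tolist())
            for _ in range(4)]
    table, summary = intersect_evidence(*sets)
    for g in table.index:
        assert table.loc[g, "has_gained_tf"] == (g in sets[0])
        assert table.loc[g, "has_gained_acetyl"] == (g in sets[1])
        assert table.loc[g, "has_gained_access"] == (g in sets[2])
        assert table.loc[g, "is_upregulated"] == (g in sets[3])
        assert table.loc[g, "nominated"] == all(g in s for s in sets)
    assert sum(summary["venn_regions"].values()) == len(set().union(*sets))
    shuffled = [set(sorted(s, reverse=True)) for s in sets]
    table2, _ = intersect_evidence(*shuffled)
    assert set(table2.index[table2["nominated"]]) == set(table.index[table["nominated"]])
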