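"""Peak-to-gene annotation, regulatory potential, BETA-style target calling.

The integration statistic follows the binding-and-expression-target-analysis
idea: every gene receives a *regulatory potential* (RP), a distance-decayed
sum over nearby binding sites; genes are ranked by RP and the RP-rank
distributions of up-, down- and non-regulated genes are compared with
two-sample Kolmogorov-Smirnov tests.  A factor whose up-regulated genes sit
at systematically better RP ranks than unaffected genes (small ks_up p) while
down-regulated genes do not (large ks_down p) is called an activator.

The final nomination step intersects four gene-level evidence flags — gained
factor binding, gained histone acetylation, gained accessibility, and
transcriptional up-regulation — and reports directional overlap percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, PeakSet

__all__ = [
    "annotate_peaks",
    "genes_with_peaks",
    "regulatory_potential",
    "beta_test",
    "BetaResult",
    "intersect_evidence",
]

TSS_WINDOW = 10_000
RP_WINDOW = 100_000
RP_DECAY_OFFSET = 0.5
RP_DECAY_SCALE = 4.0


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    tss_window: int = TSS_WINDOW,
) -> pd.DataFrame:
    """Link peaks to genes: in the gene body, or strictly closer than
    ``tss_window`` bp to the TSS.

    One row per satisfying (peak, gene) pair with columns peak_id, gene_id,
    relation (in_body preferred when both rules hold), tss_distance.  A peak
    may link to several genes; a peak satisfying neither rule yields no row.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if tss_window <= 0:
        raise ValueError("tss_window must be positive")

    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, sub in by_chrom.items():
        gstart = np.array([g.interval.start for g in sub], dtype=np.int64)
        gend = np.array([g.interval.end for g in sub], dtype=np.int64)
        gtss = np.array([g.tss for g in sub], dtype=np.int64)
        for p in peaks:
            if p.interval.chrom != chrom:
                continue
            mid = p.interval.midpoint
            dist = np.abs(gtss - mid)
            in_body = (gstart <= mid) & (mid < gend)
            near = dist < tss_window
            for j in np.flatnonzero(in_body | near):
                rows.append(
                    (
                        p.peak_id,
                        sub[j].gene_id,
                        "in_body" if in_body[j] else "near_tss",
                        int(dist[j]),
                    )
                )
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "relation", "tss_distance"]
    )


def genes_with_peaks(links: pd.DataFrame, peak_ids: Iterable[str]) -> set[str]:
    """Gene ids linked to at least one of the given peaks."""
    peak_ids = set(peak_ids)
    sel = links[links["peak_id"].isin(peak_ids)]
    return set(sel["gene_id"])


def regulatory_potential(
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    window: int = RP_WINDOW,
    decay_offset: float = RP_DECAY_OFFSET,
    decay_scale: float = RP_DECAY_SCALE,
) -> pd.DataFrame:
    """Distance-decayed regulatory potential per gene.

    rp(g) = sum over peaks whose midpoint lies within ``window`` bp of g's
    TSS of exp(-(decay_offset + decay_scale * d / window)), d the midpoint-TSS
    distance.  A peak exactly at the TSS contributes exp(-decay_offset); a
    peak at the window edge contributes exp(-(decay_offset + decay_scale)).

    Returns a DataFrame indexed by gene_id with columns rp and rp_rank
    (1 = highest rp; ties broken by gene id).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mids: dict[str, np.ndarray] = {}
    pchrom = np.array([p.interval.chrom for p in peaks])
    pmid = np.array([p.interval.midpoint for p in peaks], dtype=np.int64)
    for chrom in dict.fromkeys(pchrom):
        mids[chrom] = np.sort(pmid[pchrom == chrom])

    gene_ids = [g.gene_id for g in genes]
    rp = np.zeros(len(genes))
    for i, g in enumerate(genes):
        arr = mids.get(g.interval.chrom)
        if arr is None or arr.size == 0:
            continue
        lo = np.searchsorted(arr, g.tss - window, side="left")
        hi = np.searchsorted(arr, g.tss + window, side="right")
        d = np.abs(arr[lo:hi] - g.tss)
        d = d[d <= window]
        rp[i] = np.exp(-(decay_offset + decay_scale * d / window)).sum()

    order = np.lexsort((np.array(gene_ids, dtype=object), -rp))
    rank = np.empty(len(genes), dtype=np.int64)
    rank[order] = np.arange(1, len(genes) + 1)
    out = pd.DataFrame({"rp": rp, "rp_rank": rank},
                       index=pd.Index(gene_ids, name="gene_id"))
    return out


@dataclass
class BetaResult:
    """KS comparison of RP-rank distributions across expression classes.

    ``curves`` maps class name -> DataFrame(rank_fraction, cumulative_fraction)
    — the non-decreasing cumulative share of that class's genes found at or
    above each RP rank.  ``ks_up``/``ks_down`` are (D, p) tuples, or None when
    the corresponding class is empty (undefined, not zero).
    ``activated_ranking`` orders up-regulated genes by ascending rank product
    of RP rank and up-regulation (descending log2fc) rank.
    """

    curves: dict[str, pd.DataFrame]
    ks_up: tuple[float, float] | None
    ks_down: tuple[float, float] | None
    activated_ranking: pd.DataFrame

    @property
    def activator_verdict(self) -> bool | None:
        """True when up-genes show significant RP-rank shift and down-genes do not."""
        if self.ks_up is None or self.ks_down is None:
            return None
        return self.ks_up[1] < 0.01 and self.ks_down[1] > 0.05


def _cumulative_curve(ranks: np.ndarray, n_genes: int) -> pd.DataFrame:
    ranks = np.sort(ranks)
    return pd.DataFrame(
        {
            "rank_fraction": ranks / n_genes,
            "cumulative_fraction": np.arange(1, ranks.size + 1) / ranks.size,
        }
    )


def beta_test(rp: pd.DataFrame, degs: pd.DataFrame) -> BetaResult:
    """Compare RP-rank distributions of up/down/static genes (two-sided KS).

    ``rp`` is the output of :func:`regulatory_potential`; ``degs`` carries a
    ``klass`` column in {up, down, static} indexed by gene_id.  Every DEG gene
    must be present in ``rp``; rp genes without a DEG record count as static.
    """
    missing = degs.index.difference(rp.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} DEG genes missing from regulatory potential table "
            f"(e.g. {sorted(map(str, missing))[:3]})"
        )
    klass = pd.Series("static", index=rp.index)
    klass.loc[degs.index] = degs["klass"]
    n_genes = len(rp)

    ranks = {
        c: rp.loc[klass[klass == c].index, "rp_rank"].to_numpy(dtype=float)
        for c in ("up", "down", "static")
    }
    curves = {
        c: _cumulative_curve(r, n_genes) for c, r in ranks.items() if r.size
    }

    def ks(a: np.ndarray, b: np.ndarray):
        if a.size == 0 or b.size == 0:
            return None
        res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
        return float(res.statistic), float(res.pvalue)

    ks_up = ks(ranks["up"], ranks["static"])
    ks_down = ks(ranks["down"], ranks["static"])

    up_idx = klass[klass == "up"].index
    if len(up_idx):
        lfc = degs.loc[up_idx, "log2fc"]
        up_rank = lfc.rank(ascending=False, method="first")
        table = pd.DataFrame(
            {
                "rp_rank": rp.loc[up_idx, "rp_rank"],
                "up_rank": up_rank.astype(int),
            },
            index=up_idx,
        )
        table["rank_product"] = table["rp_rank"] * table["up_rank"]
        # deterministic order: rank product, then rp_rank, then gene id
        table = table.sort_index(kind="mergesort").sort_values(
            ["rank_product", "rp_rank"], kind="mergesort"
        )
    else:
        table = pd.DataFrame(columns=["rp_rank", "up_rank", "rank_product"])
    return BetaResult(curves=curves, ks_up=ks_up, ks_down=ks_down,
                      activated_ranking=table)


def intersect_evidence(
    gained_tf_genes: Iterable[str],
    gained_acetyl_genes: Iterable[str],
    gained_access_genes: Iterable[str],
    up_genes: Iterable[str],
    provenance: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Four-way evidence intersection nominating directly regulated genes.

    Returns (table, summary).  ``table`` has one row per gene in the union
    with boolean columns has_gained_tf / has_gained_acetyl / has_gained_access
    / is_upregulated and ``nominated`` (all four true); optional ``provenance``
    (modality -> gene -> contributing peak ids) is attached as per-modality
    comma-joined columns.  ``summary`` holds Venn region counts keyed by
    '&'-joined modality names and directional pairwise overlaps
    overlap_pct[A][B] = 100 * |A ∩ B| / |B|.
    """
    sets = {
        "gained_tf": set(gained_tf_genes),
        "gained_acetyl": set(gained_acetyl_genes),
        "gained_access": set(gained_access_genes),
        "upregulated": set(up_genes),
    }
    universe = sorted(set().union(*sets.values()))
    table = pd.DataFrame(
        {
            "has_gained_tf": [g in sets["gained_tf"] for g in universe],
            "has_gained_acetyl": [g in sets["gained_acetyl"] for g in universe],
            "has_gained_access": [g in sets["gained_access"] for g in universe],
            "is_upregulated": [g in sets["upregulated"] for g in universe],
        },
        index=pd.Index(universe, name="gene_id"),
    )
    table["nominated"] = table.all(axis=1)
    if provenance:
        for modality, genes in provenance.items():
            table[f"peaks_{modality}"] = [
                ",".join(genes.get(g, ())) for g in universe
            ]

    regions: dict[str, int] = {}
    for g in universe:
        members = [n for n, s in sets.items() if g in s]
        key = "&".join(members)
        regions[key] = regions.get(key, 0) + 1

    overlap_pct = {
        a: {
            b: (100.0 * len(sets[a] & sets[b]) / len(sets[b]) if sets[b] else float("nan"))
            for b in sets
        }
        for a in sets
    }
    summary = {
        "venn_regions": regions,
        "overlap_pct": overlap_pct,
        "n_nominated": int(table["nominated"].sum()),
    }
    return table, summary
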