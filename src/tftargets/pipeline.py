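"""End-to-end orchestration: simulate -> filter -> merge -> test -> nominate.

Chains the stage functions on in-memory objects; the CLI wraps the same
functions around files.  The main entry point, :func:`run_target_nomination`,
runs the full multiomic nomination on one simulated dataset and scores the
nominated gene set against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexp import differential_expression, differential_occupancy
from .intervals import DEFAULT_RPKM_THRESHOLD, PeakSet, filter_peaks_by_rpkm, merge_consensus
from .nominate import (
    BetaResult,
    annotate_peaks,
    beta_test,
    genes_with_peaks,
    intersect_evidence,
    regulatory_potential,
)
from .simulate import MODALITIES, SimulationConfig, TruthTable, simulate_expression, \
    simulate_genome, simulate_peaks_and_counts

__all__ = ["NominationResult", "consensus_counts", "run_target_nomination"]


@dataclass
class NominationResult:
    """Everything the end-to-end nomination run produced."""

    nominated: set[str]
    evidence: pd.DataFrame
    venn_summary: dict
    beta: BetaResult
    degs: pd.DataFrame
    diff_tables: dict[str, pd.DataFrame]
    gained_genes: dict[str, set[str]]
    truth: TruthTable
    precision: float
    recall: float


def consensus_counts(consensus: PeakSet, counts: pd.DataFrame) -> pd.DataFrame:
    """Count matrix for consensus peaks: sum of their source peaks' rows."""
    pairs = [
        (p.peak_id, src) for p in consensus for src in dict.fromkeys(p.source_ids)
    ]
    if not pairs:
        return pd.DataFrame(columns=counts.columns, dtype=int)
    cons_ids = [c for c, _ in pairs]
    src_ids = [s for _, s in pairs]
    summed = counts.loc[src_ids].groupby(pd.Index(cons_ids), sort=False).sum()
    order = [p.peak_id for p in consensus]
    return summed.reindex(order).astype(int).rename_axis("peak_id")


def run_target_nomination(
    config: SimulationConfig,
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
    alpha_occupancy: float = 0.05,
    alpha_deg: float = 0.01,
    lfc_deg: float = 1.0,
    tss_window: int = 10_000,
    rp_window: int = 100_000,
) -> NominationResult:
    """Simulate one multiomic dataset and nominate direct target genes.

    Per modality: RPKM-filter each condition's peaks, merge the survivors
    into consensus intervals, recount, and classify gained/lost/unchanged.
    Gained peaks are annotated to genes (gene body or strictly < tss_window
    from the TSS).  Expression counts yield up/down/static calls; gained
    factor peaks give a regulatory potential per gene and the BETA KS
    comparison; the four-way evidence intersection is the nominated set,
    scored for precision/recall against the planted direct targets.
    """
    genes = simulate_genome(config)
    sims, truth = simulate_peaks_and_counts(config, genes)

    diff_tables: dict[str, pd.DataFrame] = {}
    gained_genes: dict[str, set[str]] = {}
    provenance: dict[str, dict[str, list[str]]] = {}
    consensus_sets: dict[str, PeakSet] = {}
    for modality in MODALITIES:
        sim = sims[modality]
        filtered = [
            filter_peaks_by_rpkm(sim.peak_sets[cond], rpkm_threshold)
            for cond in sim.peak_sets
        ]
        consensus = merge_consensus(filtered, condition=modality)
        consensus_sets[modality] = consensus
        counts = consensus_counts(consensus, sim.counts)
        diff = differential_occupancy(
            counts, sim.group_labels, alpha=alpha_occupancy, reference="N"
        )
        diff_tables[modality] = diff
        gained_ids = set(diff.index[diff["klass"] == "gained"])
        links = annotate_peaks(consensus, genes, tss_window=tss_window)
        gained_links = links[links["peak_id"].isin(gained_ids)]
        gained_genes[modality] = set(gained_links["gene_id"])
        provenance[modality] = {
            g: sorted(sub["peak_id"]) for g, sub in gained_links.groupby("gene_id")
        }

    expr_counts, _tpm = simulate_expression(config, genes, truth)
    degs = differential_expression(
        expr_counts, ["N"] * config.n_replicates + ["EY"] * config.n_replicates,
        alpha=alpha_deg, lfc_threshold=lfc_deg, reference="N",
    )
    up_genes = set(degs.index[degs["klass"] == "up"])

    tf_consensus = consensus_sets["tf"]
    tf_gained_ids = set(
        diff_tables["tf"].index[diff_tables["tf"]["klass"] == "gained"]
    )
    gained_peaks = PeakSet(
        condition="tf_gained",
        peaks=[p for p in tf_consensus if p.peak_id in tf_gained_ids],
    )
    rp = regulatory_potential(genes, gained_peaks, window=rp_window)
    beta = beta_test(rp, degs)

    evidence, summary = intersect_evidence(
        gained_genes["tf"], gained_genes["acetyl"], gained_genes["access"],
        up_genes, provenance=provenance,
    )
    nominated = set(evidence.index[evidence["nominated"]])

    tp = len(nominated & truth.direct_targets)
    precision = tp / len(nominated) if nominated else float("nan")
    recall = tp / len(truth.direct_targets) if truth.direct_targets else float("nan")
    return NominationResult(
        nominated=nominated,
        evidence=evidence,
        venn_summary=summary,
        beta=beta,
        degs=degs,
        diff_tables=diff_tables,
        gained_genes=gained_genes,
        truth=truth,
        precision=precision,
        recall=recall,
    )
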