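"""Synthetic multiomic data with planted ground truth.

Generates everything the pipeline consumes — a gene annotation, per-modality
peak sets with negative-binomial fragment counts for two conditions, an
expression count matrix, a cohort expression matrix with a latent signature
activity, and survival times coupled to that activity — together with truth
tables recording which peaks were planted as gained/lost and which genes are
direct targets.  All randomness flows from a single seed expanded into fixed
per-stage child streams, so every stage is independently reproducible and a
rerun with the same config is byte-identical.

Count model: NB with Var = mu + dispersion * mu^2 (shared dispersion);
condition-gained peaks have their mean multiplied by 2**effect in the test
condition, lost peaks divided by the same factor.  A configurable fraction of
gained factor peaks is placed within the TSS window of designated
direct-target genes, which also receive a planted expression log2
fold-change and one gained peak per accessory modality — those genes are the
recoverable truth for the end-to-end nomination benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, Peak, PeakSet, compute_rpkm

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "ModalitySim",
    "CohortSim",
    "simulate_genome",
    "simulate_peaks_and_counts",
    "simulate_expression",
    "simulate_cohort",
    "simulate_survival",
]

# fixed stage indices for child-seed derivation (documented counter scheme)
_STAGES = {
    "genome": 0,
    "peaks_tf": 1,
    "peaks_acetyl": 2,
    "peaks_access": 3,
    "expression": 4,
    "cohort": 5,
    "survival": 6,
    "targets": 7,
}

MODALITIES = ("tf", "acetyl", "access")
CONDITIONS = ("N", "EY")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults at benchmark scale.

    Peak counts mirror a desk-scale version of a CUT&Tag/ATAC experiment:
    a few thousand peaks per modality, four replicates per condition,
    NB mean 100 with dispersion 0.05, four-fold gained peaks and a planted
    expression log2FC of 2 for target genes.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000}
    )
    n_genes: int = 800
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    peak_width: int = 500
    n_peaks: Mapping[str, int] = field(
        default_factory=lambda: {"tf": 2_000, "acetyl": 1_500, "access": 1_500}
    )
    fraction_gained: float = 0.10
    fraction_lost: float = 0.05
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    n_replicates: int = 4
    effect: float = 2.0  # log2 fold change of gained/lost peak means
    linked_fraction: float = 0.30
    tss_window: int = 10_000
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.25
    n_indirect_up: int = 60
    n_indirect_down: int = 40
    # cohort / survival layer
    n_tumor: int = 200
    n_normal: int = 44
    score_coupling: float = 0.5  # log2-units of signature-gene shift per latent SD
    cohort_noise_sd: float = 0.30
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    log_hr_per_sd: float = 0.8
    censoring_fraction: float = 0.30

    def __post_init__(self) -> None:
        for name, frac in (
            ("fraction_gained", self.fraction_gained),
            ("fraction_lost", self.fraction_lost),
            ("linked_fraction", self.linked_fraction),
            ("censoring_fraction", self.censoring_fraction),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 for differential testing")

    def rng(self, stage: str) -> np.random.Generator:
        """Child generator for a named stage (seed, stage-index) — stable
        across runs and independent across stages."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        )

    def n_gained(self, modality: str) -> int:
        return round(self.fraction_gained * self.n_peaks[modality])

    def n_linked(self) -> int:
        return round(self.linked_fraction * self.n_gained("tf"))


@dataclass
class TruthTable:
    """Planted ground truth for one simulation."""

    peak_class: dict[str, pd.Series]  # modality -> peak_id -> gained/lost/unchanged
    gene_class: pd.Series  # gene_id -> direct_target/indirect_up/indirect_down/null
    direct_targets: set[str]
    latent_scores: pd.Series | None = None  # cohort sample -> latent activity


@dataclass
class ModalitySim:
    """Simulated peaks and counts for one assay modality."""

    modality: str
    peak_sets: dict[str, PeakSet]  # condition -> PeakSet (shared intervals)
    counts: pd.DataFrame  # peak x replicate (both conditions)
    group_labels: list[str]  # condition per counts column


@dataclass
class CohortSim:
    """Simulated patient cohort: expression, tissue classes, latent activity."""

    tpm: pd.DataFrame  # gene x sample
    tissue: pd.Series  # sample -> tumor/normal
    latent: pd.Series  # sample -> latent signature activity (SD units)


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping gene bodies with random strands.

    Each chromosome is divided into equal slots (one gene per slot), the gene
    length is drawn uniformly from ``gene_length_range`` and the body placed
    uniformly within its slot, which guarantees zero pairwise overlap.
    """
    rng = config.rng("genome")
    lmin, lmax = config.gene_length_range
    total = sum(config.chrom_lengths.values())
    genes: list[GeneModel] = []
    remaining = config.n_genes
    chroms = list(config.chrom_lengths.items())
    for ci, (chrom, length) in enumerate(chroms):
        if ci == len(chroms) - 1:
            n_c = remaining
        else:
            n_c = round(config.n_genes * length / total)
            n_c = min(n_c, remaining)
        remaining -= n_c
        if n_c == 0:
            continue
        slot = length // n_c
        if slot <= lmin:
            raise ValueError(
                f"cannot fit {n_c} genes of length >= {lmin} on {chrom} "
                f"(slot {slot} bp)"
            )
        for k in range(n_c):
            glen = int(rng.integers(lmin, min(lmax, slot - 1) + 1))
            start = k * slot + int(rng.integers(0, slot - glen + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gid = f"g{len(genes) + 1:05d}"
            genes.append(
                GeneModel(gid, GenomicInterval(chrom, start, start + glen, strand), strand)
            )
    return genes


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB sample with Var = mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _slot_grid(config: SimulationConfig) -> list[tuple[str, int]]:
    """Disjoint peak slots (chrom, slot_start) covering the genome."""
    slot_w = 4 * config.peak_width
    grid = []
    for chrom, length in config.chrom_lengths.items():
        grid.extend((chrom, s) for s in range(0, length - slot_w, slot_w))
    return grid


def _pick_direct_targets(
    rng: np.random.Generator, config: SimulationConfig, genes: Sequence[GeneModel]
) -> list[GeneModel]:
    n_linked = config.n_linked()
    if n_linked > len(genes):
        raise ValueError("more linked targets requested than genes available")
    idx = rng.choice(len(genes), size=n_linked, replace=False)
    return [genes[i] for i in sorted(idx)]


def simulate_peaks_and_counts(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> tuple[dict[str, ModalitySim], TruthTable]:
    """Per-modality peak sets for both conditions with NB counts and truth.

    Gained factor peaks are planted near direct-target TSSs (``linked_fraction``
    of them); the accessory modalities (acetylation, accessibility) each plant
    one gained peak near every direct target so that multiomic intersection
    can recover the planted truth.  Peaks occupy disjoint slots, so per-
    modality consensus merging is exact.  RPKM is computed from the counts
    with the same formula the filtering stage uses.
    """
    rng_targets = config.rng("targets")
    targets = _pick_direct_targets(rng_targets, config, genes)
    slot_w = 4 * config.peak_width
    sims: dict[str, ModalitySim] = {}
    peak_truth: dict[str, pd.Series] = {}

    for modality in MODALITIES:
        rng = config.rng(f"peaks_{modality}")
        n = config.n_peaks[modality]
        n_gained = config.n_gained(modality)
        n_lost = round(config.fraction_lost * n)
        n_linked = min(len(targets), n_gained)
        grid = _slot_grid(config)
        slot_index = {cs: i for i, cs in enumerate(grid)}
        used: set[int] = set()

        placements: list[tuple[str, int, str]] = []  # (chrom, start, class)
        # planted gained peaks near each direct-target TSS
        for g in targets[:n_linked]:
            want = min(
                max(g.tss - slot_w // 2, 0),
                config.chrom_lengths[g.interval.chrom] - slot_w - 1,
            )
            base = (g.interval.chrom, (want // slot_w) * slot_w)
            i = slot_index.get(base, 0)
            while i in used:  # nearest free slot (stays well inside tss_window)
                i += 1
            used.add(i)
            chrom, sstart = grid[i]
            mid = min(max(g.tss, sstart + config.peak_width // 2),
                      sstart + slot_w - config.peak_width // 2 - 1)
            placements.append((chrom, mid - config.peak_width // 2, "gained"))

        # background peaks in random free slots
        n_background = n - n_linked
        free = np.array([i for i in range(len(grid)) if i not in used])
        chosen = rng.choice(free, size=n_background, replace=False)
        classes = (
            ["gained"] * (n_gained - n_linked)
            + ["lost"] * n_lost
            + ["unchanged"] * (n_background - (n_gained - n_linked) - n_lost)
        )
        for i, klass in zip(chosen, classes):
            chrom, sstart = grid[i]
            start = sstart + int(rng.integers(0, slot_w - config.peak_width + 1))
            placements.append((chrom, start, klass))

        order = sorted(range(len(placements)), key=lambda k: (placements[k][0], placements[k][1]))
        peak_ids = [f"{modality}_{j + 1}" for j in range(len(placements))]
        chrom_arr = [placements[k][0] for k in order]
        start_arr = [placements[k][1] for k in order]
        class_arr = [placements[k][2] for k in order]

        base_mean = rng.lognormal(mean=math.log(config.nb_mean), sigma=0.5, size=n)
        mult = np.ones(n)
        mult[np.array(class_arr) == "gained"] = 2.0**config.effect
        mult[np.array(class_arr) == "lost"] = 2.0**-config.effect
        nrep = config.n_replicates
        counts_n = _nb_draw(rng, np.tile(base_mean[:, None], (1, nrep)), config.nb_dispersion)
        counts_ey = _nb_draw(
            rng, np.tile((base_mean * mult)[:, None], (1, nrep)), config.nb_dispersion
        )
        cols = [f"N_{r + 1}" for r in range(nrep)] + [f"EY_{r + 1}" for r in range(nrep)]
        counts = pd.DataFrame(
            np.hstack([counts_n, counts_ey]),
            index=pd.Index(peak_ids, name="peak_id"),
            columns=cols,
        )

        widths = np.full(n, config.peak_width)
        rpkm = {
            "N": compute_rpkm(counts_n, widths),
            "EY": compute_rpkm(counts_ey, widths),
        }
        peak_sets = {}
        for cond in CONDITIONS:
            reps = tuple(c for c in cols if c.startswith(cond + "_"))
            cond_counts = counts[list(reps)].to_numpy()
            peaks = [
                Peak(
                    interval=GenomicInterval(chrom_arr[j], start_arr[j],
                                             start_arr[j] + config.peak_width),
                    peak_id=peak_ids[j],
                    rpkm=float(rpkm[cond][j]),
                    counts=tuple(int(c) for c in cond_counts[j]),
                )
                for j in range(n)
            ]
            peak_sets[cond] = PeakSet(condition=cond, peaks=peaks, replicate_ids=reps)

        sims[modality] = ModalitySim(
            modality=modality,
            peak_sets=peak_sets,
            counts=counts,
            group_labels=["N"] * nrep + ["EY"] * nrep,
        )
        peak_truth[modality] = pd.Series(
            class_arr, index=pd.Index(peak_ids, name="peak_id"), name="klass"
        )

    gene_class = _assign_gene_classes(rng_targets, config, genes, targets)
    truth = TruthTable(
        peak_class=peak_truth,
        gene_class=gene_class,
        direct_targets={g.gene_id for g in targets},
    )
    return sims, truth


def _assign_gene_classes(
    rng: np.random.Generator,
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    targets: Sequence[GeneModel],
) -> pd.Series:
    gene_ids = [g.gene_id for g in genes]
    klass = pd.Series("null", index=pd.Index(gene_ids, name="gene_id"), name="klass")
    klass.loc[[g.gene_id for g in targets]] = "direct_target"
    pool = [g for g in gene_ids if klass[g] == "null"]
    n_up = min(config.n_indirect_up, len(pool))
    up = rng.choice(len(pool), size=n_up, replace=False)
    klass.loc[[pool[i] for i in up]] = "indirect_up"
    pool = [g for g in gene_ids if klass[g] == "null"]
    n_down = min(config.n_indirect_down, len(pool))
    down = rng.choice(len(pool), size=n_down, replace=False)
    klass.loc[[pool[i] for i in down]] = "indirect_down"
    return klass


def simulate_expression(
    config: SimulationConfig, genes: Sequence[GeneModel], truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample NB count matrix for both conditions, plus a TPM matrix.

    Direct-target and indirect-up genes receive a log2 fold-change drawn
    N(effect_log2fc_mean, sd) in the test condition; indirect-down genes the
    negated effect; null genes none.
    """
    rng = config.rng("expression")
    gene_ids = [g.gene_id for g in genes]
    lengths = np.array([g.interval.length for g in genes], dtype=float)
    n = len(genes)
    base = rng.lognormal(mean=math.log(config.nb_mean), sigma=0.5, size=n)
    lfc = np.zeros(n)
    kl = truth.gene_class.reindex(gene_ids).to_numpy()
    up_mask = (kl == "direct_target") | (kl == "indirect_up")
    down_mask = kl == "indirect_down"
    lfc[up_mask] = rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd,
                              size=int(up_mask.sum()))
    lfc[down_mask] = rng.normal(-config.effect_log2fc_mean, config.effect_log2fc_sd,
                                size=int(down_mask.sum()))
    nrep = config.n_replicates
    counts_n = _nb_draw(rng, np.tile(base[:, None], (1, nrep)), config.nb_dispersion)
    counts_ey = _nb_draw(rng, np.tile((base * 2.0**lfc)[:, None], (1, nrep)),
                         config.nb_dispersion)
    cols = [f"N_{r + 1}" for r in range(nrep)] + [f"EY_{r + 1}" for r in range(nrep)]
    counts = pd.DataFrame(
        np.hstack([counts_n, counts_ey]),
        index=pd.Index(gene_ids, name="gene_id"), columns=cols,
    )
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    tpm = pd.DataFrame(np.nan_to_num(tpm), index=counts.index, columns=cols)
    return counts, tpm


def simulate_cohort(
    config: SimulationConfig, genes: Sequence[GeneModel], truth: TruthTable
) -> CohortSim:
    """Patient-cohort expression with a latent signature activity per sample.

    Tumor samples draw latent activity N(1, 1), normal samples N(0, 1); each
    direct-target (signature) gene is shifted by ``score_coupling`` log2 units
    per latent SD on top of multiplicative log-normal noise, so a rank-based
    single-sample score of the signature tracks the latent activity.
    """
    rng = config.rng("cohort")
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)
    samples = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"M{i + 1:03d}" for i in range(config.n_normal)
    ]
    tissue = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
        index=pd.Index(samples, name="sample_id"), name="tissue",
    )
    latent = np.concatenate([
        rng.normal(1.0, 1.0, size=config.n_tumor),
        rng.normal(0.0, 1.0, size=config.n_normal),
    ])
    base = rng.lognormal(mean=math.log(50.0), sigma=1.0, size=n)
    sig = truth.gene_class.reindex(gene_ids).isin(["direct_target"]).to_numpy()
    noise = rng.lognormal(mean=0.0, sigma=config.cohort_noise_sd, size=(n, len(samples)))
    shift = np.where(sig[:, None], 2.0 ** (config.score_coupling * latent[None, :]), 1.0)
    tpm = pd.DataFrame(
        base[:, None] * shift * noise,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.Index(samples, name="sample_id"),
    )
    return CohortSim(tpm=tpm, tissue=tissue,
                     latent=pd.Series(latent, index=tissue.index, name="latent"))


def simulate_survival(config: SimulationConfig, scores: pd.Series) -> pd.DataFrame:
    """Exponential survival with hazard proportional to exp(logHR * z).

    ``z`` is the standardized score.  Exactly round(censoring_fraction * n)
    randomly chosen samples are censored at a uniform time before their event.
    Returns a DataFrame with columns sample_id, time (days), event.
    """
    rng = config.rng("survival")
    vals = scores.to_numpy(dtype=float)
    sd = vals.std()
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    rate = config.baseline_hazard * np.exp(config.log_hr_per_sd * z)
    times = rng.exponential(1.0 / rate)
    event = np.ones(len(vals), dtype=int)
    n_cens = round(config.censoring_fraction * len(vals))
    if n_cens:
        idx = rng.choice(len(vals), size=n_cens, replace=False)
        times[idx] = rng.uniform(0.0, times[idx])
        event[idx] = 0
    return pd.DataFrame(
        {"sample_id": scores.index, "time": times, "event": event}
    ).set_index("sample_id")
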