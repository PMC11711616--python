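"""Negative-binomial differential testing for peak and gene count matrices.

A deliberately transparent DESeq-style engine: median-of-ratios size factors,
per-feature method-of-moments dispersion with a floor, a Wald test on the
log2 fold change, and Benjamini-Hochberg adjustment.  No dispersion shrinkage,
outlier handling or independent filtering is performed — the goal is a small,
auditable test whose calibration is checked by simulation, not a re-creation
of any particular package's refinements.

Classification conventions:

* occupancy/accessibility/acetylation peaks: ``gained`` (padj < alpha and
  log2fc > 0), ``lost`` (padj < alpha and log2fc < 0), else ``unchanged``;
* expression: ``up`` (padj < alpha and log2fc > lfc), ``down`` (padj < alpha
  and log2fc < -lfc), else ``static``.
"""

from __future__ import annotations

from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "estimate_size_factors",
    "nb_differential_test",
    "differential_occupancy",
    "differential_expression",
    "venn_unique_sets",
]

DISPERSION_FLOOR = 0.01
LFC_PSEUDOCOUNT = 0.5
ALPHA_OCCUPANCY = 0.05
ALPHA_DEG = 0.01
LFC_DEG = 1.0


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The per-feature geometric-mean reference excludes features with any zero
    count.  Raises if no feature has all-positive counts (add a pseudocount
    upstream in that case).
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    allpos = np.all(mat > 0, axis=1)
    if not np.any(allpos):
        raise ValueError(
            "no feature with all-positive counts; add a pseudocount to the "
            "matrix before estimating size factors"
        )
    logmat = np.log(mat[allpos])
    logref = logmat.mean(axis=1)
    sf = np.exp(np.median(logmat - logref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _classify(
    log2fc: np.ndarray, padj: np.ndarray, alpha: float, lfc_threshold: float,
    labels: tuple[str, str, str],
) -> np.ndarray:
    pos, neg, none = labels
    klass = np.full(log2fc.shape, none, dtype=object)
    sig = padj < alpha
    klass[sig & (log2fc > lfc_threshold)] = pos
    klass[sig & (log2fc < -lfc_threshold)] = neg
    return klass


def nb_differential_test(
    counts: pd.DataFrame,
    group_labels: Sequence[Hashable],
    alpha: float = ALPHA_OCCUPANCY,
    lfc_threshold: float = 0.0,
    reference: Hashable | None = None,
    dispersion_floor: float = DISPERSION_FLOOR,
    class_labels: tuple[str, str, str] = ("gained", "lost", "unchanged"),
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test on a feature x sample matrix.

    ``group_labels`` assigns each column to one of exactly two groups;
    ``reference`` names the baseline group (defaults to the first label in
    column order), and log2fc is test-over-reference.  Each group needs >= 2
    replicates for the dispersion estimate.

    Per feature: size-factor-normalized group means, log2fc with a 0.5
    pseudocount, method-of-moments NB dispersion (floored), and a Wald
    statistic referred to Student-t with n1+n2-2 df — the t reference keeps
    the test calibrated at the handful-of-replicates scale where a normal
    reference is anticonservative.  All-zero features get p = 1, log2fc = 0.

    Returns a DataFrame indexed by feature id with columns
    base_mean, log2fc, pvalue, padj, klass.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    labels = pd.Series(list(group_labels), index=counts.columns)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    if reference is None:
        reference = uniq[0]
    other = uniq[1] if reference == uniq[0] else uniq[0]
    cols1 = labels[labels == reference].index
    cols2 = labels[labels == other].index
    n1, n2 = len(cols1), len(cols2)
    if min(n1, n2) < 2:
        raise ValueError(
            "at least two replicates per group are required to estimate dispersion"
        )

    try:
        sf = estimate_size_factors(counts)
    except ValueError:
        sf = estimate_size_factors(counts + 1)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    i1 = [counts.columns.get_loc(c) for c in cols1]
    i2 = [counts.columns.get_loc(c) for c in cols2]
    x1, x2 = norm[:, i1], norm[:, i2]

    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)

    # method-of-moments dispersion pooled over groups: Var = mu + disp * mu^2
    num = (n1 - 1) * (v1 - mu1) + (n2 - 1) * (v2 - mu2)
    den = (n1 - 1) * mu1**2 + (n2 - 1) * mu2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(den > 0, num / den, 0.0)
    disp = np.maximum(disp, dispersion_floor)

    log2fc = np.log2(mu2 + LFC_PSEUDOCOUNT) - np.log2(mu1 + LFC_PSEUDOCOUNT)
    var_mean1 = (mu1 + disp * mu1**2) / n1
    var_mean2 = (mu2 + disp * mu2**2) / n2
    se_lfc = np.sqrt(
        var_mean1 / (mu1 + LFC_PSEUDOCOUNT) ** 2
        + var_mean2 / (mu2 + LFC_PSEUDOCOUNT) ** 2
    ) / np.log(2)

    allzero = (mu1 == 0) & (mu2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se_lfc > 0, log2fc / se_lfc, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    pvalue = np.where(allzero, 1.0, pvalue)
    log2fc = np.where(allzero, 0.0, log2fc)

    padj = multipletests(pvalue, method="fdr_bh")[1]
    klass = _classify(log2fc, padj, alpha, lfc_threshold, class_labels)
    klass[allzero] = class_labels[2]

    return pd.DataFrame(
        {
            "base_mean": (mu1 * n1 + mu2 * n2) / (n1 + n2),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "klass": klass,
        },
        index=counts.index.rename("feature_id"),
    )


def differential_occupancy(
    counts: pd.DataFrame,
    group_labels: Sequence[Hashable],
    alpha: float = ALPHA_OCCUPANCY,
    reference: Hashable | None = None,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Gained/lost/unchanged peak classification at padj < alpha (no fold-change cut)."""
    return nb_differential_test(
        counts, group_labels, alpha=alpha, lfc_threshold=0.0, reference=reference,
        dispersion_floor=dispersion_floor, class_labels=("gained", "lost", "unchanged"),
    )


def differential_expression(
    counts: pd.DataFrame,
    group_labels: Sequence[Hashable],
    alpha: float = ALPHA_DEG,
    lfc_threshold: float = LFC_DEG,
    reference: Hashable | None = None,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Up/down/static DEG classification at padj < alpha and |log2fc| > lfc_threshold."""
    return nb_differential_test(
        counts, group_labels, alpha=alpha, lfc_threshold=lfc_threshold,
        reference=reference, dispersion_floor=dispersion_floor,
        class_labels=("up", "down", "static"),
    )


def venn_unique_sets(named_sets: Mapping[str, set]) -> dict[str, set]:
    """Partition the union of named sets into Venn regions.

    Region keys join member-set names with '&' in input order (e.g. 'A&B' for
    elements in exactly A and B).  Every element lands in exactly one region;
    region sizes sum to the size of the union.  The region for a single name
    holds the elements unique to that set.
    """
    if len(named_sets) < 2:
        raise ValueError("at least two named sets required")
    names = list(named_sets)
    regions: dict[str, set] = {}
    universe = set().union(*named_sets.values())
    for elem in universe:
        members = [n for n in names if elem in named_sets[n]]
        regions.setdefault("&".join(members), set()).add(elem)
    return regions
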