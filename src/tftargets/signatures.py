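"""Single-sample gene-set scoring and survival stratification.

Implements the downstream cohort layer: rank-based single-sample enrichment
(ssGSEA) of a gene signature in each sample of an expression matrix,
tumor-vs-normal score comparison (Mann-Whitney), median stratification into
high/low signature groups, Mantel-Cox log-rank comparison of their survival,
and Spearman correlation between two signature scores.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

__all__ = [
    "ssgsea_score",
    "compare_groups",
    "median_stratify",
    "logrank_test",
    "spearman_corr",
]

SSGSEA_WEIGHT = 0.25


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: Iterable[str],
    weight_exponent: float = SSGSEA_WEIGHT,
    signature_id: str = "signature",
    rescale: bool = False,
) -> pd.Series:
    """Single-sample enrichment score of ``gene_set`` in every sample.

    Per sample, genes are ordered by descending expression (ties broken by
    gene id) and replaced by their ranks (rank normalization: the highest
    gene gets rank N).  Walking down the ordering, the score is the summed
    difference between the weighted in-set ECDF (weights = rank **
    ``weight_exponent``) and the unweighted out-of-set ECDF.  Being purely
    rank-based, the score is invariant to any strictly increasing transform
    of a sample's expression values.

    ``rescale=True`` min-max rescales scores across samples to [0, 1].
    Raises if no set gene is present in the matrix, naming the signature.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be non-negative")
    gene_set = set(gene_set)
    genes = expr.index.to_numpy(dtype=object)
    if expr.index.has_duplicates or expr.columns.has_duplicates:
        raise ValueError("expression matrix has duplicate gene or sample ids")
    in_set = np.array([g in gene_set for g in genes])
    if not in_set.any():
        raise ValueError(
            f"no gene of signature {signature_id!r} present in the expression matrix"
        )
    n = len(genes)
    n_out = n - int(in_set.sum())
    values = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("expression values must be finite and non-negative")

    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        # descending expression, ties by gene id (lexsort: last key is primary)
        order = np.lexsort((genes, -values[:, j]))
        ranks = np.arange(n, 0, -1, dtype=float)  # rank N for the top gene
        hit = in_set[order]
        w = np.where(hit, ranks**weight_exponent, 0.0)
        p_in = np.cumsum(w) / w.sum()
        if n_out:
            p_out = np.cumsum(~hit) / n_out
        else:
            p_out = np.zeros(n)
        scores[j] = float(np.sum(p_in - p_out))

    out = pd.Series(scores, index=expr.columns, name=signature_id)
    if rescale:
        span = out.max() - out.min()
        out = (out - out.min()) / span if span > 0 else out * 0.0
    return out


def compare_groups(
    scores: pd.Series, classes: pd.Series, group_a: str = "tumor",
    group_b: str = "normal",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing scores between two tissue classes.

    Uses the exact null when sample sizes are small without ties, otherwise
    the tie-corrected continuity-corrected normal approximation.  Returns
    (U of ``group_a``, two-sided p).
    """
    classes = classes.reindex(scores.index)
    a = scores[classes == group_a].to_numpy(dtype=float)
    b = scores[classes == group_b].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"both classes required: {group_a!r} n={a.size}, {group_b!r} n={b.size}"
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def median_stratify(scores: pd.Series) -> pd.Series:
    """Split samples into 'high' (score > median) and 'low' (score <= median).

    Scores exactly at the median go to the low group, so the high group never
    exceeds half the cohort.
    """
    if len(scores) < 2:
        raise ValueError("at least two samples required for stratification")
    med = float(np.median(scores.to_numpy(dtype=float)))
    return pd.Series(
        np.where(scores.to_numpy(dtype=float) > med, "high", "low"),
        index=scores.index,
        name="group",
    )


def logrank_test(survival: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Cox log-rank test between the 'high' and 'low' groups.

    ``survival`` needs columns time (>= 0), event (1 event / 0 censored) and
    group.  Returns (chi-square statistic with 1 df, p).  The unweighted
    observed-minus-expected statistic with hypergeometric variance is used.
    """
    for col in ("time", "event", "group"):
        if col not in survival.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if np.any(survival["time"].to_numpy(dtype=float) < 0):
        raise ValueError("survival times must be non-negative")
    groups = survival["group"]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two non-empty groups required, got {labels}")
    if int(survival["event"].sum()) == 0:
        raise ValueError("log-rank test requires at least one event")
    a = survival[groups == labels[0]]
    b = survival[groups == labels[1]]
    res = _lifelines_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def spearman_corr(
    scores_a: Sequence[float] | pd.Series, scores_b: Sequence[float] | pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed p (t approximation).

    Paired vectors, n >= 3; raises on constant input where ranks are undefined.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired one-dimensional vectors required")
    if a.size < 3:
        raise ValueError("at least three pairs required")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
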