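"""Gene-level association statistics.

Three analyses live here:

* the methylation-expression correlation over genes that are both
  expressed and methylated (Pearson and Spearman, with large-sample
  P-values);
* the splicing-enrichment contrast — at each minimum-FPKM threshold, a
  2x2 table of methylated/unmethylated x alternatively-spliced/not over
  the genes expressed at that threshold, tested with Fisher's exact
  test;
* distribution contrasts of gene length or exon count between two gene
  categories: ECDFs plus a two-sided continuity-corrected Wilcoxon
  rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .expression import GeneModel, classify_alternative_splicing
from .stats import ContingencyResult, fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "CorrelationResult",
    "DistributionContrast",
    "splicing_enrichment",
    "methylation_expression_correlation",
    "distribution_contrast",
    "ecdf",
]

DEFAULT_FPKM_GRID = (0.0, 0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman correlation over the restricted gene set."""

    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    defined: bool = True


@dataclass(frozen=True)
class DistributionContrast:
    """Two-group ECDF contrast with a rank-sum test."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    ecdf_a: pd.DataFrame  # columns: value, cdf
    ecdf_b: pd.DataFrame
    statistic: float
    wilcoxon_p: float


def ecdf(values) -> pd.DataFrame:
    """Empirical CDF as a (value, cdf) table over the sorted sample."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample for ECDF")
    return pd.DataFrame({"value": v, "cdf": np.arange(1, v.size + 1) / v.size})


def splicing_enrichment(
    methylated: pd.Series,
    models: list[GeneModel],
    transcript_fpkm: pd.Series,
    min_fpkm_grid=DEFAULT_FPKM_GRID,
) -> list[ContingencyResult]:
    """Fisher's exact enrichment of alternative splicing in methylated genes.

    At each threshold, only genes expressed there (>= 1 transcript
    passing) enter the table; rows are methylated vs unmethylated, the
    first column counts alternatively spliced genes.  A degenerate table
    (an empty row) is returned flagged ``testable=False`` rather than
    raising.
    """
    results = []
    for thr in min_fpkm_grid:
        a = b = c = d = 0
        for m in models:
            call = classify_alternative_splicing(m, transcript_fpkm, min_fpkm=thr)
            if not call.expressed:
                continue
            meth = bool(methylated[m.gene_id])
            if meth and call.alternatively_spliced:
                a += 1
            elif meth:
                b += 1
            elif call.alternatively_spliced:
                c += 1
            else:
                d += 1
        if (a + b) == 0 or (c + d) == 0:
            results.append(
                ContingencyResult(
                    table=((a, b), (c, d)),
                    proportion_a=a / (a + b) if (a + b) else math.nan,
                    proportion_b=c / (c + d) if (c + d) else math.nan,
                    odds_ratio=math.nan,
                    p_value=math.nan,
                    threshold_context=thr,
                    testable=False,
                )
            )
        else:
            res = fisher_exact_2x2([[a, b], [c, d]])
            results.append(
                ContingencyResult(
                    table=res.table,
                    proportion_a=res.proportion_a,
                    proportion_b=res.proportion_b,
                    odds_ratio=res.odds_ratio,
                    p_value=res.p_value,
                    threshold_context=thr,
                )
            )
    return results


def methylation_expression_correlation(
    gene_fpkm: pd.Series,
    gene_methylation: pd.Series,
    methylated: pd.Series,
    min_fpkm: float = 0.0,
) -> CorrelationResult:
    """Correlate gene methylation intensity with gene expression.

    Restricted to genes that are both expressed (FPKM above
    ``min_fpkm``; strictly positive when the threshold is 0) and
    methylated — the genes for which a methylation-expression coupling
    is observable at all.  ``gene_methylation`` is the per-gene region
    metric (relative mCG/CG or absolute mCG/length over the gene body).
    Returns NaN correlations flagged undefined when either variable has
    zero variance.
    """
    df = pd.DataFrame(
        {"fpkm": gene_fpkm, "meth": gene_methylation, "is_meth": methylated}
    ).dropna()
    expressed = df["fpkm"] > 0 if min_fpkm == 0 else df["fpkm"] >= min_fpkm
    sub = df[expressed & df["is_meth"]]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 genes after restriction, got {n}")
    if sub["fpkm"].nunique() == 1 or sub["meth"].nunique() == 1:
        return CorrelationResult(n, math.nan, math.nan, math.nan, math.nan, defined=False)
    pr = pearsonr(sub["meth"], sub["fpkm"])
    sr = spearmanr(sub["meth"], sub["fpkm"])
    return CorrelationResult(
        n=n,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )


def distribution_contrast(
    values_a,
    values_b,
    metric: str = "gene_length_bp",
    group_a: str = "methylated",
    group_b: str = "unmethylated",
) -> DistributionContrast:
    """ECDF contrast of a per-gene size metric between two gene groups.

    The shift is tested two-sided with the continuity-corrected normal
    approximation of the Wilcoxon rank-sum test (the convention of R's
    ``wilcox.test`` at these sample sizes).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = wilcoxon_rank_sum(a, b, alternative="two-sided", continuity=True, method="normal")
    return DistributionContrast(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=a.size,
        n_b=b.size,
        ecdf_a=ecdf(a),
        ecdf_b=ecdf(b),
        statistic=res.statistic,
        wilcoxon_p=res.pvalue,
    )
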