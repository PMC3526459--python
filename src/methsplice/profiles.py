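"""Boundary-anchored and gene-body methylation meta-profiles.

A meta-profile fixes a window of ``flank_bp`` on each side of a feature
anchor (the biological start or end), divides it into ``n_bins`` equal
intervals and computes a methylation metric per feature per bin.  Bins
are ordered 5'->3' in the direction of transcription, so bin order is
reversed on the minus strand and "after the start" always means into the
feature.  Windows are fixed-width regardless of feature length; windows
running off a chromosome edge keep truncated bins with reduced effective
lengths.

Two-class profiles (e.g. included vs skipped exons) carry a one-sided
Wilcoxon rank-sum test per bin; no multiple-testing correction is
applied across bins by default, with Bonferroni / Benjamini-Hochberg
available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .methylation import CpGSites
from .stats import wilcoxon_rank_sum

__all__ = [
    "ProfileConfig",
    "Window",
    "BinnedProfile",
    "BoundaryProfile",
    "extract_window",
    "bin_methylation",
    "boundary_profile_test",
    "genebody_quintile_profile",
]


@dataclass(frozen=True)
class ProfileConfig:
    """Geometry and testing parameters of a meta-profile.

    ``n_bins`` counts intervals across the whole +/- ``flank_bp`` window
    (the default 20 bins over +/-200 bp give 20 bp bins).  ``alpha`` is
    the per-bin significance level; ``test_side`` "greater" tests class A
    above class B.
    """

    flank_bp: int = 200
    n_bins: int = 20
    anchor: str = "start"
    metric: str = "absolute"
    alpha: float = 0.05
    test_side: str = "greater"
    correction: str = "none"  # none | bonferroni | bh

    def __post_init__(self) -> None:
        if self.flank_bp <= 0 or self.n_bins <= 0:
            raise ValueError("flank_bp and n_bins must be positive")
        if (2 * self.flank_bp) % self.n_bins != 0:
            raise ValueError("2*flank_bp must be divisible by n_bins for equal bins")
        if self.anchor not in ("start", "end"):
            raise ValueError("anchor must be 'start' or 'end'")
        if self.metric not in ("absolute", "relative"):
            raise ValueError("metric must be 'absolute' or 'relative'")
        if self.test_side not in ("greater", "less", "two-sided"):
            raise ValueError("bad test_side")
        if self.correction not in ("none", "bonferroni", "bh"):
            raise ValueError("bad correction")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def bin_width(self) -> int:
        return (2 * self.flank_bp) // self.n_bins


@dataclass(frozen=True)
class Window:
    """An oriented fixed-width window around one feature anchor.

    ``edges`` are the n_bins+1 genomic bin boundaries in ascending
    genomic order, before clipping; ``reverse`` marks minus-strand
    features whose bins must be read 3'->5' genomically to be 5'->3'
    biologically.
    """

    chrom: str
    anchor_pos: int
    edges: np.ndarray
    reverse: bool


def extract_window(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    anchor: str,
    flank_bp: int,
    n_bins: int,
    chrom_size: int | None = None,
) -> Window:
    """Bin boundaries of the +/- flank window around a feature anchor.

    The anchor is biological: on the plus strand "start" is the leftmost
    coordinate, on the minus strand it is the rightmost.  The window is
    [anchor - flank, anchor + flank) in genomic coordinates; clipping to
    the chromosome happens later via effective bin lengths, but an
    anchor lying outside the chromosome is an error.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    if anchor == "start":
        pos = start if strand == "+" else end
    elif anchor == "end":
        pos = end if strand == "+" else start
    else:
        raise ValueError("anchor must be 'start' or 'end'")
    if pos < 0 or (chrom_size is not None and pos > chrom_size):
        raise ValueError(f"anchor {pos} outside chromosome {chrom}")
    width = (2 * flank_bp) // n_bins
    edges = pos - flank_bp + width * np.arange(n_bins + 1, dtype=np.int64)
    return Window(chrom=chrom, anchor_pos=pos, edges=edges, reverse=(strand == "-"))


@dataclass
class BinnedProfile:
    """Per-feature per-bin methylation values for one window set.

    All arrays are (n_features, n_bins) with bins in 5'->3' order.
    ``relative`` is NaN in CpG-free bins; ``absolute`` uses each bin's
    effective (clipped) length, and is NaN where a bin is entirely off
    the chromosome.
    """

    absolute: np.ndarray
    relative: np.ndarray
    n_cpg: np.ndarray
    sum_mCG: np.ndarray
    effective_len: np.ndarray

    def values(self, metric: str) -> np.ndarray:
        if metric == "absolute":
            return self.absolute
        if metric == "relative":
            return self.relative
        raise ValueError(f"unknown metric {metric!r}")


def bin_methylation(
    windows: list[Window],
    sites: CpGSites,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedProfile:
    """Compute per-bin methylation for every window.

    Each bin's CpG count and summed mCG come from two binary searches on
    the per-chromosome site index; the absolute metric divides by the
    bin's effective length after clipping at [0, chromosome size].
    """
    if not windows:
        raise ValueError("no windows given")
    n_bins = len(windows[0].edges) - 1
    n_feat = len(windows)
    n_cpg = np.zeros((n_feat, n_bins), dtype=np.int64)
    sum_m = np.zeros((n_feat, n_bins))
    eff = np.zeros((n_feat, n_bins), dtype=np.int64)
    for i, w in enumerate(windows):
        pos, cum, _ = sites.arrays(w.chrom)
        hi = chrom_sizes.get(w.chrom) if chrom_sizes else None
        clipped = np.clip(w.edges, 0, hi) if hi is not None else np.maximum(w.edges, 0)
        ix = np.searchsorted(pos, clipped)
        cnt = np.diff(ix)
        sm = cum[ix[1:]] - cum[ix[:-1]]
        el = np.diff(clipped)
        if w.reverse:
            cnt, sm, el = cnt[::-1], sm[::-1], el[::-1]
        n_cpg[i], sum_m[i], eff[i] = cnt, sm, el
    with np.errstate(divide="ignore", invalid="ignore"):
        absolute = np.where(eff > 0, sum_m / np.maximum(eff, 1), np.nan)
        relative = np.where(n_cpg > 0, sum_m / np.maximum(n_cpg, 1), np.nan)
    return BinnedProfile(absolute, relative, n_cpg, sum_m, eff)


@dataclass
class BoundaryProfile:
    """Two-class boundary meta-profile with per-bin rank-sum tests."""

    config: ProfileConfig
    class_a: str
    class_b: str
    table: pd.DataFrame  # one row per bin

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _feature_windows(features: pd.DataFrame, config: ProfileConfig) -> list[Window]:
    return [
        extract_window(
            row.chrom, int(row.start), int(row.end), row.strand,
            config.anchor, config.flank_bp, config.n_bins,
        )
        for row in features.itertuples(index=False)
    ]


def boundary_profile_test(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    sites: CpGSites,
    config: ProfileConfig,
    class_a: str = "included",
    class_b: str = "skipped",
    chrom_sizes: dict[str, int] | None = None,
) -> BoundaryProfile:
    """Per-bin location test between two feature classes.

    ``features_a`` / ``features_b`` need columns (chrom, start, end,
    strand).  For every bin, the per-feature metric values of the two
    classes are compared with a Wilcoxon rank-sum test on the configured
    side (NaN values — CpG-free bins under the relative metric, or bins
    entirely off-chromosome — are excluded from that bin's samples).  A
    bin with an empty class sample is marked untestable rather than
    significant.
    """
    if len(features_a) == 0 or len(features_b) == 0:
        raise ValueError("both feature classes must be non-empty")
    prof_a = bin_methylation(_feature_windows(features_a, config), sites, chrom_sizes)
    prof_b = bin_methylation(_feature_windows(features_b, config), sites, chrom_sizes)
    vals_a = prof_a.values(config.metric)
    vals_b = prof_b.values(config.metric)

    width = config.bin_width
    offsets = -config.flank_bp + width * np.arange(config.n_bins)
    rows = []
    for j in range(config.n_bins):
        a = vals_a[:, j]
        b = vals_b[:, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        testable = a.size > 0 and b.size > 0
        if testable:
            res = wilcoxon_rank_sum(a, b, alternative=config.test_side, method="normal")
            stat, p = res.statistic, res.pvalue
            mean_a, mean_b = float(a.mean()), float(b.mean())
        else:
            stat, p = math.nan, math.nan
            mean_a = float(a.mean()) if a.size else math.nan
            mean_b = float(b.mean()) if b.size else math.nan
        rows.append(
            {
                "bin": j,
                "offset_start": int(offsets[j]),
                "offset_end": int(offsets[j] + width),
                "mean_a": mean_a,
                "mean_b": mean_b,
                "n_a": int(a.size),
                "n_b": int(b.size),
                "statistic": stat,
                "p_value": p,
                "testable": testable,
            }
        )
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy()
    ok = table["testable"].to_numpy()
    sig = np.zeros(len(table), dtype=bool)
    if ok.any():
        if config.correction == "none":
            sig[ok] = pvals[ok] < config.alpha
        else:
            method = "bonferroni" if config.correction == "bonferroni" else "fdr_bh"
            sig[ok] = multipletests(pvals[ok], alpha=config.alpha, method=method)[0]
    table["significant"] = sig
    return BoundaryProfile(config=config, class_a=class_a, class_b=class_b, table=table)


def genebody_quintile_profile(
    genes: pd.DataFrame,
    gene_fpkm: pd.Series,
    sites: CpGSites,
    config: ProfileConfig | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean methylation around gene start/end anchors per expression quintile.

    Expressed genes (FPKM > 0) are ranked by FPKM and split into five
    equal-size groups (ties broken by gene-id order; quintile 5 is the
    highest expressed).  For each quintile, each anchor and each bin the
    mean of the chosen metric over genes is reported.  ``genes`` needs
    columns (gene_id, chrom, start, end, strand).

    The default geometry is the gene-body one: +/-2 kb in 100 bp bins.
    """
    if config is None:
        config = ProfileConfig(flank_bp=2000, n_bins=40)
    expressed = gene_fpkm[gene_fpkm > 0]
    if len(expressed) < 5:
        raise ValueError("need at least 5 expressed genes for quintiles")
    order = (
        expressed.rename("fpkm")
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(["fpkm", "gene_id"], kind="mergesort")["gene_id"]
        .tolist()
    )
    quint_of = {}
    for q, chunk in enumerate(np.array_split(np.array(order, dtype=object), 5), start=1):
        for gid in chunk:
            quint_of[gid] = q

    sub = genes[genes["gene_id"].isin(quint_of)].copy()
    sub["quintile"] = sub["gene_id"].map(quint_of)

    rows = []
    for anchor in ("start", "end"):
        cfg = replace(config, anchor=anchor)
        for q in range(1, 6):
            grp = sub[sub["quintile"] == q]
            prof = bin_methylation(_feature_windows(grp, cfg), sites, chrom_sizes)
            vals = prof.values(config.metric)
            width = cfg.bin_width
            for j in range(cfg.n_bins):
                col = vals[:, j]
                col = col[~np.isnan(col)]
                rows.append(
                    {
                        "anchor": anchor,
                        "quintile": q,
                        "bin": j,
                        "offset_start": int(-cfg.flank_bp + width * j),
                        "offset_end": int(-cfg.flank_bp + width * (j + 1)),
                        "mean_metric": float(col.mean()) if col.size else math.nan,
                        "n_genes": int(col.size),
                    }
                )
    return pd.DataFrame(rows)
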