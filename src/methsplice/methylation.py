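"""CpG methylation calls and region-level methylation metrics.

Bisulfite-sequencing methylation calls arrive as one row per CpG site
with methylated and unmethylated read counts.  The per-site level is

    mCG = meth_reads / (meth_reads + unmeth_reads)

and two region aggregates are derived from it:

* relative methylation, mCG/CG  = (sum of site mCG) / (number of CpG sites)
* absolute methylation, mCG/length = (sum of site mCG) / (region length in bp)

A gene is classified methylated when its body (union span over all splice
variants, introns included) contains at least one CpG with mCG > 0.

Sites are indexed per chromosome with sorted position arrays and prefix
sums, so any interval query is two binary searches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import GeneModel

__all__ = [
    "RegionMethylation",
    "CpGSites",
    "load_methylation_calls",
    "region_methylation",
    "classify_gene_methylation",
]

logger = logging.getLogger(__name__)

METHYLATION_COLUMNS = ("chrom", "pos", "meth_reads", "unmeth_reads")


@dataclass(frozen=True)
class RegionMethylation:
    """Methylation summary of one genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    sum_mCG: float
    length_bp: int

    @property
    def relative(self) -> float:
        """mCG/CG; NaN when the region contains no CpG site."""
        return self.sum_mCG / self.n_cpg if self.n_cpg > 0 else math.nan

    @property
    def absolute(self) -> float:
        """mCG/length in 1/bp."""
        return self.sum_mCG / self.length_bp


class CpGSites:
    """Indexed collection of CpG methylation calls.

    Wraps a DataFrame with columns (chrom, pos, meth_reads, unmeth_reads,
    mCG) and keeps, per chromosome, the sorted position array plus prefix
    sums of mCG and of the "mCG > 0" indicator for O(log n) interval
    queries.
    """

    def __init__(self, frame: pd.DataFrame):
        required = set(METHYLATION_COLUMNS)
        if not required.issubset(frame.columns):
            raise ValueError(f"methylation frame must have columns {sorted(required)}")
        df = frame.copy()
        total = df["meth_reads"].to_numpy() + df["unmeth_reads"].to_numpy()
        if np.any(total < 1):
            raise ValueError("sites with zero total reads must be filtered before indexing")
        df["mCG"] = df["meth_reads"] / total
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self._df = df
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy(dtype=np.int64)
            mcg = grp["mCG"].to_numpy(dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(mcg)])
            cum_pos = np.concatenate([[0], np.cumsum((mcg > 0).astype(np.int64))])
            self._index[str(chrom)] = (pos, cum, cum_pos)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._index)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sorted positions, prefix-sum of mCG, prefix-count of mCG>0)."""
        if chrom in self._index:
            return self._index[chrom]
        empty = np.array([], dtype=np.int64)
        return empty, np.array([0.0]), np.array([0], dtype=np.int64)

    def query(self, chrom: str, start: int, end: int) -> tuple[int, float, int]:
        """(n_cpg, sum mCG, n sites with mCG > 0) for [start, end)."""
        pos, cum, cum_pos = self.arrays(chrom)
        i, j = np.searchsorted(pos, [start, end])
        return int(j - i), float(cum[j] - cum[i]), int(cum_pos[j] - cum_pos[i])


def load_methylation_calls(
    path: str | Path,
    one_based: bool = False,
    min_coverage: int = 1,
    merge_strands: bool = False,
) -> CpGSites:
    """Read a methylation-call TSV into an indexed :class:`CpGSites`.

    Expected columns (headered, tab-separated): chrom, pos, meth_reads,
    unmeth_reads.  ``one_based`` shifts positions down by one on load.
    Sites with zero total reads are rejected with a logged warning; rows
    whose numeric columns fail to parse raise a ``ValueError`` naming the
    first offending line.  ``merge_strands`` collapses records at
    adjacent coordinates (the C of each strand of one CpG) by summing
    counts at the lower coordinate.  ``min_coverage`` optionally drops
    sites below a total-read floor (default keeps everything observed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METHYLATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("pos", "meth_reads", "unmeth_reads"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based lines
            raise ValueError(f"{path}: malformed {col!r} value on line {line}")
        df[col] = parsed.astype(np.int64)
    if one_based:
        df["pos"] = df["pos"] - 1
    if np.any(df["pos"] < 0) or np.any(df["meth_reads"] < 0) or np.any(df["unmeth_reads"] < 0):
        raise ValueError(f"{path}: negative coordinate or read count")

    if merge_strands:
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        same_cpg = (
            (df["chrom"] == df["chrom"].shift())
            & (df["pos"] == df["pos"].shift() + 1)
        )
        group = (~same_cpg).cumsum()
        df = (
            df.groupby(group)
            .agg(
                chrom=("chrom", "first"),
                pos=("pos", "first"),
                meth_reads=("meth_reads", "sum"),
                unmeth_reads=("unmeth_reads", "sum"),
            )
            .reset_index(drop=True)
        )

    total = df["meth_reads"] + df["unmeth_reads"]
    zero = total == 0
    if zero.any():
        logger.warning(
            "%s: rejecting %d site(s) with zero total reads", path, int(zero.sum())
        )
        df = df[~zero]
    if min_coverage > 1:
        df = df[(df["meth_reads"] + df["unmeth_reads"]) >= min_coverage]
    return CpGSites(df.reset_index(drop=True))


def region_methylation(sites: CpGSites, chrom: str, start: int, end: int) -> RegionMethylation:
    """Methylation summary of one 0-based half-open interval."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    n, s, _ = sites.query(chrom, start, end)
    return RegionMethylation(chrom, start, end, n, s, end - start)


def classify_gene_methylation(sites: CpGSites, gene_models) -> pd.Series:
    """Methylated flag per gene: any CpG with mCG > 0 inside the gene body.

    The gene body is the union span over all splice variants, introns
    included.  Genes whose span contains no CpG site are unmethylated.
    """
    flags = {}
    for model in gene_models:
        _, _, n_pos = sites.query(model.chrom, model.start, model.end)
        flags[model.gene_id] = n_pos > 0
    out = pd.Series(flags, dtype=bool, name="methylated")
    out.index.name = "gene_id"
    return out
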