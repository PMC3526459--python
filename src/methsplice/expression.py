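"""Gene models and RNA-seq expression quantities.

Gene structures (gene -> transcripts -> exons) are loaded from GFF3/GTF
and held in lightweight immutable dataclasses using 0-based half-open
genomic coordinates.  Expression arrives as tables of RPKM (exons and
introns) and FPKM (transcripts); the classification rules are the hard
thresholds used throughout the analysis: a feature with positive RPKM is
"included" in transcription, one with zero RPKM is "skipped", and a gene
is alternatively spliced when at least two structurally distinct
transcripts clear an expression threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "Transcript",
    "GeneModel",
    "SplicingCall",
    "load_annotation",
    "compute_rpkm",
    "classify_inclusion",
    "classify_alternative_splicing",
    "gene_fpkm",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    """One splice variant: an ordered list of exon intervals.

    Exons are 0-based half-open genomic intervals, sorted and
    non-overlapping; introns are exactly the gaps between consecutive
    exons (so a single-exon transcript has none).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval {s, e} in {self.transcript_id}")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping/unsorted exons in transcript {self.transcript_id}"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span_bp(self) -> int:
        """Transcript extent including introns."""
        return self.end - self.start

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        )

    @property
    def exonic_bp(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts on one strand.

    ``gene_length_bp`` is the maximum transcript extent including introns
    over all splice variants, and ``max_exon_count`` the maximum exon
    count over variants — the per-gene size measures used in the
    length/exon-count distribution contrasts.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def start(self) -> int:
        """Union-span start over all transcripts."""
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def gene_length_bp(self) -> int:
        return max(t.span_bp for t in self.transcripts)

    @property
    def max_exon_count(self) -> int:
        return max(len(t.exons) for t in self.transcripts)

    @cached_property
    def exon_union(self) -> tuple[Interval, ...]:
        """Distinct exon intervals over all transcripts, merged and sorted."""
        ivs = sorted({iv for t in self.transcripts for iv in t.exons})
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class SplicingCall:
    """Gene-level classification at one minimum-FPKM threshold."""

    gene_id: str
    min_fpkm: float
    expressed: bool
    alternatively_spliced: bool


class AnnotationError(ValueError):
    pass


def load_annotation(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GFF3/GTF file.

    The file must carry a gene -> (mRNA|transcript) -> exon hierarchy via
    ID/Parent attributes.  1-based closed coordinates are converted to
    the internal 0-based half-open convention.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for tr in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted(
                (ex.start - 1, ex.end) for ex in db.children(tr, featuretype="exon")
            )
            if not exons:
                raise AnnotationError(f"transcript {tr.id} has no exon children")
            try:
                transcripts.append(Transcript(tr.id, gene.id, tuple(exons)))
            except ValueError as err:
                raise AnnotationError(str(err)) from err
        if not transcripts:
            raise AnnotationError(f"gene {gene.id} has no transcripts")
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(transcripts)))
    # orphan exon check: every exon must resolve to a transcript parent
    for ex in db.features_of_type("exon"):
        if not ex.attributes.get("Parent"):
            raise AnnotationError(f"exon at {ex.seqid}:{ex.start}-{ex.end} has no Parent")
    return models


def compute_rpkm(read_count: float, length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    return read_count / ((length_bp / 1e3) * (total_mapped_reads / 1e6))


def classify_inclusion(records: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """Label exon/intron expression records as included (True) or skipped.

    A feature with RPKM > 0 is included in transcription; RPKM == 0 means
    skipped.  Introns follow the same rule.
    """
    values = records[value_col].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative RPKM in expression records")
    return pd.Series(values > 0, index=records.index, name="included")


def classify_alternative_splicing(
    model: GeneModel,
    transcript_fpkm: dict[str, float] | pd.Series,
    min_fpkm: float = 0.0,
) -> SplicingCall:
    """Classify one gene as expressed / alternatively spliced at a threshold.

    A transcript passes when its FPKM is >= ``min_fpkm`` (strictly > 0
    when the threshold is 0, so unexpressed transcripts never count).
    The gene is expressed when any transcript passes and alternatively
    spliced when at least two *structurally distinct* passing transcripts
    exist; distinctness is judged on the ordered exon-interval list, so
    duplicate assemblies of the same structure do not count as splicing.
    """
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    passing = []
    for tr in model.transcripts:
        fpkm = float(transcript_fpkm[tr.transcript_id])
        ok = fpkm > 0.0 if min_fpkm == 0.0 else fpkm >= min_fpkm
        if ok:
            passing.append(tr.exons)
    distinct = len(set(passing))
    return SplicingCall(
        gene_id=model.gene_id,
        min_fpkm=min_fpkm,
        expressed=len(passing) >= 1,
        alternatively_spliced=distinct >= 2,
    )


def gene_fpkm(transcript_fpkms) -> float:
    """Gene-level FPKM: the sum of its transcripts' FPKM values."""
    vals = np.asarray(list(transcript_fpkms), dtype=float)
    if vals.size == 0:
        raise ValueError("gene has no transcripts")
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("FPKM values must be finite and non-negative")
    return float(vals.sum())
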