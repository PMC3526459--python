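"""Reference constants of the honeybee brain RNA-seq / BS-seq dataset.

Summary figures of the original *Apis mellifera* worker-brain sequencing
libraries whose analysis conventions this package reimplements.  They
are inputs for arithmetic sanity checks, not measured by this package.
"""

from __future__ import annotations

__all__ = [
    "HONEYBEE_LIBRARY",
    "duplicate_read_percent",
]

# Honeybee worker-brain paired-end RNA-seq library (Amel_2.0 alignment).
HONEYBEE_LIBRARY = {
    "total_reads": 116_791_866,
    "read_length": 104,
    "mapped_reads": 64_321_565,
    "exon_junctions": 96_823,
    "duplicate_reads": 25_956_078,
    "assembled_transcripts": 72_479,
}


def duplicate_read_percent(duplicate_reads: int, mapped_reads: int) -> float:
    """Percentage of mapped reads flagged as duplicates."""
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be positive")
    if not 0 <= duplicate_reads <= mapped_reads:
        raise ValueError("duplicate_reads must be between 0 and mapped_reads")
    return 100.0 * duplicate_reads / mapped_reads
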