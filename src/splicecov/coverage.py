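"""Per-nucleotide read depth and region read counts from indexed BAMs.

This is the samtools layer of the engine: ``pileup`` plays the role of
``mpileup`` (depth at every nucleotide of a region) and ``count_reads``
the role of ``view -c`` (reads overlapping a region).  Depth is computed
from each alignment's aligned reference blocks so that the filtering
policy is explicit and spliced reads are handled correctly: positions
under an N (intron skip) CIGAR operation contribute nothing, deleted
reference bases (D) count as covered, and there is no depth cap.

Filtering: unmapped, secondary (0x100) and supplementary (0x800) records
are excluded; duplicates and QC-fail reads are kept; no mapping-quality
threshold.  These permissive defaults mirror stock samtools behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .genemodel import GenomicInterval

__all__ = ["CoverageTrack", "pileup", "count_reads", "total_mapped"]


@dataclass
class CoverageTrack:
    """Read depth over a genomic region for one sample.

    ``depth[i]`` is the number of alignments covering position
    ``region.start + i``; ``reads_in_region`` counts the alignments that
    overlap the region by at least one aligned base.
    """

    sample_id: str
    region: GenomicInterval
    depth: np.ndarray
    reads_in_region: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.shape[0] != len(self.region):
            raise ValueError(
                f"depth length {self.depth.shape[0]} != region length {len(self.region)}"
            )
        if self.reads_in_region < 0:
            raise ValueError("reads_in_region must be non-negative")

    @property
    def max_depth(self) -> int:
        return int(self.depth.max()) if self.depth.size else 0

    def slice(self, sub: GenomicInterval) -> "CoverageTrack":
        """Restrict the track to a sub-region (depth slice; count recomputed
        upstream if needed)."""
        if not self.region.contains(sub):
            raise ValueError("sub-region not contained in track region")
        off = sub.start - self.region.start
        return CoverageTrack(
            self.sample_id, sub, self.depth[off : off + len(sub)], self.reads_in_region
        )


def _open_bam(bam: str | Path) -> pysam.AlignmentFile:
    bam = Path(bam)
    if not bam.exists():
        raise FileNotFoundError(f"BAM file not found: {bam}")
    af = pysam.AlignmentFile(str(bam), "rb")
    if not af.has_index():
        af.close()
        raise ValueError(
            f"{bam} has no index; run `samtools index {bam}` (or pysam.index) first"
        )
    return af


def _check_chromosome(af: pysam.AlignmentFile, region: GenomicInterval) -> None:
    if region.chromosome not in af.references:
        raise ValueError(
            f"chromosome {region.chromosome!r} not in BAM header; "
            f"available: {list(af.references)}"
        )


def _keep(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def pileup(bam: str | Path, region: GenomicInterval, sample_id: str = "") -> CoverageTrack:
    """Compute per-nucleotide depth over ``region``.

    Equivalent to an uncapped mpileup restricted to primary mapped
    alignments.  Each read contributes 1 to every reference position in
    its M/=/X/D blocks that falls inside the region; N gaps contribute 0.
    """
    depth = np.zeros(len(region), dtype=np.int64)
    n_reads = 0
    with _open_bam(bam) as af:
        _check_chromosome(af, region)
        for read in af.fetch(region.chromosome, region.start, region.end):
            if not _keep(read):
                continue
            overlapped = False
            pos = read.reference_start
            for op, length in read.cigartuples or []:
                if op in (0, 7, 8, 2):  # M, =, X, D: aligned to reference
                    lo = max(pos, region.start)
                    hi = min(pos + length, region.end)
                    if lo < hi:
                        depth[lo - region.start : hi - region.start] += 1
                        overlapped = True
                    pos += length
                elif op == 3:  # N: intron skip, advances reference, no coverage
                    pos += length
                # I/S/H/P do not consume reference
            if overlapped:
                n_reads += 1
    return CoverageTrack(sample_id or Path(bam).stem, region, depth, n_reads)


def count_reads(bam: str | Path, region: GenomicInterval) -> int:
    """Count primary mapped alignments overlapping ``region`` by >= 1 aligned base.

    This mirrors ``samtools view`` on the locus span: a read is counted
    once even if it extends past the region boundary, and a spliced read
    whose only contact with the region is an N gap is not counted.
    """
    n = 0
    with _open_bam(bam) as af:
        _check_chromosome(af, region)
        for read in af.fetch(region.chromosome, region.start, region.end):
            if not _keep(read):
                continue
            for block_start, block_end in read.get_blocks():
                if block_start < region.end and region.start < block_end:
                    n += 1
                    break
    return n


def total_mapped(bam: str | Path | None = None, override: int | None = None) -> int:
    """Total mapped reads in the experiment (the RPKM millions denominator).

    If ``override`` is given (e.g. the ``total_reads_mapped`` attribute of
    the compendium config) it is returned as-is; otherwise the BAM index
    statistics are summed over all references.
    """
    if override is not None:
        if override <= 0:
            raise ValueError(f"total mapped override must be positive, got {override}")
        return int(override)
    if bam is None:
        raise ValueError("need either a BAM path or an override count")
    with _open_bam(bam) as af:
        total = sum(stat.mapped for stat in af.get_index_statistics())
    if total <= 0:
        raise ValueError(f"{bam} has no mapped reads and no override was provided")
    return total
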