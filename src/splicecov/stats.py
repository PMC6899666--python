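"""Congruency and expression statistics.

Two quantities summarize a sample against a gene:

* the point-biserial correlation ``r_pb`` between the per-nucleotide
  coverage vector (continuous) and a variant's exon mask (dichotomous),
  which measures how well the read-map profile matches that splice
  variant's structure, and

* RPKM — reads per kilobase of exon per million mapped reads — in
  absolute form or as a log2 fold-change relative to control samples
  (or to the all-sample median in atlas mode).

``r_pb`` is algebraically the Pearson correlation of the coverage vector
with the 0/1 mask; the closed form below uses the population (divide-by-n)
standard deviation, a convention choice that does not affect sample
ranking.  Degenerate inputs (zero-variance coverage, all-exon masks,
zero references) yield NaN rather than an error, because a browser must
still render such samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage import CoverageTrack
from .genemodel import ExonMask, GeneModel, build_exon_mask, exon_length

__all__ = [
    "ExpressionSummary",
    "point_biserial",
    "rpkm",
    "relative_expression",
    "summarize",
]


@dataclass
class ExpressionSummary:
    """Per-sample, per-gene expression scores.

    ``rpkm_relative`` stays NaN until the reporting layer resolves the
    sample's controls; ``rpb_by_variant`` maps every variant of the gene
    to its congruency score (NaN where undefined).
    """

    sample_id: str
    gene_id: str
    reads_in_region: int
    rpkm_absolute: float
    rpkm_relative: float = float("nan")
    rpb_by_variant: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rpkm_absolute < 0:
            raise ValueError("rpkm_absolute must be non-negative")
        for vid, r in self.rpb_by_variant.items():
            if not math.isnan(r) and not -1.0 <= r <= 1.0 + 1e-12:
                raise ValueError(f"r_pb for {vid} out of [-1, 1]: {r}")


def point_biserial(track: CoverageTrack | np.ndarray, mask: ExonMask | np.ndarray) -> float:
    """Point-biserial correlation between coverage depth and exon membership.

    Parameters
    ----------
    track : CoverageTrack or 1-d array
        Continuous per-nucleotide depth.
    mask : ExonMask or 1-d array of {0,1}
        Dichotomous exon indicator of the same length.

    Returns
    -------
    float
        ``r_pb = (M1 - M0) / s * sqrt(n1 * n0 / n**2)`` where ``M1``/``M0``
        are mean depths over mask-1/mask-0 positions, ``n1``/``n0`` their
        counts and ``s`` the population standard deviation of the depth
        vector.  NaN when either vector has zero variance.
    """
    x = np.asarray(track.depth if isinstance(track, CoverageTrack) else track, dtype=float)
    m = np.asarray(mask.values if isinstance(mask, ExonMask) else mask)
    if x.shape != m.shape:
        raise ValueError(
            f"length mismatch: depth has {x.shape[0]} positions, mask has {m.shape[0]}"
        )
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 positions")
    ones = m != 0
    n1 = int(ones.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return float("nan")  # mask constant: correlation undefined
    s = x.std()  # population sd
    if s == 0.0:
        return float("nan")  # flat coverage: correlation undefined
    m1 = x[ones].mean()
    m0 = x[~ones].mean()
    r = (m1 - m0) / s * math.sqrt(n1 * n0 / n**2)
    # clip tiny floating excursions past the mathematical bound
    return float(min(1.0, max(-1.0, r)))


def rpkm(reads_in_region: int, exon_length_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of exon per million mapped reads.

    ``reads_in_region * 1e9 / (exon_length_nt * total_mapped)``.  The
    numerator counts reads overlapping the locus' full genomic span while
    the kilobase normalization uses the selected variant's exonic length —
    the engine's deliberate mixed convention (see docs/methods.md).
    """
    if exon_length_nt <= 0:
        raise ValueError(f"exon length must be positive, got {exon_length_nt}")
    if total_mapped <= 0:
        raise ValueError(f"total mapped must be positive, got {total_mapped}")
    if reads_in_region < 0:
        raise ValueError(f"read count must be non-negative, got {reads_in_region}")
    return reads_in_region * 1e9 / (exon_length_nt * total_mapped)


def relative_expression(
    sample_rpkm: float,
    control_rpkms: Sequence[float],
    atlas_mode: bool = False,
) -> float:
    """log2 fold-change of a sample's RPKM against its control reference.

    The reference is the arithmetic mean of ``control_rpkms``; in atlas
    mode ``control_rpkms`` is the full set of the compendium's RPKM values
    and the reference is their median (the no-obvious-control convention
    for developmental atlases).  Returns NaN when the reference or the
    sample value is zero (log undefined).  A sample at one quarter of its
    controls' mean scores exactly -2: a four-fold decrease.
    """
    if len(control_rpkms) == 0:
        raise ValueError("control RPKM list is empty")
    vals = np.asarray(control_rpkms, dtype=float)
    reference = float(np.median(vals)) if atlas_mode else float(vals.mean())
    if reference <= 0 or sample_rpkm <= 0:
        return float("nan")
    return math.log2(sample_rpkm / reference)


def summarize(
    track: CoverageTrack,
    gene: GeneModel,
    total_mapped: int,
    selected_variant: str,
) -> ExpressionSummary:
    """Score one sample's coverage track against a gene.

    Computes ``r_pb`` for every variant of the gene on the shared span and
    absolute RPKM from the track's region read count and the selected
    variant's exonic length.  Relative RPKM is left NaN; the reporting
    layer fills it in once controls are resolved.
    """
    if (track.region.chromosome, track.region.start, track.region.end) != (
        gene.span.chromosome,
        gene.span.start,
        gene.span.end,
    ):
        raise ValueError(
            f"track region {track.region} does not match gene span {gene.span}"
        )
    sel = gene.variant(selected_variant)  # raises KeyError if absent
    rpb = {
        v.variant_id: point_biserial(track, build_exon_mask(v, gene.span))
        for v in gene.variants
    }
    return ExpressionSummary(
        sample_id=track.sample_id,
        gene_id=gene.gene_id,
        reads_in_region=track.reads_in_region,
        rpkm_absolute=rpkm(track.reads_in_region, exon_length(sel), total_mapped),
        rpb_by_variant=rpb,
    )
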