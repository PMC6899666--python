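"""Gene models, splice variants and dichotomous exon masks.

A locus is represented as a :class:`GeneModel` holding one or more
:class:`SpliceVariant` isoforms, each a set of typed feature intervals
(exon, CDS, 5'UTR, 3'UTR).  For congruency scoring each variant is reduced
to an :class:`ExonMask`: a 0/1 vector over the gene span with 1 at every
exonic nucleotide.  All coordinates are 0-based half-open internally; the
1-based inclusive GFF3 convention is converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "SpliceVariant",
    "GeneModel",
    "ExonMask",
    "parse_gff",
    "build_exon_mask",
    "exon_length",
    "merge_intervals",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    Parameters
    ----------
    chromosome : str
        Reference sequence name.
    start, end : int
        0-based half-open bounds; ``end - start`` is the length in
        nucleotides.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unknown).  Carried for provenance;
        mask construction and coverage are strand-agnostic (unstranded
        libraries assumed).
    """

    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals by start and merge any that overlap or abut.

    Dichotomous exon semantics do not distinguish doubly-annotated bases,
    so overlapping exon records within one variant collapse to their union.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chromosome == last.chromosome and iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chromosome, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass
class SpliceVariant:
    """One mRNA isoform: ordered exons plus CDS and UTR sub-features."""

    variant_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"variant {self.variant_id} has no exons")
        exon_union = self.exons
        for kind, ivs in (("CDS", self.cds), ("5'UTR", self.utr5), ("3'UTR", self.utr3)):
            for iv in ivs:
                if not any(ex.contains(iv) for ex in exon_union):
                    # a sub-feature may straddle two merged exon blocks only
                    # if annotation is inconsistent; reject loudly
                    covered = sum(
                        max(0, min(iv.end, ex.end) - max(iv.start, ex.start))
                        for ex in exon_union
                    )
                    if covered < len(iv):
                        raise ValueError(
                            f"{kind} interval [{iv.start},{iv.end}) of variant "
                            f"{self.variant_id} is not contained in its exons"
                        )


def exon_length(variant: SpliceVariant) -> int:
    """Total exonic length of a variant in nucleotides.

    This is the length the RPKM kilobase normalization uses.
    """
    return sum(len(iv) for iv in variant.exons)


@dataclass
class GeneModel:
    """A locus: its genomic span and the splice variants annotated on it.

    The span is the union extent over *all* variants' exons so that every
    variant of a gene is scored against vectors of equal length — a
    requirement for comparing congruency scores across variants on a
    single coverage track.
    """

    gene_id: str
    span: GenomicInterval
    variants: list[SpliceVariant]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"gene {self.gene_id} has no splice variants")
        for v in self.variants:
            for ex in v.exons:
                if not self.span.contains(ex):
                    raise ValueError(
                        f"exon [{ex.start},{ex.end}) of {v.variant_id} lies outside "
                        f"the span of gene {self.gene_id}"
                    )

    def variant(self, variant_id: str) -> SpliceVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(
            f"gene {self.gene_id} has no variant {variant_id!r}; "
            f"known: {[v.variant_id for v in self.variants]}"
        )

    @classmethod
    def from_variants(cls, gene_id: str, variants: Sequence[SpliceVariant]) -> "GeneModel":
        if not variants:
            raise ValueError(f"gene {gene_id} has no splice variants")
        chrom = variants[0].exons[0].chromosome
        strand = variants[0].exons[0].strand
        start = min(ex.start for v in variants for ex in v.exons)
        end = max(ex.end for v in variants for ex in v.exons)
        return cls(gene_id, GenomicInterval(chrom, start, end, strand), list(variants))


@dataclass
class ExonMask:
    """Dichotomous exon-membership vector over a gene span for one variant."""

    variant_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("mask must be one-dimensional")
        if not self.values.any():
            raise ValueError(f"mask for {self.variant_id} has no exonic positions")

    def __len__(self) -> int:
        return int(self.values.shape[0])


def build_exon_mask(variant: SpliceVariant, span: GenomicInterval) -> ExonMask:
    """Rasterize a variant's exons into a 0/1 vector over ``span``.

    Exon features define membership: UTR-covered exon portions count as
    exonic, matching the vector the congruency score compares coverage
    against.
    """
    mask = np.zeros(len(span), dtype=np.int8)
    for ex in variant.exons:
        if not span.contains(ex):
            raise ValueError(
                f"exon [{ex.start},{ex.end}) of variant {variant.variant_id} "
                f"lies outside span [{span.start},{span.end}) on {span.chromosome}"
            )
        mask[ex.start - span.start : ex.end - span.start] = 1
    return ExonMask(variant.variant_id, mask)


# GFF3 feature types the parser understands, mapped to SpliceVariant slots.
_FEATURE_SLOTS = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}
_MRNA_TYPES = {"mRNA", "transcript"}


def parse_gff(
    path: str | Path,
    locus_filter: set[str] | None = None,
) -> dict[str, GeneModel]:
    """Read a GFF3 file into GeneModel objects keyed by gene ID.

    Parameters
    ----------
    path : path-like
        GFF3 file with gene/mRNA/exon/CDS/five_prime_UTR/three_prime_UTR
        records linked by ID/Parent attributes.
    locus_filter : set of str, optional
        If given, only genes whose ID is in the set are returned.

    Returns
    -------
    dict
        ``{gene_id: GeneModel}``.  1-based inclusive GFF coordinates are
        converted to 0-based half-open.  Features of unknown type, exons
        with unresolvable parents, and genes with zero valid variants are
        dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    known_types = set(_FEATURE_SLOTS) | _MRNA_TYPES | {"gene"}
    for ftype in db.featuretypes():
        if ftype not in known_types:
            logger.warning("ignoring %d features of unknown type %r",
                           db.count_features_of_type(ftype), ftype)

    genes: dict[str, GeneModel] = {}
    for gene_feat in db.features_of_type("gene", order_by="start"):
        gene_id = gene_feat.id
        if locus_filter is not None and gene_id not in locus_filter:
            continue
        variants: list[SpliceVariant] = []
        for mrna in db.children(gene_feat, level=1):
            if mrna.featuretype not in _MRNA_TYPES:
                continue
            slots: dict[str, list[GenomicInterval]] = {
                "exons": [], "cds": [], "utr5": [], "utr3": []
            }
            for child in db.children(mrna, level=1):
                slot = _FEATURE_SLOTS.get(child.featuretype)
                if slot is None:
                    continue
                slots[slot].append(
                    GenomicInterval(
                        child.seqid, child.start - 1, child.end, child.strand or "."
                    )
                )
            if not slots["exons"]:
                logger.warning("variant %s of gene %s has no exons; skipped",
                               mrna.id, gene_id)
                continue
            try:
                variants.append(
                    SpliceVariant(
                        mrna.id,
                        exons=slots["exons"],
                        cds=slots["cds"],
                        utr5=slots["utr5"],
                        utr3=slots["utr3"],
                    )
                )
            except ValueError as exc:
                logger.warning("rejecting variant %s of gene %s: %s", mrna.id, gene_id, exc)
        if not variants:
            logger.warning("gene %s has zero valid variants; excluded", gene_id)
            continue
        genes[gene_id] = GeneModel.from_variants(gene_id, variants)
    return genes
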