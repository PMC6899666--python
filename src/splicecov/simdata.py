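"""Synthetic multi-isoform genes and spliced short-read alignments.

Everything downstream — pileup, congruency scoring, RPKM, tables, plots —
is testable offline against fixtures this module generates with known
ground truth.  A toy locus is built from one of three alternative-splicing
archetypes (alternative acceptor site, skipped cassette exon, retained
intron) or from explicit exon structures; single-end reads are then drawn
variant-by-variant from a known isoform mixture, with start positions
uniform over transcript coordinates, and written as spliced alignments
(N CIGAR operations across introns) to a coordinate-sorted, indexed BAM.

Reads carry placeholder base calls: the engine reads coverage geometry,
never base identities.  There is no error model and no FASTQ stage —
alignments are written directly.  All randomness flows from the spec's
seed, so identical specs give byte-identical GFF3/SAM output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .config import Compendium, SampleRecord, write_config
from .genemodel import GeneModel, GenomicInterval, SpliceVariant, exon_length

__all__ = [
    "SampleSpec",
    "SimSpec",
    "GroundTruth",
    "make_gene",
    "write_gff",
    "simulate_reads",
    "make_compendium",
    "ARCHETYPES",
]

ARCHETYPES = ("acceptor", "skip", "retention")

# default sample display colors, cycled
_PALETTE = ["#E41A1C", "#377EB8", "#4DAF4A", "#984EA3", "#FF7F00", "#A65628"]


@dataclass
class SampleSpec:
    """One simulated sample: an isoform mixture at a target depth."""

    name: str
    mixture: dict[str, float]
    depth: float = 30.0
    controls: list[str] = field(default_factory=list)
    title: str = ""
    description: str = ""


@dataclass
class SimSpec:
    """Full description of a simulated locus and its samples.

    ``depth`` is the target mean exonic coverage in x; ``read_length`` in
    nucleotides.  Mixture proportions must sum to 1.  With ``archetype``
    set, the exon structure is one of the named alternative-splicing
    archetypes; ``variants`` gives explicit structures instead, as lists
    of (start, end) exon offsets relative to ``gene_start``.
    """

    seed: int = 0
    archetype: str = "skip"
    variants: list[list[tuple[int, int]]] | None = None
    gene_id: str = "SIMG01"
    chromosome: str = "chrS"
    chromosome_length: int = 20000
    gene_start: int = 1000
    read_length: int = 50
    samples: list[SampleSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variants is None and self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES} "
                "or give explicit variants"
            )
        for s in self.samples:
            total = sum(s.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {s.name}: mixture proportions sum to {total}, not 1"
                )


@dataclass
class GroundTruth:
    """What the simulator actually wrote for one sample."""

    mixture: dict[str, float]
    reads_per_variant: dict[str, int]
    total_mapped: int
    expected_coverage: np.ndarray  # over the gene span

    def to_json(self) -> dict:
        return {
            "mixture": self.mixture,
            "reads_per_variant": self.reads_per_variant,
            "total_mapped": self.total_mapped,
            "expected_coverage": [float(x) for x in self.expected_coverage],
        }


# ---------------------------------------------------------------------------
# gene construction

def _archetype_exons(archetype: str) -> list[list[tuple[int, int]]]:
    """Exon offsets (relative to gene start) for the splicing archetypes.

    Exons are 300 bp, introns 200 bp; every archetype's two isoforms
    differ by a distinguishing region of >= 60 bp, large enough for the
    congruency score to separate them at modest depth.
    """
    e = 300
    i = 200
    # shared three-exon backbone: [0,300), [500,800), [1000,1300)
    backbone = [(0, e), (e + i, 2 * e + i), (2 * e + 2 * i, 3 * e + 2 * i)]
    if archetype == "acceptor":
        # variant 2 uses an upstream alternative acceptor for exon 2,
        # extending it 80 bp into the intron
        alt = [backbone[0], (backbone[1][0] - 80, backbone[1][1]), backbone[2]]
        return [backbone, alt]
    if archetype == "skip":
        # variant 2 skips the 300 bp cassette exon
        return [backbone, [backbone[0], backbone[2]]]
    if archetype == "retention":
        # variant 2 retains intron 1: exons 1+2 fuse into one block
        fused = [(0, 2 * e + i), backbone[2]]
        return [backbone, fused]
    raise ValueError(f"unknown archetype {archetype!r}")


def _transcript_blocks(
    exons: list[GenomicInterval], t_start: int, t_len: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate window to genomic blocks across exons."""
    blocks: list[tuple[int, int]] = []
    offset = 0
    remaining_start, remaining = t_start, t_len
    for ex in exons:
        ex_len = len(ex)
        if remaining <= 0:
            break
        if remaining_start >= ex_len:
            remaining_start -= ex_len
            continue
        g_start = ex.start + remaining_start
        take = min(ex_len - remaining_start, remaining)
        blocks.append((g_start, g_start + take))
        remaining -= take
        remaining_start = 0
    if remaining > 0:
        raise ValueError("transcript window extends past the transcript end")
    return blocks


def make_gene(spec: SimSpec, gff_path: str | Path | None = None) -> GeneModel:
    """Construct the toy gene model, optionally writing it as GFF3.

    Variant IDs are ``<gene_id>.1``, ``<gene_id>.2``, ...  Each variant
    gets a 60 bp 5'UTR at the transcript start and a 60 bp 3'UTR at the
    end, with CDS in between, so annotation parsing and structure
    rendering exercise all four feature types.  Construction is fully
    deterministic.
    """
    structures = spec.variants or _archetype_exons(spec.archetype)
    variants = []
    for idx, offsets in enumerate(structures, start=1):
        exons = [
            GenomicInterval(
                spec.chromosome, spec.gene_start + a, spec.gene_start + b, "+"
            )
            for a, b in offsets
        ]
        tx_len = sum(len(ex) for ex in exons)
        utr = min(60, tx_len // 4)
        utr5 = [
            GenomicInterval(spec.chromosome, a, b, "+")
            for a, b in _transcript_blocks(exons, 0, utr)
        ]
        cds = [
            GenomicInterval(spec.chromosome, a, b, "+")
            for a, b in _transcript_blocks(exons, utr, tx_len - 2 * utr)
        ]
        utr3 = [
            GenomicInterval(spec.chromosome, a, b, "+")
            for a, b in _transcript_blocks(exons, tx_len - utr, utr)
        ]
        variants.append(
            SpliceVariant(
                f"{spec.gene_id}.{idx}", exons=exons, cds=cds, utr5=utr5, utr3=utr3
            )
        )
    gene = GeneModel.from_variants(spec.gene_id, variants)
    if gff_path is not None:
        write_gff(gene, gff_path)
    return gene


def write_gff(gene: GeneModel, path: str | Path) -> Path:
    """Serialize a GeneModel to GFF3 (1-based inclusive on output)."""
    lines = ["##gff-version 3"]

    def row(ftype: str, iv: GenomicInterval, attrs: str) -> str:
        return "\t".join(
            [
                iv.chromosome, "splicecov-sim", ftype,
                str(iv.start + 1), str(iv.end), ".", iv.strand, ".", attrs,
            ]
        )

    lines.append(row("gene", gene.span, f"ID={gene.gene_id}"))
    for v in gene.variants:
        mrna_iv = GenomicInterval(
            gene.span.chromosome, v.exons[0].start, v.exons[-1].end, v.exons[0].strand
        )
        lines.append(row("mRNA", mrna_iv, f"ID={v.variant_id};Parent={gene.gene_id}"))
        for ftype, ivs in (
            ("exon", v.exons),
            ("CDS", v.cds),
            ("five_prime_UTR", v.utr5),
            ("three_prime_UTR", v.utr3),
        ):
            for k, iv in enumerate(ivs, start=1):
                lines.append(
                    row(ftype, iv, f"ID={v.variant_id}:{ftype}:{k};Parent={v.variant_id}")
                )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# read simulation

def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Turn genomic blocks into CIGAR tuples: M runs separated by N skips."""
    cigar: list[tuple[int, int]] = []
    for j, (a, b) in enumerate(blocks):
        if j > 0:
            gap = a - blocks[j - 1][1]
            if gap > 0:
                cigar.append((3, gap))  # N
        cigar.append((0, b - a))  # M
    return cigar


def simulate_reads(
    gene: GeneModel,
    spec: SimSpec,
    sample: SampleSpec,
    out_prefix: str | Path,
) -> tuple[Path, GroundTruth]:
    """Draw reads from a known isoform mixture and write BAM + BAI.

    The number of reads is ``depth * mixture-weighted mean exonic length /
    read_length``; each read's generating variant is drawn i.i.d. from the
    mixture and its start uniform over that variant's transcript, so
    per-variant counts are binomial around the mixture proportions.
    A SAM file (``<prefix>.sam``) is kept alongside the BAM as the
    deterministic byte-level artifact.

    Returns the BAM path and the recorded ground truth.
    """
    out_prefix = Path(out_prefix)
    # crc32 keeps the per-sample stream deterministic across processes
    rng = np.random.default_rng(spec.seed ^ zlib.crc32(sample.name.encode()))
    variant_ids = list(sample.mixture)
    probs = np.array([sample.mixture[v] for v in variant_ids], dtype=float)
    exon_lens = {v.variant_id: exon_length(v) for v in gene.variants}
    mean_len = float(sum(sample.mixture[v] * exon_lens[v] for v in variant_ids))
    n_reads = int(round(sample.depth * mean_len / spec.read_length))

    choices = rng.choice(len(variant_ids), size=n_reads, p=probs) if n_reads else np.array([], dtype=int)
    records: list[tuple[int, str, list[tuple[int, int]]]] = []
    counts = {vid: 0 for vid in exon_lens}
    span_len = len(gene.span)
    expected = np.zeros(span_len, dtype=float)

    per_variant_n = {vid: int((choices == k).sum()) for k, vid in enumerate(variant_ids)}
    read_idx = 0
    for k, vid in enumerate(variant_ids):
        variant = gene.variant(vid)
        tx_len = exon_lens[vid]
        n_v = per_variant_n[vid]
        counts[vid] = n_v
        if n_v == 0:
            continue
        if tx_len < spec.read_length:
            raise ValueError(
                f"variant {vid}: transcript ({tx_len} nt) shorter than read length"
            )
        n_starts = tx_len - spec.read_length + 1
        starts = rng.integers(0, n_starts, size=n_v)
        for s in starts:
            blocks = _transcript_blocks(variant.exons, int(s), spec.read_length)
            records.append((blocks[0][0], f"sim_{vid}_{read_idx}", blocks))
            read_idx += 1
        # exact expectation of coverage at each transcript position, mapped
        # to the genome through the exon chain
        p = np.arange(tx_len)
        cov_t = (np.minimum(p, n_starts - 1) - np.maximum(0, p - spec.read_length + 1) + 1)
        cov_t = n_v * cov_t / n_starts
        t = 0
        for ex in variant.exons:
            off = ex.start - gene.span.start
            expected[off : off + len(ex)] += cov_t[t : t + len(ex)]
            t += len(ex)

    records.sort(key=lambda r: (r[0], r[1]))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chromosome, "LN": spec.chromosome_length}],
    }
    sam_path = out_prefix.with_suffix(".sam")
    bam_path = out_prefix.with_suffix(".bam")
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for pos, name, blocks in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = _blocks_to_cigar(blocks)
            a.query_sequence = "A" * spec.read_length
            a.flag = 0
            sam.write(a)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))

    truth = GroundTruth(
        mixture=dict(sample.mixture),
        reads_per_variant=counts,
        total_mapped=len(records),
        expected_coverage=expected,
    )
    return bam_path, truth


# ---------------------------------------------------------------------------
# compendium assembly

def make_compendium(
    spec: SimSpec, out_dir: str | Path, atlas_mode: bool = False
) -> tuple[Path, Path, dict[str, GroundTruth]]:
    """Build a full offline fixture set: GFF3 + per-sample BAMs + config XML.

    Control wiring follows each SampleSpec's ``controls`` list; with
    ``atlas_mode`` the dataset is flagged for median-as-control relative
    expression instead.  Ground truth for every sample is also written to
    ``ground_truth.json``.

    Returns (config path, GFF3 path, ground truth by sample name).
    """
    if not spec.samples:
        raise ValueError("spec has no samples")
    names = [s.name for s in spec.samples]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate sample names: {names}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gff_path = out_dir / f"{spec.gene_id}.gff3"
    gene = make_gene(spec, gff_path)

    truths: dict[str, GroundTruth] = {}
    records: list[SampleRecord] = []
    for i, sample in enumerate(spec.samples):
        bam_path, truth = simulate_reads(gene, spec, sample, out_dir / sample.name)
        truths[sample.name] = truth
        records.append(
            SampleRecord(
                name=sample.name,
                bam_locator=bam_path.name,
                title=sample.title or f"Simulated sample {sample.name}",
                description=sample.description
                or "mixture "
                + ", ".join(f"{v}:{p:g}" for v, p in sample.mixture.items()),
                sra_id="",
                total_reads_mapped=max(1, truth.total_mapped),
                read_map_method="simulated",
                tissue_image_key="leaf",
                color=_PALETTE[i % len(_PALETTE)],
                controls=list(sample.controls),
            )
        )
    comp = Compendium(
        dataset_id=f"sim-{spec.gene_id}", samples=records, atlas_mode=atlas_mode
    )
    config_path = out_dir / "compendium.xml"
    write_config(comp, config_path)
    (out_dir / "ground_truth.json").write_text(
        json.dumps({k: v.to_json() for k, v in truths.items()}, indent=2) + "\n"
    )
    return config_path, gff_path, truths
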