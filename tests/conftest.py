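"""Shared fixtures: toy gene models and simulated compendia.

Session-scoped simulated fixtures keep the suite fast; every BAM is
generated at test time by the simulator, never stored.
"""

from __future__ import annotations

import re

import numpy as np
import pysam
import pytest

import splicecov as sc

V1 = "SIMG01.1"
V2 = "SIMG01.2"


@pytest.fixture(scope="session")
def toy_gene() -> sc.GeneModel:
    """Two-variant gene (exon-skip archetype), built in memory."""
    return sc.make_gene(sc.SimSpec(seed=0, archetype="skip"))


@pytest.fixture(scope="session")
def skip_compendium(tmp_path_factory):
    """Two pure-isoform samples plus a 50/50 mixture, with controls wired."""
    out = tmp_path_factory.mktemp("skip_comp")
    spec = sc.SimSpec(
        seed=7,
        archetype="skip",
        samples=[
            sc.SampleSpec("pure1", {V1: 1.0, V2: 0.0}, depth=30, controls=["pure1"]),
            sc.SampleSpec("pure2", {V1: 0.0, V2: 1.0}, depth=30, controls=["pure1"]),
            sc.SampleSpec(
                "mix", {V1: 0.5, V2: 0.5}, depth=30, controls=["pure1", "pure2"],
                title="Heat stressed leaf", description="50/50 mixture",
            ),
        ],
    )
    config_path, gff_path, truths = sc.make_compendium(spec, out)
    return {
        "dir": out,
        "spec": spec,
        "config": config_path,
        "gff": gff_path,
        "truths": truths,
    }


@pytest.fixture(scope="session")
def skip_gene(skip_compendium) -> sc.GeneModel:
    return sc.parse_gff(skip_compendium["gff"])["SIMG01"]


# ---------------------------------------------------------------------------
# independent oracles (deliberately avoid the implementation's code paths)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def brute_force_depth(bam_path, region: sc.GenomicInterval) -> np.ndarray:
    """Per-base depth by regex-parsing each read's CIGAR string."""
    depth = np.zeros(len(region), dtype=int)
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(region.chromosome):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            pos = read.reference_start
            for length, op in _CIGAR_RE.findall(read.cigarstring):
                length = int(length)
                if op in "M=XD":
                    for g in range(pos, pos + length):
                        if region.start <= g < region.end:
                            depth[g - region.start] += 1
                    pos += length
                elif op == "N":
                    pos += length
    return depth


def brute_force_count(bam_path, region: sc.GenomicInterval) -> int:
    """Reads overlapping the region by >=1 aligned (M/=/X/D) base."""
    n = 0
    with pysam.AlignmentFile(str(bam_path)) as af:
        for read in af.fetch(region.chromosome):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            pos = read.reference_start
            hit = False
            for length, op in _CIGAR_RE.findall(read.cigarstring):
                length = int(length)
                if op in "M=XD":
                    if pos < region.end and region.start < pos + length:
                        hit = True
                    pos += length
                elif op == "N":
                    pos += length
            n += hit
    return n


def write_sam_bam(tmp_path, records, chrom="chrS", chrom_len=20000, name="manual"):
    """Write hand-specified alignments (pos, cigar, flag) to an indexed BAM."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    sam = tmp_path / f"{name}.sam"
    bam = tmp_path / f"{name}.bam"
    with pysam.AlignmentFile(str(sam), "wh", header=header) as fh:
        for i, (pos, cigar, flag) in enumerate(records):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i}"
            a.flag = flag
            a.reference_id = 0 if not flag & 0x4 else -1
            a.reference_start = pos if not flag & 0x4 else -1
            a.mapping_quality = 60
            if not flag & 0x4:
                a.cigarstring = cigar
            qlen = a.infer_query_length() or 10
            a.query_sequence = "A" * qlen
            fh.write(a)
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam
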