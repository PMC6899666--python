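# Methods

## Model and procedure

For one gene and one RNA-seq sample the engine computes two families of
quantities from an indexed BAM and a GFF3 annotation.

**Congruency score.** The gene span is the union extent of every
variant's exons, so that all variants of a locus are scored on vectors
of equal length against a single coverage track. Over this span the
pileup produces the coverage vector *x* (reads covering each position)
and each variant contributes a dichotomous mask *m* (1 at exonic
positions, including UTR-covered exon portions; 0 elsewhere). The
point-biserial correlation

r_pb = (M₁ − M₀)/s · √(n₁n₀/n²)

is the Pearson correlation of *x* with *m*, computed with the population
(divide-by-n) standard deviation. The sample/population choice does not
affect sample ranking — both conventions cancel in the Pearson identity
when applied consistently — and the implementation is checked against an
independent Pearson oracle to 1e−12 in the test suite. When either
vector is constant (flat or zero coverage, or an all-exon mask) the
correlation is undefined and is represented as NaN; NaN values survive
into tables and exports (rendered grey, sorted last, exported as empty
fields/null) because a browser-style report must still show such
samples rather than fail.

**Expression summary.** RPKM = reads·10⁹/(exon_length·total_mapped).
The numerator counts primary mapped reads overlapping the gene's full
genomic span (introns included) by at least one aligned base; the
kilobase denominator uses the *selected variant's* exonic length. This
mixed convention — span-based counting, exon-based length — is the
engine's deliberate contract: region counting mirrors a
`samtools view` query on the locus, and normalizing by the displayed
variant's exon length keeps values comparable across variant selections.
Relative mode is log₂(sample RPKM / reference), where the reference is
the arithmetic mean of the sample's controls (union of `controls` and
`replicate_controls` in the compendium config), or the median RPKM
across all samples when the dataset is flagged `atlas_mode` — the
convention for developmental atlases with no natural control. The
reference or sample being zero makes the log ratio undefined (NaN), not
an error.

## Coverage extraction

Depth is accumulated from each alignment's reference-consuming CIGAR
blocks rather than a pileup engine call, so the filtering policy is
explicit and uncapped:

- excluded: unmapped, secondary (0x100), supplementary (0x800);
- kept: duplicates, QC-fail reads; mapping quality threshold 0;
- D (deletion) positions count as covered, N (intron skip) positions do
  not — the appropriate treatment for spliced RNA-seq alignments;
- no maximum-depth cap.

`pysam` remains the file-format layer (BAM/BAI reading, SAM writing,
sorting, indexing). Region read counts use ≥1-aligned-base overlap, so
a spliced read that merely bridges the region with its N gap is not
counted.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| sd convention in r_pb | — | population (n) | ranking-invariant; documented for reproducibility |
| read filters | — | primary mapped only | permissive samtools-like defaults |
| relative-mode reference | RPKM | mean of controls; median of all samples in atlas mode | matches the two compendium styles |
| absolute color ceiling | RPKM | max RPKM in the current table | "max" convention for expression pictographs |
| relative color bound | log₂ | largest \|log₂ ratio\| in the table, symmetric | keeps 0 at yellow |
| export precision | sig. digits | 6 | round-trippable without false precision |

Color endpoints are #FFFF00→#FF0000 (absolute) and
#0000FF→#FFFF00→#FF0000 (relative), clamped at the bounds; undefined
values map to #D3D3D3. The named colors are fixed by the display
convention; the exact hex endpoints and clamping are this package's
documented choices.

## Synthetic data

The simulator emulates the situation the engine is built for: one locus
with two isoforms differing by a localized splicing event, sequenced
across samples with varying isoform mixtures. Three archetypes are
built in, each with 300 bp exons and 200 bp introns on a toy chromosome
`chrS`: alternative acceptor (exon 2 extended 80 bp upstream), skipped
cassette exon, and retained intron. Reads are single-end, 50 bp by
default, drawn i.i.d. from the mixture with start positions uniform
over the generating variant's transcript, then projected to genomic
coordinates with N CIGAR operations across introns. Base calls are
placeholders — every statistic in the engine depends on coverage
geometry only. Read number is depth × (mixture-weighted mean exonic
length)/read length, so per-variant counts are binomial around the
mixture proportions; all randomness derives from the spec seed (one
crc32-offset stream per sample), making GFF3 and SAM output
byte-reproducible.

Default study conditions used by the tests: 20–30× mean exonic depth,
≥50 bp distinguishing regions between isoforms, compendia of 3–6
samples. At these scales the generating isoform attains the highest
congruency score in ≥19/20 seeded pure-mixture fixtures, and a 6-sample
course whose second-isoform fraction rises 0→1 yields strictly
increasing r_pb for that isoform.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: sequencing errors and quality variation,
positional/GC bias, paired ends, multi-mapping reads, overlapping genes
on either strand, strandedness, and alignment artifacts. Real
alternative-splicing calls should treat r_pb as a triage statistic, not
evidence; differential expression requires count-based models
(DESeq2-class), which are out of scope here.

## Numerical and design choices

- Coordinates are 0-based half-open internally; the 1-based inclusive
  GFF3 convention is converted only at I/O boundaries.
- Gene span = union of all variants' exons (see above); per-variant
  spans would change r_pb values slightly but not the ranking logic,
  and would break cross-variant comparability on one track.
- Overlapping exon records within a variant are merged before mask
  construction (dichotomous semantics).
- Strand is carried through the data model but ignored in masks and
  coverage (unstranded libraries assumed).
- r_pb is clipped to [−1, 1] to absorb last-ulp floating excursions.
- Sorting is stable with config order as the tie-break; NaN sinks to
  the bottom regardless of direction. Sorting by RPKM uses the absolute
  value in absolute mode and the log₂ ratio in relative mode.
- Failed samples (unreadable BAM, bad header) become flagged rows with
  the failure reason; tables and exports never drop them silently.
- The compendium XML dialect (`<files>`/`<file>` with a fixed attribute
  inventory, comma-separated control lists, dataset-level `atlas_mode`)
  is this package's own round-trippable encoding of the standard sample
  metadata inventory; unknown attributes are preserved on read so
  foreign files survive a read/write cycle.
- The anatomical pictograph library is out of scope; the value→color
  computation is exposed directly and tested against a channel-wise
  interpolation oracle.

## Limitations

- Local BAM paths only; no remote (HTTP/S3/Drive) access.
- No base-quality awareness and no variant calling.
- Single-gene queries; no transcriptome-wide batch mode.
- RPKM read counts include intron-only reads by construction of the
  span-overlap rule; for genes with long introns and high intronic
  background the absolute values are correspondingly inflated.
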