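# Methods

## The problem

Cultivated potato is autotetraploid (2n = 4x = 48) and highly
heterozygous: at a variant site a cultivar carries up to four haplotypes
with allele dosages AAAB, AABB or ABBB, and variation can be
*intra-varietal* (segregating among one cultivar's haplotypes) or
*inter-varietal* (fixed differences between cultivars). This package
implements a transcriptome-based SNP discovery workflow for such
material — consensus calling from read alignments, two Maq- and SAMTools-style
filter chains, genome anchoring with exon-boundary and biallelic gates,
assay-candidate export — plus allele-frequency-based analysis of
germplasm structure. Everything is exercised on synthetic data with
exact planted truth.

## Consensus caller

The caller evaluates three genotypes G ∈ {hom-ref, het, hom-alt} per
pileup column. For a read base b with phred quality Q and error
probability e = 10^(−Q/10):

    P(b | G) = (1 − e)         if b is the single allele of G
             = ½(1 − e) + ½·e/3 if G is het and b is one of its alleles
             = e/3              otherwise

The likelihood is the product over covering reads; the prior is uniform.
The alternative allele is the most frequent non-reference base (ties
broken alphabetically; at a tie the runner-up is carried as an extra
allele for the downstream biallelic gate). Reported scores:

- **consensus quality** = −10·log10(1 − max posterior), confidence in
  the called genotype;
- **SNP quality** = −10·log10(posterior(hom-ref)), confidence the site
  is variant at all.

Both are capped at phred 255. Tetraploid dosage is *not* modelled: the
het genotype expects a 50/50 draw even though true dosages are 1/4, 2/4
or 3/4. This mirrors the dosage-blind AB treatment used throughout; at
the depths the chains require (≥ 20) a dosage-1/4 site still decisively
favours het over hom-ref. Columns with a non-ACGT reference base are
skipped.

## Filter chains

Two presets bind the classic parameter sets:

| rule | transcript mode | genome mode |
|---|---|---|
| depth | 20 ≤ DP ≤ 225 | 20 ≤ DP ≤ 240 |
| consensus quality | ≥ 30 | ≥ 20 |
| adjacent consensus | ≥ 20 at both flanking columns | — |
| SNP quality | — | ≥ 20 |
| mapping quality | max MAPQ ≥ 60 | max MAPQ ≥ 60 |
| density | ≤ 1 other raw SNP in ± 50 bp | same |
| indel proximity | ≥ 50 bp from any indel locus | same |
| 3'-bias | — | ≤ 10 % of alt reads in 3'-terminal 5 bases |

Conventions, applied uniformly: thresholds are inclusive on the pass
side (depth 20 passes, indel distance exactly 50 passes); the density
window is centred (± 50 bp) and counts *other* raw calls; density and
indel rules are evaluated on the raw call set before quality rules, and
since every violated rule is recorded (never only the first), the ledger
is order-independent and satisfies n_raw = n_pass + n_fail identically.

Open interpretation points, resolved as follows and configurable:

- *mapping quality*: the requirement is read as "the best-mapping
  covering read reaches MAPQ 60" (`mapq_rule="max"`); an all-reads
  variant is available.
- *adjacent consensus*: a missing neighbour column (contig end) fails
  the rule — contig-end calls are exactly the assembly artifacts it
  targets. Neighbour consensus quality is computed with the same
  three-genotype model applied to the neighbouring column.
- *3'-bias*: the window is the terminal 5 aligned bases of each read's
  3' end (leftmost aligned base for a reverse-strand read); the
  denominator is alt-supporting reads (an all-reads denominator is
  configurable). The rule exists because misaligned read ends produce
  mismatches at good base quality; it is inherently geometric and will
  discard true SNPs whose supporting reads happen to stack their 3'
  ends at the site (common near exon boundaries when transcriptome
  reads are placed on a genome).

The Sanger chain uses no quality model (trace qualities unavailable): a
call requires depth ≥ 10 with ≥ 4 reads agreeing on one alternative
base; two alternatives reaching 4 reads flag the site
non-biallelic-within-cultivar and carry both alleles. Post-filters drop
calls < 50 bp from an intron boundary and calls with > 1 additional call
in the surrounding 100 bp.

## Genome anchoring

Transcript placements are exon-block alignments (the shape a spliced
aligner emits). A transcript with multiple placements keeps only the
single best-identity one; exact ties drop the transcript, mirroring the
read-level uniqueness rule. Gates, in any order (they commute):

- identity strictly > 95 % and gap-free, else all the transcript's SNPs
  drop;
- ≥ 50 bp (transcript coordinates) from the nearest *internal* block
  junction — alignment termini are not junctions, since they reflect
  transcript completeness rather than splice sites;
- after collapsing identical genome positions across cultivars (allele
  sets unioned, provenance concatenated, conflicting reference alleles
  excluded and counted), exactly two distinct alleles across all
  cultivars including the reference.

Projection is exact block arithmetic and round-trips identically for
every aligned base. Assay export takes 60 bp of plus-strand genome
sequence each side (a typical array design context; configurable) and
rejects candidates whose flanks run off the sequence (SHORT_FLANK) or
contain another catalog SNP (POLYMORPHIC_FLANK). These two local rules
replace a proprietary vendor design score; the check covers catalog
members only, not variants the chains had already discarded.

## Population structure

Panel genotypes are dosage-blind: tetraploid heterozygous classes all
collapse to AB. Frequencies per (marker, group) are
p = (2·n_AA + n_AB) / (2·n_nonmissing), treating every clone as
contributing two alleles; in true tetraploids this biases p toward 0.5,
a limitation of the encoding (dosage is not scorable), not of the
estimator. Missing calls are excluded pairwise: a marker without data in
either group of a pair is excluded from that pair's locus count L.

Rogers distance: D = (1/L) Σ_l √(½ Σ_a (p_la − q_la)²), which for
biallelic loci equals (1/L) Σ_l |p_l − q_l| (verified to 1e-12). It is a
metric on frequency vectors (symmetry, identity, triangle inequality —
property-tested).

UPGMA joins the closest pair at height d/2 with size-weighted
arithmetic-mean updates, d(k, i∪j) = (n_i·d_ki + n_j·d_kj)/(n_i + n_j);
ties break on the lexicographically smallest active-cluster index pair
for determinism. The result is ultrametric to 1e-9 and matches both a
naive O(n³) re-implementation and average-linkage heights from a
standard clustering library. Newick serialization uses 6-decimal branch
lengths and quotes labels containing whitespace or punctuation.

Admixture-style population-number inference is out of scope; the module
works from a clone → group map supplied by the user (ungrouped clones
are excluded from distance analysis).

## Synthetic data: what it emulates, and what it does not

The generator produces single-chromosome genomes of spliced multi-exon
genes (defaults: 2-4 exons of 150-400 bp, introns 80-300 bp, both
strands), cultivar haplotypes with variants planted per exonic base at a
configurable rate (default 0.005/bp ≈ the SNP density observed in elite
cultivar transcriptomes), uniform alt dosage 1..ploidy so both
intra- and inter-varietal variants occur, and a configurable fraction of
sites (default 5 %) carrying two distinct alternative alleles.

Reads are 61 bp (emulating the sequenced lanes), single-end by default
(pairing metadata optional — no filter consumes it), emitted at their
*true* coordinates in SAM so no aligner is required: read mapping is an
input to this workflow, not part of it. In transcript space reads tile
whole transcripts; in genome space each read lies wholly within one
exon, as an unspliced aligner would place transcriptome reads. Base
errors are substitutions at a configurable rate, multiplied (default 5×)
in the 3'-terminal 5 bases; base qualities encode the per-base error
probability actually used, so the caller is calibrated to the
simulation. Optional 1-bp read indels exercise the indel-proximity
filter; a configurable fraction of reads gets MAPQ 0 to exercise the
uniqueness pre-filter.

Panels draw each clone's genotype as two alleles from its group
frequency (binomial(2, p)) — the information content of a dosage-blind
call — with group frequencies spread evenly across an interval of width
`divergence` around a random centre, so the truth |p − q| between the
extreme groups equals `divergence` at every marker and known divergence
can be recovered.

Not emulated: expression-level variation (uniform coverage per
transcript), library normalization chemistry, instrument-specific error
profiles, systematic misalignment (3' artifacts in tests are constructed
at the column level), linkage between markers, and genuine tetraploid
dosage sampling in panels. Passing tests therefore demonstrate the
correctness of the calling, filtering, anchoring and distance machinery
under the stated statistical model — not robustness to real-data
pathologies such as paralog collapse or mapping bias.

## Recovery scoring

End-to-end tests score filtered calls against planted truth. A planted
site counts toward the recall denominator only if its *realized read
geometry* admits a pass: column depth inside the configured window, ≤ 1
other planted site within 50 bp, no indel locus within 50 bp, flanking
columns present (transcript mode), a MAPQ-60 read at the site, and — in
genome mode — ≤ 10 % of the reads carrying the true alternative allele
seeing the site within their 3'-terminal window. All of these depend
only on where reads landed, not on base-calling accuracy; the 3'
condition in particular removes sites near exon ends *by design* (in
genome space roughly a third of planted sites at the default geometry).
Precision counts every passing call as false unless it sits on a planted
site with a matching alternative allele, with no eligibility conditioning.
Under this definition the study conditions give precision = recall = 1.0
with error-free reads in both chains, and ≥ 0.95 / ≥ 0.90 in genome mode
at 1 % errors with 5× 3' enrichment.

## Problem sizes and determinism

The default test and acceptance fixtures use 10 genes (~7 kb exonic),
100× depth, one cultivar per chain run, 1,000-column randomized ledger
fixtures, 50 random 8-taxon UPGMA matrices, and 2 × 100-clone panels at
200 markers — sizes chosen so the full suite runs in well under a minute
per stage on a single core while keeping binomial sampling error far
from the asserted tolerances. All generators consume a single integer
seed; identical config + seed reproduce every output byte-for-byte
(provenance headers record tool version, config hash and seed).

## Known limitations

- Pair-wise cultivar sharing on synthetic data is sparse because each
  cultivar's variants are planted independently; shared positions arise
  only by coincidence. The sharing tabulation itself is exercised
  against set-algebra oracles on randomized catalogs.
- The caller's het model is diploid; dosage-3/4 tetraploid sites are
  still called het (correct dosage-blind behaviour) but their consensus
  quality is lower than a dosage-aware model would give.
- Plain-text SAM only (desk-scale inputs); BAM/CRAM users should
  convert with samtools first.
- The Sanger caller requires the ≥ 4 supporting reads to agree on one
  alternative base; scripts that counted any non-reference read would
  call slightly more sites.
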