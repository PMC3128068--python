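# spudsnp

SNP discovery and germplasm-structure analysis for autotetraploid potato
(*Solanum tuberosum*, 2n = 4x = 48) transcriptomes, built as a tested,
reusable library with a thin command-line layer.

Potato breeding has long relied on phenotypic selection; transcriptome
sequencing of elite cultivars makes it possible to call single nucleotide
polymorphisms (SNPs) at scale and use them to genotype breeding germplasm.
This package implements that workflow end to end for researchers working
with tetraploid crops:

1. **Consensus SNP calling** from read alignments (plain SAM) via an
   explicit three-genotype maximum-likelihood caller over
   {hom-ref, het, hom-alt} with a per-base phred error model. Tetraploid
   allele dosage is deliberately not modelled — heterozygous sites are
   treated dosage-blind, matching what downstream genotyping platforms can
   score.
2. **Two NGS filter chains**: a *transcript mode* (reads aligned to
   transcript contigs; depth ∈ [20, 225], consensus quality ≥ 30, adjacent
   consensus ≥ 20, MAPQ 60, ≤ 1 other SNP per 100 bp window, ≥ 50 bp from
   indels) and a *genome mode* (reads aligned to a reference genome; depth
   ∈ [20, 240], consensus and SNP quality ≥ 20, MAPQ 60, the same density
   and indel rules, plus a 3'-bias rule that discards calls where > 10 % of
   alt-supporting reads see the variant within the terminal 5 aligned bases
   of their 3' end — the signature of alignment artifacts). Every call is
   annotated with **all** violated rules, so `n_raw = n_pass + n_fail`
   holds by construction.
3. **A low-coverage Sanger EST caller** (depth ≥ 10 with ≥ 4 reads
   supporting one alternative base) with intron-proximity and density
   post-filters.
4. **Genome anchoring**: transcript SNPs are projected onto the genome
   through exon-block alignments (identity strictly > 95 %, no gaps;
   ≥ 50 bp from internal exon junctions), collapsed across cultivars into
   a unique-position catalog, restricted to biallelic sites, exported as
   `LEFT[X/Y]RIGHT` assay design strings with local design checks, and
   tabulated for cultivar sharing/restriction.
5. **Population structure**: dosage-blind genotype matrices
   (AAAB/AABB/ABBB → AB), per-group allele frequencies
   p = (2·n_AA + n_AB) / (2·n), the Rogers distance
   D = (1/L) Σ_l √(½ Σ_a (p_la − q_la)²) — which reduces to
   (1/L) Σ|p − q| for biallelic loci — and a UPGMA tree with Newick export.
6. **A synthetic-data module** that generates spliced genomes, tetraploid
   cultivar haplotypes, 61-bp reads with truth-coordinate SAM alignments
   and truth VCFs, and group-structured genotype panels, so every stage
   can be scored against exact planted truth.

## Worked example

`examples/01_simulate_and_call.py` simulates one tetraploid cultivar at
100× over ten spliced genes with error-free reads and runs the
transcript-mode chain:

```
planted variant sites : 42
raw consensus calls   : 42
passing filtered calls: 37  (failed: 5, by rule {'DENSITY': 5})
precision 1.000 / recall 1.000 on 37 geometrically eligible truth sites
```

Every raw call is a planted site (no false positives with error-free
reads); the five failures are genuine rule hits — clusters of planted
variants violating the ≤ 1-other-SNP-per-100-bp density rule. Precision
and recall are both 1.0 on the sites whose read-placement geometry admits
a pass.

`examples/03_population_structure.py` simulates a 240-clone panel in four
market-class groups at 82 markers and prints the Rogers matrix and UPGMA
tree:

```
(chip_processing:0.082504,(russet:0.060264,(frenchfry_processing:0.041493,round_white:0.041493):0.018770):0.022240);
```

Branch lengths are in Rogers-distance units; groups join in order of
their simulated allele-frequency offsets. The other examples cover genome
anchoring/catalog building (`02`) and the one-call pipeline (`04`).

The same functionality is exposed as a CLI:

```bash
spudsnp run-all --seed 1 --outdir demo
spudsnp call-ngs --mode genome --sam reads.sam --ref genome.fa --vcf-out out.vcf
spudsnp popgen --genotypes g.tsv --groups m.tsv --out-prefix run1
```

## Layout

- `src/spudsnp/` — `synthetic`, `pileup`, `ngs`, `sanger`, `anchor`,
  `popgen`, `evaluate`, `pipeline`, `config`, `cli`, `io`
- `examples/` — narrative scripts, one per capability
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — models, parameter choices, numerical conventions,
  and known limitations
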