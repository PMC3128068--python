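"""Synthetic tetraploid transcriptome data with known ground truth.

Generates everything the SNP-discovery pipeline consumes — a reference
genome with spliced gene models, cultivar haplotypes carrying planted
intra- and inter-varietal variants, short reads with truth alignments,
and group-differentiated panel genotype matrices — so that every stage
of the pipeline can be scored against exact truth.

Variants are transcriptomic: they are planted at exonic positions only,
with per-haplotype dosage recorded, mirroring heterozygous autotetraploid
cultivars (2n = 4x = 48) where a site may segregate within a cultivar
(intra-varietal) or differ from the reference in all four haplotypes
(inter-varietal).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ConfigurationError(ValueError):
    """A generator was asked for something impossible."""


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class Gene:
    """A gene model: ordered exon intervals on a chromosome (1-based, closed)."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # ascending genomic order

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def transcript_blocks(self) -> list[tuple[int, int, int, int]]:
        """(t_start, t_end, g_start, g_end) blocks in transcript order.

        Transcript coordinates are 1-based on the spliced, strand-oriented
        transcript.  For a minus-strand gene the first transcript block is
        the genomically last exon.
        """
        exons = list(self.exons) if self.strand == "+" else list(self.exons)[::-1]
        blocks = []
        t = 1
        for g_start, g_end in exons:
            n = g_end - g_start + 1
            blocks.append((t, t + n - 1, g_start, g_end))
            t += n
        return blocks


@dataclass
class GenomeModel:
    """Chromosome sequences plus gene models and their spliced transcripts."""

    chromosomes: dict[str, str]
    genes: list[Gene]

    def transcript(self, gene: Gene) -> str:
        chrom = self.chromosomes[gene.chrom]
        spliced = "".join(chrom[s - 1 : e] for s, e in gene.exons)
        return spliced if gene.strand == "+" else revcomp(spliced)

    def transcripts(self) -> dict[str, str]:
        return {g.gene_id: self.transcript(g) for g in self.genes}

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def project_transcript_to_genome(self, gene: Gene, tpos: int) -> int:
        """1-based transcript position -> genomic position (exact block walk)."""
        for t_start, t_end, g_start, g_end in gene.transcript_blocks():
            if t_start <= tpos <= t_end:
                if gene.strand == "+":
                    return g_start + (tpos - t_start)
                return g_end - (tpos - t_start)
        raise ValueError(f"transcript position {tpos} outside {gene.gene_id}")

    def exonic_positions(self, gene: Gene) -> list[tuple[int, int]]:
        """All (tpos, gpos) pairs for a gene, in transcript order."""
        return [
            (t, self.project_transcript_to_genome(gene, t))
            for t in range(1, gene.transcript_length + 1)
        ]

    # -- serialization ------------------------------------------------------

    def write_fasta(self, path, transcripts: bool = False) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        if transcripts:
            records = [
                SeqRecord(Seq(seq), id=name, description="")
                for name, seq in self.transcripts().items()
            ]
        else:
            records = [
                SeqRecord(Seq(seq), id=name, description="")
                for name, seq in self.chromosomes.items()
            ]
        SeqIO.write(records, str(path), "fasta")

    def write_gff3(self, path) -> None:
        """Gene models as GFF3 gene/exon features."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                g_start = min(s for s, _ in g.exons)
                g_end = max(e for _, e in g.exons)
                fh.write(
                    f"{g.chrom}\tspudsnp\tgene\t{g_start}\t{g_end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tspudsnp\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                    )

    def write_exon_alignments_gff3(self, path, identity: float = 100.0) -> None:
        """Transcript->genome exon alignments (perfect placements).

        These stand in for a spliced aligner's output: each transcript is
        placed back on the genome it was spliced from, at the given percent
        identity and with no gaps.
        """
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                for t_start, t_end, g_start, g_end in g.transcript_blocks():
                    fh.write(
                        f"{g.chrom}\tspudsnp\texon_block\t{g_start}\t{g_end}\t.\t"
                        f"{g.strand}\t.\tTarget={g.gene_id} {t_start} {t_end};"
                        f"Identity={identity:.1f};Gaps=0\n"
                    )


def generate_genome(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (2, 4),
    exon_len: tuple[int, int] = (150, 400),
    intron_len: tuple[int, int] = (80, 300),
    intergenic_len: tuple[int, int] = (150, 400),
    seed: int = 0,
) -> GenomeModel:
    """Build a single synthetic chromosome carrying ``n_genes`` spliced genes."""
    if n_genes <= 0:
        raise ConfigurationError("n_genes must be positive")
    for name, lo_hi in (
        ("exons_per_gene", exons_per_gene),
        ("exon_len", exon_len),
        ("intron_len", intron_len),
        ("intergenic_len", intergenic_len),
    ):
        lo, hi = lo_hi
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"invalid range for {name}: {lo_hi}")

    rng = np.random.default_rng(seed)
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0  # 0-based running offset on chr1

    def rand_seq(n: int) -> str:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=n))

    for gi in range(n_genes):
        spacer = int(rng.integers(intergenic_len[0], intergenic_len[1] + 1))
        parts.append(rand_seq(spacer))
        pos += spacer
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        for ei in range(n_ex):
            if ei > 0:
                ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
                parts.append(rand_seq(ilen))
                pos += ilen
            elen = int(rng.integers(exon_len[0], exon_len[1] + 1))
            parts.append(rand_seq(elen))
            exons.append((pos + 1, pos + elen))  # 1-based closed
            pos += elen
        genes.append(Gene(f"gene{gi + 1:03d}", "chr1", strand, tuple(exons)))
    parts.append(rand_seq(int(rng.integers(intergenic_len[0], intergenic_len[1] + 1))))

    return GenomeModel(chromosomes={"chr1": "".join(parts)}, genes=genes)


# ---------------------------------------------------------------------------
# cultivar haplotypes


@dataclass(frozen=True)
class TruthSite:
    """One planted variant site, with exact per-haplotype alleles."""

    chrom: str
    pos: int  # genomic, 1-based
    gene_id: str
    tpos: int  # transcript coordinate, 1-based
    ref: str
    hap_alleles: tuple[str, ...]  # allele carried by each haplotype

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(self.hap_alleles) | {self.ref}

    @property
    def alts(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.hap_alleles) - {self.ref}))

    def dosage(self, allele: str) -> int:
        return sum(1 for a in self.hap_alleles if a == allele)


@dataclass
class CultivarTruth:
    """A cultivar's haplotypes as variant lists against the reference genome."""

    name: str
    ploidy: int
    sites: list[TruthSite]

    def truth_by_position(self) -> dict[tuple[str, int], TruthSite]:
        return {(s.chrom, s.pos): s for s in self.sites}

    def haplotype_variants(self, hap: int) -> list[TruthSite]:
        return [s for s in self.sites if s.hap_alleles[hap] != s.ref]

    def biallelic_sites(self) -> list[TruthSite]:
        return [s for s in self.sites if len(s.alleles) == 2]

    def write_truth_vcf(self, path) -> None:
        from .io import write_vcf, VcfRecord

        records = []
        for s in sorted(self.sites, key=lambda s: (s.chrom, s.pos)):
            dosages = ",".join(f"{a}:{s.dosage(a)}" for a in sorted(s.alleles))
            records.append(
                VcfRecord(
                    chrom=s.chrom,
                    pos=s.pos,
                    ref=s.ref,
                    alts=s.alts,
                    info={
                        "CULTIVAR": self.name,
                        "GENE": s.gene_id,
                        "TPOS": s.tpos,
                        "DOSAGE": dosages,
                    },
                )
            )
        write_vcf(path, records, extra_header=[f"##cultivar={self.name}"])


def generate_cultivar_haplotypes(
    genome: GenomeModel,
    name: str = "cultivar",
    ploidy: int = 4,
    snp_rate: float = 0.005,
    nonbiallelic_fraction: float = 0.05,
    seed: int = 0,
) -> CultivarTruth:
    """Plant variants on ``ploidy`` haplotypes at exonic positions.

    Each exonic base becomes a variant site with probability ``snp_rate``.
    At a site the number of non-reference haplotypes (the alt dosage) is
    uniform on 1..ploidy, so both intra-varietal (heterozygous) and
    inter-varietal (fixed-difference) variants occur.  A fraction
    ``nonbiallelic_fraction`` of heterozygous-capable sites receives two
    distinct alternative alleles.
    """
    if ploidy not in (2, 4):
        raise ConfigurationError(f"ploidy must be 2 or 4, got {ploidy}")
    if not 0.0 <= snp_rate <= 1.0:
        raise ConfigurationError("snp_rate must be in [0,1]")
    if not 0.0 <= nonbiallelic_fraction <= 1.0:
        raise ConfigurationError("nonbiallelic_fraction must be in [0,1]")

    rng = np.random.default_rng(seed)
    sites: list[TruthSite] = []
    for gene in genome.genes:
        transcript = genome.transcript(gene)
        for tpos in range(1, gene.transcript_length + 1):
            if rng.random() >= snp_rate:
                continue
            ref_t = transcript[tpos - 1]  # transcript-strand base
            gpos = genome.project_transcript_to_genome(gene, tpos)
            alts_pool = [b for b in BASES if b != ref_t]
            alt1 = alts_pool[int(rng.integers(0, 3))]
            dosage = int(rng.integers(1, ploidy + 1))
            hap_alleles = [ref_t] * ploidy
            alt_haps = list(rng.choice(ploidy, size=dosage, replace=False))
            for h in alt_haps:
                hap_alleles[h] = alt1
            if dosage >= 2 and rng.random() < nonbiallelic_fraction:
                alt2 = next(b for b in alts_pool if b != alt1)
                hap_alleles[alt_haps[0]] = alt2
            # truth is recorded on the genome's plus strand
            ref_g = genome.chromosomes[gene.chrom][gpos - 1]
            if gene.strand == "-":
                hap_g = tuple(revcomp(a) for a in hap_alleles)
            else:
                hap_g = tuple(hap_alleles)
            sites.append(
                TruthSite(gene.chrom, gpos, gene.gene_id, tpos, ref_g, hap_g)
            )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return CultivarTruth(name=name, ploidy=ploidy, sites=sites)


def transcript_space_truth(
    genome: GenomeModel, truth: CultivarTruth
) -> CultivarTruth:
    """Re-express a cultivar's truth on its transcript contigs.

    The transcript-mode pipeline calls SNPs against per-gene transcript
    sequences; this view keys every site by (gene_id, tpos) with alleles on
    the transcript strand, so calls can be scored without projection.
    """
    sites = []
    for s in truth.sites:
        gene = genome.gene_by_id(s.gene_id)
        if gene.strand == "-":
            hap = tuple(revcomp(a) for a in s.hap_alleles)
            ref = revcomp(s.ref)
        else:
            hap, ref = s.hap_alleles, s.ref
        sites.append(TruthSite(s.gene_id, s.tpos, s.gene_id, s.tpos, ref, hap))
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return CultivarTruth(name=truth.name, ploidy=truth.ploidy, sites=sites)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadSimConfig:
    """Short-read simulation parameters.

    61 bp reads emulate two lanes of 61-bp sequencing; errors are enriched
    at the final ``three_prime_window`` bases of each read by
    ``three_prime_multiplier`` to give the 3'-bias filter a realistic
    target.  A ``multi_map_fraction`` of reads is emitted with mapping
    quality 0 to exercise the uniqueness pre-filter.
    """

    read_length: int = 61
    depth: float = 50.0
    error_rate: float = 0.0
    three_prime_multiplier: float = 5.0
    three_prime_window: int = 5
    indel_rate: float = 0.0
    multi_map_fraction: float = 0.0
    space: str = "transcript"  # or "genome"
    paired_metadata: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if self.read_length < 20:
            raise ConfigurationError("read_length must be >= 20")
        for r in (self.error_rate, self.indel_rate, self.multi_map_fraction):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must be in [0,1]")
        if self.space not in ("transcript", "genome"):
            raise ConfigurationError("space must be 'transcript' or 'genome'")


@dataclass
class SimulatedReadSet:
    """Paths to the simulator's outputs plus the truth used to make them."""

    fastq: str
    sam: str
    truth_vcf: str
    truth: CultivarTruth
    n_reads: int


def _phred_char(q: int) -> str:
    return chr(min(max(q, 2), 40) + 33)


def _apply_errors(read: str, cfg: ReadSimConfig, rng) -> tuple[str, str]:
    """Substitution errors on a 5'->3' read; returns (seq, phred+33 quals).

    Base quality encodes the per-base error probability actually used, so
    the downstream likelihood caller is calibrated to the simulation.
    """
    out = list(read)
    quals = []
    n = len(read)
    for i in range(n):
        p = cfg.error_rate
        if n - i <= cfg.three_prime_window:
            p = min(p * cfg.three_prime_multiplier, 0.75)
        q = 40 if p <= 0 else int(round(-10.0 * math.log10(p)))
        quals.append(_phred_char(q))
        if p > 0 and rng.random() < p:
            out[i] = BASES[(BASES.index(out[i]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out), "".join(quals)


def _haplotype_sequence(ref_seq: str, variants: list[tuple[int, str]]) -> str:
    seq = list(ref_seq)
    for pos, allele in variants:
        seq[pos - 1] = allele
    return "".join(seq)


def simulate_reads(
    genome: GenomeModel,
    truth: CultivarTruth,
    cfg: ReadSimConfig,
    outdir,
    prefix: str | None = None,
) -> SimulatedReadSet:
    """Emit FASTQ reads, a truth-coordinate SAM, and a truth VCF.

    Reads carry their TRUE alignment in the SAM (no aligner is run).  In
    transcript space reads are drawn uniformly along each haplotype's
    transcript; in genome space each read lies wholly within one exon, as
    an unspliced aligner would place transcriptome reads on a genome.
    """
    import os

    import pysam

    os.makedirs(outdir, exist_ok=True)
    prefix = prefix or truth.name
    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length

    if cfg.space == "transcript":
        refs = genome.transcripts()
        t_truth = transcript_space_truth(genome, truth)
        hap_variants = {
            gid: {
                h: [
                    (s.tpos, s.hap_alleles[h])
                    for s in t_truth.sites
                    if s.gene_id == gid and s.hap_alleles[h] != s.ref
                ]
                for h in range(truth.ploidy)
            }
            for gid in refs
        }
    else:
        refs = dict(genome.chromosomes)
        hap_variants = {}
        for chrom in refs:
            hap_variants[chrom] = {
                h: [
                    (s.pos, s.hap_alleles[h])
                    for s in truth.sites
                    if s.chrom == chrom and s.hap_alleles[h] != s.ref
                ]
                for h in range(truth.ploidy)
            }

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in refs.items()],
            "PG": [{"ID": "spudsnp-sim", "PN": "spudsnp"}],
        }
    )

    fastq_path = os.path.join(outdir, f"{prefix}.fastq")
    sam_path = os.path.join(outdir, f"{prefix}.sam")
    vcf_path = os.path.join(outdir, f"{prefix}.truth.vcf")

    # windows a read may start in: whole reference (transcript) or exons (genome)
    def start_windows(ref_name: str) -> list[tuple[int, int]]:
        n = len(refs[ref_name])
        if cfg.space == "transcript":
            return [(0, n - L)] if n >= L else []
        wins = []
        for gene in genome.genes:
            if gene.chrom != ref_name:
                continue
            for s, e in gene.exons:
                if e - s + 1 >= L:
                    wins.append((s - 1, e - L))  # 0-based starts
        return wins

    n_total = 0
    with open(fastq_path, "w") as fq, pysam.AlignmentFile(
        sam_path, "w", header=header
    ) as sam:
        for ref_name, ref_seq in refs.items():
            wins = start_windows(ref_name)
            if not wins:
                continue
            span = sum(e - s + 1 for s, e in wins) + (L - 1) * len(wins)
            per_hap = max(1, int(round(cfg.depth * span / (L * truth.ploidy))))
            for hap in range(truth.ploidy):
                hseq = _haplotype_sequence(
                    ref_seq, hap_variants.get(ref_name, {}).get(hap, [])
                )
                for ri in range(per_hap):
                    w = wins[int(rng.integers(0, len(wins)))]
                    start = int(rng.integers(w[0], w[1] + 1))  # 0-based
                    raw = hseq[start : start + L]
                    cigar = f"{L}M"
                    if cfg.indel_rate > 0 and rng.random() < cfg.indel_rate:
                        cut = int(rng.integers(10, L - 10))
                        if rng.random() < 0.5:  # 1-bp deletion in the read
                            raw = hseq[start : start + cut] + hseq[
                                start + cut + 1 : start + L + 1
                            ]
                            cigar = f"{cut}M1D{L - cut}M"
                        else:  # 1-bp insertion in the read
                            ins = BASES[int(rng.integers(0, 4))]
                            raw = (
                                hseq[start : start + cut]
                                + ins
                                + hseq[start + cut : start + L - 1]
                            )
                            cigar = f"{cut}M1I{L - cut - 1}M"
                    reverse = rng.random() < 0.5
                    # the physical read is sequenced 5'->3'; for a reverse-
                    # strand placement it is the revcomp of the reference-
                    # forward segment, so its error-enriched 3' end lands on
                    # the leftmost aligned base
                    read0 = revcomp(raw) if reverse else raw
                    seq, quals = _apply_errors(read0, cfg, rng)
                    name = f"{prefix}.{ref_name}.h{hap}.r{n_total}"
                    fq.write(f"@{name}\n{seq}\n+\n{quals}\n")
                    a = pysam.AlignedSegment(header)
                    a.query_name = name
                    a.flag = 16 if reverse else 0
                    if cfg.paired_metadata:
                        a.flag |= 1
                    a.reference_id = list(refs).index(ref_name)
                    a.reference_start = start
                    a.mapping_quality = (
                        0 if rng.random() < cfg.multi_map_fraction else 60
                    )
                    a.cigarstring = cigar
                    # SAM stores SEQ in reference-forward orientation
                    if reverse:
                        a.query_sequence = revcomp(seq)
                        a.query_qualities = pysam.qualitystring_to_array(quals[::-1])
                    else:
                        a.query_sequence = seq
                        a.query_qualities = pysam.qualitystring_to_array(quals)
                    a.set_tag("NM", 0)
                    sam.write(a)
                    n_total += 1

    if cfg.space == "transcript":
        transcript_space_truth(genome, truth).write_truth_vcf(vcf_path)
    else:
        truth.write_truth_vcf(vcf_path)
    return SimulatedReadSet(fastq_path, sam_path, vcf_path, truth, n_total)


# ---------------------------------------------------------------------------
# panel genotypes


@dataclass
class PanelTruth:
    """True per-group allele-A frequencies behind a simulated panel."""

    frequencies: "object"  # pandas DataFrame markers x groups
    groups: dict[str, list[str]]


def generate_panel(
    groups: list[tuple[str, int]],
    n_markers: int = 82,
    divergence: float = 0.2,
    missing_rate: float = 0.02,
    seed: int = 0,
):
    """Simulate a markers x clones genotype matrix with group structure.

    Per marker, group allele-A frequencies are spread evenly across an
    interval of width ``divergence`` around a random centre, so the truth
    |p - q| between the two extreme groups equals ``divergence`` at every
    marker.  Each clone contributes two sampled alleles (the dosage-blind
    information content of a tetraploid AA/AB/BB call).

    Returns (GenotypeMatrix, GroupMap, PanelTruth).
    """
    import pandas as pd

    from .popgen import GenotypeMatrix, GroupMap, MISSING

    if not groups or any(n <= 0 for _, n in groups):
        raise ConfigurationError("groups must be non-empty with positive sizes")
    if not 0.0 <= divergence <= 0.5:
        raise ConfigurationError("divergence must be in [0, 0.5]")
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigurationError("missing_rate must be in [0,1]")

    rng = np.random.default_rng(seed)
    group_names = [g for g, _ in groups]
    markers = [f"snp{i + 1:04d}" for i in range(n_markers)]
    k = len(group_names)
    offsets = (
        np.zeros(1)
        if k == 1
        else np.linspace(-divergence / 2.0, divergence / 2.0, k)
    )
    lo, hi = divergence / 2.0, 1.0 - divergence / 2.0
    centers = rng.uniform(lo, hi, size=n_markers)
    freq = pd.DataFrame(
        {g: np.clip(centers + offsets[j], 0.0, 1.0) for j, g in enumerate(group_names)},
        index=markers,
    )

    clone_ids, clone_group = [], {}
    calls = {}
    for g, n in groups:
        for c in range(n):
            cid = f"{g}_{c + 1:03d}"
            clone_ids.append(cid)
            clone_group[cid] = g
            p = freq[g].to_numpy()
            n_a = rng.binomial(2, p)  # two dosage-blind allele draws
            col = np.where(n_a == 2, "AA", np.where(n_a == 1, "AB", "BB"))
            miss = rng.random(n_markers) < missing_rate
            col = np.where(miss, MISSING, col)
            calls[cid] = col
    matrix = GenotypeMatrix(pd.DataFrame(calls, index=markers))
    group_map = GroupMap(dict(clone_group))
    truth = PanelTruth(frequencies=freq, groups={g: [c for c in clone_ids if clone_group[c] == g] for g in group_names})
    return matrix, group_map, truth
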