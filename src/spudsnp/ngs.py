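"""Consensus SNP calling and the two NGS filter chains.

The caller is an explicit three-genotype maximum-likelihood model over
{hom-ref, het, hom-alt} with a per-base phred error model and a uniform
prior: under genotype G the probability of observing read base b is
(1 - e) if b is one of G's alleles (averaged 50/50 for the het), and
e/3 otherwise, where e is the base's phred error probability.  Allele
dosage in tetraploids is deliberately NOT modelled — heterozygous sites
are called simply as het, matching the dosage-blind AB treatment used
throughout.

Two filter-chain presets reproduce the Maq-style and SAMTools-style parameter sets:

* ``transcript`` mode (Maq-style, reads vs. transcript contigs): depth in
  [20, 225], consensus quality >= 30, adjacent consensus >= 20, max MAPQ
  >= 60, at most 1 other SNP within a centred 100 bp window, >= 50 bp
  from any indel locus.
* ``genome`` mode (Bowtie/SAMTools-style, reads vs. the reference
  genome): depth in [20, 240], consensus quality >= 20, SNP quality
  >= 20, max MAPQ >= 60, the same density and indel rules, plus the
  3'-bias rule: fail when more than 10% of alt-supporting reads carry
  the variant within the terminal 5 aligned bases of their 3' end.

Every call is annotated with ALL violated rules, never just the first,
so n_raw = n_pass + n_fail holds by construction and each decision can
be re-derived from the ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .pileup import PileupColumn, PileupResult

MAX_QUAL = 255.0

HOM_REF, HET, HOM_ALT = "hom_ref", "het", "hom_alt"

# rule names as they appear in ledgers and VCF FILTER columns
MIN_DEPTH = "MIN_DEPTH"
MAX_DEPTH = "MAX_DEPTH"
MIN_CONSENSUS = "MIN_CONSENSUS"
ADJACENT_CONSENSUS = "ADJACENT_CONSENSUS"
MIN_SNP_QUALITY = "MIN_SNP_QUALITY"
MAPPING_QUALITY = "MAPPING_QUALITY"
DENSITY = "DENSITY"
INDEL_DISTANCE = "INDEL_DISTANCE"
THREE_PRIME_BIAS = "THREE_PRIME_BIAS"


@dataclass
class CallerConfig:
    """Thresholds for one filter chain; presets mirror the classic Maq- and SAMTools-style sets."""

    mode: str = "transcript"
    min_depth: int = 20
    max_depth: int = 225
    min_consensus: float = 30.0
    min_adjacent_consensus: float | None = 20.0  # transcript mode only
    min_snp_quality: float | None = None  # genome mode only
    required_mapq: int = 60
    mapq_rule: str = "max"  # "max": max MAPQ >= threshold; "all": every read
    density_window: int = 100  # centred window, bp
    max_other_snps: int = 1
    min_indel_distance: int = 50
    three_prime_max_fraction: float | None = None  # genome mode only
    three_prime_window: int = 5
    three_prime_denominator: str = "alt"  # or "all"

    def __post_init__(self):
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if self.three_prime_max_fraction is not None and not (
            0.0 <= self.three_prime_max_fraction <= 1.0
        ):
            raise ValueError("three_prime_max_fraction must be in [0,1]")

    @classmethod
    def transcript_preset(cls) -> "CallerConfig":
        return cls(mode="transcript")

    @classmethod
    def genome_preset(cls) -> "CallerConfig":
        return cls(
            mode="genome",
            max_depth=240,
            min_consensus=20.0,
            min_adjacent_consensus=None,
            min_snp_quality=20.0,
            three_prime_max_fraction=0.10,
        )

    @classmethod
    def preset(cls, mode: str) -> "CallerConfig":
        if mode == "transcript":
            return cls.transcript_preset()
        if mode == "genome":
            return cls.genome_preset()
        raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SnpCall:
    cultivar: str
    ref_name: str
    pos: int
    ref: str
    alt: str
    genotype: str  # het | hom_alt
    consensus_quality: float
    snp_quality: float
    depth: int
    support: int  # reads carrying the alt allele
    extra_alts: tuple[str, ...] = ()
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    @property
    def alts(self) -> tuple[str, ...]:
        return (self.alt, *self.extra_alts)


def _phred_to_p(q: int) -> float:
    return 10.0 ** (-q / 10.0)


def genotype_log_likelihoods(
    ref: str, alt: str, bases
) -> dict[str, float]:
    """Log-likelihood of each genotype given the column's (base, qual) pairs."""
    ll = {HOM_REF: 0.0, HET: 0.0, HOM_ALT: 0.0}
    for b in bases:
        e = _phred_to_p(b.qual)
        match_p, miss_p = 1.0 - e, e / 3.0
        ll[HOM_REF] += math.log(match_p if b.base == ref else miss_p)
        ll[HOM_ALT] += math.log(match_p if b.base == alt else miss_p)
        if b.base == ref or b.base == alt:
            ll[HET] += math.log(0.5 * match_p + 0.5 * miss_p)
        else:
            ll[HET] += math.log(miss_p)
    return ll


def _posteriors(ll: dict[str, float]) -> dict[str, float]:
    m = max(ll.values())
    w = {g: math.exp(v - m) for g, v in ll.items()}
    z = sum(w.values())
    return {g: v / z for g, v in w.items()}


def _phred_of(p: float) -> float:
    if p <= 0.0:
        return MAX_QUAL
    return min(MAX_QUAL, -10.0 * math.log10(p))


def column_consensus_quality(column: PileupColumn) -> float:
    """Phred confidence in the column's best genotype (any genotype).

    Used by the adjacent-consensus rule, which inspects neighbours that
    typically carry no variant at all.
    """
    if column.depth == 0:
        return 0.0
    counts = column.base_counts()
    alt_counts = {b: c for b, c in counts.items() if b != column.ref_base}
    if alt_counts:
        alt = max(sorted(alt_counts), key=lambda b: alt_counts[b])
    else:
        alt = next(b for b in "ACGT" if b != column.ref_base)
    post = _posteriors(genotype_log_likelihoods(column.ref_base, alt, column.bases))
    best = max(post.values())
    return _phred_of(1.0 - best)


def call_consensus(column: PileupColumn, cultivar: str = "sample") -> SnpCall | None:
    """ML genotype for one column; None when the call is homozygous-reference.

    The alternative allele is the most frequent non-reference base (ties
    broken alphabetically).  Consensus quality is the phred-scaled
    probability that the called genotype is wrong; SNP quality is the
    phred-scaled posterior of hom-ref (confidence the site is variant).
    """
    if column.depth == 0:
        return None
    if column.ref_base not in "ACGT":
        return None
    counts = column.base_counts()
    alt_counts = {b: c for b, c in counts.items() if b != column.ref_base and b in "ACGT"}
    if not alt_counts:
        return None
    alt = max(sorted(alt_counts), key=lambda b: alt_counts[b])
    post = _posteriors(genotype_log_likelihoods(column.ref_base, alt, column.bases))
    genotype = max(post, key=post.get)
    if genotype == HOM_REF:
        return None
    extra = tuple(
        sorted(b for b in alt_counts if b != alt and alt_counts[b] == alt_counts[alt])
    )
    return SnpCall(
        cultivar=cultivar,
        ref_name=column.ref_name,
        pos=column.pos,
        ref=column.ref_base,
        alt=alt,
        genotype=genotype,
        consensus_quality=_phred_of(1.0 - post[genotype]),
        snp_quality=_phred_of(post[HOM_REF]),
        depth=column.depth,
        support=alt_counts[alt],
        extra_alts=extra,
    )


def call_columns(pileups: PileupResult, cultivar: str = "sample") -> list[SnpCall]:
    """Raw consensus calls over every column, sorted by (ref, pos)."""
    calls = []
    for col in pileups.sorted_columns():
        c = call_consensus(col, cultivar=cultivar)
        if c is not None:
            calls.append(c)
    return calls


# ---------------------------------------------------------------------------
# filter rules (each returns True on PASS)


def depth_rules(call: SnpCall, cfg: CallerConfig) -> list[str]:
    v = []
    if call.depth < cfg.min_depth:
        v.append(MIN_DEPTH)
    if call.depth > cfg.max_depth:
        v.append(MAX_DEPTH)
    return v


def density_rule(call: SnpCall, all_calls: list[SnpCall], cfg: CallerConfig) -> bool:
    """Pass iff at most ``max_other_snps`` OTHER raw calls lie within the
    centred ``density_window`` around the call."""
    half = cfg.density_window // 2
    n_other = sum(
        1
        for o in all_calls
        if o is not call
        and o.ref_name == call.ref_name
        and abs(o.pos - call.pos) <= half
    )
    return n_other <= cfg.max_other_snps


def indel_proximity_rule(
    call: SnpCall, pileups: PileupResult, min_distance: int = 50
) -> bool:
    """Pass iff the nearest indel locus is at least ``min_distance`` bp away
    (a distance of exactly 50 passes); no indels on the reference passes."""
    d = pileups.nearest_indel_distance(call.ref_name, call.pos)
    return d is None or d >= min_distance


def mapping_quality_rule(call: SnpCall, column: PileupColumn, cfg: CallerConfig) -> bool:
    mapqs = [b.mapq for b in column.bases]
    if not mapqs:
        return False
    if cfg.mapq_rule == "all":
        return min(mapqs) >= cfg.required_mapq
    return max(mapqs) >= cfg.required_mapq


def adjacent_consensus_rule(
    call: SnpCall, pileups: PileupResult, min_quality: float = 20.0
) -> bool:
    """Pass iff BOTH flanking columns exist and have consensus quality >=
    the threshold; a missing neighbour (contig end) fails — contig-end
    calls are exactly the assembly artifacts the rule targets."""
    for dpos in (-1, 1):
        col = pileups.columns.get((call.ref_name, call.pos + dpos))
        if col is None or column_consensus_quality(col) < min_quality:
            return False
    return True


def three_prime_bias_rule(
    call: SnpCall, column: PileupColumn, cfg: CallerConfig
) -> bool:
    """Pass iff at most ``three_prime_max_fraction`` of the alt-supporting
    reads see the variant within the terminal ``three_prime_window`` aligned
    bases of their 3' end.  With zero relevant reads the rule is vacuous."""
    if cfg.three_prime_denominator == "all":
        denom_bases = column.bases
    else:
        denom_bases = [b for b in column.bases if b.base == call.alt]
    if not denom_bases:
        return True
    in_window = sum(
        1
        for b in denom_bases
        if b.base == call.alt and b.three_prime_dist < cfg.three_prime_window
    )
    return in_window / len(denom_bases) <= cfg.three_prime_max_fraction


@dataclass
class FilterLedger:
    n_raw: int = 0
    n_pass: int = 0
    n_fail: int = 0
    by_rule: dict = field(default_factory=dict)

    def record(self, call: SnpCall) -> None:
        self.n_raw += 1
        if call.passed:
            self.n_pass += 1
        else:
            self.n_fail += 1
            for r in call.violations:
                self.by_rule[r] = self.by_rule.get(r, 0) + 1


def apply_filter_chain(
    calls: list[SnpCall], pileups: PileupResult, cfg: CallerConfig
) -> tuple[list[SnpCall], FilterLedger]:
    """Annotate every raw call with ALL violated rules; return passes + ledger.

    Density and indel rules are evaluated against the RAW call set (as
    Maq's SNPfilter does) before quality rules; since every rule is
    recorded regardless of order, the ledger is order-independent.
    """
    keys = [(c.ref_name, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (reference, position)")
    ledger = FilterLedger()
    for call in calls:
        call.violations = []
        column = pileups.columns[(call.ref_name, call.pos)]
        call.violations.extend(depth_rules(call, cfg))
        if not density_rule(call, calls, cfg):
            call.violations.append(DENSITY)
        if not indel_proximity_rule(call, pileups, cfg.min_indel_distance):
            call.violations.append(INDEL_DISTANCE)
        if call.consensus_quality < cfg.min_consensus:
            call.violations.append(MIN_CONSENSUS)
        if (
            cfg.min_snp_quality is not None
            and call.snp_quality < cfg.min_snp_quality
        ):
            call.violations.append(MIN_SNP_QUALITY)
        if not mapping_quality_rule(call, column, cfg):
            call.violations.append(MAPPING_QUALITY)
        if cfg.min_adjacent_consensus is not None and not adjacent_consensus_rule(
            call, pileups, cfg.min_adjacent_consensus
        ):
            call.violations.append(ADJACENT_CONSENSUS)
        if cfg.three_prime_max_fraction is not None and not three_prime_bias_rule(
            call, column, cfg
        ):
            call.violations.append(THREE_PRIME_BIAS)
        ledger.record(call)
    return [c for c in calls if c.passed], ledger


def calls_to_vcf_records(calls: list[SnpCall]):
    from .io import VcfRecord

    out = []
    for c in calls:
        out.append(
            VcfRecord(
                chrom=c.ref_name,
                pos=c.pos,
                ref=c.ref,
                alts=c.alts,
                qual=round(c.snp_quality, 2),
                filters=tuple(c.violations),
                info={
                    "DP": c.depth,
                    "SUP": c.support,
                    "CQ": round(c.consensus_quality, 2),
                    "SQ": round(c.snp_quality, 2),
                    "GT": c.genotype,
                    "CULTIVAR": c.cultivar,
                },
            )
        )
    return out
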