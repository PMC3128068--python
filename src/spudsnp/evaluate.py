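"""Scoring pipeline output against planted truth.

A planted site can only be recovered if the realized read placement
satisfies the chain's geometric constraints — depth inside the
configured window, no indel locus within 50 bp, at most one other
variant site in the 100 bp density window, flanking columns present for
the adjacent-consensus rule, a uniquely-mapped read at the site, and
(genome mode) at most 10% of the true-allele reads seeing the site
within their 3'-terminal window.  These are properties of where reads
landed, not of base-calling accuracy, so recovery is reported against
the geometrically eligible subset of planted sites; precision counts
every passing call, eligible or not, as false unless it was planted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ngs import CallerConfig, SnpCall
from .pileup import PileupResult
from .synthetic import CultivarTruth


@dataclass
class RecoveryMetrics:
    n_truth: int
    n_eligible: int
    n_recovered: int  # eligible sites with a correct passing call
    n_called_pass: int  # all passing calls
    n_true_pass: int  # passing calls at planted sites with a true alt allele

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.n_true_pass / self.n_called_pass if self.n_called_pass else float("nan")
        )


def eligible_truth_sites(
    truth: CultivarTruth, pileups: PileupResult, cfg: CallerConfig
) -> set[tuple[str, int]]:
    """Planted biallelic sites whose realized read geometry admits a pass.

    ``truth`` must be expressed in the calling coordinate space
    (transcript contigs for transcript mode, genome for genome mode).
    """
    half = cfg.density_window // 2
    sites = truth.sites
    eligible = set()
    for s in sites:
        if len(s.alleles) != 2:
            continue
        key = (s.chrom, s.pos)
        col = pileups.columns.get(key)
        if col is None or not (cfg.min_depth <= col.depth <= cfg.max_depth):
            continue
        n_other = sum(
            1
            for o in sites
            if o is not s and o.chrom == s.chrom and abs(o.pos - s.pos) <= half
        )
        if n_other > cfg.max_other_snps:
            continue
        d = pileups.nearest_indel_distance(s.chrom, s.pos)
        if d is not None and d < cfg.min_indel_distance:
            continue
        if max(b.mapq for b in col.bases) < cfg.required_mapq:
            continue
        if cfg.min_adjacent_consensus is not None:
            if (s.chrom, s.pos - 1) not in pileups.columns:
                continue
            if (s.chrom, s.pos + 1) not in pileups.columns:
                continue
        if cfg.three_prime_max_fraction is not None:
            true_alts = set(s.alts)
            alt_bases = [b for b in col.bases if b.base in true_alts]
            if not alt_bases:
                continue
            frac = sum(
                1 for b in alt_bases if b.three_prime_dist < cfg.three_prime_window
            ) / len(alt_bases)
            if frac > cfg.three_prime_max_fraction:
                continue
        eligible.add(key)
    return eligible


def recovery_metrics(
    truth: CultivarTruth,
    passed_calls: list[SnpCall],
    pileups: PileupResult,
    cfg: CallerConfig,
) -> RecoveryMetrics:
    """Precision/recall of a filtered call set against planted truth."""
    eligible = eligible_truth_sites(truth, pileups, cfg)
    by_pos = truth.truth_by_position()
    n_true_pass = 0
    recovered = set()
    for c in passed_calls:
        key = (c.ref_name, c.pos)
        site = by_pos.get(key)
        if site is not None and c.alt in site.alts:
            n_true_pass += 1
            if key in eligible:
                recovered.add(key)
    return RecoveryMetrics(
        n_truth=len(by_pos),
        n_eligible=len(eligible),
        n_recovered=len(recovered),
        n_called_pass=len(passed_calls),
        n_true_pass=n_true_pass,
    )
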