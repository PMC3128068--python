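"""Depth-based SNP calling for low-coverage Sanger EST contig alignments.

Sanger trace qualities are not modelled: a site is called when overall
read depth reaches 10 and at least 4 reads agree on a single alternative
base.  Post-filters remove calls within 50 bp of an intron boundary and
calls with more than one additional call in the surrounding 100 bp
window.  When two alternative bases each reach the support threshold the
site is flagged non-biallelic-within-cultivar and carried with both
alleles for the downstream biallelic gate to adjudicate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ngs import DENSITY, FilterLedger, SnpCall
from .pileup import PileupResult

INTRON_DISTANCE = "INTRON_DISTANCE"


@dataclass
class SangerConfig:
    min_depth: int = 10
    min_support: int = 4
    min_intron_distance: int = 50
    density_window: int = 100
    max_other_snps: int = 1

    def __post_init__(self):
        if self.min_support > self.min_depth:
            raise ValueError("min_support must be <= min_depth")


def call_sanger_snps(
    pileups: PileupResult, cfg: SangerConfig | None = None, cultivar: str = "sample"
) -> list[SnpCall]:
    """Emit a call iff depth >= min_depth and the most frequent non-reference
    base is supported by >= min_support reads."""
    cfg = cfg or SangerConfig()
    calls = []
    for col in pileups.sorted_columns():
        if col.depth < cfg.min_depth:
            continue
        counts = {
            b: c for b, c in col.base_counts().items() if b != col.ref_base and b in "ACGT"
        }
        if not counts:
            continue
        top = max(counts.values())
        if top < cfg.min_support:
            continue
        tied = sorted(b for b, c in counts.items() if c == top)
        alt, extra = tied[0], tuple(tied[1:])
        calls.append(
            SnpCall(
                cultivar=cultivar,
                ref_name=col.ref_name,
                pos=col.pos,
                ref=col.ref_base,
                alt=alt,
                genotype="het",
                consensus_quality=0.0,
                snp_quality=0.0,
                depth=col.depth,
                support=top,
                extra_alts=extra,
            )
        )
    return calls


def intron_distance_rule(
    call: SnpCall, exon_blocks_by_ref: dict, min_distance: int = 50
) -> bool:
    """Pass iff the call is >= min_distance bp (in transcript coordinates)
    from every internal exon junction of its contig; 50 exactly passes."""
    blocks = exon_blocks_by_ref.get(call.ref_name)
    if not blocks or len(blocks) < 2:
        return True
    best = None
    for t_start, t_end, _, _ in blocks[:-1]:
        # junction lies between t_end and t_end + 1 on the transcript
        d = (t_end - call.pos) if call.pos <= t_end else (call.pos - (t_end + 1))
        d = abs(d)
        best = d if best is None else min(best, d)
    return best >= min_distance


def sanger_post_filters(
    calls: list[SnpCall],
    exon_blocks_by_ref: dict | None = None,
    cfg: SangerConfig | None = None,
) -> tuple[list[SnpCall], FilterLedger]:
    """Annotate intron-proximity and density violations; ledger as in the
    NGS chain (n_raw = n_pass + n_fail)."""
    cfg = cfg or SangerConfig()
    half = cfg.density_window // 2
    ledger = FilterLedger()
    for call in calls:
        call.violations = []
        if exon_blocks_by_ref is not None and not intron_distance_rule(
            call, exon_blocks_by_ref, cfg.min_intron_distance
        ):
            call.violations.append(INTRON_DISTANCE)
        n_other = sum(
            1
            for o in calls
            if o is not call
            and o.ref_name == call.ref_name
            and abs(o.pos - call.pos) <= half
        )
        if n_other > cfg.max_other_snps:
            call.violations.append(DENSITY)
        ledger.record(call)
    return [c for c in calls if c.passed], ledger
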