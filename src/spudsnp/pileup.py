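"""Pileup construction from SAM alignments.

Converts read alignments into per-position columns carrying the aligned
base, base quality, mapping quality and — crucially for the 3'-bias
filter — each base's distance from its read's aligned 3' end.  For a
reverse-strand read the 3' end is the leftmost aligned base.

Coordinates are 1-based and closed throughout (VCF/GFF3 convention);
SAM's 0-based arithmetic is converted at this boundary.  Only aligned
(M) bases count toward depth; deletion-spanning reads contribute their
deleted reference positions to the indel-locus index instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)


class SamParseError(ValueError):
    pass


@dataclass(frozen=True)
class PiledBase:
    base: str
    qual: int  # phred base quality
    mapq: int  # read mapping quality
    three_prime_dist: int  # aligned bases between this base and the read 3' end
    read_id: str


@dataclass
class PileupColumn:
    ref_name: str
    pos: int  # 1-based
    ref_base: str
    bases: list[PiledBase] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.bases)

    def base_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.bases:
            counts[b.base] = counts.get(b.base, 0) + 1
        return counts

    def alt_bases(self) -> list[PiledBase]:
        return [b for b in self.bases if b.base != self.ref_base]


@dataclass
class PileupResult:
    """All columns of one alignment set plus the indel-locus index."""

    columns: dict[tuple[str, int], PileupColumn]
    indel_index: dict[str, list[int]]  # ref -> sorted indel reference positions
    n_reads_used: int = 0
    n_reads_excluded: int = 0

    def sorted_columns(self) -> list[PileupColumn]:
        return [self.columns[k] for k in sorted(self.columns)]

    def nearest_indel_distance(self, ref_name: str, pos: int) -> int | None:
        """bp to the nearest indel locus on this reference, or None."""
        import bisect

        loci = self.indel_index.get(ref_name)
        if not loci:
            return None
        i = bisect.bisect_left(loci, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(loci):
                d = abs(loci[j] - pos)
                best = d if best is None else min(best, d)
        return best


def read_alignments(sam_path):
    """Yield mapped pysam records from a plain-text SAM file.

    Unmapped records are skipped (with a logged count); malformed records
    raise :class:`SamParseError` naming the offending record index.
    """
    n_unmapped = 0
    idx = 0
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
            for rec in fh:
                idx += 1
                if rec.is_unmapped:
                    n_unmapped += 1
                    continue
                yield rec
    except (ValueError, OSError) as exc:
        raise SamParseError(
            f"malformed SAM in {sam_path} at record {idx + 1}: {exc}"
        ) from exc
    if n_unmapped:
        logger.info("skipped %d unmapped records in %s", n_unmapped, sam_path)


def build_pileups(alignments, references, unique_only: bool = True) -> PileupResult:
    """Accumulate pileup columns from an alignment stream.

    ``references`` maps reference name -> sequence (dict or pyfaidx.Fasta).
    With ``unique_only`` set, reads with mapping quality 0 or the SAM
    secondary-alignment flag are excluded before pileup — the operational
    reading of "mapped uniquely".
    """
    columns: dict[tuple[str, int], PileupColumn] = {}
    indels: dict[str, set[int]] = {}
    n_used = n_excl = 0

    def ref_base(name: str, pos1: int) -> str:
        seq = references[name]
        return str(seq[pos1 - 1 : pos1]).upper()

    for rec in alignments:
        if unique_only and (rec.mapping_quality == 0 or rec.is_secondary):
            n_excl += 1
            continue
        name = rec.reference_name
        if name not in references:
            raise KeyError(f"alignment target {name!r} missing from references")
        n_used += 1
        seq = rec.query_sequence
        quals = rec.query_qualities
        pairs = rec.get_aligned_pairs(matches_only=False)
        matched = [(q, r) for q, r in pairs if q is not None and r is not None]
        n = len(matched)
        last_r = None
        for q, r in pairs:
            if q is not None and r is not None:
                last_r = r
            elif q is None and r is not None:  # deletion from the read
                indels.setdefault(name, set()).add(r + 1)
            elif q is not None and r is None:  # insertion in the read
                anchor = (last_r + 1) if last_r is not None else rec.reference_start
                indels.setdefault(name, set()).add(anchor + 1)
        for i, (q, r) in enumerate(matched):
            dist = i if rec.is_reverse else n - 1 - i
            pos1 = r + 1
            key = (name, pos1)
            col = columns.get(key)
            if col is None:
                col = columns[key] = PileupColumn(name, pos1, ref_base(name, pos1))
            col.bases.append(
                PiledBase(
                    base=seq[q].upper(),
                    qual=int(quals[q]) if quals is not None else 30,
                    mapq=rec.mapping_quality,
                    three_prime_dist=dist,
                    read_id=rec.query_name,
                )
            )
    if n_excl:
        logger.info("excluded %d non-unique alignments", n_excl)
    return PileupResult(
        columns=columns,
        indel_index={k: sorted(v) for k, v in indels.items()},
        n_reads_used=n_used,
        n_reads_excluded=n_excl,
    )


def pileup_sam(sam_path, fasta_path, unique_only: bool = True) -> PileupResult:
    """Convenience: SAM + FASTA paths -> PileupResult."""
    refs = Fasta(str(fasta_path))
    return build_pileups(read_alignments(sam_path), refs, unique_only=unique_only)
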