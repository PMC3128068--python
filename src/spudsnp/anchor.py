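"""Anchoring transcript-space SNPs on the genome and building the
high-confidence catalog.

Transcript contigs reach the genome via exon-block alignments (a spliced
aligner's output, consumed as GFF3).  SNPs ride along by exact block
arithmetic, then pass through the gate sequence:

* exon-identity gate — the whole transcript is dropped unless its
  placement is strictly above 95% identity with no gaps;
* boundary gate — SNPs within 50 bp (transcript coordinates) of an
  internal exon-exon junction are discarded (50 exactly keeps; alignment
  termini are not junctions);
* redundancy collapse — calls from different cultivars landing on the
  same genome position merge into one catalog record with unioned
  alleles and concatenated provenance;
* biallelic gate — only positions with exactly two distinct alleles
  across all cultivars (reference included) are retained.

The catalog then feeds assay-candidate export (flanking sequence
extraction with local design checks) and the cultivar sharing /
restriction tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# drop reasons
NO_ALIGNMENT = "NO_ALIGNMENT"
LOW_IDENTITY = "LOW_IDENTITY"
GAPPED = "GAPPED"
UNPROJECTED = "UNPROJECTED"
NEAR_BOUNDARY = "NEAR_BOUNDARY"
NON_BIALLELIC = "NON_BIALLELIC"
REF_CONFLICT = "REF_CONFLICT"
SHORT_FLANK = "SHORT_FLANK"
POLYMORPHIC_FLANK = "POLYMORPHIC_FLANK"


class AlignmentValidationError(ValueError):
    pass


@dataclass
class ExonAlignmentSet:
    """One transcript's placement on the genome as ordered exon blocks.

    Blocks are (t_start, t_end, g_start, g_end), 1-based closed, in
    ascending transcript order; paired intervals have equal length.  For
    a minus-strand placement genome intervals descend as transcript
    intervals ascend.
    """

    transcript_id: str
    genome_target: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    identity: float = 100.0
    has_gaps: bool = False

    def validate(self) -> None:
        if self.strand not in "+-":
            raise AlignmentValidationError(
                f"{self.transcript_id}: bad strand {self.strand!r}"
            )
        if not self.blocks:
            raise AlignmentValidationError(f"{self.transcript_id}: no blocks")
        prev_end = 0
        for t_start, t_end, g_start, g_end in self.blocks:
            if t_end - t_start != abs(g_end - g_start):
                raise AlignmentValidationError(
                    f"{self.transcript_id}: unequal paired block lengths"
                )
            if t_start <= prev_end:
                raise AlignmentValidationError(
                    f"{self.transcript_id}: transcript blocks overlap or unordered"
                )
            prev_end = t_end
        g_spans = sorted((min(g[2], g[3]), max(g[2], g[3])) for g in self.blocks)
        for (s1, e1), (s2, e2) in zip(g_spans, g_spans[1:]):
            if s2 <= e1:
                raise AlignmentValidationError(
                    f"{self.transcript_id}: genome blocks overlap"
                )

    def project_to_genome(self, tpos: int) -> int | None:
        """Transcript position -> genome position; None outside blocks."""
        for t_start, t_end, g_start, g_end in self.blocks:
            if t_start <= tpos <= t_end:
                off = tpos - t_start
                return g_start + off if self.strand == "+" else g_start - off
        return None

    def project_to_transcript(self, gpos: int) -> int | None:
        for t_start, t_end, g_start, g_end in self.blocks:
            lo, hi = min(g_start, g_end), max(g_start, g_end)
            if lo <= gpos <= hi:
                off = gpos - g_start if self.strand == "+" else g_start - gpos
                return t_start + off
        return None

    def junction_distance(self, tpos: int) -> int | None:
        """Transcript-bp distance to the nearest internal junction, or
        None for single-block alignments (no junctions)."""
        if len(self.blocks) < 2:
            return None
        best = None
        for t_start, t_end, _, _ in self.blocks[:-1]:
            d = (t_end - tpos) if tpos <= t_end else (tpos - (t_end + 1))
            d = abs(d)
            best = d if best is None else min(best, d)
        return best


def load_exon_alignments(gff3_path) -> list[ExonAlignmentSet]:
    """Parse exon-block features (Target/Identity/Gaps attributes) into
    validated alignment sets, one per transcript."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_tr: dict[str, ExonAlignmentSet] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype != "exon_block":
            continue
        target = feat.attributes.get("Target", [None])[0]
        if target is None:
            raise AlignmentValidationError(f"exon_block without Target at {feat.start}")
        tr_id, t_start, t_end = target.split()[:3]
        identity = float(feat.attributes.get("Identity", ["100.0"])[0])
        gaps = int(feat.attributes.get("Gaps", ["0"])[0]) > 0
        t_start, t_end = int(t_start), int(t_end)
        if feat.strand == "+":
            g_start, g_end = feat.start, feat.end
        else:
            g_start, g_end = feat.end, feat.start
        aln = by_tr.get(tr_id)
        if aln is None:
            aln = by_tr[tr_id] = ExonAlignmentSet(
                tr_id, feat.seqid, feat.strand, [], identity, gaps
            )
        aln.has_gaps = aln.has_gaps or gaps
        aln.blocks.append((t_start, t_end, g_start, g_end))
    out = []
    for aln in by_tr.values():
        aln.blocks.sort(key=lambda b: b[0])
        aln.validate()
        out.append(aln)
    return out


def exon_identity_gate(
    aln: ExonAlignmentSet, min_identity: float = 95.0, forbid_gaps: bool = True
) -> bool:
    """Keep iff identity is STRICTLY above the threshold (95.0 drops) and,
    when gaps are forbidden, the placement is gap-free."""
    if aln.identity <= min_identity:
        return False
    if forbid_gaps and aln.has_gaps:
        return False
    return True


def boundary_distance_gate(
    tpos: int, aln: ExonAlignmentSet, min_distance: int = 50
) -> bool:
    """Keep iff >= min_distance bp from the nearest internal junction
    (exactly 50 keeps); single-exon interiors always keep."""
    d = aln.junction_distance(tpos)
    return d is None or d >= min_distance


def select_best_placements(
    alignments: list[ExonAlignmentSet],
) -> dict[str, ExonAlignmentSet]:
    """One placement per transcript: best identity wins; exact ties drop
    the transcript (mirrors the read-level uniqueness rule)."""
    by_tr: dict[str, list[ExonAlignmentSet]] = {}
    for a in alignments:
        by_tr.setdefault(a.transcript_id, []).append(a)
    best: dict[str, ExonAlignmentSet] = {}
    for tr, alns in by_tr.items():
        alns.sort(key=lambda a: -a.identity)
        if len(alns) > 1 and alns[0].identity == alns[1].identity:
            continue
        best[tr] = alns[0]
    return best


# ---------------------------------------------------------------------------
# catalog


@dataclass
class AnchoredSnp:
    """A genome-anchored SNP with per-cultivar allele provenance."""

    target: str
    pos: int
    ref: str
    alleles_by_cultivar: dict[str, set] = field(default_factory=dict)
    transcripts: list[tuple[str, int]] = field(default_factory=list)
    flags: set = field(default_factory=set)

    @property
    def alleles(self) -> set:
        out = {self.ref}
        for s in self.alleles_by_cultivar.values():
            out |= s
        return out

    @property
    def cultivars(self) -> set:
        return set(self.alleles_by_cultivar)

    @property
    def biallelic(self) -> bool:
        return len(self.alleles) == 2


@dataclass
class AnchorLedger:
    n_input: int = 0
    n_anchored: int = 0
    drops: dict = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.n_input += 1
        self.drops[reason] = self.drops.get(reason, 0) + 1

    def keep(self) -> None:
        self.n_input += 1
        self.n_anchored += 1

    @property
    def conserved(self) -> bool:
        return self.n_input == self.n_anchored + sum(self.drops.values())


_COMP = str.maketrans("ACGT", "TGCA")


def anchor_calls(
    calls,
    alignments: list[ExonAlignmentSet],
    min_identity: float = 95.0,
    min_boundary_distance: int = 50,
) -> tuple[list[AnchoredSnp], AnchorLedger]:
    """Project transcript-space SnpCalls onto the genome through the gate
    sequence; one AnchoredSnp per surviving call (not yet collapsed)."""
    placements = select_best_placements(alignments)
    ledger = AnchorLedger()
    anchored: list[AnchoredSnp] = []
    for call in calls:
        aln = placements.get(call.ref_name)
        if aln is None:
            ledger.drop(NO_ALIGNMENT)
            continue
        if aln.identity <= min_identity:
            ledger.drop(LOW_IDENTITY)
            continue
        if aln.has_gaps:
            ledger.drop(GAPPED)
            continue
        gpos = aln.project_to_genome(call.pos)
        if gpos is None:
            ledger.drop(UNPROJECTED)
            continue
        if not boundary_distance_gate(call.pos, aln, min_boundary_distance):
            ledger.drop(NEAR_BOUNDARY)
            continue
        if aln.strand == "-":
            ref = call.ref.translate(_COMP)
            alleles = {a.translate(_COMP) for a in call.alts} | {ref}
        else:
            ref = call.ref
            alleles = set(call.alts) | {ref}
        ledger.keep()
        anchored.append(
            AnchoredSnp(
                target=aln.genome_target,
                pos=gpos,
                ref=ref,
                alleles_by_cultivar={call.cultivar: alleles},
                transcripts=[(call.ref_name, call.pos)],
            )
        )
    return anchored, ledger


@dataclass
class AnchoredSnpCatalog:
    entries: dict[tuple[str, int], AnchoredSnp] = field(default_factory=dict)
    n_ref_conflicts: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def sorted_entries(self) -> list[AnchoredSnp]:
        return [self.entries[k] for k in sorted(self.entries)]

    def provenance(self) -> dict[str, set]:
        """cultivar -> set of (target, pos) catalog keys it contributed to."""
        out: dict[str, set] = {}
        for key, e in self.entries.items():
            for c in e.cultivars:
                out.setdefault(c, set()).add(key)
        return out


def collapse_redundant(anchored: list[AnchoredSnp]) -> AnchoredSnpCatalog:
    """Merge anchored SNPs at identical (target, position); allele sets
    union, provenance concatenates.  Conflicting reference alleles at one
    position exclude that position (flagged and counted)."""
    catalog = AnchoredSnpCatalog()
    conflicts = set()
    for snp in anchored:
        key = (snp.target, snp.pos)
        cur = catalog.entries.get(key)
        if cur is None:
            catalog.entries[key] = AnchoredSnp(
                target=snp.target,
                pos=snp.pos,
                ref=snp.ref,
                alleles_by_cultivar={c: set(a) for c, a in snp.alleles_by_cultivar.items()},
                transcripts=list(snp.transcripts),
            )
            continue
        if cur.ref != snp.ref:
            conflicts.add(key)
            continue
        for c, alleles in snp.alleles_by_cultivar.items():
            cur.alleles_by_cultivar.setdefault(c, set()).update(alleles)
        cur.transcripts.extend(snp.transcripts)
    for key in conflicts:
        del catalog.entries[key]
    catalog.n_ref_conflicts = len(conflicts)
    for e in catalog.entries.values():
        if not e.biallelic:
            e.flags.add(NON_BIALLELIC)
    return catalog


def biallelic_gate(catalog: AnchoredSnpCatalog) -> AnchoredSnpCatalog:
    """Retain only positions with exactly 2 distinct alleles observed
    across all cultivars (reference included)."""
    kept = AnchoredSnpCatalog(n_ref_conflicts=catalog.n_ref_conflicts)
    kept.entries = {
        k: e for k, e in catalog.entries.items() if len(e.alleles) == 2
    }
    return kept


# ---------------------------------------------------------------------------
# assay-candidate export


@dataclass
class DesignCandidate:
    target: str
    pos: int
    design: str | None  # "LEFT[X/Y]RIGHT" or None when rejected
    rejection: str | None = None


def extract_flanks(
    catalog: AnchoredSnpCatalog, genome_sequences, flank: int = 60
) -> list[DesignCandidate]:
    """Assay design strings with local design-constraint checks.

    Rejects entries whose flanks run off the sequence (SHORT_FLANK) or
    contain another catalog SNP (POLYMORPHIC_FLANK).  Flanks are reported
    on the genome plus strand.
    """
    keys = set(catalog.entries)
    out = []
    for e in catalog.sorted_entries():
        seq = str(genome_sequences[e.target])
        if e.pos - flank < 1 or e.pos + flank > len(seq):
            out.append(DesignCandidate(e.target, e.pos, None, SHORT_FLANK))
            continue
        near = [
            p
            for p in range(e.pos - flank, e.pos + flank + 1)
            if p != e.pos and (e.target, p) in keys
        ]
        if near:
            out.append(DesignCandidate(e.target, e.pos, None, POLYMORPHIC_FLANK))
            continue
        left = seq[e.pos - 1 - flank : e.pos - 1]
        right = seq[e.pos : e.pos + flank]
        pair = sorted(e.alleles)
        out.append(
            DesignCandidate(
                e.target, e.pos, f"{left}[{pair[0]}/{pair[1]}]{right}", None
            )
        )
    return out


def write_design_tsv(path, candidates: list[DesignCandidate], flank: int = 60) -> None:
    from .io import provenance_lines

    with open(path, "w") as fh:
        for line in provenance_lines(comment_char="#"):
            fh.write(line + "\n")
        fh.write(f"#flank_length={flank}\n")
        fh.write("#design_checks=SHORT_FLANK,POLYMORPHIC_FLANK (local rules)\n")
        fh.write("id\tdesign\trejection\n")
        for c in candidates:
            fh.write(
                f"{c.target}:{c.pos}\t{c.design or '.'}\t{c.rejection or '.'}\n"
            )


# ---------------------------------------------------------------------------
# sharing / restriction tabulation


@dataclass
class SharingReport:
    per_cultivar: "object"  # DataFrame: total, restricted
    pairwise: "object"  # DataFrame: cultivar1, cultivar2, shared, pair_restricted
    per_group: "object" | None  # DataFrame: group, common, group_restricted


def tabulate_sharing(
    catalog: AnchoredSnpCatalog,
    cultivars: list[str] | None = None,
    groups: dict[str, list[str]] | None = None,
) -> SharingReport:
    """Set-algebra tabulation of SNP sharing across cultivars.

    * total — positions the cultivar contributed to;
    * restricted — positions found in that cultivar only;
    * pairwise shared — positions in both members of a pair;
    * pair/group restricted — positions in every member of the pair/group
      and in no other cultivar.
    """
    import itertools

    import pandas as pd

    prov = catalog.provenance()
    if cultivars is None:
        cultivars = sorted(prov)
    for c in cultivars:
        prov.setdefault(c, set())
    if groups:
        for g, members in groups.items():
            unknown = set(members) - set(cultivars)
            if unknown:
                raise ValueError(f"group {g!r} names unknown cultivars: {unknown}")

    others_cache = {
        c: set().union(*(prov[o] for o in cultivars if o != c)) if len(cultivars) > 1 else set()
        for c in cultivars
    }
    per_cultivar = pd.DataFrame(
        {
            "total": [len(prov[c]) for c in cultivars],
            "restricted": [len(prov[c] - others_cache[c]) for c in cultivars],
        },
        index=pd.Index(cultivars, name="cultivar"),
    )

    rows = []
    for c1, c2 in itertools.combinations(cultivars, 2):
        shared = prov[c1] & prov[c2]
        rest = set(cultivars) - {c1, c2}
        outside = set().union(*(prov[o] for o in rest)) if rest else set()
        rows.append(
            {
                "cultivar1": c1,
                "cultivar2": c2,
                "shared": len(shared),
                "pair_restricted": len(shared - outside),
            }
        )
    pairwise = pd.DataFrame(rows)

    per_group = None
    if groups:
        grows = []
        for g, members in groups.items():
            if not members:
                continue
            common = set.intersection(*(prov[m] for m in members))
            rest = set(cultivars) - set(members)
            outside = set().union(*(prov[o] for o in rest)) if rest else set()
            grows.append(
                {
                    "group": g,
                    "common": len(common),
                    "group_restricted": len(common - outside),
                }
            )
        per_group = pd.DataFrame(grows)
    return SharingReport(per_cultivar, pairwise, per_group)


def catalog_to_vcf_records(catalog: AnchoredSnpCatalog):
    from .io import VcfRecord

    out = []
    for e in catalog.sorted_entries():
        alts = tuple(sorted(e.alleles - {e.ref}))
        out.append(
            VcfRecord(
                chrom=e.target,
                pos=e.pos,
                ref=e.ref,
                alts=alts,
                filters=tuple(sorted(e.flags)),
                info={
                    "CULTIVARS": ",".join(sorted(e.cultivars)),
                    "TRANSCRIPTS": ",".join(f"{t}:{p}" for t, p in e.transcripts),
                },
            )
        )
    return out
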