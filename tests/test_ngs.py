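"""Consensus caller against an exhaustive likelihood oracle, boundary
behaviour of every filter rule, and ledger conservation / equivalence
against a straight-line re-evaluation on randomized columns."""

import math
import random

import pytest

from conftest import make_column, make_result
from spudsnp.ngs import (
    ADJACENT_CONSENSUS,
    DENSITY,
    INDEL_DISTANCE,
    MAPPING_QUALITY,
    MAX_DEPTH,
    MIN_CONSENSUS,
    MIN_DEPTH,
    MIN_SNP_QUALITY,
    THREE_PRIME_BIAS,
    CallerConfig,
    adjacent_consensus_rule,
    apply_filter_chain,
    call_columns,
    call_consensus,
    column_consensus_quality,
    indel_proximity_rule,
    three_prime_bias_rule,
)


def oracle_genotype(ref, alt, bases):
    """Direct product of per-read error terms over the 3 genotypes."""
    likes = {}
    for g, alleles in (("hom_ref", (ref,)), ("het", (ref, alt)), ("hom_alt", (alt,))):
        prod = 1.0
        for b in bases:
            e = 10 ** (-b.qual / 10)
            p = 0.0
            for a in alleles:
                p += (1 / len(alleles)) * ((1 - e) if b.base == a else e / 3)
            prod *= p
        likes[g] = prod
    z = sum(likes.values())
    post = {g: v / z for g, v in likes.items()}
    return max(post, key=post.get), post


class TestCallConsensus:
    def test_all_ref_returns_none(self):
        assert call_consensus(make_column("A", "A" * 30)) is None

    def test_balanced_het_matches_oracle(self):
        col = make_column("A", "A" * 15 + "G" * 15)
        call = call_consensus(col)
        g, post = oracle_genotype("A", "G", col.bases)
        assert g == "het"
        assert call.genotype == "het"
        assert call.alt == "G" and call.support == 15
        err = 1.0 - post["het"]
        expected_cq = 255.0 if err <= 0 else min(255.0, -10 * math.log10(err))
        assert call.consensus_quality == pytest.approx(expected_cq, abs=1e-6)

    def test_all_alt_is_hom_alt_with_high_snp_quality(self):
        col = make_column("A", "G" * 30)
        call = call_consensus(col)
        g, post = oracle_genotype("A", "G", col.bases)
        assert g == "hom_alt" and call.genotype == "hom_alt"
        assert call.snp_quality > 20

    def test_random_columns_match_oracle(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(5, 40)
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            n_alt = rng.randint(1, n)
            quals = [rng.randint(10, 40) for _ in range(n)]
            col = make_column(ref, alt * n_alt + ref * (n - n_alt), quals=quals)
            call = call_consensus(col)
            g, post = oracle_genotype(ref, alt, col.bases)
            if g == "hom_ref":
                assert call is None
            else:
                assert call.genotype == g
                expected_sq = (
                    min(255.0, -10 * math.log10(post["hom_ref"]))
                    if post["hom_ref"] > 0
                    else 255.0
                )
                assert call.snp_quality == pytest.approx(expected_sq, abs=1e-4)

    def test_single_error_read_stays_hom_ref(self):
        # one Q30 mismatch in 30 reads is best explained as an error
        assert call_consensus(make_column("A", "A" * 29 + "G")) is None

    def test_non_acgt_reference_skipped(self):
        assert call_consensus(make_column("N", "A" * 20)) is None


def chain_fixture(depths, cfg, positions=None, ref="contig1"):
    """Columns at given positions (default spaced 200 bp) with het signal."""
    positions = positions or [200 * (i + 1) for i in range(len(depths))]
    cols = []
    for pos, d in zip(positions, depths):
        half = d // 2
        cols.append(
            make_column("A", "A" * (d - half) + "G" * half, pos=pos, ref_name=ref)
        )
    res = make_result(cols)
    calls = call_columns(res)
    return calls, res


class TestFilterBoundaries:
    @pytest.mark.parametrize(
        "depth,rule,violated",
        [
            (19, MIN_DEPTH, True),
            (20, MIN_DEPTH, False),
            (225, MAX_DEPTH, False),
            (226, MAX_DEPTH, True),
        ],
    )
    def test_transcript_depth_boundaries(self, depth, rule, violated):
        calls, res = chain_fixture([depth], CallerConfig.transcript_preset())
        _, _ = apply_filter_chain(calls, res, CallerConfig.transcript_preset())
        assert (rule in calls[0].violations) == violated

    def test_genome_mode_max_depth_240(self):
        cfg = CallerConfig.genome_preset()
        calls, res = chain_fixture([240], cfg)
        apply_filter_chain(calls, res, cfg)
        assert MAX_DEPTH not in calls[0].violations
        calls, res = chain_fixture([241], cfg)
        apply_filter_chain(calls, res, cfg)
        assert MAX_DEPTH in calls[0].violations

    def test_density_window_counts_other_calls(self):
        cfg = CallerConfig.transcript_preset()
        calls, res = chain_fixture([40, 40, 40], cfg, positions=[100, 130, 160])
        apply_filter_chain(calls, res, cfg)
        by_pos = {c.pos: c for c in calls}
        assert DENSITY in by_pos[130].violations  # 2 others within +/-50
        assert DENSITY not in by_pos[100].violations  # only 130 within +/-50
        assert DENSITY not in by_pos[160].violations

    @pytest.mark.parametrize("dist,violated", [(49, True), (50, False)])
    def test_indel_distance_boundary(self, dist, violated):
        calls, res = chain_fixture([40], CallerConfig.transcript_preset())
        res.indel_index = {"contig1": [calls[0].pos + dist]}
        assert indel_proximity_rule(calls[0], res, 50) == (not violated)

    def test_no_indels_passes(self):
        calls, res = chain_fixture([40], CallerConfig.transcript_preset())
        assert indel_proximity_rule(calls[0], res, 50)

    def test_mapping_quality_max_interpretation(self):
        cfg = CallerConfig.transcript_preset()
        col = make_column("A", "A" * 20 + "G" * 20, mapq=[59] * 40, pos=200)
        res = make_result([col])
        calls = call_columns(res)
        apply_filter_chain(calls, res, cfg)
        assert MAPPING_QUALITY in calls[0].violations
        # one read at 60 satisfies the max-MAPQ reading
        col2 = make_column("A", "A" * 20 + "G" * 20, mapq=[59] * 39 + [60], pos=200)
        res2 = make_result([col2])
        calls2 = call_columns(res2)
        apply_filter_chain(calls2, res2, cfg)
        assert MAPPING_QUALITY not in calls2[0].violations

    def test_adjacent_consensus_neighbors(self):
        center = make_column("A", "A" * 20 + "G" * 20, pos=200)
        good = make_column("C", "C" * 30, pos=199)
        good2 = make_column("T", "T" * 30, pos=201)
        res = make_result([good, center, good2])
        calls = call_columns(res)
        assert adjacent_consensus_rule(calls[0], res, 20.0)
        # a noisy neighbour (half/half at low qual) has low consensus quality
        noisy = make_column("C", "CG" * 2, quals=5, pos=199)
        assert column_consensus_quality(noisy) < 20
        res2 = make_result([noisy, center, good2])
        calls2 = call_columns(res2)
        calls2 = [c for c in calls2 if c.pos == 200]
        assert not adjacent_consensus_rule(calls2[0], res2, 20.0)

    def test_missing_neighbor_fails_adjacent_rule(self):
        center = make_column("A", "A" * 20 + "G" * 20, pos=1)
        right = make_column("C", "C" * 30, pos=2)
        res = make_result([center, right])
        calls = call_columns(res)
        assert not adjacent_consensus_rule(calls[0], res, 20.0)

    @pytest.mark.parametrize("n_window,violated", [(3, True), (1, False)])
    def test_three_prime_bias_fraction(self, n_window, violated):
        # 20 alt reads, n_window of them with the variant in the 3' terminal 5 bases
        cfg = CallerConfig.genome_preset()
        dists = [2] * n_window + [20] * (20 - n_window) + [20] * 20
        col = make_column("A", "G" * 20 + "A" * 20, three_prime_dists=dists, pos=200)
        res = make_result([col])
        calls = call_columns(res)
        assert three_prime_bias_rule(calls[0], col, cfg) == (not violated)

    def test_three_prime_rule_vacuous_without_alt_reads(self):
        cfg = CallerConfig.genome_preset()
        col = make_column("A", "A" * 20, pos=200)
        call_like = call_columns(make_result([make_column("A", "A" * 10 + "G" * 10, pos=200)]))[0]
        assert three_prime_bias_rule(call_like, col, cfg)


class TestLedger:
    def test_conservation_and_straight_line_oracle(self):
        """n_raw = n_pass + n_fail, and an independent re-evaluation of every
        rule reproduces each call's ledger on 1,000 randomized columns."""
        rng = random.Random(7)
        cols = []
        pos = 100
        for _ in range(1000):
            pos += rng.randint(1, 120)
            d = rng.randint(5, 260)
            n_alt = rng.randint(1, d)
            quals = [rng.randint(15, 40) for _ in range(d)]
            mapqs = [rng.choice([30, 60]) for _ in range(d)]
            dists = [rng.randint(0, 60) for _ in range(d)]
            cols.append(
                make_column(
                    "A",
                    "G" * n_alt + "A" * (d - n_alt),
                    quals=quals,
                    mapq=mapqs,
                    three_prime_dists=dists,
                    pos=pos,
                )
            )
        indels = {"contig1": sorted(rng.sample(range(100, pos), 50))}
        res = make_result(cols, indel_index=indels)
        cfg = CallerConfig.genome_preset()
        calls = call_columns(res)
        passed, ledger = apply_filter_chain(calls, res, cfg)
        assert ledger.n_raw == ledger.n_pass + ledger.n_fail == len(calls)
        assert len(passed) == ledger.n_pass

        import bisect

        for call in calls:
            expected = []
            col = res.columns[(call.ref_name, call.pos)]
            if call.depth < 20:
                expected.append(MIN_DEPTH)
            if call.depth > 240:
                expected.append(MAX_DEPTH)
            n_other = sum(
                1 for o in calls if o is not call and abs(o.pos - call.pos) <= 50
            )
            if n_other > 1:
                expected.append(DENSITY)
            loci = indels["contig1"]
            i = bisect.bisect_left(loci, call.pos)
            dmin = min(
                abs(loci[j] - call.pos) for j in (i - 1, i) if 0 <= j < len(loci)
            )
            if dmin < 50:
                expected.append(INDEL_DISTANCE)
            if call.consensus_quality < 20:
                expected.append(MIN_CONSENSUS)
            if call.snp_quality < 20:
                expected.append(MIN_SNP_QUALITY)
            if max(b.mapq for b in col.bases) < 60:
                expected.append(MAPPING_QUALITY)
            alt_reads = [b for b in col.bases if b.base == call.alt]
            frac = sum(1 for b in alt_reads if b.three_prime_dist < 5) / len(alt_reads)
            if frac > 0.10:
                expected.append(THREE_PRIME_BIAS)
            assert sorted(call.violations) == sorted(expected), call.pos

    def test_relaxing_thresholds_never_shrinks_pass_set(self):
        rng = random.Random(17)
        cols = []
        pos = 100
        for _ in range(300):
            pos += rng.randint(1, 150)
            d = rng.randint(5, 250)
            n_alt = rng.randint(1, d)
            cols.append(make_column("A", "G" * n_alt + "A" * (d - n_alt), pos=pos))
        res = make_result(cols)
        calls = call_columns(res)
        base_cfg = CallerConfig.transcript_preset()
        base_pass, _ = apply_filter_chain(calls, res, base_cfg)
        base_keys = {(c.ref_name, c.pos) for c in base_pass}
        for relaxed in (
            CallerConfig(mode="transcript", min_depth=10),
            CallerConfig(mode="transcript", max_depth=10000),
            CallerConfig(mode="transcript", min_consensus=0.0),
            CallerConfig(mode="transcript", min_adjacent_consensus=0.0),
            CallerConfig(mode="transcript", required_mapq=0),
            CallerConfig(mode="transcript", max_other_snps=10**6),
            CallerConfig(mode="transcript", min_indel_distance=0),
        ):
            relaxed_pass, _ = apply_filter_chain(calls, res, relaxed)
            assert base_keys <= {(c.ref_name, c.pos) for c in relaxed_pass}

    def test_three_prime_rule_removes_alignment_artifact_calls(self):
        """Columns emulating 3'-end alignment artifacts — a consistent wrong
        base carried at good quality in reads' 3'-terminal windows — are
        called raw but removed by the genome chain, with the 3'-bias rule
        alone accounting for at least half of the artifact removals."""
        rng = random.Random(29)
        cols = []
        pos = 100
        artifact_positions = set()
        for i in range(60):
            pos += rng.randint(110, 200)
            d = rng.randint(60, 120)
            if i % 2 == 0:  # artifact: all alt evidence sits in the 3' window
                n_alt = rng.randint(int(0.2 * d), int(0.4 * d))
                dists = [rng.randint(0, 4)] * n_alt + [
                    rng.randint(10, 55) for _ in range(d - n_alt)
                ]
                artifact_positions.add(pos)
            else:  # genuine het: alt positions spread uniformly along reads
                n_alt = d // 2
                dists = [rng.randint(6, 55) for _ in range(d)]
            cols.append(
                make_column(
                    "A", "G" * n_alt + "A" * (d - n_alt),
                    three_prime_dists=dists, pos=pos,
                )
            )
        res = make_result(cols)
        cfg = CallerConfig.genome_preset()
        calls = call_columns(res)
        raw_fp = [c for c in calls if c.pos in artifact_positions]
        assert raw_fp, "artifact columns must be called raw"
        passed, _ = apply_filter_chain(calls, res, cfg)
        chain_fp = [c for c in passed if c.pos in artifact_positions]
        assert len(chain_fp) < len(raw_fp)
        removed_by_rule = [
            c for c in raw_fp if THREE_PRIME_BIAS in c.violations
        ]
        assert len(removed_by_rule) >= 0.5 * len(raw_fp)
        # genuine het calls are untouched by the 3' rule
        for c in passed:
            assert c.pos not in artifact_positions or not c.violations

    def test_unsorted_calls_rejected(self):
        calls, res = chain_fixture([40, 40], CallerConfig.transcript_preset())
        with pytest.raises(ValueError):
            apply_filter_chain(list(reversed(calls)), res, CallerConfig.transcript_preset())
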