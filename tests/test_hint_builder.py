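"""Hit ranking, segment truncation, hint clustering and gene retention."""

import io
import random

import pytest

from genomeprep.hint_builder import (
    Evidence,
    GeneSupport,
    HintPolicy,
    HomologyHit,
    Rank,
    TaggedSegment,
    build_hints,
    cluster_hints,
    rank_hits,
    read_hits_tsv,
    retain_genes,
    truncate_segments,
    write_hints_gff3,
)


def hit(query="q", score=100.0, segments=((100, 200),), evidence=Evidence.PROTEIN,
        contig="c1", strand="+", rank=None):
    h = HomologyHit(query, evidence, contig, strand, score, list(segments))
    h.rank = rank
    return h


class TestRankHits:
    def test_top_two_secondary_rest_dropped(self):
        hits = [hit(score=s, segments=((i * 1000, i * 1000 + 50),))
                for i, s in enumerate((100, 90, 80, 70))]
        ranked = rank_hits(hits)
        assert [h.rank for h in ranked] == [Rank.TOP, Rank.SECONDARY, Rank.SECONDARY]
        assert [h.score for h in ranked] == [100, 90, 80]

    def test_single_hit_is_top(self):
        (h,) = rank_hits([hit()])
        assert h.rank is Rank.TOP

    def test_matches_sort_oracle_with_tiebreaks(self, rng):
        """Random scored hits (with deliberate score ties) rank exactly as a
        brute-force sort by (-score, -summed length, leftmost, contig)."""
        for _ in range(50):
            hits = []
            for i in range(rng.randint(1, 8)):
                start = rng.randint(0, 5000)
                nseg = rng.randint(1, 3)
                segs, cur = [], start
                for _ in range(nseg):
                    ln = rng.randint(10, 200)
                    segs.append((cur, cur + ln))
                    cur += ln + rng.randint(1, 50)
                hits.append(
                    hit(
                        score=float(rng.choice([50, 60, 70])),  # force ties
                        segments=segs,
                        contig=rng.choice(["c1", "c2"]),
                    )
                )
            ranked = rank_hits([h for h in hits])
            expected = sorted(
                hits,
                key=lambda h: (
                    -h.score,
                    -sum(e - s for s, e in h.cds_segments),
                    h.cds_segments[0][0],
                    h.target_contig,
                ),
            )[:3]
            assert [(h.score, h.cds_segments) for h in ranked] == [
                (h.score, h.cds_segments) for h in expected
            ]
            assert ranked[0].rank is Rank.TOP
            assert all(h.rank is Rank.SECONDARY for h in ranked[1:])


class TestTruncateSegments:
    @pytest.mark.parametrize(
        "evidence, rank, segment, expected",
        [
            (Evidence.PROTEIN, Rank.TOP, (100, 200), (103, 197)),
            (Evidence.PROTEIN, Rank.SECONDARY, (100, 200), (109, 191)),
            (Evidence.TRANSCRIPT, Rank.TOP, (100, 200), (100, 200)),
            (Evidence.TRANSCRIPT, Rank.SECONDARY, (100, 200), (103, 197)),
        ],
    )
    def test_per_side_cut_by_evidence_and_rank(self, evidence, rank, segment, expected):
        segs, dropped = truncate_segments(hit(evidence=evidence, rank=rank,
                                              segments=(segment,)))
        assert segs == [expected] and dropped == 0

    def test_overtrimmed_segment_dropped(self):
        # 15 bp segment minus 2 x 9 bp leaves nothing
        segs, dropped = truncate_segments(
            hit(evidence=Evidence.PROTEIN, rank=Rank.SECONDARY, segments=((100, 115),))
        )
        assert segs == [] and dropped == 1

    def test_unranked_hit_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            truncate_segments(hit(rank=None))

    def test_truncation_shrinks_and_is_monotone(self, rng):
        """Trimmed segments nest inside their sources, and widening any cut
        never increases total covered bp."""
        for _ in range(50):
            segs = []
            cur = 0
            for _ in range(rng.randint(1, 5)):
                cur += rng.randint(1, 100)
                ln = rng.randint(5, 300)
                segs.append((cur, cur + ln))
                cur += ln
            h = hit(evidence=Evidence.PROTEIN, rank=Rank.SECONDARY, segments=segs)
            base_policy = HintPolicy()
            wide = HintPolicy()
            wide.cut_bp = dict(base_policy.cut_bp)
            wide.cut_bp[(Evidence.PROTEIN, Rank.SECONDARY)] = 9 + rng.randint(1, 10)
            out, _ = truncate_segments(h, base_policy)
            out_wide, _ = truncate_segments(h, wide)
            for (s, e), (os_, oe) in zip(out, [x for x in segs
                                               if x[1] - x[0] >= 19]):
                assert os_ <= s < e <= oe
            assert sum(e - s for s, e in out_wide) <= sum(e - s for s, e in out)


def seg(start, end, contig="c1", strand="+", evidence=Evidence.PROTEIN):
    return TaggedSegment(contig, strand, evidence, start, end)


class TestClusterHints:
    def test_overlap_merges_with_support(self):
        (h,) = cluster_hints([seg(0, 100), seg(50, 150)])
        assert (h.start, h.end, h.support_count) == (0, 150, 2)

    def test_halfopen_abutment_stays_separate(self):
        hints = cluster_hints([seg(0, 100), seg(100, 200)])
        assert [(h.start, h.end) for h in hints] == [(0, 100), (100, 200)]

    def test_strand_and_evidence_partition(self):
        hints = cluster_hints(
            [seg(0, 100), seg(50, 150, strand="-"),
             seg(60, 160, evidence=Evidence.TRANSCRIPT)]
        )
        assert len(hints) == 3

    def test_matches_interval_union_oracle(self, rng):
        """300 random segments: merged output equals a bitmap union, outputs
        are disjoint and sorted, support counts sum to the input count."""
        segments, bitmap = [], set()
        for _ in range(300):
            s = rng.randint(0, 20_000)
            e = s + rng.randint(1, 500)
            segments.append(seg(s, e))
            bitmap.update(range(s, e))
        hints = cluster_hints(segments)
        covered = set()
        for h in hints:
            covered.update(range(h.start, h.end))
        assert covered == bitmap
        assert all(a.end <= b.start for a, b in zip(hints, hints[1:]))
        assert sum(h.support_count for h in hints) == 300


class TestRetainGenes:
    @pytest.mark.parametrize(
        "hint_flag, db_flag, kept",
        [(True, True, True), (True, False, False),
         (False, True, False), (False, False, False)],
    )
    def test_both_evidence_rule(self, hint_flag, db_flag, kept):
        ids, _ = retain_genes([GeneSupport("g1", hint_flag, db_flag)])
        assert (ids == ["g1"]) == kept

    def test_matches_and_oracle(self, rng):
        genes = [GeneSupport(f"g{i}", rng.random() < 0.5, rng.random() < 0.5)
                 for i in range(100)]
        kept, discarded = retain_genes(genes)
        assert set(kept) == {g.gene_id for g in genes
                             if g.has_hint_support and g.has_db_hit}
        assert len(kept) + sum(discarded.values()) == 100


class TestPipelineAndIO:
    def test_build_hints_end_to_end(self):
        hits = [
            hit("q1", 100, ((100, 400),)),
            hit("q1", 90, ((150, 380),)),
            hit("q2", 80, ((1000, 1100),), evidence=Evidence.PROTEIN),
        ]
        hints, counts = build_hints(hits)
        assert counts["ranked_hits"] == 3
        # q1's two protein hits overlap after trimming and merge into one hint
        assert [(h.start, h.end, h.support_count) for h in hints] == [
            (103, 397, 2),
            (1003, 1097, 1),
        ]

    def test_hits_tsv_and_gff3_roundtrip(self, tmp_path):
        tsv = tmp_path / "hits.tsv"
        tsv.write_text("q1\tc1\t+\t812.5\t100-220,300-451\n")
        (h,) = read_hits_tsv(tsv, Evidence.PROTEIN)
        assert h.cds_segments == [(100, 220), (300, 451)]
        hints, _ = build_hints([h])
        out = io.StringIO()
        n = write_hints_gff3(hints, out)
        lines = [l for l in out.getvalue().splitlines() if not l.startswith("#")]
        assert n == len(lines) == 2
        col = lines[0].split("\t")
        assert col[2] == "CDSpart" and int(col[3]) == 104 and int(col[4]) == 217
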