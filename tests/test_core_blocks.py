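import logging

import numpy as np
import pytest

from leonbis import (
    Alignment,
    CoreBlock,
    ScoreTrack,
    block_relatedness,
    detect_core_blocks,
    mark_query_related_blocks,
    score_track,
    subfamily_columns,
)
from leonbis.subfamilies import SubfamilyPartition
from leonbis.synthetic import FixtureSpec, PlantedBlock, generate_fixture


def oracle_detect(probs, window, threshold):
    """Brute-force window enumeration: union of qualifying windows."""
    n = len(probs)
    covered = np.zeros(n, dtype=bool)
    for start in range(n - window + 1):
        if np.mean(probs[start : start + window]) > threshold:
            covered[start : start + window] = True
    runs = []
    c = 0
    while c < n:
        if covered[c]:
            s = c
            while c < n and covered[c]:
                c += 1
            runs.append((s, c))
        else:
            c += 1
    return runs


class TestScoreTrack:
    def test_gap_only_column_scores_zero(self, toy_mixture):
        aln = Alignment([("a", "-ACDWLKEF"), ("b", "-ACDWLKEF")], "a")
        track = score_track(aln, [0, 1], toy_mixture)
        assert track.probs[0] == 0.0

    def test_single_observation_scores_zero(self, toy_mixture):
        # one residue + one gap: below the 2-observation floor
        aln = Alignment([("a", "WACDWLKEF"), ("b", "-ACDWLKEF")], "a")
        track = score_track(aln, [0, 1], toy_mixture)
        assert track.probs[0] == 0.0

    def test_conserved_tryptophan_column(self, toy_mixture):
        aln = Alignment([(f"s{i}", "W" + "ACDEF"[i % 5] * 4) for i in range(10)], "s0")
        track = score_track(aln, list(range(10)), toy_mixture)
        assert track.probs[0] > 0.9

    def test_member_order_invariance(self, toy_mixture):
        aln, _ = generate_fixture(
            FixtureSpec(seed=1, n_subfamilies=1, members_per_subfamily=6,
                        n_cols=60, n_unrelated=0,
                        planted_blocks=(PlantedBlock(10, 40),))
        )
        fwd = score_track(aln, list(range(6)), toy_mixture)
        rev = score_track(aln, list(range(5, -1, -1)), toy_mixture)
        np.testing.assert_array_equal(fwd.probs, rev.probs)
        np.testing.assert_array_equal(fwd.raw_S, rev.raw_S)


class TestDetectCoreBlocks:
    def test_uniform_low_track_yields_nothing(self):
        track = ScoreTrack(0, np.full(100, 0.04), np.zeros(100))
        assert detect_core_blocks(track, window=7, threshold=0.05) == []

    def test_saturated_track_yields_single_block(self):
        track = ScoreTrack(0, np.ones(50), np.ones(50))
        blocks = detect_core_blocks(track, window=7, threshold=0.05)
        assert [(b.start, b.end) for b in blocks] == [(0, 50)]
        assert blocks[0].block_score == pytest.approx(50.0)

    def test_window_wider_than_track(self, caplog):
        track = ScoreTrack(0, np.ones(5), np.ones(5))
        with caplog.at_level(logging.WARNING):
            assert detect_core_blocks(track, window=10) == []
        assert "window" in caplog.text

    @pytest.mark.parametrize("window", [1, 3, 7])
    def test_matches_brute_force_oracle(self, window):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(window, 80))
            probs = rng.uniform(0, 0.3, size=n)
            track = ScoreTrack(0, probs, rng.normal(size=n))
            got = [(b.start, b.end) for b in detect_core_blocks(track, window, 0.05)]
            assert got == oracle_detect(probs, window, 0.05)

    def test_blocks_span_at_least_window(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            probs = rng.uniform(0, 0.4, size=60)
            for b in detect_core_blocks(ScoreTrack(0, probs, probs), 7, 0.05):
                assert b.span >= 7

    def test_threshold_monotonicity(self):
        """Raising the threshold never enlarges the covered column set."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            probs = rng.uniform(0, 0.3, size=70)
            track = ScoreTrack(0, probs, probs)
            lo = {c for b in detect_core_blocks(track, 7, 0.04) for c in range(b.start, b.end)}
            hi = {c for b in detect_core_blocks(track, 7, 0.08) for c in range(b.start, b.end)}
            assert hi <= lo

    def test_bad_parameters_rejected(self):
        track = ScoreTrack(0, np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            detect_core_blocks(track, window=0)
        with pytest.raises(ValueError):
            detect_core_blocks(track, window=3, threshold=1.5)


class TestBlockRelatedness:
    def _duplicate_subfamily_setup(self, toy_mixture):
        aln, _ = generate_fixture(
            FixtureSpec(seed=5, n_subfamilies=1, members_per_subfamily=6,
                        n_cols=80, n_unrelated=0,
                        planted_blocks=(PlantedBlock(20, 60),))
        )
        cols = subfamily_columns(aln, list(range(6)))
        block = CoreBlock(0, 20, 60, 0.8, 10.0)
        return cols, block

    def test_identical_composition_blocks_related(self, toy_mixture):
        cols, block = self._duplicate_subfamily_setup(toy_mixture)
        related, score = block_relatedness(block, block, cols, cols, toy_mixture)
        assert related and score > 0

    def test_symmetry(self, toy_mixture):
        cols, block = self._duplicate_subfamily_setup(toy_mixture)
        other = CoreBlock(1, 30, 70, 0.5, 5.0)
        _, s_ab = block_relatedness(block, other, cols, cols, toy_mixture)
        _, s_ba = block_relatedness(other, block, cols, cols, toy_mixture)
        assert s_ab == pytest.approx(s_ba, abs=1e-12)

    def test_disjoint_blocks_raise(self, toy_mixture):
        cols, block = self._duplicate_subfamily_setup(toy_mixture)
        far = CoreBlock(1, 60, 80, 0.5, 5.0)
        with pytest.raises(ValueError, match="do not overlap"):
            block_relatedness(block, far, cols, cols, toy_mixture)

    def test_zero_score_is_not_related(self, toy_mixture):
        # overlap restricted to columns empty in one subfamily: R sums to 0
        from leonbis import ColumnObservation
        empty_cols = [ColumnObservation(np.zeros(20)) for _ in range(80)]
        cols, block = self._duplicate_subfamily_setup(toy_mixture)
        related, score = block_relatedness(
            block, CoreBlock(1, 20, 60, 0.5, 5.0), cols, empty_cols, toy_mixture
        )
        assert score == 0.0
        assert related is False


class TestMarkQueryRelated:
    def test_single_subfamily_all_related(self, toy_mixture):
        aln, _ = generate_fixture(
            FixtureSpec(seed=6, n_subfamilies=1, members_per_subfamily=6,
                        n_cols=80, n_unrelated=0,
                        planted_blocks=(PlantedBlock(10, 50),))
        )
        members = list(range(6))
        cols = subfamily_columns(aln, members)
        track = score_track(aln, members, toy_mixture, columns=cols)
        blocks = detect_core_blocks(track)
        assert blocks
        part = SubfamilyPartition([members], [], 0)
        mark_query_related_blocks({0: blocks}, part, {0: cols}, toy_mixture)
        assert all(b.related_to_query == "is_query_subfamily" for b in blocks)

    def test_shared_domain_links_only_domain_blocks(self, toy_mixture):
        """Two subfamilies share one planted domain and differ elsewhere:
        only the second subfamily's domain block is query-related."""
        aln, _ = generate_fixture(
            FixtureSpec(
                seed=9, n_subfamilies=2, members_per_subfamily=6, n_cols=160,
                planted_blocks=(
                    PlantedBlock(20, 70, shared=True),
                    PlantedBlock(100, 150, shared=False),
                ),
                n_unrelated=0,
            )
        )
        subs = [list(range(6)), list(range(6, 12))]
        cols = {k: subfamily_columns(aln, m) for k, m in enumerate(subs)}
        blocks = {
            k: detect_core_blocks(
                score_track(aln, m, toy_mixture, subfamily_index=k, columns=cols[k])
            )
            for k, m in enumerate(subs)
        }
        part = SubfamilyPartition(subs, [], 0)
        mark_query_related_blocks(blocks, part, cols, toy_mixture)
        for b in blocks[1]:
            overlaps_shared = b.start < 70 and b.end > 20
            assert b.related_to_query == overlaps_shared

    def test_planted_block_recovery_jaccard(self, toy_mixture):
        """Detected block columns track a planted conserved domain closely."""
        jaccards = []
        for seed in range(50):
            aln, truth = generate_fixture(
                FixtureSpec(seed=seed, n_subfamilies=1, members_per_subfamily=6,
                            n_cols=160, n_unrelated=0,
                            planted_blocks=(PlantedBlock(40, 100),))
            )
            members = list(range(6))
            track = score_track(aln, members, toy_mixture,
                                columns=subfamily_columns(aln, members))
            detected = {
                c for b in detect_core_blocks(track) for c in range(b.start, b.end)
            }
            planted = set(range(40, 100))
            jaccards.append(
                len(detected & planted) / len(detected | planted) if detected else 0.0
            )
        assert np.mean(jaccards) >= 0.8
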