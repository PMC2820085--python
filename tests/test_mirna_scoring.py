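import math
import random

import numpy as np
import pytest

from mirextra.hexamers import MiRNAHexamers
from mirextra.io_model import ExpressionInput
from mirextra.mirna_scoring import (
    combined_score,
    normalized_margin,
    optimize_weights,
    rank_mirnas,
    score_table_enrichment,
)
from mirextra.rank_stats import HexamerResult


def result(hexamer, lnp):
    return HexamerResult(hexamer, math.exp(-lnp), lnp, 5, 5)


def mh(mirna_id, h1, h2, h3):
    return MiRNAHexamers(mirna_id, h1, h2, h3)


class TestCombinedScore:
    @pytest.mark.parametrize(
        "lnps, expected",
        [
            ((10, 20, 5), 26.0),
            ((0, 0, 99), 0.0),  # hexamer 3 never contributes by default
            ((1, 0, 0), 0.6),
        ],
    )
    def test_default_weights(self, lnps, expected):
        assert combined_score(*lnps) == pytest.approx(expected)

    def test_identity_on_random_triples(self):
        rng = np.random.default_rng(0)
        for lnp1, lnp2, lnp3 in rng.uniform(0, 44, size=(1000, 3)):
            assert combined_score(lnp1, lnp2, lnp3) == lnp2 + 0.6 * lnp1

    def test_negative_lnp_rejected(self):
        with pytest.raises(ValueError):
            combined_score(-1.0, 0.0, 0.0)


class TestRankMiRNAs:
    def test_shared_seed_resolved_by_hexamer1(self):
        results = [
            result("AAAAAA", 30.0),  # shared hex2
            result("CCCCCC", 10.0),  # mir-a hex1
            result("GGGGGG", 2.0),  # mir-b hex1
            result("TTTTTT", 0.0),
        ]
        mapping = [
            mh("mir-b", "GGGGGG", "AAAAAA", "TTTTTT"),
            mh("mir-a", "CCCCCC", "AAAAAA", "TTTTTT"),
        ]
        scores = rank_mirnas(results, mapping)
        assert [s.mirna_id for s in scores] == ["mir-a", "mir-b"]
        assert scores[0].combined == pytest.approx(36.0)
        assert scores[1].combined == pytest.approx(31.2)

    def test_filter_restricts_output(self):
        results = [result(h, 1.0) for h in ("AAAAAA", "CCCCCC", "GGGGGG")]
        mapping = [
            mh("mir-x", "AAAAAA", "CCCCCC", "GGGGGG"),
            mh("mir-y", "CCCCCC", "GGGGGG", "AAAAAA"),
        ]
        scores = rank_mirnas(results, mapping, mirna_filter={"mir-x"})
        assert [s.mirna_id for s in scores] == ["mir-x"]

    def test_unknown_filter_name_skipped(self, caplog):
        results = [result(h, 1.0) for h in ("AAAAAA", "CCCCCC", "GGGGGG")]
        mapping = [mh("mir-x", "AAAAAA", "CCCCCC", "GGGGGG")]
        scores = rank_mirnas(results, mapping, mirna_filter={"mir-x", "mir-ghost"})
        assert [s.mirna_id for s in scores] == ["mir-x"]

    def test_all_zero_orders_lexicographically(self):
        results = [result(h, 0.0) for h in ("AAAAAA", "CCCCCC", "GGGGGG")]
        mapping = [
            mh("mir-c", "AAAAAA", "CCCCCC", "GGGGGG"),
            mh("mir-a", "CCCCCC", "GGGGGG", "AAAAAA"),
            mh("mir-b", "GGGGGG", "AAAAAA", "CCCCCC"),
        ]
        scores = rank_mirnas(results, mapping)
        assert [s.mirna_id for s in scores] == ["mir-a", "mir-b", "mir-c"]

    def test_missing_hexamer_result_is_error(self):
        with pytest.raises(ValueError, match="GGGGGG"):
            rank_mirnas(
                [result("AAAAAA", 1.0), result("CCCCCC", 1.0)],
                [mh("mir-x", "AAAAAA", "CCCCCC", "GGGGGG")],
            )


class TestNormalizedMargin:
    def _scores(self, specs):
        results, mapping = [], []
        hex_lnps = {}
        for mirna_id, (l1, l2, l3), triple in specs:
            mapping.append(mh(mirna_id, *triple))
            for h, l in zip(triple, (l1, l2, l3)):
                hex_lnps[h] = l
        results = [result(h, l) for h, l in hex_lnps.items()]
        return rank_mirnas(results, mapping)

    def test_direct_formula(self):
        scores = self._scores(
            [
                ("correct", (0, 30, 0), ("AAAAAA", "CCCCCC", "GGGGGG")),
                ("other", (0, 24, 0), ("ACACAC", "TTTTTT", "GTGTGT")),
            ]
        )
        assert normalized_margin(scores, "correct") == pytest.approx(0.2)

    def test_same_triple_competitor_skipped(self):
        scores = self._scores(
            [
                ("correct", (0, 30, 0), ("AAAAAA", "CCCCCC", "GGGGGG")),
                ("twin", (0, 30, 0), ("AAAAAA", "CCCCCC", "GGGGGG")),
                ("other", (0, 24, 0), ("ACACAC", "TTTTTT", "GTGTGT")),
            ]
        )
        assert normalized_margin(scores, "correct") == pytest.approx(0.2)

    def test_outranked_gives_negative_margin(self):
        scores = self._scores(
            [
                ("correct", (0, 10, 0), ("AAAAAA", "CCCCCC", "GGGGGG")),
                ("other", (0, 20, 0), ("ACACAC", "TTTTTT", "GTGTGT")),
            ]
        )
        assert normalized_margin(scores, "correct") == pytest.approx(-1.0)

    def test_zero_score_rejected(self):
        scores = self._scores(
            [("correct", (0, 0, 5), ("AAAAAA", "CCCCCC", "GGGGGG"))]
        )
        with pytest.raises(ValueError):
            normalized_margin(scores, "correct")


class TestOptimizeWeights:
    def _calibration_noise_lnp3(self):
        """Correct miRNA leads on hexamers 1/2; lnp3 favours a decoy, so
        any positive w3 strictly hurts the margin."""
        results = [
            result("AAAAAA", 20.0),  # correct hex2
            result("CCCCCC", 10.0),  # correct hex1
            result("GGGGGG", 0.0),  # correct hex3
            result("TTTTTT", 15.0),  # decoy hex2
            result("ACACAC", 5.0),  # decoy hex1
            result("GTGTGT", 40.0),  # decoy hex3: pure noise
        ]
        mapping = [
            mh("correct", "CCCCCC", "AAAAAA", "GGGGGG"),
            mh("decoy", "ACACAC", "TTTTTT", "GTGTGT"),
        ]
        return [(results, mapping, "correct")]

    def test_grid_shape(self):
        w1, w3, grid = optimize_weights(self._calibration_noise_lnp3())
        assert grid.n_points == 10_201
        assert grid.objective.shape == (101, 101)

    def test_noisy_lnp3_drives_w3_to_zero(self):
        w1, w3, _ = optimize_weights(self._calibration_noise_lnp3())
        assert w3 == 0.0
        assert w1 == 1.0  # hex1 lead is maximal here, so full weight

    def test_constant_objective_ties_to_origin(self):
        # equal proportional lead on every hexamer: margin independent of weights
        results = [
            result("AAAAAA", 30.0), result("CCCCCC", 30.0), result("GGGGGG", 30.0),
            result("TTTTTT", 24.0), result("ACACAC", 24.0), result("GTGTGT", 24.0),
        ]
        mapping = [
            mh("correct", "AAAAAA", "CCCCCC", "GGGGGG"),
            mh("other", "TTTTTT", "ACACAC", "GTGTGT"),
        ]
        w1, w3, grid = optimize_weights([(results, mapping, "correct")])
        assert (w1, w3) == (0.0, 0.0)
        assert grid.objective.max() == pytest.approx(grid.objective.min(), abs=1e-9)

    def test_argmax_matches_shuffled_exhaustive_reevaluation(self):
        calibration = self._calibration_noise_lnp3()
        w1, w3, grid = optimize_weights(calibration)
        results, mapping, correct = calibration[0]
        points = [
            (round(i * 0.01, 2), round(j * 0.01, 2))
            for i in range(101) for j in range(101)
        ]
        random.Random(0).shuffle(points)
        best_val, best_pt = -np.inf, None
        for cw1, cw3 in points:
            scores = rank_mirnas(results, mapping, w1=cw1, w3=cw3)
            margin = normalized_margin(scores, correct)
            # same lexicographic preference, evaluated independently
            if margin > best_val + 1e-12 or (
                abs(margin - best_val) <= 1e-12 and best_pt is not None
                and (cw1, cw3) < best_pt
            ):
                best_val, best_pt = margin, (cw1, cw3)
        assert best_pt == (w1, w3)
        assert grid.objective.max() == pytest.approx(best_val, abs=1e-9)


class TestScoreTableEnrichment:
    def _expression(self):
        return ExpressionInput({"g1", "g2", "g3"}, {"g4", "g5", "g6"})

    def test_separated_scores_reach_enumeration_p(self):
        table = {(f"g{i}", "mir-x"): 1.0 for i in (1, 2, 3)}
        table.update({(f"g{i}", "mir-x"): 0.0 for i in (4, 5, 6)})
        rows = score_table_enrichment(table, self._expression())
        assert rows == [("mir-x", pytest.approx(1 / 20), pytest.approx(-math.log(1 / 20)))]

    def test_constant_scores_give_p_one(self):
        table = {(f"g{i}", "mir-x"): 0.5 for i in range(1, 7)}
        (row,) = score_table_enrichment(table, self._expression())
        assert row[1] == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        table = {(f"g{i}", "mir-x"): float(v) for i, v in zip(range(1, 7), rng.random(6))}
        scaled = {k: 10 * v for k, v in table.items()}
        assert (
            score_table_enrichment(table, self._expression())
            == score_table_enrichment(scaled, self._expression())
        )

    def test_absent_gene_scored_zero_vs_dropped(self):
        table = {("g1", "mir-x"): 1.0, ("g2", "mir-x"): 1.0, ("g3", "mir-x"): 1.0,
                 ("g4", "mir-x"): 0.1, ("g5", "mir-x"): 0.1}
        # zero mode keeps g6 at 0; drop mode removes it
        rows_zero = score_table_enrichment(table, self._expression(), absent="zero")
        rows_drop = score_table_enrichment(table, self._expression(), absent="drop")
        assert rows_zero[0][1] != rows_drop[0][1]

    def test_sparse_mirna_skipped(self, caplog):
        table = {("g1", "mir-x"): 1.0}
        rows = score_table_enrichment(
            table, self._expression(), absent="drop"
        )
        assert rows == []
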