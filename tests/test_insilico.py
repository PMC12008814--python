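import math

import numpy as np
import pytest

from synlab.attribution import contribution_scores
from synlab.core import MotifInstance, motif_from_consensus
from synlab.insilico import (apply_gap_edit, design_minimal_mutation,
                             distance_sweep, double_cooperativity, enhancement,
                             fit_exponential_decay, inject_predict, move_motif,
                             spacing_perturbation)
from synlab.seqs import random_sequence
from synlab.sim import make_grammar, oracle_predictor

TEAD = "ACATTCCTG"
TFAP2C = "CCCTCAGGC"


# ----------------------------------------------------------------- enhancement
class TestEnhancement:
    def test_exact_additivity_is_zero(self):
        assert enhancement(1, 5, 3, 7) == 0.0

    def test_twofold(self):
        assert enhancement(1, 5, 3, 12) == pytest.approx(1.0)

    def test_negative_numerator_flagged_nan(self):
        assert math.isnan(enhancement(1, 5, 10, 5))

    def test_non_positive_hA_errors(self):
        with pytest.raises(ValueError):
            enhancement(1, 0, 3, 7)

    def test_monotone_in_hAB_and_hB(self, rng):
        for _ in range(50):
            h0, hA, hB = rng.uniform(0.1, 5), rng.uniform(0.5, 10), rng.uniform(0.1, 5)
            hAB = hB - h0 + rng.uniform(0.5, 20)
            e = enhancement(h0, hA, hB, hAB)
            assert enhancement(h0, hA, hB, hAB + 1) > e
            e2 = enhancement(h0, hA, hB + 0.1, hAB)
            assert math.isnan(e2) or e2 < e


# -------------------------------------------------------------- inject_predict
class TestInjectPredict:
    def test_motifB_none_identities(self, oracle):
        r = inject_predict(oracle, TEAD, None, 0, "tead4", n_backgrounds=8, seed=1)
        assert r.hB == r.h0
        assert r.hAB == r.hA

    def test_additive_grammar_interaction_zero(self, additive_grammar):
        pred = oracle_predictor(additive_grammar)
        r = inject_predict(pred, TEAD, TFAP2C, 10, "tead4", n_backgrounds=64, seed=2)
        interaction = r.hAB - r.hA - r.hB + r.h0
        assert abs(interaction) < 0.05 * r.hA

    def test_monte_carlo_stability(self, oracle):
        r1 = inject_predict(oracle, TEAD, TFAP2C, 20, "tead4", n_backgrounds=256, seed=3)
        r2 = inject_predict(oracle, TEAD, TFAP2C, 20, "tead4", n_backgrounds=256, seed=4)
        # shared-background variance reduction keeps h estimates tight
        for a, b in ((r1.hA, r2.hA), (r1.hAB, r2.hAB)):
            assert abs(a - b) < 0.1 * max(a, b)

    def test_overlapping_distance_rejected(self, oracle):
        with pytest.raises(ValueError):
            inject_predict(oracle, TEAD, TFAP2C, -3, "tead4", n_backgrounds=2)

    def test_background_motif_placed(self, oracle):
        r = inject_predict(oracle, TEAD, None, 0, "tead4", n_backgrounds=16, seed=5,
                           background_motif=TFAP2C)
        plain = inject_predict(oracle, TEAD, None, 0, "tead4", n_backgrounds=16, seed=5)
        assert r.hA > plain.hA  # anchored partner boosts the injected motif

    def test_determinism(self, oracle):
        a = inject_predict(oracle, TEAD, TFAP2C, 30, "tead4", n_backgrounds=16, seed=9)
        b = inject_predict(oracle, TEAD, TFAP2C, 30, "tead4", n_backgrounds=16, seed=9)
        assert (a.h0, a.hA, a.hB, a.hAB) == (b.h0, b.hA, b.hB, b.hAB)


# -------------------------------------------------------------- distance_sweep
class TestDistanceSweep:
    def test_boost_at_zero_distance(self, oracle):
        res = distance_sweep(oracle, TEAD, TFAP2C, [0], "tead4",
                             n_backgrounds=256, seed=6)
        # planted boost 1 + 3*exp(0) = 4 => log2(4) = 2, small leakage allowed
        assert res[0].enhancement == pytest.approx(2.0, abs=0.15)

    def test_flat_curve_for_additive_grammar(self, additive_grammar):
        pred = oracle_predictor(additive_grammar)
        res = distance_sweep(pred, TEAD, TFAP2C, [0, 40, 100], "tead4",
                             n_backgrounds=64, seed=7)
        for r in res:
            assert abs(r.enhancement) < 0.1

    def test_tau_recovery(self, oracle):
        distances = [0, 10, 20, 30, 40, 60, 80, 100, 120, 150]
        res = distance_sweep(oracle, TEAD, TFAP2C, distances, "tead4",
                             n_backgrounds=256, seed=8)
        _, tau = fit_exponential_decay(distances, [r.enhancement for r in res])
        assert abs(tau - 40.0) / 40.0 < 0.25

    def test_yap1_tracks_tead4(self, oracle):
        res4 = distance_sweep(oracle, TEAD, TFAP2C, [0, 50], "tead4",
                              n_backgrounds=32, seed=10)
        resy = distance_sweep(oracle, TEAD, TFAP2C, [0, 50], "yap1",
                              n_backgrounds=32, seed=10)
        for a, b in zip(res4, resy):
            assert a.enhancement == pytest.approx(b.enhancement)

    def test_directionality(self, oracle):
        # only tead4 is boosted by tfap2c; the reverse direction stays flat
        fwd = inject_predict(oracle, TEAD, TFAP2C, 5, "tead4", n_backgrounds=128, seed=11)
        rev = inject_predict(oracle, TFAP2C, TEAD, 5, "tfap2c", n_backgrounds=128, seed=11)
        assert fwd.enhancement > 1.5
        assert abs(rev.enhancement) < 0.15


# -------------------------------------------------------- double_cooperativity
class TestDoubleCooperativity:
    def test_kappa_recovery(self, grammar, oracle):
        dbl = grammar.motifs["tead_double"].consensus
        r = double_cooperativity(oracle, dbl, 11, "tead4", n_backgrounds=256, seed=12)
        assert abs(r.fold - 4.0) / 4.0 < 0.2

    def test_kappa_one_additive(self, additive_grammar):
        pred = oracle_predictor(additive_grammar)
        dbl = additive_grammar.motifs["tead_double"].consensus
        r = double_cooperativity(pred, dbl, 11, "tead4", n_backgrounds=256, seed=13)
        assert 0.9 <= r.fold <= 1.1

    def test_esc_like_grammar_kappa_two(self, default_cfg):
        default_cfg["motifs"][0]["amplitude"] = 8.0  # lower-amplitude cell state
        default_cfg["strict_rules"][0]["kappa"] = 2.0
        g = make_grammar(default_cfg)
        pred = oracle_predictor(g)
        dbl = g.motifs["tead_double"].consensus
        r = double_cooperativity(pred, dbl, 11, "tead4", n_backgrounds=256, seed=14)
        assert abs(r.fold - 2.0) / 2.0 < 0.2

    def test_invalid_split(self, oracle):
        with pytest.raises(ValueError):
            double_cooperativity(oracle, TEAD, 0, "tead4", n_backgrounds=2)


# ------------------------------------------------------- spacing_perturbation
class TestSpacingPerturbation:
    def test_one_bp_deletion_kills_cooperativity(self, grammar, oracle):
        dbl = grammar.motifs["tead_double"].consensus
        rep = spacing_perturbation(oracle, dbl, (9, 11), [("delete", 1)],
                                   "tead4", n_backgrounds=64, seed=15)
        assert rep["wildtype"]["fold"] > 3
        assert rep["delete1"]["fold"] < 1.3

    def test_zero_edit_identical(self, grammar, oracle):
        dbl = grammar.motifs["tead_double"].consensus
        rep = spacing_perturbation(oracle, dbl, (9, 11), [("delete", 0)],
                                   "tead4", n_backgrounds=16, seed=16)
        assert rep["delete0"]["sequence"] == dbl
        assert rep["delete0"]["fold"] == rep["wildtype"]["fold"]

    def test_insert_then_delete_restores(self, grammar):
        dbl = grammar.motifs["tead_double"].consensus
        edited, span = apply_gap_edit(dbl, (9, 11), "insert", 2)
        back, _ = apply_gap_edit(edited, span, "delete", 2)
        assert back == dbl

    def test_core_destroying_edit_rejected(self, grammar):
        dbl = grammar.motifs["tead_double"].consensus
        with pytest.raises(ValueError):
            apply_gap_edit(dbl, (9, 11), "delete", 3)


# ---------------------------------------------------- design_minimal_mutation
def _fixture_map_with_instance(oracle, rng, motif_seq=TEAD, width=400):
    bg = random_sequence(width, rng)
    seq = bg[:200] + motif_seq + bg[200 + len(motif_seq):]
    cmap = contribution_scores(oracle, seq, "tead4")
    inst = MotifInstance("seq", 200, 200 + len(motif_seq), "+", "tead")
    return cmap, inst


class TestDesignMinimalMutation:
    def test_argmax_pair_selection(self):
        from synlab.attribution.contrib import ContributionMap
        scores = np.zeros(20)
        scores[5:14] = [0.9, 0.1, 0.8, 0.0, 0.2, 0.3, 0.05, 0.15, 0.25]
        cmap = ContributionMap("c", 0, 20, "t", scores,
                               sequence="ACGTA" + TEAD + "ACGTAC")
        inst = MotifInstance("c", 5, 14, "+", "tead")
        motif = motif_from_consensus("tead", TEAD)
        _, report = design_minimal_mutation(cmap, inst, motif, k=2)
        assert report.positions == [5, 7]

    def test_k_zero_unchanged(self, oracle, rng):
        cmap, inst = _fixture_map_with_instance(oracle, rng)
        motif = motif_from_consensus("tead", TEAD)
        edited, report = design_minimal_mutation(cmap, inst, motif, k=0)
        assert edited == cmap.sequence
        assert report.positions == []

    def test_mutation_halves_prediction(self, oracle, rng):
        cmap, inst = _fixture_map_with_instance(oracle, rng)
        motif = motif_from_consensus("tead", TEAD)
        edited, _ = design_minimal_mutation(cmap, inst, motif, k=2)
        before = oracle.predict(cmap.sequence)["tead4"][2]
        after = oracle.predict(edited)["tead4"][2]
        assert after < 0.5 * before

    def test_tie_break_flagged(self, oracle, rng):
        cmap, inst = _fixture_map_with_instance(oracle, rng)
        motif = motif_from_consensus("tead", TEAD)
        _, report = design_minimal_mutation(cmap, inst, motif, k=2)
        # oracle gives equal contributions across the motif: leftmost wins
        assert report.tie_break_used
        assert report.positions == [200, 201]


# ------------------------------------------------------------------ move_motif
class TestMoveMotif:
    def _setup(self, oracle, rng, gap=20):
        bg = random_sequence(500, rng)
        seq = bg[:200] + TFAP2C + bg[209:209 + gap] + TEAD + bg[209 + gap + 9:]
        seq = seq[:500]
        cmap = contribution_scores(oracle, seq, "tead4")
        anchor = MotifInstance("seq", 200, 209, "+", "tfap2c")
        inst = MotifInstance("seq", 209 + gap, 209 + gap + 9, "+", "tead")
        motif = motif_from_consensus("tead", TEAD)
        return seq, cmap, anchor, inst, motif

    def test_moving_away_reduces_counts(self, oracle, rng):
        seq, cmap, anchor, inst, motif = self._setup(oracle, rng, gap=20)
        moved = move_motif(seq, inst, anchor, 60, cmap, motif)
        near = oracle.predict(seq)["tead4"][2]
        far = oracle.predict(moved)["tead4"][2]
        assert far < near

    def test_length_preserved(self, oracle, rng):
        seq, cmap, anchor, inst, motif = self._setup(oracle, rng)
        moved = move_motif(seq, inst, anchor, 80, cmap, motif)
        assert len(moved) == len(seq)

    def test_same_gap_round_trip_near_wildtype(self, oracle, rng):
        seq, cmap, anchor, inst, motif = self._setup(oracle, rng, gap=40)
        moved = move_motif(seq, inst, anchor, 40, cmap, motif)
        wt = oracle.predict(seq)["tead4"][2]
        rt = oracle.predict(moved)["tead4"][2]
        assert rt == pytest.approx(wt, rel=0.05)

    def test_overlapping_target_rejected(self, oracle, rng):
        seq, cmap, anchor, inst, motif = self._setup(oracle, rng, gap=20)
        with pytest.raises(ValueError):
            move_motif(seq, inst, anchor, 22, cmap, motif)  # overlaps original
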