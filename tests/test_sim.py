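import numpy as np
import pytest

from synlab.core import MotifInstance
from synlab.seqs import random_sequence, revcomp
from synlab.sim import (GrammarError, OracleError, SyntheticGenome, make_grammar,
                        annotate_occupancies, expected_profiles, oracle_occupancy,
                        oracle_predictor, simulate_genome, simulate_profiles)


# ---------------------------------------------------------------- make_grammar
class TestMakeGrammar:
    def test_default_has_two_single_motifs(self, grammar):
        assert grammar.motifs["tead"].consensus == "ACATTCCTG"
        assert grammar.motifs["tfap2c"].consensus == "CCCTCAGGC"
        assert {m.name for m in grammar.single_motifs()} == {"tead", "tfap2c"}

    def test_double_motif_materialized(self, grammar):
        assert grammar.motifs["tead_double"].consensus == "ACATTCCTGGCACATTCCTG"

    def test_purely_additive_grammar_accepted(self, additive_grammar):
        assert additive_grammar.strict_rules[0].kappa == 1.0
        assert additive_grammar.soft_rules[0].c == 0.0

    def test_tau_zero_rejected(self, default_cfg):
        default_cfg["soft_rules"][0]["tau"] = 0.0
        with pytest.raises(GrammarError):
            make_grammar(default_cfg)

    def test_kappa_below_one_rejected(self, default_cfg):
        default_cfg["strict_rules"][0]["kappa"] = 0.5
        with pytest.raises(GrammarError):
            make_grammar(default_cfg)

    def test_unknown_key_rejected(self, default_cfg):
        default_cfg["bogus"] = 1
        with pytest.raises(GrammarError):
            make_grammar(default_cfg)

    def test_deterministic(self, default_cfg):
        g1, g2 = make_grammar(default_cfg), make_grammar(default_cfg)
        assert g1.motifs == g2.motifs and g1.soft_rules == g2.soft_rules


# ------------------------------------------------------------- simulate_genome
class TestSimulateGenome:
    def test_zero_density_pure_background(self, grammar):
        g = simulate_genome(grammar, 1, 2000, density=0.0, seed=3)
        assert g.truth == []
        assert set(g.contigs["syn1"]) <= set("ACGT")

    def test_instance_count_near_expectation(self):
        # single-motif grammar so the analytic expectation is exact:
        # E[n] = n_contigs * contig_len * density / 1000
        cfg = {"motifs": [{"name": "tead", "consensus": "ACATTCCTG",
                           "task": "tead4", "amplitude": 20.0}]}
        g = make_grammar(cfg)
        genome = simulate_genome(g, 4, 500_000, density=0.05, seed=1)
        expect = 4 * 500_000 * 0.05 / 1000
        sd = np.sqrt(expect)
        assert abs(len(genome.truth) - expect) < 4 * sd

    def test_determinism(self, grammar):
        a = simulate_genome(grammar, 2, 5000, 0.2, seed=7, pair_fraction=0.5)
        b = simulate_genome(grammar, 2, 5000, 0.2, seed=7, pair_fraction=0.5)
        assert a.contigs == b.contigs
        assert [(i.contig, i.start, i.strand, i.motif_name) for i in a.truth] == \
               [(i.contig, i.start, i.strand, i.motif_name) for i in b.truth]

    def test_planted_instances_do_not_overlap(self, small_genome):
        by_contig = {}
        for i in small_genome.truth:
            by_contig.setdefault(i.contig, []).append(i)
        for insts in by_contig.values():
            insts = sorted(insts, key=lambda i: i.start)
            for a, b in zip(insts, insts[1:]):
                assert a.end <= b.start

    def test_planted_sequence_matches_consensus(self, grammar):
        genome = simulate_genome(grammar, 1, 20_000, 0.2, seed=5)
        for inst in genome.truth:
            assert genome.instance_sequence(inst) == grammar.motifs[inst.motif_name].consensus

    def test_gc_fraction(self, grammar):
        genome = simulate_genome(grammar, 1, 100_000, 0.0, gc=0.6, seed=2)
        s = genome.contigs["syn1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.6) < 0.01

    def test_short_contig_rejected(self, grammar):
        with pytest.raises(ValueError):
            simulate_genome(grammar, 1, 500, 0.1, seed=1)


# ------------------------------------------------------------ oracle_occupancy
class TestOracleOccupancy:
    def _one_instance_genome(self, grammar, motif_name, seq_override=None, rng_seed=9):
        rng = np.random.default_rng(rng_seed)
        bg = random_sequence(3000, rng, gc=0.42)
        cons = seq_override or grammar.motifs[motif_name].consensus
        seq = bg[:1000] + cons + bg[1000 + len(cons):]
        inst = MotifInstance("c", 1000, 1000 + len(cons), "+", motif_name)
        return SyntheticGenome({"c": seq}, [inst]), inst

    def test_consensus_no_partner_equals_amplitude(self, grammar):
        genome, inst = self._one_instance_genome(grammar, "tead")
        occ = oracle_occupancy(grammar, genome, inst)
        assert occ == pytest.approx(grammar.motifs["tead"].amplitude)

    def test_soft_boost_closed_form(self, grammar):
        # boost = 1 + 3*exp(-d/40); at d=0 the boost is 4
        genome, inst = self._one_instance_genome(grammar, "tead")
        partner = MotifInstance("c", 1009, 1018, "+", "tfap2c")
        genome.contigs["c"] = (genome.contigs["c"][:1009] + "CCCTCAGGC"
                               + genome.contigs["c"][1018:])
        genome.truth.append(partner)
        occ = oracle_occupancy(grammar, genome, inst)
        assert occ == pytest.approx(4.0 * grammar.motifs["tead"].amplitude)

    def test_double_occupancy_is_kappa_times_sum(self, grammar):
        # independent brute force of the stated formula: kappa * (A + A)
        genome, inst = self._one_instance_genome(grammar, "tead_double")
        occ = oracle_occupancy(grammar, genome, inst)
        kappa = grammar.strict_rules[0].kappa
        A = grammar.motifs["tead"].amplitude
        assert occ == pytest.approx(kappa * (A + A))

    def test_unknown_motif_errors(self, grammar):
        genome, inst = self._one_instance_genome(grammar, "tead")
        bad = inst.copy(motif_name="nope")
        with pytest.raises(OracleError):
            oracle_occupancy(grammar, genome, bad)

    def test_mismatch_reduces_occupancy(self, grammar):
        genome, inst = self._one_instance_genome(grammar, "tead", seq_override="ACATTCCTT")
        occ = oracle_occupancy(grammar, genome, inst)
        assert 0 < occ < grammar.motifs["tead"].amplitude


# ----------------------------------------------------------- simulate_profiles
class TestSimulateProfiles:
    def test_background_only_mean(self):
        cfg = {"motifs": [{"name": "m", "consensus": "ACATTCCTG",
                           "task": "t", "amplitude": 0.0}]}
        g = make_grammar(cfg)
        genome = simulate_genome(g, 1, 200_000, 0.0, seed=1)
        profs = simulate_profiles(genome, g, depth=0.1, seed=2)
        p = profs["t"]["syn1"]
        for arr in (p.plus, p.minus):
            se = np.sqrt(0.1 / len(arr))
            assert abs(arr.mean() - 0.1) < 3 * se

    def test_reads_confined_to_kernel_support(self, grammar):
        genome = simulate_genome(grammar, 1, 2000, 0.0, seed=4)
        # plant one consensus manually
        seq = genome.contigs["syn1"]
        genome.contigs["syn1"] = seq[:1000] + "ACATTCCTG" + seq[1009:]
        genome.truth = [MotifInstance("syn1", 1000, 1009, "+", "tead")]
        annotate_occupancies(grammar, genome)
        profs = simulate_profiles(genome, grammar, depth=0.0, seed=5)
        p = profs["tead4"]["syn1"]
        support = np.zeros(2000, dtype=bool)
        support[1000 - 5 - 20:1000 - 5 + 21] = True   # plus kernel
        support[1008 + 5 - 20:1008 + 5 + 21] = True   # minus kernel
        assert p.plus[~support].sum() == 0
        assert p.minus[~support].sum() == 0

    def test_total_reads_poisson_concentration(self, grammar, small_genome):
        profs = simulate_profiles(small_genome, grammar, depth=0.05, seed=6)
        for task in ("tead4", "tfap2c"):
            expect = sum(i.occupancy for i in small_genome.truth
                         if grammar.motifs[i.motif_name].task == task)
            expect += 0.05 * sum(small_genome.contig_lengths().values()) * 2
            total = sum(p.total for p in profs[task].values())
            assert abs(total - expect) < 4 * np.sqrt(expect)

    def test_determinism(self, grammar, small_genome):
        a = simulate_profiles(small_genome, grammar, depth=0.05, seed=8)
        b = simulate_profiles(small_genome, grammar, depth=0.05, seed=8)
        for task in a:
            for contig in a[task]:
                assert np.array_equal(a[task][contig].plus, b[task][contig].plus)
                assert np.array_equal(a[task][contig].minus, b[task][contig].minus)

    def test_indirect_task_tracks_driver_expectation(self, grammar, small_genome):
        exp = expected_profiles(small_genome, grammar, depth=0.05)
        for contig in exp["yap1"]:
            assert np.allclose(exp["yap1"][contig].plus, exp["tead4"][contig].plus)

    def test_kernel_normalization(self, grammar):
        # each instance contributes expected reads equal to its occupancy
        genome = simulate_genome(grammar, 1, 5000, 0.0, seed=9)
        seq = genome.contigs["syn1"]
        genome.contigs["syn1"] = seq[:2000] + "ACATTCCTG" + seq[2009:]
        genome.truth = [MotifInstance("syn1", 2000, 2009, "+", "tead")]
        annotate_occupancies(grammar, genome)
        exp = expected_profiles(genome, grammar, depth=0.0)
        p = exp["tead4"]["syn1"]
        assert p.total == pytest.approx(genome.truth[0].occupancy, rel=1e-9)

    def test_strand_symmetry_of_expected_profiles(self, grammar):
        genome = simulate_genome(grammar, 1, 3000, 0.0, seed=10)
        seq = genome.contigs["syn1"]
        seq = seq[:1500] + "ACATTCCTG" + seq[1509:]
        genome.contigs["syn1"] = seq
        genome.truth = [MotifInstance("syn1", 1500, 1509, "+", "tead")]
        annotate_occupancies(grammar, genome)
        exp = expected_profiles(genome, grammar, depth=0.0)["tead4"]["syn1"]

        L = len(seq)
        mirrored = SyntheticGenome({"syn1": revcomp(seq)},
                                   [MotifInstance("syn1", L - 1509, L - 1500, "-", "tead")])
        annotate_occupancies(grammar, mirrored)
        exp_m = expected_profiles(mirrored, grammar, depth=0.0)["tead4"]["syn1"]
        assert np.allclose(exp_m.plus, exp.minus[::-1])
        assert np.allclose(exp_m.minus, exp.plus[::-1])

    def test_negative_binomial_option(self, grammar, small_genome):
        profs = simulate_profiles(small_genome, grammar, depth=0.05, seed=6, noise="nb")
        assert all((p.plus >= 0).all() for c in profs.values() for p in c.values())


# ------------------------------------------------------------ oracle_predictor
class TestOraclePredictor:
    def test_background_only_flat(self, grammar):
        pred = oracle_predictor(grammar, depth=0.1)
        # composition chosen to avoid near-consensus matches
        seq = "ACGT" * 100
        out = pred.predict(seq)
        plus, minus, total = out["tead4"]
        assert np.allclose(plus, 0.1) and np.allclose(minus, 0.1)
        assert total == pytest.approx(0.1 * 400 * 2)

    def test_single_consensus_window_counts(self, grammar, rng):
        pred = oracle_predictor(grammar, depth=0.01)
        bg = random_sequence(1000, rng)
        seq = bg[:500] + "ACATTCCTG" + bg[509:]
        base = pred.predict(bg)["tead4"][2]
        plus, minus, total = pred.predict(seq)["tead4"]
        win = slice(479, 529)  # 50 bp centered on the motif
        captured = plus[win].sum() + minus[win].sum()
        # closed form: most of A_t plus local background
        assert captured == pytest.approx(grammar.motifs["tead"].amplitude + 1.0, rel=0.12)
        assert total == pytest.approx(base + grammar.motifs["tead"].amplitude, rel=0.05)

    def test_deterministic(self, grammar, rng):
        pred = oracle_predictor(grammar)
        seq = random_sequence(800, rng)
        a = pred.predict(seq)
        b = pred.predict(seq)
        for task in a:
            assert np.array_equal(a[task][0], b[task][0])

    def test_non_acgt_rejected(self, grammar):
        pred = oracle_predictor(grammar)
        with pytest.raises(Exception):
            pred.predict("ACGTNACGT" * 50)

    def test_additivity_limit(self, additive_grammar, rng):
        # with c=0 and kappa=1 prediction of a two-motif sequence equals the
        # sum of single-motif predictions minus one background
        pred = oracle_predictor(additive_grammar, depth=0.02)
        bg = random_sequence(1000, rng)
        sA = bg[:300] + "ACATTCCTG" + bg[309:]
        sB = bg[:600] + "CCCTCAGGC" + bg[609:]
        sAB = sA[:600] + "CCCTCAGGC" + sA[609:]
        for task in ("tead4", "tfap2c"):
            a = pred.predict(sA)[task][2]
            b = pred.predict(sB)[task][2]
            ab = pred.predict(sAB)[task][2]
            o = pred.predict(bg)[task][2]
            assert ab == pytest.approx(a + b - o, abs=1e-9)

    def test_strict_pair_merged(self, grammar, rng):
        pred = oracle_predictor(grammar, depth=0.0)
        bg = random_sequence(1000, rng)
        dbl = grammar.motifs["tead_double"].consensus
        seq = bg[:500] + dbl + bg[500 + len(dbl):]
        total = pred.predict(seq)["tead4"][2]
        spurious = pred.predict(bg)["tead4"][2]
        assert total - spurious == pytest.approx(4 * 2 * 20.0, rel=1e-6)
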