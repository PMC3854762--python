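import numpy as np
import pandas as pd
import pytest

from ccdock.config import Config
from ccdock.environment import (Environment, false_positives_at,
                                interaction_rank, ir_distribution,
                                rank_recovery_table, sample_environments,
                                signature)
from ccdock.synth import make_planted_nii


def matrix(values, labels):
    return pd.DataFrame(np.asarray(values, dtype=float),
                        index=labels, columns=labels)


class TestInteractionRank:
    def test_strict_maximum_gives_rank_one(self):
        m = matrix([[0, 0.9, 0.1, 0.2],
                    [0.9, 0, 0.3, 0.1],
                    [0.1, 0.3, 0, 0.4],
                    [0.2, 0.1, 0.4, 0]], list("abcd"))
        assert interaction_rank(m, ("a", "b")) == 1

    def test_minimum_in_both_rows_gives_scope_size(self):
        m = matrix([[0.5, 0.01, 0.6, 0.7],
                    [0.01, 0.5, 0.8, 0.9],
                    [0.6, 0.8, 0.5, 0.2],
                    [0.7, 0.9, 0.2, 0.5]], list("abcd"))
        assert interaction_rank(m, ("a", "b")) == 4

    def test_best_of_two_rows(self):
        # pair (a, b): rank 3 in row a, rank 1 in row b -> 1
        m = matrix([[0, 0.2, 0.5, 0.9],
                    [0.9, 0, 0.3, 0.1],
                    [0.5, 0.3, 0, 0.4],
                    [0.9, 0.1, 0.4, 0]], list("abcd"))
        assert interaction_rank(m, ("a", "b")) == 1

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(8)
        labels = [f"p{i}" for i in range(4)]
        v = rng.uniform(0, 1, (4, 4))
        m = matrix(v, labels)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                r1 = 1 + sum(v[i, k] > v[i, j] for k in range(4))
                r2 = 1 + sum(v[j, k] > v[j, i] for k in range(4))
                assert interaction_rank(m, (labels[i], labels[j])) == min(r1, r2)

    def test_masked_entry_raises(self):
        m = matrix([[0, np.nan], [np.nan, 0]], list("ab"))
        with pytest.raises(ValueError):
            interaction_rank(m, ("a", "b"))

    def test_rank_bounds(self):
        rng = np.random.default_rng(1)
        labels = [f"p{i}" for i in range(6)]
        m = matrix(rng.uniform(0, 1, (6, 6)), labels)
        for scope_n in (2, 4, 6):
            scope = labels[:scope_n]
            r = interaction_rank(m, (labels[0], labels[1]), scope)
            assert 1 <= r <= scope_n


class TestSampleEnvironments:
    complexes = [(f"r{i}", f"l{i}") for i in range(25)]

    def test_sizes_and_target_membership(self):
        envs = sample_environments(self.complexes, self.complexes[0],
                                   n_sets=10, n_complexes=20, seed=0)
        assert len(envs) == 10
        for e in envs:
            assert len(e.complexes) == 20
            assert len(e.proteins) == 40
            assert e.target in e.complexes

    def test_single_complex_environment(self):
        envs = sample_environments(self.complexes, self.complexes[3],
                                   n_sets=2, n_complexes=1, seed=0)
        assert all(e.complexes == [self.complexes[3]] for e in envs)

    def test_deterministic_in_seed(self):
        a = sample_environments(self.complexes, self.complexes[0],
                                n_sets=5, n_complexes=10, seed=42)
        b = sample_environments(self.complexes, self.complexes[0],
                                n_sets=5, n_complexes=10, seed=42)
        assert [e.complexes for e in a] == [e.complexes for e in b]

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            sample_environments(self.complexes[:3], self.complexes[0],
                                n_sets=1, n_complexes=10, seed=0)

    def test_environment_must_contain_target(self):
        with pytest.raises(ValueError):
            Environment([("r1", "l1")], ("r2", "l2"))


class TestIRDistribution:
    def test_arithmetic(self):
        # hand-planted ranks {1, 2, 3} -> mean 2, population sd sqrt(2/3)
        ranks = np.array([1.0, 2.0, 3.0])
        assert ranks.mean() == 2.0
        assert ranks.std() == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_rank_zero_sd(self):
        nii, bench = make_planted_nii(8, noise=0.0, seed=0)
        target = bench.pairs[0]
        envs = sample_environments(bench.pairs, target, n_sets=5,
                                   n_complexes=4, seed=1)
        mean_ir, sd_ir, ranks, aucs = ir_distribution(nii, target, envs)
        assert sd_ir == 0.0
        assert mean_ir == 1.0

    def test_target_only_environment(self):
        nii, bench = make_planted_nii(6, noise=0.02, seed=3)
        target = bench.pairs[2]
        envs = sample_environments(bench.pairs, target, n_sets=3,
                                   n_complexes=1, seed=1)
        mean_ir, _, _, _ = ir_distribution(nii, target, envs)
        assert mean_ir == 1.0


class TestSignature:
    def test_three_population_recovery(self):
        nii, bench = make_planted_nii(20, noise=0.03, seed=5,
                                      promiscuous="C004_r", inert="C009_l")
        query = bench.pairs[0][0]
        cfg = Config(label_t_low=5, label_t_high_margin=10, label_s_stable=5)
        sigs = signature(query, ["C000_l", "C004_r", "C009_l"], nii,
                         bench.pairs, seed=2, n_sets=10, n_complexes=10,
                         config=cfg)
        by = {s.candidate: s for s in sigs}
        assert by["C000_l"].label == "strong_competitor"   # native partner
        assert by["C004_r"].label == "strong_competitor"   # promiscuous plant
        assert by["C009_l"].label == "never_competes"      # inert plant

    def test_false_positive_counting(self):
        nii, bench = make_planted_nii(20, noise=0.03, seed=5,
                                      promiscuous="C004_r")
        query = bench.pairs[0][0]
        sigs = signature(query, ["C000_l", "C004_r", "C009_l"], nii,
                         bench.pairs, seed=2, n_sets=5, n_complexes=10)
        fp = false_positives_at(query, sigs, "C000_l", ir_threshold=3.0)
        assert fp == 1  # only the promiscuous plant competes

    def test_threshold_above_max_counts_all(self):
        nii, bench = make_planted_nii(12, noise=0.03, seed=6)
        query = bench.pairs[0][0]
        cands = ["C000_l", "C003_r", "C005_l"]
        sigs = signature(query, cands, nii, bench.pairs, seed=2,
                         n_sets=3, n_complexes=6)
        assert false_positives_at(query, sigs, "C000_l",
                                  ir_threshold=1e9) == 2


class TestRankRecovery:
    def test_perfect_matrix_recovers_everyone(self):
        nii, bench = make_planted_nii(10, noise=0.0, seed=0)
        t = rank_recovery_table(nii, bench.pairs)
        assert (t["count"] == 20).all()

    def test_native_always_last(self):
        labels = [f"p{i}" for i in range(6)]
        v = np.full((6, 6), 0.5)
        pairs = [("p0", "p1"), ("p2", "p3"), ("p4", "p5")]
        for a, b in pairs:
            i, j = labels.index(a), labels.index(b)
            v[i, j] = v[j, i] = 0.01
        m = matrix(v, labels)
        t = rank_recovery_table(m, pairs, fractions=(0.1, 0.5, 1.0))
        assert t.iloc[0]["count"] == 0
        assert t.iloc[-1]["count"] == 6

    def test_hand_tallied_counts(self):
        # 10 proteins; native ranks planted per protein via row values
        nii, bench = make_planted_nii(5, noise=0.0, seed=0)
        t = rank_recovery_table(nii, bench.pairs, fractions=(0.01, 0.2, 0.5))
        # noise-free plant: every native pair is rank 1
        assert t["top"].tolist() == [1, 2, 5]
        assert t["count"].tolist() == [10, 10, 10]

    def test_counts_monotone(self):
        nii, bench = make_planted_nii(8, noise=0.3, seed=9)
        t = rank_recovery_table(nii, bench.pairs)
        assert t["count"].is_monotonic_increasing
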