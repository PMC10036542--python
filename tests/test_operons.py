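"""Operon pair voting, chaining, operon values, and profile clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bactgrn.io import Gene, GenomeAnnotation
from bactgrn.operons import (
    N_DETECTORS, OperonCall, OperonDetectorConfig, PairCall, chain_operons,
    cluster_operons, detect_operon_pairs, operon_values, pair_f1,
)
from bactgrn.synth import ARCHETYPES


def two_gene_annotation(gap=50, strand2="+"):
    return GenomeAnnotation([
        Gene("c", 100, 600, "g1", "+"),
        Gene("c", 600 + gap, 1100 + gap, "g2", strand2),
    ])


def expr_means(profiles):
    return pd.DataFrame(profiles, columns=["control", "t1", "t2", "t3", "t4"]).T.T


class TestPairVoting:
    def test_flat_identical_coverage_gets_all_votes(self):
        ann = two_gene_annotation(gap=50)
        cov = {"s1": np.full(1300, 20.0)}
        means = pd.DataFrame(
            [[10, 20, 30, 20, 10], [11, 22, 33, 22, 11]],
            index=["g1", "g2"], columns=list("abcde"),
        )
        calls = detect_operon_pairs(cov, ann, means)
        assert len(calls) == 1
        assert calls[0].n_votes == N_DETECTORS

    def test_opposite_strands_not_a_candidate(self):
        ann = two_gene_annotation(strand2="-")
        cov = {"s1": np.full(1300, 20.0)}
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5]] * 2, index=["g1", "g2"], columns=list("abcde")
        )
        assert detect_operon_pairs(cov, ann, means) == []

    def test_uncovered_wide_gap_fails_the_vote(self):
        """Well-covered genes separated by a silent 200 bp gap with
        uncorrelated dynamics collect at most two votes."""
        ann = two_gene_annotation(gap=200)
        rng = np.random.default_rng(0)
        cov = np.zeros(1400)
        cov[100:600] = 30 + rng.normal(0, 1, 500)
        cov[800:1300] = 28 + rng.normal(0, 1, 500)
        means = pd.DataFrame(
            [[10, 20, 5, 30, 2], [20, 5, 30, 2, 10]],
            index=["g1", "g2"], columns=list("abcde"),
        )
        calls = detect_operon_pairs({"s": cov}, ann, means)
        assert calls[0].n_votes <= 2
        # the specific detectors that must fail: gap distance, homogeneity,
        # gap coverage, sliding window
        v = calls[0].votes
        assert v[0] == 0 and v[2] == 0 and v[4] == 0

    def test_votes_invariant_to_sample_ordering(self):
        ann = two_gene_annotation()
        rng = np.random.default_rng(5)
        t1 = 20 + rng.normal(0, 2, 1300)
        t2 = 40 + rng.normal(0, 2, 1300)
        means = pd.DataFrame(
            [[10, 20, 30, 20, 10]] * 2, index=["g1", "g2"], columns=list("abcde")
        )
        a = detect_operon_pairs({"x": t1, "y": t2}, ann, means)
        b = detect_operon_pairs({"y": t2, "x": t1}, ann, means)
        assert [c.votes for c in a] == [c.votes for c in b]


class TestChaining:
    def ann(self, n):
        genes = [Gene("c", 1000 * i, 1000 * i + 800, f"g{i+1}", "+") for i in range(n)]
        return GenomeAnnotation(genes)

    def call(self, g1, g2, positive=True):
        votes = (1, 1, 1, 1, 0, 0) if positive else (1, 0, 0, 0, 0, 0)
        return PairCall(g1, g2, votes)

    def test_transitive_chain(self):
        calls = [self.call("g1", "g2"), self.call("g2", "g3")]
        ops = chain_operons(calls, self.ann(3))
        assert [op.members for op in ops] == [("g1", "g2", "g3")]

    def test_broken_chain_splits(self):
        calls = [
            self.call("g1", "g2"), self.call("g2", "g3", positive=False),
            self.call("g3", "g4"),
        ]
        ops = chain_operons(calls, self.ann(4))
        assert [op.members for op in ops] == [("g1", "g2"), ("g3", "g4")]

    def test_genes_in_at_most_one_operon(self, dataset0, matrix0):
        calls = detect_operon_pairs(
            dataset0.coverage, dataset0.annotation, matrix0.timepoint_means()
        )
        ops = chain_operons(calls, dataset0.annotation)
        members = [g for op in ops for g in op.members]
        assert len(members) == len(set(members))


class TestOperonValues:
    def test_mean_of_two(self):
        z = pd.DataFrame(
            [[1.0, 0.0], [3.0, 2.0]], index=["a", "b"], columns=["t0", "t1"]
        )
        prof = operon_values([OperonCall(("a", "b"), (6,))], z)
        assert prof.iloc[0].tolist() == [2.0, 1.0]

    def test_identical_members_reproduce_profile(self):
        z = pd.DataFrame(
            [[0.5, -0.5, 1.5]] * 3, index=["a", "b", "c"], columns=["t0", "t1", "t2"]
        )
        prof = operon_values([OperonCall(("a", "b", "c"), (5, 4))], z)
        assert np.allclose(prof.iloc[0], [0.5, -0.5, 1.5])

    def test_matches_tabular_recomputation(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(12)]
        z = pd.DataFrame(rng.normal(size=(12, 5)), index=genes,
                         columns=[f"t{j}" for j in range(5)])
        ops = [OperonCall(tuple(genes[0:4]), (3, 4, 5)),
               OperonCall(tuple(genes[6:9]), (6, 6))]
        prof = operon_values(ops, z)
        # independent recomputation through a melted long-format table
        long = z.reset_index().melt(id_vars="index", var_name="t")
        for row, op in zip(prof.index, ops):
            sub = long[long["index"].isin(op.members)]
            expected = sub.groupby("t")["value"].mean()
            for t in z.columns:
                assert prof.at[row, t] == pytest.approx(expected[t])

    def test_linearity_in_member_zscores(self):
        z = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                         columns=["t0", "t1"])
        op = [OperonCall(("a", "b"), (4,))]
        assert np.allclose(operon_values(op, 3 * z), 3 * operon_values(op, z))

    def test_missing_member_is_an_error(self):
        z = pd.DataFrame([[1.0]], index=["a"], columns=["t0"])
        with pytest.raises(KeyError):
            operon_values([OperonCall(("a", "ghost"), (4,))], z)


class TestClusterOperons:
    def archetype_profiles(self, rng, copies=10, noise=0.05):
        rows, labels = [], []
        for i, pattern in enumerate(ARCHETYPES.values()):
            base = np.array(pattern)
            sd = base.std() or 1.0
            zbase = (base - base.mean()) / sd
            for _ in range(copies):
                rows.append(zbase + rng.normal(0, noise, size=5))
                labels.append(i)
        cols = ["control", "t1", "t2", "t3", "t4"]
        return pd.DataFrame(rows, columns=cols), labels

    def test_recovers_planted_archetypes(self):
        rng = np.random.default_rng(21)
        profiles, truth = self.archetype_profiles(rng)
        labels, centroids = cluster_operons(profiles, k=6, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert centroids.shape == (6, 5)

    def test_k_equals_n_gives_singletons(self):
        prof = pd.DataFrame(np.eye(4), columns=list("abcd"))
        labels, _ = cluster_operons(prof, k=4, seed=1)
        assert labels.nunique() == 4

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(30, 5)))
        l1, _ = cluster_operons(prof, k=6, seed=5)
        l2, _ = cluster_operons(prof, k=6, seed=5)
        assert (l1 == l2).all()

    def test_too_few_profiles_rejected(self):
        with pytest.raises(ValueError):
            cluster_operons(pd.DataFrame(np.eye(3)), k=6)


class TestPlantedOperons:
    def test_pairwise_f1_against_truth(self, dataset0, matrix0):
        calls = detect_operon_pairs(
            dataset0.coverage, dataset0.annotation, matrix0.timepoint_means()
        )
        assert pair_f1(calls, dataset0.truth.operon_pairs()) >= 0.9

    def test_gene_fraction_in_operons_near_planted(self, dataset0, matrix0):
        calls = detect_operon_pairs(
            dataset0.coverage, dataset0.annotation, matrix0.timepoint_means()
        )
        ops = chain_operons(calls, dataset0.annotation)
        called = {g for op in ops for g in op.members}
        planted = {g for op in dataset0.truth.true_operons for g in op}
        frac_called = len(called) / len(dataset0.annotation)
        frac_planted = len(planted) / len(dataset0.annotation)
        assert abs(frac_called - frac_planted) <= 0.10
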