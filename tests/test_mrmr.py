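"""Discretization, plug-in mutual information and the greedy mRMR ranking.

The ranking oracle is an independent brute-force greedy that re-derives every
mutual information from scratch at every step with the scalar
``mutual_information`` function.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissueclf import (
    ExpressionMatrix,
    SampleLabels,
    ValidationError,
    discretize_expression,
    mutual_information,
    rank_features_mrmr,
    read_ranked_list,
    write_ranked_list,
)
from tissueclf.mrmr import DiscretizedMatrix


def matrix_from_rows(rows, prefix="G"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return ExpressionMatrix(
        pd.DataFrame(
            rows,
            index=pd.Index([f"{prefix}{i}" for i in range(rows.shape[0])], name="Name"),
            columns=[f"S{i}" for i in range(rows.shape[1])],
        )
    )


class TestDiscretization:
    def test_outlier_maps_to_high_state(self):
        # values (0,0,0,100): mu=25, sigma=43.30; only 100 exceeds mu+sigma,
        # and 0 < mu-sigma is false (mu-sigma = -18.3), so rest are state 0
        disc = discretize_expression(matrix_from_rows([0, 0, 0, 100]), alpha=1.0)
        assert disc.states.tolist() == [[0, 0, 0, 1]]
        mu, sigma = 25.0, np.std([0, 0, 0, 100.0])
        assert disc.thresholds[0, 0] == pytest.approx(mu - sigma)
        assert disc.thresholds[0, 1] == pytest.approx(mu + sigma)

    def test_hand_computed_three_states(self):
        # mu=3, sigma=sqrt(2): 1 < 3-1.41, 5 > 3+1.41, middle stays 0
        disc = discretize_expression(matrix_from_rows([1, 3, 3, 3, 5]), alpha=1.0)
        assert disc.states.tolist() == [[-1, 0, 0, 0, 1]]

    def test_constant_gene_all_zero_states(self):
        disc = discretize_expression(matrix_from_rows([7, 7, 7, 7]))
        assert (disc.states == 0).all()

    def test_huge_alpha_collapses_to_zero_state(self):
        rng = np.random.default_rng(0)
        disc = discretize_expression(matrix_from_rows(rng.gamma(2, 2, 50)), alpha=1e9)
        assert (disc.states == 0).all()


class TestMutualInformation:
    def test_constant_x_gives_zero(self):
        assert mutual_information(["a"] * 10, list("abababababa"[:10])) == 0.0

    def test_identical_uniform_binary_is_one_bit(self):
        x = ["a", "b"] * 50
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_plug_in_sum_on_fixed_joint_table(self):
        # counts: (a,u)=4 (a,v)=1 (b,u)=1 (b,v)=4 over 10 samples
        x = list("aaaaabbbbb")
        y = list("uuuuvuvvvv")
        expected = 0.0
        counts = {("a", "u"): 4, ("a", "v"): 1, ("b", "u"): 1, ("b", "v"): 4}
        for (xi, yi), c in counts.items():
            pxy = c / 10
            px = sum(v for k, v in counts.items() if k[0] == xi) / 10
            py = sum(v for k, v in counts.items() if k[1] == yi) / 10
            expected += pxy * math.log2(pxy / (px * py))
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mutual_information([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetric_and_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        x = rng.integers(-1, 2, size=n)
        y = rng.integers(-1, 2, size=n)
        mi = mutual_information(x, y)
        assert mi >= 0.0
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)

    def test_equals_marginal_entropy_when_identical(self):
        rng = np.random.default_rng(13)
        x = rng.choice(["a", "b", "c"], size=300, p=[0.5, 0.3, 0.2])
        _, counts = np.unique(x, return_counts=True)
        p = counts / counts.sum()
        entropy = -(p * np.log2(p)).sum()
        assert mutual_information(x, x) == pytest.approx(entropy, abs=1e-12)


def brute_force_mrmr(states, class_labels, gene_ids, criterion="MID"):
    """Reference greedy: recompute every MI from scratch at every step."""
    n_genes = len(gene_ids)
    relevance = [mutual_information(states[g], class_labels) for g in range(n_genes)]
    order = [int(np.argmax(relevance))]
    while len(order) < n_genes:
        best_gene, best_score = None, -np.inf
        for g in range(n_genes):
            if g in order:
                continue
            red = np.mean([mutual_information(states[g], states[s]) for s in order])
            if criterion == "MID":
                score = relevance[g] - red
            else:
                score = relevance[g] / max(red, 1e-12)
            if score > best_score:  # strict: ties keep the earlier gene
                best_gene, best_score = g, score
        order.append(best_gene)
    return [gene_ids[g] for g in order]


def _disc_from_states(states):
    states = np.asarray(states, dtype=np.int8)
    n_genes, n_samples = states.shape
    return DiscretizedMatrix(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        sample_ids=[f"S{i}" for i in range(n_samples)],
        states=states,
        thresholds=np.tile([-0.5, 0.5], (n_genes, 1)),
    )


def _labels_for(sample_ids, class_labels):
    return SampleLabels(dict(zip(sample_ids, class_labels)))


class TestMRMRRanking:
    @pytest.mark.parametrize("criterion", ["MID", "MIQ"])
    def test_matches_brute_force_greedy(self, criterion):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n_genes = int(rng.integers(3, 11))
            states = rng.integers(-1, 2, size=(n_genes, 60))
            classes = [f"C{j}" for j in rng.integers(0, 3, size=60)]
            classes[:3] = ["C0", "C1", "C2"]
            disc = _disc_from_states(states)
            labels = _labels_for(disc.sample_ids, classes)
            ranked = rank_features_mrmr(disc, labels, criterion=criterion)
            expected = brute_force_mrmr(states, classes, disc.gene_ids, criterion)
            assert ranked.gene_ids == expected

    def test_single_gene_scored_by_relevance(self):
        states = np.array([[-1, -1, 1, 1]])
        disc = _disc_from_states(states)
        labels = _labels_for(disc.sample_ids, ["A", "A", "B", "B"])
        ranked = rank_features_mrmr(disc, labels)
        assert ranked.gene_ids == ["G0"]
        assert ranked.scores[0] == pytest.approx(1.0)  # MI = 1 bit

    def test_planted_label_copy_ranks_first(self):
        rng = np.random.default_rng(15)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            classes = list(rng.integers(0, 3, size=90))
            planted = np.array(classes) - 1  # states mirror the label
            noise = rng.integers(-1, 2, size=(20, 90))
            states = np.vstack([noise[:10], planted, noise[10:]])
            disc = _disc_from_states(states)
            labels = _labels_for(disc.sample_ids, [f"C{c}" for c in classes])
            ranked = rank_features_mrmr(disc, labels)
            assert ranked.gene_ids[0] == "G10"

    def test_output_is_permutation_and_deterministic(self):
        rng = np.random.default_rng(16)
        states = rng.integers(-1, 2, size=(12, 40))
        disc = _disc_from_states(states)
        labels = _labels_for(disc.sample_ids, ["A"] * 20 + ["B"] * 20)
        first = rank_features_mrmr(disc, labels)
        second = rank_features_mrmr(disc, labels)
        assert sorted(first.gene_ids) == sorted(disc.gene_ids)
        assert first.gene_ids == second.gene_ids

    def test_duplicated_gene_not_ranked_directly_after_twin(self):
        # G2 copies the class exactly (top relevance); G0 == G1 are noisy
        # views of the class, so the twin's redundancy with its copy exceeds
        # its relevance and a weaker but less redundant gene (G3) outranks it
        rng = np.random.default_rng(17)
        classes = rng.integers(0, 3, size=120)
        noisy = np.where(classes == 0, -1, 1)
        flips = rng.random(120) < 0.15
        noisy = np.where(flips, -noisy, noisy)
        exact = classes - 1
        weak = np.where(classes == 2, 1, -1)
        weak = np.where(rng.random(120) < 0.3, 0, weak)
        states = np.vstack([noisy, noisy, exact, weak])
        disc = _disc_from_states(states)
        labels = _labels_for(disc.sample_ids, [f"C{c}" for c in classes])
        ranked = rank_features_mrmr(disc, labels)
        assert ranked.gene_ids[0] == "G2"
        assert ranked.gene_ids[1] == "G0"
        # twin G1 must not come straight after its duplicate
        assert ranked.gene_ids[2] != "G1"

    def test_single_class_rejected(self):
        disc = _disc_from_states(np.array([[1, -1, 0]]))
        labels = _labels_for(disc.sample_ids, ["A", "A", "A"])
        with pytest.raises(ValidationError, match="two tissue classes"):
            rank_features_mrmr(disc, labels)

    def test_first_gene_always_argmax_relevance(self, small_planted):
        disc = discretize_expression(small_planted.matrix)
        ranked = rank_features_mrmr(disc, small_planted.labels, top_n=5)
        tags = small_planted.labels.for_samples(disc.sample_ids)
        relevance = [
            mutual_information(disc.states[i], tags) for i in range(len(disc.gene_ids))
        ]
        assert ranked.gene_ids[0] == disc.gene_ids[int(np.argmax(relevance))]


def test_ranked_list_round_trip(tmp_path):
    rng = np.random.default_rng(18)
    states = rng.integers(-1, 2, size=(6, 30))
    disc = _disc_from_states(states)
    labels = _labels_for(disc.sample_ids, ["A"] * 15 + ["B"] * 15)
    ranked = rank_features_mrmr(disc, labels)
    path = tmp_path / "ranked.tsv"
    write_ranked_list(ranked, path)
    back = read_ranked_list(path)
    assert back.gene_ids == ranked.gene_ids
    assert np.allclose(back.scores, ranked.scores)
    assert back.criterion == ranked.criterion
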