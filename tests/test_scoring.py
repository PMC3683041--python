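"""Sufficient statistics, CPD estimation and hyperedge weights."""

import math

import numpy as np
import pytest

from diprog.hypercore import HyperDAG, HyperEdge
from diprog.scoring import (
    DataMatrix,
    constrain_cpd,
    count,
    edge_bic_weight,
    edge_loglik_weight,
    fit_cpds,
    ml_cpd,
    network_score,
)
from diprog.simulate import random_network, sample_data

from conftest import random_binary_data


def direct_joint_loglik(D, parent_sets, flavor, epsilon):
    """Independent row-by-row oracle for the joint log-likelihood.

    Estimates every conditional by literal row counting (no shared code
    with the vectorized scoring path), applies the flavor cap, and sums
    log-probabilities observation by observation.
    """
    X = D.values
    total = 0.0
    for row in X:
        for v in range(D.n):
            pa = parent_sets.get(v, ())
            sel = np.ones(len(X), dtype=bool)
            for p in pa:
                sel &= X[:, p] == row[p]
            denom = sel.sum()
            theta = (X[sel, v] == 1).sum() / denom
            if pa:
                if flavor == "monotone" and not all(row[p] == 1 for p in pa):
                    theta = min(theta, epsilon)
                if flavor == "semimonotone" and all(row[p] == 0 for p in pa):
                    theta = min(theta, epsilon)
            p_obs = theta if row[v] == 1 else 1.0 - theta
            total += math.log(p_obs)
    return total


class TestCount:
    def test_direct_count(self):
        D = DataMatrix([[1, 1], [1, 0], [0, 0]])
        assert count(D, {0: 1}) == 2

    def test_empty_assignment_counts_all_rows(self):
        D = DataMatrix([[1, 1], [1, 0], [0, 0]])
        assert count(D, {}) == 3

    def test_partition_identity(self, rng):
        D = random_binary_data(rng, 50, 3)
        assert count(D, {1: 0}) + count(D, {1: 1}) == D.m

    def test_unknown_variable(self):
        D = DataMatrix([[0]])
        with pytest.raises(KeyError):
            count(D, {"nope": 1})


class TestMlCpd:
    def test_ratio(self):
        col_pa = [1] * 10 + [0] * 5
        col_ch = [1] * 7 + [0] * 3 + [0] * 5
        D = DataMatrix(np.column_stack([col_ch, col_pa]))
        cpd = ml_cpd(D, 0, [1])
        assert cpd.prob[1] == pytest.approx(0.7)

    def test_child_identically_zero(self, rng):
        X = random_binary_data(rng, 30, 2).values.copy()
        X[:, 0] = 0
        cpd = ml_cpd(DataMatrix(X), 0, [1])
        assert (cpd.prob[cpd.observed] == 0).all()

    def test_marginal_when_parentless(self):
        D = DataMatrix([[1], [1], [0], [0], [0]])
        cpd = ml_cpd(D, 0)
        assert cpd.n_rows == 1
        assert cpd.prob[0] == pytest.approx(2 / 5)

    def test_unobserved_assignment_flagged(self):
        D = DataMatrix([[1, 1, 1], [0, 1, 1]])  # parents never (0,0),(0,1),(1,0)
        cpd = ml_cpd(D, 0, [1, 2])
        assert list(cpd.observed) == [False, False, False, True]
        assert cpd.prob[3] == pytest.approx(0.5)


class TestConstrainCpd:
    @pytest.fixture
    def base(self):
        return ml_cpd(
            DataMatrix(
                np.array(
                    [
                        # child, p1, p2 blocks engineered to give .5/.5/.5/.9
                        *[[1, 0, 0]] * 5, *[[0, 0, 0]] * 5,
                        *[[1, 1, 0]] * 5, *[[0, 1, 0]] * 5,
                        *[[1, 0, 1]] * 5, *[[0, 0, 1]] * 5,
                        *[[1, 1, 1]] * 9, *[[0, 1, 1]] * 1,
                    ]
                )
            ),
            0,
            [1, 2],
        )

    def test_monotone_caps_all_but_all_ones(self, base):
        capped = constrain_cpd(base, "monotone", 0.2)
        assert list(capped.prob) == pytest.approx([0.2, 0.2, 0.2, 0.9])
        assert capped.prob[:-1].max() <= 0.2

    def test_semimonotone_caps_only_all_zeros(self, base):
        capped = constrain_cpd(base, "semimonotone", 0.2)
        assert list(capped.prob) == pytest.approx([0.2, 0.5, 0.5, 0.9])

    def test_epsilon_one_is_inactive(self, base):
        assert list(constrain_cpd(base, "monotone", 1.0).prob) == list(base.prob)

    def test_general_unchanged(self, base):
        assert constrain_cpd(base, "general", 0.2) is base

    def test_nonpositive_epsilon_rejected(self, base):
        with pytest.raises(ValueError, match="epsilon"):
            constrain_cpd(base, "monotone", 0.0)

    def test_cap_is_min_not_overwrite(self):
        D = DataMatrix([[0, 0]] * 99 + [[1, 0]] + [[1, 1]] * 10)
        cpd = ml_cpd(D, 0, [1])  # theta(0) = 0.01 < eps
        capped = constrain_cpd(cpd, "monotone", 0.2)
        assert capped.prob[0] == pytest.approx(0.01)

    def test_parentless_cpd_never_capped(self):
        D = DataMatrix([[1], [1], [1], [0]])
        cpd = ml_cpd(D, 0)
        for flavor in ("monotone", "semimonotone"):
            assert constrain_cpd(cpd, flavor, 0.2).prob[0] == pytest.approx(0.75)


class TestEdgeWeights:
    def test_deterministic_edge_has_zero_weight(self, rng):
        pa = (rng.random(200) < 0.5).astype(int)
        D = DataMatrix(np.column_stack([pa, pa]))
        w = edge_loglik_weight(D, HyperEdge(0, [1]), "general")
        assert w == pytest.approx(0.0)

    def test_marginal_weight_formula(self):
        m, k = 100, 30
        D = DataMatrix(np.array([[1]] * k + [[0]] * (m - k)))
        w = edge_loglik_weight(D, HyperEdge(0))
        expected = k * math.log(k / m) + (m - k) * math.log(1 - k / m)
        assert w == pytest.approx(expected, rel=1e-12)

    def test_weight_is_negative_conditional_entropy(self, rng):
        """w(e) = -m * H(child | parents) in nats, general flavor."""
        D = random_binary_data(rng, 300, 4)
        X = D.values
        edge = HyperEdge(0, [1, 2])
        # independent entropy computation from the empirical joint
        H_cond = 0.0
        for u in range(4):
            sel = (X[:, 1] == (u & 1)) & (X[:, 2] == (u >> 1))
            nu = sel.sum()
            if nu == 0:
                continue
            for x in (0, 1):
                nx = ((X[:, 0] == x) & sel).sum()
                if nx:
                    H_cond -= (nx / len(X)) * math.log(nx / nu)
        w = edge_loglik_weight(D, edge, "general")
        assert w == pytest.approx(-len(X) * H_cond, rel=1e-9)

    def test_weight_nonpositive_and_finite(self, rng):
        D = random_binary_data(rng, 100, 5)
        for seed in range(20):
            r = np.random.default_rng(seed)
            child = int(r.integers(5))
            others = [v for v in range(5) if v != child]
            pa = r.choice(others, size=int(r.integers(0, 3)), replace=False)
            for flavor in ("monotone", "semimonotone", "general"):
                w = edge_loglik_weight(D, HyperEdge(child, pa), flavor, 0.2)
                assert np.isfinite(w) and w <= 1e-12

    def test_general_weight_at_least_monotone(self, rng):
        D = random_binary_data(rng, 150, 4)
        for child in range(4):
            pa = [v for v in range(4) if v != child][:2]
            e = HyperEdge(child, pa)
            assert edge_loglik_weight(D, e, "general") >= edge_loglik_weight(
                D, e, "monotone", 0.2
            ) - 1e-12

    def test_bic_penalty_arithmetic(self):
        m = round(math.e ** 2)  # log m ~ 2 -> penalty ~ 1 for a parentless edge
        D = DataMatrix(np.array([[1], [0]] * (m // 2) + [[1]] * (m % 2)))
        w = edge_loglik_weight(D, HyperEdge(0))
        b = edge_bic_weight(D, HyperEdge(0))
        assert b == pytest.approx(w - 0.5 * math.log(m) * 1)

    def test_bic_penalty_scales_with_parent_count(self, rng):
        D = random_binary_data(rng, 128, 3)
        e2, e0 = HyperEdge(0, [1, 2]), HyperEdge(0)
        gap = (edge_bic_weight(D, e2) - edge_loglik_weight(D, e2)) - (
            edge_bic_weight(D, e0) - edge_loglik_weight(D, e0)
        )
        assert gap == pytest.approx(-0.5 * math.log(D.m) * 3)

    def test_bic_penalty_vanishes_per_sample(self):
        net = random_network(4, 2, "general", 0.2, seed=5)
        gaps = []
        for m in (100, 10000):
            D = sample_data(net, m, seed=6)
            e = HyperEdge(0, tuple(v for v in range(1, 3)))
            gaps.append(
                (edge_loglik_weight(D, e) - edge_bic_weight(D, e)) / m
            )
        assert gaps[1] < gaps[0]


class TestNetworkScore:
    @pytest.mark.parametrize("flavor", ["general", "monotone", "semimonotone"])
    def test_decomposability_matches_direct_joint_loglik(self, flavor):
        for seed in range(6):
            net = random_network(5, 3, flavor, 0.2, seed=seed)
            D = sample_data(net, 150, seed=seed + 100)
            H = net.hyperdag
            score = network_score(D, H, "loglik", flavor, 0.2)
            oracle = direct_joint_loglik(D, H.parent_sets(), flavor, 0.2)
            assert score == pytest.approx(oracle, rel=1e-9)

    def test_decomposed_score_equals_stored_cpd_loglik(self, rng):
        D = random_binary_data(rng, 120, 4)
        H = HyperDAG(4, [HyperEdge(0), HyperEdge(1, [0]),
                         HyperEdge(2, [0, 1]), HyperEdge(3)])
        net = fit_cpds(D, H, "monotone", 0.2)
        assert network_score(D, net, "loglik") == pytest.approx(
            net.loglik(D), rel=1e-12
        )

    def test_single_vertex_network_scores_marginal(self):
        D = DataMatrix([[1], [0], [0]])
        H = HyperDAG(1, [HyperEdge(0)])
        expected = math.log(1 / 3) + 2 * math.log(2 / 3)
        assert network_score(D, H, "loglik") == pytest.approx(expected)

    def test_adding_parent_never_decreases_loglik(self, rng):
        D = random_binary_data(rng, 200, 4)
        for child in range(4):
            others = [v for v in range(4) if v != child]
            w_prev = edge_loglik_weight(D, HyperEdge(child), "general")
            for size in (1, 2, 3):
                w = edge_loglik_weight(
                    D, HyperEdge(child, others[:size]), "general"
                )
                assert w >= w_prev - 1e-9
                w_prev = w
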