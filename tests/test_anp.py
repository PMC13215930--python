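"""ANP: priorities, consistency gate, supermatrix stages, limit, weights.

Eigenvector results are checked against closed forms (2x2, uniform) and a
brute-force power-iteration oracle run to 1e-14; limits against absorbing-
chain and periodic-chain closed forms.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ismanp import anp
from ismanp.synthetic import (
    JudgmentSpec,
    generate_judgment,
    generate_random_dag,
    random_consistent_judgments,
    uniform_judgments,
)


def _power_iteration_oracle(P, iters=10_000, tol=1e-14):
    """Independent principal-eigenpair oracle by plain power iteration."""
    P = np.asarray(P, dtype=float)
    v = np.full(P.shape[0], 1.0 / P.shape[0])
    lam = 0.0
    for _ in range(iters):
        w = P @ v
        lam_new = np.linalg.norm(w)
        w = w / lam_new
        if np.max(np.abs(w - v)) < tol:
            v = w
            lam = lam_new
            break
        v, lam = w, lam_new
    v = np.abs(v)
    lam = float((P @ v)[0] / v[0])
    return v / v.sum(), lam


TOY_3X3 = np.array([[1.0, 2.0, 6.0], [0.5, 1.0, 4.0], [1 / 6, 0.25, 1.0]])


class TestPriorityVector:
    def test_consistent_2x2_closed_form(self):
        pv = anp.priority_vector([[1, 2], [0.5, 1]])
        np.testing.assert_allclose(pv.weights, [2 / 3, 1 / 3], atol=1e-12)
        assert pv.lambda_max == pytest.approx(2.0, abs=1e-12)

    def test_all_ones_uniform(self):
        pv = anp.priority_vector(np.ones((4, 4)))
        np.testing.assert_allclose(pv.weights, np.full(4, 0.25), atol=1e-12)
        assert pv.lambda_max == pytest.approx(4.0, abs=1e-12)

    def test_matches_power_iteration_oracle(self):
        pv = anp.priority_vector(TOY_3X3)
        w_oracle, lam_oracle = _power_iteration_oracle(TOY_3X3)
        np.testing.assert_allclose(pv.weights, w_oracle, atol=1e-10)
        assert pv.lambda_max == pytest.approx(lam_oracle, abs=1e-10)

    def test_non_reciprocal_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            anp.priority_vector([[1, 2], [0.7, 1]])


class TestConsistency:
    def test_ratio_matrix_has_zero_cr(self):
        w = np.array([0.5, 0.3, 0.2])
        rep = anp.consistency(w[:, None] / w[None, :])
        assert rep.cr == pytest.approx(0.0, abs=1e-9)
        assert rep.passed

    def test_order_two_defined_zero(self):
        rep = anp.consistency([[1, 5], [0.2, 1]])
        assert rep.cr == 0.0 and rep.passed

    def test_cr_from_oracle_lambda(self):
        _, lam = _power_iteration_oracle(TOY_3X3)
        expected_cr = ((lam - 3) / 2) / 0.58
        rep = anp.consistency(TOY_3X3)
        assert rep.cr == pytest.approx(expected_cr, abs=1e-9)

    def test_order_beyond_table_needs_flag(self):
        w = np.linspace(1, 2, 11)
        P = w[:, None] / w[None, :]
        with pytest.raises(ValueError, match="decompose"):
            anp.consistency(P)
        rep = anp.consistency(P, extend_ri=True)
        assert rep.cr == pytest.approx(0.0, abs=1e-9)


class TestBuildNetwork:
    def test_bundled_sources_and_sinks(self, network):
        assert network.sources == ("F1", "F8", "F15", "F16")
        assert network.sinks == ("F4", "F5", "F18")

    def test_identity_all_sources_and_sinks(self):
        net = anp.build_network(np.eye(3, dtype=int), {f"F{i}": "c" for i in (1, 2, 3)})
        assert net.sources == net.sinks == ("F1", "F2", "F3")

    def test_unclustered_factor_rejected(self):
        with pytest.raises(ValueError, match="F2"):
            anp.build_network(np.eye(2, dtype=int), {"F1": "c"})


class TestAssembleUnweighted:
    def _net(self, A, clusters=None):
        n = A.shape[0]
        return anp.build_network(
            A, clusters or {f"F{i + 1}": "c" for i in range(n)}
        )

    def test_single_target_and_sink_rules(self):
        A = np.array([[0, 1], [0, 0]])
        W0 = anp.assemble_unweighted(self._net(A), None)
        np.testing.assert_allclose(W0.to_numpy(), [[0, 0], [1, 1]])

    def test_two_target_priorities(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = 1
        judgment = anp.Judgment("F1", ("F2", "F3"), np.array([[1, 3], [1 / 3, 1]]))
        W0 = anp.assemble_unweighted(self._net(A), {"F1": judgment})
        np.testing.assert_allclose(W0["F1"].to_numpy(), [0, 0.75, 0.25], atol=1e-12)
        np.testing.assert_allclose(W0.to_numpy().sum(axis=0), 1.0)

    def test_missing_judgment_names_criterion_and_set(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = 1
        with pytest.raises(ValueError, match=r"F1.*\['F2', 'F3'\]"):
            anp.assemble_unweighted(self._net(A), None)

    def test_wrong_element_set_rejected(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = 1
        bad = anp.Judgment("F1", ("F2", "F1"), np.ones((2, 2)))
        with pytest.raises(ValueError, match="requires"):
            anp.assemble_unweighted(self._net(A), {"F1": bad})

    def test_columns_sum_to_one_on_bundled_network(self, network):
        W0 = anp.assemble_unweighted(network, uniform_judgments(network))
        np.testing.assert_allclose(W0.to_numpy().sum(axis=0), 1.0, atol=1e-12)


class TestClusterWeights:
    def test_two_cluster_closed_form(self):
        A = np.array([[0, 1], [0, 0]])
        net = anp.build_network(A, {"F1": "a", "F2": "b"})
        # column 'a' links to {b}; column 'b' (sink self-loop) links to {b}
        CA = anp.cluster_weight_matrix(net, uniform=True)
        assert CA.loc["b", "a"] == 1.0
        assert CA.loc["b", "b"] == 1.0
        assert CA.loc["a", "a"] == 0.0

    def test_judged_split(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = 1  # a -> {b, c}
        net = anp.build_network(A, {"F1": "a", "F2": "b", "F3": "c"})
        judgment = anp.Judgment("a", ("b", "c"), np.array([[1, 2], [0.5, 1]]))
        CA = anp.cluster_weight_matrix(net, {"a": judgment})
        assert CA.loc["b", "a"] == pytest.approx(2 / 3)
        assert CA.loc["c", "a"] == pytest.approx(1 / 3)

    def test_unlinked_cluster_judgment_rejected(self):
        A = np.array([[0, 1], [0, 0]])
        net = anp.build_network(A, {"F1": "a", "F2": "b"})
        bad = anp.Judgment("b", ("a", "b"), np.ones((2, 2)))
        with pytest.raises(ValueError, match="not linked"):
            anp.cluster_weight_matrix(net, {"b": bad})

    def test_uniform_fallback_fills_equal_shares(self, network):
        CA = anp.cluster_weight_matrix(network, uniform=True)
        sums = CA.to_numpy().sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        nonzero_counts = (CA.to_numpy() > 0).sum(axis=0)
        for c, count in zip(CA.columns, nonzero_counts):
            col = CA[c].to_numpy()
            np.testing.assert_allclose(col[col > 0], 1.0 / count, atol=1e-12)

    def test_weighted_matrix_is_column_stochastic(self, network):
        W0 = anp.assemble_unweighted(network, uniform_judgments(network))
        CA = anp.cluster_weight_matrix(network, uniform=True)
        W = anp.apply_cluster_weights(W0, CA, network.cluster_of)
        np.testing.assert_allclose(W.to_numpy().sum(axis=0), 1.0, atol=1e-9)

    def test_blockwise_scaling_matches_elementwise_oracle(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = A[1, 2] = 1
        clusters = {"F1": "a", "F2": "a", "F3": "b"}
        net = anp.build_network(A, clusters)
        W0 = anp.assemble_unweighted(net, uniform_judgments(net))
        CA = anp.cluster_weight_matrix(net, uniform=True)
        W = anp.apply_cluster_weights(W0, CA, clusters)
        raw = W0.to_numpy().copy()
        for i, fi in enumerate(W0.index):
            for j, fj in enumerate(W0.columns):
                raw[i, j] *= CA.loc[clusters[fi], clusters[fj]]
        raw = raw / raw.sum(axis=0)
        np.testing.assert_allclose(W.to_numpy(), raw, atol=1e-12)


class TestLimit:
    def test_identity_converges_immediately(self):
        res = anp.limit_supermatrix(np.eye(3))
        assert res.method == "power"
        np.testing.assert_allclose(res.matrix.to_numpy(), np.eye(3))

    def test_absorbing_chain_closed_form(self):
        W = np.array([[0.0, 0.0], [1.0, 1.0]])  # transient F1 -> absorbing F2
        res = anp.limit_supermatrix(W)
        assert res.method == "power"
        np.testing.assert_allclose(res.matrix.to_numpy(), [[0, 0], [1, 1]], atol=1e-12)

    def test_periodic_chain_falls_back_to_cesaro(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = anp.limit_supermatrix(W)
        assert res.method == "cesaro"
        np.testing.assert_allclose(res.matrix.to_numpy(), 0.5 * np.ones((2, 2)), atol=1e-12)

    def test_power_method_idempotent(self, network):
        W0 = anp.assemble_unweighted(network, uniform_judgments(network))
        CA = anp.cluster_weight_matrix(network, uniform=True)
        W = anp.apply_cluster_weights(W0, CA, network.cluster_of)
        res = anp.limit_supermatrix(W)
        assert res.method == "power"
        L = res.matrix.to_numpy()
        assert np.max(np.abs(L @ W.to_numpy() - L)) < 1e-8

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            anp.limit_supermatrix(np.array([[0.5, 0.2], [0.2, 0.5]]))


class TestGlobalWeights:
    def test_identity_limit_uniform_tied_ranks(self):
        table = anp.global_weights(anp.limit_supermatrix(np.eye(2)))
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])
        assert list(table["rank"]) == [1, 1]

    def test_absorbing_chain_weights(self):
        res = anp.limit_supermatrix(np.array([[0.0, 0.0], [1.0, 1.0]]))
        table = anp.global_weights(res)
        np.testing.assert_allclose(table["weight"], [0.0, 1.0], atol=1e-12)
        assert list(table["rank"]) == [2, 1]

    @pytest.mark.parametrize("seed", range(12))
    def test_source_factors_weigh_zero_for_any_judgments(self, network, seed):
        """Structural-zero law: factors nothing influences can acquire no
        limit mass, whatever the (positive) judgment values."""
        judgments = random_consistent_judgments(network, seed=seed)
        result = anp.anp_pipeline(network, judgments)
        w = result.weights["weight"]
        assert float(w[["F1", "F8", "F15", "F16"]].abs().max()) < 1e-9
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestPipeline:
    def _toy(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[0, 2] = A[1, 2] = 1  # F1 -> {F2, F3}, F2 -> F3
        clusters = {"F1": "a", "F2": "a", "F3": "b"}
        return anp.build_network(A, clusters)

    def test_end_to_end_equals_manual_stage_composition(self):
        net = self._toy()
        judgments = {
            "F1": anp.Judgment("F1", ("F2", "F3"), np.array([[1, 3], [1 / 3, 1]]))
        }
        result = anp.anp_pipeline(net, judgments)
        W0 = anp.assemble_unweighted(net, judgments)
        CA = anp.cluster_weight_matrix(net, uniform=True)
        W = anp.apply_cluster_weights(W0, CA, net.cluster_of)
        limit = anp.limit_supermatrix(W)
        expected = anp.global_weights(limit)
        pd.testing.assert_frame_equal(result.weights, expected)

    def test_deterministic_rerun(self, network):
        judgments = random_consistent_judgments(network, seed=3)
        r1 = anp.anp_pipeline(network, judgments)
        r2 = anp.anp_pipeline(network, judgments)
        pd.testing.assert_frame_equal(r1.weights, r2.weights)
        np.testing.assert_array_equal(
            r1.limit.matrix.to_numpy(), r2.limit.matrix.to_numpy()
        )

    def test_inconsistent_judgment_refused_by_name(self):
        net = self._toy()
        bad = anp.Judgment(
            "F1", ("F2", "F3"), np.array([[1.0, 9.0], [1 / 9, 1.0]])
        )
        # make it genuinely inconsistent: need >=3 elements for CR > 0
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[0, 2] = A[0, 3] = 1
        net = anp.build_network(A, {f"F{i + 1}": "a" for i in range(4)})
        P = np.array([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]])
        bad = anp.Judgment("F1", ("F2", "F3", "F4"), P)
        with pytest.raises(ValueError, match="F1.*CR"):
            anp.anp_pipeline(net, {"F1": bad})
        result = anp.anp_pipeline(net, {"F1": bad}, allow_inconsistent=True)
        assert not result.consistency["F1"].passed

    def test_consistent_judgments_recover_true_weights(self):
        spec = JudgmentSpec(weights=(0.5, 0.3, 0.2))
        judgment = generate_judgment(spec, elements=("a", "b", "c"))
        pv = anp.priority_vector(judgment.matrix)
        np.testing.assert_allclose(pv.weights, [0.5, 0.3, 0.2], atol=1e-9)
        assert anp.consistency(judgment.matrix).cr == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10**6))
    def test_rank_one_perturbation_scales_priorities(self, seed):
        """2x2 closed form: multiplying by a reciprocal rank-one perturbation
        (v_i/v_j) maps priorities to the normalized product."""
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.2, 1.0, 2)
        v = rng.uniform(0.2, 1.0, 2)
        P = (w[:, None] / w[None, :]) * (v[:, None] / v[None, :])
        pv = anp.priority_vector(P)
        expected = w * v / (w * v).sum()
        np.testing.assert_allclose(pv.weights, expected, atol=1e-9)


class TestEstimator:
    def test_fit_on_bundled_network(self, study, reachability):
        est = anp.AnalyticNetworkProcess(
            clusters=study.cluster_of, cluster_order=study.cluster_order
        )
        est.fit(reachability, judgments="uniform")
        assert est.limit_method_ == "power"
        assert est.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert float(est.weights_[list(est.network_.sources)].max()) == 0.0
        assert est.get_params()["orientation"] == "influence"

    def test_dependence_orientation_flips_zeros(self, study, reachability):
        """Under the dependence orientation the *sinks* (nothing to compare
        with respect to) become absorbing instead of the sources."""
        est = anp.AnalyticNetworkProcess(
            clusters=study.cluster_of,
            cluster_order=study.cluster_order,
            orientation="dependence",
        )
        est.fit(reachability, judgments="uniform")
        w = est.weights_
        assert float(w[["F4", "F5", "F18"]].abs().max()) < 1e-9
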