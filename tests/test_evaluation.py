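import itertools

import networkx as nx
import numpy as np
import pytest

from spikeconn.evaluation import (
    degree_metrics,
    path_clustering,
    receiver_probability,
    receiver_vs_indegree,
    score,
)
from spikeconn.matrices import ConnectivityMatrix
from spikeconn.synthetic import NetworkModel, SpikeTrainSet


def matrix_from_edges(n, edges):
    m = np.zeros((n, n), int)
    for s, d in edges:
        m[s, d] = 1
    return ConnectivityMatrix(m)


class TestScore:
    def _truth(self, n, edges):
        return NetworkModel(n, [(s, d, 1.0, 1.0) for s, d in edges])

    def test_perfect_reconstruction(self):
        truth = self._truth(4, [(0, 1), (1, 2), (3, 0)])
        res = score(matrix_from_edges(4, [(0, 1), (1, 2), (3, 0)]), truth)
        assert (res.tp_rate, res.fp_rate, res.delta, res.acc) == (1, 0, 1, 1)

    def test_empty_prediction(self):
        truth = self._truth(4, [(0, 1), (1, 2)])
        res = score(matrix_from_edges(4, []), truth)
        assert res.TP == res.FP == 0
        assert res.delta == 0
        assert res.acc == 1 - 2 / 12

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            t = rng.integers(0, 2, (5, 5))
            p = rng.integers(0, 2, (5, 5))
            np.fill_diagonal(t, 0)
            np.fill_diagonal(p, 0)
            if t.sum() == 0:
                continue
            truth = self._truth(5, list(zip(*np.nonzero(t))))
            res = score(ConnectivityMatrix(p), truth)
            tp = fp = tn = fn = 0
            for i, j in itertools.permutations(range(5), 2):
                if p[i, j] and t[i, j]:
                    tp += 1
                elif p[i, j]:
                    fp += 1
                elif t[i, j]:
                    fn += 1
                else:
                    tn += 1
            assert (res.TP, res.FP, res.TN, res.FN) == (tp, fp, tn, fn)
            assert res.n_tot == 20
            assert res.delta <= res.tp_rate

    def test_rejects_empty_truth(self):
        with pytest.raises(ValueError):
            score(matrix_from_edges(3, []), NetworkModel(3, []))


class TestDegreeMetrics:
    def test_cycle_has_no_hubs(self):
        m = matrix_from_edges(3, [(0, 1), (1, 2), (2, 0)])
        gm = degree_metrics(m)
        np.testing.assert_array_equal(gm.in_degree, [1, 1, 1])
        np.testing.assert_array_equal(gm.out_degree, [1, 1, 1])
        assert not gm.hubs.any()
        assert gm.max_hub_size == 0

    def test_star_hub_detected(self):
        m = matrix_from_edges(7, [(i, 0) for i in range(1, 7)])
        gm = degree_metrics(m)
        assert gm.hubs[0] and gm.hubs.sum() == 1
        assert gm.max_hub_size == 6

    def test_degree_sums_equal_edge_count(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, (8, 8))
        np.fill_diagonal(a, 0)
        gm = degree_metrics(ConnectivityMatrix(a))
        assert gm.in_degree.sum() == gm.out_degree.sum() == a.sum()

    def test_in_degree_fraction_nan_for_isolated(self):
        m = matrix_from_edges(3, [(0, 1)])
        gm = degree_metrics(m)
        assert np.isnan(gm.in_degree_fraction[2])
        assert gm.in_degree_fraction[1] == 1.0


class TestPathClustering:
    def test_bidirectional_triangle(self):
        edges = [(a, b) for a in range(3) for b in range(3) if a != b]
        pl, cc = path_clustering(matrix_from_edges(3, edges))
        assert pl == 1.0
        assert cc == 1.0

    def test_directed_chain_hand_enumeration(self):
        pl, cc = path_clustering(
            matrix_from_edges(4, [(0, 1), (1, 2), (2, 3)]))
        assert pl == pytest.approx(10 / 6)
        assert cc == 0.0

    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(2)
        a = (rng.random((8, 8)) < 0.25).astype(int)
        np.fill_diagonal(a, 0)
        pl, cc = path_clustering(ConnectivityMatrix(a))
        g = nx.from_numpy_array(a, create_using=nx.DiGraph)
        lengths = [
            d for src, dd in nx.all_pairs_shortest_path_length(g)
            for dst, d in dd.items() if dst != src
        ]
        assert pl == pytest.approx(np.mean(lengths))
        assert cc == pytest.approx(
            np.mean(list(nx.clustering(nx.Graph(g.to_undirected())).values()))
        )

    def test_no_edges_gives_missing_path_length(self):
        pl, _cc = path_clustering(matrix_from_edges(3, []))
        assert np.isnan(pl)


class TestReceiverProbability:
    def test_pure_receiver(self):
        trains = SpikeTrainSet(
            2, [np.array([1.0, 2.0, 3.0]), np.array([1.005, 2.005, 3.005])],
            4.0)
        est = receiver_probability(trains, window=15.0)
        assert est.receiver_prob[1] == 1.0
        assert est.receiver_prob[0] == 0.0

    def test_hand_enumerated_counts(self):
        # neuron 0 at 1.000; neuron 1 at 0.990 and 1.010; neuron 2 at 1.020
        trains = SpikeTrainSet(
            3,
            [np.array([1.000]), np.array([0.990, 1.010]), np.array([1.020])],
            2.0,
        )
        est = receiver_probability(trains, window=15.0)
        # around neuron 0's spike: left [0.985, 1.0): 0.990 -> s-=1;
        # right (1.0, 1.015]: 1.010 -> s+=1 (1.020 outside)
        assert est.s_minus[0] == 1 and est.s_plus[0] == 1
        # neuron 2 at 1.020: left window [1.005, 1.020): 1.010 -> s-=1
        assert est.s_minus[2] == 1 and est.s_plus[2] == 0

    def test_boundary_convention(self):
        # spike exactly at t - window is counted (closed outer end);
        # exactly at t is counted on neither side
        trains = SpikeTrainSet(
            2, [np.array([1.000]), np.array([0.985, 1.000])], 2.0)
        est = receiver_probability(trains, window=15.0)
        assert est.s_minus[0] == 1
        assert est.s_plus[0] == 0

    def test_silent_neuron_reports_missing(self):
        trains = SpikeTrainSet(2, [np.array([1.0]), np.array([])], 2.0)
        est = receiver_probability(trains)
        assert np.isnan(est.receiver_prob[1])


class TestReceiverVsIndegree:
    def _metrics(self, frac):
        gm = degree_metrics(matrix_from_edges(len(frac), []))
        gm.in_degree_fraction = np.asarray(frac, float)
        return gm

    def _est(self, probs):
        from spikeconn.evaluation import ReceiverEstimate

        p = np.asarray(probs, float)
        s_minus = np.round(1_000_000 * p).astype(int)
        return ReceiverEstimate(1_000_000 - s_minus, s_minus, 15.0)

    def test_collinear_points(self):
        est = self._est([0.0, 0.25, 0.5, 0.75, 1.0])
        slope, intercept, r2 = receiver_vs_indegree(
            est, self._metrics([0.0, 0.25, 0.5, 0.75, 1.0]))
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(4)
        x = rng.random(20)
        y = 0.6 * x + 0.1 + rng.normal(0, 0.05, 20)
        est = self._est(x)
        slope, intercept, r2 = receiver_vs_indegree(est, self._metrics(y))
        X = np.vstack([x, np.ones_like(x)]).T
        beta, res, _rk, _sv = np.linalg.lstsq(X, y, rcond=None)
        # the estimate stores probabilities as count ratios, so agreement
        # holds to the count resolution
        assert slope == pytest.approx(beta[0], abs=1e-4)
        assert intercept == pytest.approx(beta[1], abs=1e-4)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - res[0] / ss_tot, abs=1e-4)

    def test_degenerate_predictor_rejected(self):
        est = self._est([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            receiver_vs_indegree(est, self._metrics([0.1, 0.2, 0.3, 0.4]))
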