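import numpy as np
import pytest

from dynconn.adtf import TimeVaryingNetwork
from dynconn.errors import ParameterError, StatisticsError
from dynconn.netstats import (NetworkProperties, edge_group_test,
                              graph_properties, pearson_association,
                              snapshot_series, subject_properties)
from oracle_helpers import graph_metrics_bruteforce


def net(w, times=None, labels=None):
    w = np.asarray(w, dtype=float)
    if w.ndim == 2:
        w = w[None]
    labels = labels or tuple(f"n{i}" for i in range(w.shape[1]))
    times = times if times is not None else np.arange(w.shape[0], dtype=float)
    return TimeVaryingNetwork(w=w, times_ms=np.asarray(times, dtype=float),
                              band_hz=(1.0, 30.0), channel_labels=labels)


class TestGraphProperties:
    def test_complete_unit_triangle_closed_form(self):
        w = 1.0 - np.eye(3)
        q = graph_properties(w)
        assert q.C == pytest.approx(1.0)
        assert q.L == pytest.approx(1.0)
        assert q.Ge == pytest.approx(1.0)
        assert q.Le == pytest.approx(1.0)

    def test_three_node_path_by_exhaustive_enumeration(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        q = graph_properties(w)
        assert q.C == 0.0
        assert q.L == pytest.approx(4.0 / 3.0)     # mean of {1, 1, 2}
        assert q.Ge == pytest.approx(5.0 / 6.0)    # mean of {1, 1, 1/2}
        assert q.Le == 0.0

    def test_empty_graph_sentinels(self):
        q = graph_properties(np.zeros((4, 4)))
        assert q.C == 0.0 and q.Ge == 0.0 and q.Le == 0.0
        assert np.isinf(q.L)

    def test_too_small_or_negative_rejected(self):
        with pytest.raises(ParameterError):
            graph_properties(np.zeros((1, 1)))
        with pytest.raises(ParameterError):
            graph_properties(np.array([[0, -1.0], [1.0, 0]]))

    @pytest.mark.parametrize("n_nodes", [3, 4, 5])
    def test_agrees_with_bruteforce_oracle_on_random_graphs(self, n_nodes):
        rng = np.random.default_rng(n_nodes)
        for _ in range(60):
            w = rng.random((n_nodes, n_nodes))
            w *= rng.random(w.shape) < 0.7           # some absent edges
            q = graph_properties(w)
            sym = (w + w.T) / 2.0
            np.fill_diagonal(sym, 0.0)
            C, L, Ge, Le = graph_metrics_bruteforce(sym)
            assert q.C == pytest.approx(C, abs=1e-9)
            assert q.L == pytest.approx(L, abs=1e-9) or (np.isinf(q.L) and np.isinf(L))
            assert q.Ge == pytest.approx(Ge, abs=1e-9)
            assert q.Le == pytest.approx(Le, abs=1e-9)

    def test_directed_variant_reduces_to_symmetric_case(self):
        w = 1.0 - np.eye(3)
        q = graph_properties(w, directed_handling="directed")
        assert q.C == pytest.approx(1.0)
        assert q.Ge == pytest.approx(1.0)

    def test_uniform_scaling_scales_efficiency(self, rng):
        w = rng.random((6, 6))
        q1 = graph_properties(w)
        q2 = graph_properties(3.0 * w)
        assert q2.Ge == pytest.approx(3.0 * q1.Ge)
        assert q2.L == pytest.approx(q1.L / 3.0)

    def test_connectivity_strength_moves_all_metrics_monotonically(self):
        """Dialling planted coupling up: C, Ge, Le rise and L falls."""
        from dynconn.simulate import SimulationScenario, subject_static_network
        scn = SimulationScenario.desk_scale()
        props = [graph_properties(
            subject_static_network(scn, "MCS", s, edge_noise_sd=0.0).w[0])
            for s in (0.5, 1.0, 1.5)]
        for a, b in zip(props, props[1:]):
            assert b.C > a.C and b.Ge > a.Ge and b.Le > a.Le and b.L < a.L


class TestEdgeGroupTest:
    def make_groups(self, rng, n=5, n_subj=8, shift=None):
        base = rng.random((1, n, n)) * 0.2 + 0.2
        A = [net(base[0] + 0.01 * rng.standard_normal((n, n))) for _ in range(n_subj)]
        B = []
        for _ in range(n_subj):
            w = base[0] + 0.01 * rng.standard_normal((n, n))
            if shift is not None:
                w[shift] -= 0.5
            B.append(net(w))
        return A, B

    def test_identical_groups_retain_nothing(self, rng):
        A, _ = self.make_groups(rng)
        d = edge_group_test(A, list(A), time_ms=0.0)
        assert d.edges == []

    def test_planted_edge_is_the_only_retention(self):
        rng = np.random.default_rng(4)
        A, B = self.make_groups(rng, shift=(2, 1))   # sink 2 <- source 1
        d = edge_group_test(A, B, time_ms=0.0, alpha=1e-6)
        assert [(e.source, e.sink, e.direction) for e in d.edges] == \
            [("n1", "n2", "A>B")]

    def test_alpha_zero_gives_empty_set(self, rng):
        A, B = self.make_groups(rng, shift=(1, 0))
        assert edge_group_test(A, B, 0.0, alpha=0.0).edges == []

    def test_small_group_rejected(self, rng):
        A, B = self.make_groups(rng)
        with pytest.raises(StatisticsError):
            edge_group_test(A[:1], B, 0.0)

    def test_retention_pattern_is_scale_invariant(self):
        rng = np.random.default_rng(9)
        A, B = self.make_groups(rng, shift=(3, 0))
        d1 = edge_group_test(A, B, 0.0)
        A10 = [net(10 * x.w[0]) for x in A]
        B10 = [net(10 * x.w[0]) for x in B]
        d2 = edge_group_test(A10, B10, 0.0)
        assert d1.edge_set() == d2.edge_set()

    def test_null_edge_retention_matches_alpha(self):
        """Uncorrected edge retention under the group null ~ alpha."""
        rng = np.random.default_rng(123)
        retained = total = 0
        for _ in range(60):
            n = 12
            A = [net(rng.random((n, n))) for _ in range(8)]
            B = [net(rng.random((n, n))) for _ in range(8)]
            d = edge_group_test(A, B, 0.0, alpha=0.05)
            retained += len(d.edges)
            total += n * (n - 1)
        assert abs(retained / total - 0.05) < 0.01


class TestSnapshots:
    def test_default_call_yields_five_networks(self, rng):
        nets_a = [net(rng.random((4, 3, 3)), times=[100, 200, 600, 1000])
                  for _ in range(4)]
        nets_b = [net(rng.random((4, 3, 3)), times=[100, 200, 600, 1000])
                  for _ in range(4)]
        out = snapshot_series(nets_a, nets_b)
        assert len(out) == 5

    def test_empty_times_list_is_empty_result(self, rng):
        nets_a = [net(rng.random((1, 3, 3))) for _ in range(3)]
        assert snapshot_series(nets_a, nets_a, times_ms=()) == []

    def test_snapshot_uses_nearest_grid_sample(self, rng):
        a = [net(rng.random((2, 3, 3)), times=[0.0, 500.0]) for _ in range(3)]
        b = [net(rng.random((2, 3, 3)), times=[0.0, 500.0]) for _ in range(3)]
        d = edge_group_test(a, b, time_ms=400.0)
        assert d.time_ms == 500.0


class TestSubjectProperties:
    def test_time_constant_network_equals_single_slice(self, rng):
        w = rng.random((3, 3))
        tv = net(np.repeat(w[None], 5, axis=0))
        q_tv = subject_properties(tv, window_ms=(0, 4))
        q_slice = graph_properties(w)
        assert q_tv.as_dict() == pytest.approx(q_slice.as_dict())

    def test_single_sample_window(self, rng):
        tv = net(rng.random((5, 3, 3)))
        q = subject_properties(tv, window_ms=(2, 2))
        assert q.as_dict() == pytest.approx(graph_properties(tv.w[2]).as_dict())

    def test_two_slice_average_equals_midpoint_matrix(self, rng):
        w1, w2 = rng.random((3, 3)), rng.random((3, 3))
        tv = net(np.stack([w1, w2]))
        q = subject_properties(tv, window_ms=(0, 1))
        assert q.as_dict() == pytest.approx(
            graph_properties((w1 + w2) / 2).as_dict())

    def test_metrics_then_average_mode(self, rng):
        tv = net(rng.random((4, 3, 3)))
        q = subject_properties(tv, window_ms=(0, 3), mode="metrics_then_average")
        expect = np.mean([graph_properties(tv.w[i]).C for i in range(4)])
        assert q.C == pytest.approx(expect)


class TestAssociation:
    def props_from(self, values):
        return [NetworkProperties(C=v, L=1 / max(v, 1e-9), Ge=v, Le=v)
                for v in values]

    def test_perfect_linearity_gives_r_one(self):
        scores = np.arange(10.0)
        props = self.props_from(2 * scores + 1)
        res = {a.property: a for a in pearson_association(props, scores)}
        assert res["C"].r == pytest.approx(1.0)
        assert res["C"].p < 1e-12

    def test_anticorrelation_gives_minus_one(self):
        scores = np.arange(3.0, 13.0)
        props = self.props_from(-scores)
        res = {a.property: a for a in pearson_association(props, scores)}
        assert res["Ge"].r == pytest.approx(-1.0)

    def test_planted_rho_recovered_within_sampling_interval(self):
        rng = np.random.default_rng(77)
        rho, n = 0.5, 16
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        props = self.props_from(5 + z[:, 0])
        res = {a.property: a for a in pearson_association(props, 10 + 3 * z[:, 1])}
        # 95% sampling interval of r at rho=.5, n=16 (Fisher z)
        lo = np.tanh(np.arctanh(rho) - 1.96 / np.sqrt(n - 3))
        hi = np.tanh(np.arctanh(rho) + 1.96 / np.sqrt(n - 3))
        assert lo <= res["C"].r <= hi

    def test_zero_variance_is_flagged_not_crashed(self):
        props = self.props_from([1.0, 1.0, 1.0, 1.0])
        res = {a.property: a for a in pearson_association(props, [1, 2, 3, 4])}
        assert res["C"].note == "zero variance"
        assert np.isnan(res["C"].r)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(StatisticsError):
            pearson_association(self.props_from([1.0, 2.0]), [1, 2])
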