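"""Connectivity, NBS mass statistic and graph measures."""

import itertools
from collections import deque

import numpy as np
import pytest

from insightrc import network as net
from insightrc import synthetic as syn
from insightrc.containers import ConnectivityStack


class TestFcMatrix:
    def test_fisher_z_equals_atanh_of_pearson(self, rng):
        ts = rng.standard_normal((5, 200))
        z = net.fc_matrix(ts, np.ones(200, dtype=bool))
        r = np.corrcoef(ts)
        iu = np.triu_indices(5, k=1)
        np.testing.assert_allclose(z[iu], np.arctanh(r[iu]), atol=1e-12)
        assert np.isnan(np.diag(z)).all()

    def test_known_correlation_closed_form(self):
        # two series engineered to correlate exactly 0.5
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to a
        x = a
        y = 0.5 * a + np.sqrt(1 - 0.25) * b
        z = net.fc_matrix(np.vstack([x, y]), np.ones(n, dtype=bool))
        assert z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-10)

    def test_block_selection(self, rng):
        ts = rng.standard_normal((3, 100))
        mask = np.zeros(100, dtype=bool)
        mask[10:40] = True
        z_mask = net.fc_matrix(ts, mask)
        z_slice = net.fc_matrix(ts, [(10, 40)])
        np.testing.assert_allclose(z_mask, z_slice, equal_nan=True)
        r = np.corrcoef(ts[:, 10:40])
        assert z_mask[0, 1] == pytest.approx(np.arctanh(r[0, 1]))

    def test_constant_roi_named_in_error(self, rng):
        ts = rng.standard_normal((3, 50))
        ts[1] = 2.0
        with pytest.raises(ValueError, match="B"):
            net.fc_matrix(ts, np.ones(50, dtype=bool), roi_names=["A", "B", "C"])

    def test_identical_series_masked_with_warning(self, rng):
        row = rng.standard_normal(60)
        ts = np.vstack([row, row, rng.standard_normal(60)])
        with pytest.warns(UserWarning, match="Fisher z undefined"):
            z = net.fc_matrix(ts, np.ones(60, dtype=bool))
        assert np.isnan(z[0, 1])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="5 samples"):
            net.fc_matrix(rng.standard_normal((3, 50)), [(0, 3)])


def _stack_from_diffs(diffs, base=None, rng=None):
    """Build a 2-condition stack whose HI-LO differences equal ``diffs``."""
    diffs = np.asarray(diffs, dtype=float)
    s, r, _ = diffs.shape
    lo = np.zeros((s, r, r)) if base is None else base
    z = np.empty((s, 2, 1, r, r))
    z[:, 1, 0] = lo
    z[:, 0, 0] = lo + diffs
    for a in range(2):
        for i in range(s):
            np.fill_diagonal(z[i, a, 0], np.nan)
    return ConnectivityStack(z=z, subjects=list(range(s)),
                             roi_names=[f"R{i}" for i in range(r)])


class TestConnectionContrast:
    def test_identical_conditions_give_zero_t(self, rng):
        d = np.zeros((6, 4, 4))
        base = rng.standard_normal((6, 4, 4))
        base = (base + base.transpose(0, 2, 1)) / 2
        t = net.connection_contrast(_stack_from_diffs(d, base=base))
        iu = np.triu_indices(4, 1)
        assert np.allclose(np.nan_to_num(t[iu]), 0.0)

    def test_matches_hand_computation_on_four_subjects(self):
        vals = np.array([0.1, 0.3, 0.2, 0.4])
        d = np.zeros((4, 3, 3))
        d[:, 0, 1] = d[:, 1, 0] = vals
        t = net.connection_contrast(_stack_from_diffs(d))
        expected = vals.mean() / (vals.std(ddof=1) / np.sqrt(4))
        assert t[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_in_condition_labels(self, rng):
        d = rng.standard_normal((6, 4, 4))
        d = (d + d.transpose(0, 2, 1)) / 2
        stack = _stack_from_diffs(d)
        flipped = ConnectivityStack(
            z=stack.z[:, ::-1], subjects=stack.subjects,
            roi_names=stack.roi_names,
        )
        t1 = net.connection_contrast(stack)
        t2 = net.connection_contrast(flipped)
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(t1[iu], -t2[iu], atol=1e-10)


class TestNbsMass:
    def test_mass_is_sum_of_squared_suprathreshold_t(self, rng):
        # n = 6 subjects; values m +/- sqrt(5) give a paired t of exactly m
        s5 = np.sqrt(5.0)
        edge_t2 = 2.0 + s5 * np.array([1, -1, 1, -1, 1, -1])
        edge_t3 = 3.0 + s5 * np.array([1, -1, 1, -1, 1, -1])
        d = np.zeros((6, 5, 5))
        d[:, 0, 1] = d[:, 1, 0] = edge_t2
        d[:, 2, 3] = d[:, 3, 2] = edge_t3
        # remaining edges: mean-zero, below threshold
        d[:, 0, 4] = d[:, 4, 0] = 0.01 * np.array([1, -1, 1, -1, 1, -1])
        res = net.nbs_mass_test(_stack_from_diffs(d), edge_alpha=0.1,
                                n_perm=99, seed=0)
        assert res.mass == pytest.approx(4.0 + 9.0, abs=1e-9)
        assert set(res.edges) == {("R0", "R1"), ("R2", "R3")}

    def test_no_suprathreshold_edges_gives_unit_p(self, rng):
        d = 0.001 * rng.standard_normal((8, 4, 4))
        d = (d + d.transpose(0, 2, 1)) / 2
        d -= d.mean(axis=0, keepdims=True)  # exactly mean-zero edges
        res = net.nbs_mass_test(_stack_from_diffs(d), n_perm=49, seed=0)
        assert res.fwe_p == 1.0

    def test_seeded_reproducibility(self, rng):
        d = rng.standard_normal((8, 5, 5))
        d = (d + d.transpose(0, 2, 1)) / 2
        stack = _stack_from_diffs(d)
        a = net.nbs_mass_test(stack, n_perm=199, seed=7)
        b = net.nbs_mass_test(stack, n_perm=199, seed=7)
        assert a.fwe_p == b.fwe_p and a.mass == b.mass

    def test_detects_injected_subnetwork_with_high_power(self):
        cfg = syn.SimulationConfig(
            n_subjects=31, n_items=20, n_runs=2, trials_per_run=10,
            fc_condition_delta=0.3,
        )
        detected = 0
        for rep in range(10):
            trials = syn.simulate_trials(cfg, seed=400 + rep)
            ts = syn.simulate_roi_timeseries(trials, cfg, seed=400 + rep)
            stack = net.build_connectivity_stack(ts)
            res = net.nbs_mass_test(stack, n_perm=99, seed=rep)
            detected += res.fwe_p < 0.05
        assert detected >= 8
        # the detected component should involve the injected subnetwork
        assert set(cfg.fc_subnetwork) & set(res.component_rois)


class TestThresholdAdjacency:
    def test_subthreshold_correlations_give_empty_graph(self):
        z = np.arctanh(np.full((4, 4), 0.05))
        np.fill_diagonal(z, np.nan)
        assert not net.threshold_adjacency(z, 0.1).any()

    def test_negative_correlations_never_edges(self):
        z = np.arctanh(np.array([[0.0, -0.9], [-0.9, 0.0]]))
        np.fill_diagonal(z, np.nan)
        assert not net.threshold_adjacency(z, 0.1).any()

    def test_edge_sets_nested_over_thresholds(self, rng):
        r = np.clip(rng.uniform(-0.9, 0.9, (8, 8)), -0.95, 0.95)
        r = (r + r.T) / 2
        z = np.arctanh(r)
        np.fill_diagonal(z, np.nan)
        prev = None
        for thr in np.arange(0.1, 0.81, 0.1):
            adj = net.threshold_adjacency(z, thr)
            if prev is not None:
                assert not (adj & ~prev).any()  # no new edges at higher thr
            prev = adj

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            net.threshold_adjacency(np.zeros((3, 3)), 1.5)


# ---------------------------------------------------------------------------
# Independent brute-force graph oracle: BFS distances + triangle enumeration
# ---------------------------------------------------------------------------

def _bfs_distances(adj, start):
    n = len(adj)
    dist = {start: 0}
    q = deque([start])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    del dist[start]
    return dist


def _oracle_measures(adj):
    n = len(adj)
    rows = []
    inv_sum = 0.0
    all_d = []
    for i in range(n):
        neigh = np.flatnonzero(adj[i])
        deg = len(neigh)
        # clustering: realized / possible edges among neighbours
        if deg >= 2:
            links = sum(
                adj[u, v] for u, v in itertools.combinations(neigh, 2)
            )
            clust = 2.0 * links / (deg * (deg - 1))
        else:
            clust = 0.0
        # local efficiency: global efficiency of neighbour-induced subgraph
        if deg >= 2:
            sub = adj[np.ix_(neigh, neigh)]
            acc = 0.0
            for u in range(deg):
                du = _bfs_distances(sub, u)
                acc += sum(1.0 / d for d in du.values())
            leff = acc / (deg * (deg - 1))
        else:
            leff = 0.0
        dists = _bfs_distances(adj, i)
        inv_sum += sum(1.0 / d for d in dists.values())
        all_d.extend(dists.values())
        pl = np.mean(list(dists.values())) if dists else np.nan
        rows.append((deg, clust, leff, pl))
    geff = inv_sum / (n * (n - 1))
    net_pl = np.mean(all_d) if all_d else np.nan
    return rows, geff, net_pl


class TestGraphMeasures:
    def test_triangle_graph_hand_values(self):
        adj = np.ones((3, 3), dtype=bool)
        np.fill_diagonal(adj, False)
        out = net.graph_measures(adj)
        nodes = out[out.node != "__network__"]
        assert (nodes.degree == 2).all()
        assert (nodes.clustering == 1.0).all()
        assert (nodes.path_length == 1.0).all()
        netrow = out[out.node == "__network__"].iloc[0]
        assert netrow.global_efficiency == pytest.approx(1.0)
        assert netrow.path_length == pytest.approx(1.0)

    def test_path_graph_hand_values(self):
        adj = np.array(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool
        )
        out = net.graph_measures(adj, roi_names=["a", "b", "c"])
        mid = out[out.node == "b"].iloc[0]
        assert mid.clustering == 0.0
        netrow = out[out.node == "__network__"].iloc[0]
        assert netrow.path_length == pytest.approx(4.0 / 3.0)
        assert netrow.global_efficiency == pytest.approx(5.0 / 6.0)

    def test_matches_bruteforce_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            p = rng.uniform(0.15, 0.7)
            adj = rng.random((8, 8)) < p
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            out = net.graph_measures(adj)
            nodes = out[out.node != "__network__"]
            rows, geff, net_pl = _oracle_measures(adj)
            for (deg, clust, leff, pl), (_, row) in zip(rows, nodes.iterrows()):
                assert row.degree == deg
                assert row.clustering == pytest.approx(clust, abs=1e-12)
                assert row.local_efficiency == pytest.approx(leff, abs=1e-12)
                np.testing.assert_allclose(row.path_length, pl, atol=1e-12)
            netrow = out[out.node == "__network__"].iloc[0]
            assert netrow.global_efficiency == pytest.approx(geff, abs=1e-12)
            np.testing.assert_allclose(netrow.path_length, net_pl, atol=1e-12)

    def test_degree_sums_to_twice_edge_count(self, rng):
        adj = rng.random((10, 10)) < 0.3
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        out = net.graph_measures(adj)
        total = out[out.node != "__network__"].degree.sum()
        assert total == 2 * np.triu(adj, 1).sum()

    def test_invariant_under_node_relabeling(self, rng):
        adj = rng.random((7, 7)) < 0.4
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        perm = rng.permutation(7)
        a = net.graph_measures(adj)
        b = net.graph_measures(adj[np.ix_(perm, perm)])
        a_nodes = a[a.node != "__network__"].iloc[perm].reset_index(drop=True)
        b_nodes = b[b.node != "__network__"].reset_index(drop=True)
        for col in ("degree", "clustering", "local_efficiency", "path_length"):
            np.testing.assert_allclose(
                a_nodes[col].to_numpy(dtype=float),
                b_nodes[col].to_numpy(dtype=float),
                atol=1e-12,
            )


class TestAggregateAndContrast:
    def test_identical_conditions_yield_zero_t_and_no_rejections(self, rng):
        base = rng.standard_normal((8, 6, 6)) * 0.3
        base = (base + base.transpose(0, 2, 1)) / 2
        stack = _stack_from_diffs(np.zeros((8, 6, 6)), base=base)
        out = net.aggregate_and_contrast(stack, thresholds=(0.1, 0.2, 0.3))
        assert np.allclose(out["network"].t, 0.0)
        assert (out["roi"].p_fdr > 0.05).all()

    def test_constant_measure_aggregation_returns_constant(self):
        # complete graph at every threshold: every measure constant
        r = np.full((4, 4), 0.95)
        z = np.arctanh(r)
        np.fill_diagonal(z, np.nan)
        d = np.zeros((6, 4, 4))
        stack = _stack_from_diffs(d, base=np.tile(z, (6, 1, 1)))
        out = net.aggregate_and_contrast(stack, thresholds=(0.1, 0.4, 0.8))
        subj = out["subject_measures"]
        nodes = subj[subj.node != "__network__"]
        assert np.allclose(nodes.degree, 3.0)
        assert np.allclose(nodes.clustering, 1.0)

    def test_injected_subnetwork_shows_highest_degree_contrast(self, small_config,
                                                               small_timeseries):
        stack = net.build_connectivity_stack(small_timeseries)
        out = net.aggregate_and_contrast(stack)
        deg = out["roi"].query("measure == 'degree'").set_index("node")
        contrast = deg.mean_HI - deg.mean_LO
        top = set(contrast.nlargest(4).index)
        assert len(top & set(small_config.fc_subnetwork)) >= 3
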