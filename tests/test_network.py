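"""Coherence matrices, binarization, and clustering-coefficient tests.

Clustering is cross-checked against both an exhaustive neighbour-pair
oracle and networkx.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from flightlfp.network import (binarize, clustering, coherence_matrix,
                               network_by_state)

FS = 1000.0


def clustering_oracle(adj):
    """Brute force: for each node enumerate neighbour pairs, count edges."""
    n = adj.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        d = len(nb)
        if d < 2:
            continue
        e = sum(adj[u, v] for u, v in itertools.combinations(nb, 2))
        cc[i] = 2.0 * e / (d * (d - 1))
    return cc


class TestCoherence:
    def _white(self, rng, n_ch=4, dur=3.0):
        return rng.standard_normal((n_ch, int(dur * FS)))

    def test_unit_diagonal(self, rng):
        net = coherence_matrix(self._white(rng), FS)
        assert np.allclose(np.diag(net.matrix), 1.0)

    def test_symmetry_and_range(self, rng):
        m = coherence_matrix(self._white(rng), FS).matrix
        assert np.allclose(m, m.T)
        assert np.nanmin(m) >= 0 and np.nanmax(m) <= 1 + 1e-12

    def test_independent_channels_low_coherence(self, rng):
        # 4 s window / 0.5 s segments / 50% overlap -> 15 averaging segments
        net = coherence_matrix(self._white(rng, dur=4.0), FS)
        iu = np.triu_indices(4, k=1)
        assert net.matrix[iu].max() < 0.2

    def test_shared_source_closed_form(self, rng):
        """x_i = s + n_i with equal powers: MSC -> SNR^2/(1+SNR)^2 = 1/4."""
        n = int(20 * FS)
        s = rng.standard_normal(n)
        x = np.vstack([s + rng.standard_normal(n),
                       s + rng.standard_normal(n)])
        net = coherence_matrix(x, FS, band=(1.0, 400.0))
        assert net.matrix[0, 1] == pytest.approx(0.25, abs=0.05)

    def test_amplitude_scaling_invariance(self, rng):
        x = self._white(rng)
        m1 = coherence_matrix(x, FS).matrix
        x2 = x.copy()
        x2[1] *= 137.0
        m2 = coherence_matrix(x2, FS).matrix
        assert np.allclose(m1, m2, atol=1e-12)

    def test_silent_channel_flagged_undefined(self, rng):
        x = self._white(rng)
        x[2] = 0.0
        net = coherence_matrix(x, FS)
        assert 2 in net.undefined_channels
        assert np.isnan(net.matrix[2, 0]) and np.isnan(net.matrix[0, 2])

    def test_window_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            coherence_matrix(rng.standard_normal((4, 600)), FS)


class TestBinarize:
    def test_all_equal_offdiagonal_ties_keep_all(self):
        m = np.full((5, 5), 0.4)
        np.fill_diagonal(m, 1.0)
        adj = binarize(m, density=0.3)
        iu = np.triu_indices(5, k=1)
        assert adj[iu].sum() == iu[0].size  # every tie kept

    def test_zero_offdiagonal_empty_graph(self):
        adj = binarize(np.eye(6), density=0.3)
        assert not adj.any()

    def test_four_node_toy_matches_sort_oracle(self):
        m = np.array([
            [1.0, 0.9, 0.1, 0.2],
            [0.9, 1.0, 0.5, 0.3],
            [0.1, 0.5, 1.0, 0.8],
            [0.2, 0.3, 0.8, 1.0],
        ])
        adj = binarize(m, density=0.34)  # keep top 2 of 6 pairs
        expect = np.zeros((4, 4), dtype=int)
        expect[0, 1] = expect[1, 0] = 1
        expect[2, 3] = expect[3, 2] = 1
        assert np.array_equal(adj, expect)

    def test_absolute_rule(self):
        m = np.array([[1.0, 0.7, 0.2], [0.7, 1.0, 0.4], [0.2, 0.4, 1.0]])
        adj = binarize(m, rule="absolute", threshold=0.5)
        assert adj.sum() == 2 and adj[0, 1] == 1

    def test_density_monotonicity(self, rng):
        """Raising the density never removes any node's neighbour edges."""
        for _ in range(10):
            m = rng.random((8, 8))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
            prev = None
            for dens in (0.1, 0.3, 0.5, 0.8):
                e = clustering(binarize(m, density=dens)).neighbor_edges
                if prev is not None:
                    assert np.all(e >= prev)
                prev = e


class TestClustering:
    def test_complete_graph_all_ones(self):
        adj = 1 - np.eye(8, dtype=int)
        met = clustering(adj)
        assert np.allclose(met.clustering_coeff, 1.0)
        assert met.mean_clustering == pytest.approx(1.0)

    def test_path_middle_node_zero(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        met = clustering(adj)
        assert met.clustering_coeff[1] == 0.0
        assert met.neighbor_edges[1] == 0

    def test_matches_bruteforce_and_networkx(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            adj = (rng.random((n, n)) < 0.4).astype(int)
            adj = np.triu(adj, k=1)
            adj = adj + adj.T
            met = clustering(adj)
            assert np.allclose(met.clustering_coeff, clustering_oracle(adj))
            g = nx.from_numpy_array(adj)
            nx_cc = np.array([nx.clustering(g, i) for i in range(n)])
            assert np.allclose(met.clustering_coeff, nx_cc)

    def test_rejects_directed_or_self_loops(self):
        bad = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError):
            clustering(bad)
        with pytest.raises(ValueError):
            clustering(np.eye(3, dtype=int))


class TestNetworkByState:
    def test_planted_u_shape_in_clustering(self, flight60):
        cfg, truth = flight60["cfg"], flight60["truth"]
        df = network_by_state(truth.clean_lfp, cfg.fs_lfp,
                              flight60["segments"])
        means = df.groupby("state")["mean_clustering"].mean()
        assert means["deceleration"] > means["steady"]
        assert means["acceleration"] > means["steady"]

    def test_null_effects_no_state_difference(self, flight60_null):
        from flightlfp.stats import compare_groups
        cfg, truth = flight60_null["cfg"], flight60_null["truth"]
        df = network_by_state(truth.clean_lfp, cfg.fs_lfp,
                              flight60_null["segments"])
        groups = [df.loc[df.state == s, "mean_clustering"].to_numpy()
                  for s in ("acceleration", "steady", "deceleration")]
        assert compare_groups(*groups).pvalue > 0.05

    def test_single_window_single_row(self, flight60):
        cfg, truth = flight60["cfg"], flight60["truth"]
        seg = [s for s in flight60["segments"] if 5 < s.start_s < 50][0]
        df = network_by_state(truth.clean_lfp, cfg.fs_lfp, [seg])
        assert len(df) == 1 and df.iloc[0]["state"] == seg.label

    def test_qc_flagged_windows_skipped(self, flight60):
        import copy
        cfg, truth = flight60["cfg"], flight60["truth"]
        segs = [copy.deepcopy(s) for s in flight60["segments"][10:14]]
        segs[0].qc_flags.add("gps_gap")
        df = network_by_state(truth.clean_lfp, cfg.fs_lfp, segs)
        assert len(df) == 3 and df.attrs["skipped_windows"] == 1
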