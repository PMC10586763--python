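"""Centrality, window aggregation, comparisons and hub detection."""

import math

import numpy as np
import pytest

from conftest import betweenness_bruteforce, random_network
from lspprn.align import ResidueNetwork
from lspprn.metrics import (
    aggregate_windows,
    betweenness_centrality,
    degree_centrality,
    detect_hubs,
    edge_distances,
    percent_difference,
)


def _net(weights, n=None):
    nodes = sorted({i for e in weights for i in e})
    n = n or len(nodes)
    idx = tuple(range(1, n + 1))
    return ResidueNetwork(
        n_residues=n, weights=dict(weights),
        residue_indices=idx, residue_labels=tuple(f"A{i}" for i in idx),
    )


class TestDegree:
    def test_complete_graph(self):
        w = {(i, j): 1.0 for i in range(1, 5) for j in range(i + 1, 5)}
        assert degree_centrality(_net(w)) == {1: 3.0, 2: 3.0, 3: 3.0, 4: 3.0}

    def test_path_graph_sums(self):
        dc = degree_centrality(_net({(1, 2): 0.5, (2, 3): 0.25}))
        assert dc == {1: 0.5, 2: 0.75, 3: 0.25}

    def test_equals_matrix_row_sums(self, rng):
        net = random_network(rng, 20)
        M = np.zeros((20, 20))
        for (i, j), w in net.weights.items():
            M[i - 1, j - 1] = M[j - 1, i - 1] = w
        dc = degree_centrality(net)
        np.testing.assert_allclose(
            [dc[i] for i in range(1, 21)], M.sum(axis=1), atol=1e-12
        )


class TestEdgeDistances:
    def test_closed_forms(self):
        d = edge_distances(_net({(1, 2): 1.0, (2, 3): math.exp(-1)}))
        assert d[(1, 2)] == 0.0
        assert d[(2, 3)] == pytest.approx(1.0)

    def test_monotone_in_weight(self, rng):
        ws = sorted(rng.uniform(0.01, 1.0, size=20))
        ds = [edge_distances(_net({(1, 2): w}))[(1, 2)] for w in ws]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_invalid_weight_rejected_at_construction(self):
        with pytest.raises(ValueError, match=r"outside \(0, 1\]"):
            _net({(1, 2): 1.5})
        with pytest.raises(ValueError, match=r"outside \(0, 1\]"):
            _net({(1, 2): 0.0})


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness_centrality(_net({(1, 2): 0.5, (2, 3): 0.9}))
        assert bc == {1: 0.0, 2: 1.0, 3: 0.0}

    def test_four_cycle_equal_split(self):
        w = {(1, 2): 0.5, (2, 3): 0.5, (3, 4): 0.5, (1, 4): 0.5}
        bc = betweenness_centrality(_net(w))
        assert all(v == pytest.approx(0.5) for v in bc.values())

    def test_disconnected_pairs_contribute_nothing(self):
        bc = betweenness_centrality(_net({(1, 2): 0.5, (3, 4): 0.5}, n=5))
        assert all(v == 0.0 for v in bc.values())

    def test_zero_distance_edges_are_legal(self):
        """W=1 edges (D=0) are handled: ties in total distance refine by
        hop count, so a fully conserved triangle routes pairs directly."""
        w = {(1, 2): 1.0, (2, 3): 1.0, (1, 3): 1.0, (3, 4): 0.5}
        bc = betweenness_centrality(_net(w))
        oracle = betweenness_bruteforce(_net(w))
        for v in bc:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)
        assert bc[3] == pytest.approx(2.0)  # bridges 4 to 1 and 2

    def test_parallel_zero_paths_split_credit(self):
        """Two equal-hop zero-distance routes both count."""
        w = {(1, 2): 1.0, (2, 4): 1.0, (1, 3): 1.0, (3, 4): 1.0}
        bc = betweenness_centrality(_net(w))
        assert bc[2] == pytest.approx(0.5)
        assert bc[3] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_networkx_on_positive_distances(self, seed):
        """Independent cross-check against the networkx implementation
        (valid where no zero-distance edges exist)."""
        import networkx as nx
        from lspprn.metrics import to_networkx

        net = random_network(np.random.default_rng(100 + seed), 12, p=0.4)
        ours = betweenness_centrality(net)
        ref = nx.betweenness_centrality(
            to_networkx(net), weight="distance", normalized=False
        )
        for v in ours:
            assert ours[v] == pytest.approx(ref[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_exhaustive_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, int(rng.integers(4, 9)), p=0.5)
        bc = betweenness_centrality(net)
        oracle = betweenness_bruteforce(net)
        for v in oracle:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_invariant_under_distance_rescaling(self, rng):
        """W → W^c rescales every distance by the same factor c (this is
        what changing the log base does), leaving shortest paths and BC
        unchanged."""
        net = random_network(rng, 10, p=0.5)
        for c in (0.5, 2.0):
            scaled = _net({e: w**c for e, w in net.weights.items()}, n=10)
            a = betweenness_centrality(net)
            b = betweenness_centrality(scaled)
            for v in a:
                assert a[v] == pytest.approx(b[v], abs=1e-9)


class TestAggregation:
    def test_identical_windows_zero_se(self):
        dc = {1: 2.0, 2: 3.0}
        bc = {1: 0.0, 2: 1.0}
        prof = aggregate_windows([(0, dc, bc), (1, dc, bc), (2, dc, bc)], "WT")
        np.testing.assert_allclose(prof.dc_mean, [2.0, 3.0])
        np.testing.assert_allclose(prof.dc_se, [0.0, 0.0])
        assert prof.n_windows == 3

    def test_two_window_hand_arithmetic(self):
        prof = aggregate_windows(
            [(0, {1: 1.0}, {1: 0.0}), (1, {1: 3.0}, {1: 0.0})], "WT"
        )
        assert prof.dc_mean[0] == pytest.approx(2.0)
        # sample SD = sqrt(2), SE = sqrt(2)/sqrt(2) = 1
        assert prof.dc_se[0] == pytest.approx(1.0)

    def test_fifteen_windows_match_direct_formula(self, rng):
        vals = rng.normal(5.0, 1.0, size=(15, 4))
        per_window = [
            (k, {i + 1: vals[k, i] for i in range(4)},
             {i + 1: 0.0 for i in range(4)})
            for k in range(15)
        ]
        prof = aggregate_windows(per_window, "WT")
        np.testing.assert_allclose(prof.dc_mean, vals.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            prof.dc_se, vals.std(axis=0, ddof=1) / np.sqrt(15), atol=1e-12
        )

    def test_se_shrinks_with_window_count(self, rng):
        """SE scales ~1/sqrt(m) for i.i.d. window values."""
        ses = []
        for m in (4, 16, 64):
            vals = rng.normal(0.0, 1.0, size=(m, 1))
            per_window = [(k, {1: vals[k, 0]}, {1: 0.0}) for k in range(m)]
            ses.append(aggregate_windows(per_window, "x").dc_se[0])
        assert ses[0] > ses[1] > ses[2]

    def test_roster_mismatch_raises(self):
        with pytest.raises(ValueError, match="roster"):
            aggregate_windows(
                [(0, {1: 1.0}, {1: 0.0}), (1, {2: 1.0}, {2: 0.0})], "x"
            )

    def test_requires_two_windows(self):
        with pytest.raises(ValueError):
            aggregate_windows([(0, {1: 1.0}, {1: 0.0})], "x")


class TestPercentDifference:
    def _profile(self, label, dc_rows):
        m = np.asarray(dc_rows, float)
        return aggregate_windows(
            [(k, {i + 1: m[k, i] for i in range(m.shape[1])},
              {i + 1: 0.0 for i in range(m.shape[1])})
             for k in range(m.shape[0])],
            label,
        )

    def test_identical_profiles_zero(self):
        p = self._profile("WT", [[1.0, 2.0], [1.0, 2.0]])
        rep = percent_difference(p, p, "DC")
        np.testing.assert_allclose(rep.pct_diff, [0.0, 0.0])

    def test_plus_fifty_percent(self):
        ref = self._profile("WT", [[2.0], [2.0]])
        mut = self._profile("M", [[3.0], [3.0]])
        rep = percent_difference(mut, ref, "DC")
        assert rep.pct_diff[0] == pytest.approx(50.0)
        assert rep.mutant_label == "M" and rep.reference_label == "WT"

    def test_zero_reference_flagged_not_dropped(self):
        ref = self._profile("WT", [[0.0, 1.0], [0.0, 1.0]])
        mut = self._profile("M", [[1.0, 2.0], [1.0, 2.0]])
        rep = percent_difference(mut, ref, "DC")
        assert rep.undefined == (1,)
        assert np.isnan(rep.pct_diff[0])
        assert rep.pct_diff[1] == pytest.approx(100.0)

    def test_roster_mismatch_raises(self):
        ref = self._profile("WT", [[1.0], [1.0]])
        mut = self._profile("M", [[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="roster"):
            percent_difference(mut, ref)


class TestDetectHubs:
    @staticmethod
    def _clique(members, w=1.0):
        m = sorted(members)
        return {(i, j): w for a, i in enumerate(m) for j in m[a + 1:]}

    def test_two_cliques_weak_bridge(self):
        w = {**self._clique(range(1, 6)), **self._clique(range(6, 11), 0.9)}
        w[(5, 6)] = 0.05
        part = detect_hubs(_net(w))
        assert set(part.communities) == {
            frozenset(range(1, 6)), frozenset(range(6, 11))
        }
        # ranked by mean DC: the W=1 clique first
        assert part.communities[0] == frozenset(range(1, 6))
        assert part.community_mean_dc[0] > part.community_mean_dc[1]

    def test_single_clique(self):
        part = detect_hubs(_net(self._clique(range(1, 6))))
        assert part.communities == (frozenset(range(1, 6)),)

    def test_isolated_residues_get_own_community(self):
        part = detect_hubs(_net(self._clique(range(1, 4)), n=5))
        assert frozenset([4]) in part.communities
        assert frozenset([5]) in part.communities

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_two_block_recovery(self, seed):
        """≥90% assignment accuracy on a noisy planted 2-block network."""
        rng = np.random.default_rng(seed)
        n = 20
        truth = {i: 0 if i <= 10 else 1 for i in range(1, n + 1)}
        w = {}
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p_in, p_out = 0.8, 0.1
                if rng.random() < (p_in if truth[i] == truth[j] else p_out):
                    w[(i, j)] = float(rng.uniform(0.4, 1.0))
        part = detect_hubs(_net(w, n=n))
        # map each detected community to its majority planted label
        correct = 0
        for c in part.communities:
            labels = [truth[v] for v in c]
            correct += max(labels.count(0), labels.count(1))
        assert correct / n >= 0.9

    def test_deterministic(self, rng):
        net = random_network(rng, 15, p=0.3)
        a = detect_hubs(net)
        b = detect_hubs(net)
        assert a.communities == b.communities
        assert a.labels == b.labels
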