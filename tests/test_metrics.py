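"""Network measures against brute-force oracles; inequality and timing measures."""

import itertools

import numpy as np
import pytest

from trophallaxis.metrics import (
    activity_distributions,
    build_network,
    global_efficiency,
    lorenz_gini,
    node_centralities,
    t50,
)
from trophallaxis.model_core import Caste
from trophallaxis.simulator import TrophallaxisEvent


def ev(donor, receiver, t_start=1, t_end=1, amount=10.0, dc=Caste.NF, rc=Caste.NF):
    return TrophallaxisEvent(donor_id=donor, receiver_id=receiver, t_start=t_start,
                             t_end=t_end, amount=amount,
                             donor_caste_at_start=dc, receiver_caste_at_start=rc)


def net_from_edges(edges, n):
    events = [ev(a, b) for a, b in edges]
    return build_network(events, range(n))


# ---------------------------------------------------------------------------
# brute-force shortest-path oracles (small n only)


def brute_distances(n, edges, directed):
    adj = {(a, b) for a, b in edges}
    if not directed:
        adj |= {(b, a) for a, b in edges}
    INF = float("inf")
    d = [[0 if i == j else (1 if (i, j) in adj else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_efficiency(n, edges):
    d = brute_distances(n, edges, directed=False)
    return sum(1.0 / d[i][j] for i in range(n) for j in range(n)
               if i != j and d[i][j] != float("inf")) / (n * (n - 1))


def brute_closeness(n, edges):
    """Hop-count closeness with the reachable-component normalization."""
    d = brute_distances(n, edges, directed=False)
    out = []
    for i in range(n):
        reach = [d[j][i] for j in range(n) if j != i and d[j][i] != float("inf")]
        if not reach:
            out.append(0.0)
            continue
        r = len(reach)
        out.append((r / sum(reach)) * (r / (n - 1)))
    return out


def brute_betweenness(n, edges):
    """Directed betweenness by exhaustive simple-path enumeration."""
    adj = {i: [b for a, b in edges if a == i] for i in range(n)}
    INF = float("inf")
    score = [0.0] * n
    for s, t in itertools.permutations(range(n), 2):
        # enumerate all simple paths s -> t
        paths, stack = [], [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
        if not paths:
            continue
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p[1:-1])
            score[v] += through / len(shortest)
    norm = (n - 1) * (n - 2)
    return [x / norm for x in score] if norm else score


# ---------------------------------------------------------------------------


def test_build_network_counts_and_isolates():
    events = [ev(0, 1), ev(0, 1), ev(0, 1), ev(1, 0)]
    net = build_network(events, range(5))
    assert net.n_nodes == 5
    assert net.graph[0][1]["weight"] == 3
    assert net.graph[1][0]["weight"] == 1
    assert net.graph[0][1]["amount"] == 30.0
    empty = build_network([], range(53))
    assert empty.n_nodes == 53 and empty.graph.number_of_edges() == 0
    with pytest.raises(ValueError):
        build_network([ev(0, 99)], range(5))


def test_efficiency_closed_forms():
    assert global_efficiency(net_from_edges([(0, 1)], 2)) == pytest.approx(1.0)
    assert global_efficiency(net_from_edges([(0, 1), (1, 2)], 3)) == pytest.approx(5 / 6)
    assert global_efficiency(net_from_edges([], 4)) == 0.0
    with pytest.raises(ValueError):
        global_efficiency(net_from_edges([], 1))


def test_star_center_has_full_betweenness():
    edges = [(0, leaf) for leaf in range(1, 6)]
    cent = node_centralities(net_from_edges(edges, 6), betweenness_directed=False)
    assert cent.loc[0, "betweenness"] == pytest.approx(1.0)
    assert all(cent.loc[leaf, "betweenness"] == 0 for leaf in range(1, 6))


def test_triangle_is_fully_clustered():
    cent = node_centralities(net_from_edges([(0, 1), (1, 2), (2, 0)], 3))
    assert np.allclose(cent["clustering"], 1.0)


def test_isolate_conventions():
    cent = node_centralities(net_from_edges([(0, 1)], 3))
    assert cent.loc[2].tolist() == [0.0, 0.0, 0.0]


def test_metrics_match_brute_force_on_small_graphs():
    """Efficiency, closeness and directed betweenness agree with exhaustive
    path enumeration on random digraphs of up to 6 nodes."""
    rng = np.random.default_rng(42)
    for trial in range(25):
        n = int(rng.integers(2, 7))
        possible = [(a, b) for a in range(n) for b in range(n) if a != b]
        k = int(rng.integers(0, len(possible) + 1))
        idx = rng.choice(len(possible), size=k, replace=False)
        edges = [possible[i] for i in idx]
        net = net_from_edges(edges, n)
        assert global_efficiency(net) == pytest.approx(brute_efficiency(n, edges))
        cent = node_centralities(net)
        assert np.allclose(cent["closeness"], brute_closeness(n, edges))
        assert np.allclose(cent["betweenness"], brute_betweenness(n, edges), atol=1e-9)


def test_efficiency_monotone_under_edge_addition():
    rng = np.random.default_rng(3)
    n = 6
    possible = [(a, b) for a in range(n) for b in range(n) if a != b]
    rng.shuffle(possible)
    edges, last = [], 0.0
    for e in possible:
        edges.append(e)
        eff = global_efficiency(net_from_edges(edges, n))
        assert eff >= last - 1e-12
        last = eff


class TestLorenzGini:
    def test_equal_counts_zero(self):
        _, g = lorenz_gini([5, 5, 5, 5])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_single_active_ant(self):
        _, g = lorenz_gini([0, 0, 0, 12])
        assert g == pytest.approx(0.75)

    def test_permutation_and_scale_invariance(self):
        counts = [3, 0, 7, 1, 9, 9, 2]
        _, g = lorenz_gini(counts)
        _, g_perm = lorenz_gini(counts[::-1])
        _, g_scaled = lorenz_gini([10 * c for c in counts])
        assert g == pytest.approx(g_perm) == pytest.approx(g_scaled)

    def test_bounds_and_errors(self):
        _, g = lorenz_gini([0] * 52 + [1])
        assert g == pytest.approx(1 - 1 / 53)
        with pytest.raises(ValueError):
            lorenz_gini([0, 0, 0])
        with pytest.raises(ValueError):
            lorenz_gini([1, -2, 3])

    def test_lorenz_curve_convex_and_monotone(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=40)
        counts[0] = 5  # ensure not all zero
        pts, _ = lorenz_gini(counts)
        y = pts[:, 1]
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(np.diff(y, 2) >= -1e-12)  # slopes nondecreasing (sorted shares)


class TestT50:
    def test_uniform_starts(self):
        events = [ev(0, 1, t, t) for t in range(1, 101)]
        assert t50(events) == 50

    def test_point_mass(self):
        assert t50([ev(0, 1, 10, 12)] * 7) == 10

    def test_toy_log(self):
        events = [ev(0, 1, t, t) for t in (3, 7, 7, 900)]
        assert t50(events) == 7

    def test_horizon_and_errors(self):
        events = [ev(0, 1, t, t) for t in (3, 7, 7, 900)]
        assert t50(events, horizon=100) == 7
        with pytest.raises(ValueError):
            t50([])


def test_activity_single_event():
    castes = {i: Caste.NF for i in range(5)}
    profile = activity_distributions([ev(0, 1)], range(5), castes)
    t = profile.table
    assert t.loc[0, "given"] == 1 and t.loc[1, "received"] == 1
    assert t.loc[2:, "total"].sum() == 0


def test_activity_hand_tally_and_conservation():
    castes = {0: Caste.F, 1: Caste.F, 2: Caste.NF, 3: Caste.NF, 4: Caste.NF}
    events = [ev(0, 2), ev(0, 2), ev(0, 3), ev(2, 3), ev(2, 4), ev(1, 0)]
    profile = activity_distributions(events, range(5), castes)
    t = profile.table
    assert t["given"].tolist() == [3, 1, 2, 0, 0]
    assert t["received"].tolist() == [1, 0, 2, 2, 1]
    assert t["given"].sum() == t["received"].sum() == len(events)
    # caste-split histograms cover all individuals, including inactive ones
    f_given = profile.histogram("given", Caste.F)
    nf_given = profile.histogram("given", Caste.NF)
    assert int(f_given.mul(f_given.index).sum() + nf_given.mul(nf_given.index).sum()) == 6
    assert nf_given.loc[0] == 2  # two inactive non-forager donors
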