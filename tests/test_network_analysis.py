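"""Rankings, intersections, receptor subnetworks, differential networks."""

import numpy as np
import pytest

from grnrewire.grn_construction import Evidence, GRN
from grnrewire.network_analysis import (
    diff_network,
    diff_receptor_network,
    intersect_networks,
    pagerank_scores,
    rank_regulators_by_outdegree,
    rank_regulators_by_pagerank,
    receptor_subnetwork,
)

from conftest import random_grn


def ev(peak="p", motif="M", pv=1e-5):
    return Evidence(peak, motif, "+", 0, pv)


def grn_from_edges(edges, receptors=()):
    grn = GRN()
    for tf, gene in edges:
        grn.add_edge(tf, gene, ev(f"p_{tf}_{gene}"))
    for r in receptors:
        if r in grn.roles:
            grn.add_role(r, "receptor")
    return grn


# ---------------------------------------------------------------- outdegree


def test_outdegree_ranks_by_distinct_targets():
    grn = grn_from_edges([("T1", "g1"), ("T1", "g2"), ("T2", "g1")])
    ranking = rank_regulators_by_outdegree(grn)
    assert ranking.entries == (("T1", 2.0), ("T2", 1.0))


def test_outdegree_ties_break_lexicographically():
    grn = grn_from_edges([("Tb", "g1"), ("Ta", "g2"), ("Tc", "g3")])
    assert rank_regulators_by_outdegree(grn).names() == ["Ta", "Tb", "Tc"]


def test_outdegree_matches_brute_force_census():
    rng = np.random.default_rng(21)
    grn = random_grn(rng, n_tfs=12, n_genes=40)
    census = {tf: len({g for (t, g) in grn.edges if t == tf}) for tf in grn.tfs()}
    expected = sorted(census.items(), key=lambda kv: (-kv[1], kv[0]))[:20]
    assert list(rank_regulators_by_outdegree(grn, k=20).entries) == [
        (tf, float(c)) for tf, c in expected
    ]


# ----------------------------------------------------------------- pagerank


def dense_pagerank(grn, damping=0.85, reverse=True):
    """Oracle: solve the stationary equations with a dense linear system."""
    nodes = sorted(grn.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    P = np.zeros((n, n))  # P[i, j] = probability of stepping i -> j
    for (tf, gene) in grn.edges:
        s, d = (gene, tf) if reverse else (tf, gene)
        P[idx[s], idx[d]] = 1.0
    row_sums = P.sum(axis=1)
    for i in range(n):
        P[i] = P[i] / row_sums[i] if row_sums[i] else 1.0 / n
    pi = np.linalg.solve(np.eye(n) - damping * P.T, np.full(n, (1 - damping) / n))
    return dict(zip(nodes, pi / pi.sum()))


def test_edgeless_network_gives_uniform_scores():
    grn = GRN()
    for name in "abcd":
        grn.add_role(name, "gene")
    scores, converged, _ = pagerank_scores(grn)
    assert converged
    assert all(s == pytest.approx(0.25, abs=1e-9) for s in scores.values())


def test_pagerank_scores_sum_to_one_and_match_dense_solve():
    rng = np.random.default_rng(33)
    for _ in range(5):
        grn = random_grn(rng, n_tfs=10, n_genes=30)
        scores, converged, _ = pagerank_scores(grn)
        assert converged
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
        oracle = dense_pagerank(grn)
        err = max(abs(scores[v] - oracle[v]) for v in scores)
        assert err < 1e-8


def test_pagerank_agrees_with_networkx_on_forward_graph():
    import networkx as nx

    rng = np.random.default_rng(40)
    grn = random_grn(rng, n_tfs=8, n_genes=20)
    scores, _, _ = pagerank_scores(grn, reverse=False)
    g = nx.DiGraph(list(grn.edges))
    g.add_nodes_from(grn.nodes())
    nx_scores = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=500)
    err = max(abs(scores[v] - nx_scores[v]) for v in scores)
    assert err < 1e-7


def test_reversed_pagerank_ranks_regulators_not_targets():
    # hub TF regulating many genes must outrank every gene-only node
    grn = grn_from_edges([("Thub", f"g{i}") for i in range(10)])
    ranking = rank_regulators_by_pagerank(grn, k=5)
    assert ranking.names()[0] == "Thub"


def test_nonconvergence_is_flagged_but_returns_scores():
    grn = grn_from_edges([("T1", "g1"), ("T2", "g2")])
    scores, converged, residual = pagerank_scores(grn, max_iter=1)
    assert not converged
    assert residual > 0
    assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------------ intersections


def test_two_network_intersection_counts():
    g1 = grn_from_edges([("T", "a"), ("T", "b")])
    g2 = grn_from_edges([("T", "b"), ("T", "c")])
    table = intersect_networks({"one": g1, "two": g2}, "genes")
    assert table.unique == {"one": 1, "two": 1}
    assert table.signatures[("one", "two")] == {"b"}


def test_identical_networks_all_in_full_intersection():
    g = grn_from_edges([("T", "a"), ("T", "b")])
    table = intersect_networks({"x": g, "y": g, "z": g}, "genes")
    assert set(table.signatures) == {("x", "y", "z")}
    assert table.unique == {"x": 0, "y": 0, "z": 0}


def test_signature_counts_match_per_element_enumeration():
    rng = np.random.default_rng(17)
    nets = {name: random_grn(rng, n_tfs=6, n_genes=15) for name in "abc"}
    table = intersect_networks(nets, "genes")
    sets = {name: nets[name].genes() for name in nets}
    for e in set().union(*sets.values()):
        sig = tuple(sorted(name for name in sets if e in sets[name]))
        assert e in table.signatures[sig]
    matrix = table.membership_matrix()
    for name in nets:
        assert set(matrix.index[matrix[name]]) == sets[name]


# --------------------------------------------------------------- receptors


def test_receptor_subnetwork_keeps_only_regulated_receptors():
    grn = grn_from_edges(
        [("T1", "r"), ("T2", "r"), ("T3", "g")], receptors=["r"]
    )
    sub = receptor_subnetwork(grn)
    assert set(sub.edges) == {("T1", "r"), ("T2", "r")}
    assert sub.nodes() == {"T1", "T2", "r"}


def test_receptor_subnetwork_empty_when_no_receptor_regulated():
    grn = grn_from_edges([("T1", "g1")])
    assert receptor_subnetwork(grn).edges == {}


def test_receptor_subnetwork_is_idempotent():
    rng = np.random.default_rng(29)
    grn = random_grn(rng)
    sub = receptor_subnetwork(grn)
    assert receptor_subnetwork(sub) == sub


def test_receptor_subnetwork_recovers_planted_receptor_edges(dataset):
    truth, grn = dataset["truth"], dataset["grn_a"]
    sub = receptor_subnetwork(grn)
    planted_receptor_edges = {
        (tf, g) for (tf, g) in truth.planted_edges if g in truth.receptors
    }
    assert planted_receptor_edges <= set(sub.edges)
    for (tf, g) in sub.edges:
        assert g in truth.receptors


# -------------------------------------------------------------------- diffs


def test_diff_detects_lost_receptor_with_regulator_count():
    a = grn_from_edges([("T1", "g1"), ("T1", "r")], receptors=["r"])
    b = grn_from_edges([("T1", "g1")])
    d = diff_network(a, b)
    assert d.edges_lost == {("T1", "r")}
    assert dict(d.receptors_lost) == {"r": 1}
    assert d.nodes_lost == {"r"}


def test_diff_of_identical_networks_is_empty():
    rng = np.random.default_rng(2)
    grn = random_grn(rng)
    d = diff_network(grn, grn)
    assert not d.edges_lost and not d.edges_gained
    assert not d.nodes_lost and not d.nodes_gained
    assert not d.receptors_lost


def test_diff_is_antisymmetric_under_swap():
    rng = np.random.default_rng(14)
    a, b = random_grn(rng), random_grn(rng)
    ab, ba = diff_network(a, b), diff_network(b, a)
    assert ab.edges_lost == ba.edges_gained
    assert ab.edges_gained == ba.edges_lost
    assert ab.nodes_lost == ba.nodes_gained


def test_diff_receptor_network_restricts_to_edges_absent_from_b():
    a = grn_from_edges([("T1", "r"), ("T2", "r"), ("T3", "g")], receptors=["r"])
    b = grn_from_edges([("T2", "r")], receptors=["r"])
    out = diff_receptor_network(a, b)
    assert set(out.edges) == {("T1", "r")}
    assert "receptor" in out.roles["r"]


def test_synthetic_shutdown_recovered_exactly(dataset):
    truth = dataset["truth"]
    d = diff_network(dataset["grn_a"], dataset["grn_b"])
    assert set(d.receptors_lost) == set(truth.shutdown_receptors)
    (receptor,) = truth.shutdown_receptors
    planted_regs = {tf for (tf, g) in truth.planted_edges if g == receptor}
    assert d.receptors_lost[receptor] >= len(planted_regs)
    assert truth.condition_B_deleted_edges <= d.edges_lost
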