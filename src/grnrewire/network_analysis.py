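"""Analyses over constructed GRNs.

Hub-regulator ranking (out-degree census and PageRank), multi-network set
intersections (UpSet-style membership tables), receptor regulatory
subnetworks, and differential networks between two conditions.

PageRank is run on the *reversed* edge set by default: on TF→gene edges a
standard PageRank concentrates mass on heavily regulated genes, whereas
reversing the edges lets rank flow from targets to their regulators, so
the PageRank ranking is comparable with the out-degree ranking of hub
TFs. The direction is a parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .grn_construction import GRN

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorRanking",
    "DiffResult",
    "rank_regulators_by_outdegree",
    "rank_regulators_by_pagerank",
    "pagerank_scores",
    "intersect_networks",
    "receptor_subnetwork",
    "diff_network",
    "diff_receptor_network",
]


@dataclass(frozen=True)
class RegulatorRanking:
    """Top-k TFs by a hub score; ties broken lexicographically by name."""

    entries: tuple[tuple[str, float], ...]  # (tf_name, score), scores non-increasing
    method: str  # "outdegree" | "pagerank"
    k: int

    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


@dataclass(frozen=True)
class DiffResult:
    """Set differences between two GRNs, A (reference) vs B.

    ``receptors_lost`` maps each receptor regulated in A but not regulated
    in B to its number of regulators in A.
    """

    edges_lost: frozenset[tuple[str, str]]
    edges_gained: frozenset[tuple[str, str]]
    nodes_lost: frozenset[str]
    nodes_gained: frozenset[str]
    receptors_lost: Mapping[str, int]


def _top_k(scores: dict[str, float], method: str, k: int) -> RegulatorRanking:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return RegulatorRanking(tuple(ordered), method, k)


def rank_regulators_by_outdegree(grn: GRN, k: int = 20) -> RegulatorRanking:
    """TFs ranked by number of distinct target genes."""
    scores = {tf: float(len(grn.targets_of(tf))) for tf in grn.tfs()}
    return _top_k(scores, "outdegree", k)


def pagerank_scores(
    grn: GRN,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
    reverse: bool = True,
) -> tuple[dict[str, float], bool, float]:
    """PageRank over the GRN's nodes by power iteration.

    Uniform teleport, uniform redistribution of dangling-node mass,
    stopping when the L1 change between iterates drops below ``tol``.
    Returns (scores, converged, final L1 residual); on non-convergence the
    last iterate is returned, flagged, with a warning logged. Scores sum
    to 1 within 1e-9.
    """
    nodes = sorted(grn.nodes())
    if not nodes:
        raise ValueError("PageRank needs a non-empty network")
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    out_edges: list[list[int]] = [[] for _ in range(n)]
    for (tf, gene) in grn.edges:
        src, dst = (gene, tf) if reverse else (tf, gene)
        out_edges[idx[src]].append(idx[dst])
    out_deg = np.array([len(e) for e in out_edges], dtype=float)
    dangling = out_deg == 0

    x = np.full(n, 1.0 / n)
    converged = False
    residual = np.inf
    for _ in range(max_iter):
        new = np.zeros(n)
        for i, targets in enumerate(out_edges):
            if targets:
                share = x[i] / out_deg[i]
                for j in targets:
                    new[j] += share
        dangling_mass = x[dangling].sum()
        new = damping * (new + dangling_mass / n) + (1.0 - damping) / n
        residual = float(np.abs(new - x).sum())
        x = new
        if residual < tol:
            converged = True
            break
    x = x / x.sum()  # remove accumulated float drift
    if not converged:
        logger.warning(
            "PageRank did not converge in %d iterations (L1 residual %.3g)",
            max_iter, residual,
        )
    return {nodes[i]: float(x[i]) for i in range(n)}, converged, residual


def rank_regulators_by_pagerank(
    grn: GRN,
    k: int = 20,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
    reverse: bool = True,
) -> RegulatorRanking:
    """Top-k TFs by PageRank score (reversed edges by default)."""
    scores, _, _ = pagerank_scores(grn, damping, tol, max_iter, reverse)
    tf_scores = {tf: scores[tf] for tf in grn.tfs()}
    return _top_k(tf_scores, "pagerank", k)


def _element_set(grn: GRN, element: str) -> set[str]:
    if element == "genes":
        return grn.genes()
    if element == "tfs":
        return grn.tfs()
    if element == "receptors":
        return grn.receptors()
    raise ValueError(f"unknown element kind {element!r}")


@dataclass
class IntersectionTable:
    """UpSet-style breakdown of element membership across networks.

    ``signatures`` maps a presence pattern (sorted tuple of network names)
    to the elements showing exactly that pattern; ``unique`` gives, per
    network, the count of elements found in that network only.
    """

    element: str
    names: tuple[str, ...]
    signatures: dict[tuple[str, ...], set[str]]
    unique: dict[str, int]

    def counts(self) -> dict[tuple[str, ...], int]:
        return {sig: len(members) for sig, members in self.signatures.items()}

    def membership_matrix(self) -> pd.DataFrame:
        """Boolean element × network membership matrix (UpSet input)."""
        elements: list[str] = []
        rows: list[list[bool]] = []
        for sig, members in self.signatures.items():
            for e in members:
                elements.append(e)
                rows.append([name in sig for name in self.names])
        df = pd.DataFrame(rows, index=elements, columns=list(self.names))
        return df.sort_index()


def intersect_networks(
    named_grns: Mapping[str, GRN], element: str = "genes"
) -> IntersectionTable:
    """Per-signature membership of genes/TFs/receptors across networks.

    Every element present in at least one network is binned by the exact
    subset of networks containing it; "unique" elements have a singleton
    signature (present in exactly one network of the collection).
    """
    names = tuple(sorted(named_grns))
    sets = {name: _element_set(named_grns[name], element) for name in names}
    signatures: dict[tuple[str, ...], set[str]] = {}
    for e in set().union(*sets.values()) if sets else set():
        sig = tuple(name for name in names if e in sets[name])
        signatures.setdefault(sig, set()).add(e)
    unique = {
        name: len(signatures.get((name,), set()))
        for name in names
    }
    return IntersectionTable(element, names, signatures, unique)


def receptor_subnetwork(grn: GRN) -> GRN:
    """Induced subnetwork of regulated receptors and their upstream TFs.

    Keeps every receptor-role node with at least one incoming edge, all
    its incoming edges, and the TFs sourcing them; nothing else.
    """
    sub = GRN()
    regulated_receptors = grn.receptors()
    for (tf, gene), ev in grn.edges.items():
        if gene in regulated_receptors:
            sub.add_edge(tf, gene, *ev)
            sub.add_role(gene, "receptor")
    # a TF that is itself a receptor keeps the flag only if regulated here
    for name in sub.nodes():
        if "receptor" in grn.roles.get(name, set()) and "gene" in sub.roles[name]:
            sub.add_role(name, "receptor")
    return sub


def diff_network(grn_a: GRN, grn_b: GRN) -> DiffResult:
    """Exact set differences between two GRNs (edge identity = (tf, gene)).

    ``receptors_lost`` lists receptors regulated in A that receive no edge
    in B, each with its regulator count in A — the rewiring readout for a
    receptor shut down in condition B.
    """
    edges_a, edges_b = set(grn_a.edges), set(grn_b.edges)
    nodes_a, nodes_b = grn_a.nodes(), grn_b.nodes()
    receptors_lost = {
        r: len(grn_a.regulators_of(r))
        for r in grn_a.receptors()
        if r not in grn_b.receptors()
    }
    return DiffResult(
        edges_lost=frozenset(edges_a - edges_b),
        edges_gained=frozenset(edges_b - edges_a),
        nodes_lost=frozenset(nodes_a - nodes_b),
        nodes_gained=frozenset(nodes_b - nodes_a),
        receptors_lost=receptors_lost,
    )


def diff_receptor_network(grn_a: GRN, grn_b: GRN) -> GRN:
    """Receptor subnetwork of A restricted to edges absent from B —
    the differential receptor regulatory network."""
    sub_a = receptor_subnetwork(grn_a)
    out = GRN()
    for (tf, gene), ev in sub_a.edges.items():
        if (tf, gene) not in grn_b.edges:
            out.add_edge(tf, gene, *ev)
            if "receptor" in sub_a.roles.get(gene, set()):
                out.add_role(gene, "receptor")
    return out
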