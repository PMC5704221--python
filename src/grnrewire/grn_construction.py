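"""Join motif hits with peak→gene assignments into a TF→gene network.

An edge TF → gene exists when some peak is both assigned to the gene and
contains a significant hit of one of the TF's motifs. Each edge carries
its full evidence (every qualifying hit), and nodes are typed with roles:
``TF`` for edge sources, ``gene`` for edge targets, ``receptor`` for any
node on a supplied receptor list. A dimer motif attributed to k TFs
yields k edges sharing the same evidence.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, NamedTuple, Sequence

from .motif_scanning import MotifHit
from .peak_annotation import PeakGeneAssignment

__all__ = ["Evidence", "GRN", "build_grn", "network_summary"]


class Evidence(NamedTuple):
    """One motif hit supporting an edge."""

    peak_id: str
    motif_id: str
    strand: str
    offset: int
    pvalue: float


class GRN:
    """Directed TF→gene network with typed nodes and per-edge evidence.

    ``edges`` maps (tf, gene) to a sorted tuple of :class:`Evidence`;
    ``roles`` maps node name to a set drawn from {"TF", "gene",
    "receptor"}. Self-edges (a TF regulating its own gene) are allowed.
    """

    def __init__(self) -> None:
        self.edges: dict[tuple[str, str], tuple[Evidence, ...]] = {}
        self.roles: dict[str, set[str]] = {}

    # -- construction -----------------------------------------------------

    def add_role(self, name: str, role: str) -> None:
        if role not in ("TF", "gene", "receptor"):
            raise ValueError(f"unknown node role {role!r}")
        self.roles.setdefault(name, set()).add(role)

    def add_edge(self, tf: str, gene: str, *evidence: Evidence) -> None:
        if not evidence:
            raise ValueError(f"edge {tf}->{gene}: evidence must be non-empty")
        key = (tf, gene)
        merged = set(self.edges.get(key, ())) | set(evidence)
        self.edges[key] = tuple(sorted(merged))
        self.add_role(tf, "TF")
        self.add_role(gene, "gene")

    # -- queries ----------------------------------------------------------

    def nodes(self) -> set[str]:
        return set(self.roles)

    def tfs(self) -> set[str]:
        return {n for n, r in self.roles.items() if "TF" in r}

    def genes(self) -> set[str]:
        return {n for n, r in self.roles.items() if "gene" in r}

    def receptors(self) -> set[str]:
        """Receptor-role nodes that are regulated (receive ≥1 edge)."""
        return {n for n, r in self.roles.items() if "receptor" in r and "gene" in r}

    def targets_of(self, tf: str) -> set[str]:
        return {g for (t, g) in self.edges if t == tf}

    def regulators_of(self, gene: str) -> set[str]:
        return {t for (t, g) in self.edges if g == gene}

    def n_peaks(self, tf: str, gene: str) -> int:
        return len({e.peak_id for e in self.edges[(tf, gene)]})

    def best_pvalue(self, tf: str, gene: str) -> float:
        return min(e.pvalue for e in self.edges[(tf, gene)])

    def self_edges(self) -> set[tuple[str, str]]:
        return {(t, g) for (t, g) in self.edges if t == g}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GRN):
            return NotImplemented
        return self.edges == other.edges and self.roles == other.roles

    def __repr__(self) -> str:
        return f"GRN({len(self.roles)} nodes, {len(self.edges)} edges)"

    def to_networkx(self):
        """Export as a networkx.DiGraph with role and evidence attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for name, roles in self.roles.items():
            g.add_node(name, roles=frozenset(roles))
        for (tf, gene), ev in self.edges.items():
            g.add_edge(tf, gene, evidence=ev, n_peaks=self.n_peaks(tf, gene),
                       best_pvalue=self.best_pvalue(tf, gene))
        return g


def build_grn(
    assignments: Sequence[PeakGeneAssignment],
    hits: Sequence[MotifHit],
    motif_to_tfs: Mapping[str, Sequence[str]],
    receptors: Iterable[str] = (),
    known_peak_ids: Iterable[str] | None = None,
) -> GRN:
    """Construct the GRN from the two upstream tables.

    An edge t → g is created for every hit of a motif of t in a peak that
    is assigned to g; hits in peaks with no gene assignment contribute
    nothing. When ``known_peak_ids`` is given (the peak file's id set),
    hits referencing ids outside it are rejected with the offenders
    listed. The result is independent of input order.
    """
    if known_peak_ids is not None:
        known = set(known_peak_ids)
        unknown = sorted({h.peak_id for h in hits} - known)
        if unknown:
            raise ValueError(f"hits reference unknown peak ids: {unknown}")

    genes_of_peak: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        genes_of_peak[a.peak_id].add(a.gene_id)

    grn = GRN()
    pending: dict[tuple[str, str], set[Evidence]] = defaultdict(set)
    for h in hits:
        tfs = motif_to_tfs.get(h.motif_id)
        if tfs is None:
            raise ValueError(f"hit references unmapped motif {h.motif_id!r}")
        for gene in genes_of_peak.get(h.peak_id, ()):
            ev = Evidence(h.peak_id, h.motif_id, h.strand, h.offset, h.pvalue)
            for tf in tfs:
                pending[(tf, gene)].add(ev)
    for (tf, gene), ev in pending.items():
        grn.add_edge(tf, gene, *ev)
    receptor_set = set(receptors)
    for name in grn.nodes() & receptor_set:
        grn.add_role(name, "receptor")
    return grn


def network_summary(grn: GRN) -> dict[str, int]:
    """Node/edge counts by role, plus evidence-level pair counts.

    ``n_edges`` counts distinct (TF, gene) pairs; ``n_tf_peak_gene_triples``
    counts distinct (TF, peak, gene) evidence triples — the two readings of
    a network's "regulatory pair" count.
    """
    triples = {
        (tf, e.peak_id, gene)
        for (tf, gene), evs in grn.edges.items()
        for e in evs
    }
    return {
        "n_nodes": len(grn.nodes()),
        "n_tfs": len(grn.tfs()),
        "n_genes": len(grn.genes()),
        "n_receptors": len(grn.receptors()),
        "n_edges": len(grn.edges),
        "n_tf_peak_gene_triples": len(triples),
    }
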