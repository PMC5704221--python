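"""End-to-end orchestration: peaks → assignments → hits → GRN → analyses.

``run_condition`` executes the per-condition chain and writes every
intermediate table; ``run_comparison`` runs two conditions, diffs the
networks, tests the lost-edge target genes for gene-set enrichment, and
selects differentially expressed genes. All outputs are deterministic
functions of the inputs: the manifest records parameter values and input
checksums, and the on-disk run log carries stages and record counts only
(wall times go to stderr), so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import io_formats as io
from .enrichment_expression import hypergeom_enrich, modulated_genes, write_modulated
from .grn_construction import GRN, build_grn, network_summary
from .motif_scanning import ScanConfig, scan_all, write_hits
from .network_analysis import (
    diff_network,
    diff_receptor_network,
    rank_regulators_by_outdegree,
    rank_regulators_by_pagerank,
    receptor_subnetwork,
)
from .peak_annotation import assign_peaks_to_genes, write_assignments

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_condition", "run_comparison"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``peaks`` maps condition name → peak file. The two-condition
    comparison treats the first name as the reference (condition A).
    """

    genome: str
    genes: str
    peaks: dict[str, str]
    motifs: str
    receptors: str
    outdir: str
    gmt: str | None = None
    expression: str | None = None
    expression_labels: str | None = None
    window: int = 2000
    alpha: float = 1e-4
    pseudocount: float = 0.01
    granularity: float = 0.001
    k: int = 20
    damping: float = 0.85
    pagerank_tol: float = 1e-10
    pagerank_max_iter: int = 200
    pagerank_reverse: bool = True
    expr_threshold: float = 0.01
    expr_method: str = "welch"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            alpha=self.alpha,
            pseudocount=self.pseudocount,
            granularity=self.granularity,
        )

    def validate_paths(self, conditions: list[str] | None = None) -> None:
        """Fail before any computation if a referenced input is missing."""
        required = {"genome": self.genome, "genes": self.genes,
                    "motifs": self.motifs, "receptors": self.receptors}
        for name in conditions if conditions is not None else self.peaks:
            if name not in self.peaks:
                raise FileNotFoundError(f"no peak file configured for {name!r}")
            required[f"peaks[{name}]"] = self.peaks[name]
        for key in ("gmt", "expression", "expression_labels"):
            if getattr(self, key):
                required[key] = getattr(self, key)
        missing = {k: v for k, v in required.items() if not Path(v).is_file()}
        if missing:
            detail = "; ".join(f"{k}: {v}" for k, v in sorted(missing.items()))
            raise FileNotFoundError(f"missing input files — {detail}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _RunLog:
    """Stage log: counts to file (deterministic), timing to stderr."""

    def __init__(self, path: Path) -> None:
        self.path = path
        self.lines: list[str] = []

    def stage(self, name: str, t0: float, **counts: int) -> None:
        detail = " ".join(f"{k}={v}" for k, v in counts.items())
        self.lines.append(f"{name}\t{detail}".rstrip())
        logger.info("%s: %s (%.2fs)", name, detail, time.perf_counter() - t0)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _write_manifest(config: PipelineConfig, outdir: Path, inputs: dict[str, str]) -> None:
    manifest = {
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("genome", "genes", "peaks", "motifs", "receptors",
                         "gmt", "expression", "expression_labels", "outdir")
        },
        # file name only (not the absolute path) so identical runs rooted
        # at different directories stay byte-identical
        "inputs": {name: {"file": Path(p).name, "sha256": _sha256(p)}
                   for name, p in sorted(inputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _write_ranking(ranking, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\ttf\tscore\n")
        for i, (tf, score) in enumerate(ranking.entries, start=1):
            fh.write(f"{i}\t{tf}\t{score!r}\n")


def run_condition(config: PipelineConfig, condition: str) -> GRN:
    """Build and analyse one condition's GRN; write all intermediates.

    Outputs under ``<outdir>/<condition>/``: assignments.tsv, hits.tsv,
    grn.tsv, ranking_outdegree.tsv, ranking_pagerank.tsv,
    receptor_subnetwork.tsv, summary.json, manifest.json, run.log.
    """
    config.validate_paths([condition])
    outdir = Path(config.outdir) / condition
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")

    t0 = time.perf_counter()
    peaks = io.read_peaks(config.peaks[condition], "narrowPeak")
    genes = io.read_gene_annotation(config.genes)
    motifs = io.read_meme_motifs(config.motifs)
    receptors = io.read_gene_list(config.receptors)
    log.stage("load", t0, peaks=len(peaks), genes=len(genes),
              motifs=len(motifs), receptors=len(receptors))

    t0 = time.perf_counter()
    assignments = assign_peaks_to_genes(peaks, genes, config.window)
    write_assignments(assignments, outdir / "assignments.tsv")
    log.stage("assign", t0, assignments=len(assignments))

    t0 = time.perf_counter()
    hits = scan_all(peaks, config.genome, motifs, config.scan_config())
    motif_to_tfs = {m.motif_id: m.tf_names for m in motifs}
    write_hits(hits, motif_to_tfs, outdir / "hits.tsv")
    log.stage("scan", t0, hits=len(hits))

    t0 = time.perf_counter()
    grn = build_grn(assignments, hits, motif_to_tfs, receptors,
                    known_peak_ids={p.peak_id for p in peaks})
    io.write_network(grn, outdir / "grn.tsv")
    summary = network_summary(grn)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    log.stage("build", t0, **summary)

    t0 = time.perf_counter()
    _write_ranking(rank_regulators_by_outdegree(grn, config.k),
                   outdir / "ranking_outdegree.tsv")
    if grn.nodes():
        _write_ranking(
            rank_regulators_by_pagerank(
                grn, config.k, config.damping, config.pagerank_tol,
                config.pagerank_max_iter, config.pagerank_reverse),
            outdir / "ranking_pagerank.tsv")
    io.write_network(receptor_subnetwork(grn), outdir / "receptor_subnetwork.tsv")
    log.stage("analyse", t0)

    _write_manifest(config, outdir, {
        "genome": config.genome, "genes": config.genes, "motifs": config.motifs,
        "receptors": config.receptors, "peaks": config.peaks[condition],
    })
    log.flush()
    return grn


def run_comparison(config: PipelineConfig) -> dict:
    """Run both conditions and compare them (first name = reference A).

    Writes, under ``<outdir>/comparison/``: diff.json, the differential
    receptor network, an enrichment table of the lost-edge target genes
    (universe = genes of GRN A), and the modulated-gene table when an
    expression matrix is configured. Returns a result dict with the two
    GRNs, the diff, and the tables.
    """
    names = list(config.peaks)
    if len(names) != 2:
        raise ValueError(f"comparison needs exactly 2 conditions, got {names}")
    config.validate_paths(names)
    name_a, name_b = names
    grn_a = run_condition(config, name_a)
    grn_b = run_condition(config, name_b)

    outdir = Path(config.outdir) / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")

    t0 = time.perf_counter()
    diff = diff_network(grn_a, grn_b)
    diff_grn = diff_receptor_network(grn_a, grn_b)
    io.write_network(diff_grn, outdir / "diff_receptor_network.tsv")
    diff_payload = {
        "condition_a": name_a,
        "condition_b": name_b,
        "n_edges_a": len(grn_a.edges),
        "n_edges_b": len(grn_b.edges),
        "edges_lost": sorted(list(e) for e in diff.edges_lost),
        "edges_gained": sorted(list(e) for e in diff.edges_gained),
        "nodes_lost": sorted(diff.nodes_lost),
        "nodes_gained": sorted(diff.nodes_gained),
        "receptors_lost": dict(sorted(diff.receptors_lost.items())),
    }
    (outdir / "diff.json").write_text(json.dumps(diff_payload, indent=1) + "\n")
    log.stage("diff", t0, edges_lost=len(diff.edges_lost),
              edges_gained=len(diff.edges_gained),
              receptors_lost=len(diff.receptors_lost))

    enrichment = None
    if config.gmt:
        t0 = time.perf_counter()
        lost_targets = {gene for (_tf, gene) in diff.edges_lost}
        universe = grn_a.genes()
        if lost_targets:
            enrichment = hypergeom_enrich(lost_targets & universe,
                                          io.read_gmt(config.gmt), universe)
            with open(outdir / "enrichment.tsv", "w") as fh:
                fh.write("set_name\toverlap\tset_size\tquery_size\tuniverse_size"
                         "\tpvalue\tbh_adjusted\n")
                for r in enrichment:
                    fh.write(f"{r.set_name}\t{r.overlap}\t{r.set_size}\t{r.query_size}"
                             f"\t{r.universe_size}\t{r.pvalue!r}\t{r.bh_adjusted!r}\n")
            log.stage("enrich", t0, sets=len(enrichment))

    modulated = None
    if config.expression and config.expression_labels:
        t0 = time.perf_counter()
        expr = io.read_expression(config.expression, config.expression_labels)
        groups = sorted(set(expr.groups.values()))
        modulated = modulated_genes(expr, groups[0], groups[1],
                                    config.expr_threshold, method=config.expr_method)
        write_modulated(modulated, outdir / "modulated.tsv")
        modulated.zscores.to_csv(outdir / "modulated_zscores.tsv", sep="\t",
                                 float_format="%.6f")
        log.stage("expression", t0, selected=len(modulated.selected_genes()))

    log.flush()
    return {
        "grn_a": grn_a,
        "grn_b": grn_b,
        "diff": diff,
        "diff_receptor_network": diff_grn,
        "enrichment": enrichment,
        "modulated": modulated,
    }
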