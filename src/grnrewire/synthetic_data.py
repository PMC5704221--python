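"""Self-contained toy dataset generator with known regulatory ground truth.

The generator emulates the inputs of a chromatin-accessibility GRN study:
an i.i.d. background genome, gene loci with TSSs, a motif library of
high-information-content PWMs (one per TF, plus decoy TFs whose motifs
are never planted, so precision is measurable), accessibility peaks
placed within the assignment window of each gene's TSS, binding sites
planted inside those peaks for designated TF→gene edges, a receptor
list, and a two-condition design: condition B mimics a tumor-infiltrated
state by removing the accessible regions upstream of chosen "shutdown"
receptors, whose expression is correspondingly down-shifted in a grouped
expression matrix.

Every random draw flows through one seeded generator, and all writers
emit records in a fixed order, so a fixed seed yields byte-identical
output trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .io_formats import (
    ALPHABET,
    GeneModel,
    Peak,
    PWM,
    write_gene_annotation,
    write_gmt,
    write_meme_motifs,
    write_peaks,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "expected_background_hits"]

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    planting_rate is the probability that a designated TF→gene edge
    actually receives a binding site; motif_information_content_min (bits
    per column) controls motif degeneracy — 2.0 gives point-mass
    (consensus-only) motifs. shutdown_receptors defaults to the first
    receptor; shutdown_mode "delete_peaks" removes the receptor's peaks
    from condition B wholesale, "delete_sites" keeps the peaks but splits
    them around the planted sites.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 30
    n_tfs: int = 6
    n_decoy_tfs: int = 2
    n_receptors: int = 6
    tfs_per_gene: int = 2
    n_peaks_per_gene: int = 1
    peak_width: int = 200
    planting_rate: float = 1.0
    motif_width: int = 10
    motif_information_content_min: float = 2.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    shutdown_receptors: tuple[str, ...] | None = None
    shutdown_mode: str = "delete_peaks"
    n_samples_per_group: int = 5
    expression_log2fc: float = 2.0
    expression_sd: float = 0.25
    expression_base_mean_range: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_tfs",
                     "n_receptors", "tfs_per_gene", "n_peaks_per_gene",
                     "peak_width", "motif_width", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if self.n_decoy_tfs < 0:
            raise ValueError("n_decoy_tfs must be ≥ 0")
        if not (0 < self.planting_rate <= 1):
            raise ValueError("planting_rate must be in (0, 1]")
        b = np.asarray(self.background, dtype=float)
        if b.shape != (4,) or np.any(b <= 0) or abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive values summing to 1")
        if self.motif_width >= self.peak_width:
            raise ValueError("motif_width must be smaller than peak_width")
        if self.tfs_per_gene > self.n_tfs:
            raise ValueError("tfs_per_gene cannot exceed n_tfs")
        if self.n_receptors > self.n_genes:
            raise ValueError("n_receptors cannot exceed n_genes")
        if self.shutdown_mode not in ("delete_peaks", "delete_sites"):
            raise ValueError(f"unknown shutdown_mode {self.shutdown_mode!r}")
        genes_per_chrom = -(-self.n_genes // self.n_chromosomes)
        spacing = self.chrom_length // (genes_per_chrom + 1)
        if spacing < 2 * 2000 + 2 * self.peak_width:
            raise ValueError(
                "genes too dense: increase chrom_length or reduce n_genes "
                "(TSS spacing must exceed twice the assignment window)"
            )


@dataclass(frozen=True)
class PlantedSite:
    peak_id: str
    motif_id: str
    offset: int  # within the peak
    strand: str
    tf: str
    gene: str


@dataclass
class GroundTruth:
    """What the generator planted, for scoring the pipeline's recovery."""

    planted_edges: set[tuple[str, str]]
    planted_sites: list[PlantedSite]
    condition_B_deleted_edges: set[tuple[str, str]]
    receptors: list[str]
    shutdown_receptors: list[str]

    def to_json(self) -> str:
        payload = {
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "planted_sites": [
                [s.peak_id, s.motif_id, s.offset, s.strand, s.tf, s.gene]
                for s in self.planted_sites
            ],
            "condition_B_deleted_edges": sorted(
                list(e) for e in self.condition_B_deleted_edges
            ),
            "receptors": self.receptors,
            "shutdown_receptors": self.shutdown_receptors,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def expected_background_hits(
    total_scanned_length: int | Iterable[int], alpha: float, w: int
) -> float:
    """Expected number of both-strand hits at p-threshold ``alpha`` when
    scanning i.i.d. background sequence: 2·(L−w+1)·alpha per sequence.

    ``total_scanned_length`` is one sequence length or an iterable of
    lengths (summed).
    """
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    lengths = (
        [total_scanned_length]
        if isinstance(total_scanned_length, (int, np.integer))
        else list(total_scanned_length)
    )
    total = 0.0
    for length in lengths:
        if length < w:
            raise ValueError("scanned length must be ≥ motif width")
        total += 2.0 * (length - w + 1) * alpha
    return total


def _column_for_ic(ic_min: float) -> float:
    """Off-consensus mass d for a column (1−d, d/3, d/3, d/3) whose
    information content (2 + Σ p·log2 p bits) meets ``ic_min``."""
    if ic_min >= 2.0:
        return 0.0
    # small margin so the 6-decimal MEME serialization cannot drop a
    # column below the configured floor
    ic_min = min(2.0, ic_min + 1e-4)

    def ic(d: float) -> float:
        if d == 0:
            return 2.0
        p = np.array([1 - d, d / 3, d / 3, d / 3])
        return 2.0 + float((p * np.log2(p)).sum())

    lo, hi = 0.0, 0.75  # ic(0.75) = 0 (uniform)
    for _ in range(60):
        mid = (lo + hi) / 2
        if ic(mid) >= ic_min:
            lo = mid
        else:
            hi = mid
    return lo


def _make_motif(consensus: str, d: float) -> np.ndarray:
    w = len(consensus)
    mat = np.full((w, 4), d / 3)
    for i, base in enumerate(consensus):
        mat[i, ALPHABET.index(base)] = 1.0 - d
    return mat


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def simulate(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Write the full dataset into ``outdir`` and return the ground truth.

    Files written: genome.fa, genes.bed, motifs.meme, peaks_A.narrowPeak,
    peaks_B.narrowPeak, receptors.txt, genesets.gmt, expression.tsv,
    labels.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=float)

    # --- genome: i.i.d. background bases -------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {
        name: rng.choice(4, size=config.chrom_length, p=bg).astype(np.int8)
        for name in chrom_names
    }

    # --- genes: evenly spaced loci, receptors first ---------------------
    symbols = [f"R{i + 1:02d}" for i in range(config.n_receptors)] + [
        f"G{i + 1:02d}" for i in range(config.n_genes - config.n_receptors)
    ]
    order = rng.permutation(config.n_genes)  # scatter receptors over loci
    genes: list[GeneModel] = []
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)
    spacing = config.chrom_length // (genes_per_chrom + 1)
    gene_len = 1000
    for slot, sym_idx in enumerate(order):
        chrom = chrom_names[slot // genes_per_chrom]
        pos = spacing * (slot % genes_per_chrom + 1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(symbols[sym_idx], symbols[sym_idx], chrom, strand,
                      pos, pos + gene_len)
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    receptors = sorted(symbols[: config.n_receptors])
    shutdown = (
        list(config.shutdown_receptors)
        if config.shutdown_receptors is not None
        else [receptors[0]]
    )
    unknown = set(shutdown) - set(receptors)
    if unknown:
        raise ValueError(f"shutdown_receptors not in receptor list: {sorted(unknown)}")

    # --- motifs: distinct consensus per TF, decoys included -------------
    tf_names = [f"TF{i + 1}" for i in range(config.n_tfs)] + [
        f"DECOY{i + 1}" for i in range(config.n_decoy_tfs)
    ]
    d = _column_for_ic(config.motif_information_content_min)
    used: set[str] = set()
    motifs: list[PWM] = []
    for tf in tf_names:
        for _ in range(_MAX_ATTEMPTS):
            consensus = "".join(
                ALPHABET[i] for i in rng.choice(4, size=config.motif_width, p=bg)
            )
            if consensus not in used and _revcomp(consensus) not in used:
                break
        else:
            raise RuntimeError("could not draw a distinct motif consensus")
        used.add(consensus)
        used.add(_revcomp(consensus))
        motifs.append(PWM(f"M_{tf}", (tf,), _make_motif(consensus, d)))
    real_tfs = tf_names[: config.n_tfs]
    motif_by_tf = {m.tf_names[0]: m for m in motifs}

    # --- peaks near each TSS, and planted sites -------------------------
    peaks: list[Peak] = []
    peaks_by_gene: dict[str, list[Peak]] = {}
    half = (config.peak_width - 1) // 2
    for g in genes:
        gp: list[Peak] = []
        for j in range(config.n_peaks_per_gene):
            for _ in range(_MAX_ATTEMPTS):
                off = int(rng.integers(-1400, 1401))
                start = g.tss + off - half
                end = start + config.peak_width
                if 0 <= start and end <= config.chrom_length:
                    break
            else:
                raise RuntimeError(
                    f"could not place a peak for gene {g.symbol} within bounds"
                )
            gp.append(Peak(g.chrom, start, end, f"peak_{g.symbol}_{j + 1}", half))
        peaks_by_gene[g.symbol] = gp
        peaks.extend(gp)

    designated: dict[str, list[str]] = {}
    for g in genes:
        picks = rng.choice(config.n_tfs, size=config.tfs_per_gene, replace=False)
        designated[g.symbol] = [real_tfs[i] for i in sorted(picks)]

    planted_sites: list[PlantedSite] = []
    planted_edges: set[tuple[str, str]] = set()
    occupied: dict[str, list[tuple[int, int]]] = {p.peak_id: [] for p in peaks}
    for g in genes:
        for tf in designated[g.symbol]:
            if rng.random() > config.planting_rate:
                continue
            motif = motif_by_tf[tf]
            peak = peaks_by_gene[g.symbol][
                int(rng.integers(config.n_peaks_per_gene))
            ]
            for _ in range(_MAX_ATTEMPTS):
                off = int(rng.integers(0, config.peak_width - config.motif_width + 1))
                span = (off, off + config.motif_width)
                if all(span[1] <= s or span[0] >= e
                       for s, e in occupied[peak.peak_id]):
                    break
            else:
                raise RuntimeError(
                    f"could not place a non-overlapping site in {peak.peak_id}"
                )
            occupied[peak.peak_id].append(span)
            strand = "+" if rng.random() < 0.5 else "-"
            site_seq = motif.consensus if strand == "+" else _revcomp(motif.consensus)
            arr = chroms[peak.chrom]
            for i, base in enumerate(site_seq):
                arr[peak.start + off + i] = ALPHABET.index(base)
            planted_sites.append(
                PlantedSite(peak.peak_id, motif.motif_id, off, strand, tf, g.symbol)
            )
            planted_edges.add((tf, g.symbol))

    # --- condition B: close chromatin upstream of shutdown receptors ----
    deleted_edges = {(tf, gene) for (tf, gene) in planted_edges if gene in shutdown}
    shutdown_set = set(shutdown)
    if config.shutdown_mode == "delete_peaks":
        shutdown_peak_ids = {
            p.peak_id for sym in shutdown_set for p in peaks_by_gene[sym]
        }
        peaks_b = [p for p in peaks if p.peak_id not in shutdown_peak_ids]
    else:  # delete_sites: split each affected peak around its planted sites
        sites_by_peak: dict[str, list[tuple[int, int]]] = {}
        for s in planted_sites:
            if s.gene in shutdown_set:
                sites_by_peak.setdefault(s.peak_id, []).append(
                    (s.offset, s.offset + config.motif_width)
                )
        peaks_b = []
        for p in peaks:
            if p.peak_id not in sites_by_peak:
                peaks_b.append(p)
                continue
            cut = sorted(sites_by_peak[p.peak_id])
            pos = 0
            for frag_i, (s, e) in enumerate(cut):
                if s > pos:
                    peaks_b.append(
                        Peak(p.chrom, p.start + pos, p.start + s,
                             f"{p.peak_id}_f{frag_i + 1}", None)
                    )
                pos = e
            if pos < p.width:
                peaks_b.append(
                    Peak(p.chrom, p.start + pos, p.end,
                         f"{p.peak_id}_f{len(cut) + 1}", None)
                )

    # --- expression: log-normal noise around group means ----------------
    lo, hi = config.expression_base_mean_range
    base_mean = rng.uniform(lo, hi, size=config.n_genes)
    gene_syms = sorted(symbols)
    sym_index = {s: i for i, s in enumerate(sorted(symbols))}
    n = config.n_samples_per_group
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    log2_vals = np.empty((config.n_genes, 2 * n))
    for row, sym in enumerate(gene_syms):
        mu = base_mean[sym_index[sym]]
        mu_b = mu - config.expression_log2fc if sym in shutdown_set else mu
        log2_vals[row, :n] = rng.normal(mu, config.expression_sd, size=n)
        log2_vals[row, n:] = rng.normal(mu_b, config.expression_sd, size=n)
    values = np.maximum(np.exp2(log2_vals) - 1.0, 0.0)

    # --- write everything ------------------------------------------------
    letters = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    with open(outdir / "genome.fa", "w") as fh:
        for name in chrom_names:
            fh.write(f">{name}\n")
            seq = letters[chroms[name]].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gene_annotation(genes, outdir / "genes.bed")
    write_meme_motifs(motifs, outdir / "motifs.meme", config.background)
    write_peaks(peaks, outdir / "peaks_A.narrowPeak")
    write_peaks(peaks_b, outdir / "peaks_B.narrowPeak")
    with open(outdir / "receptors.txt", "w") as fh:
        for r in receptors:
            fh.write(r + "\n")
    write_gmt(
        {f"targets_{tf}": [g for g, tfs in designated.items() if tf in tfs]
         for tf in real_tfs},
        outdir / "genesets.gmt",
    )
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene\t" + "\t".join(sample_ids) + "\n")
        for row, sym in enumerate(gene_syms):
            fh.write(sym + "\t" + "\t".join(f"{v:.6f}" for v in values[row]) + "\n")
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for s in sample_ids:
            fh.write(f"{s}\t{'groupA' if s.startswith('A') else 'groupB'}\n")

    truth = GroundTruth(
        planted_edges=planted_edges,
        planted_sites=planted_sites,
        condition_B_deleted_edges=deleted_edges,
        receptors=receptors,
        shutdown_receptors=sorted(shutdown),
    )
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    return truth
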