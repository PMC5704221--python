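"""Generator contracts: determinism, planted-site fidelity, A/B deltas."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from pyfaidx import Fasta

from grnrewire.io_formats import read_meme_motifs, read_peaks
from grnrewire.synthetic_data import (
    SimulationConfig,
    expected_background_hits,
    simulate,
)


def tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.suffix != ".fai"
    }


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    truth = simulate(SimulationConfig(seed=5), outdir)
    return outdir, truth


def test_fixed_seed_gives_byte_identical_trees(tmp_path):
    cfg = SimulationConfig(seed=123, n_genes=10, chrom_length=120_000)
    simulate(cfg, tmp_path / "one")
    simulate(cfg, tmp_path / "two")
    assert tree_digest(tmp_path / "one") == tree_digest(tmp_path / "two")


def test_planted_sites_reread_from_fasta_match_consensus(sim):
    outdir, truth = sim
    peaks = {p.peak_id: p for p in read_peaks(outdir / "peaks_A.narrowPeak")}
    motifs = {m.motif_id: m for m in read_meme_motifs(outdir / "motifs.meme")}
    genome = Fasta(str(outdir / "genome.fa"), sequence_always_upper=True)
    assert truth.planted_sites
    for site in truth.planted_sites:
        peak = peaks[site.peak_id]
        w = motifs[site.motif_id].width
        seq = str(genome[peak.chrom][peak.start + site.offset : peak.start + site.offset + w])
        if site.strand == "-":
            seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert seq == motifs[site.motif_id].consensus


def test_condition_b_differs_only_at_shutdown_receptor_peaks(sim):
    outdir, truth = sim
    peaks_a = {p.peak_id: p for p in read_peaks(outdir / "peaks_A.narrowPeak")}
    peaks_b = {p.peak_id: p for p in read_peaks(outdir / "peaks_B.narrowPeak")}
    removed = set(peaks_a) - set(peaks_b)
    assert not set(peaks_b) - set(peaks_a)
    shutdown = set(truth.shutdown_receptors)
    assert removed == {
        pid for pid in peaks_a if pid.split("_")[1] in shutdown
    }
    for pid in peaks_b:
        assert peaks_b[pid] == peaks_a[pid]


def test_deleted_edges_are_planted_edges_of_shutdown_receptors(sim):
    _, truth = sim
    assert truth.condition_B_deleted_edges <= truth.planted_edges
    assert all(
        gene in truth.shutdown_receptors
        for (_tf, gene) in truth.condition_B_deleted_edges
    )


def test_every_planted_edge_has_a_site_within_window_of_target_tss(sim):
    outdir, truth = sim
    from grnrewire.io_formats import read_gene_annotation
    from grnrewire.peak_annotation import peak_position

    peaks = {p.peak_id: p for p in read_peaks(outdir / "peaks_A.narrowPeak")}
    tss = {g.symbol: g.tss for g in read_gene_annotation(outdir / "genes.bed")}
    edges_with_sites = set()
    for site in truth.planted_sites:
        peak = peaks[site.peak_id]
        assert abs(tss[site.gene] - peak_position(peak)) <= 2000
        edges_with_sites.add((site.tf, site.gene))
    assert edges_with_sites == truth.planted_edges


def test_decoy_motifs_present_but_never_planted(sim):
    outdir, truth = sim
    motifs = read_meme_motifs(outdir / "motifs.meme")
    decoys = {m.motif_id for m in motifs if m.tf_names[0].startswith("DECOY")}
    assert len(decoys) == SimulationConfig().n_decoy_tfs
    assert not decoys & {s.motif_id for s in truth.planted_sites}


def test_delete_sites_mode_splits_peaks_around_sites(tmp_path):
    cfg = SimulationConfig(seed=9, shutdown_mode="delete_sites", n_genes=10,
                           chrom_length=120_000)
    truth = simulate(cfg, tmp_path)
    peaks_a = {p.peak_id: p for p in read_peaks(tmp_path / "peaks_A.narrowPeak")}
    peaks_b = read_peaks(tmp_path / "peaks_B.narrowPeak")
    shutdown_sites = [s for s in truth.planted_sites
                      if s.gene in truth.shutdown_receptors]
    assert shutdown_sites
    for site in shutdown_sites:
        parent = peaks_a[site.peak_id]
        lo = parent.start + site.offset
        hi = lo + cfg.motif_width
        for frag in peaks_b:
            if frag.chrom == parent.chrom:
                assert frag.end <= lo or frag.start >= hi or (
                    frag.start >= parent.end or frag.end <= parent.start
                )


def test_expression_shifts_only_shutdown_receptors(sim):
    outdir, truth = sim
    from grnrewire.io_formats import read_expression

    expr = read_expression(outdir / "expression.tsv", outdir / "labels.tsv")
    log2 = np.log2(expr.values + 1)
    a = log2[[s for s in expr.values.columns if s.startswith("A")]].mean(axis=1)
    b = log2[[s for s in expr.values.columns if s.startswith("B")]].mean(axis=1)
    delta = a - b
    for r in truth.shutdown_receptors:
        assert delta[r] > 1.0  # configured lfc 2 minus noise
    others = delta.drop(index=truth.shutdown_receptors)
    assert (others.abs() < 1.0).all()


@pytest.mark.parametrize(
    "length,alpha,w,expected",
    [
        (1000, 1e-3, 1, 2.0),
        (1000, 0.0, 5, 0.0),
        (10**6, 1e-4, 10, 2 * (10**6 - 9) * 1e-4),
    ],
)
def test_expected_background_hits_closed_form(length, alpha, w, expected):
    assert expected_background_hits(length, alpha, w) == pytest.approx(expected)


def test_expected_background_hits_sums_over_sequences():
    assert expected_background_hits([100, 200], 1e-2, 10) == pytest.approx(
        2 * (91 + 191) * 1e-2
    )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"planting_rate": 0.0},
        {"planting_rate": 1.5},
        {"n_genes": 0},
        {"background": (0.5, 0.5, 0.0, 0.0)},
        {"motif_width": 300},
        {"n_genes": 500},  # too dense for the default chromosome length
        {"shutdown_mode": "nope"},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_low_information_content_motifs_keep_consensus_dominant(tmp_path):
    cfg = SimulationConfig(seed=4, motif_information_content_min=1.0,
                           n_genes=8, chrom_length=120_000)
    simulate(cfg, tmp_path)
    for m in read_meme_motifs(tmp_path / "motifs.meme"):
        p = m.probabilities
        ic = 2.0 + (p * np.log2(np.where(p > 0, p, 1))).sum(axis=1)
        assert (ic >= 1.0 - 1e-6).all()
        assert (p.max(axis=1) > 0.5).all()
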