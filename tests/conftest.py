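"""Shared fixtures: one simulated dataset per session, random-GRN helper."""

from __future__ import annotations

import numpy as np
import pytest

from grnrewire.experiments import build_condition_grn
from grnrewire.grn_construction import GRN, Evidence
from grnrewire.synthetic_data import SimulationConfig, simulate

DATASET_SEED = 11


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default-config synthetic dataset plus both condition GRNs."""
    outdir = tmp_path_factory.mktemp("synth")
    truth = simulate(SimulationConfig(seed=DATASET_SEED), outdir)
    grn_a = build_condition_grn(outdir, "peaks_A.narrowPeak")
    grn_b = build_condition_grn(outdir, "peaks_B.narrowPeak")
    return {"dir": outdir, "truth": truth, "grn_a": grn_a, "grn_b": grn_b}


def random_grn(rng: np.random.Generator, n_tfs: int = 8, n_genes: int = 25,
               edge_prob: float = 0.15, receptor_frac: float = 0.2) -> GRN:
    """A random TF→gene network with synthetic evidence, for oracle tests."""
    grn = GRN()
    tfs = [f"T{i}" for i in range(n_tfs)]
    genes = [f"g{i}" for i in range(n_genes)]
    for tf in tfs:
        for gene in genes:
            if rng.random() < edge_prob:
                grn.add_edge(
                    tf, gene,
                    Evidence(f"p_{gene}", f"M_{tf}", "+",
                             int(rng.integers(0, 100)), float(rng.uniform(0, 1e-4))),
                )
    for gene in genes:
        if rng.random() < receptor_frac and gene in grn.roles:
            grn.add_role(gene, "receptor")
    return grn
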