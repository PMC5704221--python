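"""Build the condition A ("blood") and condition B ("tumor") networks.

Runs peak→gene assignment, motif scanning and the GRN join for both peak
files via the pipeline, writing all intermediates under
scratch/analysis/run and the per-condition network summaries to
results/network_summaries.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from grnrewire.grn_construction import network_summary
from grnrewire.pipeline import PipelineConfig, run_condition

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
RUN = ROOT / "scratch" / "analysis" / "run"


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        genome=str(DATA / "genome.fa"),
        genes=str(DATA / "genes.bed"),
        peaks={"blood": str(DATA / "peaks_A.narrowPeak"),
               "tumor": str(DATA / "peaks_B.narrowPeak")},
        motifs=str(DATA / "motifs.meme"),
        receptors=str(DATA / "receptors.txt"),
        gmt=str(DATA / "genesets.gmt"),
        expression=str(DATA / "expression.tsv"),
        expression_labels=str(DATA / "labels.tsv"),
        outdir=str(RUN),
    )


def main() -> None:
    if not DATA.is_dir():
        sys.exit("run 01_simulate.py first")
    config = pipeline_config()
    rows = []
    for condition in config.peaks:
        grn = run_condition(config, condition)
        rows.append({"condition": condition, **network_summary(grn)})
    table = pd.DataFrame(rows).set_index("condition")
    out = ROOT / "results" / "network_summaries.tsv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, sep="\t")
    print(table)
    a, b = table.loc["blood"], table.loc["tumor"]
    print(
        f"\nThe tumor-condition network is smaller: {b.n_edges} vs {a.n_edges} "
        f"edges and {b.n_receptors} vs {a.n_receptors} regulated receptors — "
        f"the planted chromatin shutdown removes regulation, exactly the "
        f"network-size reduction expected for tumor-infiltrating cells."
    )


if __name__ == "__main__":
    main()
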