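"""Generate the two-condition synthetic dataset used by all later steps.

Writes the dataset (genome, genes, motifs, peaks for a "blood" condition A
and a "tumor" condition B with one shutdown receptor, receptor list, gene
sets, expression matrix) under scratch/analysis/data, and a small summary
of what was planted under results/.
"""

import json
import sys
from pathlib import Path

from grnrewire.synthetic_data import SimulationConfig, simulate

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis" / "data"
SEED = 7


def main() -> None:
    config = SimulationConfig(seed=SEED)
    truth = simulate(config, DATA)
    summary = {
        "seed": SEED,
        "n_genes": config.n_genes,
        "n_tfs": config.n_tfs,
        "n_decoy_tfs": config.n_decoy_tfs,
        "n_receptors": config.n_receptors,
        "n_planted_edges": len(truth.planted_edges),
        "n_planted_sites": len(truth.planted_sites),
        "shutdown_receptors": truth.shutdown_receptors,
        "n_condition_B_deleted_edges": len(truth.condition_B_deleted_edges),
    }
    out = ROOT / "results" / "simulation_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=1) + "\n")
    print(f"dataset -> {DATA}")
    print(json.dumps(summary, indent=1))
    print(
        f"\nPlanted {summary['n_planted_edges']} TF->gene edges; condition B "
        f"closes the chromatin upstream of {truth.shutdown_receptors}, deleting "
        f"{summary['n_condition_B_deleted_edges']} of those edges."
    )


if __name__ == "__main__":
    sys.exit(main())
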