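"""Compare the two condition networks and extract the rewired receptors.

Computes the full edge/node diff, the differential receptor regulatory
network (receptor edges present in blood but gone in tumor), gene-set
enrichment of the lost-edge targets, and checks the result against the
planted ground truth. Writes results/differential_network.json and
results/lost_edge_enrichment.tsv.
"""

import json
import sys
from pathlib import Path

from grnrewire.enrichment_expression import hypergeom_enrich
from grnrewire.io_formats import read_gmt, read_network
from grnrewire.network_analysis import diff_network, diff_receptor_network

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis" / "run"
DATA = ROOT / "scratch" / "analysis" / "data"


def main() -> None:
    if not (RUN / "tumor" / "grn.tsv").is_file():
        sys.exit("run 02_build_networks.py first")
    grn_a = read_network(RUN / "blood" / "grn.tsv")
    grn_b = read_network(RUN / "tumor" / "grn.tsv")
    truth = json.loads((DATA / "truth.json").read_text())

    diff = diff_network(grn_a, grn_b)
    receptor_diff = diff_receptor_network(grn_a, grn_b)
    payload = {
        "n_edges_blood": len(grn_a.edges),
        "n_edges_tumor": len(grn_b.edges),
        "edges_lost": sorted(list(e) for e in diff.edges_lost),
        "receptors_lost": dict(sorted(diff.receptors_lost.items())),
        "differential_receptor_edges": sorted(list(e) for e in receptor_diff.edges),
        "planted_shutdown_receptors": truth["shutdown_receptors"],
        "shutdown_recovered_exactly":
            sorted(diff.receptors_lost) == sorted(truth["shutdown_receptors"]),
    }
    out = ROOT / "results" / "differential_network.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(payload, indent=1) + "\n")
    print(json.dumps(payload, indent=1))

    lost_targets = {gene for (_tf, gene) in diff.edges_lost} & grn_a.genes()
    if lost_targets:
        results = hypergeom_enrich(lost_targets, read_gmt(DATA / "genesets.gmt"),
                                   grn_a.genes())
        with open(ROOT / "results" / "lost_edge_enrichment.tsv", "w") as fh:
            fh.write("set_name\toverlap\tset_size\tpvalue\tbh_adjusted\n")
            for r in results:
                fh.write(f"{r.set_name}\t{r.overlap}\t{r.set_size}"
                         f"\t{r.pvalue:.4g}\t{r.bh_adjusted:.4g}\n")
        top = results[0]
        print(f"\ntop enriched set among lost-edge targets: {top.set_name} "
              f"(k={top.overlap}/{top.set_size}, p={top.pvalue:.3g})")

    verdict = "matches" if payload["shutdown_recovered_exactly"] else "DIFFERS FROM"
    print(f"receptors_lost {verdict} the planted shutdown set "
          f"{truth['shutdown_receptors']}.")


if __name__ == "__main__":
    main()
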