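"""Over-representation analysis and differential-expression selection.

``hypergeom_enrich`` tests a query gene set against a GMT library with
the classical hypergeometric upper tail (the local, deterministic
replacement for a web enrichment service), Benjamini–Hochberg adjusted
across the library. ``modulated_genes`` selects differentially expressed
genes between two sample groups (Welch's t on log2(x+1) by default,
p < 0.01) and exports z-scored rows for heatmap rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

__all__ = ["EnrichmentResult", "ModulatedGeneTable", "hypergeom_enrich", "modulated_genes"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation test.

    k of the n query genes fall in the set (K members in a universe of
    N); ``pvalue`` is P(X ≥ k) for X hypergeometric(N, K, n).
    """

    set_name: str
    overlap: int  # k
    set_size: int  # K (within the universe)
    query_size: int  # n
    universe_size: int  # N
    pvalue: float
    bh_adjusted: float


def hypergeom_enrich(
    query: Iterable[str],
    library: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail ORA of ``query`` against every library set.

    Library sets are intersected with the universe before testing; the
    query must be a subset of the universe. Results are BH-adjusted
    across the library and sorted by (pvalue, set_name).
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("empty universe")
    if not query_set:
        raise ValueError("empty query")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n, big_n = len(query_set), len(universe_set)
    rows = []
    for name in sorted(library):
        members = set(library[name]) & universe_set
        k_obs = len(query_set & members)
        big_k = len(members)
        # P(X >= k) with X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k_obs - 1, big_n, big_k, n))
        p = min(p, 1.0)
        rows.append((name, k_obs, big_k, p))
    pvals = [r[3] for r in rows]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(name, k, big_k, n, big_n, p, max(float(a), p))
        for (name, k, big_k, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.pvalue, r.set_name))
    return results


@dataclass
class ModulatedGeneTable:
    """Per-gene differential test plus heatmap-ready rows.

    ``table`` columns: mean_a, mean_b, stat, pvalue, selected, flagged
    (flagged marks zero-variance degenerate genes whose p is set to 1).
    ``zscores`` holds the selected genes' transformed expression rows
    standardized to mean 0, sd 1 across samples.
    """

    table: pd.DataFrame
    zscores: pd.DataFrame
    group_a: str
    group_b: str
    threshold: float

    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def modulated_genes(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    threshold: float = 0.01,
    transform: str = "log2p1",
    method: str = "welch",
) -> ModulatedGeneTable:
    """Two-group differential test on every gene of the matrix.

    ``transform`` "log2p1" applies log2(x+1) before testing (the default
    normalization for count-scale expression); "none" tests raw values.
    ``method`` "welch" is a two-sided unequal-variance t-test;
    "mannwhitney" a two-sided rank test. Genes with zero variance in both
    groups get p = 1 and are flagged rather than tested.
    """
    samples_a = expr.samples_in_group(group_a)
    samples_b = expr.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    if transform == "log2p1":
        values = np.log2(expr.values + 1.0)
    elif transform == "none":
        values = expr.values.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    a = values[samples_a].to_numpy()
    b = values[samples_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)

    pvals = np.ones(len(values))
    stat = np.zeros(len(values))
    ok = ~degenerate
    if ok.any():
        if method == "welch":
            res = stats.ttest_ind(a[ok], b[ok], axis=1, equal_var=False)
            stat[ok], pvals[ok] = res.statistic, res.pvalue
        elif method == "mannwhitney":
            res = stats.mannwhitneyu(a[ok], b[ok], axis=1, alternative="two-sided")
            stat[ok], pvals[ok] = res.statistic, res.pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
    pvals = np.nan_to_num(pvals, nan=1.0)

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "stat": stat,
            "pvalue": pvals,
            "selected": pvals < threshold,
            "flagged": degenerate,
        },
        index=values.index,
    )
    sel = values.loc[table.index[table["selected"]]]
    if len(sel):
        row_sd = sel.std(axis=1, ddof=0)
        row_sd = row_sd.replace(0, 1.0)
        zscores = sel.sub(sel.mean(axis=1), axis=0).div(row_sd, axis=0)
    else:
        zscores = sel
    return ModulatedGeneTable(table, zscores, group_a, group_b, threshold)


def write_modulated(result: ModulatedGeneTable, path) -> None:
    result.table.to_csv(path, sep="\t", float_format="%.6g")


def heatmap_png(result: ModulatedGeneTable, path) -> None:
    """Optional: render the z-scored selected genes as a heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.2 * len(result.zscores))))
    im = ax.imshow(result.zscores.to_numpy(), aspect="auto", cmap="RdYlGn")
    ax.set_yticks(range(len(result.zscores)), result.zscores.index, fontsize=6)
    ax.set_xticks(range(result.zscores.shape[1]), result.zscores.columns,
                  rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
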