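"""Assign accessibility peaks to genes whose TSS falls within a window.

This is the nearest-TSS/window stage of GRN construction: a peak is
associated with every gene whose TSS lies within ``window`` bp (default
2000, inclusive on both sides) of the peak's anchor position. The anchor
is the summit when the peak has one, otherwise the interval midpoint.
Peaks may map to zero, one or many genes, and genes to many peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GeneModel, Peak

DEFAULT_WINDOW = 2000

__all__ = ["PeakGeneAssignment", "peak_position", "assign_peaks_to_genes", "DEFAULT_WINDOW"]


@dataclass(frozen=True)
class PeakGeneAssignment:
    """A (peak, gene) association.

    ``distance`` is signed, gene TSS minus peak position, measured on the
    genome (not relative to the gene's strand).
    """

    peak_id: str
    gene_id: str
    distance: int


def peak_position(peak: Peak) -> int:
    """Single-point anchor of a peak: summit if present, else midpoint.

    The midpoint of ``[start, end)`` is ``floor((start + end - 1) / 2)``,
    so a width-1 peak anchors at its only base.
    """
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end - 1) // 2


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[PeakGeneAssignment]:
    """All (peak, gene) pairs with ``|tss - peak_position| <= window``.

    Uses per-chromosome sorted TSS arrays and binary search, so it runs in
    O((P+G) log G) rather than the all-pairs O(P·G); results are sorted by
    (peak_id, gene_id). The boundary is inclusive: a TSS exactly ``window``
    bp away is assigned.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom in {g.chrom for g in genes}:
        chrom_genes = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id)
        )
        by_chrom[chrom] = (np.array([g.tss for g in chrom_genes]), chrom_genes)

    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        entry = by_chrom.get(peak.chrom)
        if entry is None:
            continue
        tss_arr, chrom_genes = entry
        pos = peak_position(peak)
        lo = int(np.searchsorted(tss_arr, pos - window, side="left"))
        hi = int(np.searchsorted(tss_arr, pos + window, side="right"))
        for g in chrom_genes[lo:hi]:
            out.append(PeakGeneAssignment(peak.peak_id, g.gene_id, g.tss - pos))
    out.sort(key=lambda a: (a.peak_id, a.gene_id))
    return out


def write_assignments(assignments, path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tgene_id\tdistance\n")
        for a in assignments:
            fh.write(f"{a.peak_id}\t{a.gene_id}\t{a.distance}\n")


def read_assignments(path) -> list[PeakGeneAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "peak_id\tgene_id\tdistance":
            raise ValueError(f"{path}: bad assignments header")
        for line in fh:
            peak_id, gene_id, distance = line.rstrip("\n").split("\t")
            out.append(PeakGeneAssignment(peak_id, gene_id, int(distance)))
    return out
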