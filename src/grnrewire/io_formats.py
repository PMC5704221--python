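"""Readers and writers for every on-disk format the pipeline touches.

All genomic coordinates in this package are BED-style: 0-based, half-open
``[start, end)``. The transcription start site (TSS) of a ``-``-strand gene
is ``end - 1``. Output writers sort records so that repeated runs produce
byte-identical files.

Formats handled here:

* BED3 / BED6 / ENCODE narrowPeak (peaks and gene models)
* MEME minimal motif format (position weight matrices)
* GMT gene-set libraries
* plain-text gene lists (one symbol per line)
* TSV expression matrices with a separate sample→group label file
* the package's own edge-list network TSV (columns ``TF, gene, n_peaks,
  best_pvalue, evidence``) with node roles carried in ``## node`` header
  comments so that ``read_network(write_network(G)) == G``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"

__all__ = [
    "ALPHABET",
    "Peak",
    "GeneModel",
    "PWM",
    "ExpressionMatrix",
    "FormatError",
    "read_peaks",
    "read_gene_annotation",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_gene_list",
    "read_gmt",
    "read_expression",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """A file violated the contract of its declared dialect."""


@dataclass(frozen=True)
class Peak:
    """An accessibility peak: a genomic interval with an optional summit.

    ``summit_offset`` is relative to ``start`` (narrowPeak column 10);
    ``None`` means the assay reported no summit.
    """

    chrom: str
    start: int
    end: int
    peak_id: str
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"peak {self.peak_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise FormatError(
                f"peak {self.peak_id!r}: summit offset {self.summit_offset} "
                f"outside [0, {self.end - self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene locus. The TSS anchors peak-to-gene assignment."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        """0-based TSS: ``start`` on '+', ``end - 1`` on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over A,C,G,T with its TF attribution.

    ``probabilities`` has shape ``(width, 4)``; every row sums to 1.
    ``tf_names`` may list several TFs for dimer motifs; each TF receives
    every hit of the motif.
    """

    motif_id: str
    tf_names: tuple[str, ...]
    probabilities: np.ndarray  # (w, 4), rows sum to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise FormatError(f"motif {self.motif_id!r}: matrix must be (w, 4)")
        if np.any(p < 0):
            raise FormatError(f"motif {self.motif_id!r}: negative probabilities")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise FormatError(f"motif {self.motif_id!r}: rows do not sum to 1")
        if len(self.tf_names) < 1:
            raise FormatError(f"motif {self.motif_id!r}: no TF names")

    @property
    def width(self) -> int:
        return int(self.probabilities.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))


@dataclass
class ExpressionMatrix:
    """Gene symbols × sample ids of non-negative values plus group labels."""

    values: pd.DataFrame  # index: gene symbols, columns: sample ids
    groups: dict[str, str]  # sample id -> group name

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene symbols: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group label: {missing}")
        if len(set(self.groups[s] for s in self.values.columns)) < 2:
            raise FormatError("expression matrix needs at least 2 groups")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read a BED3 or narrowPeak file into a list of :class:`Peak`.

    ``peak_id`` comes from column 4 when present, otherwise it is generated
    as ``"<chrom>:<start>-<end>"``. narrowPeak column 10 of ``-1`` maps to
    an absent summit. Malformed coordinates and duplicate ids are rejected
    with the offending line number.
    """
    if dialect not in ("bed3", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    min_fields = 3 if dialect == "bed3" else 10
    peaks: list[Peak] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected ≥{min_fields} fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            peak_id = (
                fields[3]
                if len(fields) >= 4 and fields[3] not in ("", ".")
                else f"{chrom}:{start}-{end}"
            )
            if peak_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate peak id {peak_id!r}")
            seen.add(peak_id)
            summit: int | None = None
            if dialect == "narrowPeak":
                try:
                    s = int(fields[9])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad summit column") from exc
                summit = None if s == -1 else s
            try:
                peaks.append(Peak(chrom, start, end, peak_id, summit))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak (10 columns, summit −1 when absent)."""
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t0\t-1\t-1\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# genes


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, name, score, strand).

    The BED name is both ``gene_id`` and ``symbol``. Unknown chromosome
    names are accepted here; they are validated against the genome later.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 fields")
            chrom, name, strand = fields[0], fields[3], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            try:
                genes.append(GeneModel(name, name, chrom, strand, start, end))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not genes:
        raise FormatError(f"{path}: empty gene annotation")
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def _tf_names_from_motif_name(name: str, alt: str | None) -> tuple[str, ...]:
    # Alternate name is the TF symbol when present; "::" separates the
    # partners of a dimer motif; a purely numeric "_N" suffix (database
    # variant numbering) is stripped.
    label = alt if alt else name
    parts = label.split("::")
    out = []
    for part in parts:
        head, _, tail = part.rpartition("_")
        if head and tail.isdigit():
            part = head
        out.append(part)
    return tuple(out)


def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal-format motif file into :class:`PWM` objects.

    Requires a ``MEME version`` line, an ACGT alphabet, and at least one
    MOTIF block with a ``letter-probability matrix`` header. Rows are
    renormalised to sum exactly to 1; a row off by more than 1e-3 is
    rejected.
    """
    text = Path(path).read_text()
    if "MEME version" not in text:
        raise FormatError(f"{path}: missing 'MEME version' header")
    lines = text.splitlines()
    alphabet_seen = False
    for line in lines:
        if line.startswith("ALPHABET"):
            alphabet_seen = True
            letters = line.split("=", 1)[-1].strip() if "=" in line else ""
            if letters and letters != "ACGT":
                raise FormatError(f"{path}: alphabet {letters!r} is not ACGT")
    if not alphabet_seen:
        raise FormatError(f"{path}: missing ALPHABET line")

    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}: MOTIF line without a name")
            motif_id = tokens[1]
            alt = tokens[2] if len(tokens) >= 3 else None
            # seek the letter-probability header
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                if lines[j].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"{path}: motif {motif_id!r} has no letter-probability matrix"
                    )
                j += 1
            if j == len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id!r} has no letter-probability matrix"
                )
            header = lines[j]
            w = None
            toks = header.replace("=", " = ").split()
            for t_idx, tok in enumerate(toks):
                if tok == "w" and t_idx + 2 < len(toks) and toks[t_idx + 1] == "=":
                    w = int(toks[t_idx + 2])
            if w is None:
                raise FormatError(f"{path}: motif {motif_id!r}: header lacks 'w='")
            rows = []
            k = j + 1
            while len(rows) < w:
                if k >= len(lines):
                    raise FormatError(
                        f"{path}: motif {motif_id!r}: matrix truncated "
                        f"({len(rows)}/{w} rows)"
                    )
                row_line = lines[k].strip()
                k += 1
                if not row_line:
                    continue
                vals = [float(v) for v in row_line.split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {motif_id!r}: matrix row with {len(vals)} values"
                    )
                rows.append(vals)
            mat = np.array(rows, dtype=float)
            sums = mat.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"{path}: motif {motif_id!r}: row {bad} sums to {sums[bad]:.4f}"
                )
            mat = mat / sums[:, None]
            motifs.append(PWM(motif_id, _tf_names_from_motif_name(motif_id, alt), mat))
            i = k
        else:
            i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def write_meme_motifs(
    motifs: Sequence[PWM],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write motifs in MEME minimal format (one alt name = first TF)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background)
        )
        for m in motifs:
            alt = "::".join(m.tf_names)
            fh.write(f"MOTIF {m.motif_id} {alt}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probabilities:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# gene lists, GMT, expression


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' comments and blanks ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    if not out:
        raise FormatError(f"{path}: empty gene list")
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs ≥3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = sorted(sets[name])
            fh.write(name + "\t-\t" + "\t".join(genes) + "\n")


def read_expression(
    matrix_path: str | Path, labels_path: str | Path
) -> ExpressionMatrix:
    """Read a TSV matrix (first column = gene symbol) and its labels file
    (two columns ``sample<TAB>group`` with a header)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.empty:
        raise FormatError(f"{matrix_path}: empty expression matrix")
    labels = pd.read_csv(labels_path, sep="\t")
    if labels.shape[1] < 2:
        raise FormatError(f"{labels_path}: need sample and group columns")
    groups = dict(zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, matrix_path, labels_path) -> None:
    expr.values.to_csv(matrix_path, sep="\t", float_format="%.6f")
    with open(labels_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in expr.values.columns:
            fh.write(f"{s}\t{expr.groups[s]}\n")


# ---------------------------------------------------------------------------
# network edge-list TSV

_NETWORK_HEADER = "TF\tgene\tn_peaks\tbest_pvalue\tevidence"


def write_network(grn, path: str | Path) -> None:
    """Write a GRN as an edge-list TSV, sorted by (TF, gene).

    Node roles (TF / gene / receptor) are carried in ``## node`` comment
    lines so the round trip preserves receptor flags and isolated nodes.
    Evidence items are ``peak_id|motif_id|strand|offset|pvalue`` joined
    by ';'.
    """
    with open(path, "w") as fh:
        for name in sorted(grn.roles):
            roles = ",".join(sorted(grn.roles[name]))
            fh.write(f"## node\t{name}\t{roles}\n")
        fh.write(_NETWORK_HEADER + "\n")
        for (tf, gene) in sorted(grn.edges):
            ev = grn.edges[(tf, gene)]
            ev_str = ";".join(
                f"{e.peak_id}|{e.motif_id}|{e.strand}|{e.offset}|{e.pvalue!r}"
                for e in sorted(ev)
            )
            n_peaks = len({e.peak_id for e in ev})
            best = min(e.pvalue for e in ev)
            fh.write(f"{tf}\t{gene}\t{n_peaks}\t{best!r}\t{ev_str}\n")


def read_network(path: str | Path):
    """Inverse of :func:`write_network`; returns a GRN."""
    from .grn_construction import GRN, Evidence

    grn = GRN()
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("## node\t"):
                _, name, roles = line.split("\t")
                for role in roles.split(","):
                    if role:
                        grn.add_role(name, role)
                continue
            if not header_seen:
                if line != _NETWORK_HEADER:
                    raise FormatError(f"{path}:{lineno}: bad network header")
                header_seen = True
                continue
            tf, gene, _n_peaks, _best, ev_str = line.split("\t")
            for item in ev_str.split(";"):
                peak_id, motif_id, strand, offset, pvalue = item.split("|")
                grn.add_edge(
                    tf,
                    gene,
                    Evidence(peak_id, motif_id, strand, int(offset), float(pvalue)),
                )
    if not header_seen:
        raise FormatError(f"{path}: empty network file")
    return grn
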