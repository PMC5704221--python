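# Methods

## Overview

`grnrewire` infers a directed gene regulatory network (GRN) from
chromatin accessibility and compares such networks between cell
conditions. The chain is the classical peak-centric construction:

1. **Peak→gene assignment.** Each accessibility peak is reduced to a
   single anchor point (the narrowPeak summit when present, else the
   interval midpoint) and associated with every gene whose TSS lies
   within ±2,000 bp of that anchor (closed interval). No nearest-gene
   tie-break is applied: a peak may regulate several genes, and a gene
   may collect several peaks.
2. **Motif scanning.** Every PWM in the motif library is scored along
   both strands of every peak sequence as a log2-odds against a 0-order
   background; occurrences with exact p-value ≤ 1e-4 are kept.
3. **Network join.** An edge TF → gene is created when some peak is both
   assigned to the gene and contains a significant hit of one of the
   TF's motifs. Edges carry all supporting hits as evidence; nodes are
   typed TF / gene / receptor.
4. **Analyses.** Hub regulators by out-degree and by PageRank, receptor
   regulatory subnetworks, UpSet-style set intersections across several
   networks, and exact edge/node set differences between two conditions,
   with a dedicated readout for receptors regulated in condition A but
   disconnected in condition B.
5. **Orthogonal validation.** A two-group differential test on an
   expression matrix confirms (or not) that rewired receptors are also
   transcriptionally down-modulated, and a local hypergeometric
   over-representation test annotates the lost-edge targets against a
   GMT library.

All genomic coordinates are 0-based half-open; the TSS of a minus-strand
gene is `end − 1`.

## Exact motif p-values

A PWM `p` is first regularized with a pseudocount ε against the
background `b`: `p'[i][x] = (p[i][x] + ε·b[x]) / (1 + ε)` (default
ε = 0.01), then converted to a score matrix `s[i][x] = log2(p'[i][x] /
b[x])` in bits. The null distribution of the window score — the sum of
`s[i][X_i]` over positions with `X_i` i.i.d. from `b` — is computed
exactly by dynamic programming on an integer grid: every matrix cell is
rounded to the nearest multiple of the granularity (default 0.001 bits)
and the integer-score distribution is built by position-wise
convolution. The scanner scores each window with the *same* integer
matrix, so the p-value attached to a hit is the exact upper-tail
probability of its discretized score; a real-valued score queried
against the distribution is floored onto the grid first, so reported
p-values are never underestimates. The grid size is capped (default
10^7 cells) and the error message advises a coarser granularity when a
pathological matrix exceeds it.

Numerical details worth knowing:

* the per-position rounding shifts a width-w score by at most w/2 grid
  steps, far below any decision boundary at the default granularity;
* windows containing `N` are skipped entirely rather than scored with
  background probabilities;
* the threshold is inclusive (p ≤ α): discretization already rounds the
  reported p-value conservatively upward, so a strict comparison would
  double-penalize boundary scores;
* minus-strand hits are computed by scoring the forward window with the
  reverse-complemented matrix, which is algebraically identical to
  scoring the reverse-complemented window.

The test suite checks the DP against exhaustive enumeration over all
4^w words for w ≤ 8, and checks the scanner's hit count on 2 Mb of
i.i.d. background against the analytic expectation 2(L−w+1)·α.

## Hub-regulator ranking

Out-degree ranking scores each TF by its number of distinct target
genes. PageRank uses damping 0.85, uniform teleport, uniform
redistribution of dangling mass, and a power iteration that stops when
the L1 change falls below 1e-10 (non-convergence returns the last
iterate, flagged and logged). PageRank runs on the **reversed** edge set
by default: on TF→gene edges the standard walk accumulates mass on
heavily regulated genes, whereas the reversed walk lets rank flow from
targets to their regulators, making the two hub rankings comparable —
on the synthetic data they agree essentially everywhere, matching the
behaviour expected of peak-derived networks where both statistics are
driven by the same binding-site counts. The direction is exposed as a
flag. Ties in either ranking break lexicographically by TF name so
output is deterministic.

## Differential networks

Edge identity for comparisons is the (TF, gene) pair; evidence is
deliberately ignored, since rewiring is about the wiring. `diff_network`
returns exact set differences plus `receptors_lost`: receptors regulated
in A that receive no edge in B, each with its regulator count in A.
`diff_receptor_network` is the displayable object — the receptor
subnetwork of A restricted to edges absent from B.

## Enrichment and expression

The over-representation test is the hypergeometric upper tail
P(X ≥ k) with the library intersected against the chosen universe
(default: all regulated genes of the GRN under analysis), BH-adjusted
across the library. It replaces web-service enrichment so runs are
self-contained and deterministic.

The modulated-gene selection applies Welch's unequal-variance t-test,
two-sided, on log2(x+1)-transformed values, selecting genes with
p < 0.01. A Mann–Whitney alternative is available; the transform can be
disabled. Genes with zero variance in both groups are assigned p = 1
and flagged rather than tested. At 5 samples per group the
Welch–Satterthwaite approximation is mildly conservative (realized
type-I error ≈ 0.8% at the 1% threshold in the null calibration), which
we accept as the cost of not assuming equal variances.

## Synthetic data generator

The generator emulates the *structure* of an accessibility study, not
its biochemistry:

* **Genome**: i.i.d. bases with configurable composition (default
  uniform), 2 chromosomes × 300 kb. The i.i.d. choice makes the
  false-positive calibration of the scanner analytic and exact.
* **Genes**: 30 loci, evenly spaced (far enough apart that assignment
  windows never overlap two genes), random strand; 6 are designated
  receptors.
* **Motifs**: one per TF (6 real + 2 decoy TFs), width 10, by default
  point-mass (consensus-only) columns; a minimum per-column information
  content below 2 bits produces degenerate `(1−d, d/3, d/3, d/3)`
  columns instead. Consensus sequences are drawn distinct, including
  from each other's reverse complements. Decoy motifs are never
  planted, so edge precision is measurable.
* **Peaks**: one 200-bp peak per gene with its summit within ±1,400 bp
  of the TSS. Each gene is designated 2 regulating TFs; with
  probability `planting_rate` (default 1) the edge receives a consensus
  site written into the genome at a uniform-random, non-overlapping
  offset on a random strand.
* **Condition B** ("tumor-infiltrated"): the peaks upstream of the
  shutdown receptors (default: the first receptor) are removed
  wholesale, emulating closed chromatin; an alternative mode keeps the
  peaks but splits them around the planted sites. All other peaks are
  byte-identical between conditions.
* **Expression**: log2-normal noise (sd 0.25) around per-gene baseline
  means drawn from U(4, 8), 5 samples per group; shutdown receptors
  have their group-B mean shifted down by 2 log2 units. Values are
  written as `2^z − 1`, so the default log2(x+1) transform in the test
  recovers exactly normal data.

Defaults were chosen once as realistic small-scale analogues (motif
widths ~10 as in curated databases, 200-bp ATAC-like peaks, few-hundred
fold fewer genes than a genome) and are the conditions under which the
guarantees in the test suite are stated. The generator does **not**
model GC-content structure, dinucleotide composition, overlapping genes,
distal enhancers, footprint shapes, replicate variability, or read-level
noise — so passing tests demonstrate the correctness of the algorithms
and their calibration under the stated null, not performance on real
tissue data, where motif redundancy and open-chromatin composition are
far harsher.

With the defaults, chance background hits of a width-10 consensus are
rare (≈0.09 expected per dataset), so planted-edge recall is exactly 1
and precision stays ≥ 0.95; the shutdown receptor is recovered exactly
in essentially all seeds.

## Determinism

All randomness flows through one `numpy` generator seeded from the
config; writers emit records in sorted order; the run manifest stores
parameter values and input checksums (file names, not absolute paths);
the on-disk run log contains stages and record counts only, with wall
times going to stderr. Two runs with the same seed produce byte-identical
output trees, which the test suite asserts at the file-digest level.

## Problem sizes

The bundled analyses and tests run at deliberately small scale — 30
genes, 8 motifs, 2 Mb calibration scans, 100-seed recovery sweeps,
10,000-gene null matrices — sizes chosen so the full suite completes in
a few minutes on one CPU while every statistical check retains enough
resolution (4-SD bands at these n) to fail loudly if the machinery is
wrong.

## Known limitations

* The scanner's null is 0-order; higher-order Markov backgrounds and
  q-value/FDR filtering across hits are out of scope.
* Peak→gene assignment is the window rule only — no exon/intron/UTR
  feature classification and no expression-based pruning of edges.
* The hypergeometric ORA reproduces the schema of pathway-enrichment
  reports, not any particular web service's combined scores.
* Edge evidence is binary presence; no affinity weighting or
  multiple-hit boosting is attempted.
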