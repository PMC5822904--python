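# Methods

## Sampling model of the EST screen

A cDNA library is modelled as `est_total` independent draws from the source
tissue's transcript-frequency distribution; a gene at frequency `f`
therefore contributes a `Binomial(est_total, f)` number of clones. Pooling
libraries of one tissue class sums the draws, so each pool is itself a
binomial sample. The screen estimates `f` from the inflorescence pool
(`f = m/M`, matched over total ESTs) and asks, for each noninflorescence
pool, how probable its observed matched count `n` out of `N` would be at
that frequency:

    P(n; N, f) = C(N, n) f^n (1 − f)^(N − n)

This is the binomial **point** probability, implemented exactly as printed
(log-gamma for the coefficient, assembled and exponentiated in log space; a
dedicated `log_sampling_probability` avoids underflow at pool sizes of 10^4
and more, where P can drop below the smallest positive float). A lower-tail
cumulative variant exists behind `tail_sum=True` for sensitivity analyses
but is never the default: the point mass is the published statistic, and at
the extreme depletion the screen demands the two differ by little.

Decision rules, per gene:

* **SOLE** — matched ESTs come only from inflorescence libraries (`m > 0`,
  all pools `n = 0`). Threshold-independent.
* **SIGNIFICANT** — `m > 0` and every pool with `N > 0` has either `n = 0`
  or `P ≤ threshold` *and* `n/N < f`. The second clause is a directionality
  guard: the point pmf is symmetric in its tails, so without it a pool
  strongly *enriched* for the gene would also count as evidence of
  inflorescence predominance. The guard is on by default and can be
  disabled (`direction_guard=False`) to recover the bare printed rule.
* **FAIL** — otherwise.

Each comparison pool must pass separately (the "any of the other tissues"
reading); a merged-pool variant is available behind `merged_pool=True`.
Pools with no retained libraries are recorded with `N = 0` and can never
block a pass — with as few as three libraries in a pool (the stem pool of
the motivating study), absence of evidence must not read as evidence of
absence. No multiple-testing correction is applied, matching the original
procedure; the number of genes tested is reported so users can adjust post
hoc. Thresholds default to `1e-4` for the contig tier and `1e-2` for the
CDS re-screen.

Libraries with fewer than 1000 ESTs, or flagged as normalized/enriched, are
excluded before pooling: normalization deliberately flattens clone
frequencies, destroying the quantity the screen measures.

## RNA-seq statistics

* **FPKM** = `count × 10^9 / (length_bp × mapped_total)` — the standard
  length- and depth-normalized unit.
* **RES** of focal tissue A = `(expr_A − expr_B)/expr_A`, where B maximizes
  expression over the comparison tissues; ties break by a fixed canonical
  tissue order so outputs are deterministic. Undefined (flagged, NaN) when
  `expr_A = 0`; equals 1 exactly when the gene is absent everywhere else.
* **χ² test**: Pearson on the 2×2 table `[[count, depth − count]]` for the
  two samples, df = 1, no continuity correction by default (a Yates variant
  sits behind `yates=True`). Counts are compared raw against depths, not
  length-normalized — both samples measure the same gene, so length cancels
  from the proportion comparison. Significance is strict (`p < α`,
  α = 0.05). The degenerate table with both counts zero is defined as
  statistic 0, p = 1. Tests feed on raw counts; a "significantly higher"
  call additionally requires the focal FPKM to exceed the reference (the
  test itself is two-sided).
* **Heat-map abundance**: per tissue the max-over-stages FPKM divided by the
  gene-set mean FPKM, then `log2(quotient + 0.01)`. Base 2 and the
  pseudocount are configurable; 0.01 keeps a zero-FPKM gene two decades
  below a gene at the mean without compressing the informative range.
* **2^−ΔΔCT** for qPCR cross-checks.

Where a tissue has several developmental stages (the inflorescence's Z32,
Z39, Z65), the stage with maximal FPKM represents the tissue — for RES, for
the heat-map quotient, and for the classifier's significance calls alike.

## Expression groups

The six-subgroup taxonomy is formalized as a decision list evaluated
G3 → G2 → G1, with vegetative set {root, leaf, stem, grain}:

* LOW_DATA: every tissue below `negligible_fpkm`.
* G3 (stamen-specific): all vegetative tissues negligible, stamen expressed
  and significantly above each of them; G3-1 if the inflorescence time
  course is itself negligible, G3-2 if it is also significantly above the
  vegetative tissues.
* G2: some vegetative expression, but stamen or pistil significantly above
  every vegetative tissue; G2-1 if the pistil is, G2-2 otherwise.
* G1: inflorescence significantly above every vegetative tissue; G1-2 if
  stamen, pistil and all vegetative tissues are negligible, else G1-1.
* UNCLASSIFIED: no clause fires.

`negligible_fpkm` defaults to 0.5 — below one read per two kilobases at
10 M mapped reads, i.e. indistinguishable from mapping noise; it was never
quantified in the source taxonomy and is exposed as a parameter. Every
clause evaluated is kept in an evidence map, so an assignment can be
re-derived and overlap cases audited. The published RES range of the
stamen-specific group (0.82–1.0) is treated as a descriptive outcome, not a
gate: the classifier recomputes RES for reporting only.

The RNA-seq support filter applies the same machinery upstream of
classification: a screened gene is kept iff some inflorescence stage, the
stamen, or the pistil is significantly above every vegetative tissue. Genes
with no expression rows are kept but flagged `no_rnaseq_data` rather than
dropped — an atlas of nine tissue/stage cells can simply miss a gene's
expression window.

## Synthetic data

The generator emulates exactly the structure the statistics assume, no more:

* **EST side**: each library is one multinomial draw over genes, so column
  sums conserve library sizes and pools are binomial in every gene —
  matching the screen's model by construction. The default design has 200
  genes and 11 libraries (three inflorescence libraries of 20,000 ESTs;
  every noninflorescence pool ≥ 30,000 ESTs); 10 genes are implanted as
  sole-inflorescence and 10 as 50-fold enriched over a 1e-5 baseline
  frequency, putting their implanted inflorescence frequency at 5e-4 (≈ 30
  expected matches in the 60,000-EST pool). Background genes share the
  residual mass uniformly; a separate null design gives every gene identical
  frequency in every tissue. The CDS tier optionally thins matches
  binomially (`tier2_retention`, default 1.0: tiers identical, tier effects
  opt-in).
* **RNA-seq side**: `count ~ Poisson(FPKM_design × length × depth / 10^9)` —
  pure sampling noise, which is all the χ²-on-proportions machinery assumes.
  A designed FPKM of zero yields exactly zero reads. Archetype designs place
  five genes per subgroup at wide margins (expressed levels ≥ 20× the
  negligible threshold, silent levels ≤ 0.1×, depth 10^7, length 1.5 kb)
  plus seven zero-read genes for the LOW_DATA route.

What passing these tests does **not** show about real data: real EST
libraries are not multinomial (cloning bias, directional libraries, vector
trimming), real RNA-seq is overdispersed relative to Poisson (a negative
binomial option would be the first extension), homology matching upstream of
the count matrices introduces errors the tier labels cannot see, and real
expression profiles sit near the decision margins rather than 20× away from
them. The calibration and recovery rates reported by the acceptance script
are properties of the designed universes, not of any wheat dataset.

All draws derive from one seed through `numpy` seed sequences split per
library, so adding a library does not reshuffle the others' draws and every
artifact is bit-reproducible.

## The catalog

The packaged TSV transcribes the published 59-set catalog one row per
subgenome slot, as printed — including two defects of the printed table that
the loader corrects and documents: a duplicated "IDG022" block whose second
occurrence is loaded as the otherwise-missing IDG028 (the printed totals are
consistent only under that reading), and the two IDG050 rows merged into one
set with two copies each on 6A and 6D. Summary percentages are computed on
gene *copies*, not sets, and rounded half-up to one decimal — the only
convention that reproduces the published 68.2% / 5.3% split. Group
membership is a property of each chromosome token, so a set with copies on
4A and 5D contributes to groups 4 and 5.

## Problem sizes

Default analyses run 200-gene EST universes and ≤ 50-gene RNA-seq designs;
the oracle grid for the screening statistic covers ~500 points up to pool
size 10^4. The full test suite and the acceptance script each complete in
seconds on one CPU.

## Known limitations

* The screen consumes precomputed matched-count matrices; homology search,
  contig assembly and gene prediction are out of scope by design.
* The point-probability statistic is kept as printed; whether the original
  procedure intended a cumulative tail is not decidable from the source, and
  the `tail_sum` flag exists precisely to measure the difference.
* The classifier is a rule-based formalization of a taxonomy that may have
  been applied partly by expert judgement; its counts on real data need not
  match the published group sizes, and no such comparison is claimed.
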