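# Methods

## The biological question and the analysis it dictates

Wing imaginal discs regenerate well early in the third larval instar (L3)
and poorly by late L3. A class of enhancers — damage-responsive,
maturity-silenced (DRMS) — explains part of this decline: they open upon
injury in young discs but are epigenetically shut off as the tissue
matures. Finding them genome-wide from whole-disc ATAC-seq requires three
comparisons over a common peak atlas: damaged vs undamaged at each stage
(damage response), and late-damaged vs early-damaged (maturity silencing),
followed by an intersection.

The dominating practical obstacle is **responder dilution**: only the cells
near the ablated territory remodel their chromatin, so a whole-disc library
mixes a small responding fraction *f* with a large unresponsive background.
If responding cells open a peak by $\Delta$ log2 units, the bulk mean is

$$ m = \mu\,[(1-f) + f\,2^{\Delta}], $$

so a cell-level 8-fold opening at *f* = 0.15 appears as a bulk fold change
of only 2.05 (log2FC ≈ 1.04). This is why the classification uses relaxed
cutoffs (padj < 0.1, log2FC > 0.5) rather than a conventional padj < 0.05,
and it is the arithmetic the synthetic generator is built around.

## Atlas construction

Per-condition peak calls ranked by caller score are truncated to the top
*n* = 11,500 (ties at the boundary broken by (chrom, start) so runs
reproduce), pooled, and merged by transitive closure of ≥ 1 bp overlap.
Coordinates are 0-based half-open throughout (GFF3 is converted on read);
"≥ 1 bp" is strict, so book-ended intervals remain separate. Merging is
idempotent and order-independent, and the merged bases equal the union of
input bases — these invariants are asserted against a brute-force
union-find oracle in the tests. Counting follows featureCounts'
`allowMultiOverlap` contract: each fragment increments every atlas peak it
overlaps by ≥ 1 bp. An optional chromosome allow-list (default
chr2L/2R/3L/3R/4/X) restricts the atlas.

## The differential engine — a stand-in, not a clone

The published analysis used DESeq2. This package deliberately implements
its own negative-binomial engine rather than call one, keeping each choice
inspectable:

* **Size factors** — median-of-ratios over rows positive in all samples;
  total-count fallback (with warning) if no such row exists. Note the
  estimator's known property: with a sizeable fraction of one-directional
  truly-changed peaks, factors absorb part of the shift (a few percent at
  10–20 % responders), biasing fold changes slightly toward zero.
* **Dispersion** — per-peak method-of-moments
  $\hat\alpha = \max(0, (s^2-\bar m)/\bar m^2)$ within replicate groups,
  pooled with df weights, then shrunk 50/50 toward the fitted trend
  $\alpha(\mu) = a_0 + a_1/\mu$ (least squares across peaks). All-zero
  peaks get NaN and are excluded from testing and from the BH family.
* **Wald test** — log2FC is the log ratio of size-factor-normalized group
  means with a 0.5 pseudo-mean guarding zeros; the SE comes from the NB
  delta method, $\mathrm{Var}(\bar m_g) = n_g^{-2}\sum_j (m_g/s_j +
  \alpha m_g^2)$; two-sided p from the normal reference; BH step-up padj.
* **Not implemented** (and why the published peak counts are not expected
  to reproduce exactly): DESeq2's Cox–Reid dispersion MLE, LFC shrinkage
  estimators, independent filtering, and outlier replacement. The engine is
  instead validated by calibration (type-I error within Monte-Carlo bands
  at nominal 0.01/0.05/0.1 with dispersion at truth) and by parameter
  recovery (mean bias of a planted unit log2FC below 0.2), in
  `tests/test_acceptance.py`.

Signal tracks are per-condition binned coverage z-scores (default 10 bp
bins); difference tracks are bin-wise z-subtractions. Exactly uniform
coverage yields the well-defined limit z ≡ 0.

## Classification

All threshold comparisons are strict (`padj < cut`, `|log2FC| > cut`), so
boundary values are excluded — the convention of reporting "padj < 0.1".
Maturity silencing is direction *down* in the late-damaged vs early-damaged
contrast with late as numerator; the orientation is recorded in the output
metadata. The call-set object asserts its own algebra
(drms = dr_early ∩ ms, dr_both = dr_early ∩ dr_late) at construction, and
relaxing padj 0.05 → 0.1 provably only grows sets.

## Annotation

"Nearest two genes" means the two genes of smallest distance regardless of
side or strand (distance 0 on gene-body overlap, else the edge gap); a
per-side mode and a TSS-distance mode exist but the defaults match the
strand-agnostic edge-gap reading. Feature categories are assigned by peak
midpoint under the precedence active promoter > active exon > active
intron > other open chromatin > other; midpoint assignment keeps small
fixtures deterministic. When a category map is derived from gene models,
promoters are TSS ± 250 bp windows of active genes. Enrichment uses
two-sided Fisher exact tests on (in/out of category) × (in/out of subset),
BH-corrected across categories; background-weighted folds average to 1 by
construction.

## Sequence screens

Motif scanning matches IUPAC degenerate consensi position-by-position on
both strands, reporting minus-strand hits in plus-strand coordinates.
Default patterns are literature consensus sites — AP-1 `TGASTCA`
(note: its own reverse complement, so every site reports once per strand),
Pho core `GCCAT`, Sp1 `GGGCGG` — and are config-overridable; the screened
17 bp element is user input, not hard-coded. Conserved blocks are maximal
runs of byte-identical sequence present in *all* input orthologs
(simultaneous identity, not pairwise), found by `min_len`-mer anchoring on
the reference and maximal bidirectional extension; blocks whose reference
span is contained in a longer block's span are dropped. `min_len` < 8 is
refused as a combinatorial guard. Exact k-mer search reports palindromic
sites once per strand at identical coordinates.

## The synthetic generator

Defaults (chosen once, as the realistic study conditions):

| parameter | default | rationale |
|---|---|---|
| conditions | early/late L3 × damaged/undamaged | the 2×2 study design |
| replicates | 3 | three full biological repeats per condition |
| baseline accessibility $\mu_i$ | log-normal, median 200, sdlog 1.0 | ATAC peak strengths are heavy-tailed over orders of magnitude |
| dispersion α | 0.05 | typical bulk biological replicate variability |
| dilution fraction f | 0.15 | the regenerating zone is a small minority of the disc; no measured value exists, so f is a free simulation parameter, not an estimate |
| planted effects Δ | 3.0 (moderate) / 5.0 (strong), half each | a realistic effect-size range: moderate responders land near the bulk detection threshold after dilution (log2FC ≈ 1.04), strong ones are unambiguous (≈ 2.43) |
| depth factors | log-normal(0, 0.15) | forces nontrivial normalization |
| boundary jitter | ± 25 bp | condition peak sets overlap without being identical |

Labels partition peaks into null, damage-responsive (early / late / both),
maturity-silenced, and drms. Damage-responsive effects are applied through
the dilution mixture in the relevant damaged condition(s). Pure
maturity-silenced peaks are planted as a *whole-tissue* early-stage
elevation (mixture fraction 1): developmental silencing affects the entire
disc, unlike blastema-restricted damage responses. DRMS peaks apply the
diluted damage mixture in early-damaged only, so in expectation they are
more accessible in early-damaged than in either early-undamaged or
late-damaged. A consequence worth noting: early-only responders are
*operationally* DRMS-like (their response is absent late), mirroring the
continuum in real data; truth-based recovery tests therefore key on the
`drms` label and the `strong` flag.

What the generator does **not** emulate: read-level data (FASTQ), Tn5
insertion bias, fragment-length structure, peak-caller statistics,
chromatin-state heterogeneity, and correlated (co-regulated) peaks. Passing
tests therefore demonstrate correctness of the analysis logic and
calibration under the NB model — not robustness to alignment artifacts or
model misspecification in real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000–12,000 simulated peaks, chosen as the
smallest sizes at which the statistical properties under test (calibration
bands, Monte-Carlo closed forms, recovery) are stable. Oracle-equivalence
suites run ≥ 100 random instances per primitive at small sizes where
brute force is exact. Ties are broken deterministically everywhere
(mergesort, (chrom, start) ordering); all randomness descends from a
single seed split per stage via `SeedSequence`; manifests of identical
seeded runs are byte-identical (timings go to the log, not the manifest).

## Known limitations

* The published peak counts (e.g. 14,142 atlas peaks; 222 early-L3
  damage-responsive; 729 maturity-silenced; 28 DRMS) depend on the
  deposited sequencing data and the exact upstream tool versions; they are
  not recomputable from simulations, and the NB engine here is not a
  DESeq2 clone (see above). The pipeline reports exact fractions (e.g.
  28/222 = 12.6 %) rather than rounded presentation values.
* The final published DRMS enhancer list also relied on manual curation of
  browser traces; that step is inherently human and out of scope.
* Fisher-exact enrichment on very small DRMS sets (tens of peaks) has low
  power; folds are reported alongside p-values for that reason.
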