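# drms-scan

Discovery of **damage-responsive, maturity-silenced (DRMS) enhancers** from
ATAC-seq chromatin-accessibility data.

Regenerating tissues such as *Drosophila* wing imaginal discs lose the
ability to regenerate as they mature. One mechanism behind this loss is
epigenetic: enhancers that open in response to tissue damage early in the
third larval instar (L3) are progressively silenced — largely via
Polycomb-group machinery — so that by late L3 the same damage no longer
activates them. `drms-scan` implements the genome-wide screen for such
elements: it takes scored ATAC peak calls and fragment counts from a
two-stage × two-treatment design (early/late L3 × damaged/undamaged discs,
three biological replicates each), and produces the classified DRMS peak
set together with gene annotation and enhancer sequence screens.

The package is aimed at regeneration and chromatin biologists who have
peak-caller output and a count matrix in hand, and at methodologists who
want a fully simulated, ground-truthed version of this study design to test
analysis choices against.

## What it computes

1. **Union peak atlas.** The top *n* = 11,500 peaks per condition (ranked by
   caller score) are pooled and merged wherever intervals overlap by ≥ 1 bp
   (0-based half-open coordinates; book-ended intervals stay separate).
   Fragments are then counted per atlas peak with multi-overlap semantics
   (a fragment spanning *k* peaks increments all *k*).
2. **Differential accessibility.** For each atlas peak *i* with counts
   $K_{ij} \sim \mathrm{NB}(s_j \mu_i,\ \alpha_i)$
   (variance $m + \alpha m^2$), size factors $s_j$ are estimated by
   median-of-ratios, dispersions $\alpha_i$ by method-of-moments shrunk
   50/50 toward a fitted trend $\alpha(\mu) = a_0 + a_1/\mu$, and each
   contrast is tested with a Wald statistic
   $z = \widehat{\mathrm{LFC}} / \mathrm{SE}$ on the log2 ratio of
   normalized group means, with Benjamini–Hochberg correction. This engine
   is a documented stand-in for DESeq2 (see `docs/methods.md`).
3. **DRMS classification.** With strict cutoffs padj < 0.1 and
   |log2FC| > 0.5: *damage-responsive* peaks open upon damage
   (damaged vs undamaged, per stage); *maturity-silenced* peaks lose
   accessibility with age in damaged tissue (late-damaged vs early-damaged,
   log2FC < −0.5); **DRMS = damage-responsive-early ∩ maturity-silenced**.
4. **Annotation.** Nearest two genes per peak (strand-agnostic, gene-body
   or TSS distance) and midpoint-based genomic feature categories
   (active promoter > exon > intron > other open chromatin > other), with
   Fisher-exact category enrichment of the DRMS set against the atlas.
5. **Sequence screens.** IUPAC consensus scans on both strands (AP-1
   `TGASTCA`, Pho `GCCAT`, Sp1 `GGGCGG` by default), detection of maximal
   ≥ 50 bp blocks of identical sequence across orthologous enhancers, and
   genome-wide exact search for a query k-mer (e.g. a 17 bp sequence shared
   between enhancers at different loci).

A first-class **synthetic-data module** generates the whole design —
genomes, gene models, orthologous enhancer sequences, scored peak sets and
NB count matrices with planted effects — including the key confounder of
whole-tissue assays: only a fraction *f* of cells in a damaged disc are
regenerating, so a peak opening $2^\Delta$-fold in responding cells shows a
bulk fold change of only $(1-f) + f\,2^\Delta$.

## Worked example

Run the full synthetic pipeline at the default design (2,000 atlas peaks,
f = 0.15, dispersion 0.05, three replicates per condition):

```python
from drms_scan.simulate import SimDesign, make_truth, simulate_counts
from drms_scan.diffacc import size_factors, estimate_dispersion, nb_wald_test
from drms_scan.classify import call_set, classify_drms

design = SimDesign(seed=7)
truth = make_truth(design)
counts, table = simulate_counts(design, truth)
factors = size_factors(counts)
disp = estimate_dispersion(counts, factors, table)
contrasts = {
    "dr_early": (("earlyL3", "damaged"), ("earlyL3", "undamaged")),
    "dr_late":  (("lateL3", "damaged"), ("lateL3", "undamaged")),
    "ms":       (("lateL3", "damaged"), ("earlyL3", "damaged")),
}
res = {k: nb_wald_test(counts, table, c, dispersion=disp, factors=factors)
       for k, c in contrasts.items()}
cs = classify_drms(
    call_set(res["dr_early"], "up", 0.1, 0.5),
    call_set(res["dr_late"], "up", 0.1, 0.5),
    call_set(res["ms"], "down", 0.1, 0.5),
)
print(cs.summary())
```

prints

```
{'n_dr_early': 80, 'n_dr_late': 36, 'n_dr_both': 11, 'n_ms': 129,
 'n_drms': 61, 'drms_fraction_of_dr_early': 0.7625,
 'padj_cut': 0.1, 'lfc_cut': 0.5,
 'ms_contrast': 'lateL3:damaged vs earlyL3:damaged (down)'}
```

That is: 80 peaks open upon damage in early L3 but only 36 in late L3 (11
at both stages), 129 lose accessibility with maturity under damage, and 61
fall in the DRMS intersection. The truth for this seed planted 30 DRMS
peaks (plus 40 early-only responders, which are operationally DRMS-like);
all 18 strongly planted DRMS peaks are recovered. The same run is available
from the shell:

```bash
drms-scan run --seed 7 --out-dir drms_run
```

which writes the atlas, counts, per-contrast differential tables, call
sets, annotation and motif reports, plus a deterministic `manifest.json`
of output digests.

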