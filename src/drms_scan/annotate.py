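"""Gene and feature-category annotation of atlas peaks.

Peaks are mapped to their nearest two genes (by gap between peak edge and
gene-body edge, strand-agnostic; a TSS-distance mode is available) and to a
genomic feature category (active promoter / exon / intron / other open
chromatin / other) by the location of the peak midpoint under a fixed
precedence. Category enrichment of a peak subset against the full atlas
uses two-sided Fisher exact tests with BH correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from drms_scan.diffacc import bh_adjust

logger = logging.getLogger(__name__)

CATEGORY_PRECEDENCE = [
    "active_promoter",
    "active_exon",
    "active_intron",
    "other_open_chromatin",
    "other",
]


def nearest_two_genes(
    peak: tuple[str, int, int],
    genes: pd.DataFrame,
    mode: str = "gene_body",
) -> list[tuple[str, int]]:
    """The two genes closest to a peak, regardless of strand or side.

    Distance is 0 when the peak overlaps the gene body, else the gap between
    the closest edges; ``mode='tss'`` measures instead from the peak to the
    TSS position. Ties are broken by gene start, then gene id. Returns up to
    two (gene_id, distance) pairs; fewer when the chromosome has fewer
    genes (with a warning when empty).
    """
    chrom, pstart, pend = peak
    sub = genes[genes["chrom"] == chrom]
    if len(sub) == 0:
        logger.warning("no genes on %s", chrom)
        return []
    if mode == "gene_body":
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        dist = np.maximum(0, np.maximum(gs - pend, pstart - ge))
    elif mode == "tss":
        t = sub["tss"].to_numpy()
        dist = np.where((t >= pstart) & (t < pend), 0, np.minimum(np.abs(t - pstart), np.abs(t - (pend - 1))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = sorted(
        range(len(sub)),
        key=lambda i: (dist[i], sub["start"].iloc[i], sub["gene_id"].iloc[i]),
    )
    return [(sub["gene_id"].iloc[i], int(dist[i])) for i in order[:2]]


def annotate_peaks_with_genes(
    peaks: pd.DataFrame, genes: pd.DataFrame, mode: str = "gene_body"
) -> pd.DataFrame:
    """Nearest-two-genes table for every peak (long format)."""
    rows = []
    for _, p in peaks.iterrows():
        hits = nearest_two_genes((p["chrom"], p["start"], p["end"]), genes, mode=mode)
        for rank, (gid, d) in enumerate(hits, 1):
            rows.append((p["peak_id"], rank, gid, d))
    return pd.DataFrame(rows, columns=["peak_id", "rank", "gene_id", "distance"])


def build_category_map(
    genes: pd.DataFrame,
    atlas_peaks: pd.DataFrame | None = None,
    active_genes: set[str] | None = None,
    promoter_halfwidth: int = 250,
) -> pd.DataFrame:
    """Derive a feature-category interval map from gene models.

    Active genes (all genes when no activity list is given) contribute
    TSS +/- ``promoter_halfwidth`` promoter windows, exon intervals, and
    intron intervals (gene body minus exons). Atlas peaks, when given,
    contribute ``other_open_chromatin``. Precedence at lookup time resolves
    overlaps, so intervals here may overlap freely.
    """
    rows = []
    for _, g in genes.iterrows():
        if active_genes is not None and g["gene_id"] not in active_genes:
            continue
        t = int(g["tss"])
        rows.append((g["chrom"], max(0, t - promoter_halfwidth), t + promoter_halfwidth + 1, "active_promoter"))
        exons = sorted(g["exons"]) if isinstance(g["exons"], (list, tuple)) else []
        for es, ee in exons:
            rows.append((g["chrom"], es, ee, "active_exon"))
        prev = g["start"]
        for es, ee in exons:
            if es > prev:
                rows.append((g["chrom"], prev, es, "active_intron"))
            prev = max(prev, ee)
        if prev < g["end"]:
            rows.append((g["chrom"], prev, g["end"], "active_intron"))
    if atlas_peaks is not None:
        for _, p in atlas_peaks.iterrows():
            rows.append((p["chrom"], p["start"], p["end"], "other_open_chromatin"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


def categorize_peak(peak: tuple[str, int, int], category_map: pd.DataFrame) -> str:
    """Category of the peak midpoint under the fixed precedence order."""
    chrom, pstart, pend = peak
    mid = (pstart + pend) // 2
    sub = category_map[
        (category_map["chrom"] == chrom)
        & (category_map["start"] <= mid)
        & (mid < category_map["end"])
    ]
    if len(sub) == 0:
        return "other"
    cats = set(sub["category"])
    for c in CATEGORY_PRECEDENCE:
        if c in cats:
            return c
    return "other"


def categorize_peaks(peaks: pd.DataFrame, category_map: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [
            categorize_peak((p["chrom"], p["start"], p["end"]), category_map)
            for _, p in peaks.iterrows()
        ],
        index=peaks["peak_id"].to_numpy(),
        name="category",
    )


def category_enrichment(
    subset_cats: pd.Series, background_cats: pd.Series
) -> pd.DataFrame:
    """Fold enrichment and Fisher exact p per category, subset vs background.

    The subset must be contained in the background. For each category the
    2x2 table is (in/out of category) x (in/out of subset) over background
    peaks; fold = subset fraction / background fraction; p two-sided Fisher
    exact, BH-adjusted across categories. Categories absent from the
    background get NaN fold and p.
    """
    if not set(subset_cats.index) <= set(background_cats.index):
        raise ValueError("subset peaks must be contained in background")
    n_bg = len(background_cats)
    n_sub = len(subset_cats)
    rows = []
    cats = [c for c in CATEGORY_PRECEDENCE if (background_cats == c).any()] + sorted(
        set(background_cats) - set(CATEGORY_PRECEDENCE)
    )
    for c in cats:
        bg_in = int((background_cats == c).sum())
        sub_in = int((subset_cats == c).sum())
        a = sub_in
        b = n_sub - sub_in
        cc = bg_in - sub_in
        d = (n_bg - n_sub) - (bg_in - sub_in)
        _, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
        bg_frac = bg_in / n_bg
        sub_frac = sub_in / n_sub if n_sub else np.nan
        fold = sub_frac / bg_frac if bg_frac > 0 else np.nan
        rows.append((c, sub_in, n_sub, bg_in, n_bg, fold, p))
    out = pd.DataFrame(
        rows,
        columns=["category", "subset_in", "subset_n", "background_in", "background_n", "fold", "pvalue"],
    )
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
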