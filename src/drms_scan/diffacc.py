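"""Normalization, replicate QC, and negative-binomial differential testing.

The engine is a documented stand-in for DESeq2, not a clone:

* size factors by the median-of-ratios estimator;
* per-peak dispersions by method-of-moments within replicate groups,
  shrunk 50/50 toward a fitted mean-dispersion trend a0 + a1/mu;
* a Wald test on the log2 ratio of size-factor-normalized group means,
  with the standard error from the NB delta method;
* Benjamini-Hochberg adjustment across all tested peaks.

Counts follow the NB(mean m, dispersion alpha) convention with
Var = m + alpha * m^2. Results table mirrors the DESeq2 column layout
(baseMean, log2FoldChange, lfcSE, pvalue, padj).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: pseudo normalized count added to each group mean before taking log2,
#: stabilizing fold changes of low/zero-count peaks
PSEUDO_MEAN = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For rows positive in every sample, factor_j = median_i of
    counts_ij / geometric_mean_i(counts). Falls back to total-count ratios
    (scaled to geometric mean 1) when no row is all-positive.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        logger.warning("no peak positive in all samples; using total-count ratios")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        f = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    sub = mat[positive]
    loggeo = np.mean(np.log(sub), axis=1)
    f = np.exp(np.median(np.log(sub) - loggeo[:, None], axis=0))
    return pd.Series(f, index=counts.columns, name="size_factor")


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: entry * 1e6 / column total."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total counts")
    return counts * 1e6 / totals


def replicate_correlation(normalized: pd.DataFrame, order: bool = False) -> pd.DataFrame:
    """Sample x sample Pearson correlation matrix.

    Constant columns have undefined correlation and yield NaN. With
    ``order=True`` rows/columns are reordered by average-linkage
    hierarchical clustering of 1 - r for display.
    """
    if normalized.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    corr = normalized.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    const = normalized.nunique(axis=0) <= 1
    for s in normalized.columns[const]:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
        corr.loc[s, s] = 1.0
    if order and not const.any():
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        d = squareform((1 - corr.values), checks=False)
        leaves = hierarchy.leaves_list(hierarchy.average(d))
        corr = corr.iloc[leaves, leaves]
    return corr


def _group_columns(design: pd.DataFrame, stage: str, damage: str) -> list[str]:
    sel = design[(design["stage"] == stage) & (design["damage"] == damage)]
    return list(sel["sample"])


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: pd.DataFrame,
    shrink: float = 0.5,
) -> pd.Series:
    """Per-peak NB dispersion alpha, method-of-moments with trend shrinkage.

    Within each (stage, damage) replicate group the raw estimate is
    alpha_g = max(0, (s^2 - m) / m^2) on size-factor-normalized counts,
    pooled across groups weighted by group degrees of freedom. Raw estimates
    are then shrunk ``shrink``/(1-``shrink``) toward the trend
    alpha(mu) = a0 + a1/mu fitted across peaks. All-zero peaks get NaN and
    are excluded from testing downstream.
    """
    norm = counts.div(factors, axis=1)
    groups = design.groupby(["stage", "damage"])["sample"].apply(list)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    mean_all = norm.mean(axis=1).to_numpy()
    for cols in groups:
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, np.nan)
        a = np.clip(a, 0.0, None)
        w = len(cols) - 1
        ok = ~np.isnan(a)
        num[ok] += w * a[ok]
        den[ok] += w
    with np.errstate(invalid="ignore"):
        raw = num / den
    raw[den == 0] = np.nan
    # trend fit alpha = a0 + a1/mu over peaks with defined raw estimates
    ok = ~np.isnan(raw) & (mean_all > 0)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_all[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.nanmean(raw), 1e-8) if ok.any() else 0.01, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mean_all, 1e-12)
    alpha = (1 - shrink) * raw + shrink * trend
    alpha = np.clip(alpha, 0.0, None)
    alpha[mean_all == 0] = np.nan
    return pd.Series(alpha, index=counts.index, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} p_(j) * m / j, capped at 1; invariant to input
    order; monotone nondecreasing in the p-value rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[tuple[str, str], tuple[str, str]],
    dispersion: pd.Series | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of differential accessibility between two condition groups.

    ``contrast`` is ((stage_A, damage_A), (stage_B, damage_B)); the reported
    log2FoldChange has group A as numerator. Per peak:

    * log2FC = log2((mA + 0.5) / (mB + 0.5)) of size-factor-normalized
      group means;
    * Var(mean_g) = (1/n_g^2) * sum_j (m_g / s_j + alpha * m_g^2), the NB
      variance of normalized counts, and SE(log2FC) by the delta method;
    * z = log2FC / SE, two-sided p from the normal reference, BH padj over
      all peaks with defined dispersion.

    Returns a frame with baseMean, log2FoldChange, lfcSE, pvalue, padj,
    indexed like ``counts``. Peaks with undefined dispersion (all-zero) get
    NaN statistics and are excluded from the BH family.
    """
    (stage_a, dmg_a), (stage_b, dmg_b) = contrast
    cols_a = _group_columns(design, stage_a, dmg_a)
    cols_b = _group_columns(design, stage_b, dmg_b)
    for name, cols in ((f"{stage_a}:{dmg_a}", cols_a), (f"{stage_b}:{dmg_b}", cols_b)):
        if len(cols) < 2:
            raise ValueError(f"contrast group {name} has < 2 samples in design")
    if factors is None:
        factors = size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors, design)
    alpha = dispersion.reindex(counts.index).to_numpy(dtype=float)

    norm = counts.div(factors, axis=1)
    ma = norm[cols_a].mean(axis=1).to_numpy()
    mb = norm[cols_b].mean(axis=1).to_numpy()
    base_mean = norm.mean(axis=1).to_numpy()

    lfc = np.log2((ma + PSEUDO_MEAN) / (mb + PSEUDO_MEAN))

    def _var_log_mean(m: np.ndarray, cols: list[str]) -> np.ndarray:
        s = factors[cols].to_numpy(dtype=float)
        n = len(cols)
        mm = np.maximum(m, PSEUDO_MEAN)
        var_mean = (mm[:, None] / s[None, :] + alpha[:, None] * mm[:, None] ** 2).sum(
            axis=1
        ) / n**2
        return var_mean / mm**2  # delta method: Var(ln mean)

    with np.errstate(invalid="ignore"):
        se = np.sqrt(_var_log_mean(ma, cols_a) + _var_log_mean(mb, cols_b)) / np.log(2)
        z = lfc / se
    p = 2 * stats.norm.sf(np.abs(z))

    testable = ~np.isnan(alpha)
    p = np.where(testable, p, np.nan)
    padj = np.full_like(p, np.nan)
    padj[testable] = bh_adjust(p[testable])
    if (~testable).any():
        logger.info("%d all-zero peaks excluded from testing", int((~testable).sum()))

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.where(testable, lfc, np.nan),
            "lfcSE": np.where(testable, se, np.nan),
            "pvalue": p,
            "padj": padj,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# signal tracks


def signal_track(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 10,
) -> pd.DataFrame:
    """Binned z-score coverage track from pooled fragments.

    Coverage per fixed-size bin is the number of fragment bases falling in
    the bin; z = (coverage - genome-wide mean) / sd. Raises on a
    zero-variance track. Returns a bedGraph-like frame
    (chrom, start, end, z).
    """
    pieces = []
    for chrom, size in chrom_sizes.items():
        nbins = int(np.ceil(size / bin_size))
        cov = np.zeros(nbins)
        sub = fragments[fragments["chrom"] == chrom]
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                cov[b0] += e - s
            else:
                cov[b0] += (b0 + 1) * bin_size - s
                cov[b1] += e - b1 * bin_size
                cov[b0 + 1 : b1] += bin_size
        starts = np.arange(nbins) * bin_size
        ends = np.minimum(starts + bin_size, size)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "cov": cov}))
    track = pd.concat(pieces, ignore_index=True)
    sd = track["cov"].std(ddof=0)
    if sd == 0:
        # exactly uniform coverage: deviations are identically zero, so the
        # z-track is the well-defined limit 0 everywhere
        track["z"] = 0.0
    else:
        track["z"] = (track["cov"] - track["cov"].mean()) / sd
    return track[["chrom", "start", "end", "z"]]


def subtract_tracks(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Bin-wise difference track z_a - z_b over identical bins."""
    if not (a[["chrom", "start", "end"]].reset_index(drop=True)
            .equals(b[["chrom", "start", "end"]].reset_index(drop=True))):
        raise ValueError("tracks are not on identical bins")
    out = a[["chrom", "start", "end"]].copy()
    out["z"] = a["z"].to_numpy() - b["z"].to_numpy()
    return out


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
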