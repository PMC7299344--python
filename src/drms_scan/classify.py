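"""Threshold-and-intersection classification of DRMS peaks.

Three differential contrasts feed the classifier:

* early damaged vs early undamaged  -> damage-responsive early (up),
* late damaged vs late undamaged    -> damage-responsive late (up),
* late damaged vs early damaged     -> maturity-silenced (down; late is
  the numerator, so silenced peaks have log2FC < -lfc_cut).

DRMS peaks are those both damage-responsive in the early stage and
maturity-silenced. All threshold comparisons are strict, so a peak sitting
exactly at a cutoff is excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


def call_set(
    diff: pd.DataFrame,
    direction: str,
    padj_cut: float = 0.1,
    lfc_cut: float = 0.5,
) -> set[str]:
    """Peaks passing padj < padj_cut and a strict one-sided fold cut.

    ``direction='up'`` requires log2FoldChange > lfc_cut; ``'down'``
    requires log2FoldChange < -lfc_cut. Peaks with missing padj (excluded
    from testing) are skipped and counted in a log message.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if not (0 < padj_cut <= 1):
        raise ValueError("padj_cut must be in (0, 1]")
    if lfc_cut < 0:
        raise ValueError("lfc_cut must be >= 0")
    if len(diff) == 0:
        return set()
    missing = diff["padj"].isna()
    if missing.any():
        logger.info("%d peaks lack padj and are not callable", int(missing.sum()))
    ok = diff["padj"] < padj_cut
    if direction == "up":
        ok &= diff["log2FoldChange"] > lfc_cut
    else:
        ok &= diff["log2FoldChange"] < -lfc_cut
    return set(diff.index[ok.fillna(False)])


@dataclass
class DRMSCallSet:
    """Derived peak sets with the thresholds that produced them."""

    dr_early: set[str]
    dr_late: set[str]
    ms: set[str]
    dr_both: set[str] = field(default_factory=set)
    drms: set[str] = field(default_factory=set)
    padj_cut: float = 0.1
    lfc_cut: float = 0.5
    ms_contrast: str = "lateL3:damaged vs earlyL3:damaged (down)"

    def __post_init__(self) -> None:
        self.dr_both = self.dr_early & self.dr_late
        self.drms = self.dr_early & self.ms
        assert self.drms <= self.dr_early and self.drms <= self.ms
        assert self.dr_both == self.dr_early & self.dr_late

    def summary(self) -> dict:
        n_dr_early = len(self.dr_early)
        return {
            "n_dr_early": n_dr_early,
            "n_dr_late": len(self.dr_late),
            "n_dr_both": len(self.dr_both),
            "n_ms": len(self.ms),
            "n_drms": len(self.drms),
            "drms_fraction_of_dr_early": (
                len(self.drms) / n_dr_early if n_dr_early else float("nan")
            ),
            "padj_cut": self.padj_cut,
            "lfc_cut": self.lfc_cut,
            "ms_contrast": self.ms_contrast,
        }


def classify_drms(
    dr_early: set[str],
    dr_late: set[str],
    ms: set[str],
    padj_cut: float = 0.1,
    lfc_cut: float = 0.5,
) -> DRMSCallSet:
    """Intersect the three call sets into the DRMS call set."""
    return DRMSCallSet(
        dr_early=set(dr_early),
        dr_late=set(dr_late),
        ms=set(ms),
        padj_cut=padj_cut,
        lfc_cut=lfc_cut,
    )


_SET_COLS = ["dr_early", "dr_late", "dr_both", "ms", "drms"]


def summarize(callset: DRMSCallSet, atlas_ids: list[str], tsv_path, json_path) -> None:
    """Write per-peak membership TSV and a JSON count summary.

    The TSV has one sorted row per atlas peak with 0/1 membership columns;
    the JSON carries the ``summary()`` dict. Together they round-trip the
    call set losslessly via :func:`read_callset`.
    """
    rows = []
    for pid in sorted(atlas_ids):
        rows.append(
            [pid] + [int(pid in getattr(callset, c)) for c in _SET_COLS]
        )
    df = pd.DataFrame(rows, columns=["peak_id"] + _SET_COLS)
    df.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(callset.summary(), fh, indent=1)


def read_callset(tsv_path, json_path) -> DRMSCallSet:
    """Reconstruct a call set from :func:`summarize` output."""
    df = pd.read_csv(tsv_path, sep="\t")
    with open(json_path) as fh:
        meta = json.load(fh)
    sets = {c: set(df.loc[df[c] == 1, "peak_id"]) for c in _SET_COLS}
    return DRMSCallSet(
        dr_early=sets["dr_early"],
        dr_late=sets["dr_late"],
        ms=sets["ms"],
        padj_cut=meta["padj_cut"],
        lfc_cut=meta["lfc_cut"],
        ms_contrast=meta["ms_contrast"],
    )
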