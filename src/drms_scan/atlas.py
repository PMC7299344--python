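"""Union peak atlas construction and fragment counting.

Per-condition peak calls (ranked by a caller score, e.g. the MACS2 q-score)
are reduced to their top-n strongest peaks, concatenated across conditions,
and merged wherever intervals overlap by at least 1 bp. All coordinates are
0-based half-open (BED convention); bookended intervals (overlap exactly
0 bp) are *not* merged. Counting follows the featureCounts
``allowMultiOverlap`` contract: a fragment overlapping k atlas peaks
increments all k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "score"]


def _validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Check interval sanity; raise naming the first offending record."""
    bad = peaks.index[peaks["start"] >= peaks["end"]]
    if len(bad):
        row = peaks.loc[bad[0]]
        raise ValueError(
            f"malformed interval {row['chrom']}:{row['start']}-{row['end']} "
            f"(start >= end)"
        )
    if (peaks["start"] < 0).any():
        raise ValueError("negative start coordinate")
    return peaks


@dataclass
class PeakAtlas:
    """A merged, non-overlapping union peak set with stable ids.

    ``peaks`` is sorted by (chrom, start) and carries a ``peak_id`` column of
    the form ``chrom:start-end``. ``provenance`` maps each atlas peak id to
    the set of input condition labels whose peaks it absorbed (empty when
    inputs carried no labels).
    """

    peaks: pd.DataFrame
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.peaks
        # invariant: sorted, non-overlapping within chromosome
        for chrom, grp in p.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if len(grp) > 1 and (starts[1:] < ends[:-1]).any():
                raise ValueError(f"atlas peaks overlap on {chrom}")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def ids(self) -> list[str]:
        return list(self.peaks["peak_id"])

    def to_bed(self, path) -> None:
        out = self.peaks[["chrom", "start", "end", "peak_id"]]
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "PeakAtlas":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
        )
        df["peak_id"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        return cls(df)


def select_top_peaks(peaks: pd.DataFrame, n: int) -> pd.DataFrame:
    """Return the ``n`` highest-scoring peaks.

    Ties at the n-th rank are broken by (chrom, start) ascending so repeated
    runs are reproducible. If fewer than ``n`` peaks are available all are
    returned and a warning is logged.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    _validate_peaks(peaks)
    if len(peaks) < n:
        logger.warning("requested top %d peaks but only %d available", n, len(peaks))
        n = len(peaks)
    ranked = peaks.sort_values(
        by=["score", "chrom", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return ranked.head(n).reset_index(drop=True)


def merge_overlapping(peaks: pd.DataFrame) -> PeakAtlas:
    """Merge the transitive closure of >= 1 bp overlaps into single intervals.

    Each merged peak spans min(start)..max(end) of its component intervals.
    Under half-open coordinates, abutting intervals (end_a == start_b) overlap
    by 0 bp and stay separate. The operation is idempotent and invariant to
    input order. An optional ``condition`` column feeds atlas provenance.
    """
    _validate_peaks(peaks)
    has_cond = "condition" in peaks.columns
    rows = []
    provenance: dict[str, set[str]] = {}
    for chrom, grp in peaks.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        conds = grp["condition"].to_numpy() if has_cond else None
        cur_s, cur_e = int(starts[0]), int(ends[0])
        cur_c: set[str] = {conds[0]} if has_cond else set()
        for i in range(1, len(grp)):
            s, e = int(starts[i]), int(ends[i])
            if s < cur_e:  # strict: >=1 bp overlap required
                cur_e = max(cur_e, e)
                if has_cond:
                    cur_c.add(conds[i])
            else:
                pid = f"{chrom}:{cur_s}-{cur_e}"
                rows.append((chrom, cur_s, cur_e, pid))
                provenance[pid] = cur_c
                cur_s, cur_e = s, e
                cur_c = {conds[i]} if has_cond else set()
        pid = f"{chrom}:{cur_s}-{cur_e}"
        rows.append((chrom, cur_s, cur_e, pid))
        provenance[pid] = cur_c
    merged = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    return PeakAtlas(merged, provenance)


def count_in_atlas(
    fragments: dict[str, pd.DataFrame], atlas: PeakAtlas
) -> pd.DataFrame:
    """Count fragments per sample overlapping each atlas peak by >= 1 bp.

    ``fragments`` maps sample id to a BED3-like frame (chrom, start, end).
    A fragment overlapping k peaks increments all k cells (the
    ``allowMultiOverlap`` behaviour). Returns a peaks x samples integer
    frame indexed by atlas peak id.

    Uses a sorted-boundary sweep: since atlas peaks are disjoint within a
    chromosome, the peaks a fragment [s, e) touches form a contiguous run
    locatable with two binary searches.
    """
    ids = atlas.ids
    counts = pd.DataFrame(
        0, index=pd.Index(ids, name="peak_id"), columns=list(fragments), dtype=np.int64
    )
    # per-chromosome sorted peak boundary arrays
    bychrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in atlas.peaks.groupby("chrom", sort=False):
        bychrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp.index.to_numpy(),
        )
    id_arr = np.asarray(ids, dtype=object)
    for sample, frags in fragments.items():
        if len(frags) == 0:
            logger.warning("sample %s has zero fragments; column of zeros", sample)
            continue
        _validate_peaks(frags.assign(score=0.0))
        col = np.zeros(len(ids), dtype=np.int64)
        for chrom, grp in frags.groupby("chrom", sort=False):
            if chrom not in bychrom:
                continue
            pstart, pend, prow = bychrom[chrom]
            fs = grp["start"].to_numpy()
            fe = grp["end"].to_numpy()
            # first peak with end > fragment start; last peak with start < fragment end
            lo = np.searchsorted(pend, fs, side="right")
            hi = np.searchsorted(pstart, fe, side="left")
            for l, h in zip(lo, hi):
                if h > l:
                    col[prow[l:h]] += 1
        counts[sample] = col
    counts.index = pd.Index(id_arr, name="peak_id")
    return counts
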