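"""Readers and writers for the plain-text formats the pipeline speaks.

BED6 scored peaks, BED3 fragments, TSV count matrices (first column
``chrom:start-end`` peak ids, header row of sample ids), sample design
sheets, and FASTA via Bio.SeqIO.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_scored_peaks_bed(path) -> pd.DataFrame:
    """Read BED6 scored peaks (score column 5 carries the ranking score)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4],
    )
    return df[["chrom", "start", "end", "score"]]


def write_scored_peaks_bed(peaks: pd.DataFrame, path) -> None:
    out = peaks.copy()
    out["name"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def read_fragments_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
    )


def read_fragment_dir(directory) -> dict[str, pd.DataFrame]:
    """One BED3 file per sample; sample id is the file stem."""
    out = {}
    for p in sorted(Path(directory).glob("*.bed")):
        out[p.stem] = read_fragments_bed(p)
    return out


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="peak_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        path,
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_category_bed(path) -> pd.DataFrame:
    """Category map: BED with the name column holding the category label."""
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "category"], usecols=[0, 1, 2, 3],
    )


def write_category_bed(cmap: pd.DataFrame, path) -> None:
    cmap[["chrom", "start", "end", "category"]].to_csv(
        path, sep="\t", header=False, index=False
    )
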