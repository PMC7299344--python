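"""Pipeline configuration: YAML-backed, with the published defaults.

Defaults mirror the printed analysis parameters: top 11,500 peaks per
condition, differential cutoffs padj < 0.1 (with the stricter 0.05 also
reported) and |log2FC| > 0.5, the six-chromosome allow-list, and a 10 bp
track bin size.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from drms_scan.motifs import DEFAULT_MOTIFS
from drms_scan.simulate import SimDesign

DEFAULT_CHROMOSOMES = ["chr2L", "chr2R", "chr3L", "chr3R", "chr4", "chrX"]


@dataclass
class PipelineConfig:
    out_dir: str = "drms_run"
    seed: int = 0
    n_top: int = 11500
    padj_cuts: tuple[float, float] = (0.05, 0.1)
    lfc_cut: float = 0.5
    chromosomes: list[str] = field(default_factory=lambda: list(DEFAULT_CHROMOSOMES))
    bin_size: int = 10
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    sim: SimDesign = field(default_factory=SimDesign)
    # optional real inputs; when absent the sim block is used
    peak_beds: dict[str, str] = field(default_factory=dict)  # condition -> BED6
    counts_tsv: str | None = None
    design_tsv: str | None = None
    gff3: str | None = None
    genome_fasta: str | None = None
    category_bed: str | None = None

    def validate(self) -> None:
        if self.n_top < 0:
            raise ValueError("n_top must be >= 0")
        lo, hi = self.padj_cuts
        if not (0 < lo <= hi <= 1):
            raise ValueError("padj_cuts must satisfy 0 < strict <= relaxed <= 1")
        for name in ("counts_tsv", "design_tsv", "gff3", "genome_fasta", "category_bed"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for cond, p in self.peak_beds.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"peak_beds[{cond}]: {p}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["padj_cuts"] = list(self.padj_cuts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "conditions" in sim:
                sim["conditions"] = [tuple(c) for c in sim["conditions"]]
            d["sim"] = SimDesign(**sim)
        if "padj_cuts" in d:
            d["padj_cuts"] = tuple(d["padj_cuts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
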