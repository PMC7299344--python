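"""Synthetic chromatin-accessibility data with planted DRMS structure.

Emulates the study design of a regenerating-tissue ATAC-seq experiment:
4 conditions (early/late third-instar larval stage x damaged/undamaged
tissue) x 3 biological replicates. The central realism ingredient is
*responder dilution*: only a fraction ``f`` of cells in a damaged disc are
regenerating, so a damage-responsive peak that opens 2^delta-fold in those
cells shows a bulk mean of only

    mu * [(1 - f) + f * 2^delta]

in the whole-tissue assay. Maturity silencing, by contrast, is a
tissue-wide developmental process and is planted undiluted.

Counts are negative binomial with Var = m + alpha * m^2; per-peak baseline
accessibility is heavy-tailed (log-normal), as in real ATAC peak atlases.
All outputs are deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("earlyL3", "lateL3")
DAMAGES = ("damaged", "undamaged")
DEFAULT_CONDITIONS = [(s, d) for s in STAGES for d in DAMAGES]

LABELS = (
    "null",
    "damage_responsive_early",
    "damage_responsive_late",
    "damage_responsive_both",
    "maturity_silenced",
    "drms",
)

#: default fraction of atlas peaks planted per non-null label
DEFAULT_LABEL_FRACTIONS = {
    "damage_responsive_early": 0.02,
    "damage_responsive_late": 0.01,
    "damage_responsive_both": 0.01,
    "maturity_silenced": 0.03,
    "drms": 0.015,
}


@dataclass
class SimDesign:
    """Parameters of the simulated study.

    Attributes
    ----------
    n_peaks:
        Number of atlas regions to simulate.
    conditions:
        (stage, damage) pairs; defaults to the full 2x2 design.
    n_replicates:
        Biological replicates per condition (default 3).
    dilution_fraction:
        Fraction ``f`` of damaged tissue that is actually responding,
        0 < f <= 1. Default 0.15.
    dispersion:
        NB dispersion alpha (Var = m + alpha m^2), default 0.05.
    base_mean:
        Median expected accessibility counts per peak; per-peak baselines
        are log-normal around this with sdlog ``base_sdlog``.
    base_sdlog:
        Spread of per-peak baselines on the log scale (default 1.0).
    effect_lfc:
        Planted log2 effect size delta in responding cells for the
        moderate tier (default 3.0). After whole-tissue dilution at the
        default f = 0.15 this corresponds to a bulk log2FC of about 1.0 --
        near the call threshold, like the borderline responders real
        whole-disc assays struggle to detect.
    strong_effect_lfc:
        Effect for the strong tier (default 5.0; bulk log2FC about 2.4 at
        f = 0.15), emulating the clearest responders.
    strong_fraction:
        Fraction of planted peaks assigned to the strong tier (default 0.5).
    seed:
        Root RNG seed.
    """

    n_peaks: int = 2000
    conditions: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_CONDITIONS)
    )
    n_replicates: int = 3
    dilution_fraction: float = 0.15
    dispersion: float = 0.05
    base_mean: float = 200.0
    base_sdlog: float = 1.0
    effect_lfc: float = 3.0
    strong_effect_lfc: float = 5.0
    strong_fraction: float = 0.5
    seed: int = 0
    label_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_FRACTIONS)
    )
    depth_sdlog: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.dilution_fraction <= 1):
            raise ValueError("dilution_fraction must be in (0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be > 0")
        if self.n_peaks < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        for stage, damage in self.conditions:
            if stage not in STAGES or damage not in DAMAGES:
                raise ValueError(f"unknown condition ({stage}, {damage})")

    def design_table(self) -> pd.DataFrame:
        """Sample sheet: one row per (condition, replicate)."""
        rows = [
            (f"{s}_{d}_rep{r + 1}", s, d, r + 1)
            for s, d in self.conditions
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows, columns=["sample", "stage", "damage", "replicate"])


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: peak intervals, labels, planted effects."""

    peaks: pd.DataFrame  # chrom, start, end, peak_id, label, effect_lfc
    baselines: np.ndarray  # per-peak expected counts mu_i
    conserved_blocks: list[tuple[int, int]] = field(default_factory=list)
    motif_positions: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.peaks["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}")

    def labels(self) -> pd.Series:
        return self.peaks.set_index("peak_id")["label"]

    def to_json(self, path) -> None:
        obj = {
            "peaks": self.peaks.to_dict(orient="records"),
            "baselines": [float(x) for x in self.baselines],
            "conserved_blocks": [list(b) for b in self.conserved_blocks],
            "motif_positions": self.motif_positions,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            peaks=pd.DataFrame(obj["peaks"]),
            baselines=np.asarray(obj["baselines"], dtype=float),
            conserved_blocks=[tuple(b) for b in obj["conserved_blocks"]],
            motif_positions=obj.get("motif_positions", {}),
        )


# ---------------------------------------------------------------------------
# genome and gene models


def make_genome(seed: int, length: int, gene_count: int):
    """Random genome sequence plus non-overlapping gene models.

    Returns ``(sequence, gene_models)`` where the sequence is uppercase ACGT
    of the requested length and gene_models is a frame with gene id, strand,
    TSS, and exon intervals (0-based half-open), laid out on alternating
    strands in evenly spaced slots. Deterministic per seed.
    """
    if gene_count > 0 and length < 10 * gene_count * 1000:
        raise ValueError(
            f"length {length} too small for {gene_count} genes "
            f"(need >= {10 * gene_count * 1000})"
        )
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    slot = length // gene_count if gene_count else length
    rows = []
    for g in range(gene_count):
        lo, hi = g * slot, (g + 1) * slot
        span = int(rng.integers(2000, min(8000, slot // 2)))
        start = int(rng.integers(lo, hi - span))
        end = start + span
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
        tss = start if strand == "+" else end - 1
        rows.append((f"gene{g + 1:03d}", "chrS", start, end, strand, tss, exons))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss", "exons"]
    )
    return seq, genes


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 (1-based closed coordinates on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(
                f"{g.chrom}\tdrms_scan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (es, ee) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tdrms_scan\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def read_gff3(path) -> pd.DataFrame:
    """Read gene models from GFF3 into the internal half-open convention."""
    rows = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, ftype, start1, end1, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            start, end = int(start1) - 1, int(end1)  # to half-open
            if ftype == "gene":
                rows.append((attrs.get("ID", attrs.get("Name", "?")), chrom, start, end, strand))
            elif ftype == "exon":
                exons.setdefault(attrs.get("Parent", "?"), []).append((start, end))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    genes["exons"] = genes["gene_id"].map(lambda g: sorted(exons.get(g, [])))
    return genes


# ---------------------------------------------------------------------------
# orthologous enhancer sequences

_SUBS = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def make_orthologs(
    ref_enhancer: str,
    n_species: int,
    conserved_blocks: list[tuple[int, int]],
    mut_rate: float,
    seed: int,
) -> list[str]:
    """Diverged ortholog sequences with exactly conserved blocks.

    Every base inside a conserved block is copied verbatim into each
    ortholog; every base outside is substituted independently with
    probability ``mut_rate`` (always to a different base). Blocks are
    half-open subintervals of the reference and must be disjoint.
    """
    if not (0 <= mut_rate < 1):
        raise ValueError("mut_rate must be in [0, 1)")
    blocks = sorted(conserved_blocks)
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping conserved blocks ({s1},{e1}) and ({s2},{e2})")
    for s, e in blocks:
        if not (0 <= s < e <= len(ref_enhancer)):
            raise ValueError(f"block ({s},{e}) outside reference")
    protected = np.zeros(len(ref_enhancer), dtype=bool)
    for s, e in blocks:
        protected[s:e] = True
    rng = np.random.default_rng(seed)
    out = []
    ref = list(ref_enhancer)
    for _ in range(n_species):
        seq = ref.copy()
        hits = np.flatnonzero((rng.random(len(ref)) < mut_rate) & ~protected)
        for i in hits:
            seq[i] = _SUBS[ref[i]][rng.integers(3)]
        out.append("".join(seq))
    return out


# ---------------------------------------------------------------------------
# counts and peaks

_CHROMS = ["chr2L", "chr2R", "chr3L", "chr3R"]


def _truth_intervals(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out n_peaks disjoint atlas regions across synthetic chromosomes."""
    n = design.n_peaks
    per = int(np.ceil(n / len(_CHROMS)))
    rows = []
    k = 0
    for chrom in _CHROMS:
        pos = 1000
        for _ in range(per):
            if k >= n:
                break
            width = int(rng.integers(250, 600))
            gap = int(rng.integers(400, 1500))
            rows.append((chrom, pos, pos + width))
            pos += width + gap
            k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["peak_id"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    return df


def make_truth(design: SimDesign) -> SyntheticTruth:
    """Assign labels and planted effects to a fresh set of atlas regions."""
    rng = np.random.default_rng(design.seed)
    peaks = _truth_intervals(design, rng)
    n = len(peaks)
    labels = np.array(["null"] * n, dtype=object)
    counts = {
        lab: int(round(frac * n)) for lab, frac in design.label_fractions.items()
    }
    order = rng.permutation(n)
    pos = 0
    for lab in sorted(counts):  # stable label layout
        c = counts[lab]
        labels[order[pos : pos + c]] = lab
        pos += c
    peaks["label"] = labels
    planted = labels != "null"
    strong = planted & (rng.random(n) < design.strong_fraction)
    peaks["effect_lfc"] = np.where(
        strong, design.strong_effect_lfc, np.where(planted, design.effect_lfc, 0.0)
    )
    peaks["strong"] = strong
    baselines = rng.lognormal(
        mean=np.log(design.base_mean) - design.base_sdlog**2 / 2,
        sigma=design.base_sdlog,
        size=n,
    )
    return SyntheticTruth(peaks=peaks, baselines=baselines)


def expected_mixture_factor(label: str, stage: str, damage: str, f: float, delta: float) -> float:
    """Expected bulk fold factor (1-f_eff) + f_eff * 2^delta for one condition.

    Damage-responsive effects live in the responding fraction f of damaged
    tissue; pure maturity silencing is a whole-tissue early-stage elevation
    (f_eff = 1).
    """
    active_diluted = (
        (label == "damage_responsive_early" and stage == "earlyL3" and damage == "damaged")
        or (label == "damage_responsive_late" and stage == "lateL3" and damage == "damaged")
        or (label == "damage_responsive_both" and damage == "damaged")
        or (label == "drms" and stage == "earlyL3" and damage == "damaged")
    )
    if active_diluted:
        return (1 - f) + f * 2.0**delta
    if label == "maturity_silenced" and stage == "earlyL3":
        return 2.0**delta
    return 1.0


def simulate_counts(design: SimDesign, truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the peaks x samples NB count matrix.

    mean(i, j) = s_j * mu_i * mixture_factor(label_i, condition_j); counts
    are NB(mean m, dispersion alpha) drawn as gamma-Poisson (Poisson when
    alpha = 0). Returns (counts, design_table); counts are indexed by peak
    id with one column per sample. Deterministic per design.seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    table = design.design_table()
    n_samples = len(table)
    depth = rng.lognormal(mean=0.0, sigma=design.depth_sdlog, size=n_samples)
    mu = truth.baselines
    labels = truth.peaks["label"].to_numpy()
    deltas = truth.peaks["effect_lfc"].to_numpy()
    f = design.dilution_fraction
    alpha = design.dispersion
    mat = np.empty((len(mu), n_samples), dtype=np.int64)
    for j, row in table.iterrows():
        factors = np.array(
            [
                expected_mixture_factor(lab, row.stage, row.damage, f, d)
                for lab, d in zip(labels, deltas)
            ]
        )
        m = depth[j] * mu * factors
        if alpha == 0:
            mat[:, j] = rng.poisson(m)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=m * alpha)
            mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(
        mat, index=pd.Index(truth.peaks["peak_id"], name="peak_id"), columns=table["sample"]
    )
    return counts, table


def simulate_scored_peaks(
    truth: SyntheticTruth,
    design: SimDesign,
    n_top_pool: int | None = None,
    noise_peaks: int = 0,
    jitter: int = 25,
) -> dict[str, pd.DataFrame]:
    """Per-condition scored peak sets standing in for ranked caller output.

    Each condition's set contains every truth peak accessible in it, scored
    by the log of its simulated mean accessibility (plus small noise so
    ranks are not exactly tied across conditions), with boundaries jittered
    by up to ``jitter`` bp, plus ``noise_peaks`` condition-specific decoy
    intervals placed in the gaps between truth peaks. Keys are
    "stage_damage" labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    out = {}
    f = design.dilution_fraction
    labels = truth.peaks["label"].to_numpy()
    deltas = truth.peaks["effect_lfc"].to_numpy()
    mu = truth.baselines
    ends_by_chrom = truth.peaks.groupby("chrom")["end"].max()
    for stage, damage in design.conditions:
        cond = f"{stage}_{damage}"
        factors = np.array(
            [
                expected_mixture_factor(lab, stage, damage, f, d)
                for lab, d in zip(labels, deltas)
            ]
        )
        mean = mu * factors
        df = truth.peaks[["chrom", "start", "end"]].copy()
        if jitter:
            df["start"] = np.maximum(
                0, df["start"] + rng.integers(-jitter, jitter + 1, size=len(df))
            )
            df["end"] = df["end"] + rng.integers(-jitter, jitter + 1, size=len(df))
            df["end"] = np.maximum(df["end"], df["start"] + 50)
        df["score"] = np.log10(mean + 1) + rng.normal(0, 0.01, size=len(df))
        if noise_peaks:
            rows = []
            for _ in range(noise_peaks):
                chrom = _CHROMS[rng.integers(len(_CHROMS))]
                hi = int(ends_by_chrom.get(chrom, 10000)) + 50000
                s = int(rng.integers(0, hi))
                rows.append((chrom, s, s + int(rng.integers(150, 400)),
                             float(10 ** rng.normal(-0.5, 0.3) * 0.5)))
            noise = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
            df = pd.concat([df, noise], ignore_index=True)
        df["condition"] = cond
        if n_top_pool is not None:
            df = df.sort_values(
                ["score", "chrom", "start"], ascending=[False, True, True]
            ).head(n_top_pool)
        out[cond] = df.reset_index(drop=True)
    return out
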