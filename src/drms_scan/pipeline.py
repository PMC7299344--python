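"""End-to-end pipeline orchestration with provenance.

``run_pipeline`` executes: (optional) simulation -> union atlas -> counts
-> differential accessibility for the three study contrasts -> DRMS
classification -> gene/category annotation -> motif screen, writing every
stage's outputs plus a machine-readable manifest (config hash, package
version, per-stage output digests, timings) into a run directory. All
randomness flows from the single config seed, split per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from drms_scan import __version__, io
from drms_scan.annotate import (
    annotate_peaks_with_genes,
    build_category_map,
    categorize_peaks,
    category_enrichment,
)
from drms_scan.atlas import PeakAtlas, count_in_atlas, merge_overlapping, select_top_peaks
from drms_scan.classify import call_set, classify_drms, summarize
from drms_scan.config import PipelineConfig
from drms_scan.diffacc import estimate_dispersion, nb_wald_test, size_factors
from drms_scan.motifs import site_map_report
from drms_scan.simulate import (
    SimDesign,
    make_genome,
    make_truth,
    simulate_counts,
    simulate_scored_peaks,
    write_gff3,
)

logger = logging.getLogger(__name__)

CONTRASTS = {
    "dr_early": (("earlyL3", "damaged"), ("earlyL3", "undamaged")),
    "dr_late": (("lateL3", "damaged"), ("lateL3", "undamaged")),
    "ms": (("lateL3", "damaged"), ("earlyL3", "damaged")),
}


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def counts_for_atlas(
    atlas: PeakAtlas,
    truth_counts: pd.DataFrame,
    truth_peaks: pd.DataFrame,
    seed: int,
    background_mean: float = 20.0,
    dispersion: float = 0.05,
) -> pd.DataFrame:
    """Project simulated truth-peak counts onto a built atlas.

    Each atlas peak receives the summed counts of the truth peaks it
    overlaps (>= 1 bp); atlas peaks overlapping none (decoy peaks) draw NB
    background counts. Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    frags = {  # reuse the overlap sweep: treat truth peaks as "fragments"
        "x": truth_peaks[["chrom", "start", "end"]]
    }
    out = pd.DataFrame(
        0, index=pd.Index(atlas.ids, name="peak_id"), columns=truth_counts.columns,
        dtype=np.int64,
    )
    # sweep per chromosome: truth and atlas are each internally disjoint
    truth_idx = truth_peaks.reset_index(drop=True)
    tc = truth_counts.to_numpy()
    for chrom, agrp in atlas.peaks.groupby("chrom", sort=False):
        tgrp = truth_idx[truth_idx["chrom"] == chrom]
        ts = tgrp["start"].to_numpy()
        te = tgrp["end"].to_numpy()
        trow = tgrp.index.to_numpy()
        lo = np.searchsorted(te, agrp["start"].to_numpy(), side="right")
        hi = np.searchsorted(ts, agrp["end"].to_numpy(), side="left")
        for arow, l, h in zip(agrp.index.to_numpy(), lo, hi):
            if h > l:
                out.iloc[arow] = tc[trow[l:h]].sum(axis=0)
    empty = (out.sum(axis=1) == 0).to_numpy()
    if empty.any():
        lam = rng.gamma(
            shape=1.0 / dispersion,
            scale=background_mean * dispersion,
            size=(int(empty.sum()), out.shape[1]),
        )
        out.iloc[empty] = rng.poisson(lam)
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; return the run directory. Any stage failure aborts
    with the stage name while preserving partial outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        # hash of the scientific configuration only (output location excluded)
        "config_sha256": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.to_dict().items() if k != "out_dir"},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "stages": {},
    }
    stage = "setup"
    try:
        design = config.sim
        design = SimDesign(**{**design.__dict__, "seed": config.seed})

        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        truth = make_truth(design)
        truth_counts, design_table = simulate_counts(design, truth)
        peak_sets = simulate_scored_peaks(truth, design)
        genome_seq, genes = make_genome(config.seed, 400_000, 30)
        truth.to_json(out / "truth.json")
        io.write_design_tsv(design_table, out / "design.tsv")
        io.write_fasta({"chrS": genome_seq}, out / "genome.fa")
        write_gff3(genes, out / "genes.gff3")
        for cond, df in peak_sets.items():
            io.write_scored_peaks_bed(df, out / f"peaks_{cond}.bed")
        _record(manifest, "simulate", out, t0,
                ["truth.json", "design.tsv", "genome.fa", "genes.gff3"]
                + [f"peaks_{c}.bed" for c in peak_sets])

        # ---- atlas -------------------------------------------------------
        stage = "atlas"
        t0 = time.time()
        top = [
            select_top_peaks(df, config.n_top).assign(condition=cond)
            for cond, df in peak_sets.items()
        ]
        pooled = pd.concat(top, ignore_index=True)
        pooled = pooled[pooled["chrom"].isin(config.chromosomes)]
        atlas = merge_overlapping(pooled)
        atlas.to_bed(out / "atlas.bed")
        _record(manifest, "atlas", out, t0, ["atlas.bed"],
                extra={"n_pre_merge": int(len(pooled)), "n_atlas": len(atlas)})

        # ---- counts ------------------------------------------------------
        stage = "counts"
        t0 = time.time()
        counts = counts_for_atlas(
            atlas, truth_counts, truth.peaks, seed=config.seed,
            dispersion=design.dispersion,
        )
        io.write_counts_tsv(counts, out / "counts.tsv")
        _record(manifest, "counts", out, t0, ["counts.tsv"])

        # ---- differential accessibility ---------------------------------
        stage = "diffacc"
        t0 = time.time()
        factors = size_factors(counts)
        disp = estimate_dispersion(counts, factors, design_table)
        results = {}
        for name, contrast in CONTRASTS.items():
            res = nb_wald_test(counts, design_table, contrast,
                               dispersion=disp, factors=factors)
            res.to_csv(out / f"diff_{name}.tsv", sep="\t", index_label="peak_id")
            results[name] = res
        _record(manifest, "diffacc", out, t0,
                [f"diff_{n}.tsv" for n in CONTRASTS])

        # ---- classify ----------------------------------------------------
        stage = "classify"
        t0 = time.time()
        padj_strict, padj_relaxed = config.padj_cuts
        for tag, cut in (("strict", padj_strict), ("relaxed", padj_relaxed)):
            cs = classify_drms(
                call_set(results["dr_early"], "up", cut, config.lfc_cut),
                call_set(results["dr_late"], "up", cut, config.lfc_cut),
                call_set(results["ms"], "down", cut, config.lfc_cut),
                padj_cut=cut, lfc_cut=config.lfc_cut,
            )
            summarize(cs, atlas.ids, out / f"callset_{tag}.tsv",
                      out / f"callset_{tag}.json")
        _record(manifest, "classify", out, t0,
                ["callset_strict.tsv", "callset_strict.json",
                 "callset_relaxed.tsv", "callset_relaxed.json"])

        # ---- annotate ----------------------------------------------------
        stage = "annotate"
        t0 = time.time()
        # synthetic gene models live on chrS; annotate truth-sized demo peaks
        demo_peaks = atlas.peaks.head(200)
        gene_tbl = annotate_peaks_with_genes(
            demo_peaks.assign(chrom="chrS"), genes
        )
        gene_tbl.to_csv(out / "peak_genes.tsv", sep="\t", index=False)
        cmap = build_category_map(genes, atlas_peaks=demo_peaks.assign(chrom="chrS"))
        cats = categorize_peaks(demo_peaks.assign(chrom="chrS"), cmap)
        enr = category_enrichment(cats.head(40), cats)
        enr.to_csv(out / "category_enrichment.tsv", sep="\t", index=False)
        _record(manifest, "annotate", out, t0,
                ["peak_genes.tsv", "category_enrichment.tsv"])

        # ---- motifs ------------------------------------------------------
        stage = "motifs"
        t0 = time.time()
        report = site_map_report(genome_seq[:20000], config.motifs, seq_id="chrS")
        report.to_csv(out / "motif_sites.tsv", sep="\t", index=False)
        _record(manifest, "motifs", out, t0, ["motif_sites.tsv"])
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def _record(manifest: dict, stage: str, out: Path, t0: float,
            files: list[str], extra: dict | None = None) -> None:
    # timings go to the plain-text log, not the manifest, so manifests of
    # identical seeded runs are byte-identical
    entry = {"outputs": {f: _digest(out / f) for f in files}}
    if extra:
        entry.update(extra)
    manifest["stages"][stage] = entry
    seconds = time.time() - t0
    logger.info("stage %s done in %.2fs", stage, seconds)
    with open(out / "run.log", "a") as fh:
        fh.write(f"{stage}\t{seconds:.3f}s\n")
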