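import itertools

import numpy as np
import pandas as pd
import pytest

from drms_scan.simulate import SimDesign, make_truth, simulate_counts


def peaks_frame(rows):
    """Build a scored-peak frame from (chrom, start, end, score) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1000, width=60):
    rows = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, span))
        rows.append((c, s, s + int(rng.integers(1, width)), float(rng.random())))
    return peaks_frame(rows)


@pytest.fixture(scope="session")
def default_run():
    """One full simulation + differential run at the default design, seed 7.

    Shared across tests that probe classification to avoid recomputing the
    NB tests.
    """
    from drms_scan.classify import call_set, classify_drms
    from drms_scan.diffacc import estimate_dispersion, nb_wald_test, size_factors

    design = SimDesign(seed=7)
    truth = make_truth(design)
    counts, table = simulate_counts(design, truth)
    factors = size_factors(counts)
    disp = estimate_dispersion(counts, factors, table)
    contrasts = {
        "dr_early": (("earlyL3", "damaged"), ("earlyL3", "undamaged")),
        "dr_late": (("lateL3", "damaged"), ("lateL3", "undamaged")),
        "ms": (("lateL3", "damaged"), ("earlyL3", "damaged")),
    }
    results = {
        name: nb_wald_test(counts, table, c, dispersion=disp, factors=factors)
        for name, c in contrasts.items()
    }
    return {
        "design": design,
        "truth": truth,
        "counts": counts,
        "table": table,
        "results": results,
    }


def within_condition_pairs(table):
    for _, grp in table.groupby(["stage", "damage"]):
        yield from itertools.combinations(grp["sample"], 2)
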