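"""Enhancer sequence screening: IUPAC motif scans, conserved blocks, k-mers.

Implements the three sequence analyses used to dissect bipartite
damage-responsive/silencing enhancers:

* degenerate-consensus scanning on both strands (AP-1 ``TGASTCA``, the
  Pleiohomeotic core ``GCCAT``, Sp1 ``GGGCGG`` by default -- literature
  consensus patterns, overridable in config);
* detection of maximal blocks of byte-identical sequence (default >= 50 bp)
  shared by every species in a set of orthologous enhancer sequences;
* genome-wide exact search for a query k-mer on both strands (e.g. a 17 bp
  sequence shared between distinct enhancer loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DEFAULT_MOTIFS = {
    "AP-1": "TGASTCA",
    "Pho": "GCCAT",
    "Sp1": "GGGCGG",
}

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based, plus-strand coordinates of the match span
    length: int
    strand: str
    motif: str
    matched: str  # plus-strand substring at [start, start+length)


def _check_iupac(pattern: str) -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
    return pattern


def _match_at(seq: str, i: int, pattern: str) -> bool:
    for j, p in enumerate(pattern):
        if seq[i + j] not in IUPAC[p]:
            return False
    return True


def scan_iupac(
    sequence: str,
    pattern: str,
    motif_name: str = "motif",
    seq_id: str = "seq",
    both_strands: bool = True,
) -> list[MotifHit]:
    """All matches of a degenerate IUPAC pattern, both strands by default.

    Minus-strand hits are reported in plus-strand coordinates of the match
    span; overlapping hits are all reported; hits are sorted by (start,
    strand).
    """
    pattern = _check_iupac(pattern)
    seq = sequence.upper()
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        if _match_at(seq, i, pattern):
            hits.append(MotifHit(seq_id, i, k, "+", motif_name, seq[i : i + k]))
    if both_strands:
        rc_pattern = reverse_complement(pattern)
        for i in range(len(seq) - k + 1):
            if _match_at(seq, i, rc_pattern):
                hits.append(MotifHit(seq_id, i, k, "-", motif_name, seq[i : i + k]))
    return sorted(hits, key=lambda h: (h.start, h.strand))


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of identical sequence present in every input species."""

    starts: tuple[int, ...]  # one start per species, reference first
    length: int
    sequence: str


def find_conserved_blocks(sequences: list[str], min_len: int = 50) -> list[ConservedBlock]:
    """Maximal common substrings of length >= min_len shared by all species.

    Anchored by exact ``min_len``-mers of the first (reference) sequence
    located in every other sequence, then extended maximally left and right
    while all species stay identical. Overlapping or duplicate maximal
    blocks are deduplicated; output is sorted by reference coordinate.
    ``min_len`` below 8 is refused as a combinatorial guard.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    if any(len(s) == 0 for s in sequences):
        raise ValueError("sequences must be non-empty")
    seqs = [s.upper() for s in sequences]
    ref = seqs[0]
    others = seqs[1:]
    # k-mer position index per non-reference species
    indexes = []
    for s in others:
        idx: dict[str, list[int]] = {}
        for i in range(len(s) - min_len + 1):
            idx.setdefault(s[i : i + min_len], []).append(i)
        indexes.append(idx)
    seen: set[tuple[int, ...]] = set()
    blocks = []
    for i in range(len(ref) - min_len + 1):
        kmer = ref[i : i + min_len]
        cand = [idx.get(kmer) for idx in indexes]
        if any(c is None for c in cand):
            continue
        # extend every combination? anchor each candidate tuple greedily:
        # one block per combination, deduped by the extended coordinates
        from itertools import product

        for combo in product(*cand):
            pos = [i, *combo]
            # extend left
            while all(p > 0 for p in pos) and len(
                {seqs[s][pos[s] - 1] for s in range(len(seqs))}
            ) == 1:
                pos = [p - 1 for p in pos]
            # extend right
            length = min_len + (i - pos[0])
            while all(p + length < len(seqs[s]) for s, p in enumerate(pos)) and len(
                {seqs[s][p + length] for s, p in enumerate(pos)}
            ) == 1:
                length += 1
            key = tuple(pos) + (length,)
            if key in seen:
                continue
            seen.add(key)
            blocks.append(
                ConservedBlock(tuple(pos), length, ref[pos[0] : pos[0] + length])
            )
    # drop blocks whose reference span is contained in another block's span
    # (shorter matches at alternate occurrences of a longer conserved run)
    uniq = sorted(set(blocks), key=lambda b: (b.starts[0], -b.length))
    kept: list[ConservedBlock] = []
    for b in uniq:
        s, e = b.starts[0], b.starts[0] + b.length
        if any(
            k.starts[0] <= s and e <= k.starts[0] + k.length and
            (k.starts[0], k.length) != (s, b.length)
            for k in kept
        ):
            continue
        kept.append(b)
    # equal reference spans from different occurrence combinations: keep one
    seen_spans: set[tuple[int, int]] = set()
    final = []
    for b in kept:
        span = (b.starts[0], b.length)
        if span in seen_spans:
            continue
        seen_spans.add(span)
        final.append(b)
    return final


def exact_motif_search(
    genome: dict[str, str], query: str, both_strands: bool = True
) -> list[MotifHit]:
    """All exact occurrences of an ACGT query across genome sequences.

    A palindromic query is reported once per strand with identical
    coordinates. Ambiguous bases are refused (use :func:`scan_iupac`).
    """
    query = query.upper()
    if set(query) - set("ACGT"):
        raise ValueError("ambiguous bases in query; use scan_iupac for IUPAC patterns")
    k = len(query)
    rc = reverse_complement(query)
    hits = []
    for seq_id, seq in genome.items():
        seq = seq.upper()
        for strand, q in (("+", query), ("-", rc)):
            if not both_strands and strand == "-":
                continue
            i = seq.find(q)
            while i != -1:
                hits.append(MotifHit(seq_id, i, k, strand, f"kmer:{query}", seq[i : i + k]))
                i = seq.find(q, i + 1)
    return sorted(hits, key=lambda h: (h.seq_id, h.start, h.strand))


def site_map_report(
    sequence: str,
    motifs: dict[str, str] | None = None,
    seq_id: str = "seq",
) -> pd.DataFrame:
    """Ordered table of all configured motif sites in one sequence.

    The textual analogue of an annotated enhancer schematic: one row per
    site with motif name, position, strand (orientation) and matched
    sequence, sorted by coordinate then motif name. Output is independent
    of the order motifs are configured in.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    rows = []
    for name in motifs:
        for h in scan_iupac(sequence, motifs[name], motif_name=name, seq_id=seq_id):
            rows.append((h.seq_id, h.start, h.start + h.length, h.strand, h.motif, h.matched))
    df = pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "strand", "motif", "matched"]
    )
    return df.sort_values(["start", "motif", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def hits_to_bed6(hits: list[MotifHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.start + h.length}\t{h.motif}\t0\t{h.strand}\n"
            )
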