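"""Pairwise ANI and greedy clustering into species-level viral populations.

Viral populations are defined as contigs larger than 5 kbp clustering at
>= 95% average nucleotide identity (ANI) over >= 80% of the shorter
sequence, represented by their longest member.  Two ANI routes are
provided:

``method="seed"``
    Anchored alignment: exact-match k-mer seeds (default k = 15) on both
    strands are grouped into gap-free diagonal blocks, the best colinear
    chain of blocks is selected, terminal blocks are extended gap-free to
    the overlap ends, and ANI is the match fraction over all chained
    columns.  This reproduces nucmer-style ANI on substitution-divergent
    sequences at desk scale.

``method="dp"``
    Quadratic dynamic-programming alignment (unit-cost semi-global: the
    shorter sequence aligned within the longer, via edlib), used as the
    exact route for short sequences and as the independent oracle for the
    seeded chain.

``method="auto"`` (default) uses DP when the longer sequence is at most
``DP_MAX_LEN`` bp and the seeded chain otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from viropop.io_formats import ContigRecord

__all__ = [
    "PairwiseAlignmentSummary",
    "Population",
    "pairwise_ani",
    "cluster_populations",
]

#: sequences up to this length use the exact DP route under method="auto"
DP_MAX_LEN = 2000
DEFAULT_SEED_LENGTH = 15
#: k-mers occurring more often than this in the indexed sequence are skipped
MAX_KMER_OCCURRENCES = 8

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

# A,C,G,T -> 0..3; query N -> 4, target N -> 5 so N never matches anything
_ENC_A = np.full(256, 4, dtype=np.uint8)
_ENC_B = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC_A[_b] = _i
    _ENC_B[_b] = _i


class UnalignableError(ValueError):
    """Raised when a sequence has no alignable (non-N) bases."""


@dataclass(frozen=True)
class PairwiseAlignmentSummary:
    """ANI and aligned fraction between two contigs.

    ``aligned_fraction_shorter`` is aligned bases on the shorter contig
    divided by its length (the "over 80% of the shortest sequence"
    criterion); ``strand`` is the orientation of the better-scoring
    alignment.
    """

    query_id: str
    target_id: str
    ani_percent: float
    aligned_fraction_shorter: float
    strand: str  # plus | minus


@dataclass(frozen=True)
class Population:
    """A species-level cluster; the representative is the longest member."""

    representative_id: str
    member_ids: tuple[str, ...]  # representative first
    representative_length: int


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the window contains an N."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    codes[~valid] = -1
    return codes


def _seed_hits(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions (apos, bpos) of shared exact k-mers, capped per k-mer."""
    ka = _kmer_codes(a, k)
    kb = _kmer_codes(b, k)
    if ka.size == 0 or kb.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(ka, kind="stable")
    sorted_ka = ka[order]
    lo = np.searchsorted(sorted_ka, kb, side="left")
    hi = np.searchsorted(sorted_ka, kb, side="right")
    counts = hi - lo
    valid = (kb >= 0) & (counts > 0) & (counts <= MAX_KMER_OCCURRENCES)
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    reps = counts[idx]
    bpos = np.repeat(idx, reps)
    # ranges into the sorted index for each hit
    starts = np.repeat(lo[idx], reps)
    offsets = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    apos = order[starts + offsets]
    return apos.astype(np.int64), bpos.astype(np.int64)


def _diagonal_blocks(
    a: np.ndarray, b: np.ndarray, apos: np.ndarray, bpos: np.ndarray, k: int
) -> list[tuple[int, int, int, int]]:
    """Collapse seed hits into gap-free blocks, one per supported diagonal.

    Returns (astart, bstart, span, matches) per diagonal, where the block
    spans from the first to the last seed on that diagonal and matches are
    counted by direct column comparison (N never matches).
    """
    diag = apos - bpos
    blocks = []
    for d in np.unique(diag):
        sel = diag == d
        b0 = int(bpos[sel].min())
        b1 = int(bpos[sel].max()) + k
        span = b1 - b0
        m = int(np.count_nonzero(a[b0 + d : b1 + d] == b[b0:b1]))
        blocks.append((int(b0 + d), b0, span, m))
    return blocks


def _chain_blocks(blocks: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Greedy colinear chain: take blocks by descending matches, keep those
    compatible (non-overlapping, same order) with all already kept."""
    chain: list[tuple[int, int, int, int]] = []
    for blk in sorted(blocks, key=lambda t: (-t[3], t[0])):
        a0, b0, span, _ = blk
        a1, b1 = a0 + span, b0 + span
        ok = True
        for c in chain:
            ca0, cb0, cspan, _ = c
            ca1, cb1 = ca0 + cspan, cb0 + cspan
            before = a1 <= ca0 and b1 <= cb0
            after = a0 >= ca1 and b0 >= cb1
            if not (before or after):
                ok = False
                break
        if ok:
            chain.append(blk)
    return sorted(chain, key=lambda t: t[0])


def _seeded_strand_alignment(
    a: np.ndarray, b: np.ndarray, k: int
) -> tuple[int, int]:
    """(matches, aligned_columns) of the chained+extended alignment of b
    against a on one strand; (0, 0) when no seed is found."""
    apos, bpos = _seed_hits(a, b, k)
    if apos.size == 0:
        return 0, 0
    blocks = _chain_blocks(_diagonal_blocks(a, b, apos, bpos, k))
    if not blocks:
        return 0, 0
    matches = sum(m for *_xs, m in blocks)
    columns = sum(span for _a, _b, span, _m in blocks)
    # gap-free extension of the terminal blocks to the overlap ends
    a0, b0, _, _ = blocks[0]
    ext = min(a0, b0)
    if ext > 0:
        matches += int(np.count_nonzero(a[a0 - ext : a0] == b[b0 - ext : b0]))
        columns += ext
    aL, bL, span, _ = blocks[-1]
    a1, b1 = aL + span, bL + span
    ext = min(a.size - a1, b.size - b1)
    if ext > 0:
        matches += int(np.count_nonzero(a[a1 : a1 + ext] == b[b1 : b1 + ext]))
        columns += ext
    return matches, columns


def _ani_seeded(long_seq: str, short_seq: str, k: int) -> tuple[float, float, str]:
    a = _ENC_A[np.frombuffer(long_seq.encode(), dtype=np.uint8)]
    best = (0, 0, "plus")
    for strand, sseq in (("plus", short_seq), ("minus", _revcomp(short_seq))):
        b = _ENC_B[np.frombuffer(sseq.encode(), dtype=np.uint8)]
        m, cols = _seeded_strand_alignment(a, b, k)
        if m > best[0]:
            best = (m, cols, strand)
    matches, columns, strand = best
    if columns == 0:
        return 0.0, 0.0, "plus"
    ani = 100.0 * matches / columns
    af = min(1.0, columns / len(short_seq))
    return ani, af, strand


def _ani_dp(long_seq: str, short_seq: str) -> tuple[float, float, str]:
    """Semi-global DP alignment of the shorter sequence within the longer."""
    best = None
    for strand, sseq in (("plus", short_seq), ("minus", _revcomp(short_seq))):
        res = edlib.align(sseq, long_seq, mode="HW", task="path")
        if best is None or res["editDistance"] < best[1]["editDistance"]:
            best = (strand, res)
    strand, res = best
    matches = columns = qaligned = 0
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        count = int(count)
        columns += count
        if op == "=":
            matches += count
        if op in ("=", "X", "I"):
            qaligned += count
    if columns == 0:
        return 0.0, 0.0, "plus"
    ani = 100.0 * matches / columns
    af = qaligned / len(short_seq)
    return ani, af, strand


def pairwise_ani(
    a: ContigRecord,
    b: ContigRecord,
    method: str = "auto",
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> PairwiseAlignmentSummary:
    """Compute ANI and aligned fraction between two contigs.

    Symmetric under argument swap (the pair is canonicalised internally:
    the shorter sequence is aligned against the longer).  Raises
    :class:`UnalignableError` when either sequence contains only N.
    """
    for rec in (a, b):
        if set(rec.sequence) <= {"N"}:
            raise UnalignableError(f"contig {rec.contig_id!r}: unalignable (all N)")
    if method not in ("auto", "seed", "dp"):
        raise ValueError(f"unknown method {method!r}")

    # canonical order: longer first, ties by id, so ani(a,b) == ani(b,a)
    first, second = sorted((a, b), key=lambda r: (-r.length, r.contig_id))
    if method == "auto":
        method = "dp" if first.length <= DP_MAX_LEN else "seed"
    if method == "dp":
        ani, af, strand = _ani_dp(first.sequence, second.sequence)
    else:
        ani, af, strand = _ani_seeded(first.sequence, second.sequence, seed_length)
    return PairwiseAlignmentSummary(
        query_id=a.contig_id,
        target_id=b.contig_id,
        ani_percent=ani,
        aligned_fraction_shorter=af,
        strand=strand,
    )


def cluster_populations(
    contigs: list[ContigRecord],
    min_length_bp: int = 5000,
    ani_threshold: float = 95.0,
    af_threshold: float = 0.80,
    method: str = "auto",
) -> list[Population]:
    """Greedily cluster contigs into viral populations.

    Contigs with length <= ``min_length_bp`` are excluded ("larger than
    5 kbp" read strictly).  Retained contigs are scanned longest-first
    (ties by id ascending); each joins the first existing population whose
    representative it matches at ANI >= ``ani_threshold`` and aligned
    fraction >= ``af_threshold`` (both inclusive), else founds a new
    population.  The founder — the longest member — is the representative.
    Output is sorted by representative length descending; the partition is
    invariant to input order.
    """
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids")
    retained = [c for c in contigs if c.length > min_length_bp]
    retained.sort(key=lambda c: (-c.length, c.contig_id))

    reps: list[ContigRecord] = []
    members: list[list[str]] = []
    for contig in retained:
        placed = False
        for i, rep in enumerate(reps):
            summ = pairwise_ani(rep, contig, method=method)
            if summ.ani_percent >= ani_threshold and summ.aligned_fraction_shorter >= af_threshold:
                members[i].append(contig.contig_id)
                placed = True
                break
        if not placed:
            reps.append(contig)
            members.append([contig.contig_id])

    populations = [
        Population(
            representative_id=rep.contig_id,
            member_ids=tuple(mem),
            representative_length=rep.length,
        )
        for rep, mem in zip(reps, members)
    ]
    populations.sort(key=lambda p: (-p.representative_length, p.representative_id))
    return populations
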