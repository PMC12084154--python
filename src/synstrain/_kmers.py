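"""Vectorized k-mer encoding and exact-match anchor discovery.

Shared substrate for the homology search (seeding) and the synteny-block
finder (maximal exact matches). Sequences are encoded as int8 arrays with
A/C/G/T -> 0..3 and every other character -> -1; k-mers touching a -1 base
are never enumerated, which implements the rule that ambiguous bases (N and
other IUPAC codes) neither seed nor anchor.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (-1 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and integer codes of all valid (ambiguity-free) k-mers.

    Returns (positions, codes), both int64, sorted by position.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ok = np.ones(n, dtype=bool)
    enc = np.zeros(n, dtype=np.int64)
    valid = codes >= 0
    safe = np.where(valid, codes, 0).astype(np.int64)
    for j in range(k):
        ok &= valid[j : j + n]
        enc = enc * 4 + safe[j : j + n]
    pos = np.nonzero(ok)[0].astype(np.int64)
    return pos, enc[pos]


def _frequent_codes(codes: np.ndarray, max_occ: int) -> np.ndarray:
    """Sorted array of k-mer codes occurring more than max_occ times."""
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq[counts > max_occ]


class KmerProfile:
    """Repeat-filtered k-mer content of one sequence, reusable across pairs.

    k-mers occurring more than ``max_occ`` times in the sequence are dropped
    at construction, so matching two profiles reproduces the pairwise
    "frequent in either sequence" masking rule.
    """

    __slots__ = ("k", "pos", "codes", "sorted_codes", "sorted_pos")

    def __init__(self, seq: str, k: int = 11, max_occ: int = 8):
        self.k = k
        pos, codes = kmer_codes(encode(seq), k)
        bad = _frequent_codes(codes, max_occ)
        if bad.size:
            keep = ~np.isin(codes, bad)
            pos, codes = pos[keep], codes[keep]
        self.pos, self.codes = pos, codes
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order]


def shared_kmer_hits(
    seq_a: str | KmerProfile,
    seq_b: str | KmerProfile,
    k: int = 11,
    max_occ: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """All (a_pos, b_pos) pairs where the two sequences share a k-mer.

    k-mers occurring more than ``max_occ`` times in either sequence are
    ignored (repeat masking). Accepts raw strings or precomputed
    ``KmerProfile`` objects. Returns parallel int64 arrays.
    """
    pa = seq_a if isinstance(seq_a, KmerProfile) else KmerProfile(seq_a, k, max_occ)
    pb = seq_b if isinstance(seq_b, KmerProfile) else KmerProfile(seq_b, k, max_occ)
    if pa.pos.size == 0 or pb.pos.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lo = np.searchsorted(pb.sorted_codes, pa.codes, side="left")
    hi = np.searchsorted(pb.sorted_codes, pa.codes, side="right")
    counts = hi - lo
    n_hits = int(counts.sum())
    if n_hits == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    a_hits = np.repeat(pa.pos, counts)
    # expand the [lo, hi) ranges into flat indices of the sorted b codes
    take = np.repeat(lo, counts) + (
        np.arange(n_hits) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    b_hits = pb.sorted_pos[take]
    return a_hits, b_hits


def diagonal_runs(
    a_hits: np.ndarray, b_hits: np.ndarray, k: int
) -> list[tuple[int, int, int]]:
    """Merge shared k-mer hits into maximal same-diagonal runs.

    Overlapping/adjacent hits on one diagonal collapse to a single run.
    Returns (a_start, b_start, length) triples sorted by (diagonal, a_start).
    """
    if a_hits.size == 0:
        return []
    diag = b_hits - a_hits
    order = np.lexsort((a_hits, diag))
    a_s, d_s = a_hits[order], diag[order]
    new_run = np.ones(a_s.size, dtype=bool)
    new_run[1:] = (np.diff(d_s) != 0) | (np.diff(a_s) > k)
    starts = np.nonzero(new_run)[0]
    ends = np.append(starts[1:], a_s.size) - 1
    out = []
    for s, e in zip(starts, ends):
        a0 = int(a_s[s])
        length = int(a_s[e]) - a0 + k
        out.append((a0, a0 + int(d_s[s]), length))
    return out
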