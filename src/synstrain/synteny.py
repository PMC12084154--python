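"""Synteny-block detection and region-pair synteny scoring.

Within each region-specific bin, every pair of homologous ~5-kbp sequences
is compared: maximal exact-match anchors are found, the highest-coverage
colinear chain of anchors is selected, and consecutive anchors are grouped
into synteny blocks wherever the inter-anchor gap in either sequence stays
within ``max_gap`` bp and the diagonal shift between them stays within
``max_sep`` bp (both default 15). A lone substitution therefore never splits
a block, while an indel longer than 15 bp — or a dense cluster of several
substitutions — does.

The pair is then summarized by the synteny score

    score = 1 + log10((Ov / len) / B)

where ``B`` is the number of synteny blocks, ``Ov`` the accumulated block
length measured on the shorter sequence and ``len`` the length of the
shorter sequence. The score has a maximum of 1, attained exactly when a
single block covers the shorter sequence end to end; extra blocks and lost
overlap both push it down (it can go negative for heavily rearranged pairs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from ._kmers import KmerProfile, diagonal_runs, shared_kmer_hits

log = logging.getLogger(__name__)

DEFAULT_K = 11
DEFAULT_MAX_OCC = 8
DEFAULT_MAX_GAP = 15
DEFAULT_MAX_SEP = 15
#: minimum accumulated block length for a pair to be scored, at the default
#: 1-kbp region + 2-kbp flanks (0.96 x 5000)
DEFAULT_MIN_OVERLAP = 4800


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between two sequences."""

    a_start: int
    b_start: int
    length: int

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length


@dataclass(frozen=True)
class SyntenyBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int


@dataclass(frozen=True)
class PairwiseRegionScore:
    """Synteny summary of one region pair: B blocks covering Ov of len bp."""

    region_id: str
    sample_a: str
    sample_b: str
    blocks: int  # B
    overlap: int  # Ov, accumulated block length on the shorter sequence
    length: int  # len of the shorter sequence
    score: float


def find_anchors(
    seq_a: str,
    seq_b: str,
    k: int = DEFAULT_K,
    max_occ: int = DEFAULT_MAX_OCC,
    profile_a: KmerProfile | None = None,
    profile_b: KmerProfile | None = None,
) -> list[Anchor]:
    """Maximal exact matches between two sequences (forward strand only).

    Shared k-mers are merged along diagonals and each run is extended
    outward base-by-base to its maximal extent (recovering bases lost to
    the ``max_occ`` repeat filter). Duplicates arising from extension are
    collapsed. Precomputed ``KmerProfile`` objects may be supplied when the
    same sequence takes part in many pairs.
    """
    if not seq_a or not seq_b:
        raise ValueError("find_anchors requires non-empty sequences")
    a_hits, b_hits = shared_kmer_hits(profile_a or seq_a, profile_b or seq_b,
                                      k=k, max_occ=max_occ)
    runs = diagonal_runs(a_hits, b_hits, k)
    la, lb = len(seq_a), len(seq_b)
    seen: set[tuple[int, int, int]] = set()
    anchors: list[Anchor] = []
    for a0, b0, length in runs:
        while a0 > 0 and b0 > 0 and seq_a[a0 - 1] == seq_b[b0 - 1] \
                and seq_a[a0 - 1] in "ACGT":
            a0 -= 1
            b0 -= 1
            length += 1
        while a0 + length < la and b0 + length < lb \
                and seq_a[a0 + length] == seq_b[b0 + length] \
                and seq_a[a0 + length] in "ACGT":
            length += 1
        key = (a0, b0, length)
        if key not in seen:
            seen.add(key)
            anchors.append(Anchor(a0, b0, length))
    anchors.sort(key=lambda a: (a.a_start, a.b_start))
    return anchors


def _best_colinear_chain(anchors: Sequence[Anchor]) -> list[Anchor]:
    """Highest-coverage colinear subset of anchors (crossings resolved).

    Quadratic chaining DP; anchors may overlap by a few bases (shared indel
    flanks), in which case the overlap is discounted from the gain.
    """
    n = len(anchors)
    if n <= 1:
        return list(anchors)
    srt = sorted(anchors, key=lambda a: (a.a_start, a.b_start))
    # fast path: already colinear (monotone in all coordinates, the common
    # case for near-identical pairs) -- the full set is the optimal chain
    if all(
        p.a_start < c.a_start and p.b_start < c.b_start
        and p.a_end < c.a_end and p.b_end < c.b_end
        for p, c in zip(srt, srt[1:])
    ):
        return srt
    order = sorted(range(n), key=lambda i: (anchors[i].a_start,
                                            anchors[i].b_start))
    best = [0.0] * n
    prev = [-1] * n
    for oi, i in enumerate(order):
        ai = anchors[i]
        best[i] = float(ai.length)
        for j in order[:oi]:
            aj = anchors[j]
            if ai.a_start <= aj.a_start or ai.b_start <= aj.b_start:
                continue
            if ai.a_end <= aj.a_end or ai.b_end <= aj.b_end:
                continue
            overlap = max(0, aj.a_end - ai.a_start, aj.b_end - ai.b_start)
            if overlap >= ai.length:
                continue
            cand = best[j] + ai.length - overlap
            if cand > best[i]:
                best[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    chain.reverse()
    return chain


def chain_blocks(
    anchors: Sequence[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    max_sep: int = DEFAULT_MAX_SEP,
) -> list[SyntenyBlock]:
    """Group colinear anchors into synteny blocks.

    Consecutive anchors of the highest-coverage colinear chain join the same
    block iff the inter-anchor gap is at most ``max_gap`` bp in both
    sequences and the absolute diagonal shift between them is at most
    ``max_sep`` bp. Block spans run from the first anchor's start to the
    last anchor's end in each sequence.
    """
    if not anchors:
        return []
    chain = _best_colinear_chain(anchors)
    groups: list[list[Anchor]] = [[chain[0]]]
    for prv, cur in zip(chain, chain[1:]):
        gap_a = cur.a_start - prv.a_end
        gap_b = cur.b_start - prv.b_end
        if gap_a <= max_gap and gap_b <= max_gap \
                and abs(gap_b - gap_a) <= max_sep:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    blocks: list[SyntenyBlock] = []
    for g in groups:
        a0, a1 = g[0].a_start, g[-1].a_end
        b0, b1 = g[0].b_start, g[-1].b_end
        if blocks:  # trim any residual overlap with the previous block
            a0 = max(a0, blocks[-1].a_end)
            b0 = max(b0, blocks[-1].b_end)
        if a1 > a0 and b1 > b0:
            blocks.append(SyntenyBlock(a0, a1, b0, b1))
    return blocks


def synteny_score(
    blocks: Sequence[SyntenyBlock],
    len_a: int,
    len_b: int,
    region_id: str = "",
    sample_a: str = "",
    sample_b: str = "",
) -> Optional[PairwiseRegionScore]:
    """Evaluate score = 1 + log10((Ov/len)/B) for one block set.

    ``Ov`` is the accumulated block length measured on the shorter sequence
    and ``len`` the shorter sequence's length. Returns ``None`` when there
    are no blocks (the comparison is unscorable).
    """
    B = len(blocks)
    if B == 0:
        return None
    length = min(len_a, len_b)
    if len_a <= len_b:
        ov = sum(b.a_end - b.a_start for b in blocks)
    else:
        ov = sum(b.b_end - b.b_start for b in blocks)
    ov = min(ov, length)
    score = 1.0 + math.log10((ov / length) / B)
    return PairwiseRegionScore(region_id, sample_a, sample_b, B, ov,
                               length, score)


def score_pair(
    seq_a: str,
    seq_b: str,
    region_id: str = "",
    sample_a: str = "",
    sample_b: str = "",
    k: int = DEFAULT_K,
    max_occ: int = DEFAULT_MAX_OCC,
    max_gap: int = DEFAULT_MAX_GAP,
    max_sep: int = DEFAULT_MAX_SEP,
    profile_a: KmerProfile | None = None,
    profile_b: KmerProfile | None = None,
) -> Optional[PairwiseRegionScore]:
    """Anchor, chain and score one sequence pair (None if unscorable)."""
    anchors = find_anchors(seq_a, seq_b, k=k, max_occ=max_occ,
                           profile_a=profile_a, profile_b=profile_b)
    blocks = chain_blocks(anchors, max_gap=max_gap, max_sep=max_sep)
    return synteny_score(blocks, len(seq_a), len(seq_b), region_id,
                         sample_a, sample_b)


def score_bin(
    bin_seqs,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    k: int = DEFAULT_K,
    max_occ: int = DEFAULT_MAX_OCC,
    max_gap: int = DEFAULT_MAX_GAP,
    max_sep: int = DEFAULT_MAX_SEP,
) -> list[PairwiseRegionScore]:
    """All-versus-all scoring of one region-specific bin.

    ``bin_seqs`` is a sequence of objects with ``sample_id``, ``region_id``
    and ``sequence`` attributes (one per sample). Pairs whose accumulated
    block length falls below ``min_overlap`` bp, or that yield no blocks at
    all, are dropped (logged). With a non-default flank size, pass
    ``min_overlap = 0.96 * (region_length + 2*flank)``.
    """
    results: list[PairwiseRegionScore] = []
    members = sorted(bin_seqs, key=lambda m: m.sample_id)
    for ma, mb in combinations(members, 2):
        res = score_pair(
            ma.sequence, mb.sequence, region_id=ma.region_id,
            sample_a=ma.sample_id, sample_b=mb.sample_id,
            k=k, max_occ=max_occ, max_gap=max_gap, max_sep=max_sep,
        )
        if res is None:
            log.info("unscorable pair (%s, %s) in region %s: no blocks",
                     ma.sample_id, mb.sample_id, ma.region_id)
            continue
        if res.overlap < min_overlap:
            log.info("dropping pair (%s, %s) in region %s: Ov %d < %d",
                     ma.sample_id, mb.sample_id, ma.region_id, res.overlap,
                     min_overlap)
            continue
        results.append(res)
    return results


def scores_table(scores: Iterable[PairwiseRegionScore]):
    """Per-region scores as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "region_id": s.region_id,
                "sample_a": s.sample_a,
                "sample_b": s.sample_b,
                "B": s.blocks,
                "Ov": s.overlap,
                "len": s.length,
                "score": s.score,
            }
            for s in scores
        ]
    )
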