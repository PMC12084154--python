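"""Homology search of central regions against sample assemblies.

Each 1-kbp central region is searched against every sample assembly at
BLAST-like stringency (identity >= 97%, query coverage >= 70%). The engine
is an exact k-mer seed index (word size 11) over all contigs of all samples:
seeds are clustered per diagonal band (half-width 64) on both strands, the
cluster's span is extended ungapped at both ends, and the spanned segments
are re-scored by an optimal edit-distance alignment (edlib) to obtain the
reported identity. Hits that pass are retrieved together with 2-kbp flanks
on each side — hits lacking a full flank on either side are excluded — and
grouped into region-specific bins holding at most one sequence per sample
(the highest-scoring hit).

A BLAST tabular file (outfmt 6) produced externally can be ingested instead
of running the internal engine.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import edlib
import numpy as np

from ._kmers import encode, kmer_codes, revcomp
from .fragmenter import CentralRegion

log = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 11
DEFAULT_MIN_IDENTITY = 0.97
DEFAULT_MIN_QCOV = 0.70
DEFAULT_FLANK = 2000
DEFAULT_BAND = 64


@dataclass(frozen=True)
class RegionHit:
    region_id: str
    sample_id: str
    contig_id: str
    target_start: int  # 0-based half-open, forward strand of the target
    target_end: int
    strand: str  # '+' or '-'
    identity: float
    query_coverage: float
    score: float


@dataclass(frozen=True)
class FlankedSequence:
    """A retrieved hit plus its flanks, oriented like the reference."""

    region_id: str
    sample_id: str
    contig_id: str
    span_start: int
    span_end: int
    sequence: str
    score: float = 0.0


class SearchIndex:
    """k-mer position index over the contigs of all sample assemblies."""

    def __init__(self, k: int = DEFAULT_WORD_SIZE):
        self.k = k
        self.samples: dict[str, dict[str, str]] = {}
        self._contig_key: list[tuple[str, str]] = []
        self._codes: np.ndarray | None = None
        self._pos: np.ndarray | None = None
        self._contig_idx: np.ndarray | None = None

    def add_sample(self, sample_id: str, contigs: Mapping[str, str]) -> None:
        if sample_id in self.samples:
            raise ValueError(f"duplicate sample_id {sample_id!r}")
        if not contigs or all(len(s) == 0 for s in contigs.values()):
            log.warning("sample %s has an empty assembly; skipped", sample_id)
            return
        self.samples[sample_id] = {c: s.upper() for c, s in contigs.items()}
        self._codes = None  # invalidate

    def _build(self) -> None:
        codes_parts, pos_parts, idx_parts = [], [], []
        self._contig_key = []
        for sample_id in sorted(self.samples):
            for contig_id in sorted(self.samples[sample_id]):
                seq = self.samples[sample_id][contig_id]
                pos, codes = kmer_codes(encode(seq), self.k)
                ci = len(self._contig_key)
                self._contig_key.append((sample_id, contig_id))
                codes_parts.append(codes)
                pos_parts.append(pos)
                idx_parts.append(np.full(pos.size, ci, np.int64))
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = (np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64))[order]
        self._contig_idx = (np.concatenate(idx_parts) if idx_parts else np.empty(0, np.int64))[order]

    def lookup_many(self, query_codes: np.ndarray, query_pos: np.ndarray):
        """All (q_pos, contig_index, t_pos) seed matches for a query."""
        if self._codes is None:
            self._build()
        lo = np.searchsorted(self._codes, query_codes, side="left")
        hi = np.searchsorted(self._codes, query_codes, side="right")
        counts = hi - lo
        n = int(counts.sum())
        if n == 0:
            return (np.empty(0, np.int64),) * 3
        q = np.repeat(query_pos, counts)
        flat = np.repeat(lo, counts) + (
            np.arange(n) - np.repeat(np.cumsum(counts) - counts, counts)
        )
        return q, self._contig_idx[flat], self._pos[flat]

    def contig(self, sample_id: str, contig_id: str) -> str:
        return self.samples[sample_id][contig_id]

    def contig_key(self, index: int) -> tuple[str, str]:
        return self._contig_key[index]


def index_assemblies(
    assemblies: Mapping[str, Mapping[str, str]], k: int = DEFAULT_WORD_SIZE
) -> SearchIndex:
    """Build a SearchIndex from {sample_id: {contig_id: sequence}}."""
    if not assemblies:
        raise ValueError("no sample assemblies provided")
    index = SearchIndex(k=k)
    for sample_id, contigs in assemblies.items():
        index.add_sample(sample_id, contigs)
    return index


def _alignment_stats(query: str, target: str) -> tuple[float, int, int]:
    """(identity, matches, columns) of the optimal global alignment."""
    res = edlib.align(query, target, mode="NW", task="path")
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    matches = columns - res["editDistance"]
    return matches / columns, matches, columns


def search_region(
    region: CentralRegion,
    index: SearchIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_qcov: float = DEFAULT_MIN_QCOV,
    band: int = DEFAULT_BAND,
) -> list[RegionHit]:
    """Find all loci homologous to a central region in every sample.

    Both strands are searched; each reported hit satisfies the identity and
    query-coverage gates, and overlapping hits at one target locus are
    merged into the best one.
    """
    k = index.k
    qlen = len(region.sequence)
    if qlen < k:
        raise ValueError(f"region {region.region_id} shorter than word size")
    hits: list[RegionHit] = []
    for strand in "+-":
        query = region.sequence if strand == "+" else revcomp(region.sequence)
        qpos, qcodes = kmer_codes(encode(query), k)
        if qpos.size == 0:
            continue
        q_hits, c_idx, t_hits = index.lookup_many(qcodes, qpos)
        if q_hits.size == 0:
            continue
        # cluster seeds per contig and diagonal band
        order = np.lexsort((t_hits - q_hits, c_idx))
        q_s, c_s, t_s = q_hits[order], c_idx[order], t_hits[order]
        diag = t_s - q_s
        brk = np.ones(q_s.size, bool)
        brk[1:] = (np.diff(c_s) != 0) | (np.diff(diag) > band)
        starts = np.nonzero(brk)[0]
        ends = np.append(starts[1:], q_s.size)
        for s, e in zip(starts, ends):
            qs, qe = int(q_s[s:e].min()), int(q_s[s:e].max()) + k
            if (qe - qs) / qlen < min_qcov:
                continue  # cheap prefilter; extension below only adds
            sample_id, contig_id = index.contig_key(int(c_s[s]))
            contig = index.contig(sample_id, contig_id)
            ts, te = int(t_s[s:e].min()), int(t_s[s:e].max()) + k
            # ungapped extension of the chained span at both ends
            while qs > 0 and ts > 0 and query[qs - 1] == contig[ts - 1] \
                    and query[qs - 1] in "ACGT":
                qs -= 1
                ts -= 1
            while qe < qlen and te < len(contig) \
                    and query[qe] == contig[te] and query[qe] in "ACGT":
                qe += 1
                te += 1
            qcov = (qe - qs) / qlen
            if qcov < min_qcov:
                continue
            identity, matches, columns = _alignment_stats(query[qs:qe],
                                                          contig[ts:te])
            if identity < min_identity:
                continue
            ed = columns - matches  # edit operations in the span
            hits.append(
                RegionHit(
                    region_id=region.region_id,
                    sample_id=sample_id,
                    contig_id=contig_id,
                    target_start=ts,
                    target_end=te,
                    strand=strand,
                    identity=identity,
                    query_coverage=qcov,
                    score=float(matches - 2 * ed),
                )
            )
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[RegionHit]) -> list[RegionHit]:
    """Keep the best hit among those overlapping on one target locus."""
    by_locus: dict[tuple[str, str], list[RegionHit]] = defaultdict(list)
    for h in hits:
        by_locus[(h.sample_id, h.contig_id)].append(h)
    merged: list[RegionHit] = []
    for group in by_locus.values():
        group.sort(key=lambda h: h.target_start)
        kept: list[RegionHit] = []
        for h in group:
            if kept and h.target_start < kept[-1].target_end:
                if h.score > kept[-1].score:
                    kept[-1] = h
            else:
                kept.append(h)
        merged.extend(kept)
    merged.sort(key=lambda h: (h.sample_id, h.contig_id, h.target_start))
    return merged


def retrieve_flanked(
    hit: RegionHit, index: SearchIndex, flank: int = DEFAULT_FLANK
) -> Optional[FlankedSequence]:
    """Extend a hit by ``flank`` bp on each side; None when excluded.

    Hits with less than ``flank`` bp available on either side of the hit on
    its contig are excluded (logged). Minus-strand hits are reverse-
    complemented so every sequence in a bin shares the reference
    orientation.
    """
    contig = index.contig(hit.sample_id, hit.contig_id)
    if hit.target_start < 0 or hit.target_end > len(contig):
        raise RuntimeError("hit coordinates outside contig (invariant breach)")
    if hit.target_start < flank or len(contig) - hit.target_end < flank:
        log.info(
            "excluding hit %s@%s:%d-%d: less than %d bp of flank available",
            hit.region_id, hit.contig_id, hit.target_start, hit.target_end,
            flank,
        )
        return None
    span_start = hit.target_start - flank
    span_end = hit.target_end + flank
    seq = contig[span_start:span_end]
    if hit.strand == "-":
        seq = revcomp(seq)
    return FlankedSequence(
        region_id=hit.region_id,
        sample_id=hit.sample_id,
        contig_id=hit.contig_id,
        span_start=span_start,
        span_end=span_end,
        sequence=seq,
        score=hit.score,
    )


def bin_hits(
    flanked: Iterable[FlankedSequence],
) -> dict[str, list[FlankedSequence]]:
    """Group retrieved sequences into region-specific bins.

    Within a bin at most one sequence per sample is kept: the highest-
    scoring one, ties broken by leftmost span then contig id (logged when a
    sample had several passing hits for the region).
    """
    bins: dict[str, dict[str, FlankedSequence]] = defaultdict(dict)
    for fs in flanked:
        cur = bins[fs.region_id].get(fs.sample_id)
        if cur is None:
            bins[fs.region_id][fs.sample_id] = fs
            continue
        log.info("sample %s has multiple hits for region %s; keeping best",
                 fs.sample_id, fs.region_id)
        best = min(
            (cur, fs),
            key=lambda f: (-f.score, f.span_start, f.contig_id),
        )
        bins[fs.region_id][fs.sample_id] = best
    return {
        region_id: [by_sample[s] for s in sorted(by_sample)]
        for region_id, by_sample in sorted(bins.items())
    }


def read_blast_tab(
    path: str | Path,
    region_lengths: Mapping[str, int] | None = None,
    default_region_length: int = 1000,
) -> list[RegionHit]:
    """Ingest precomputed hits in BLAST tabular format (outfmt 6).

    Expected columns: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore, with qseqid the region id and sseqid
    ``sample|contig``. Subject coordinates with sstart > send denote a
    minus-strand hit. Identity/coverage gating is left to the caller.
    """
    hits: list[RegionHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed BLAST tabular line: {line!r}")
            qseqid, sseqid = f[0], f[1]
            if "|" not in sseqid:
                raise ValueError(
                    f"sseqid {sseqid!r} is not in 'sample|contig' form")
            sample_id, contig_id = sseqid.split("|", 1)
            sstart, send = int(f[8]), int(f[9])
            strand = "+" if send >= sstart else "-"
            t0, t1 = (sstart - 1, send) if strand == "+" else (send - 1, sstart)
            qlen = (region_lengths or {}).get(qseqid, default_region_length)
            hits.append(
                RegionHit(
                    region_id=qseqid,
                    sample_id=sample_id,
                    contig_id=contig_id,
                    target_start=t0,
                    target_end=t1,
                    strand=strand,
                    identity=float(f[2]) / 100.0,
                    query_coverage=(int(f[7]) - int(f[6]) + 1) / qlen,
                    score=float(f[11]),
                )
            )
    return hits


def hits_table(hits: Iterable[RegionHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "region_id": h.region_id,
                "sample_id": h.sample_id,
                "contig_id": h.contig_id,
                "target_start": h.target_start,
                "target_end": h.target_end,
                "strand": h.strand,
                "identity": h.identity,
                "query_coverage": h.query_coverage,
                "score": h.score,
            }
            for h in hits
        ]
    )
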