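"""In-silico evolution of bacterial sequence populations and fixtures.

A population of independent lineages (star genealogy) descends from one
random ancestral region. Each generation, every site of a lineage
substitutes to a uniformly chosen different base with probability
``mu_snp``, and indel events strike with per-site probability ``mu_indel``
(insertion or deletion equiprobable, inserted bases uniform, lengths from a
configurable distribution, default uniform 1-50 bp). The default
configuration matches the validation conditions: a 20-kbp region, 20
lineages, 3,000 generations, substitutions at 1e-6 per nucleotide per
generation or indels at 1e-7 events per nucleotide per generation, with
population snapshots every 150 generations.

Two regimes are of interest: substitution-only evolution barely moves the
synteny score (isolated SNPs do not split blocks), while indel-only
evolution collapses it (any indel beyond the 15-bp chaining gap splits a
block) despite a tenfold lower event rate.

The module also provides one-shot mutation helpers and generators for toy
metagenomic assemblies and labeled within/between-host populations used to
exercise the pipeline and the threshold calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from . import synteny

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    region_length: int = 20_000
    generations: int = 3_000
    mu_snp: float = 1e-6
    mu_indel: float = 1e-7
    indel_len: tuple[int, int] = (1, 50)  # uniform, inclusive
    n_lineages: int = 20
    sample_every: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if self.mu_snp < 0 or self.mu_indel < 0:
            raise ValueError("mutation rates must be non-negative")


def snp_only(seed: int = 0, **kwargs) -> SimConfig:
    """Substitution-only regime (1e-6 subs/nt/generation)."""
    return SimConfig(mu_indel=0.0, seed=seed, **kwargs)


def indel_only(seed: int = 0, **kwargs) -> SimConfig:
    """Indel-only regime (1e-7 events/nt/generation)."""
    return SimConfig(mu_snp=0.0, seed=seed, **kwargs)


@dataclass(frozen=True)
class PopulationSample:
    generation: int
    sequences: tuple[str, ...]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate_generation(seq: np.ndarray, rng: np.random.Generator,
                       mu_snp: float, mu_indel: float,
                       indel_len: tuple[int, int]) -> np.ndarray:
    """One generation of mutation on a 0..3-coded sequence array."""
    L = seq.size
    if mu_snp > 0 and L > 0:
        n_sub = rng.binomial(L, mu_snp)
        if n_sub:
            sites = rng.choice(L, size=n_sub, replace=False)
            seq = seq.copy()
            seq[sites] = (seq[sites] + rng.integers(1, 4, size=n_sub)) % 4
    if mu_indel > 0 and L > 0:
        n_ind = rng.binomial(L, mu_indel)
        for _ in range(n_ind):
            pos = int(rng.integers(0, seq.size + 1))
            length = int(rng.integers(indel_len[0], indel_len[1] + 1))
            if rng.random() < 0.5:  # deletion
                seq = np.delete(seq, np.s_[pos : pos + length])
            else:  # insertion of uniform random bases
                ins = rng.integers(0, 4, size=length, dtype=seq.dtype)
                seq = np.insert(seq, pos, ins)
    return seq


def evolve(config: SimConfig) -> list[PopulationSample]:
    """Evolve independent lineages from a shared ancestor; snapshot regularly.

    Snapshots are taken at generation 0 and every ``sample_every``
    generations thereafter (plus the final generation if it is not on the
    grid). Fully reproducible under ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    ancestor = master.integers(0, 4, size=config.region_length,
                               dtype=np.uint8)
    lineage_rngs = [
        np.random.default_rng(s)
        for s in master.integers(0, 2**31 - 1, size=config.n_lineages)
    ]
    lineages = [ancestor.copy() for _ in range(config.n_lineages)]
    snapshots = [PopulationSample(0, tuple(_decode(s) for s in lineages))]
    for gen in range(1, config.generations + 1):
        for i, rng in enumerate(lineage_rngs):
            lineages[i] = _mutate_generation(
                lineages[i], rng, config.mu_snp, config.mu_indel,
                config.indel_len,
            )
        if gen % config.sample_every == 0 or gen == config.generations:
            snapshots.append(
                PopulationSample(gen, tuple(_decode(s) for s in lineages))
            )
    return snapshots


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    return 100.0 * (columns - res["editDistance"]) / columns


def simulation_summary(
    samples: Sequence[PopulationSample],
    mode: str = "snp",
    max_gap: int = synteny.DEFAULT_MAX_GAP,
    max_sep: int = synteny.DEFAULT_MAX_SEP,
) -> pd.DataFrame:
    """Per-timepoint aggregates of pairwise identity and synteny score.

    Every unordered lineage pair (190 pairs for 20 lineages) is scored on
    the full region — the single-region setup of the validation
    simulations. Columns: generation, mean/min identity, mean/min synteny
    score, mean block count, n_pairs.
    """
    from ._kmers import KmerProfile

    rows = []
    for snap in samples:
        seqs = snap.sequences
        profiles = [KmerProfile(s, synteny.DEFAULT_K, synteny.DEFAULT_MAX_OCC)
                    for s in seqs]
        idents, scores, blocks = [], [], []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                idents.append(pairwise_identity(seqs[i], seqs[j]))
                res = synteny.score_pair(seqs[i], seqs[j],
                                         max_gap=max_gap, max_sep=max_sep,
                                         profile_a=profiles[i],
                                         profile_b=profiles[j])
                if res is not None:
                    scores.append(res.score)
                    blocks.append(res.blocks)
        rows.append(
            {
                "mode": mode,
                "generation": snap.generation,
                "n_pairs": len(idents),
                "mean_identity": float(np.mean(idents)),
                "min_identity": float(np.min(idents)),
                "mean_score": float(np.mean(scores)) if scores else np.nan,
                "min_score": float(np.min(scores)) if scores else np.nan,
                "mean_blocks": float(np.mean(blocks)) if blocks else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summary_minima(summary: pd.DataFrame) -> dict[str, float]:
    """Across-timepoint minima of the per-timepoint means."""
    return {
        "min_mean_identity": float(summary["mean_identity"].min()),
        "min_mean_score": float(summary["mean_score"].min()),
    }


# ---------------------------------------------------------------------------
# One-shot mutation and fixture generators


def mutate_sequence(
    seq: str,
    rng: np.random.Generator,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    indel_len: tuple[int, int] = (1, 50),
) -> str:
    """Apply accumulated substitutions/indels to a sequence in one shot.

    ``sub_rate`` and ``indel_rate`` are expected events per site (i.e.,
    rate x generations). Equivalent to the generational process when
    multiple hits are rare.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[arr]
    codes = _mutate_generation(codes, rng, min(sub_rate, 1.0), 0.0, indel_len)
    if indel_rate > 0:
        n_ind = rng.poisson(indel_rate * len(seq))
        for _ in range(n_ind):
            pos = int(rng.integers(0, codes.size + 1))
            length = int(rng.integers(indel_len[0], indel_len[1] + 1))
            if rng.random() < 0.5:
                codes = np.delete(codes, np.s_[pos : pos + length])
            else:
                ins = rng.integers(0, 4, size=length, dtype=codes.dtype)
                codes = np.insert(codes, pos, ins)
    return _decode(codes)


def make_toy_dataset(
    seed: int = 0,
    n_samples: int = 3,
    n_regions: int = 4,
    region_length: int = 1000,
    spacing: int = 4000,
    flank: int = 2000,
    sub_rate: float = 0.002,
    n_decoys: int = 2,
    decoy_length: int = 6000,
):
    """Toy reference + per-sample assemblies with planted strain variants.

    The reference is one contig long enough for ``n_regions`` central
    regions; each sample assembly carries a lightly mutated copy of the
    reference (a distinct strain) plus random decoy contigs with no
    homology to it. Returns (reference, assemblies, metadata) where
    reference and each assembly are {contig_id: sequence} and metadata maps
    sample -> {"host": ..., "timepoint": ...}.
    """
    rng = np.random.default_rng(seed)
    period = region_length + spacing
    ref_len = (n_regions - 1) * period + region_length + 2 * flank + period
    ref_seq = random_sequence(ref_len, rng)
    reference = {"ref_contig": ref_seq}
    assemblies = {}
    metadata = {}
    for i in range(n_samples):
        sample_id = f"sample{i:02d}"
        strain = mutate_sequence(ref_seq, rng, sub_rate=sub_rate)
        contigs = {"strain_contig": strain}
        for d in range(n_decoys):
            contigs[f"decoy{d}"] = random_sequence(decoy_length, rng)
        assemblies[sample_id] = contigs
        metadata[sample_id] = {"host": f"host{i:02d}", "timepoint": "t0"}
    return reference, assemblies, metadata


def make_labeled_population(
    seed: int = 0,
    species_id: str = "speciesA",
    n_donors: int = 8,
    n_regions: int = 220,
    region_length: int = 5000,
    between_sub_rate: float = 0.004,
    between_indel_rate: float = 3e-4,
    within_sub_rate: float = 3e-4,
    within_indel_rate: float = 2e-5,
    indel_len: tuple[int, int] = (1, 30),
):
    """Within/between-host populations for calibration experiments.

    Each donor carries a strain derived from the species reference at
    between-host divergence; two longitudinal samples per donor (t0, t1)
    add small within-host divergence on top. Region scores are computed
    with the synteny engine for every sample pair over every region.
    Returns (region_scores, metadata) with metadata mapping sample ->
    (donor, timepoint), ready for APSS subsampling and ROC calibration.
    """
    rng = np.random.default_rng(seed)
    refs = [random_sequence(region_length, rng) for _ in range(n_regions)]
    sample_regions: dict[str, list[str]] = {}
    metadata: dict[str, tuple[str, str]] = {}
    for d in range(n_donors):
        donor = f"donor{d:02d}"
        ancestors = [
            mutate_sequence(r, rng, between_sub_rate, between_indel_rate,
                            indel_len)
            for r in refs
        ]
        for t in ("t0", "t1"):
            sample_id = f"{donor}_{t}"
            sample_regions[sample_id] = [
                mutate_sequence(a, rng, within_sub_rate, within_indel_rate,
                                indel_len)
                for a in ancestors
            ]
            metadata[sample_id] = (donor, t)
    from ._kmers import KmerProfile

    samples = sorted(sample_regions)
    profiles = {
        s: [KmerProfile(seq, synteny.DEFAULT_K, synteny.DEFAULT_MAX_OCC)
            for seq in sample_regions[s]]
        for s in samples
    }
    min_overlap = int(0.96 * region_length)
    scores: list[synteny.PairwiseRegionScore] = []
    for i, sa in enumerate(samples):
        for sb in samples[i + 1 :]:
            for ridx in range(n_regions):
                res = synteny.score_pair(
                    sample_regions[sa][ridx], sample_regions[sb][ridx],
                    region_id=f"region{ridx:04d}", sample_a=sa, sample_b=sb,
                    profile_a=profiles[sa][ridx], profile_b=profiles[sb][ridx],
                )
                if res is not None and res.overlap >= min_overlap:
                    scores.append(res)
    return scores, metadata
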