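"""Average pairwise synteny score (APSS): subsampling and classification.

For each pair of samples, ``n`` region-specific synteny scores are drawn
uniformly without replacement and averaged into the APSS; pairs with fewer
than ``n`` scored regions are excluded. The draw for each (species, pair, n)
is seeded independently from the master seed, so adding samples to a dataset
never perturbs the subsample drawn for an existing pair.

The default subsampling sweep is n = 40, 60, 80, 100 and 200 regions. An
APSS above the same-strain threshold (default 0.95, calibrated for human-gut
species) designates the two conspecific populations as the same strain.
"""

from __future__ import annotations

import logging
import zlib
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synteny import PairwiseRegionScore

log = logging.getLogger(__name__)

DEFAULT_N_SWEEP = (40, 60, 80, 100, 200)
DEFAULT_SAME_STRAIN_THRESHOLD = 0.95


@dataclass(frozen=True)
class ApssRecord:
    species_id: str
    sample_a: str
    sample_b: str
    n: int
    available_regions: int
    apss: float
    seed: int


def _pair_seed(master_seed: int, species_id: str, sample_a: str,
               sample_b: str, n: int) -> int:
    """Stable per-(species, pair, n) RNG seed below 2**31."""
    key = f"{species_id}|{sample_a}|{sample_b}|{n}|{master_seed}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def group_scores_by_pair(
    scores: Iterable[PairwiseRegionScore],
) -> dict[tuple[str, str], list[PairwiseRegionScore]]:
    """Group region scores by unordered sample pair (canonical order)."""
    grouped: dict[tuple[str, str], list[PairwiseRegionScore]] = defaultdict(list)
    for s in scores:
        a, b = sorted((s.sample_a, s.sample_b))
        grouped[(a, b)].append(s)
    return dict(grouped)


def subsample_apss(
    scores: Iterable[PairwiseRegionScore] | Mapping[tuple[str, str], Sequence[PairwiseRegionScore]],
    n: int,
    seed: int,
    species_id: str = "species",
) -> list[ApssRecord]:
    """Draw n region scores per pair (without replacement) and average them.

    Pairs with fewer than ``n`` scored regions are excluded (logged).
    """
    if n <= 0:
        raise ValueError("n must be a positive integer")
    grouped = (
        scores if isinstance(scores, Mapping) else group_scores_by_pair(scores)
    )
    records: list[ApssRecord] = []
    for (a, b) in sorted(grouped):
        pair_scores = grouped[(a, b)]
        avail = len(pair_scores)
        if avail < n:
            log.info("excluding pair (%s, %s): %d regions < n=%d",
                     a, b, avail, n)
            continue
        pair_seed = _pair_seed(seed, species_id, a, b, n)
        rng = np.random.default_rng(pair_seed)
        values = np.array([s.score for s in pair_scores])
        chosen = rng.choice(avail, size=n, replace=False)
        records.append(
            ApssRecord(species_id, a, b, n, avail,
                       float(values[chosen].mean()), pair_seed)
        )
    return records


def apss_iterations(
    scores: Iterable[PairwiseRegionScore] | Mapping,
    n: int,
    seed: int,
    iterations: int = 100,
    species_id: str = "species",
) -> pd.DataFrame:
    """Per-iteration APSS for each pair, with mean and sd columns.

    Re-draws the subsample ``iterations`` times (iteration index folded into
    the seed) — the resampling scheme used for threshold calibration.
    """
    grouped = (
        scores if isinstance(scores, Mapping) else group_scores_by_pair(scores)
    )
    rows = []
    for (a, b) in sorted(grouped):
        pair_scores = grouped[(a, b)]
        avail = len(pair_scores)
        if avail < n:
            continue
        values = np.array([s.score for s in pair_scores])
        draws = np.empty(iterations)
        for it in range(iterations):
            rng = np.random.default_rng(
                _pair_seed(seed, species_id, a, b, n) + it
            )
            draws[it] = values[rng.choice(avail, size=n, replace=False)].mean()
        rows.append(
            {
                "species_id": species_id, "sample_a": a, "sample_b": b,
                "n": n, "available_regions": avail,
                "apss_mean": draws.mean(), "apss_sd": draws.std(ddof=1),
                "iterations": iterations,
            }
        )
    return pd.DataFrame(rows)


def apss_matrix(records: Sequence[ApssRecord]) -> pd.DataFrame:
    """Symmetric sample x sample APSS matrix; missing pairs are NaN.

    Records must come from one species and one subsampling depth;
    conflicting duplicate records for a pair raise ``ValueError``.
    """
    if records:
        species = {r.species_id for r in records}
        depths = {r.n for r in records}
        if len(species) > 1 or len(depths) > 1:
            raise ValueError("records span multiple species or depths")
    seen: dict[tuple[str, str], float] = {}
    for r in records:
        key = tuple(sorted((r.sample_a, r.sample_b)))
        if key in seen and seen[key] != r.apss:
            raise ValueError(f"conflicting duplicate records for pair {key}")
        seen[key] = r.apss
    samples = sorted({s for key in seen for s in key})
    mat = pd.DataFrame(np.nan, index=samples, columns=samples)
    for (a, b), v in seen.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def classify_same_strain(
    apss: float, threshold: float = DEFAULT_SAME_STRAIN_THRESHOLD
) -> str:
    """'same' iff APSS strictly exceeds the same-strain threshold."""
    return "same" if apss > threshold else "different"


def records_table(records: Iterable[ApssRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "n": r.n,
                "available_regions": r.available_regions,
                "apss": r.apss,
            }
            for r in records
        ]
    )
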