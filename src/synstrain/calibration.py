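"""Same-strain threshold calibration via ROC curves and Youden's J.

Sample pairs are labeled from metadata alone: pairs from the same donor at
different timepoints form the within-host (same strain, positive) set and
pairs from different donors the between-host (negative) set. For each
species and subsampling depth an ROC is built over all candidate APSS
cutpoints (midpoints between consecutive distinct observed values) and the
cutpoint maximizing Youden's J = sensitivity + specificity - 1 is the
species' optimal APSS; ties resolve toward the higher, more specific
threshold. The per-depth "threshold APSS" is the unweighted mean of the
per-species optima, themselves averaged over repeated subsampling draws.

Train/test splitting is by donor, never by sample, so no donor contributes
pairs to both sides of the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .apss import ApssRecord, subsample_apss

log = logging.getLogger(__name__)

WITHIN_HOST = "within_host"
BETWEEN_HOST = "between_host"


@dataclass(frozen=True)
class LabeledPair:
    sample_a: str
    sample_b: str
    apss: float
    label: str


@dataclass(frozen=True)
class ThresholdRecord:
    species_id: str
    n: int
    optimal_apss: float
    J: float
    sensitivity: float
    specificity: float
    iterations: int = 1


def label_pairs(
    records: Sequence[ApssRecord],
    metadata: Mapping[str, tuple[str, str]],
) -> list[LabeledPair]:
    """Label APSS records as within-host or between-host from metadata.

    ``metadata`` maps sample id -> (donor, timepoint). Self-pairs, and
    same-donor pairs at the same timepoint (technical replicates), are
    excluded. A sample missing from the metadata raises ``KeyError`` naming
    it.
    """
    labeled: list[LabeledPair] = []
    for r in records:
        for s in (r.sample_a, r.sample_b):
            if s not in metadata:
                raise KeyError(f"sample {s!r} missing from metadata")
        if r.sample_a == r.sample_b:
            continue
        donor_a, time_a = metadata[r.sample_a]
        donor_b, time_b = metadata[r.sample_b]
        if donor_a == donor_b:
            if time_a == time_b:
                log.info("excluding same-donor same-timepoint pair (%s, %s)",
                         r.sample_a, r.sample_b)
                continue
            label = WITHIN_HOST
        else:
            label = BETWEEN_HOST
        labeled.append(LabeledPair(r.sample_a, r.sample_b, r.apss, label))
    return labeled


def _confusion(values: np.ndarray, labels: np.ndarray,
               threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of 'same iff apss > threshold'."""
    pos = labels == WITHIN_HOST
    neg = ~pos
    sens = float((values[pos] > threshold).mean())
    spec = float((values[neg] <= threshold).mean())
    return sens, spec


def roc_youden(
    pairs: Sequence[LabeledPair],
    species_id: str = "species",
    n: int = 0,
) -> tuple[pd.DataFrame, ThresholdRecord]:
    """ROC over all candidate cutpoints plus the Youden-optimal threshold.

    Candidates are midpoints between consecutive distinct APSS values, with
    one sentinel below the minimum and one above the maximum. Requires at
    least one pair of each label.
    """
    labels = np.array([p.label for p in pairs])
    values = np.array([p.apss for p in pairs])
    if WITHIN_HOST not in labels or BETWEEN_HOST not in labels:
        raise ValueError("roc_youden needs at least one pair of each label")
    distinct = np.unique(values)
    candidates = np.concatenate(
        [[distinct[0] - 1e-9], (distinct[:-1] + distinct[1:]) / 2,
         [distinct[-1] + 1e-9]]
    )
    rows = []
    best = None
    for t in candidates:
        sens, spec = _confusion(values, labels, t)
        J = sens + spec - 1
        rows.append({"threshold": t, "sensitivity": sens,
                     "specificity": spec, "J": J})
        # ties broken toward the higher (more specific) threshold
        if best is None or J >= best["J"] - 1e-12 and (
            J > best["J"] + 1e-12 or t > best["threshold"]
        ):
            best = rows[-1]
    roc = pd.DataFrame(rows)
    record = ThresholdRecord(
        species_id=species_id, n=n, optimal_apss=float(best["threshold"]),
        J=float(best["J"]), sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
    )
    return roc, record


def calibrate_species(
    region_scores,
    metadata: Mapping[str, tuple[str, str]],
    n: int,
    seed: int,
    iterations: int = 100,
    species_id: str = "species",
) -> ThresholdRecord:
    """Species-level optimal APSS averaged over repeated subsampling draws.

    Each iteration re-draws the n-region subsample (iteration index folded
    into the seed), labels the resulting APSS values and finds the Youden
    optimum; the returned record averages threshold, J, sensitivity and
    specificity over iterations.
    """
    thresholds, js, sens, spec = [], [], [], []
    for it in range(iterations):
        records = subsample_apss(region_scores, n=n, seed=seed + it,
                                 species_id=species_id)
        pairs = label_pairs(records, metadata)
        _, rec = roc_youden(pairs, species_id=species_id, n=n)
        thresholds.append(rec.optimal_apss)
        js.append(rec.J)
        sens.append(rec.sensitivity)
        spec.append(rec.specificity)
    return ThresholdRecord(
        species_id=species_id, n=n,
        optimal_apss=float(np.mean(thresholds)), J=float(np.mean(js)),
        sensitivity=float(np.mean(sens)), specificity=float(np.mean(spec)),
        iterations=iterations,
    )


def aggregate_thresholds(
    records: Sequence[ThresholdRecord], n: int | None = None
) -> float:
    """Per-depth threshold APSS: unweighted mean of per-species optima."""
    if n is not None:
        records = [r for r in records if r.n == n]
    if not records:
        raise ValueError("no threshold records to aggregate")
    return float(np.mean([r.optimal_apss for r in records]))


def evaluate_threshold(
    pairs: Sequence[LabeledPair], threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of a fixed threshold on labeled pairs."""
    labels = np.array([p.label for p in pairs])
    values = np.array([p.apss for p in pairs])
    return _confusion(values, labels, threshold)


def split_donors(
    metadata: Mapping[str, tuple[str, str]],
    test_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Split samples into train/test sets by donor (never by sample)."""
    donors = sorted({d for d, _ in metadata.values()})
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(donors))
    n_test = int(round(test_fraction * len(donors)))
    test_donors = {donors[i] for i in perm[:n_test]}
    train = {s for s, (d, _) in metadata.items() if d not in test_donors}
    test = {s for s, (d, _) in metadata.items() if d in test_donors}
    return train, test


def thresholds_table(records: Sequence[ThresholdRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id, "n": r.n,
                "optimal_apss": r.optimal_apss, "J": r.J,
                "sensitivity": r.sensitivity, "specificity": r.specificity,
                "iterations": r.iterations,
            }
            for r in records
        ]
    )
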