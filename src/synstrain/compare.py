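"""Dual-metric (synteny vs SNP) comparisons and group-contrast statistics.

Two downstream analyses combine APSS with an externally supplied SNP-based
strain similarity (popANI, consumed as a table and never computed here):

* ``modes_enrichment`` — rank all strain comparisons by each metric, take
  the most-similar 5% under each, and test every species for enrichment in
  each top set with an upper-tail hypergeometric test. The log10 ratio of
  the two enrichment p-values separates species whose diversity is
  dominated by point mutations (hypermutators, enriched in the popANI top
  set) from species dominated by structural change (hyper-recombinators,
  enriched in the APSS top set).

* ``group_contrast`` — per species, compare APSS between sample pairs from
  the same geographic region and pairs from different regions with a
  one-sided Wilcoxon-Mann-Whitney test (Benjamini-Hochberg corrected) and
  report Cohen's d with the conventional magnitude bins.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

SAME_REGION = "same_region"
DIFFERENT_REGION = "different_region"

DEFAULT_TOP_FRACTION = 0.05


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) drawing n from N with K marked: C(K,k) C(N-K,n-k) / C(N,n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(N, K, n, k) < 0:
        raise ValueError(
            f"invalid hypergeometric arguments N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.pmf(k, N, K, n))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Enrichment probability P(X >= k)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(
            f"invalid hypergeometric arguments N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def modes_enrichment(
    pairs: pd.DataFrame,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> pd.DataFrame:
    """Per-species enrichment in the top-similarity sets of both metrics.

    ``pairs`` needs columns species_id, sample_a, sample_b, apss, popani
    (one row per strain comparison detected by both tools). The top set
    size is floor(top_fraction * N), at least 1; ties at the boundary are
    broken by stable input order. Returns one row per species with K,
    k_apss, k_popani, p_apss, p_popani, log10_ratio = log10(p_popani /
    p_apss) (positive -> structural-change-enriched / hyper-recombinator,
    negative -> SNP-enriched / hypermutator) and enrichment = min(p).
    """
    required = {"species_id", "apss", "popani"}
    if missing := required - set(pairs.columns):
        raise ValueError(f"pairs table missing columns {sorted(missing)}")
    N = len(pairs)
    if N < 20:
        raise ValueError("need at least 20 dual-metric pairs")
    n_top = max(1, int(math.floor(top_fraction * N)))
    top_apss = pairs.sort_values("apss", ascending=False,
                                 kind="stable").head(n_top)
    top_popani = pairs.sort_values("popani", ascending=False,
                                   kind="stable").head(n_top)
    totals = pairs["species_id"].value_counts()
    k_apss = top_apss["species_id"].value_counts()
    k_popani = top_popani["species_id"].value_counts()
    rows = []
    for species, K in totals.items():
        ka = int(k_apss.get(species, 0))
        kp = int(k_popani.get(species, 0))
        p_a = hypergeom_upper_tail(N, int(K), n_top, ka)
        p_p = hypergeom_upper_tail(N, int(K), n_top, kp)
        rows.append(
            {
                "species_id": species, "N": N, "n_top": n_top, "K": int(K),
                "k_apss": ka, "k_popani": kp,
                "p_apss": p_a, "p_popani": p_p,
                "log10_ratio": math.log10(p_p / p_a),
                "enrichment": min(p_a, p_p),
            }
        )
    return pd.DataFrame(rows).sort_values("species_id").reset_index(drop=True)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    nx, ny = len(x), len(y)
    pooled = math.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
        / (nx + ny - 2)
    )
    if pooled == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / pooled)


def d_magnitude(d: float) -> str:
    ad = abs(d)
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


def group_contrast(
    records: pd.DataFrame,
    alpha: float = 0.05,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Same-region vs different-region APSS contrast, per species.

    ``records`` needs columns species_id, apss, group (same_region /
    different_region). One-sided alternative: same-region APSS greater.
    The exact rank-sum distribution is used when the combined group size is
    at most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction. Species with an empty group are
    skipped (logged). Returns species_id, n_same, n_diff, p, q (BH), d,
    magnitude.
    """
    rows = []
    for species, sub in records.groupby("species_id"):
        x = sub.loc[sub["group"] == SAME_REGION, "apss"].to_numpy()
        y = sub.loc[sub["group"] == DIFFERENT_REGION, "apss"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            log.info("skipping species %s: one group empty", species)
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = ("exact"
                  if len(x) + len(y) <= exact_max_n and not has_ties
                  else "asymptotic")
        p = float(stats.mannwhitneyu(x, y, alternative="greater",
                                     method=method).pvalue)
        d = cohens_d(x, y) if len(x) + len(y) > 2 else 0.0
        rows.append(
            {
                "species_id": species, "n_same": len(x), "n_diff": len(y),
                "p": p, "d": d, "magnitude": d_magnitude(d),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["species_id", "n_same", "n_diff", "p", "q", "d",
                     "magnitude"]
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], alpha=alpha, method="fdr_bh")[1]
    return out[["species_id", "n_same", "n_diff", "p", "q", "d",
                "magnitude"]].sort_values("species_id").reset_index(drop=True)


def read_popani_table(path) -> pd.DataFrame:
    """Read a popANI TSV (sample_a, sample_b, species, popani)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_a", "sample_b", "species", "popani"}
    if missing := required - set(df.columns):
        raise ValueError(f"popANI table missing columns {sorted(missing)}")
    return df.rename(columns={"species": "species_id"})
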