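"""Synteny-distance trees, tree comparison and strain-similarity networks.

APSS values convert to synteny distances d = |APSS - 1|, which are placed
in a symmetric matrix and clustered by UPGMA (deterministic tie-breaking by
lexicographic cluster label). Tree similarity is measured with the classic
Robinson-Foulds distance (count of bipartitions present in exactly one
tree), and its significance with a label-shuffle randomization: the leaf
labels of the synteny tree are permuted (default 100,000 iterations) and
the p-value is the add-one-smoothed fraction of permutations whose RF
distance to the second tree is at most the observed one — so the smallest
attainable p at the default is just below 1e-5.

Strain-similarity networks have hosts as nodes and host pairs with
APSS >= 0.75 as edges, weighted by -log10(APSS); hosts left without any
edge (singletons) are removed.
"""

from __future__ import annotations

import io
import logging
import math
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Phylo

from .apss import ApssRecord, apss_matrix

log = logging.getLogger(__name__)

DEFAULT_MIN_APSS = 0.75
DEFAULT_SHUFFLE_ITERATIONS = 100_000


def synteny_distance_matrix(
    records: Sequence[ApssRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Symmetric matrix of synteny distances d = |APSS - 1| (0 diagonal)."""
    mat = records if isinstance(records, pd.DataFrame) else apss_matrix(records)
    dist = (mat - 1).abs()
    np.fill_diagonal(dist.values, 0.0)
    return dist


def upgma_tree(matrix: pd.DataFrame) -> str:
    """UPGMA agglomeration of a complete distance matrix; returns newick.

    Merge heights follow the standard arithmetic-average update; ties are
    broken by the lexicographically smallest pair of cluster labels, where
    a cluster is labeled by its smallest member leaf. An incomplete matrix
    raises ``ValueError`` listing the missing pairs.
    """
    labels = list(matrix.index)
    if len(labels) < 3:
        raise ValueError("UPGMA needs a matrix over at least 3 samples")
    missing = [
        (a, b)
        for a, b in combinations(labels, 2)
        if pd.isna(matrix.loc[a, b]) or pd.isna(matrix.loc[b, a])
    ]
    if missing:
        raise ValueError(f"incomplete distance matrix; missing pairs {missing}")
    # cluster state: label -> (newick subtree, height, size)
    clusters = {lab: (lab, 0.0, 1) for lab in labels}
    dist = {
        frozenset((a, b)): float(matrix.loc[a, b])
        for a, b in combinations(labels, 2)
    }
    while len(clusters) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], tuple(sorted((a, b))))
                for a, b in combinations(sorted(clusters), 2)
            ),
        )
        d_ab, (a, b) = best
        nwk_a, h_a, n_a = clusters.pop(a)
        nwk_b, h_b, n_b = clusters.pop(b)
        height = d_ab / 2
        merged_label = min(a, b)
        nwk = (
            f"({nwk_a}:{max(height - h_a, 0.0):.10g},"
            f"{nwk_b}:{max(height - h_b, 0.0):.10g})"
        )
        for c in clusters:
            d_ac = dist.pop(frozenset((a, c)))
            d_bc = dist.pop(frozenset((b, c)))
            dist[frozenset((merged_label, c))] = (
                n_a * d_ac + n_b * d_bc
            ) / (n_a + n_b)
        dist.pop(frozenset((a, b)), None)
        clusters[merged_label] = (nwk, height, n_a + n_b)
    (nwk, _, _), = clusters.values()
    return nwk + ";"


def _splits(newick: str) -> tuple[frozenset[str], set[frozenset[str]]]:
    """(leaf set, nontrivial splits) of a newick tree, root-independent.

    Each split is canonicalized as the side *not* containing the
    lexicographically smallest leaf, so rooted and unrooted encodings of
    the same topology compare equal.
    """
    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = frozenset(t.name for t in tree.get_terminals())
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return leaves, splits


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Classic Robinson-Foulds: bipartitions present in exactly one tree."""
    leaves_a, splits_a = _splits(newick_a)
    leaves_b, splits_b = _splits(newick_b)
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    return len(splits_a ^ splits_b)


def rf_shuffle_test(
    newick_a: str,
    newick_b: str,
    iterations: int = DEFAULT_SHUFFLE_ITERATIONS,
    seed: int = 0,
) -> tuple[int, float]:
    """Observed RF distance plus a label-shuffle p-value.

    Labels of tree A (the synteny tree) are permuted ``iterations`` times;
    p = (#permutations with RF <= observed + 1) / (iterations + 1).
    """
    leaves_a, splits_a = _splits(newick_a)
    leaves_b, splits_b = _splits(newick_b)
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    labels = sorted(leaves_a)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    ref = 0  # canonical side excludes index 0 after permutation
    idx_a = [np.fromiter((pos[x] for x in s), int) for s in splits_a]
    full = frozenset(range(n))

    def canon(indices: frozenset[int]) -> frozenset[int]:
        return full - indices if ref in indices else indices

    splits_b_idx = {
        canon(frozenset(pos[x] for x in s)) for s in splits_b
    }
    observed = len(
        {canon(frozenset(pos[x] for x in s)) for s in splits_a}
        ^ splits_b_idx
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(iterations):
        perm = rng.permutation(n)
        shuffled = {canon(frozenset(int(perm[i]) for i in s)) for s in idx_a}
        if len(shuffled ^ splits_b_idx) <= observed:
            hits += 1
    p = (hits + 1) / (iterations + 1)
    return observed, p


def export_network(
    records: Sequence[ApssRecord],
    host_metadata: Mapping[str, Mapping[str, str]],
    min_apss: float = DEFAULT_MIN_APSS,
) -> nx.Graph:
    """Build the strain-similarity network over hosts.

    ``host_metadata`` maps sample id -> attributes including 'host' (plus
    optional 'country'/'region'). Sample-pair APSS values aggregate to the
    host pair by maximum. Edges with APSS below ``min_apss`` are dropped,
    edge weight is -log10(APSS) (APSS clamped to <= 1), and hosts without
    any remaining edge are removed.
    """
    graph = nx.Graph()
    edges: dict[tuple[str, str], float] = {}
    for r in records:
        for s in (r.sample_a, r.sample_b):
            if s not in host_metadata or "host" not in host_metadata[s]:
                raise KeyError(f"sample {s!r} missing host metadata")
        host_a = host_metadata[r.sample_a]["host"]
        host_b = host_metadata[r.sample_b]["host"]
        if host_a == host_b:
            continue
        key = tuple(sorted((host_a, host_b)))
        edges[key] = max(edges.get(key, -math.inf), r.apss)
    host_attrs: dict[str, dict] = {}
    for s, attrs in host_metadata.items():
        host_attrs.setdefault(attrs["host"], {
            k: v for k, v in attrs.items() if k != "host"
        })
    for (a, b), apss in sorted(edges.items()):
        if apss < min_apss:
            continue
        weight = -math.log10(min(apss, 1.0))
        for h in (a, b):
            graph.add_node(h, **host_attrs.get(h, {}))
        graph.add_edge(a, b, apss=apss, weight=weight)
    graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def edge_list_table(graph: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"host_a": a, "host_b": b, "apss": d["apss"],
             "weight": d["weight"]}
            for a, b, d in sorted(graph.edges(data=True))
        ]
    )


def write_phylip_matrix(matrix: pd.DataFrame, path) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for name in matrix.index:
            row = " ".join(f"{matrix.loc[name, c]:.6f}" for c in matrix.columns)
            fh.write(f"{name} {row}\n")
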