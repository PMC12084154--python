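import numpy as np
import pytest
from Bio import Align

from conftest import substitute
from synstrain._kmers import revcomp
from synstrain.fragmenter import CentralRegion
from synstrain.search import (
    bin_hits,
    index_assemblies,
    read_blast_tab,
    retrieve_flanked,
    search_region,
)


def region_from(seq: str, species="sp", contig="c", start=0) -> CentralRegion:
    return CentralRegion(species, contig, start, start + len(seq), seq)


@pytest.fixture
def contig(random_seq):
    return random_seq(10_000)


# ---------------------------------------------------------------------------
# index


def test_index_reports_samples_and_lookup(random_seq):
    asm = {"s1": {"c1": random_seq(500)}, "s2": {"c1": random_seq(500)}}
    index = index_assemblies(asm)
    assert set(index.samples) == {"s1", "s2"}


def test_duplicate_sample_rejected(random_seq):
    index = index_assemblies({"s1": {"c": random_seq(100)}})
    with pytest.raises(ValueError, match="duplicate"):
        index.add_sample("s1", {"c": "ACGTACGTACGT"})


def test_empty_assembly_skipped_with_warning(random_seq, caplog):
    index = index_assemblies({"s1": {"c": random_seq(100)}, "s2": {}})
    assert "s2" not in index.samples


def test_kmers_spanning_n_not_indexed(random_seq):
    seq = random_seq(50) + "N" + random_seq(50)
    index = index_assemblies({"s1": {"c": seq}})
    index._build()
    positions = set(index._pos.tolist())
    # no indexed k-mer overlaps the N at offset 50
    assert all(p + 11 <= 50 or p > 50 for p in positions)


# ---------------------------------------------------------------------------
# search


def test_exact_substring_found_with_full_identity(contig):
    index = index_assemblies({"s1": {"c1": contig}})
    hits = search_region(region_from(contig[3000:4000]), index)
    assert len(hits) == 1
    h = hits[0]
    assert (h.target_start, h.target_end) == (3000, 4000)
    assert h.identity == 1.0 and h.query_coverage == 1.0
    assert h.strand == "+"


def test_forty_substitutions_fall_below_identity_gate(contig):
    query = contig[3000:4000]
    for pos in range(12, 1000, 25):  # 40 spread-out substitutions
        query = substitute(query, pos)
    index = index_assemblies({"s1": {"c1": contig}})
    assert search_region(region_from(query), index) == []


def test_truncated_homology_fails_coverage_gate(contig, random_seq):
    # only the first 650 bp of the query exist in the target
    query = contig[3000:3650] + random_seq(350)
    index = index_assemblies({"s1": {"c1": contig}})
    assert search_region(region_from(query), index) == []


def test_minus_strand_hit_detected(contig):
    query = revcomp(contig[3000:4000])
    index = index_assemblies({"s1": {"c1": contig}})
    hits = search_region(region_from(query), index)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert (hits[0].target_start, hits[0].target_end) == (3000, 4000)


def test_reference_self_search_returns_source_locus(contig):
    index = index_assemblies({"ref": {"c1": contig}})
    hits = search_region(region_from(contig[5000:6000]), index)
    assert any(
        h.target_start == 5000 and h.identity == 1.0 for h in hits
    )


def test_results_invariant_to_sample_order(contig, random_seq):
    other = random_seq(8000)
    query = region_from(contig[3000:4000])
    h1 = search_region(query, index_assemblies({"a": {"c": contig},
                                                "b": {"c": other}}))
    h2 = search_region(query, index_assemblies({"b": {"c": other},
                                                "a": {"c": contig}}))
    assert h1 == h2


def test_reported_identity_matches_alignment_oracle(contig):
    # independent oracle: optimal global alignment by Biopython
    query = contig[3000:4000]
    query = substitute(substitute(query, 100), 700)
    query = query[:500] + query[505:]  # small deletion
    index = index_assemblies({"s1": {"c1": contig}})
    hits = search_region(region_from(query), index)
    assert len(hits) == 1
    h = hits[0]
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1,
                                    open_gap_score=-2, extend_gap_score=-1)
    target = contig[h.target_start : h.target_end]
    aln = aligner.align(query, target)[0]
    counts = aln.counts()
    oracle_identity = counts.identities / (
        counts.identities + counts.mismatches + counts.gaps
    )
    assert h.identity == pytest.approx(oracle_identity, abs=0.005)


# ---------------------------------------------------------------------------
# flank retrieval


def test_flank_retrieval_coordinates(contig):
    index = index_assemblies({"s1": {"c1": contig}})
    hits = search_region(region_from(contig[3000:4000]), index)
    fs = retrieve_flanked(hits[0], index)
    assert (fs.span_start, fs.span_end) == (1000, 6000)
    assert len(fs.sequence) == 5000
    assert fs.sequence == contig[1000:6000]


def test_insufficient_flank_excluded(contig):
    index = index_assemblies({"s1": {"c1": contig}})
    hits = search_region(region_from(contig[1500:2500]), index)
    assert len(hits) == 1  # upstream flank would be only 1500 bp
    assert retrieve_flanked(hits[0], index) is None


def test_minus_strand_flank_is_reverse_complemented(contig):
    index = index_assemblies({"s1": {"c1": contig}})
    hits = search_region(region_from(revcomp(contig[3000:4000])), index)
    fs = retrieve_flanked(hits[0], index)
    assert fs.sequence == revcomp(contig[1000:6000])


# ---------------------------------------------------------------------------
# binning


def test_bin_keeps_one_sequence_per_sample(contig, random_seq):
    from synstrain.search import FlankedSequence

    fs = [
        FlankedSequence("r0", "s1", "c", 0, 10, "ACGTACGTAC", score=980),
        FlankedSequence("r0", "s1", "c", 50, 60, "ACGTACGTAC", score=400),
        FlankedSequence("r0", "s2", "c", 0, 10, "ACGTACGTAC", score=500),
        FlankedSequence("r1", "s1", "c", 0, 10, "ACGTACGTAC", score=100),
    ]
    bins = bin_hits(fs)
    assert set(bins) == {"r0", "r1"}
    assert len(bins["r0"]) == 2
    s1_kept = next(f for f in bins["r0"] if f.sample_id == "s1")
    assert s1_kept.score == 980


def test_single_sample_bin_retained(random_seq):
    from synstrain.search import FlankedSequence

    bins = bin_hits([FlankedSequence("r0", "s1", "c", 0, 10, "A" * 10)])
    assert len(bins["r0"]) == 1


# ---------------------------------------------------------------------------
# BLAST tabular ingestion


def test_blast_tab_roundtrip(tmp_path):
    line = ("c:0\tsampleX|contig7\t99.5\t1000\t5\t0\t1\t1000\t2001\t3000"
            "\t0.0\t1800\n")
    path = tmp_path / "hits.tsv"
    path.write_text(line)
    hits = read_blast_tab(path)
    h = hits[0]
    assert h.sample_id == "sampleX" and h.contig_id == "contig7"
    assert (h.target_start, h.target_end, h.strand) == (2000, 3000, "+")
    assert h.identity == pytest.approx(0.995)
    assert h.query_coverage == pytest.approx(1.0)


def test_blast_tab_minus_strand(tmp_path):
    line = ("c:0\ts|c\t98.0\t1000\t20\t0\t1\t1000\t3000\t2001\t0.0\t1700\n")
    path = tmp_path / "hits.tsv"
    path.write_text(line)
    h = read_blast_tab(path)[0]
    assert h.strand == "-"
    assert (h.target_start, h.target_end) == (2000, 3000)
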