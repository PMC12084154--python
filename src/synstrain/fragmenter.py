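"""Fragment reference genomes into equally spaced central regions.

Each reference (one genome per species, complete or in contigs) is sliced
into 1-kbp query windows whose starts are 5 kbp apart (1-kbp region + 4-kbp
spacing), so consecutive central regions leave 4 kbp of unsampled sequence
between them. These windows are the homology-search queries; each will later
collect a bin of ~5-kbp homologous regions (hit plus 2-kbp flanks) from the
sample assemblies.

Conventions: coordinates are 0-based half-open throughout; windows anchor at
contig position 0 and a partial terminal window is dropped, so region
identifiers (``contig:start``) are deterministic for a given reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: characters accepted in reference contigs (IUPAC nucleotide codes)
IUPAC_NT = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class CentralRegion:
    """A query slice of the reference genome, with provenance coordinates."""

    species_id: str
    contig_id: str
    start: int  # 0-based, inclusive
    end: int  # exclusive
    sequence: str

    @property
    def region_id(self) -> str:
        return f"{self.contig_id}:{self.start}"

    @property
    def header(self) -> str:
        return f"{self.species_id}|{self.contig_id}|{self.start}-{self.end}"


def fragment_reference(
    genome: Mapping[str, str],
    species_id: str = "species",
    region_length: int = 1000,
    spacing: int = 4000,
    max_n_fraction: float = 0.10,
) -> list[CentralRegion]:
    """Slice every contig into central regions of ``region_length`` bp.

    Windows start at offsets 0, region_length+spacing, 2*(region_length+
    spacing), ...; only full-length windows are emitted. Windows whose
    fraction of ambiguous (non-ACGT) bases exceeds ``max_n_fraction`` are
    skipped and logged: they cannot seed a meaningful homology search.

    Raises ``ValueError`` for an empty genome, non-positive parameters, or a
    contig containing non-IUPAC characters (named in the message).
    """
    if not genome:
        raise ValueError("empty genome: no contigs to fragment")
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if spacing < 0:
        raise ValueError("spacing must be non-negative")
    period = region_length + spacing
    regions: list[CentralRegion] = []
    for contig_id, seq in genome.items():
        seq = seq.upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"contig {contig_id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        for start in range(0, len(seq) - region_length + 1, period):
            window = seq[start : start + region_length]
            n_frac = sum(1 for b in window if b not in "ACGT") / region_length
            if n_frac > max_n_fraction:
                log.info(
                    "skipping region %s:%d (ambiguous fraction %.2f > %.2f)",
                    contig_id, start, n_frac, max_n_fraction,
                )
                continue
            regions.append(
                CentralRegion(species_id, contig_id, start,
                              start + region_length, window)
            )
    return regions


# ---------------------------------------------------------------------------
# FASTA / manifest I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an ordered {id: sequence} mapping."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_regions_fasta(regions: Iterable[CentralRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.header}\n{r.sequence}\n")


def regions_manifest(regions: Iterable[CentralRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "contig_id": r.contig_id,
                "start": r.start,
                "end": r.end,
                "region_id": r.region_id,
            }
            for r in regions
        ]
    )
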