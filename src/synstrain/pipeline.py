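"""End-to-end orchestration: fragment -> search -> score -> APSS.

``run_full_pipeline`` executes the whole flow for one or more reference
species against a collection of per-sample assemblies, writing per-stage
artifacts (central regions, hits, region scores, APSS tables) and a run
manifest recording parameters and the master seed. Completed stages are
detected by their output files and skipped on resume, so deleting an
intermediate and re-running reproduces the same final tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import apss as apss_mod
from . import search as search_mod
from . import synteny as synteny_mod
from .fragmenter import fragment_reference, read_fasta, regions_manifest, \
    write_regions_fasta

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    references: dict[str, str]  # species_id -> FASTA path
    assemblies: dict[str, str]  # sample_id -> FASTA path
    output_dir: str = "synstrain_out"
    metadata: str | None = None
    region_length: int = 1000
    spacing: int = 4000
    word_size: int = 11
    min_identity: float = 0.97
    min_qcov: float = 0.70
    flank: int = 2000
    max_gap: int = 15
    max_sep: int = 15
    min_overlap: int | None = None  # None -> 0.96*(region_length+2*flank)
    n_sweep: tuple[int, ...] = apss_mod.DEFAULT_N_SWEEP
    same_strain_threshold: float = 0.95
    seed: int = 0
    blast_tab: str | None = None

    def resolved_min_overlap(self) -> int:
        if self.min_overlap is not None:
            return self.min_overlap
        return int(0.96 * (self.region_length + 2 * self.flank))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "n_sweep" in raw:
            raw["n_sweep"] = tuple(raw["n_sweep"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.references:
            raise ValueError("at least one reference is required")
        if len(self.assemblies) < 2:
            raise ValueError("at least two sample assemblies are required")
        for label, paths in (("reference", self.references),
                             ("assembly", self.assemblies)):
            for key, p in paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label} {key!r}: {p} not found")
        if not (0 < self.min_identity <= 1 and 0 < self.min_qcov <= 1):
            raise ValueError("identity/coverage thresholds must be in (0, 1]")


def run_full_pipeline(config: RunConfig, resume: bool = True) -> pd.DataFrame:
    """Run all stages; returns the final APSS table (also written to TSV)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "run_manifest.json"
    manifest = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    assemblies = {s: read_fasta(p) for s, p in config.assemblies.items()}
    index = search_mod.index_assemblies(assemblies, k=config.word_size)

    all_records = []
    for species_id, ref_path in sorted(config.references.items()):
        species_dir = out / species_id
        species_dir.mkdir(exist_ok=True)

        # stage 1: fragmentation
        regions_fa = species_dir / "central_regions.fasta"
        manifest_tsv = species_dir / "central_regions.tsv"
        genome = read_fasta(ref_path)
        regions = fragment_reference(
            genome, species_id=species_id,
            region_length=config.region_length, spacing=config.spacing,
        )
        if not (resume and regions_fa.exists()):
            write_regions_fasta(regions, regions_fa)
            regions_manifest(regions).to_csv(manifest_tsv, sep="\t",
                                             index=False)
        log.info("[%s] %d central regions", species_id, len(regions))
        manifest["stages"][f"{species_id}:fragment"] = len(regions)

        # stage 2: homology search + flank retrieval + binning
        scores_tsv = species_dir / "region_scores.tsv"
        if resume and scores_tsv.exists():
            scores_df = pd.read_csv(scores_tsv, sep="\t")
            scores = [
                synteny_mod.PairwiseRegionScore(
                    r.region_id, r.sample_a, r.sample_b, r.B, r.Ov,
                    r["len"], r.score)
                for _, r in scores_df.iterrows()
            ]
            log.info("[%s] resumed %d region scores", species_id, len(scores))
        else:
            if config.blast_tab:
                lengths = {r.region_id: len(r.sequence) for r in regions}
                hits = [
                    h for h in search_mod.read_blast_tab(
                        config.blast_tab, region_lengths=lengths)
                    if h.identity >= config.min_identity
                    and h.query_coverage >= config.min_qcov
                ]
            else:
                hits = []
                for region in regions:
                    hits.extend(
                        search_mod.search_region(
                            region, index,
                            min_identity=config.min_identity,
                            min_qcov=config.min_qcov,
                        )
                    )
            search_mod.hits_table(hits).to_csv(
                species_dir / "hits.tsv", sep="\t", index=False)
            flanked = []
            for h in hits:
                fs = search_mod.retrieve_flanked(h, index,
                                                 flank=config.flank)
                if fs is not None:
                    flanked.append(fs)
            bins = search_mod.bin_hits(flanked)
            manifest["stages"][f"{species_id}:hits"] = len(hits)
            manifest["stages"][f"{species_id}:flanked"] = len(flanked)

            # stage 3: synteny scoring
            scores = []
            for region_id, members in bins.items():
                scores.extend(
                    synteny_mod.score_bin(
                        members,
                        min_overlap=config.resolved_min_overlap(),
                        max_gap=config.max_gap, max_sep=config.max_sep,
                    )
                )
            synteny_mod.scores_table(scores).to_csv(scores_tsv, sep="\t",
                                                    index=False)
        manifest["stages"][f"{species_id}:region_scores"] = len(scores)

        # stage 4: APSS subsampling over the n sweep
        for n in config.n_sweep:
            records = apss_mod.subsample_apss(
                scores, n=n, seed=config.seed, species_id=species_id)
            all_records.extend(records)
            manifest["stages"][f"{species_id}:apss_n{n}"] = len(records)

    apss_df = apss_mod.records_table(all_records)
    apss_df.to_csv(out / "apss.tsv", sep="\t", index=False)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return apss_df
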