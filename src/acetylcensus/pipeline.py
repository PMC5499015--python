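"""End-to-end census driver: profiles -> scores -> E-values -> hit table -> counts.

Reads a study bundle (per-species proteome FASTA, per-class seed alignments,
species table) from disk, builds one profile per family class, calibrates
each profile's Gumbel E-value law on random background sequences, scores
every protein against every profile, classifies hits into the accept/review/
reject zones, validates review hits by reciprocal best hit against the seed
sequences, and tabulates family sizes per species.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import census as census_mod
from .census import (
    ACCEPT_THRESHOLD,
    REVIEW_THRESHOLD,
    HitRecord,
    PairScorer,
    ScoredCandidate,
    classify,
    confirm_review_hits,
    tabulate_family_sizes,
)
from .io import SeqRecord, read_fasta, read_species_table
from .profiles import (
    GumbelCalibration,
    ProfileModel,
    SeedAlignment,
    build_profile,
    calibrate_evalue,
    evalue,
    score_proteins,
)


@dataclass
class CensusInputs:
    """Everything the census stage consumes."""

    species: dict[str, str]                      # species_id -> species_type
    proteomes: dict[str, list[SeqRecord]]        # species_id -> proteins
    seeds: dict[str, SeedAlignment]              # class label -> seed alignment
    class_to_family: dict[str, str]              # class label -> top-level family


@dataclass
class CensusResult:
    """Hits, per-species family counts and the models that produced them."""

    hits: list[HitRecord]
    tabulation: pd.DataFrame
    profiles: dict[str, ProfileModel]
    calibrations: dict[str, GumbelCalibration]
    db_size: int

    def hit_frame(self) -> pd.DataFrame:
        return census_mod.hit_table(self.hits)

    def counted_members(
        self, family_map: Mapping[str, str] | None = None, include_review: bool = True
    ) -> dict[str, dict[str, set[str]]]:
        """Counted hits as species_id -> family -> set of protein ids."""
        out: dict[str, dict[str, set[str]]] = {}
        for rec in self.hits:
            if rec.rank != "primary":
                continue
            if not (rec.status == "accepted" or (
                include_review and rec.status == "review" and rec.rbh_confirmed is True
            )):
                continue
            fam = family_map.get(rec.family, rec.family) if family_map else rec.family
            out.setdefault(rec.species_id, {}).setdefault(fam, set()).add(rec.protein_id)
        return out


def class_family(label: str) -> str:
    """Map a class/profile label onto its top-level family (HDA_classI -> HDA)."""
    return label.split("_class")[0]


def load_inputs(bundle_dir: str | Path) -> CensusInputs:
    """Load species table, proteomes and seed alignments from a study bundle."""
    bundle = Path(bundle_dir)
    species = read_species_table(bundle / "species.tsv")
    proteomes = {
        sp: read_fasta(bundle / "proteomes" / f"{sp}.fasta", kind="protein")
        for sp in species
    }
    seeds = {}
    for path in sorted((bundle / "seeds").glob("*.afa")):
        label = path.stem
        rows = read_fasta(path, kind="protein", allow_gaps=True)
        seeds[label] = SeedAlignment(family=label, rows=tuple(rows))
    return CensusInputs(
        species=species,
        proteomes=proteomes,
        seeds=seeds,
        class_to_family={label: class_family(label) for label in seeds},
    )


def ungapped_references(seeds: Mapping[str, SeedAlignment]) -> dict[str, list[SeqRecord]]:
    """Seed alignment rows with gaps stripped, as RBH reference sets per class."""
    return {
        label: [
            SeqRecord(r.id, r.description, r.sequence.replace("-", "").replace(".", ""))
            for r in aln.rows
        ]
        for label, aln in seeds.items()
    }


def run_census(
    inputs: CensusInputs,
    seed: int = 0,
    accept_threshold: float = ACCEPT_THRESHOLD,
    review_threshold: float = REVIEW_THRESHOLD,
    pseudocount: float = 1.0,
    n_random: int = 1000,
    include_review: bool = True,
    do_rbh: bool = True,
) -> CensusResult:
    """Run the full classification stage and tabulate family sizes.

    The E-value calibration length is the median protein length of the pooled
    proteomes; the database size is the total number of proteins scored.
    Review-zone primary hits are confirmed by reciprocal best hit against the
    pooled seed sequences (reverse direction over the species' own candidate
    proteins) before they are counted.
    """
    profiles = {label: build_profile(aln, pseudocount=pseudocount) for label, aln in inputs.seeds.items()}

    all_proteins = [p for recs in inputs.proteomes.values() for p in recs]
    db_size = len(all_proteins)
    median_len = int(statistics.median(len(p) for p in all_proteins))
    calibrations = {
        label: calibrate_evalue(prof, n_random=n_random, length=median_len,
                                seed=(seed * 1009 + i) % (2**31))
        for i, (label, prof) in enumerate(sorted(profiles.items()))
    }

    scored: list[ScoredCandidate] = []
    for sp, records in inputs.proteomes.items():
        per_label = {label: score_proteins(profiles[label], records) for label in sorted(profiles)}
        for i, rec in enumerate(records):
            for label in sorted(profiles):
                s = float(per_label[label][i])
                e = evalue(calibrations[label], s, db_size)
                scored.append(ScoredCandidate(rec.id, sp, label, s, e))

    records = classify(scored, accept_threshold=accept_threshold, review_threshold=review_threshold)

    if do_rbh:
        references = ungapped_references(inputs.seeds)
        proteins = {p.id: p for p in all_proteins}
        query_sets = {}
        for rec in records:
            if rec.rank == "primary" and rec.status in ("accepted", "review"):
                query_sets.setdefault(rec.species_id, []).append(proteins[rec.protein_id])
        records = confirm_review_hits(records, proteins, references, query_sets, scorer=PairScorer())

    tabulation = tabulate_family_sizes(
        records,
        inputs.species,
        include_review=include_review,
        family_map=inputs.class_to_family,
        families=sorted(set(inputs.class_to_family.values())),
    )
    return CensusResult(
        hits=records,
        tabulation=tabulation,
        profiles=profiles,
        calibrations=calibrations,
        db_size=db_size,
    )


def run_promoter_stage(
    bundle_dir: str | Path,
    family_genes: Mapping[str, Mapping[str, set[str]]],
    length: int = 2000,
    alpha: float = 0.05,
    threshold: float = 0.5,
):
    """Promoter pipeline for a study bundle: extract, scan, enrich, conserve.

    ``family_genes`` maps species_id -> family -> gene ids (e.g. from
    :meth:`CensusResult.counted_members`).  The universe for each species is
    every gene with an extractable promoter.  Returns (enrichment results,
    conservation results).
    """
    from .io import read_gene_locations, read_motif_library
    from .promoters import conserve, enrich, extract_promoter, scan_promoters

    bundle = Path(bundle_dir)
    elements = read_motif_library(bundle / "motifs.tsv")
    species = read_species_table(bundle / "species.tsv")
    enrichments = []
    for sp in species:
        genome = {r.id: r.sequence for r in read_fasta(bundle / "genomes" / f"{sp}.fasta", "nucleotide")}
        loci = read_gene_locations(bundle / "loci" / f"{sp}.tsv")
        promoters = [extract_promoter(genome, locus, length=length) for locus in loci]
        promoters = [p for p in promoters if p.sequence]
        universe = {p.gene_id for p in promoters}
        matches = scan_promoters(promoters, elements)
        for family, genes in sorted(family_genes.get(sp, {}).items()):
            members = set(genes) & universe
            if not members:
                continue
            enrichments.extend(
                enrich(sp, family, members, universe, matches, elements, alpha=alpha)
            )
    return enrichments, conserve(enrichments, threshold=threshold)


def run_localization_stage(bundle_dir: str | Path):
    """Consensus localization for every protein of a study bundle."""
    from .io import read_prediction_table
    from .localization import consensus_table

    bundle = Path(bundle_dir)
    species = read_species_table(bundle / "species.tsv")
    table = read_prediction_table(bundle / "predictions.tsv")
    results = []
    for sp in species:
        proteome = read_fasta(bundle / "proteomes" / f"{sp}.fasta", kind="protein")
        results.extend(consensus_table(proteome, table))
    return results
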