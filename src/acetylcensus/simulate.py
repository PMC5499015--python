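"""Synthetic study generator: every pipeline input with planted, known truth.

Emulates, at desk scale, a compendium of 53 sequenced photosynthetic
eukaryotes plus 4 non-photosynthetic reference organisms: per-species
proteomes carrying planted acetylation-enzyme family members derived from
per-class consensus sequences, seed alignments for profile building, genomes
with gene loci and cis-elements planted into promoter regions, domain
annotation tables, and five-predictor localization tables.  Each planted fact
is recorded in truth TSVs so that every pipeline stage can be scored against
ground truth.  Identical configurations (same seed) produce byte-identical
output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    COMPARTMENTS,
    SPECIES_TYPES,
    GeneLocus,
    MotifElement,
    SeqRecord,
    write_fasta,
    write_tsv,
)
from .profiles import AMINO_ACIDS, background_frequencies
from .promoters import MatchRecord, PromoterRegion, enrich, scan_element

PREDICTORS = ("wolf_psort", "targetp", "slp_local", "predsl", "predotar")

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


# configuration ------------------------------------------------------------


@dataclass(frozen=True)
class DomainSpec:
    """One domain planted on a family class: relative span and per-type prevalence."""

    name: str
    rel_start: float
    rel_end: float
    prevalence: Mapping[str, float] | float
    source: str = "pfam_like"

    def prob(self, species_type: str) -> float:
        if isinstance(self.prevalence, (int, float)):
            return float(self.prevalence)
        return float(self.prevalence.get(species_type, 0.0))


@dataclass(frozen=True)
class FamilyClassSpec:
    """A family class/profile: its top-level family, protein length and compartment."""

    name: str
    family: str
    length: int
    compartment: str
    domains: tuple[DomainSpec, ...] = ()


@dataclass(frozen=True)
class MotifSpec:
    """A cis-element and the family whose promoters it is planted into."""

    element: MotifElement
    target_family: str | None
    insert_prob: float
    background_prob: float


@dataclass(frozen=True)
class SimConfig:
    seed: int
    species_counts: Mapping[str, int]
    classes: tuple[FamilyClassSpec, ...]
    family_means: Mapping[str, Mapping[str, float]]   # family -> species_type -> mean count
    motif_specs: tuple[MotifSpec, ...]
    genes_per_species: int = 200
    n_scaffolds: int = 4
    n_background_proteins: int = 25
    seed_rows: int = 8
    seed_divergence: float = 0.06
    member_divergence: float = 0.15
    count_jitter: int = 1
    promoter_length: int = 2000
    gene_length: int = 300
    intergenic_spacer: int = 200
    predictor_accuracy: float = 0.9
    no_start_met_fraction: float = 0.05
    edge_gene_fraction: float = 0.5   # chance a scaffold's first gene has a truncated promoter
    background_protein_length: int = 350


_DEFAULT_SPECIES_COUNTS = {
    "dicot": 17,
    "monocot": 8,
    "green_algae": 15,
    "red_algae_glaucophyte": 5,
    "heterokont_other": 8,
    "non_photosynthetic": 4,
}

# Mean planted family sizes per species type (the study's headline averages):
# columns: dicot, monocot, green_algae, red_algae_glaucophyte, heterokont_other,
# non_photosynthetic.
_DEFAULT_FAMILY_MEANS = {
    "HDA": dict(zip(SPECIES_TYPES, (11, 13, 11, 2, 9, 5))),
    "HDT": dict(zip(SPECIES_TYPES, (2, 3, 0, 0, 0, 0))),
    "SRT": dict(zip(SPECIES_TYPES, (2, 2, 3, 2, 8, 8))),
    "GNAT": dict(zip(SPECIES_TYPES, (3, 3, 3, 1, 3, 3))),
    "MYST": dict(zip(SPECIES_TYPES, (2, 2, 2, 2, 2, 4))),
    "CBP": dict(zip(SPECIES_TYPES, (4, 5, 1, 0, 1, 1))),
    "TAF250": dict(zip(SPECIES_TYPES, (2, 2, 1, 1, 1, 1))),
}

_LAND = ("dicot", "monocot")
_ALGAL = ("green_algae", "heterokont_other")


def _default_classes() -> tuple[FamilyClassSpec, ...]:
    """The default class/profile structure: HDA and SRT split into classes,
    GNAT into its three classes, the remaining families one profile each."""
    rare = DomainSpec("BRCT", 0.02, 0.08, 0.03)  # below the 5% display floor
    return (
        FamilyClassSpec("HDA_classI", "HDA", 400, "nucleus",
                        (DomainSpec("Hist_deacetyl", 0.15, 0.85, 1.0), rare)),
        FamilyClassSpec("HDA_classII", "HDA", 400, "nucleus",
                        (DomainSpec("Hist_deacetyl", 0.2, 0.9, 1.0),
                         DomainSpec("Ankyrin", 0.02, 0.12, {t: 1.0 for t in _ALGAL}))),
        FamilyClassSpec("SRT_classI", "SRT", 350, "nucleus",
                        (DomainSpec("SIR2", 0.2, 0.9, 1.0, "prosite_like"),)),
        FamilyClassSpec("SRT_classII", "SRT", 350, "mitochondrion",
                        (DomainSpec("SIR2", 0.2, 0.9, 1.0, "prosite_like"),)),
        FamilyClassSpec("SRT_classIV", "SRT", 350, "cytosol",
                        (DomainSpec("SIR2", 0.25, 0.95, 1.0, "prosite_like"),)),
        FamilyClassSpec("HDT", "HDT", 300, "nucleus",
                        (DomainSpec("Nucleoplasmin", 0.05, 0.35, {"monocot": 1.0, "non_photosynthetic": 0.6}),
                         DomainSpec("CENP-T", 0.6, 0.8, {"dicot": 1.0}))),
        FamilyClassSpec("GNAT_classI", "GNAT", 380, "chloroplast",
                        (DomainSpec("Acetyltransf_1", 0.3, 0.7, 1.0),)),
        FamilyClassSpec("GNAT_classII", "GNAT", 380, "nucleus",
                        (DomainSpec("Acetyltransf_1", 0.35, 0.75, 1.0),
                         DomainSpec("MOZ_SAS", 0.05, 0.2, {"dicot": 1.0}))),
        FamilyClassSpec("GNAT_classIII", "GNAT", 380, "cytosol",
                        (DomainSpec("Acetyltransf_1", 0.3, 0.7, 1.0),)),
        FamilyClassSpec("MYST", "MYST", 360, "nucleus",
                        (DomainSpec("MOZ_SAS", 0.35, 0.8, 1.0),
                         DomainSpec("PHD", 0.05, 0.15, {"non_photosynthetic": 1.0}))),
        FamilyClassSpec("CBP", "CBP", 500, "nucleus",
                        (DomainSpec("KAT11", 0.45, 0.75, 1.0),
                         DomainSpec("PHD", 0.15, 0.25, {t: 1.0 for t in _LAND + _ALGAL}),
                         DomainSpec("KIX", 0.05, 0.18, {"non_photosynthetic": 1.0}),
                         DomainSpec("Bromodomain", 0.02, 0.1, {"heterokont_other": 1.0}))),
        FamilyClassSpec("TAF250", "TAF250", 450, "nucleus",
                        (DomainSpec("DUF3591", 0.3, 0.6, 1.0),
                         DomainSpec("Bromodomain", 0.75, 0.95, 1.0),
                         DomainSpec("Ubiquitin", 0.08, 0.18, {t: 1.0 for t in _LAND}))),
    )


def _default_motifs() -> tuple[MotifSpec, ...]:
    """Default cis-element library with one planted (family, element) pair per family.

    Elements are rare under the null (10-mers, 1% background insertion, ~0.2%
    incidental match rate in a 2 kb promoter) so that, as in a genome-scale
    universe where element-bearing promoters are a small fraction of all
    genes, even a single-gene family can reach the 0.05 enrichment cutoff.
    """
    def el(name, pattern, category):
        return MotifElement(name, pattern, category)

    bg = 0.01
    return (
        MotifSpec(el("ABRE-like", "TACGTGTCAC", "cold_drought"), "HDA", 0.9, bg),
        MotifSpec(el("DRE-like", "TACCGACATG", "cold_drought"), "CBP", 0.9, bg),
        MotifSpec(el("ABF-binding", "CACGTGGCAT", "cold_drought"), "MYST", 0.9, bg),
        MotifSpec(el("CBF1BS_COR15a", "TGGCCGACCT", "cold_drought"), None, 0.0, bg),
        MotifSpec(el("HBOXCONSENSUSPVCHS", "CCTACCTACC", "light_circadian"), "SRT", 0.9, bg),
        MotifSpec(el("CCA1-binding", "GAAAATCTAG", "light_circadian"), "GNAT", 0.9, bg),
        MotifSpec(el("EMHVCHORD", "TGTAAAGTGG", "other"), "TAF250", 0.9, bg),
        MotifSpec(el("CArG", "CCAAATTTGG", "other"), "HDT", 0.9, bg),
    )


def default_config(seed: int, **overrides) -> SimConfig:
    """The default study configuration (53 photosynthetic + 4 reference species)."""
    kwargs = dict(
        seed=seed,
        species_counts=dict(_DEFAULT_SPECIES_COUNTS),
        classes=_default_classes(),
        family_means={f: dict(m) for f, m in _DEFAULT_FAMILY_MEANS.items()},
        motif_specs=_default_motifs(),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def small_config(seed: int, **overrides) -> SimConfig:
    """A reduced configuration for fast end-to-end runs: fewer, smaller species."""
    kwargs = dict(
        species_counts={
            "dicot": 3, "monocot": 2, "green_algae": 2,
            "red_algae_glaucophyte": 2, "heterokont_other": 2, "non_photosynthetic": 2,
        },
        genes_per_species=60,
        n_background_proteins=8,
        n_scaffolds=2,
    )
    kwargs.update(overrides)
    return default_config(seed, **kwargs)


# sequence helpers ---------------------------------------------------------


def random_protein(rng: np.random.Generator, length: int, start_met: bool = True) -> str:
    bg = background_frequencies()
    idx = rng.choice(20, size=length, p=bg)
    seq = "".join(AMINO_ACIDS[i] for i in idx)
    if start_met:
        return "M" + seq[1:]
    if seq[0] == "M":
        seq = "A" + seq[1:]
    return seq


def random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random uniform nucleotide sequence as an uint8 array over b'ACGT'."""
    return _NT[rng.integers(0, 4, size=length)]


def mutate_family_member(
    consensus: SeqRecord, divergence: float, seed: int | np.random.Generator
) -> SeqRecord:
    """Per-site substitution from the background distribution with the given rate.

    A substituted site is redrawn from the background, so it can coincide with
    the original residue (the effective Hamming rate carries the usual
    resampling correction).
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(consensus.sequence)
    bg = background_frequencies()
    hits = rng.random(len(seq)) < divergence
    draws = rng.choice(20, size=len(seq), p=bg)
    for i in np.nonzero(hits)[0]:
        seq[i] = AMINO_ACIDS[draws[i]]
    return SeqRecord(consensus.id, consensus.description, "".join(seq))


def plant_motif(
    scaffold: np.ndarray,
    locus: GeneLocus,
    element: MotifElement,
    offset: int,
    insert: bool = True,
    promoter_length: int = 2000,
) -> None:
    """Write an element into a gene's promoter at the given oriented offset.

    ``offset`` is 0-based within the promoter as :func:`~acetylcensus.promoters.
    extract_promoter` orients it, so a subsequent scan finds the pattern at
    exactly that offset.  Minus-strand genes receive the reverse complement at
    the mirrored genomic position.  With ``insert`` false the scaffold is left
    untouched.
    """
    if not insert:
        return
    pat = element.pattern.encode()
    if locus.strand == "+":
        pstart0 = max(0, locus.start - 1 - promoter_length)  # 0-based promoter start
        plen = (locus.start - 1) - pstart0
        if offset < 0 or offset + len(pat) > plen:
            raise ValueError(f"no feasible slot for {element.name} at offset {offset} (promoter {plen} nt)")
        g = pstart0 + offset
        scaffold[g : g + len(pat)] = np.frombuffer(pat, dtype=np.uint8)
    else:
        pend0 = min(len(scaffold), locus.end + promoter_length)  # 0-based exclusive
        plen = pend0 - locus.end
        if offset < 0 or offset + len(pat) > plen:
            raise ValueError(f"no feasible slot for {element.name} at offset {offset} (promoter {plen} nt)")
        rc = pat.translate(bytes.maketrans(b"ACGTN", b"TGCAN"))[::-1]
        g = pend0 - offset - len(pat)
        scaffold[g : g + len(rc)] = np.frombuffer(rc, dtype=np.uint8)


# the full bundle ----------------------------------------------------------


@dataclass
class SimBundle:
    """Paths and truth tables of one simulated study."""

    out_dir: Path
    config: SimConfig
    species: dict[str, str]
    class_to_family: dict[str, str]
    truth_families: pd.DataFrame       # protein_id, species_id, class_label, family
    truth_counts: pd.DataFrame         # species_id x family planted counts
    truth_localization: pd.DataFrame   # protein_id, compartment
    truth_enrichment: pd.DataFrame     # species_id, family, element, planted
    truth_motifs: pd.DataFrame         # species_id, gene_id, element, offset


def _species_ids(counts: Mapping[str, int]) -> dict[str, str]:
    species = {}
    for stype in SPECIES_TYPES:
        for i in range(counts.get(stype, 0)):
            species[f"{stype}_{i + 1:02d}"] = stype
    return species


def _make_seed_alignment(
    rng: np.random.Generator, cls: FamilyClassSpec, consensus: SeqRecord, cfg: SimConfig
) -> list[SeqRecord]:
    rows = []
    for i in range(cfg.seed_rows):
        rec = mutate_family_member(consensus, cfg.seed_divergence, rng)
        rows.append(list(rec.sequence))
    # two columns gapped in >=50% of rows (dropped from match states) and one
    # lightly gapped column (kept), to exercise the 50% rule downstream
    width = len(consensus.sequence)
    heavy = rng.choice(np.arange(5, width), size=2, replace=False)
    n_heavy = math.ceil(cfg.seed_rows * 0.625)
    for col in heavy:
        for r in rng.choice(cfg.seed_rows, size=n_heavy, replace=False):
            rows[r][col] = "-"
    light_col = int(rng.integers(5, width))
    for r in rng.choice(cfg.seed_rows, size=max(1, cfg.seed_rows // 4), replace=False):
        rows[r][light_col] = "-"
    return [
        SeqRecord(f"{cls.name}_seed{i + 1}", f"{cls.name}_seed{i + 1}", "".join(row))
        for i, row in enumerate(rows)
    ]


def simulate(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate the full input bundle plus truth tables under ``out_dir``.

    Deterministic per config: identical configs give byte-identical files.
    Raises when a gene footprint cannot fit its scaffold.
    """
    out = Path(out_dir)
    for sub in ("seeds", "proteomes", "genomes", "loci", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    species = _species_ids(config.species_counts)
    classes = {c.name: c for c in config.classes}
    class_to_family = {c.name: c.family for c in config.classes}
    family_classes: dict[str, list[str]] = {}
    for c in config.classes:
        family_classes.setdefault(c.family, []).append(c.name)
    families = sorted(family_classes)

    # 1. class consensus sequences and seed alignments
    consensus: dict[str, SeqRecord] = {}
    for c in config.classes:
        seq = random_protein(rng, c.length, start_met=True)
        consensus[c.name] = SeqRecord(f"{c.name}_consensus", f"{c.name}_consensus", seq)
        seeds = _make_seed_alignment(rng, c, consensus[c.name], config)
        write_fasta(seeds, out / "seeds" / f"{c.name}.afa")

    # 2. per-species proteomes, domains, localization
    truth_family_rows = []
    truth_counts = pd.DataFrame(0, index=list(species), columns=families, dtype=int)
    truth_loc_rows = []
    domain_rows = []
    prediction_rows = []
    member_genes: dict[str, dict[str, str]] = {}  # species -> gene_id -> family
    proteomes: dict[str, list[SeqRecord]] = {}

    for sp, stype in species.items():
        records: list[SeqRecord] = []
        member_genes[sp] = {}
        gene_no = 0
        for fam in families:
            mean = float(config.family_means.get(fam, {}).get(stype, 0.0))
            if mean <= 0:
                continue
            count = int(round(mean)) + int(rng.integers(-config.count_jitter, config.count_jitter + 1))
            count = max(0, count)
            truth_counts.loc[sp, fam] = count
            for i in range(count):
                cls = classes[family_classes[fam][i % len(family_classes[fam])]]
                gene_no += 1
                pid = f"{sp}_g{gene_no:03d}"
                rec = mutate_family_member(consensus[cls.name], config.member_divergence, rng)
                tail = int(rng.integers(0, max(1, cls.length // 10)))
                seq = "M" + rec.sequence[1:] + random_protein(rng, tail + 1, start_met=False)[: tail]
                member = SeqRecord(pid, pid, seq)
                records.append(member)
                member_genes[sp][pid] = fam
                truth_family_rows.append((pid, sp, cls.name, fam))
                truth_loc_rows.append((pid, cls.compartment))
                for dom in cls.domains:
                    if rng.random() < dom.prob(stype):
                        start = max(1, int(round(dom.rel_start * len(seq))))
                        end = min(len(seq), max(start, int(round(dom.rel_end * len(seq)))))
                        domain_rows.append((pid, dom.name, start, end, dom.source))
        for i in range(config.n_background_proteins):
            gene_no += 1
            pid = f"{sp}_g{gene_no:03d}"
            length = int(rng.integers(round(config.background_protein_length * 0.6),
                                      round(config.background_protein_length * 1.4)))
            start_met = rng.random() >= config.no_start_met_fraction
            records.append(SeqRecord(pid, pid, random_protein(rng, length, start_met=start_met)))
            truth_loc_rows.append((pid, COMPARTMENTS[int(rng.integers(0, len(COMPARTMENTS)))]))
        proteomes[sp] = records
        write_fasta(records, out / "proteomes" / f"{sp}.fasta")

        # five predictor calls per protein
        acc = config.predictor_accuracy
        truth_by_pid = dict(truth_loc_rows)
        for rec in records:
            true_comp = truth_by_pid[rec.id]
            for predictor in PREDICTORS:
                u = rng.random()
                if u < acc:
                    call = true_comp
                elif u < acc + (1.0 - acc) / 2.0:
                    call = "none"
                else:
                    others = [c for c in COMPARTMENTS if c != true_comp]
                    call = others[int(rng.integers(0, len(others)))]
                prediction_rows.append((rec.id, predictor, call))

    # 3. genomes, loci and motif planting
    truth_motif_rows = []
    planted_pairs = {(m.target_family, m.element.name) for m in config.motif_specs if m.target_family}
    for sp, stype in species.items():
        gene_ids = [r.id for r in proteomes[sp]]
        n_filler = config.genes_per_species - len(gene_ids)
        if n_filler < 0:
            raise ValueError(f"genes_per_species too small for {sp} ({len(gene_ids)} proteins)")
        gene_ids = gene_ids + [f"{sp}_f{i + 1:03d}" for i in range(n_filler)]

        per_scaffold = math.ceil(len(gene_ids) / config.n_scaffolds)
        loci: list[GeneLocus] = []
        scaffolds: dict[str, np.ndarray] = {}
        for si in range(config.n_scaffolds):
            chunk = gene_ids[si * per_scaffold : (si + 1) * per_scaffold]
            if not chunk:
                continue
            name = f"{sp}_scaf{si + 1}"
            segments: list[GeneLocus] = []
            cursor = 0  # 0-based length laid out so far
            for gi, gid in enumerate(chunk):
                edge = gi == 0 and rng.random() < config.edge_gene_fraction
                strand = "+" if (edge or rng.random() < 0.5) else "-"
                upstream = (
                    int(rng.integers(100, config.promoter_length))
                    if edge
                    else config.promoter_length
                )
                if strand == "+":
                    start = cursor + upstream + 1
                    end = start + config.gene_length - 1
                    cursor = end + config.intergenic_spacer
                else:
                    start = cursor + 1
                    end = start + config.gene_length - 1
                    cursor = end + upstream + config.intergenic_spacer
                segments.append(GeneLocus(gid, name, start, end, strand))
            total = cursor + 100
            scaffold = random_dna(rng, total)
            scaffolds[name] = scaffold
            loci.extend(segments)

        loci_by_scaffold: dict[str, list[GeneLocus]] = {}
        for locus in loci:
            loci_by_scaffold.setdefault(locus.scaffold, []).append(locus)

        # plant elements
        for locus in loci:
            fam = member_genes[sp].get(locus.gene_id)
            scaffold = scaffolds[locus.scaffold]
            if locus.strand == "+":
                plen = min(config.promoter_length, locus.start - 1)
            else:
                plen = min(config.promoter_length, len(scaffold) - locus.end)
            occupied: list[tuple[int, int]] = []
            for spec in config.motif_specs:
                p = spec.insert_prob if (fam and (fam, spec.element.name) in planted_pairs
                                         and spec.target_family == fam) else spec.background_prob
                if rng.random() >= p:
                    continue
                patlen = len(spec.element.pattern)
                if plen < patlen:
                    continue
                offset = None
                for _ in range(50):
                    o = int(rng.integers(0, plen - patlen + 1))
                    if all(o + patlen <= a or o >= b for a, b in occupied):
                        offset = o
                        break
                if offset is None:
                    continue
                occupied.append((offset, offset + patlen))
                plant_motif(scaffold, locus, spec.element, offset,
                            promoter_length=config.promoter_length)
                truth_motif_rows.append((sp, locus.gene_id, spec.element.name, offset))

        write_fasta(
            [SeqRecord(name, name, arr.tobytes().decode("ascii")) for name, arr in scaffolds.items()],
            out / "genomes" / f"{sp}.fasta",
        )
        write_tsv(
            out / "loci" / f"{sp}.tsv",
            ("gene_id", "scaffold", "start", "end", "strand"),
            [(l.gene_id, l.scaffold, l.start, l.end, l.strand) for l in loci],
        )

    # 4. shared tables
    write_tsv(out / "species.tsv", ("species_id", "species_type"), species.items())
    write_tsv(
        out / "motifs.tsv",
        ("name", "pattern", "category"),
        [(m.element.name, m.element.pattern, m.element.category) for m in config.motif_specs],
    )
    write_tsv(out / "domains.tsv", ("protein_id", "domain_name", "start", "end", "source"), domain_rows)
    write_tsv(out / "predictions.tsv", ("protein_id", "predictor", "call"), prediction_rows)

    # 5. truth tables
    truth_families = pd.DataFrame(
        truth_family_rows, columns=["protein_id", "species_id", "class_label", "family"]
    )
    truth_localization = pd.DataFrame(truth_loc_rows, columns=["protein_id", "compartment"])
    enr_rows = []
    for sp in species:
        for spec in config.motif_specs:
            if spec.target_family is None:
                continue
            possesses = truth_counts.loc[sp, spec.target_family] > 0
            enr_rows.append(
                (sp, spec.target_family, spec.element.name, bool(possesses and spec.insert_prob > spec.background_prob))
            )
    truth_enrichment = pd.DataFrame(enr_rows, columns=["species_id", "family", "element", "planted"])
    truth_motifs = pd.DataFrame(truth_motif_rows, columns=["species_id", "gene_id", "element", "offset"])

    truth_families.to_csv(out / "truth" / "families.tsv", sep="\t", index=False, lineterminator="\n")
    truth_counts.rename_axis("species_id").reset_index().to_csv(
        out / "truth" / "counts.tsv", sep="\t", index=False, lineterminator="\n"
    )
    truth_localization.to_csv(out / "truth" / "localization.tsv", sep="\t", index=False, lineterminator="\n")
    truth_enrichment.to_csv(out / "truth" / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")
    truth_motifs.to_csv(out / "truth" / "motif_positions.tsv", sep="\t", index=False, lineterminator="\n")
    with open(out / "config.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")

    return SimBundle(
        out_dir=out,
        config=config,
        species=species,
        class_to_family=class_to_family,
        truth_families=truth_families,
        truth_counts=truth_counts,
        truth_localization=truth_localization,
        truth_enrichment=truth_enrichment,
        truth_motifs=truth_motifs,
    )


# light-weight generators for statistical calibration ----------------------


def _random_promoters(rng: np.random.Generator, n: int, length: int) -> list[str]:
    block = random_dna(rng, n * length).tobytes().decode("ascii")
    return [block[i * length : (i + 1) * length] for i in range(n)]


def null_enrichment_rate(
    seed: int,
    n_species: int = 1000,
    n_genes: int = 150,
    n_family: int = 15,
    promoter_length: int = 300,
    patterns: Sequence[str] = ("TACGTGTC", "TACCGACA", "CCTACCTA", "GAAAATCT", "TGTAAAGT"),
    alpha: float = 0.05,
) -> tuple[int, int]:
    """Fraction of (species, element) null tests called enriched at ``alpha``.

    Every species is background-only (no planted signal); returns
    (n_enriched, n_tests) over ``n_species`` independently drawn species.
    """
    rng = np.random.default_rng(seed)
    elements = [MotifElement(f"el{i}", p, "other") for i, p in enumerate(patterns)]
    n_enriched = n_tests = 0
    for s in range(n_species):
        proms = _random_promoters(rng, n_genes, promoter_length)
        genes = [f"g{i}" for i in range(n_genes)]
        matches = [
            scan_element(PromoterRegion(genes[i], proms[i], False), el)
            for i in range(n_genes)
            for el in elements
        ]
        family = set(rng.choice(genes, size=n_family, replace=False))
        results = enrich(f"null{s}", "FAM", family, set(genes), matches, elements, alpha=alpha)
        n_tests += len(results)
        n_enriched += sum(r.enriched for r in results)
    return n_enriched, n_tests


def planted_enrichment_power(
    seed: int,
    n_replicates: int = 200,
    n_genes: int = 1000,
    n_family: int = 10,
    insert_prob: float = 0.9,
    background_prob: float = 0.05,
    promoter_length: int = 500,
    pattern: str = "TACGTGTC",
    alpha: float = 0.05,
) -> float:
    """Power of the enrichment test under the planted-signal scenario.

    Each replicate plants the element in ``insert_prob`` of the family's
    promoters and ``background_prob`` of the rest, then runs the scan +
    hypergeometric test; returns the fraction of replicates with p < alpha.
    """
    rng = np.random.default_rng(seed)
    element = MotifElement("planted", pattern, "other")
    hits = 0
    for _ in range(n_replicates):
        proms = _random_promoters(rng, n_genes, promoter_length)
        genes = [f"g{i}" for i in range(n_genes)]
        family = set(genes[:n_family])
        matches = []
        for i, g in enumerate(genes):
            seq = proms[i]
            p = insert_prob if g in family else background_prob
            if rng.random() < p:
                o = int(rng.integers(0, len(seq) - len(pattern) + 1))
                seq = seq[:o] + pattern + seq[o + len(pattern):]
            matches.append(scan_element(PromoterRegion(g, seq, False), element))
        res = enrich("rep", "FAM", family, set(genes), matches, [element], alpha=alpha)
        hits += res[0].enriched
    return hits / n_replicates
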