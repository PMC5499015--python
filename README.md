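# acetylcensus

A genome-scale census of the enzymes of reversible protein acetylation —
lysine acetyltransferases (KATs: MYST, GNAT, CBP, TAF<sub>II</sub>250) and
lysine deacetylases (KDACs: HDA/RPD3, SRT/sirtuin, HDT/HD2-tuin) — across
photosynthetic eukaryotes, from glaucophytes and algae to monocots and
dicots.  The package is aimed at comparative genomicists who want a tested,
reproducible version of the standard family-census workflow:

1. **Family classification** — per-class profile models built from seed
   multiple alignments (columns with < 50% gaps become match states with
   pseudocount-smoothed emission log-odds); candidate proteomes are scored by
   affine-gap local alignment and converted to E-values through a seeded
   Gumbel calibration on random background sequences.  Hits with
   E < 10⁻¹⁰⁰ are accepted outright; hits with 10⁻¹⁰⁰ ≤ E ≤ 10⁻³ enter a
   review zone and are only counted after reciprocal-best-hit validation
   (BLOSUM62 local alignment) against the family references; everything else
   is rejected.
2. **Domain architecture** — per (family × species-type) group: exact median
   protein length, per-domain prevalence with a 5% display floor, and
   positional histograms after rescaling every domain interval to the group
   median.
3. **Subcellular localization** — consensus over five predictor calls: a
   single compartment when ≥ 3 of 5 agree, otherwise primary/secondary by
   vote frequency; proteins lacking an initial methionine are left
   unpredicted.
4. **Promoter elements** — 2000 bp strand-aware upstream promoters (truncated
   at scaffold ends), exact non-overlapping motif matches (greedy leftmost),
   per-species hypergeometric enrichment P(X ≥ k) at p < 0.05, and a
   cross-species conservation call when an element is enriched in ≥ 50% of
   the species possessing the family.
5. **Family-size statistics** — species × family count matrices compared
   across species-type groups with the tie-corrected Kruskal–Wallis H test.
6. **Synthetic studies** — a deterministic generator that emulates a
   53-genome compendium (plus 4 non-photosynthetic references) with planted
   family members, domains, localization calls and promoter elements, and
   writes the ground truth alongside, so every stage can be scored against
   what was planted.

## Worked example

Simulate a small four-species study, run the census, and compare family
sizes between dicots and monocots:

```bash
census simulate --seed 3 --out demo --small   # writes proteomes/, seeds/, genomes/, truth/ ...
census classify --bundle demo --seed 3 --out hits.tsv --counts counts.tsv
census compare --counts counts.tsv --species demo/species.tsv --groups "dicot;monocot"
```

With a four-species configuration (`species_counts={"dicot": 2, "monocot": 2}`,
45 genes per species) this prints a hit table and the count matrix

```
            CBP  GNAT  HDA  HDT  MYST  SRT  TAF250
species_id
dicot_01      5     4   11    1     1    1       2
dicot_02      3     3   12    2     3    1       1
monocot_01    5     2   12    3     1    2       1
monocot_02    6     4   12    4     3    1       3
```

which reproduces the generator's planted truth table
(`demo/truth/counts.tsv`) cell for cell: every planted member is recovered
at 15% sequence divergence and no background protein is mis-assigned.  Each
number is the count of genes that species encodes for the family, the same
quantity a census of real proteomes tabulates.  The remaining stages follow
the same pattern:

```bash
census localize --proteome demo/proteomes/dicot_01.fasta --predictions demo/predictions.tsv --out loc.tsv
census promoters --genome demo/genomes/dicot_01.fasta --loci demo/loci/dicot_01.tsv --out prom.fasta
census scan      --promoters prom.fasta --motifs demo/motifs.tsv --out matches.tsv
census enrich    --matches matches.tsv --families famsets.tsv --motifs demo/motifs.tsv --out enr.tsv
census conserve  --enrichments enr.tsv --out cons.tsv
```

(`famsets.tsv` is a two-column `gene_id`/`family` TSV naming each family's
gene set — in practice the counted genes from the hit table.)

For the library API (`build_profile`, `score_protein`, `classify`,
`profile_group`, `consensus`, `extract_promoter`, `enrich`, `conserve`,
`simulate`, ...) see the module docstrings; `acetylcensus.pipeline.run_census`
drives the whole classification stage and returns a `CensusResult` with the
hit records, the species × family tabulation and the fitted models.

As a calibration reference, the Kruskal–Wallis helper returns
`H = 3.857, p = 0.0495` for the two groups {1,2,3} vs {4,5,6}.

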