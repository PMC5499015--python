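# Methods

This note documents the models and procedures implemented in `acetylcensus`,
the choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Profile models and scoring

A family profile is built from a seed multiple alignment.  Alignment columns
with ≥ 50% gap characters are excluded from the match states; for each kept
column the emission probability of residue *a* is

    e(a) = (c_a + τ·b_a) / (n_obs + τ)

where `c_a` is the residue count in the column, `n_obs` the number of
non-gap observations, `b` a fixed background amino-acid frequency vector
(Robinson–Robinson style, embedded in the package) and `τ > 0` the
pseudocount (default 1.0).  Emissions sum to one exactly and shrink toward
the background as data thin out.  Scores are natural-log odds `ln e(a)/b_a`.

Candidates are scored by Smith–Waterman-style local alignment of the protein
against the ordered match columns, with three states (match, insertion,
deletion) and affine gaps on the log-odds scale: a gap of length *k* costs
11 + *k* (open −11 charged once, extend −1 per gapped position — the
BLOSUM62/BLAST convention).  Alignments start and end in a match state;
insertion and deletion runs are never adjacent (canonical form).  An unknown
residue (X) scores 0, i.e. background-neutral.  The implementation is a
batched dynamic program (sequences right-padded with a −∞-emission sentinel,
which provably leaves scores unchanged); it is verified against exhaustive
enumeration of all canonical local alignments on small instances.

## E-values

Because full Plan-7 HMM machinery and its calibrated E-values are out of
scope, scores are converted to E-values through an explicit extreme-value
calibration: `n_random` i.i.d. background sequences (default 1000, length =
median proteome length) are scored against the profile and a Gumbel law is
fitted by the method of moments (λ = π/(σ√6), μ = mean − γ/λ).  Then

    E(s) = D · (1 − exp(−exp(−λ(s − μ))))

with `D` the database size (number of proteins searched), clamped to
[0, D].  The calibration is seeded and reproducible; a zero-variance score
set (e.g. a flat profile) is an error.  Method-of-moments fitting of local
alignment score maxima is approximate in the far tail, so the absolute
magnitude of extremely small E-values should be read as order-of-magnitude;
the two decision thresholds below sit so far apart (97 orders of magnitude)
that the zone assignment is insensitive to this.

## Accept / review / reject zones and reciprocal best hit

Hits are partitioned purely by E-value: accepted below 1×10⁻¹⁰⁰, review
between 1×10⁻¹⁰⁰ and 1×10⁻³ inclusive, rejected above.  Both thresholds are
parameters.  A protein scored against several family profiles is assigned to
the family with the minimum E-value; the other profiles are recorded as
secondary hits and never counted.  An exact E-value tie for the best family
demotes the hit to review.

The review zone replaces a human curation step with its automatable core: a
reciprocal-best-hit (RBH) check by pairwise local alignment (BLOSUM62,
affine −11/−1).  Forward, the candidate's best-scoring reference sequence
must belong to the claimed family (a cross-family score tie is ambiguous and
fails).  Reverse, that reference — re-scored against the species' candidate
set plus the candidate — must rank the candidate strictly top.  The reverse
direction is defined over the candidate set because the interface carries no
second database; with an empty candidate set the check reduces to the
forward best-hit test.  Review hits failing RBH are excluded from counts;
`include_review` (default on in the pipeline driver) controls whether
RBH-confirmed review hits are counted at all, since either convention is
defensible for a published census table.

## Family-size tabulation and statistics

Counts are tabulated per (species, family), with class-level profiles
(HDA classes I/II, SRT classes I/II/IV, GNAT classes I–III) collapsed onto
their top-level family; species with zero hits appear as zero rows.  Group
comparisons use the Kruskal–Wallis rank test with tie correction and the
chi-square approximation (scipy), with the degenerate all-tied case defined
as H = 0, p = 1.  Each species-type group must contribute at least two
species.

## Domain-architecture profiles

For each (family, species-type) group: the median protein length is the
exact lower median (an attained length, since the bar it draws marks a real
protein size); every domain interval [start, end] (1-based, inclusive) is
rescaled linearly to [start/L·M, end/L·M] where L is the protein length and
M the group median; prevalence is the fraction of group proteins carrying at
least one copy (multiple copies count once); domains below 5% prevalence are
dropped *after* prevalence is computed, so denominators are always the full
group size.  Positional histograms use 100 bins partitioning [0, M]; the
default (plotted) histogram is per-protein (fraction of proteins whose
rescaled interval overlaps the bin), with a per-occurrence variant also
computed.  Bin-wise, per-protein frequency never exceeds prevalence.

## Localization consensus

A pure function of the leading residue and the multiset of five predictor
calls: no initial methionine → unpredicted; any compartment with ≥ 3 votes →
single location; otherwise primary/secondary by vote frequency.  "none"
calls never enter the counts, but the 3-vote bar stays absolute (3 of 5, not
3 of the non-none calls).  Count ties are broken by a fixed priority
(nucleus > cytosol > mitochondrion > chloroplast > secretory > other),
chosen because nuclear/cytosolic calls dominate observed predictions; some
deterministic total order is required and the choice only affects tied
primary/secondary reports, never single verdicts.  An all-"none" vote with a
leading methionine is reported with no compartment and flagged low-evidence.
The rule is verified against exhaustive enumeration of all 6⁵ = 7,776 vote
patterns.

## Promoters, enrichment, conservation

Promoters are the `length` (default 2000) bases upstream of the gene start
on the coding strand: plus strand [start−length, start−1], minus strand
[end+1, end+length] reverse-complemented, truncated (not discarded) at
scaffold ends.  Coordinates are 1-based inclusive at every file boundary and
converted to 0-based half-open in exactly one helper.  Promoters are not
trimmed at upstream neighboring genes.

Elements are exact DNA strings scanned greedily left to right without
overlap; for a fixed exact pattern the greedy-leftmost count equals the
maximum non-overlapping match count (verified against a brute-force oracle).
Only the oriented promoter strand is scanned by default.

Enrichment is per (species, family, element): the sampling unit is the gene,
with k = family genes containing ≥ 1 match, K = universe genes containing
≥ 1 match, n = family size, N = universe size (all genes with an extractable
promoter), and p = P(X ≥ k) under Hypergeometric(N, K, n) (scipy upper
tail, exact for the sizes used).  The cutoff is raw p < 0.05 with no
multiple-testing correction, matching standard practice for this analysis;
Benjamini–Hochberg is available behind a flag and off by default.
Occurrence counts and match offsets are tracked and reported but do not
enter the test.  An element is conserved for a family when it is enriched in
≥ 50% of the species examined, where a species is examined only if it
possesses the family; the boundary (exactly half) counts as conserved.

## Synthetic studies

`simulate()` writes a complete input bundle plus truth tables,
deterministically per seed (identical configs give byte-identical files).
The default configuration emulates the compiled compendium: 53
photosynthetic species across five species-type groups plus 4
non-photosynthetic references (57 total).  Planted mean family sizes per
species type follow the census averages the workflow is meant to recover
(e.g. HDA ≈ 11 per dicot and green alga, 13 per monocot, 9 per heterokont,
5 per non-photosynthetic reference; HDT in land plants only; CBP absent from
red algae; GNAT = 3 per organism except red algae), with ±1 per-species
jitter so that group comparisons have within-group variance.  Members are
drawn by per-site substitution from a per-class consensus at divergence 0.15
(seed alignments at 0.06 with planted gappy columns to exercise the 50%
rule); localization predictors are correct with probability 0.9, otherwise
"none" or a wrong compartment; one cis-element per family is planted into
90% of that family's promoters against a 1% background insertion rate.

Desk-scale sizing choices (the package's own): per-species proteomes carry
the planted members plus 25 background proteins, while the gene/promoter
universe is 200 genes per species (filler genes have loci and promoters but
no simulated protein, as enrichment samples genes, not proteins); protein
lengths are per-family constants (300–500 aa) with small C-terminal length
jitter; genomes are uniform-random nucleotide scaffolds with one
promoter-clear slot per gene and a configurable fraction of scaffold-initial
genes placed closer than the promoter length to the scaffold edge to
exercise truncation.  The default cis-elements are 10-mers at 1% background
so that element-bearing promoters are a small fraction of the universe, as
in a genome-scale gene universe where even a single-gene family can clear
the 0.05 cutoff; the spec-level power scenario (element in 90% of 10 family
promoters vs 5% background in a 1000-gene universe) is kept as its own
generator and is tested separately.

What passing on synthetic data shows — and does not.  The generator plants
i.i.d. substitutions from a fixed background: there is no tree-structured
evolution, no indels within domains, no codon-level linkage between genome
and proteome, no compositional bias, and real predictor errors are not
independent across tools.  Recovery on these studies therefore demonstrates
the correctness and calibration of the pipeline's decision rules
(thresholds, voting, counting, testing), not the sensitivity of profile
search against deeply diverged natural sequences.

## Numerical and degenerate-input conventions

Tie-breaks are documented at each site: cross-family RBH score ties →
ambiguous; exact E-value ties → review; localization count ties → fixed
compartment priority; conservation at exactly the threshold → conserved.
Degenerate inputs: empty sequences, empty family sets, empty groups,
all-gap alignment columns and invalid hypergeometric configurations are
errors; a pattern longer than its promoter is a zero-count match, not an
error; an all-filtered domain profile renders a header-only table with a
warning.  E-value evaluation is clamped to [0, D] and computed stably at
both tails.  All file outputs are UTF-8 TSV/FASTA with LF line endings.

## Problem sizes used in the shipped checks

The test suite runs a reduced 12-species study once per session for the
end-to-end closure checks; statistical calibration uses 1,000 null species
(type-I rate ≤ 0.07 at α = 0.05) and 200 planted replicates (power ≥ 0.99);
the acceptance script runs the full 57-species default study with
`n_random = 1000` E-value calibration.  These sizes were chosen so the whole
suite completes in minutes on one CPU while keeping every statistical check
adequately powered.
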