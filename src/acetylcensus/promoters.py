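"""Promoter extraction, exact motif scanning and hypergeometric enrichment.

Promoters are the 2000 bp immediately upstream of a gene's 5' end on its
coding strand (reverse-complemented for minus-strand genes) and are truncated,
not discarded, when the gene sits closer than 2000 bp to a scaffold end.
Elements are exact DNA strings matched greedily left to right without
overlap.  Per (species, family, element), enrichment of element-bearing
promoters in the family's gene set against the species' gene universe is
tested with the upper-tail hypergeometric probability at p < 0.05, and an
element is called conserved for a family when it is enriched in at least half
of the species that possess the family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .io import GeneLocus, MotifElement, SeqRecord, zero_based_interval

PROMOTER_LENGTH = 2000
DEFAULT_ALPHA = 0.05
CONSERVATION_THRESHOLD = 0.5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRegion:
    """Upstream promoter sequence, oriented along the gene's coding strand."""

    gene_id: str
    sequence: str
    truncated: bool

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchRecord:
    """Non-overlapping exact matches of one element in one promoter."""

    gene_id: str
    element_name: str
    starts: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one element in one family's promoters."""

    species_id: str
    family: str
    element_name: str
    k: int          # family genes with >= 1 match
    K: int          # universe genes with >= 1 match
    n: int          # family set size
    N: int          # universe size
    p: float
    enriched: bool


@dataclass(frozen=True)
class ConservationResult:
    """Cross-species conservation verdict for one (family, element) pair."""

    family: str
    element_name: str
    n_species_enriched: int
    n_species_examined: int
    conserved: bool

    @property
    def fraction(self) -> float:
        return self.n_species_enriched / self.n_species_examined


def extract_promoter(
    genome: Mapping[str, str], locus: GeneLocus, length: int = PROMOTER_LENGTH
) -> PromoterRegion:
    """Extract the upstream promoter of a gene, clipped at scaffold ends.

    Plus strand: positions [start - length, start - 1]; minus strand:
    positions [end + 1, end + length], reverse-complemented.  The truncated
    flag is set whenever clipping shortened the region.
    """
    if locus.scaffold not in genome:
        raise ValueError(f"scaffold {locus.scaffold} not in genome")
    scaffold = genome[locus.scaffold]
    if locus.end > len(scaffold):
        raise ValueError(f"locus {locus.gene_id} extends past scaffold end ({locus.end} > {len(scaffold)})")

    if locus.strand == "+":
        start1 = max(1, locus.start - length)
        end1 = locus.start - 1
        truncated = locus.start - length < 1
        if end1 < start1:
            return PromoterRegion(locus.gene_id, "", True)
        s, e = zero_based_interval(start1, end1)
        return PromoterRegion(locus.gene_id, scaffold[s:e], truncated)

    start1 = locus.end + 1
    end1 = min(len(scaffold), locus.end + length)
    truncated = locus.end + length > len(scaffold)
    if end1 < start1:
        return PromoterRegion(locus.gene_id, "", True)
    s, e = zero_based_interval(start1, end1)
    return PromoterRegion(locus.gene_id, reverse_complement(scaffold[s:e]), truncated)


def scan_element(promoter: PromoterRegion, element: MotifElement) -> MatchRecord:
    """Greedy leftmost exact non-overlapping scan of the oriented promoter.

    At each position a full pattern match is recorded and the scan jumps by
    the pattern length; otherwise it advances by one.  For exact fixed-length
    patterns this attains the maximum non-overlapping match count.  A pattern
    longer than the promoter yields zero matches.
    """
    starts: list[int] = []
    seq, pat = promoter.sequence, element.pattern
    pos = seq.find(pat)
    while pos != -1:
        starts.append(pos)
        pos = seq.find(pat, pos + len(pat))
    return MatchRecord(promoter.gene_id, element.name, tuple(starts))


def scan_promoters(
    promoters: Iterable[PromoterRegion], elements: Sequence[MotifElement]
) -> list[MatchRecord]:
    """Scan every promoter for every element."""
    return [scan_element(p, el) for p in promoters for el in elements]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) — the enrichment upper tail.

    Drawing n genes from a universe of N that contains K element-bearing
    genes, the probability of seeing at least the observed k.
    """
    if not (0 <= k <= min(n, K) and k <= n <= N and K <= N and K >= 0):
        raise ValueError(f"invalid hypergeometric configuration k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich(
    species_id: str,
    family: str,
    family_genes: set[str],
    universe_genes: set[str],
    matches: Iterable[MatchRecord],
    elements: Sequence[MotifElement],
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Per-element enrichment of a family's promoters within one species.

    The sampling unit is the gene: k and K count genes with at least one
    match (occurrence counts are tracked upstream but do not enter the test).
    With ``fdr`` set, the enriched flag uses Benjamini-Hochberg adjusted
    p-values instead of the raw cutoff.
    """
    if not family_genes:
        raise ValueError("empty family gene set")
    if not family_genes <= universe_genes:
        raise ValueError("family genes must be a subset of the universe")
    present: dict[str, set[str]] = {el.name: set() for el in elements}
    for m in matches:
        if m.count > 0 and m.element_name in present and m.gene_id in universe_genes:
            present[m.element_name].add(m.gene_id)

    N, n = len(universe_genes), len(family_genes)
    raw: list[tuple[str, int, int, float]] = []
    for el in elements:
        K = len(present[el.name])
        k = len(present[el.name] & family_genes)
        raw.append((el.name, k, K, hypergeom_upper(k, K, n, N)))

    if fdr and raw:
        adjusted = stats.false_discovery_control([p for *_, p in raw], method="bh")
        flags = [q < alpha for q in adjusted]
    else:
        flags = [p < alpha for *_, p in raw]

    return [
        EnrichmentResult(species_id, family, name, k, K, n, N, p, bool(flag))
        for (name, k, K, p), flag in zip(raw, flags)
    ]


def conserve(
    results: Iterable[EnrichmentResult],
    threshold: float = CONSERVATION_THRESHOLD,
) -> list[ConservationResult]:
    """Cross-species conservation verdicts per (family, element).

    A species is "examined" for a family when it contributed any enrichment
    result for it (i.e. it possesses the family); an element is conserved
    when enriched in at least ``threshold`` of those species.
    """
    examined: dict[str, set[str]] = {}
    enriched_in: dict[tuple[str, str], set[str]] = {}
    elements_of: dict[str, set[str]] = {}
    for r in results:
        examined.setdefault(r.family, set()).add(r.species_id)
        elements_of.setdefault(r.family, set()).add(r.element_name)
        if r.enriched:
            enriched_in.setdefault((r.family, r.element_name), set()).add(r.species_id)

    if not examined:
        raise ValueError("no species examined")
    out = []
    for family in sorted(examined):
        n_exam = len(examined[family])
        for element in sorted(elements_of[family]):
            n_enr = len(enriched_in.get((family, element), ()))
            out.append(
                ConservationResult(family, element, n_enr, n_exam, n_enr / n_exam >= threshold)
            )
    return out
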