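import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetylcensus.io import GeneLocus, MotifElement
from acetylcensus.promoters import (
    MatchRecord,
    PromoterRegion,
    conserve,
    enrich,
    extract_promoter,
    hypergeom_upper,
    reverse_complement,
    scan_element,
    EnrichmentResult,
)


def dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def locus(gene="g1", scaffold="s1", start=2500, end=2800, strand="+"):
    return GeneLocus(gene, scaffold, start, end, strand)


class TestExtractPromoter:
    def test_plus_strand_full_window(self, rng):
        genome = {"s1": dna(rng, 5000)}
        region = extract_promoter(genome, locus(start=2500))
        assert region.sequence == genome["s1"][499:2499]
        assert region.length == 2000 and not region.truncated

    def test_plus_strand_truncated_at_scaffold_start(self, rng):
        genome = {"s1": dna(rng, 5000)}
        region = extract_promoter(genome, locus(start=1500))
        assert region.sequence == genome["s1"][:1499]
        assert region.length == 1499 and region.truncated

    def test_minus_strand_reverse_complemented(self, rng):
        genome = {"s1": dna(rng, 6000)}
        region = extract_promoter(genome, locus(start=1000, end=1400, strand="-"))
        assert region.sequence == reverse_complement(genome["s1"][1400:3400])
        assert not region.truncated
        again = extract_promoter(genome, locus(start=1000, end=1400, strand="-"))
        assert again.sequence == region.sequence

    def test_minus_strand_truncated_at_scaffold_end(self, rng):
        genome = {"s1": dna(rng, 3000)}
        region = extract_promoter(genome, locus(start=2000, end=2500, strand="-"))
        assert region.length == 500 and region.truncated

    def test_gene_at_scaffold_start_yields_empty_promoter(self, rng):
        genome = {"s1": dna(rng, 3000)}
        region = extract_promoter(genome, locus(start=1, end=300))
        assert region.sequence == "" and region.truncated

    def test_unknown_scaffold_and_overhang_are_errors(self, rng):
        genome = {"s1": dna(rng, 1000)}
        with pytest.raises(ValueError, match="not in genome"):
            extract_promoter(genome, locus(scaffold="s2"))
        with pytest.raises(ValueError, match="past scaffold end"):
            extract_promoter(genome, locus(start=900, end=1200))


def max_nonoverlap_count(seq: str, pattern: str) -> int:
    """Independent oracle: all match positions, then the maximum set of
    pairwise non-overlapping matches by dynamic programming."""
    positions = [i for i in range(len(seq) - len(pattern) + 1) if seq[i : i + len(pattern)] == pattern]
    best_at = {}
    best = 0
    for p in positions:
        prev = max((v for q, v in best_at.items() if q + len(pattern) <= p), default=0)
        best_at[p] = prev + 1
        best = max(best, best_at[p])
    return best


class TestScanElement:
    def scan(self, seq, pattern):
        return scan_element(PromoterRegion("g", seq, False), MotifElement("el", pattern, "other"))

    def test_greedy_leftmost_on_overlapping_pattern(self):
        rec = self.scan("AAAA", "AA")
        assert rec.starts == (0, 2) and rec.count == 2

    def test_no_match(self):
        assert self.scan("ACGT", "GG").count == 0

    def test_pattern_equal_to_promoter(self):
        rec = self.scan("ACGTACG", "ACGTACG")
        assert rec.starts == (0,)

    def test_pattern_longer_than_promoter_is_zero_not_error(self):
        assert self.scan("ACG", "ACGT").count == 0

    def test_greedy_attains_maximum_nonoverlap_count(self, rng):
        for _ in range(300):
            seq = dna(rng, int(rng.integers(5, 80)))
            plen = int(rng.integers(2, 5))
            pattern = dna(rng, plen)
            rec = self.scan(seq, pattern)
            assert rec.count == max_nonoverlap_count(seq, pattern)
            assert all(b - a >= plen for a, b in zip(rec.starts, rec.starts[1:]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=60),
        pattern=st.text(alphabet="ACGT", min_size=2, max_size=6),
    )
    def test_nonoverlap_invariant_holds_for_all_inputs(self, seq, pattern):
        rec = self.scan(seq, pattern)
        assert all(b - a >= len(pattern) for a, b in zip(rec.starts, rec.starts[1:]))
        for s in rec.starts:
            assert seq[s : s + len(pattern)] == pattern


class TestHypergeom:
    def test_zero_successes_is_certain(self):
        assert hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_exact_small_case(self):
        assert hypergeom_upper(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_saturation(self):
        assert hypergeom_upper(4, 10, 4, 10) == pytest.approx(1.0)

    def test_invalid_configuration_is_error(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 2, 4, 10)

    def test_matches_enumeration(self):
        for N in (6, 9, 12):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(min(n, K) + 1):
                        expected = sum(
                            math.comb(K, j) * math.comb(N - K, n - j)
                            for j in range(k, min(n, K) + 1)
                        ) / math.comb(N, n)
                        assert hypergeom_upper(k, K, n, N) == pytest.approx(expected, rel=1e-9)


class TestEnrich:
    elements = [MotifElement("el", "ACGT", "other")]

    def matches(self, present):
        return [MatchRecord(g, "el", (0,)) for g in present]

    def test_ubiquitous_element_not_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        res = enrich("sp", "HDA", {"g0", "g1"}, universe, self.matches(universe), self.elements)
        assert res[0].p == 1.0 and not res[0].enriched

    def test_family_equal_to_universe_saturates(self):
        universe = {"g0", "g1", "g2"}
        res = enrich("sp", "HDA", universe, universe, self.matches({"g0"}), self.elements)
        assert res[0].k == res[0].K and res[0].p == 1.0

    def test_concentrated_element_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        family = {f"g{i}" for i in range(5)}
        res = enrich("sp", "HDA", family, universe, self.matches(family), self.elements)
        assert res[0].enriched and res[0].k == 5 and res[0].K == 5

    def test_empty_family_is_error(self):
        with pytest.raises(ValueError, match="empty family"):
            enrich("sp", "HDA", set(), {"g0"}, [], self.elements)

    def test_family_outside_universe_is_error(self):
        with pytest.raises(ValueError, match="subset"):
            enrich("sp", "HDA", {"zz"}, {"g0"}, [], self.elements)

    def test_fdr_flag_is_more_conservative(self):
        universe = {f"g{i}" for i in range(40)}
        family = {f"g{i}" for i in range(4)}
        elements = [MotifElement(f"el{j}", "ACGT", "other") for j in range(6)]
        matches = [MatchRecord(g, el.name, (0,)) for el in elements[:1] for g in list(family)[:3]]
        raw = enrich("sp", "HDA", family, universe, matches, elements)
        adj = enrich("sp", "HDA", family, universe, matches, elements, fdr=True)
        assert sum(r.enriched for r in adj) <= sum(r.enriched for r in raw)


class TestConserve:
    def result(self, sp, enriched, family="HDA", element="el"):
        return EnrichmentResult(sp, family, element, 1, 1, 1, 10, 0.01 if enriched else 0.9, enriched)

    def test_three_of_five_conserved(self):
        results = [self.result(f"sp{i}", i < 3) for i in range(5)]
        (c,) = conserve(results)
        assert c.fraction == pytest.approx(0.6) and c.conserved

    def test_two_of_five_not_conserved(self):
        results = [self.result(f"sp{i}", i < 2) for i in range(5)]
        (c,) = conserve(results)
        assert c.fraction == pytest.approx(0.4) and not c.conserved

    def test_exactly_half_counts_as_conserved(self):
        results = [self.result(f"sp{i}", i < 2) for i in range(4)]
        (c,) = conserve(results)
        assert c.fraction == pytest.approx(0.5) and c.conserved

    def test_examined_species_limited_to_family_possessors(self):
        results = [self.result(f"sp{i}", True, family="HDT") for i in range(2)]
        results += [self.result(f"sp{i}", False, family="HDA") for i in range(6)]
        by_family = {c.family: c for c in conserve(results)}
        assert by_family["HDT"].n_species_examined == 2 and by_family["HDT"].conserved
        assert by_family["HDA"].n_species_examined == 6

    def test_no_results_is_error(self):
        with pytest.raises(ValueError):
            conserve([])
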