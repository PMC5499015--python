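import itertools

import numpy as np
import pytest

from acetylcensus.census import (
    HitRecord,
    PairScorer,
    ScoredCandidate,
    classify,
    compare_family_sizes,
    kruskal_wallis,
    reciprocal_best_hit,
    tabulate_family_sizes,
)
from acetylcensus.io import SeqRecord
from conftest import random_protein_string


def cand(pid, fam, e, sp="sp1"):
    return ScoredCandidate(pid, sp, fam, score=100.0, evalue=e)


class TestClassify:
    @pytest.mark.parametrize(
        "e,status",
        [(1e-150, "accepted"), (1e-100, "review"), (1e-50, "review"), (1e-3, "review"), (0.01, "rejected")],
    )
    def test_evalue_zones(self, e, status):
        (rec,) = classify([cand("p1", "HDA", e)])
        assert rec.status == status

    def test_partition_covers_every_hit_once(self):
        hits = [cand(f"p{i}", "HDA", e) for i, e in enumerate(np.logspace(-120, 1, 30))]
        records = classify(hits)
        assert len(records) == 30
        assert all(r.status in ("accepted", "review", "rejected") for r in records)

    def test_best_family_is_primary_others_secondary(self):
        records = classify([cand("p1", "HDA", 1e-120), cand("p1", "SRT", 1e-5)])
        primary = [r for r in records if r.rank == "primary"]
        secondary = [r for r in records if r.rank == "secondary"]
        assert [r.family for r in primary] == ["HDA"]
        assert [r.family for r in secondary] == ["SRT"]

    def test_exact_tie_demoted_to_review(self):
        records = classify([cand("p1", "HDA", 1e-120), cand("p1", "SRT", 1e-120)])
        (primary,) = [r for r in records if r.rank == "primary"]
        assert primary.status == "review"

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            classify([], accept_threshold=1e-3, review_threshold=1e-100)


class TestReciprocalBestHit:
    def refs(self, rng):
        a = random_protein_string(rng, 60)
        b = random_protein_string(rng, 60)
        return {
            "A": [SeqRecord(f"A{i}", "", a[:i] + a[i:]) for i in range(2)],
            "B": [SeqRecord(f"B{i}", "", b) for i in range(2)],
        }

    def test_identity_confirms_family(self, rng):
        refs = self.refs(rng)
        candidate = SeqRecord("c", "", refs["A"][0].sequence)
        assert reciprocal_best_hit(candidate, refs) == "A"

    def test_cross_family_tie_is_ambiguous(self):
        seq = "MKWVTFISLLFLFSSAYS"
        refs = {"A": [SeqRecord("a", "", seq)], "B": [SeqRecord("b", "", seq)]}
        assert reciprocal_best_hit(SeqRecord("c", "", seq), refs) is None

    def test_reverse_direction_rejects_outcompeted_candidate(self, rng):
        refs = self.refs(rng)
        near_identical = SeqRecord("twin", "", refs["A"][0].sequence)
        diverged = list(refs["A"][0].sequence)
        for i in range(0, 60, 4):
            diverged[i] = "A" if diverged[i] != "A" else "G"
        candidate = SeqRecord("c", "", "".join(diverged))
        assert reciprocal_best_hit(candidate, refs, query_set=[near_identical]) is None
        assert reciprocal_best_hit(candidate, refs) == "A"

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError):
            reciprocal_best_hit(SeqRecord("c", "", "MK"), {"A": []})

    def test_agrees_with_exhaustive_all_pairs_oracle(self, rng):
        """Brute-force oracle: compute the full pairwise score matrix, then apply
        the forward/reverse argmax definition directly."""
        scorer = PairScorer()
        for _ in range(8):
            seqs = [SeqRecord(f"s{i}", "", random_protein_string(rng, 30)) for i in range(9)]
            refs = {"A": seqs[0:3], "B": seqs[3:6]}
            flat = seqs[0:6]
            for candidate in seqs[6:9]:
                query = seqs[6:9]
                got = reciprocal_best_hit(candidate, refs, query_set=query, scorer=scorer)
                # oracle
                fwd = [(scorer.score(candidate, r), fam) for fam in ("A", "B") for r in refs[fam]]
                top = max(s for s, _ in fwd)
                fams = {fam for s, fam in fwd if s == top}
                expected = None
                if len(fams) == 1:
                    fam = fams.pop()
                    best_ref = next(
                        r for r in refs[fam] if scorer.score(candidate, r) == top
                    )
                    rev = scorer.score(best_ref, candidate)
                    if all(
                        scorer.score(best_ref, q) < rev
                        for q in query
                        if q.id != candidate.id
                    ):
                        expected = fam
                assert got == expected


class TestTabulation:
    species = {"spX": "dicot", "spY": "monocot"}

    def rec(self, pid, fam, status, sp="spX", rbh="not_run", rank="primary"):
        return HitRecord(pid, sp, fam, 10.0, 1e-120, status, rbh, rank)

    def test_counts_accepted_hits(self):
        records = [self.rec(f"p{i}", "HDA", "accepted") for i in range(3)]
        tab = tabulate_family_sizes(records, self.species)
        assert tab.loc["spX", "HDA"] == 3
        assert tab.loc["spY", "HDA"] == 0  # zero row present, not omitted

    def test_include_review_counts_only_rbh_confirmed(self):
        records = [
            self.rec("p1", "HDA", "accepted"),
            self.rec("p2", "HDA", "review", rbh=True),
            self.rec("p3", "HDA", "review", rbh=False),
        ]
        assert tabulate_family_sizes(records, self.species).loc["spX", "HDA"] == 1
        assert tabulate_family_sizes(records, self.species, include_review=True).loc["spX", "HDA"] == 2

    def test_secondary_records_never_counted(self):
        records = [self.rec("p1", "HDA", "accepted"), self.rec("p1", "SRT", "accepted", rank="secondary")]
        tab = tabulate_family_sizes(records, self.species)
        assert tab.loc["spX", "SRT"] == 0

    def test_unknown_species_is_error(self):
        with pytest.raises(ValueError, match="unknown species"):
            tabulate_family_sizes([self.rec("p1", "HDA", "accepted", sp="nope")], self.species)

    def test_family_map_collapses_classes(self):
        records = [self.rec("p1", "HDA_classI", "accepted"), self.rec("p2", "HDA_classII", "accepted")]
        tab = tabulate_family_sizes(records, self.species, family_map={"HDA_classI": "HDA", "HDA_classII": "HDA"})
        assert tab.loc["spX", "HDA"] == 2


class TestKruskalWallis:
    def test_reference_value_two_groups(self):
        H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert H == pytest.approx(3.857, abs=5e-4)
        assert 0 < p < 1

    def test_all_tied_gives_zero_H_unit_p(self):
        H, p = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert (H, p) == (0.0, 1.0)

    def test_rank_invariance_under_within_group_permutation(self):
        H1, _ = kruskal_wallis([[3, 1, 2], [6, 4, 5]])
        H2, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert H1 == pytest.approx(H2)

    def test_compare_family_sizes_across_type_groups(self):
        import pandas as pd

        species = {f"d{i}": "dicot" for i in range(3)} | {f"a{i}": "green_algae" for i in range(3)}
        tab = pd.DataFrame(
            {"HDA": [11, 12, 11, 2, 3, 2], "SRT": [2, 2, 2, 2, 2, 2]},
            index=list(species),
        )
        results = {r.family: r for r in compare_family_sizes(tab, species, [["dicot"], ["green_algae"]])}
        assert results["HDA"].p < 0.05
        assert results["SRT"].H == 0.0 and results["SRT"].p == 1.0
        assert results["HDA"].group_sizes == (3, 3)

    def test_small_group_is_error(self):
        import pandas as pd

        species = {"d1": "dicot", "d2": "dicot", "m1": "monocot"}
        tab = pd.DataFrame({"HDA": [1, 2, 3]}, index=list(species))
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_family_sizes(tab, species, [["dicot"], ["monocot"]])
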