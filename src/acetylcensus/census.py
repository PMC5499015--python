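"""Family classification, reciprocal-best-hit validation and family-size statistics.

Candidates scored against family profiles are partitioned into three E-value
zones: accepted (E < 1e-100), review (1e-100 <= E <= 1e-3) and rejected
(E > 1e-3).  Review-zone hits carry no statistical guarantee and are validated
by a reciprocal-best-hit check against the family reference sequences before
they are counted.  Family sizes per species are tabulated into a species x
family matrix and compared across species-type groups with the tie-corrected
Kruskal-Wallis rank test (chi-square approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SeqRecord

ACCEPT_THRESHOLD = 1e-100
REVIEW_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ScoredCandidate:
    """A protein scored against one family profile."""

    protein_id: str
    species_id: str
    family: str
    score: float
    evalue: float


@dataclass(frozen=True)
class HitRecord:
    """Classified hit: E-value zone status plus optional RBH confirmation.

    ``rank`` is "primary" for the protein's best-family assignment and
    "secondary" for the other families it was scored against.
    """

    protein_id: str
    species_id: str
    family: str
    score: float
    evalue: float
    status: str                     # accepted | review | rejected
    rbh_confirmed: bool | str = "not_run"
    rank: str = "primary"


def _zone(evalue: float, accept: float, review: float) -> str:
    if evalue < accept:
        return "accepted"
    if evalue <= review:
        return "review"
    return "rejected"


def classify(
    hits: Iterable[ScoredCandidate],
    accept_threshold: float = ACCEPT_THRESHOLD,
    review_threshold: float = REVIEW_THRESHOLD,
) -> list[HitRecord]:
    """Partition scored candidates into accepted/review/rejected hit records.

    Status is a pure function of (evalue, thresholds).  A protein scored
    against several families is assigned (rank="primary") to the family with
    the minimum E-value; the remaining families are recorded with
    rank="secondary".  An exact E-value tie for the best family demotes the
    primary hit to review status.
    """
    if not accept_threshold < review_threshold:
        raise ValueError("accept_threshold must be < review_threshold")
    by_protein: dict[str, list[ScoredCandidate]] = {}
    order: list[str] = []
    for h in hits:
        if h.protein_id not in by_protein:
            order.append(h.protein_id)
        by_protein.setdefault(h.protein_id, []).append(h)

    records: list[HitRecord] = []
    for pid in order:
        cands = sorted(by_protein[pid], key=lambda c: (c.evalue, c.family))
        best = cands[0]
        status = _zone(best.evalue, accept_threshold, review_threshold)
        tied = len(cands) > 1 and cands[1].evalue == best.evalue
        if tied and status == "accepted":
            status = "review"
        records.append(
            HitRecord(best.protein_id, best.species_id, best.family, best.score, best.evalue, status)
        )
        for c in cands[1:]:
            records.append(
                HitRecord(
                    c.protein_id, c.species_id, c.family, c.score, c.evalue,
                    _zone(c.evalue, accept_threshold, review_threshold), rank="secondary",
                )
            )
    return records


# reciprocal best hit ------------------------------------------------------


class PairScorer:
    """Cached BLOSUM62 local-alignment scorer (affine -11/-1 gaps)."""

    def __init__(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        # first gapped position costs 12, each further one 1 (gap of length k: 11 + k)
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        self._aligner = aligner
        self._cache: dict[tuple[str, str], float] = {}

    def score(self, a: SeqRecord, b: SeqRecord) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        if key not in self._cache:
            self._cache[key] = float(self._aligner.score(a.sequence, b.sequence))
        return self._cache[key]


def reciprocal_best_hit(
    candidate: SeqRecord,
    family_references: Mapping[str, Sequence[SeqRecord]],
    query_set: Sequence[SeqRecord] = (),
    scorer: PairScorer | None = None,
) -> str | None:
    """Validate a candidate by reciprocal best hit against family references.

    Forward: the candidate's best-scoring reference (pairwise local alignment,
    BLOSUM62) determines the family; a score tie across different families is
    ambiguous and returns None.  Reverse: that reference, re-scored against
    the query set plus the candidate, must rank the candidate top (ties other
    than with itself fail).  Returns the confirmed family or None.
    """
    if not family_references or any(len(v) == 0 for v in family_references.values()):
        raise ValueError("reference sets must be non-empty")
    scorer = scorer or PairScorer()

    best_refs: list[tuple[str, SeqRecord]] = []
    best_score = -np.inf
    for family, refs in family_references.items():
        for ref in refs:
            s = scorer.score(candidate, ref)
            if s > best_score:
                best_score, best_refs = s, [(family, ref)]
            elif s == best_score:
                best_refs.append((family, ref))
    families = {fam for fam, _ in best_refs}
    if len(families) != 1:
        return None  # ambiguous tie across families
    family, ref = best_refs[0]

    ref_to_candidate = scorer.score(ref, candidate)
    for other in query_set:
        if other.id == candidate.id:
            continue
        if scorer.score(ref, other) >= ref_to_candidate:
            return None
    return family


def confirm_review_hits(
    records: list[HitRecord],
    proteins: Mapping[str, SeqRecord],
    family_references: Mapping[str, Sequence[SeqRecord]],
    query_sets: Mapping[str, Sequence[SeqRecord]] | None = None,
    scorer: PairScorer | None = None,
) -> list[HitRecord]:
    """Run RBH validation for primary review-zone hits; returns updated records.

    ``query_sets`` optionally maps species_id to that species' candidate
    proteins used for the reverse direction of the check.
    """
    scorer = scorer or PairScorer()
    out = []
    for rec in records:
        if rec.rank == "primary" and rec.status == "review":
            qs = query_sets.get(rec.species_id, ()) if query_sets else ()
            confirmed = reciprocal_best_hit(
                proteins[rec.protein_id], family_references, query_set=qs, scorer=scorer
            )
            out.append(replace(rec, rbh_confirmed=(confirmed == rec.family)))
        else:
            out.append(rec)
    return out


# tabulation ---------------------------------------------------------------


def tabulate_family_sizes(
    records: Iterable[HitRecord],
    species: Mapping[str, str],
    include_review: bool = False,
    family_map: Mapping[str, str] | None = None,
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count hits per (species, family) into a species x family integer matrix.

    Accepted primary hits always count; review-zone primary hits count only
    when ``include_review`` is set and the hit was RBH-confirmed.  Every
    species in the species table gets a row, zeros included.  ``family_map``
    optionally collapses profile/class labels onto top-level family names.
    """
    counted: list[tuple[str, str]] = []
    fams: set[str] = set(families or [])
    for rec in records:
        fam = family_map.get(rec.family, rec.family) if family_map else rec.family
        fams.add(fam)
        if rec.rank != "primary":
            continue
        if rec.species_id not in species:
            raise ValueError(f"protein {rec.protein_id} has unknown species {rec.species_id}")
        if rec.status == "accepted" or (
            include_review and rec.status == "review" and rec.rbh_confirmed is True
        ):
            counted.append((rec.species_id, fam))

    columns = families if families is not None else sorted(fams)
    tab = pd.DataFrame(0, index=list(species.keys()), columns=list(columns), dtype=int)
    for sp, fam in counted:
        tab.loc[sp, fam] += 1
    tab.index.name = "species_id"
    return tab


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis comparison of one family's sizes across species-type groups."""

    family: str
    H: float
    p: float
    group_sizes: tuple[int, ...]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p for >= 2 groups.

    All-tied data (zero rank variance) is the degenerate no-evidence case:
    H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    flat = [x for g in groups for x in g]
    if len(set(flat)) == 1:
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(min(p, 1.0))


def compare_family_sizes(
    tab: pd.DataFrame,
    species: Mapping[str, str],
    grouping: Sequence[Sequence[str]],
) -> list[KWResult]:
    """Kruskal-Wallis comparison of each family's per-species counts across groups.

    ``grouping`` is a list of species-type sets, e.g. [{"dicot", "monocot"},
    {"green_algae"}].  Each group must contribute >= 2 species.
    """
    if len(grouping) < 2:
        raise ValueError("need >= 2 groups of species types")
    group_members: list[list[str]] = []
    for g in grouping:
        types = set(g)
        members = [sp for sp in tab.index if species.get(sp) in types]
        if len(members) < 2:
            raise ValueError(f"group {sorted(types)} has fewer than 2 species")
        group_members.append(members)

    results = []
    for family in tab.columns:
        samples = [[float(tab.loc[sp, family]) for sp in members] for members in group_members]
        H, p = kruskal_wallis(samples)
        results.append(KWResult(family=family, H=H, p=p, group_sizes=tuple(len(s) for s in samples)))
    return results


def hit_table(records: Iterable[HitRecord]) -> pd.DataFrame:
    """Hit records as a DataFrame with the TSV column layout."""
    return pd.DataFrame(
        [
            (r.protein_id, r.species_id, r.family, r.score, r.evalue, r.status, r.rbh_confirmed, r.rank)
            for r in records
        ],
        columns=["protein_id", "species_id", "family", "score", "evalue", "status", "rbh_confirmed", "rank"],
    )
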