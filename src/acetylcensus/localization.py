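"""Consensus subcellular localization from five predictor calls.

The rule: a protein lacking an initial methionine gets no prediction at all
("unpredicted"); otherwise a compartment named by at least 3 of the 5
predictors is reported as the single location; failing that, the most and
second-most frequent compartments become primary and secondary locations.
"none" calls never enter the vote counts, but the 3-vote bar stays absolute
(3 of 5, not 3 of the non-none calls).  Count ties are broken by a fixed
compartment priority (nucleus > cytosol > mitochondrion > chloroplast >
secretory > other), making the rule a pure function of the leading residue
and the multiset of calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import COMPARTMENTS, N_PREDICTORS, SeqRecord

SINGLE_VOTE_BAR = 3

_PRIORITY = {c: i for i, c in enumerate(COMPARTMENTS)}


@dataclass(frozen=True)
class ConsensusLocalization:
    """Consensus verdict for one protein."""

    protein_id: str
    mode: str                      # single | primary_secondary | unpredicted
    primary: str | None
    secondary: str | None
    votes: dict[str, int] = field(default_factory=dict)
    low_evidence: bool = False


def consensus(protein: SeqRecord, calls: Sequence[str]) -> ConsensusLocalization:
    """Apply the 3-of-5 consensus rule to one protein's predictor calls."""
    if len(calls) != N_PREDICTORS:
        raise ValueError(f"{protein.id}: expected {N_PREDICTORS} predictor calls, got {len(calls)}")
    valid = set(COMPARTMENTS) | {"none"}
    bad = [c for c in calls if c not in valid]
    if bad:
        raise ValueError(f"{protein.id}: unknown compartment labels {bad}")
    votes = dict(Counter(c for c in calls if c != "none"))

    if not protein.sequence.startswith("M"):
        return ConsensusLocalization(protein.id, "unpredicted", None, None, votes)

    ranked = sorted(votes, key=lambda c: (-votes[c], _PRIORITY[c]))
    if ranked and votes[ranked[0]] >= SINGLE_VOTE_BAR:
        return ConsensusLocalization(protein.id, "single", ranked[0], None, votes)
    primary = ranked[0] if ranked else None
    secondary = ranked[1] if len(ranked) > 1 else None
    return ConsensusLocalization(
        protein.id, "primary_secondary", primary, secondary, votes, low_evidence=not votes
    )


def consensus_table(
    proteome: Sequence[SeqRecord], table: Mapping[str, Mapping[str, str]]
) -> list[ConsensusLocalization]:
    """Consensus verdicts for a whole proteome, one row per protein.

    ``table`` maps protein_id -> {predictor: call}; predictor order is
    insignificant (votes are counted, not positional).  Proteins missing from
    the table are a hard error listing the ids.
    """
    missing = sorted(p.id for p in proteome if p.id not in table)
    if missing:
        raise ValueError(f"proteins without predictions: {', '.join(missing)}")
    return [consensus(p, list(table[p.id].values())) for p in proteome]


def consensus_frame(results: Sequence[ConsensusLocalization]) -> pd.DataFrame:
    """Consensus results as a DataFrame matching the output TSV layout."""
    import json

    return pd.DataFrame(
        [
            (r.protein_id, r.mode, r.primary or "", r.secondary or "", json.dumps(r.votes, sort_keys=True))
            for r in results
        ],
        columns=["protein_id", "mode", "primary", "secondary", "votes_json"],
    )
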