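"""Position-specific profile models for protein family detection.

A profile is built from a seed multiple alignment: alignment columns with
fewer than 50% gaps become match columns, each carrying per-residue emission
probabilities (maximum a posteriori with a Dirichlet-like pseudocount toward
the background) expressed as natural-log odds against the background.
Candidate proteins are scored by affine-gap local alignment against the
profile, and scores are turned into E-values through a seeded Gumbel
(extreme-value) calibration on random background sequences.

The gap model follows the BLOSUM62 convention: a gap of length k costs
11 + k on the log-odds scale (gap_open = -11 charged once per gap, plus
gap_extend = -1 per gapped position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Robinson & Robinson style background amino-acid frequencies (normalized).
_BACKGROUND = {
    "A": 0.0780, "C": 0.0193, "D": 0.0537, "E": 0.0629, "F": 0.0386,
    "G": 0.0737, "H": 0.0219, "I": 0.0514, "K": 0.0574, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0711, "T": 0.0584, "V": 0.0644, "W": 0.0132, "Y": 0.0321,
}

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0


def background_frequencies() -> np.ndarray:
    """The built-in background amino-acid frequency vector (sums to 1)."""
    bg = np.array([_BACKGROUND[aa] for aa in AMINO_ACIDS], dtype=float)
    return bg / bg.sum()


def encode_protein(sequence: str) -> np.ndarray:
    """Encode a protein string as indices into AMINO_ACIDS; unknowns (X) -> -1."""
    return np.array([AA_INDEX.get(aa, -1) for aa in sequence], dtype=np.int64)


@dataclass(frozen=True)
class SeedAlignment:
    """A family's seed multiple alignment: equal-length gapped rows."""

    family: str
    rows: tuple[SeqRecord, ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError(f"seed alignment {self.family}: need >= 2 rows")
        lengths = {len(r.sequence) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"seed alignment {self.family}: rows have unequal lengths {sorted(lengths)}")
        n = len(self.rows)
        width = lengths.pop()
        usable = 0
        for j in range(width):
            gaps = sum(1 for r in self.rows if r.sequence[j] in "-.")
            if gaps / n < 0.5:
                usable += 1
        if usable == 0:
            raise ValueError(f"seed alignment {self.family}: no column with <50% gaps")

    @property
    def width(self) -> int:
        return len(self.rows[0].sequence)


@dataclass
class ProfileModel:
    """Per-column emission model with log-odds scores against the background."""

    family: str
    emissions: np.ndarray          # (n_columns, 20) probabilities, rows sum to 1
    log_odds: np.ndarray           # (n_columns, 20) natural-log odds vs background
    background: np.ndarray         # (20,) frequencies
    pseudocount: float
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND

    @property
    def n_columns(self) -> int:
        return self.emissions.shape[0]


def build_profile(
    alignment: SeedAlignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProfileModel:
    """Build a :class:`ProfileModel` from a seed alignment.

    Columns with >= 50% gaps are dropped from the match states.  For a kept
    column, emission(a) = (count_a + pseudocount * bg_a) / (n_observed +
    pseudocount), so emissions sum to one exactly and shrink toward the
    background as observations thin out.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = background_frequencies() if background is None else np.asarray(background, dtype=float)
    if bg.shape != (20,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 20-vector summing to 1")

    n_rows = len(alignment.rows)
    cols = []
    for j in range(alignment.width):
        residues = [r.sequence[j] for r in alignment.rows]
        gaps = sum(1 for c in residues if c in "-.")
        if gaps / n_rows >= 0.5:
            continue
        counts = np.zeros(20)
        for c in residues:
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1.0
        n_obs = counts.sum()
        cols.append((counts + pseudocount * bg) / (n_obs + pseudocount))
    if not cols:
        raise ValueError(f"alignment {alignment.family}: no usable columns")
    emissions = np.array(cols)
    log_odds = np.log(emissions) - np.log(bg)[None, :]
    return ProfileModel(
        family=alignment.family,
        emissions=emissions,
        log_odds=log_odds,
        background=bg,
        pseudocount=pseudocount,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def _encode_any(protein: SeqRecord | str | np.ndarray) -> np.ndarray:
    if isinstance(protein, SeqRecord):
        return encode_protein(protein.sequence)
    if isinstance(protein, str):
        return encode_protein(protein)
    return np.asarray(protein, dtype=np.int64)


def score_proteins(profile: ProfileModel, proteins: "list | tuple") -> np.ndarray:
    """Local-alignment log-odds scores of many proteins against one profile.

    Batched Smith-Waterman-style dynamic programming over (residue, match
    column) with affine gaps; alignments start and end in a match state.
    Sequences are right-padded to a common length with a sentinel whose
    emission is -inf, which leaves every score exactly equal to the
    single-sequence computation.  A residue unknown to the alphabet (X)
    scores 0 (background-neutral).
    """
    encoded = [_encode_any(p) for p in proteins]
    if any(e.shape[0] == 0 for e in encoded):
        raise ValueError("cannot score an empty sequence")
    n = len(encoded)
    if n == 0:
        return np.zeros(0)
    L = max(e.shape[0] for e in encoded)
    codes = np.full((n, L), -2, dtype=np.int64)          # -2 = padding
    for i, e in enumerate(encoded):
        codes[i, : e.shape[0]] = e

    go = profile.gap_open + profile.gap_extend   # first gapped position
    ge = profile.gap_extend                      # each further gapped position
    neg = -np.inf
    lo = profile.log_odds
    gather = np.where(codes >= 0, codes, 0)
    unknown = codes == -1
    pad = codes == -2
    idx = np.arange(L, dtype=float)
    ins_start = go - ge * idx                    # added to m for the Ix running max
    ix_base = ge * (idx - 1.0)

    prev_m = np.full((n, L), neg)
    prev_ix = np.full((n, L), neg)
    prev_iy = np.full((n, L), neg)
    best = np.full(n, neg)
    for j in range(profile.n_columns):
        emis = lo[j].take(gather)
        emis[unknown] = 0.0
        emis[pad] = neg
        # M: match residue i with column j; may start fresh (local, floor 0)
        diag = np.zeros((n, L))
        if j > 0:
            stacked = np.maximum(np.maximum(prev_m, prev_ix), prev_iy)
            diag[:, 1:] = np.maximum(0.0, stacked[:, :-1])
        m = emis + diag
        # Iy: column j consumed by a deletion (no residue)
        iy = np.maximum(prev_m + go, prev_iy + ge) if j > 0 else np.full((n, L), neg)
        # Ix: residue i consumed by an insertion after column j;
        # Ix[i] = max_{k<=i-1} m[k] + go + ge*(i-1-k), via a running max.
        run = np.maximum.accumulate(m + ins_start, axis=1)
        ix = np.full((n, L), neg)
        if L > 1:
            ix[:, 1:] = run[:, :-1] + ix_base[1:]
        np.maximum(best, m.max(axis=1), out=best)
        prev_m, prev_ix, prev_iy = m, ix, iy
    return best


def score_protein(profile: ProfileModel, protein: SeqRecord | str | np.ndarray) -> float:
    """Best local-alignment log-odds score of one protein against the profile.

    Deterministic; raises on empty sequence.  See :func:`score_proteins` for
    the alignment model.
    """
    return float(score_proteins(profile, [protein])[0])


@dataclass(frozen=True)
class GumbelCalibration:
    """Gumbel (extreme-value) score calibration for one family profile."""

    family: str
    mu: float
    lam: float
    n_random: int
    length: int
    seed: int


def calibrate_evalue(
    profile: ProfileModel, n_random: int = 1000, length: int = 350, seed: int = 0
) -> GumbelCalibration:
    """Fit a Gumbel law to scores of random background sequences (method of moments).

    lambda = pi / (sigma * sqrt(6)), mu = mean - gamma / lambda, from the
    scores of ``n_random`` i.i.d. background sequences of the given length.
    Seeded and reproducible; degenerate (zero-variance) score sets are an error.
    """
    if n_random < 200:
        raise ValueError("n_random must be >= 200 for a usable calibration")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = rng.choice(20, size=(n_random, length), p=profile.background)
    chunk = max(1, int(2_000_000 / max(1, length)))
    scores = np.concatenate(
        [score_proteins(profile, list(seqs[i : i + chunk])) for i in range(0, n_random, chunk)]
    )
    sigma = float(scores.std(ddof=1))
    if sigma == 0.0:
        raise ValueError(f"degenerate score distribution for family {profile.family}")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(scores.mean()) - np.euler_gamma / lam
    return GumbelCalibration(
        family=profile.family, mu=mu, lam=lam, n_random=n_random, length=length, seed=seed
    )


def evalue(calibration: GumbelCalibration, score: float, db_size: int) -> float:
    """E-value of a score: db_size * P(Gumbel >= score), clamped to [0, db_size].

    E = db_size * (1 - exp(-exp(-lambda (score - mu)))); monotone decreasing
    in score.  For strong scores this is effectively db_size *
    exp(-lambda (score - mu)).
    """
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    z = calibration.lam * (score - calibration.mu)
    # 1 - exp(-exp(-z)) computed stably: for large z -> exp(-z); for very
    # negative z the tail saturates at 1.
    if z > 40.0:
        tail = math.exp(-z)
    elif z < -40.0:
        tail = 1.0
    else:
        tail = -math.expm1(-math.exp(-z))
    e = db_size * tail
    return min(max(e, 0.0), float(db_size))
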