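"""Domain-architecture profiles per (family, species type) group.

Summarizes a group of proteins as its exact median length (lower median for
even group sizes, so the value is an attained protein length), per-domain
prevalence (fraction of proteins carrying at least one copy) and a binned
positional frequency histogram after rescaling every domain interval to the
group median length.  Domains present in fewer than 5% of the group's
proteins are filtered out after prevalence is computed, so denominators are
always the full group size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import DomainAnnotation, SeqRecord, write_tsv

logger = logging.getLogger(__name__)

DEFAULT_BINS = 100
MIN_PREVALENCE = 0.05


@dataclass(frozen=True)
class GroupKey:
    """A (family, species_type) cell of the domain-architecture figures."""

    family: str
    species_type: str


@dataclass
class DomainProfile:
    """Positional domain summary for one group of proteins.

    ``positional_frequency`` holds the per-protein histogram (fraction of
    proteins whose rescaled domain interval overlaps each bin); the
    per-occurrence variant counts every domain copy separately.
    """

    group: GroupKey
    n_proteins: int
    median_length: int
    bins: int
    prevalence: dict[str, float] = field(default_factory=dict)
    positional_frequency: dict[str, np.ndarray] = field(default_factory=dict)
    occurrence_frequency: dict[str, np.ndarray] = field(default_factory=dict)


def median_length(proteins: Sequence[SeqRecord]) -> int:
    """Exact median of protein lengths; lower of the two middle values for even n."""
    if not proteins:
        raise ValueError("empty group")
    lengths = sorted(len(p) for p in proteins)
    return lengths[(len(lengths) - 1) // 2]


def rescale_domain(annotation: DomainAnnotation, protein_length: int, median: int) -> tuple[float, float]:
    """Scale a domain interval from its protein's length to the group median.

    s = start / L * median, e = end / L * median (real-valued); the mapping is
    monotone, so nesting is preserved.
    """
    if median < 1:
        raise ValueError("median must be >= 1")
    if not (1 <= annotation.start <= annotation.end <= protein_length):
        raise ValueError(
            f"domain {annotation.domain_name} [{annotation.start},{annotation.end}] "
            f"outside protein of length {protein_length}"
        )
    scale = median / protein_length
    return annotation.start * scale, annotation.end * scale


def _bin_span(s: float, e: float, width: float, n_bins: int) -> tuple[int, int]:
    """Indices [first, last] of the bins overlapped by interval [s, e]."""
    first = min(int(np.floor(s / width)), n_bins - 1)
    last = min(int(np.ceil(e / width)) - 1, n_bins - 1)
    return first, max(last, first)


def profile_group(
    proteins: Sequence[SeqRecord],
    annotations: Iterable[DomainAnnotation],
    group: GroupKey,
    bins: int = DEFAULT_BINS,
    min_prevalence: float = MIN_PREVALENCE,
) -> DomainProfile:
    """Build the :class:`DomainProfile` for one group.

    prevalence(d) is the fraction of group proteins with >= 1 annotation of d
    (a protein with multiple copies counts once); domains below
    ``min_prevalence`` are dropped after that computation.  Bins partition
    [0, median] evenly; the per-protein frequency of bin b is the fraction of
    proteins whose rescaled interval(s) of d overlap b.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if not proteins:
        raise ValueError("empty group")
    lengths = {p.id: len(p) for p in proteins}
    ann_by_domain: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        if ann.protein_id not in lengths:
            raise ValueError(f"annotation for {ann.protein_id} outside group {group}")
        ann_by_domain.setdefault(ann.domain_name, []).append(ann)

    n = len(proteins)
    med = median_length(proteins)
    width = med / bins
    profile = DomainProfile(group=group, n_proteins=n, median_length=med, bins=bins)

    for domain in sorted(ann_by_domain):
        anns = ann_by_domain[domain]
        carriers = {a.protein_id for a in anns}
        prev = len(carriers) / n
        if prev < min_prevalence:
            continue
        per_protein = {pid: np.zeros(bins, dtype=bool) for pid in carriers}
        per_occurrence = np.zeros(bins)
        for a in anns:
            s, e = rescale_domain(a, lengths[a.protein_id], med)
            first, last = _bin_span(s, e, width, bins)
            per_protein[a.protein_id][first : last + 1] = True
            per_occurrence[first : last + 1] += 1.0
        stacked = np.stack(list(per_protein.values()))
        profile.prevalence[domain] = prev
        profile.positional_frequency[domain] = stacked.sum(axis=0) / n
        profile.occurrence_frequency[domain] = per_occurrence / n
    return profile


def render_profile(
    profile: DomainProfile, out_tsv: str | Path, out_image: str | Path | None = None
) -> None:
    """Write the profile's bin values as TSV; optionally draw the histogram.

    The TSV (group, domain, prevalence, bin_index, frequency) always carries
    ``bins`` rows per retained domain; an all-filtered profile yields a
    header-only file with a warning.  The image is cosmetic.
    """
    rows = []
    for domain in sorted(profile.prevalence):
        prev = profile.prevalence[domain]
        freqs = profile.positional_frequency[domain]
        for b in range(profile.bins):
            rows.append(
                (profile.group.family, profile.group.species_type, domain,
                 f"{prev:.6g}", b, f"{freqs[b]:.6g}")
            )
    if not rows:
        logger.warning("profile for %s has no domains above the prevalence floor", profile.group)
    write_tsv(out_tsv, ("family", "species_type", "domain", "prevalence", "bin_index", "frequency"), rows)

    if out_image is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 2.5))
        x = (np.arange(profile.bins) + 0.5) * profile.median_length / profile.bins
        ax.hlines(0, 0, profile.median_length, colors="black", linewidth=3)
        for domain, freqs in profile.positional_frequency.items():
            ax.bar(x, freqs, width=profile.median_length / profile.bins, alpha=0.6, label=domain)
        ax.set_xlabel(f"position (aa, median length {profile.median_length})")
        ax.set_ylabel("fraction of proteins")
        ax.set_title(f"{profile.group.family} / {profile.group.species_type} (n={profile.n_proteins})")
        if profile.positional_frequency:
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_image, dpi=120)
        plt.close(fig)


def group_proteins(
    proteins: Mapping[str, SeqRecord],
    membership: Mapping[str, str],
    species_types: Mapping[str, str],
    protein_species: Mapping[str, str],
) -> dict[GroupKey, list[SeqRecord]]:
    """Partition family-member proteins into (family, species_type) groups."""
    groups: dict[GroupKey, list[SeqRecord]] = {}
    for pid, family in membership.items():
        sp = protein_species[pid]
        key = GroupKey(family=family, species_type=species_types[sp])
        groups.setdefault(key, []).append(proteins[pid])
    return groups
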