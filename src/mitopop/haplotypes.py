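"""Haplotype collapsing, frequency tabulation and private/shared status.

Sequences that are identical over the filtered sites share a haplotype.
Haplotypes are labelled H1..Hh in order of first occurrence in the input; the
labels carry no meaning beyond that ordering. A haplotype is *private* when it
is observed in exactly one population and *shared* otherwise; a *singleton*
has global count 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import AlignmentMatrix, PopulationMap

__all__ = [
    "HaplotypeTable",
    "HaplotypeSharingSummary",
    "collapse_haplotypes",
    "classify_sharing",
    "segregating_sites",
]


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-population counts and memberships."""

    labels: list[str]  # H1..Hh, first-occurrence order
    sequences: list[str]  # one per haplotype, over {A,C,G,T}
    members: list[list[str]]  # sample ids carrying each haplotype
    counts: pd.DataFrame  # index: labels, columns: populations, integer counts
    subpop_counts: pd.DataFrame  # same but per subpopulation

    @property
    def h(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    def frequencies(self, population: str | None = None) -> np.ndarray:
        """Relative haplotype frequencies p_i, pooled or within one population."""
        if population is None:
            c = self.total_counts
        else:
            c = self.counts[population].to_numpy()
        tot = c.sum()
        if tot == 0:
            raise ValueError(f"no samples in unit {population!r}")
        return c / tot

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "sequence", self.sequences)
        df.insert(1, "total_count", self.total_counts)
        return df


@dataclass
class HaplotypeSharingSummary:
    """Private/shared classification of haplotypes across populations."""

    status: dict[str, str]  # label -> "private" | "shared"
    presence: pd.DataFrame  # boolean label x population presence pattern
    private_by_population: dict[str, int]
    private_percent: float
    shared_percent: float
    singletons: list[str]  # labels with global count 1
    #: per haplotype, percentage of all haplotypes it represents, keyed by the
    #: exact set of populations it occurs in (full presence/absence pattern)
    pattern_percent: dict[frozenset, float]


def collapse_haplotypes(alignment: AlignmentMatrix, popmap: PopulationMap) -> HaplotypeTable:
    """Collapse identical rows of a gap-free alignment into haplotypes."""
    popmap.validate_against(alignment.ids)
    seqs = alignment.sequences()
    order: dict[str, int] = {}
    members: list[list[str]] = []
    for sid, seq in zip(alignment.ids, seqs):
        k = order.get(seq)
        if k is None:
            order[seq] = len(members)
            members.append([sid])
        else:
            members[k].append(sid)
    hap_seqs = list(order)
    labels = [f"H{i + 1}" for i in range(len(hap_seqs))]

    pops = popmap.populations()
    subs = popmap.subpopulations()
    counts = pd.DataFrame(0, index=labels, columns=pops, dtype=int)
    sub_counts = pd.DataFrame(0, index=labels, columns=subs, dtype=int)
    for lab, mem in zip(labels, members):
        for sid in mem:
            counts.loc[lab, popmap.population[sid]] += 1
            sub_counts.loc[lab, popmap.subpopulation[sid]] += 1
    return HaplotypeTable(labels, hap_seqs, members, counts, sub_counts)


def classify_sharing(table: HaplotypeTable, popmap: PopulationMap) -> HaplotypeSharingSummary:
    """Tag each haplotype private (one population) or shared (several).

    With a single population every haplotype is private by definition.
    Percentages are fractions of the total haplotype count, reported to full
    precision (round for display).
    """
    presence = table.counts > 0
    n_pops_per_hap = presence.sum(axis=1)
    status = {
        lab: ("private" if k <= 1 else "shared")
        for lab, k in n_pops_per_hap.items()
    }
    private_by_pop = {
        pop: int(((presence[pop]) & (n_pops_per_hap == 1)).sum())
        for pop in table.counts.columns
    }
    h = table.h
    n_private = sum(1 for s in status.values() if s == "private")
    private_pct = 100.0 * n_private / h
    patterns: dict[frozenset, int] = {}
    for lab in table.labels:
        pat = frozenset(presence.columns[presence.loc[lab]])
        patterns[pat] = patterns.get(pat, 0) + 1
    singletons = [lab for lab, c in zip(table.labels, table.total_counts) if c == 1]
    return HaplotypeSharingSummary(
        status=status,
        presence=presence,
        private_by_population=private_by_pop,
        private_percent=private_pct,
        shared_percent=100.0 - private_pct,
        singletons=singletons,
        pattern_percent={p: 100.0 * c / h for p, c in patterns.items()},
    )


def segregating_sites(alignment: AlignmentMatrix) -> tuple[int, list[int]]:
    """Number of polymorphic columns S and their 1-based positions."""
    mat = alignment.matrix
    poly = (mat != mat[0]).any(axis=0)
    positions = [int(i) + 1 for i in np.nonzero(poly)[0]]
    return len(positions), positions
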