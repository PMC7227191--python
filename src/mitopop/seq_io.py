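"""Sequence and population-map input.

Reads aligned same-locus nucleotide sequences (multi-FASTA) together with a
three-level population map (subpopulation -> population -> group) and applies
the complete-deletion site filter: every alignment column containing a gap,
``N`` or any IUPAC ambiguity code in *any* sequence is removed before analysis,
so that downstream statistics operate on a clean {A,C,G,T} matrix.

Coordinates are 0-based half-open internally; any reported site positions are
1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AlignmentMatrix",
    "PopulationMap",
    "read_fasta",
    "read_popmap",
    "popmap_from_prefixes",
    "complete_deletion",
]

#: characters permitted in raw input (IUPAC nucleotide codes, N, gap)
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN-")
#: characters that survive complete deletion
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (e.g. one cox1 amplicon)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has empty identifier")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - IUPAC_CHARS
        if bad:
            raise ValueError(
                f"invalid residue {sorted(bad)} in sequence {self.id!r}: "
                "expected IUPAC nucleotide codes"
            )


@dataclass
class AlignmentMatrix:
    """n aligned sequences over L sites, as an (n, L) array of single chars.

    After :func:`complete_deletion` every cell is in {A,C,G,T}.
    """

    ids: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n, L)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate identifier in alignment")
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise ValueError("alignment must have at least one row and column")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> str:
        return "".join(self.matrix[self.ids.index(sample_id)])

    def sequences(self) -> list[str]:
        return ["".join(r) for r in self.matrix]

    def subset(self, keep_ids: Sequence[str]) -> "AlignmentMatrix":
        """Row subset preserving this alignment's row order."""
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.ids) if s in keep]
        missing = keep - {self.ids[i] for i in idx}
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return AlignmentMatrix([self.ids[i] for i in idx], self.matrix[idx])

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "AlignmentMatrix":
        records = list(records)
        if not records:
            raise ValueError("no sequences")
        lengths = {len(r.residues) for r in records}
        if len(lengths) > 1:
            raise ValueError(
                f"sequences of unequal length {sorted(lengths)}: inputs must be "
                "pre-aligned, equal-length amplicons"
            )
        mat = np.array([list(r.residues) for r in records], dtype="<U1")
        return cls([r.id for r in records], mat)


@dataclass
class PopulationMap:
    """Three-level sample hierarchy: sample -> subpopulation -> population -> group."""

    subpopulation: dict[str, str]
    population: dict[str, str]
    group: dict[str, str]
    #: retained for reporting; insertion order of first appearance
    _sub_to_pop: dict[str, str] = field(default_factory=dict)
    _pop_to_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, sub in self.subpopulation.items():
            pop = self.population[sample]
            grp = self.group[sample]
            prev = self._sub_to_pop.setdefault(sub, pop)
            if prev != pop:
                raise ValueError(
                    f"inconsistent hierarchy: subpopulation {sub!r} assigned to "
                    f"populations {prev!r} and {pop!r}"
                )
            prevg = self._pop_to_group.setdefault(pop, grp)
            if prevg != grp:
                raise ValueError(
                    f"inconsistent hierarchy: population {pop!r} assigned to "
                    f"groups {prevg!r} and {grp!r}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.subpopulation)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population.values()))

    def subpopulations(self) -> list[str]:
        return list(dict.fromkeys(self.subpopulation.values()))

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.group.values()))

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.population.items() if p == population]

    def subpop_members(self, subpopulation: str) -> list[str]:
        return [s for s, p in self.subpopulation.items() if p == subpopulation]

    def restrict(self, samples: Sequence[str]) -> "PopulationMap":
        keep = [s for s in self.samples if s in set(samples)]
        return PopulationMap(
            {s: self.subpopulation[s] for s in keep},
            {s: self.population[s] for s in keep},
            {s: self.group[s] for s in keep},
        )

    def validate_against(self, ids: Sequence[str]) -> None:
        missing = [s for s in ids if s not in self.subpopulation]
        if missing:
            raise ValueError(f"missing assignment for samples: {missing[:5]}")

    def with_grouping(self, pop_to_group: Mapping[str, str]) -> "PopulationMap":
        """Same sample/population structure under an alternative group layer
        (e.g. the ecological regrouping of populations)."""
        unknown = set(self.populations()) - set(pop_to_group)
        if unknown:
            raise ValueError(f"no group given for populations: {sorted(unknown)}")
        return PopulationMap(
            dict(self.subpopulation),
            dict(self.population),
            {s: pop_to_group[p] for s, p in self.population.items()},
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA into uppercased :class:`SequenceRecord` objects.

    Order is preserved; duplicate identifiers and non-IUPAC residues are
    rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def read_popmap(path: str | Path, records: Sequence[SequenceRecord] | None = None) -> PopulationMap:
    """Read a tab-separated population map.

    Expected columns: ``sample_id``, ``subpopulation``, ``population``,
    ``group`` (header row required). If ``records`` is given, every record id
    must be assigned.
    """
    sub: dict[str, str] = {}
    pop: dict[str, str] = {}
    grp: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "subpopulation", "population", "group"]
        if [h.strip() for h in header] != expected:
            raise ValueError(f"popmap header must be {expected!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"popmap line {lineno}: expected 4 columns")
            sample, s, p, g = (x.strip() for x in parts)
            if sample in sub:
                raise ValueError(f"duplicate sample {sample!r} in popmap")
            sub[sample], pop[sample], grp[sample] = s, p, g
    pm = PopulationMap(sub, pop, grp)
    if records is not None:
        pm.validate_against([r.id for r in records])
    return pm


def popmap_from_prefixes(records: Sequence[SequenceRecord]) -> PopulationMap:
    """Convenience mapping from the leading alphabetic prefix of sample codes
    (field codes such as BMSA65 / BEMB402 / TLG103 encode the sampling block).

    Each prefix becomes simultaneously the subpopulation, population and group
    label; use :meth:`PopulationMap.with_grouping` for coarser groupings.
    """
    sub: dict[str, str] = {}
    for r in records:
        prefix = "".join(c for c in r.id if c.isalpha())
        prefix = prefix or r.id
        sub[r.id] = prefix
    return PopulationMap(dict(sub), dict(sub), dict(sub))


def complete_deletion(
    alignment: AlignmentMatrix,
) -> tuple[AlignmentMatrix, np.ndarray]:
    """Drop every column containing any character outside {A,C,G,T}.

    Gaps, ``N`` and IUPAC ambiguity codes all count as missing data; a column
    is removed if any row is missing there. Returns the filtered alignment and
    the 0-based indices of retained columns (idempotent: a clean alignment is
    returned unchanged).
    """
    mat = alignment.matrix
    clean = np.isin(mat, list(UNAMBIGUOUS))
    ok = clean.all(axis=0)
    kept = np.nonzero(ok)[0]
    if kept.size == 0:
        raise ValueError("no analyzable sites: every column contains missing data")
    return AlignmentMatrix(list(alignment.ids), mat[:, kept]), kept
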