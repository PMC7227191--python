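"""Pairwise-difference matrix and standard diversity indices.

For n aligned sequences over L clean sites:

* ``d_ij`` — count of differing sites between sequences i and j (Hamming),
* ``K``   — mean pairwise difference, (2 / n(n-1)) * sum_{i<j} d_ij,
* ``pi``  — nucleotide diversity per site, K / L,
* ``Hd``  — haplotype diversity, n (1 - sum p_i^2) / (n - 1) over haplotype
  frequencies p_i (unbiased; the probability that two random sequences carry
  different haplotypes).

No multiple-hit correction is applied by default: values are raw counts, the
convention of the diversity tables this package mirrors. A Jukes-Cantor
corrected pi is available behind an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .haplotypes import HaplotypeTable, collapse_haplotypes, segregating_sites
from .seq_io import AlignmentMatrix, PopulationMap

__all__ = [
    "DistanceMatrix",
    "DiversitySummary",
    "pairwise_differences",
    "summarize_diversity",
]


@dataclass
class DistanceMatrix:
    """Symmetric integer matrix of pairwise nucleotide-difference counts."""

    ids: list[str]
    d: np.ndarray  # (n, n) int
    L: int

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def submatrix(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep_ids]
        return DistanceMatrix(list(keep_ids), self.d[np.ix_(idx, idx)], self.L)

    def mean_pairwise(self) -> float:
        n = self.n
        if n < 2:
            raise ValueError("insufficient sequences: need n >= 2")
        iu = np.triu_indices(n, k=1)
        return float(self.d[iu].sum()) * 2.0 / (n * (n - 1))


@dataclass
class DiversitySummary:
    unit: str
    n: int
    h: int
    S: int
    K: float
    pi: float
    Hd: float
    L: int


def pairwise_differences(alignment: AlignmentMatrix) -> DistanceMatrix:
    """Exact Hamming difference counts over all sequence pairs."""
    if alignment.n < 2:
        raise ValueError("insufficient sequences: need n >= 2")
    # '<U1' stores one uint32 code point per cell, so this view is (n, L)
    codes = alignment.matrix.view(np.uint32)
    d = np.zeros((alignment.n, alignment.n), dtype=np.int64)
    # block the comparison to bound memory on large n
    block = max(1, int(4e7) // max(1, alignment.n * alignment.L))
    for start in range(0, alignment.n, block):
        stop = min(alignment.n, start + block)
        d[start:stop] = (codes[start:stop, None, :] != codes[None, :, :]).sum(axis=2)
    return DistanceMatrix(list(alignment.ids), d, alignment.L)


def haplotype_diversity(counts: np.ndarray) -> float:
    """Nei's unbiased haplotype (gene) diversity from haplotype counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("insufficient sequences: need n >= 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def summarize_diversity(
    alignment: AlignmentMatrix,
    table: HaplotypeTable | None = None,
    unit: str = "pooled",
    jukes_cantor: bool = False,
) -> DiversitySummary:
    """Table-1-style indices (n, h, S, K, pi, Hd) for one analysis unit.

    ``table`` may be passed to reuse an existing haplotype collapse; otherwise
    the alignment is collapsed with a trivial single-population map.
    """
    if alignment.n < 2:
        raise ValueError("insufficient sequences: need n >= 2")
    if table is None:
        pm = PopulationMap(
            {s: unit for s in alignment.ids},
            {s: unit for s in alignment.ids},
            {s: unit for s in alignment.ids},
        )
        table = collapse_haplotypes(alignment, pm)
    S, _ = segregating_sites(alignment)
    dist = pairwise_differences(alignment)
    K = dist.mean_pairwise()
    pi = K / alignment.L
    if jukes_cantor:
        pi = -0.75 * math.log1p(-4.0 * pi / 3.0)
    Hd = haplotype_diversity(table.total_counts)
    return DiversitySummary(unit, alignment.n, table.h, S, K, pi, Hd, alignment.L)
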