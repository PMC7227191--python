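"""Haploid coalescent data generator.

Generates FASTA + population-map fixtures with the statistical structure the
analysis assumes: island-model population structure across demes, optional
instantaneous (sudden) expansion, and finite-sites sequences of a fixed locus
length. Mutations are placed on genealogy branches and each is assigned a
distinct uniformly chosen site (collisions redrawn), so pairwise sequence
differences equal mutation-path lengths — the infinite-sites behaviour the
neutrality tests assume — while still emitting valid nucleotide FASTA.

Scales: time is measured in per-deme coalescent units (a within-deme pair
coalesces at rate 1); ``theta`` is the scaled per-locus mutation rate on that
scale (single constant deme: E[K] = theta, E[S] = theta * a1(n)); ``migration``
is the scaled rate M = 2Nm, each lineage migrating at rate M/2, so the
island-model gene-flow conversions in :mod:`mitopop.differentiation` apply
directly with Nm = M/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import coalescent
from .seq_io import AlignmentMatrix, PopulationMap

__all__ = [
    "CoalescentConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_fixed_s",
    "make_study_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CoalescentConfig:
    """Study-design parameters for one simulated dataset.

    ``expansion`` is (time, magnitude): an instantaneous ``magnitude``-fold
    size increase ``time`` mutational units ago (the scale of the mismatch
    parameter tau), applied to the demes listed in ``expanded_demes`` (all
    demes when None).
    """

    sample_sizes: Sequence[int] = (20,)
    theta: float = 5.0
    migration: float = 1.0
    expansion: tuple[float, float] | None = None
    expanded_demes: Sequence[int] | None = None
    L: int = 570
    seed: int | None = None
    deme_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.migration < 0:
            raise ValueError("migration must be non-negative")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.expansion is not None:
            t, mag = self.expansion
            if t < 0 or mag <= 0:
                raise ValueError("expansion time must be >= 0 and magnitude > 0")
        if self.L < 1:
            raise ValueError("locus length must be positive")


@dataclass
class SimulatedDataset:
    alignment: AlignmentMatrix
    popmap: PopulationMap
    config: CoalescentConfig
    tmrca: float
    total_branch_length: float
    n_mutations: int

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA + popmap TSV + true-parameter YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "sequences.fasta"
        with open(fasta, "w") as fh:
            for sid, row in zip(self.alignment.ids, self.alignment.sequences()):
                fh.write(f">{sid}\n{row}\n")
        popmap = outdir / "popmap.tsv"
        with open(popmap, "w") as fh:
            fh.write("sample_id\tsubpopulation\tpopulation\tgroup\n")
            for s in self.popmap.samples:
                fh.write(
                    f"{s}\t{self.popmap.subpopulation[s]}\t"
                    f"{self.popmap.population[s]}\t{self.popmap.group[s]}\n"
                )
        params = outdir / "true_parameters.yaml"
        cfg = self.config
        with open(params, "w") as fh:
            yaml.safe_dump(
                {
                    "sample_sizes": list(map(int, cfg.sample_sizes)),
                    "theta": float(cfg.theta),
                    "migration": float(cfg.migration),
                    "expansion": list(cfg.expansion) if cfg.expansion else None,
                    "L": int(cfg.L),
                    "seed": cfg.seed,
                    "tmrca": float(self.tmrca),
                    "total_branch_length": float(self.total_branch_length),
                    "n_mutations": int(self.n_mutations),
                },
                fh,
            )
        return {"fasta": fasta, "popmap": popmap, "params": params}


def _sequences_from_mutations(
    gen: coalescent.Genealogy,
    branches: np.ndarray,
    L: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emit an (n, L) character matrix from an all-A ancestral sequence.

    Each mutation gets a distinct site (uniform, collisions redrawn) and a
    random non-ancestral target base on that site's current background.
    """
    n = gen.n
    S = len(branches)
    if S > L:
        raise ValueError(f"cannot place {S} mutations on {L} sites")
    sites: list[int] = []
    used: set[int] = set()
    while len(sites) < S:
        s = int(rng.integers(L))
        if s not in used:
            used.add(s)
            sites.append(s)
    mat = np.full((n, L), "A", dtype="<U1")
    children: dict[int, list[int]] = {}
    for v in range(2 * n - 2):
        children.setdefault(int(gen.parent[v]), []).append(v)
    for b, site in zip(branches, sites):
        alt = _BASES[_BASES != "A"][rng.integers(3)]
        stack = [int(b)]
        while stack:
            v = stack.pop()
            if v < n:
                mat[v, site] = alt
            else:
                stack.extend(children[v])
    return mat


def simulate_dataset(config: CoalescentConfig) -> SimulatedDataset:
    """Simulate one structured-coalescent dataset per ``config``."""
    rng = np.random.default_rng(config.seed)
    d = len(config.sample_sizes)
    names = list(config.deme_names) if config.deme_names else [
        f"pop{i + 1}" for i in range(d)
    ]

    profiles = None
    if config.expansion is not None:
        t_mut, mag = config.expansion
        t_coal = t_mut / config.theta  # mutational -> coalescent units
        expanded = (
            set(range(d))
            if config.expanded_demes is None
            else set(config.expanded_demes)
        )
        profiles = [
            (((0.0, 1.0), (t_coal, 1.0 / mag)) if i in expanded else ((0.0, 1.0),))
            for i in range(d)
        ]

    if d == 1:
        gen = coalescent.sim_tree(
            int(config.sample_sizes[0]), rng,
            size_profile=profiles[0] if profiles else ((0.0, 1.0),),
        )
    else:
        gen = coalescent.sim_island_tree(
            config.sample_sizes, config.migration, rng, size_profiles=profiles
        )
    branches = coalescent.place_poisson_mutations(gen, config.theta, rng)
    mat = _sequences_from_mutations(gen, branches, config.L, rng)

    ids: list[str] = []
    sub: dict[str, str] = {}
    pop: dict[str, str] = {}
    node = 0
    for i, sz in enumerate(config.sample_sizes):
        for j in range(int(sz)):
            sid = f"{names[i]}_{j + 1:03d}"
            ids.append(sid)
            sub[sid] = names[i]
            pop[sid] = names[i]
            node += 1
    popmap = PopulationMap(sub, pop, dict(pop))
    return SimulatedDataset(
        AlignmentMatrix(ids, mat),
        popmap,
        config,
        tmrca=gen.tmrca,
        total_branch_length=gen.total_length,
        n_mutations=len(branches),
    )


def simulate_fixed_s(
    n: int, S: int, seed: int | None = None
) -> tuple[np.ndarray, int, float]:
    """Neutral constant-size sample with exactly S segregating mutations.

    Returns (pairwise difference matrix, haplotype count, mean pairwise
    difference K) — the ingredients of the fixed-S neutrality nulls.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if S < 1:
        raise ValueError("need S >= 1")
    rng = np.random.default_rng(seed)
    gen = coalescent.sim_tree(n, rng)
    branches = coalescent.place_fixed_mutations(gen, S, rng)
    dmat = coalescent.pairwise_from_mutations(gen, branches)
    part = coalescent.haplotype_partition(gen, branches)
    c = coalescent.carrier_counts(gen, branches)
    K = float(np.sum(c * (n - c))) * 2.0 / (n * (n - 1))
    return dmat, int(part.max()) + 1, K


def make_study_fixture(seed: int | None = None) -> SimulatedDataset:
    """End-to-end pipeline fixture emulating the field study design.

    Three populations of sizes (88, 88, 87) over a 570 bp locus, island-model
    migration chosen so pairwise differentiation falls in the 0.05-0.15 band,
    the first deme given a recent 10x expansion. Each deme's samples are
    split into three subpopulations (the within-population layer carries no
    simulated structure, matching the near-zero subpopulation differentiation
    the design assumes).
    """
    config = CoalescentConfig(
        sample_sizes=(88, 88, 87),
        theta=5.0,
        migration=6.0,
        expansion=(1.0, 10.0),
        expanded_demes=(0,),
        L=570,
        seed=seed,
        deme_names=("popA", "popB", "popC"),
    )
    ds = simulate_dataset(config)
    # carve three subpopulations per deme out of the sample order
    sub = dict(ds.popmap.subpopulation)
    for name in ("popA", "popB", "popC"):
        members = ds.popmap.members(name)
        k = len(members)
        cuts = [0, k // 3, 2 * k // 3, k]
        for j in range(3):
            for s in members[cuts[j] : cuts[j + 1]]:
                sub[s] = f"{name}_s{j + 1}"
    ds.popmap = PopulationMap(sub, dict(ds.popmap.population), dict(ds.popmap.group))
    return ds
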