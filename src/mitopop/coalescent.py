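"""Low-level haploid coalescent machinery.

Genealogies are stored in arrays indexed by node id: leaves are 0..n-1 (time
0), internal nodes n..2n-2 in coalescence order, so a parent always has a
larger id than its children. Time runs backwards from the sample. Mutations
are attached to branches (identified by the child-end node id); under the
at-most-one-mutation-per-site convention used throughout, the number of
pairwise differences between two leaves equals the number of mutations on the
path between them, which lets most statistics be computed from carrier counts
alone.

Two time scales appear:

* *coalescent units* — a within-deme pair coalesces at rate 1; mutations are
  dropped at rate theta/2 per lineage, so E[pairwise difference] = theta for a
  single constant deme.
* *mutational units* — a pair accumulates differences at rate 1 (the scale of
  the mismatch-distribution parameter tau); pair coalescence rate is 1/theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Genealogy",
    "sim_tree",
    "sim_island_tree",
    "place_fixed_mutations",
    "place_poisson_mutations",
    "carrier_counts",
    "haplotype_partition",
    "pairwise_from_mutations",
]


@dataclass
class Genealogy:
    """Binary coalescent tree over n leaves (2n-1 nodes)."""

    n: int
    parent: np.ndarray  # node -> parent id, -1 at root
    time: np.ndarray  # node -> height (0 at leaves)
    leaf_count: np.ndarray  # node -> number of subtended leaves

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        out = np.zeros(2 * self.n - 1)
        nonroot = np.arange(2 * self.n - 2)
        out[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return out

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


def _piecewise_waiting_time(
    t: float, rate_now, profile: Sequence[tuple[float, float]], u: float
) -> float:
    """Inverse-CDF draw of the next event time with piecewise-constant rates.

    ``rate_now(size_factors)`` maps the per-interval relative sizes to a total
    rate; ``profile`` is a list of (start_time, size_factor) breakpoints.
    """
    target = -np.log(u)
    if len(profile) == 1:
        return t + target / rate_now(profile[0][1])
    acc = 0.0
    cur = t
    # locate current interval
    idx = 0
    for i, (start, _) in enumerate(profile):
        if start <= cur:
            idx = i
    while True:
        rate = rate_now(profile[idx][1])
        nxt = profile[idx + 1][0] if idx + 1 < len(profile) else np.inf
        if rate <= 0:
            if nxt == np.inf:
                return np.inf
            cur = nxt
            idx += 1
            continue
        span = nxt - cur
        need = (target - acc) / rate
        if need <= span:
            return cur + need
        acc += rate * span
        cur = nxt
        idx += 1


def sim_tree(
    n: int,
    rng: np.random.Generator,
    size_profile: Sequence[tuple[float, float]] = ((0.0, 1.0),),
) -> Genealogy:
    """Single-deme Kingman coalescent with piecewise-constant population size.

    ``size_profile`` lists (time, relative_size) changepoints looking backwards
    from the present; with k lineages the coalescence rate at time t is
    C(k,2) / size(t). The default is the constant-size coalescent.
    """
    if n < 2:
        raise ValueError("need at least two lineages")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    leaf_count = np.ones(2 * n - 1, dtype=np.int64)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        pair_rate = k * (k - 1) / 2.0
        t = _piecewise_waiting_time(
            t, lambda s: pair_rate / s, size_profile, rng.random()
        )
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        leaf_count[nxt] = leaf_count[a] + leaf_count[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n, parent, time, leaf_count)


def sim_island_tree(
    sample_sizes: Sequence[int],
    migration: float,
    rng: np.random.Generator,
    size_profiles: Sequence[Sequence[tuple[float, float]]] | None = None,
) -> Genealogy:
    """Structured coalescent under the finite island model.

    Within deme i the pair coalescence rate is 1/size_i(t) (per-deme
    coalescent units); each lineage migrates at rate ``migration``/2, choosing
    a destination uniformly among the other demes. ``size_profiles`` gives one
    piecewise-constant (time, relative_size) profile per deme.
    """
    d = len(sample_sizes)
    n = int(sum(sample_sizes))
    if n < 2:
        raise ValueError("need at least two lineages")
    if migration < 0:
        raise ValueError("migration rate must be non-negative")
    if size_profiles is None:
        size_profiles = [((0.0, 1.0),) for _ in range(d)]
    # global breakpoints where any deme changes size
    breaks = sorted({tp for prof in size_profiles for tp, _ in prof})

    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    leaf_count = np.ones(2 * n - 1, dtype=np.int64)
    deme_of: dict[int, int] = {}
    node = 0
    for i, sz in enumerate(sample_sizes):
        for _ in range(int(sz)):
            deme_of[node] = i
            node += 1
    active: list[int] = list(range(n))
    t = 0.0
    nxt = n

    def size_at(i: int, when: float) -> float:
        s = size_profiles[i][0][1]
        for tp, val in size_profiles[i]:
            if tp <= when:
                s = val
        return s

    while len(active) > 1:
        # lineages per deme
        per = np.zeros(d, dtype=np.int64)
        for x in active:
            per[deme_of[x]] += 1
        while True:
            coal = np.array(
                [c * (c - 1) / 2.0 / size_at(i, t) for i, c in enumerate(per)]
            )
            mig_rate = len(active) * migration / 2.0 if d > 1 else 0.0
            total = coal.sum() + mig_rate
            if total <= 0:
                # no migration and every deme at its local MRCA: the remaining
                # lineages meet in a single ancestral deme from here backwards
                anc = deme_of[active[0]]
                for x in active:
                    deme_of[x] = anc
                per[:] = 0
                per[anc] = len(active)
                continue
            dt = rng.exponential(1.0 / total)
            upcoming = [b for b in breaks if t < b <= t + dt]
            if upcoming:
                t = upcoming[0]  # rates change; redraw from the breakpoint
                continue
            t = t + dt
            break
        if rng.random() < mig_rate / total:
            x = active[rng.integers(len(active))]
            src = deme_of[x]
            dst = rng.integers(d - 1)
            deme_of[x] = dst if dst < src else dst + 1
        else:
            probs = coal / coal.sum()
            i = rng.choice(d, p=probs)
            here = [x for x in active if deme_of[x] == i]
            a_idx, b_idx = rng.choice(len(here), size=2, replace=False)
            a, b = here[a_idx], here[b_idx]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            leaf_count[nxt] = leaf_count[a] + leaf_count[b]
            deme_of[nxt] = i
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
    return Genealogy(n, parent, time, leaf_count)


def place_fixed_mutations(gen: Genealogy, S: int, rng: np.random.Generator) -> np.ndarray:
    """Drop exactly S mutations on branches with probability proportional to
    branch length; returns the child-end node id of each mutation."""
    lens = gen.branch_lengths()[:-1]  # root excluded
    p = lens / lens.sum()
    return rng.choice(lens.size, size=int(S), p=p)


def place_poisson_mutations(
    gen: Genealogy, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson(theta * total_length / 2) mutations uniform on branches."""
    mean = theta * gen.total_length / 2.0
    S = rng.poisson(mean)
    if S == 0:
        return np.empty(0, dtype=np.int64)
    return place_fixed_mutations(gen, S, rng)


def carrier_counts(gen: Genealogy, branches: np.ndarray) -> np.ndarray:
    """Number of sampled leaves carrying each mutation."""
    return gen.leaf_count[branches]


def haplotype_partition(gen: Genealogy, branches: np.ndarray) -> np.ndarray:
    """Assign each leaf an integer haplotype id implied by the mutations.

    Two leaves share an id iff no mutation separates them.
    """
    n = gen.n
    muts_on: dict[int, list[int]] = {}
    for m, b in enumerate(branches):
        muts_on.setdefault(int(b), []).append(m)
    sig: list[frozenset | None] = [None] * (2 * n - 1)
    sig[gen.root] = frozenset()
    for v in range(gen.root - 1, -1, -1):
        s = sig[gen.parent[v]]
        own = muts_on.get(v)
        sig[v] = s | frozenset(own) if own else s
    seen: dict[frozenset, int] = {}
    out = np.empty(n, dtype=np.int64)
    for leaf in range(n):
        out[leaf] = seen.setdefault(sig[leaf], len(seen))
    return out


def pairwise_from_mutations(gen: Genealogy, branches: np.ndarray) -> np.ndarray:
    """Full (n, n) pairwise-difference matrix implied by the mutations."""
    n = gen.n
    S = len(branches)
    if S == 0:
        return np.zeros((n, n), dtype=np.int64)
    carriers = np.zeros((S, n), dtype=np.int64)
    children: dict[int, list[int]] = {}
    for v in range(2 * n - 2):
        children.setdefault(int(gen.parent[v]), []).append(v)
    # leaves below each branch, found once per mutated branch
    for m, b in enumerate(branches):
        stack = [int(b)]
        while stack:
            v = stack.pop()
            if v < n:
                carriers[m, v] = 1
            else:
                stack.extend(children[v])
    r = carriers.sum(axis=0)
    cross = carriers.T @ carriers
    return r[:, None] + r[None, :] - 2 * cross
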