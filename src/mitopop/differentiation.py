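"""Hierarchical AMOVA, pairwise fixation indices and gene-flow conversion.

The analysis of molecular variance partitions squared pairwise distances
(here, raw nucleotide-difference counts treated as squared Euclidean
distances) into hierarchical variance components with unequal-sample-size
coefficients:

* three-level design — groups / populations within groups / individuals:
  components Va (among groups), Vb (among populations within groups), Vc
  (within populations), with fixation indices F_CT = Va/V, F_SC = Vb/(Vb+Vc),
  F_ST = (Va+Vb)/V;
* two-level design — populations / individuals: Va (among populations) and
  Vb (within), with Phi_ST = Va/(Va+Vb).

Significance comes from label permutations, one scheme per index: whole
populations permuted across groups for F_CT, individuals permuted across
populations within their group for F_SC, and individuals permuted freely for
F_ST. P-values are the plain proportion of permuted statistics >= the
observed one (no +1 correction by default, so p = 0 can occur, matching the
convention of the standard AMOVA software).

Pairwise "F_ST" between two populations is the two-level Phi_ST computed on
the pair; a haplotype-identity variant (distance 0/1, i.e. differentiation in
haplotype frequencies only) is available via ``statistic="haplotype"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix
from .seq_io import PopulationMap

__all__ = [
    "AmovaResult",
    "PairwiseFstResult",
    "amova",
    "pairwise_fst",
    "nm_from_fst",
    "apparent_density",
]

_TIE_TOL = 1e-12


@dataclass
class AmovaResult:
    design: str  # "3-level" or "2-level"
    table: pd.DataFrame  # strata x (df, SS, variance, percent, percent_floored)
    indices: dict[str, float]  # F_CT / F_SC / F_ST (or Phi_ST)
    p_values: dict[str, float]
    coefficients: dict[str, float]  # the n-style unequal-size coefficients
    permutations: int
    seed: int | None


@dataclass
class PairwiseFstResult:
    pair: tuple[str, str]
    fst: float
    p_value: float
    permutations: int
    nm: float


def _within_ss(d: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (sum of pairwise d within group) / group size."""
    tot = 0.0
    for idx in groups:
        if idx.size < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        tot += sub.sum() / (2.0 * idx.size)
    return tot


def _two_level_components(
    d: np.ndarray, pops: list[np.ndarray]
) -> tuple[float, float, float, float]:
    """(SS_among, SS_within, Va, Vw) for a populations/individuals design."""
    n = d.shape[0]
    sizes = np.array([p.size for p in pops], dtype=float)
    ss_total = d.sum() / (2.0 * n)
    ss_within = _within_ss(d, pops)
    ss_among = ss_total - ss_within
    df_among = len(pops) - 1
    df_within = n - len(pops)
    if df_among < 1 or df_within < 1:
        raise ValueError("degenerate design: need >=2 populations with >=2 members total")
    ms_among = ss_among / df_among
    vw = ss_within / df_within
    n0 = (n - np.sum(sizes**2) / n) / df_among
    va = (ms_among - vw) / n0
    return ss_among, ss_within, va, vw


def _phi_st_two_level(d: np.ndarray, pops: list[np.ndarray]) -> float:
    _, _, va, vw = _two_level_components(d, pops)
    tot = va + vw
    return va / tot if tot != 0 else 0.0


def _three_level_stats(
    d: np.ndarray, pop_idx: list[np.ndarray], group_of_pop: np.ndarray
) -> dict:
    """Full SS decomposition and components for groups/populations/individuals."""
    n = d.shape[0]
    P = len(pop_idx)
    G = int(group_of_pop.max()) + 1
    sizes = np.array([p.size for p in pop_idx], dtype=float)
    group_idx = [
        np.concatenate([pop_idx[p] for p in range(P) if group_of_pop[p] == g])
        for g in range(G)
    ]
    g_sizes = np.array([g.size for g in group_idx], dtype=float)

    ss_total = d.sum() / (2.0 * n)
    ss_wp = _within_ss(d, pop_idx)
    ss_wg = _within_ss(d, group_idx)  # total SS within each group
    ss_ap_wg = ss_wg - ss_wp  # among populations within groups
    ss_ag = ss_total - ss_wg  # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    if df_ag < 1 or df_ap < 1 or df_wp < 1:
        raise ValueError("degenerate design: each stratum needs >=2 units")

    vc = ss_wp / df_wp
    sum_sq_by_group = np.array(
        [np.sum(sizes[group_of_pop == g] ** 2) for g in range(G)]
    )
    n_prime = (n - np.sum(sum_sq_by_group / g_sizes)) / df_ap
    n_dprime = (np.sum(sum_sq_by_group / g_sizes) - np.sum(sizes**2) / n) / df_ag
    n_tprime = (n - np.sum(g_sizes**2) / n) / df_ag

    ms_ap = ss_ap_wg / df_ap
    ms_ag = ss_ag / df_ag
    vb = (ms_ap - vc) / n_prime
    va = (ms_ag - vc - n_dprime * vb) / n_tprime
    return dict(
        ss=(ss_ag, ss_ap_wg, ss_wp, ss_total),
        df=(df_ag, df_ap, df_wp),
        components=(va, vb, vc),
        coefficients={"n'": n_prime, "n''": n_dprime, "n'''": n_tprime},
    )


def amova(
    dist: DistanceMatrix,
    popmap: PopulationMap,
    levels: int = 3,
    permutations: int = 10000,
    seed: int | None = None,
) -> AmovaResult:
    """Distance-based AMOVA over the hierarchy in ``popmap``.

    For ``levels=3`` the strata are group / population-within-group /
    individual, where "population" is the popmap's subpopulation layer nested
    in its group-defining population layer when both are distinct; the strata
    actually used are taken from the popmap: groups = popmap groups,
    populations = popmap subpopulations.
    """
    popmap = popmap.restrict(dist.ids)
    popmap.validate_against(dist.ids)
    d = dist.d.astype(float)
    pos = {s: i for i, s in enumerate(dist.ids)}
    rng = np.random.default_rng(seed)

    if levels == 2:
        pops = [
            np.array([pos[s] for s in popmap.members(p)]) for p in popmap.populations()
        ]
        ss_among, ss_within, va, vw = _two_level_components(d, pops)
        n = d.shape[0]
        total = va + vw
        phi = va / total
        # permutation: individuals across populations
        count = 0
        labels = np.concatenate([np.full(p.size, i) for i, p in enumerate(pops)])
        order = np.concatenate(pops)
        base = np.empty(n, dtype=int)
        base[order] = labels
        for _ in range(permutations):
            perm = rng.permutation(base)
            ppops = [np.nonzero(perm == i)[0] for i in range(len(pops))]
            if _phi_st_two_level(d, ppops) >= phi - _TIE_TOL:
                count += 1
        p_val = count / permutations if permutations else math.nan
        sizes = [p.size for p in pops]
        table = pd.DataFrame(
            {
                "df": [len(pops) - 1, n - len(pops), n - 1],
                "SS": [ss_among, ss_within, ss_among + ss_within],
                "variance": [va, vw, total],
                "percent": [100 * va / total, 100 * vw / total, 100.0],
            },
            index=["among_populations", "within_populations", "total"],
        )
        table["percent_floored"] = table["percent"].clip(lower=0.0)
        n0 = (n - sum(s * s for s in sizes) / n) / (len(pops) - 1)
        return AmovaResult(
            "2-level", table, {"Phi_ST": phi}, {"Phi_ST": p_val},
            {"n0": n0}, permutations, seed,
        )

    if levels != 3:
        raise ValueError("levels must be 2 or 3")

    sub_labels = popmap.subpopulations()
    pop_idx = [
        np.array([pos[s] for s in popmap.subpop_members(sp)]) for sp in sub_labels
    ]
    groups = popmap.groups()
    if len(groups) < 2:
        raise ValueError("degenerate design: 3-level AMOVA needs >= 2 groups")
    group_of_pop = np.array(
        [groups.index(popmap.group[popmap.subpop_members(sp)[0]]) for sp in sub_labels]
    )
    st = _three_level_stats(d, pop_idx, group_of_pop)
    va, vb, vc = st["components"]
    total = va + vb + vc
    f_ct = va / total
    f_sc = vb / (vb + vc)
    f_st = (va + vb) / total

    n = d.shape[0]
    c_ct = c_sc = c_st = 0
    for _ in range(permutations):
        # F_CT: whole populations shuffled across groups (group sizes kept)
        perm_groups = rng.permutation(group_of_pop)
        try:
            s = _three_level_stats(d, pop_idx, perm_groups)
            pa, pb, pc = s["components"]
            if pa / (pa + pb + pc) >= f_ct - _TIE_TOL:
                c_ct += 1
        except ValueError:
            c_ct += 1  # unusable permutation counted conservatively

        # F_SC: individuals shuffled across populations within their group
        new_pop_idx = [np.empty(0, dtype=int)] * len(pop_idx)
        for g in range(len(groups)):
            members = [p for p in range(len(pop_idx)) if group_of_pop[p] == g]
            pool = np.concatenate([pop_idx[p] for p in members])
            pool = rng.permutation(pool)
            off = 0
            for p in members:
                k = pop_idx[p].size
                new_pop_idx[p] = pool[off : off + k]
                off += k
        s = _three_level_stats(d, new_pop_idx, group_of_pop)
        pa, pb, pc = s["components"]
        if pb / (pb + pc) >= f_sc - _TIE_TOL:
            c_sc += 1

        # F_ST: individuals shuffled across populations regardless of group
        pool = rng.permutation(n)
        off = 0
        flat = []
        for p in range(len(pop_idx)):
            k = pop_idx[p].size
            flat.append(pool[off : off + k])
            off += k
        s = _three_level_stats(d, flat, group_of_pop)
        pa, pb, pc = s["components"]
        if (pa + pb) / (pa + pb + pc) >= f_st - _TIE_TOL:
            c_st += 1

    B = permutations if permutations else 1
    p_vals = {
        "F_CT": c_ct / B if permutations else math.nan,
        "F_SC": c_sc / B if permutations else math.nan,
        "F_ST": c_st / B if permutations else math.nan,
    }
    ss_ag, ss_ap, ss_wp, ss_total = st["ss"]
    df_ag, df_ap, df_wp = st["df"]
    table = pd.DataFrame(
        {
            "df": [df_ag, df_ap, df_wp, n - 1],
            "SS": [ss_ag, ss_ap, ss_wp, ss_total],
            "variance": [va, vb, vc, total],
            "percent": [
                100 * va / total,
                100 * vb / total,
                100 * vc / total,
                100.0,
            ],
        },
        index=[
            "among_groups",
            "among_populations_within_groups",
            "within_populations",
            "total",
        ],
    )
    table["percent_floored"] = table["percent"].clip(lower=0.0)
    return AmovaResult(
        "3-level",
        table,
        {"F_CT": f_ct, "F_SC": f_sc, "F_ST": f_st},
        p_vals,
        st["coefficients"],
        permutations,
        seed,
    )


def pairwise_fst(
    dist: DistanceMatrix,
    popmap: PopulationMap,
    permutations: int = 10000,
    seed: int | None = None,
    statistic: str = "phi",
    level: str = "population",
) -> tuple[pd.DataFrame, pd.DataFrame, list[PairwiseFstResult]]:
    """Pairwise Phi_ST between all (sub)population pairs with permutation p.

    Returns (fst lower-triangle matrix, p-value matrix, per-pair results).
    ``statistic="haplotype"`` replaces nucleotide distances with haplotype
    identity (0/1), i.e. differentiation in haplotype frequencies alone.
    """
    popmap = popmap.restrict(dist.ids)
    if level == "population":
        units = popmap.populations()
        members = {u: popmap.members(u) for u in units}
    elif level == "subpopulation":
        units = popmap.subpopulations()
        members = {u: popmap.subpop_members(u) for u in units}
    else:
        raise ValueError("level must be 'population' or 'subpopulation'")
    if len(units) < 2:
        raise ValueError("need >= 2 populations")
    for u in units:
        if len(members[u]) < 2:
            raise ValueError(f"insufficient sample in population {u!r}")

    d_full = dist.d.astype(float)
    if statistic == "haplotype":
        d_full = (d_full > 0).astype(float)
    elif statistic != "phi":
        raise ValueError("statistic must be 'phi' or 'haplotype'")

    pos = {s: i for i, s in enumerate(dist.ids)}
    rng = np.random.default_rng(seed)
    fst_m = pd.DataFrame(np.nan, index=units, columns=units)
    p_m = pd.DataFrame(np.nan, index=units, columns=units)
    results = []
    for i, u in enumerate(units):
        fst_m.loc[u, u] = 0.0
        for v in units[i + 1 :]:
            ia = np.array([pos[s] for s in members[u]])
            ib = np.array([pos[s] for s in members[v]])
            both = np.concatenate([ia, ib])
            d = d_full[np.ix_(both, both)]
            na = ia.size
            pops = [np.arange(na), np.arange(na, both.size)]
            obs = _phi_st_two_level(d, pops)
            count = 0
            for _ in range(permutations):
                perm = rng.permutation(both.size)
                if (
                    _phi_st_two_level(d, [perm[:na], perm[na:]])
                    >= obs - _TIE_TOL
                ):
                    count += 1
            p = count / permutations if permutations else math.nan
            nm = nm_from_fst(obs) if obs > 0 else math.inf
            fst_m.loc[v, u] = obs
            p_m.loc[v, u] = p
            results.append(PairwiseFstResult((u, v), obs, p, permutations, nm))
    return fst_m, p_m, results


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow for a haploid maternal marker:
    Nm = (1 - F_ST) / (2 F_ST), the effective number of female migrants per
    generation. F_ST <= 0 maps to +inf (unbounded gene flow sentinel)."""
    if fst > 1:
        raise ValueError("F_ST cannot exceed 1")
    if fst <= 0:
        return math.inf
    return (1.0 - fst) / (2.0 * fst)


def apparent_density(total_flies: float, traps: int, days: float) -> float:
    """Apparent tsetse density FTD = total catch / (traps x trap-days)."""
    if total_flies < 0 or traps < 0 or days < 0:
        raise ValueError("trap survey quantities must be non-negative")
    effort = traps * days
    if effort == 0:
        raise ValueError("no trapping effort: traps x days must be positive")
    return total_flies / effort
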