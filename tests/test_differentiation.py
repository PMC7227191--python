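"""AMOVA, pairwise fixation indices and gene-flow conversions."""

import itertools
import math

import numpy as np
import pytest

from mitopop.differentiation import (
    amova,
    apparent_density,
    nm_from_fst,
    pairwise_fst,
)
from mitopop.diversity import pairwise_differences
from mitopop.seq_io import AlignmentMatrix, PopulationMap

from .conftest import random_alignment, random_popmap


def hudson_fst(d, idx_a, idx_b):
    """1 - (mean within)/(mean between) on a two-population design."""
    within = [d[i, j] for i, j in itertools.combinations(idx_a, 2)]
    within += [d[i, j] for i, j in itertools.combinations(idx_b, 2)]
    between = [d[i, j] for i in idx_a for j in idx_b]
    mw, mb = np.mean(within), np.mean(between)
    return 1.0 - mw / mb if mb > 0 else 0.0


class TestTwoLevelAmova:
    def test_toy4_hand_decomposition(self, toy4_alignment, toy4_popmap):
        dist = pairwise_differences(toy4_alignment)
        res = amova(dist, toy4_popmap, levels=2, permutations=0)
        t = res.table
        assert t.loc["total", "SS"] == pytest.approx(1.75)
        assert t.loc["within_populations", "SS"] == pytest.approx(0.5)
        assert t.loc["among_populations", "variance"] == pytest.approx(0.5)
        assert t.loc["within_populations", "variance"] == pytest.approx(0.25)
        assert res.indices["Phi_ST"] == pytest.approx(2 / 3, abs=1e-12)

    def test_percent_sums_and_df_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            aln = random_alignment(rng, n=12)
            pm = random_popmap(rng, aln.ids, n_pops=3)
            dist = pairwise_differences(aln)
            res = amova(dist, pm, levels=2, permutations=0)
            assert res.table["percent"][:-1].sum() == pytest.approx(100, abs=0.1)
            assert res.table["df"][:-1].sum() == aln.n - 1
            assert (res.table["SS"] >= -1e-9).all()

    def test_matches_hudson_on_equal_sized_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            aln = random_alignment(rng, n=10)
            pops = {s: ("A" if i < 5 else "B") for i, s in enumerate(aln.ids)}
            pm = PopulationMap(dict(pops), dict(pops), {s: "G" for s in pops})
            dist = pairwise_differences(aln)
            res = amova(dist, pm, levels=2, permutations=0)
            expected = hudson_fst(dist.d.astype(float), list(range(5)), list(range(5, 10)))
            assert res.indices["Phi_ST"] == pytest.approx(expected, abs=1e-9)

    def test_every_individual_its_own_population_is_degenerate(self, toy4_alignment):
        ids = toy4_alignment.ids
        pm = PopulationMap({s: s for s in ids}, {s: s for s in ids},
                           {s: "G" for s in ids})
        dist = pairwise_differences(toy4_alignment)
        with pytest.raises(ValueError, match="degenerate design"):
            amova(dist, pm, levels=2, permutations=0)


class TestThreeLevelAmova:
    @staticmethod
    def _nested_design(rng, n_groups=2, pops_per_group=2, n_per_pop=4):
        n = n_groups * pops_per_group * n_per_pop
        aln = random_alignment(rng, n=n, L=30)
        sub, pop, grp = {}, {}, {}
        i = 0
        for g in range(n_groups):
            for p in range(pops_per_group):
                for _ in range(n_per_pop):
                    s = aln.ids[i]
                    sub[s] = f"g{g}p{p}"
                    pop[s] = f"g{g}p{p}"
                    grp[s] = f"g{g}"
                    i += 1
        return aln, PopulationMap(sub, pop, grp)

    def test_component_structure_and_percent_sum(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            aln, pm = self._nested_design(rng)
            dist = pairwise_differences(aln)
            res = amova(dist, pm, levels=3, permutations=0)
            t = res.table
            assert t["percent"][:-1].sum() == pytest.approx(100, abs=0.1)
            assert t["df"][:-1].sum() == aln.n - 1
            va, vb, vc = t["variance"][:-1]
            assert res.indices["F_CT"] == pytest.approx(va / (va + vb + vc))
            assert res.indices["F_SC"] == pytest.approx(vb / (vb + vc))
            assert res.indices["F_ST"] == pytest.approx((va + vb) / (va + vb + vc))

    def test_ss_decomposition_matches_brute_force(self):
        rng = np.random.default_rng(23)
        aln, pm = self._nested_design(rng)
        d = pairwise_differences(aln).d.astype(float)
        n = aln.n
        res = amova(pairwise_differences(aln), pm, levels=3, permutations=0)
        # brute force: SS from literal sums over index sets
        ss_total = sum(d[i, j] for i in range(n) for j in range(i + 1, n)) / n
        pos = {s: i for i, s in enumerate(aln.ids)}
        ss_wp = 0.0
        for sp in pm.subpopulations():
            idx = [pos[s] for s in pm.subpop_members(sp)]
            ss_wp += sum(d[i, j] for i in idx for j in idx if i < j) / len(idx)
        ss_wg = 0.0
        for g in pm.groups():
            idx = [pos[s] for s, gg in pm.group.items() if gg == g]
            ss_wg += sum(d[i, j] for i in idx for j in idx if i < j) / len(idx)
        assert res.table.loc["total", "SS"] == pytest.approx(ss_total, abs=1e-9)
        assert res.table.loc["within_populations", "SS"] == pytest.approx(ss_wp, abs=1e-9)
        assert res.table.loc["among_groups", "SS"] == pytest.approx(
            ss_total - ss_wg, abs=1e-9
        )

    def test_single_group_rejected(self, toy4_alignment, toy4_popmap):
        dist = pairwise_differences(toy4_alignment)
        with pytest.raises(ValueError, match="degenerate|>= 2 groups"):
            amova(dist, toy4_popmap, levels=3, permutations=0)

    def test_permutation_pvalues_in_range_and_seeded(self):
        rng = np.random.default_rng(31)
        aln, pm = self._nested_design(rng)
        dist = pairwise_differences(aln)
        r1 = amova(dist, pm, levels=3, permutations=199, seed=5)
        r2 = amova(dist, pm, levels=3, permutations=199, seed=5)
        assert r1.p_values == r2.p_values
        assert all(0 <= p <= 1 for p in r1.p_values.values())


class TestPairwiseFst:
    def test_toy4_exhaustive_permutation_p(self, toy4_alignment, toy4_popmap):
        dist = pairwise_differences(toy4_alignment)
        _, _, results = pairwise_fst(dist, toy4_popmap, permutations=10000, seed=2)
        (r,) = results
        assert r.fst == pytest.approx(2 / 3, abs=1e-12)
        # 3 distinct 2+2 partitions; only the observed one reaches 2/3
        assert r.p_value == pytest.approx(1 / 3, abs=3 * math.sqrt((1 / 3) * (2 / 3) / 10000))

    def test_duplicated_population_gives_null_fst(self, toy4_alignment):
        doubled = AlignmentMatrix(
            toy4_alignment.ids + [f"{s}b" for s in toy4_alignment.ids],
            np.vstack([toy4_alignment.matrix, toy4_alignment.matrix]),
        )
        pops = {s: ("A" if not s.endswith("b") else "B") for s in doubled.ids}
        pm = PopulationMap(dict(pops), dict(pops), {s: "G" for s in pops})
        dist = pairwise_differences(doubled)
        _, _, results = pairwise_fst(dist, pm, permutations=500, seed=3)
        (r,) = results
        # no differentiation signal: the point estimate is zero or (slightly)
        # negative and the permutation test is far from significance
        assert r.fst < 0.05
        assert r.p_value > 0.5

    def test_haplotype_frequency_variant_differs_from_phi(self, toy4_alignment, toy4_popmap):
        dist = pairwise_differences(toy4_alignment)
        _, _, phi = pairwise_fst(dist, toy4_popmap, permutations=0, seed=0)
        _, _, hap = pairwise_fst(
            dist, toy4_popmap, permutations=0, seed=0, statistic="haplotype"
        )
        assert 0 <= hap[0].fst <= 1
        assert hap[0].fst != pytest.approx(phi[0].fst)

    def test_monte_carlo_matches_exhaustive_on_small_case(self):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, n=8, L=20)
        pops = {s: ("A" if i < 4 else "B") for i, s in enumerate(aln.ids)}
        pm = PopulationMap(dict(pops), dict(pops), {s: "G" for s in pops})
        dist = pairwise_differences(aln)
        _, _, results = pairwise_fst(dist, pm, permutations=4000, seed=7)
        (r,) = results
        # exhaustive: all 4+4 splits of the eight individuals
        d = dist.d.astype(float)
        obs = r.fst
        stats = []
        for combo in itertools.combinations(range(8), 4):
            rest = [i for i in range(8) if i not in combo]
            from mitopop.differentiation import _phi_st_two_level

            stats.append(_phi_st_two_level(d, [np.array(combo), np.array(rest)]))
        exact = np.mean([s >= obs - 1e-12 for s in stats])
        se = math.sqrt(exact * (1 - exact) / 4000) + 1e-9
        assert r.p_value == pytest.approx(exact, abs=3 * se + 0.02)


class TestGeneFlowAndDensity:
    @pytest.mark.parametrize(
        "fst,expected", [(0.5, 0.5), (1.0, 0.0), (0.152, 2.7895)]
    )
    def test_nm_island_model_values(self, fst, expected):
        assert nm_from_fst(fst) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_fst_is_unbounded_sentinel(self):
        assert math.isinf(nm_from_fst(0.0))
        assert math.isinf(nm_from_fst(-0.02))

    def test_fst_above_one_invalid(self):
        with pytest.raises(ValueError):
            nm_from_fst(1.2)

    @pytest.mark.parametrize(
        "flies,traps,days,expected",
        [(70, 10, 7, 1.0), (0, 10, 7, 0.0), (1158, 10, 7, 16.54)],
    )
    def test_apparent_density(self, flies, traps, days, expected):
        assert apparent_density(flies, traps, days) == pytest.approx(expected, abs=5e-3)

    def test_no_trapping_effort_rejected(self):
        with pytest.raises(ValueError, match="no trapping effort"):
            apparent_density(10, 0, 7)
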