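"""Coalescent simulator calibration and reproducibility."""

import numpy as np
import pytest

from mitopop.diversity import pairwise_differences
from mitopop.haplotypes import segregating_sites
from mitopop.neutrality import tajima_constants, tajimas_d
from mitopop.differentiation import pairwise_fst
from mitopop.simulate import (
    CoalescentConfig,
    make_study_fixture,
    simulate_dataset,
    simulate_fixed_s,
)


class TestReproducibility:
    def test_byte_identical_fasta_for_same_seed(self, tmp_path):
        cfg = dict(sample_sizes=(6, 6), theta=3.0, migration=1.0, L=100)
        a = simulate_dataset(CoalescentConfig(**cfg, seed=42))
        b = simulate_dataset(CoalescentConfig(**cfg, seed=42))
        pa = a.write(tmp_path / "a")["fasta"].read_bytes()
        pb = b.write(tmp_path / "b")["fasta"].read_bytes()
        assert pa == pb
        c = simulate_dataset(CoalescentConfig(**cfg, seed=43))
        assert c.write(tmp_path / "c")["fasta"].read_bytes() != pa

    def test_fixed_s_deterministic(self):
        a = simulate_fixed_s(10, 4, seed=7)
        b = simulate_fixed_s(10, 4, seed=7)
        assert np.array_equal(a[0], b[0]) and a[1:] == b[1:]

    def test_dimensions_match_config(self):
        ds = simulate_dataset(
            CoalescentConfig(sample_sizes=(5, 7), theta=2.0, L=80, seed=1)
        )
        assert ds.alignment.n == 12 and ds.alignment.L == 80
        assert ds.popmap.populations() == ["pop1", "pop2"]
        assert len(ds.popmap.members("pop2")) == 7


class TestCalibration:
    def test_watterson_and_pairwise_theta(self):
        # E[S] = theta a1(n), E[K] = theta for a single constant-size deme
        n, theta, reps = 20, 5.0, 2000
        a1 = tajima_constants(n).a1
        Ss, Ks = [], []
        for i in range(reps):
            ds = simulate_dataset(
                CoalescentConfig(sample_sizes=(n,), theta=theta, L=570, seed=50_000 + i)
            )
            Ss.append(segregating_sites(ds.alignment)[0])
            Ks.append(pairwise_differences(ds.alignment).mean_pairwise())
        assert np.mean(Ss) == pytest.approx(theta * a1, rel=0.03)
        assert np.mean(Ks) == pytest.approx(theta, rel=0.05)

    def test_agrees_with_msprime_watterson(self):
        # independent oracle: msprime's haploid coalescent at matching scale
        msprime = pytest.importorskip("msprime")
        n, theta, reps = 15, 3.0, 300
        ours = []
        for i in range(reps):
            ds = simulate_dataset(
                CoalescentConfig(sample_sizes=(n,), theta=theta, L=570, seed=60_000 + i)
            )
            ours.append(segregating_sites(ds.alignment)[0])
        other = []
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=1.0, num_replicates=reps,
                random_seed=99,
            )
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, random_seed=17 + i, discrete_genome=False
            )
            other.append(mts.num_sites)
        sem = np.std(ours + other) * np.sqrt(1 / reps + 1 / reps)
        assert abs(np.mean(ours) - np.mean(other)) < 3.5 * sem

    def test_fixed_s_single_mutation_splits_sample(self):
        for seed in range(10):
            d, k, K = simulate_fixed_s(8, 1, seed=seed)
            vals = set(d[np.triu_indices(8, 1)])
            assert vals == {0, 1}
            assert k == 2

    def test_fixed_s_mean_d_small_negative_bias(self):
        n, S = 88, 9
        ds = [
            tajimas_d(n, S, simulate_fixed_s(n, S, seed=70_000 + i)[2])
            for i in range(400)
        ]
        assert -0.2 < np.mean(ds) < 0.1


class TestStructure:
    def test_phi_st_decreases_with_migration(self):
        means = []
        for j, M in enumerate((0.1, 1.0, 10.0)):
            vals = []
            for i in range(12):
                ds = simulate_dataset(
                    CoalescentConfig(
                        sample_sizes=(10, 10, 10), theta=3.0, migration=M,
                        L=570, seed=80_000 + 1000 * j + i,
                    )
                )
                dist = pairwise_differences(ds.alignment)
                _, _, res = pairwise_fst(dist, ds.popmap, permutations=0, seed=0)
                vals.extend(r.fst for r in res)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_isolated_demes_approach_fixation(self):
        vals = []
        for i in range(10):
            ds = simulate_dataset(
                CoalescentConfig(
                    sample_sizes=(8, 8), theta=8.0, migration=0.0, L=570,
                    seed=90_000 + i,
                )
            )
            dist = pairwise_differences(ds.alignment)
            _, _, res = pairwise_fst(dist, ds.popmap, permutations=0, seed=0)
            vals.append(res[0].fst)
        assert np.mean(vals) > 0.5

    def test_expanded_deme_has_more_negative_tajimas_d(self):
        diffs = []
        for seed in range(20):
            base = dict(sample_sizes=(25,), theta=2.0, L=570)
            exp = simulate_dataset(
                CoalescentConfig(**base, expansion=(0.5, 20.0), seed=200_000 + seed)
            )
            const = simulate_dataset(
                CoalescentConfig(**base, seed=300_000 + seed)
            )
            d_pair = []
            for ds in (exp, const):
                S = segregating_sites(ds.alignment)[0]
                if S == 0:
                    d_pair.append(0.0)
                    continue
                K = pairwise_differences(ds.alignment).mean_pairwise()
                d_pair.append(tajimas_d(ds.alignment.n, S, K))
            diffs.append(d_pair[0] - d_pair[1])
        assert np.mean(diffs) < -0.5


class TestStudyFixture:
    def test_design_shape(self):
        ds = make_study_fixture(seed=1)
        assert ds.alignment.n == 263
        assert ds.alignment.L == 570
        assert len(ds.popmap.populations()) == 3
        assert len(ds.popmap.subpopulations()) == 9
        sizes = sorted(len(ds.popmap.members(p)) for p in ds.popmap.populations())
        assert sizes == [87, 88, 88]

    def test_expanded_deme_lowest_mean_tajimas_d(self):
        # the expansion signature is a property of the mean over replicates;
        # any single realization is dominated by coalescent noise
        from mitopop.haplotypes import segregating_sites

        means = {}
        for pop in ("popA", "popB", "popC"):
            means[pop] = []
        for seed in range(20):
            ds = make_study_fixture(seed=seed)
            for pop in means:
                sub = ds.alignment.subset(ds.popmap.members(pop))
                S = segregating_sites(sub)[0]
                K = pairwise_differences(sub).mean_pairwise()
                means[pop].append(tajimas_d(sub.n, S, K))
        assert np.mean(means["popA"]) < np.mean(means["popB"])
        assert np.mean(means["popA"]) < np.mean(means["popC"])

    def test_phi_st_near_island_model_expectation(self):
        # pairwise expectation for demes in a d-island model:
        # Phi ~ (d-1)/(M d + d - 1), i.e. 1/(1 + 2 Nm_eff), Nm_eff = M d / (2(d-1))
        d, M = 3, 6.0
        expected = (d - 1) / (M * d + d - 1)
        vals = []
        for seed in range(8):
            ds = make_study_fixture(seed=400_000 + seed)
            dist = pairwise_differences(ds.alignment)
            _, _, res = pairwise_fst(dist, ds.popmap, permutations=0, seed=0)
            # exclude the expanded deme (popA): expansion perturbs its Phi
            vals.append(
                np.mean([r.fst for r in res if "popA" not in r.pair])
            )
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * mc_se + 0.02


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(theta=0.0), dict(migration=-1.0), dict(sample_sizes=(0,)),
         dict(L=0), dict(expansion=(-1.0, 10.0)), dict(expansion=(1.0, 0.0))],
    )
    def test_bad_configs_rejected(self, kwargs):
        base = dict(sample_sizes=(5,), theta=1.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            CoalescentConfig(**base)
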