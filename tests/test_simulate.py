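"""Penetrance models, the fixture pool, and the family simulator."""

import numpy as np
import pytest

from hapcore.clustering import CoreSystem, select_core
from hapcore.haplotypes import hamming
from hapcore.pedigree import AFFECTED, validate_family
from hapcore.simulate import (
    DiseaseModel,
    SimConfig,
    _FamilySampler,
    allele_freq_in_cases,
    make_fixture_pool,
    penetrances,
    simulate_dataset,
    simulate_family,
)

# All 27 penetrance triples (scaled by 10^4 and rounded) for K = 1%:
# (additive, dominant, recessive) per (r, p) setting.
PENETRANCE_TABLE = {
    (3.0, 0.10): ((71, 214, 357), (72, 217, 217), (98, 98, 294)),
    (3.0, 0.25): ((50, 150, 250), (53, 160, 160), (89, 89, 267)),
    (3.0, 0.50): ((33, 100, 167), (40, 120, 120), (67, 67, 200)),
    (2.5, 0.10): ((77, 192, 308), (78, 195, 195), (99, 99, 246)),
    (2.5, 0.25): ((57, 143, 229), (60, 151, 151), (91, 91, 229)),
    (2.5, 0.50): ((40, 100, 160), (47, 118, 118), (73, 73, 182)),
    (2.0, 0.10): ((83, 167, 250), (84, 168, 168), (99, 99, 198)),
    (2.0, 0.25): ((67, 133, 200), (70, 139, 139), (94, 94, 188)),
    (2.0, 0.50): ((50, 100, 150), (57, 114, 114), (80, 80, 160)),
}


class TestPenetrances:
    @pytest.mark.parametrize("r,p", sorted(PENETRANCE_TABLE))
    @pytest.mark.parametrize(
        "mi,mode", list(enumerate(["additive", "dominant", "recessive"]))
    )
    def test_all_27_settings_scaled_and_rounded(self, r, p, mi, mode):
        expected = PENETRANCE_TABLE[(r, p)][mi]
        f = penetrances(mode, r, p, 0.01)
        assert tuple(round(1e4 * x) for x in f) == expected

    @pytest.mark.parametrize("mode", ["additive", "dominant", "recessive"])
    @pytest.mark.parametrize("r,p", sorted(PENETRANCE_TABLE))
    def test_prevalence_identity(self, mode, r, p):
        K = 0.01
        f0, f1, f2 = penetrances(mode, r, p, K)
        prev = (1 - p) ** 2 * f0 + 2 * p * (1 - p) * f1 + p**2 * f2
        assert prev == pytest.approx(K, abs=1e-10)
        assert f0 <= f1 <= f2

    def test_no_effect_collapses_to_prevalence(self):
        for mode in ("additive", "dominant", "recessive"):
            assert penetrances(mode, 1.0, 0.3, 0.01) == pytest.approx((0.01,) * 3)

    def test_infeasible_model_rejected(self):
        with pytest.raises(ValueError):
            penetrances("recessive", 3.0, 0.01, 0.5)


class TestAlleleFreqInCases:
    def test_recessive_worked_example(self):
        m = DiseaseModel.from_mode("recessive", 2.0, 0.1, 0.01)
        assert round(allele_freq_in_cases(m), 2) == 0.11

    def test_additive_worked_example(self):
        m = DiseaseModel.from_mode("additive", 2.0, 0.12, 0.01)
        assert round(allele_freq_in_cases(m), 2) == 0.21

    def test_null_model_equals_population_frequency(self):
        m = DiseaseModel.null(p=0.37)
        assert allele_freq_in_cases(m) == pytest.approx(0.37)


class TestFixturePool:
    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5])
    def test_structure_and_exact_carrier_frequency(self, p):
        pool = make_fixture_pool(target_p=p, seed=5)
        t = pool.table
        assert t.frequencies[:10].sum() == pytest.approx(0.9, abs=1e-9)
        assert len(pool.true_cores) == 10
        assert pool.carrier_frequency == pytest.approx(p, abs=1e-9)
        assert t.n_markers == 13
        assert 15 <= len(t) <= 16

    def test_every_non_core_is_one_step_from_a_core(self):
        pool = make_fixture_pool(target_p=0.25, seed=5)
        cores = pool.true_cores
        for h in pool.table.haplotypes:
            if h in cores:
                continue
            assert min(hamming(h, c) for c in cores) == 1
        cs = CoreSystem.build(pool.table, 0.9)
        assert len(cs.layers) == 1

    def test_pool_without_liability_target(self):
        pool = make_fixture_pool(target_p=None, seed=5)
        assert len(pool.table) == 15
        assert pool.carrier_frequency == 0.0

    def test_zero_rare_mass_pool_identifies_perfectly(self):
        pool = make_fixture_pool(
            n_haplotypes=10, n_cores=10, core_mass=1.0, target_p=None, seed=5
        )
        core = select_core(pool.table, 0.9)
        assert {pool.table.haplotypes[i] for i in core} <= set(pool.true_cores)


class TestSimulateFamily:
    def test_null_transmission_matches_pool_frequencies(self, pool25, rng):
        """With flat penetrances the proband's haplotypes are plain draws
        from the pool (chi-square goodness of fit on many probands)."""
        model = DiseaseModel.null(p=0.25)
        sampler = _FamilySampler(pool25, model)
        counts = np.zeros(len(pool25.table))
        n = 8000
        for i in range(n):
            fam = sampler.sample(rng, 0, f"F{i}")
            # proband carries the father's and mother's transmitted haplotypes
            pro = fam.children[0]
            assert pro.affection == AFFECTED
        # count transmitted haplotypes directly from the sampler's draws
        rng2 = np.random.default_rng(1)
        for _ in range(n):
            j, u = sampler._draw_proband_pair(rng2)
            counts[j] += 1
            counts[u] += 1
        expected = pool25.table.frequencies * 2 * n
        mask = expected > 5
        chi2_stat = ((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2_stat, mask.sum() - 1) > 1e-4

    def test_proband_carrier_rate_matches_case_allele_frequency(self, pool25):
        """The liability-allele rate among proband haplotypes reproduces
        P(A|D) within Monte-Carlo error."""
        model = DiseaseModel.from_mode("additive", 3.0, 0.25, 0.01)
        sampler = _FamilySampler(pool25, model)
        carrier = pool25.carrier_indicator()
        rng = np.random.default_rng(2)
        n = 20000
        hits = 0
        for _ in range(n):
            j, u = sampler._draw_proband_pair(rng)
            hits += carrier[j] + carrier[u]
        rate = hits / (2 * n)
        target = allele_freq_in_cases(model)
        se = np.sqrt(target * (1 - target) / (2 * n))
        assert abs(rate - target) < 4 * se

    def test_simulated_family_is_mendelian_clean(self, pool25, rng):
        model = DiseaseModel.from_mode("recessive", 2.0, 0.1, 0.01)
        for i in range(50):
            fam = simulate_family(pool25, model, n_extra_children=2, rng=rng)
            assert validate_family(fam) == []


class TestSimulateDataset:
    def test_deterministic_given_seed(self, pool25, tmp_path):
        from hapcore.io import write_ped

        cfg = SimConfig(30, pool25, DiseaseModel.null(p=0.25), seed=8, sibship_seed=8)
        a, _ = simulate_dataset(cfg)
        b, _ = simulate_dataset(cfg)
        pa, pb = tmp_path / "a.ped", tmp_path / "b.ped"
        write_ped(a, pa)
        write_ped(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_mean_sibship_size_one_plus_poisson_two(self, pool25):
        cfg = SimConfig(1000, pool25, DiseaseModel.null(p=0.25), seed=9)
        fams, _ = simulate_dataset(cfg)
        mean_kids = np.mean([f.n_children for f in fams])
        assert mean_kids == pytest.approx(3.0, abs=0.2)

    def test_sibship_sizes_fixed_across_replicates(self, pool25):
        sizes = []
        for rep in range(2):
            cfg = SimConfig(
                50, pool25, DiseaseModel.null(p=0.25),
                seed=100 + rep, sibship_seed=77,
            )
            fams, truth = simulate_dataset(cfg)
            sizes.append([f.n_children for f in fams])
        assert sizes[0] == sizes[1]

    def test_admixture_records_population_labels(self, pool25):
        pool_b = make_fixture_pool(target_p=0.1, seed=99)
        cfg = SimConfig(
            20,
            [(pool25, 12), (pool_b, 8)],
            DiseaseModel.null(p=0.25),
            seed=10,
        )
        fams, truth = simulate_dataset(cfg)
        assert fams.n == 20
        assert truth.populations == [0] * 12 + [1] * 8
        assert len(truth.true_cores) == 2

    def test_admixture_counts_must_sum(self, pool25):
        cfg = SimConfig(10, [(pool25, 4), (pool25, 4)], DiseaseModel.null(p=0.25))
        with pytest.raises(ValueError):
            simulate_dataset(cfg)
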