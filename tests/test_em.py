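"""EM frequency estimation against closed forms and exhaustive-grid MLEs."""

import numpy as np
import pytest

from hapcore.clustering import CoreSystem
from hapcore.em import (
    ExplanationData,
    TrNtrFrequencies,
    em_core_coded,
    em_frequencies,
    em_tr_ntr,
    family_loglik_alt,
    family_loglik_null,
    pooled_estimate,
)
from hapcore.haplotypes import HaplotypeTable
from hapcore.pedigree import AFFECTED, UNAFFECTED
from hapcore.phase import build_explanations
from hapcore.simulate import DiseaseModel, SimConfig, simulate_dataset

from helpers import family_set, grid_mle, loglik_oracle, make_family

TAB3 = HaplotypeTable(["11", "21", "22"], [0.5, 0.3, 0.2])


@pytest.fixture(scope="module")
def toy_fams():
    """Three 2-marker families with genuine phase ambiguity."""
    fams = [
        make_family(("11", "22"), ("21", "22"), [("11", "21", AFFECTED)], "F1"),
        make_family(("21", "21"), ("11", "22"), [("21", "22", AFFECTED),
                                                 ("21", "11", UNAFFECTED)], "F2"),
        make_family(("11", "21"), ("11", "21"), [("11", "11", AFFECTED)], "F3"),
    ]
    return family_set(fams)


class TestFamilyLoglik:
    def test_single_unambiguous_explanation_closed_form(self):
        fam = make_family(("11", "11"), ("11", "11"),
                          [("11", "11", AFFECTED), ("11", "11", UNAFFECTED)])
        es = build_explanations(fam, TAB3)
        freqs = np.array([0.5, 0.3, 0.2])
        # one explanation: pi_0^4 times s = 4 for the single extra child
        assert family_loglik_null(es, freqs) == pytest.approx(np.log(0.5**4 * 4))

    def test_matches_brute_force_oracle(self, toy_fams):
        freqs = np.array([0.6, 0.3, 0.1])
        total = sum(
            family_loglik_null(build_explanations(fam, TAB3), freqs)
            for fam in toy_fams
        )
        assert total == pytest.approx(loglik_oracle(toy_fams, TAB3, freqs))

    def test_alt_nests_null_and_matches_oracle(self, toy_fams):
        tr = np.array([0.2, 0.5, 0.3])
        ntr = np.array([0.6, 0.3, 0.1])
        tn = TrNtrFrequencies(tr, ntr)
        total = sum(
            family_loglik_alt(build_explanations(fam, TAB3), tn)
            for fam in toy_fams
        )
        assert total == pytest.approx(loglik_oracle(toy_fams, TAB3, tr, ntr))
        same = TrNtrFrequencies(tr, tr)
        for fam in toy_fams:
            es = build_explanations(fam, TAB3)
            assert family_loglik_alt(es, same) == pytest.approx(
                family_loglik_null(es, tr)
            )

    def test_zero_frequency_floored_to_finite(self, toy_fams):
        freqs = np.array([1.0, 0.0, 0.0])
        es = build_explanations(toy_fams.families[0], TAB3)
        assert np.isfinite(family_loglik_null(es, freqs))


class TestEmFrequencies:
    def test_unambiguous_families_reduce_to_counting(self):
        # each family contributes 4 known haplotype slots
        fams = family_set([
            make_family(("11", "11"), ("21", "21"), [("11", "21", AFFECTED)], "F1"),
            make_family(("21", "21"), ("21", "21"), [("21", "21", AFFECTED)], "F2"),
        ])
        res = em_frequencies(fams, TAB3)
        np.testing.assert_allclose(res.frequencies, [2 / 8, 6 / 8, 0.0], atol=1e-9)

    def test_matches_grid_search_mle(self, toy_fams):
        """EM frequencies agree with an exhaustive 1e-3 simplex grid search."""
        res = em_frequencies(toy_fams, TAB3)
        grid_hat, grid_ll = grid_mle(toy_fams, TAB3, n_dim=3, step=1e-3)
        assert np.abs(np.asarray(res.frequencies) - grid_hat).max() < 1.5e-3
        assert res.loglik >= grid_ll - 1e-9

    def test_loglik_trace_non_decreasing(self, null_dataset):
        fams, _ = null_dataset
        res = em_frequencies(fams)
        diffs = np.diff(res.trace)
        assert (diffs >= -1e-9).all()
        assert res.converged

    def test_invariant_to_family_order_and_relabeling(self, toy_fams):
        from hapcore.pedigree import FamilySet

        res = em_frequencies(toy_fams, TAB3)
        rev = FamilySet(toy_fams.panel, list(reversed(toy_fams.families)))
        res_rev = em_frequencies(rev, TAB3)
        np.testing.assert_allclose(res.frequencies, res_rev.frequencies, atol=1e-7)

        perm = [2, 0, 1]
        tab_perm = HaplotypeTable([TAB3.haplotypes[i] for i in perm],
                                  TAB3.frequencies[perm])
        res_perm = em_frequencies(toy_fams, tab_perm)
        for h in TAB3.haplotypes:
            a = res.frequencies[TAB3.index_of(h)]
            b = res_perm.frequencies[tab_perm.index_of(h)]
            assert a == pytest.approx(b, abs=1e-7)

    def test_parameter_recovery_on_simulated_data(self, pool25):
        """500 simulated families pin the pool frequencies within 0.03."""
        cfg = SimConfig(500, pool25, DiseaseModel.null(p=0.25), seed=17)
        fams, _ = simulate_dataset(cfg)
        table, _, _ = pooled_estimate(fams)
        err = []
        for h, f in zip(pool25.table.haplotypes, pool25.table.frequencies):
            est = table.frequencies[table.index_of(h)] if h in table.haplotypes else 0.0
            err.append(abs(est - f))
        assert max(err) < 0.03

    def test_estimation_error_shrinks_with_sample_size(self, pool25):
        errors = {}
        for N in (100, 400):
            errs = []
            for rep in range(3):
                cfg = SimConfig(N, pool25, DiseaseModel.null(p=0.25), seed=31 + rep)
                fams, _ = simulate_dataset(cfg)
                table, _, _ = pooled_estimate(fams)
                est = {h: f for h, f in zip(table.haplotypes, table.frequencies)}
                errs.append(max(
                    abs(est.get(h, 0.0) - f)
                    for h, f in zip(pool25.table.haplotypes, pool25.table.frequencies)
                ))
            errors[N] = np.median(errs)
        assert errors[400] < errors[100]


class TestEmTrNtr:
    def test_vectors_are_distributions_and_nest_null(self, toy_fams):
        null = em_frequencies(toy_fams, TAB3)
        alt = em_tr_ntr(toy_fams, TAB3)
        assert abs(alt.frequencies.tr.sum() - 1) < 1e-9
        assert abs(alt.frequencies.ntr.sum() - 1) < 1e-9
        assert alt.loglik >= null.loglik - 1e-9

    def test_matches_tr_ntr_grid_search(self, toy_fams):
        alt = em_tr_ntr(toy_fams, TAB3)
        (gt, gn), grid_ll = grid_mle(
            toy_fams, TAB3, n_dim=3, step=0.01, tr_ntr=True
        )
        assert alt.loglik >= grid_ll - 1e-9
        assert np.abs(alt.frequencies.tr - gt).max() < 0.02
        assert np.abs(alt.frequencies.ntr - gn).max() < 0.02

    def test_null_data_tr_close_to_ntr(self, pool25):
        cfg = SimConfig(400, pool25, DiseaseModel.null(p=0.25), seed=13)
        fams, _ = simulate_dataset(cfg)
        table, _, _ = pooled_estimate(fams)
        alt = em_tr_ntr(fams, table)
        assert np.abs(alt.frequencies.tr - alt.frequencies.ntr).max() < 0.08

    def test_disease_data_shifts_carrier_mass_to_transmitted(self, disease_dataset, pool25):
        fams, truth = disease_dataset
        table, _, _ = pooled_estimate(fams)
        alt = em_tr_ntr(fams, table)
        carrier = np.array(
            [h[pool25.liability_index] == "2" for h in table.haplotypes]
        )
        tr_mass = alt.frequencies.tr[carrier].sum()
        ntr_mass = alt.frequencies.ntr[carrier].sum()
        assert tr_mass > ntr_mass + 0.05


class TestEmCoreCoded:
    def test_mass_one_clustering_is_identity(self, toy_fams):
        null = em_frequencies(toy_fams, TAB3)
        est = TAB3.with_frequencies(np.maximum(null.frequencies, 1e-9) /
                                    np.maximum(null.frequencies, 1e-9).sum())
        cs = CoreSystem.build(est, mass=1.0)
        res = em_core_coded(toy_fams, cs, TAB3, mode="null")
        assert res.loglik == pytest.approx(null.loglik, abs=1e-6)

    def test_single_core_likelihood_constant(self):
        tab = HaplotypeTable(["11"], [1.0])
        fams = family_set([
            make_family(("11", "11"), ("11", "11"), [("11", "11", AFFECTED)]),
        ])
        cs = CoreSystem.build(tab, mass=0.9)
        null = em_core_coded(fams, cs, tab, mode="null")
        alt = em_core_coded(fams, cs, tab, mode="alternative")
        assert null.loglik == pytest.approx(alt.loglik, abs=1e-9)

    def test_two_cores_one_rare_matches_grid_search(self, toy_fams):
        """Core-coded MLE agrees with a 1-D exhaustive search over the
        2-core simplex, scoring the rare haplotype by its recode row."""
        est = TAB3.with_frequencies([0.55, 0.35, 0.10])
        cs = CoreSystem.build(est, mass=0.9)  # cores {11, 21}, rare 22
        A = cs.recode_matrix(est)
        res = em_core_coded(toy_fams, cs, TAB3, mode="null")
        scores = lambda g: A @ np.asarray(g, float)  # noqa: E731
        ghat, grid_ll = grid_mle(
            toy_fams, TAB3, n_dim=2, step=1e-3, scores=scores
        )
        assert res.loglik >= grid_ll - 1e-9
        assert np.abs(np.asarray(res.frequencies) - ghat).max() < 1.5e-3
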