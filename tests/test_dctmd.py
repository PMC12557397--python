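"""dcTMD free-energy estimation from nonequilibrium work curves."""

import numpy as np
import pytest

from pathsim import (KB, Partition, WorkEnsemble, free_energy,
                     generate_work_ensemble, integrate_work,
                     pathwise_free_energy, work_normality_diagnostics)
from pathsim.cluster import QUESTION_CLUSTER
from pathsim.dctmd import resample_works


class TestIntegrateWork:
    def test_constant_force(self):
        x = np.linspace(0, 2, 21)
        forces = np.full((3, x.size), 5.0)
        we = integrate_work(forces, x, temperature=300.0)
        np.testing.assert_allclose(we.works[:, -1], 10.0, rtol=1e-12)
        np.testing.assert_allclose(we.works[:, 0], 0.0)

    def test_zero_force(self):
        x = np.linspace(0, 1, 5)
        we = integrate_work(np.zeros((2, 5)), x, 300.0)
        assert np.all(we.works == 0.0)

    def test_linear_force_quadratic_work(self):
        x = np.linspace(0, 1, 2001)
        a = 3.0
        we = integrate_work(np.tile(a * x, (2, 1)), x, 300.0)
        assert we.works[0, -1] == pytest.approx(a / 2, abs=1e-6)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            integrate_work(np.zeros((2, 3)), np.array([0.0, 1.0, 1.0]), 300.0)


class TestFreeEnergy:
    def test_identical_works_no_dissipation(self):
        x = np.linspace(0, 1, 6)
        w = np.tile(x * 4.0, (5, 1))
        prof = free_energy(WorkEnsemble(x, w, 300.0))
        np.testing.assert_allclose(prof.deltaG, x * 4.0)
        np.testing.assert_allclose(prof.dissipative_work, 0.0)

    def test_gaussian_moments_analytic_value(self):
        # W ~ Normal(30, 20) at the probe point, k_B T = 2.494 kJ/mol:
        # dG = 30 - 20 / (2 * 2.494) = 25.99 kJ/mol
        temperature = 2.494 / KB
        n = 10_000
        rng = np.random.default_rng(42)
        sample = rng.normal(30.0, np.sqrt(20.0), n)
        works = np.column_stack([np.zeros(n), sample])
        prof = free_energy(WorkEnsemble(np.array([0.0, 1.0]), works, temperature))
        expected = 30.0 - 20.0 / (2 * 2.494)
        se = np.sqrt(20.0 / n + 2 * 20.0 ** 2 / (n - 1) / (2 * 2.494) ** 2)
        assert abs(prof.deltaG[1] - expected) < 3 * se

    def test_generative_model_recovery(self):
        x = np.linspace(0, 2, 25)
        dg = 10.0 * np.sin(np.pi * x / 4) ** 2
        wd = 8.0 * x / x[-1]
        we = generate_work_ensemble(dg, wd, temperature=300.0, n=1000,
                                    x_grid=x, seed=7)
        prof = free_energy(we)
        var = 2 * KB * 300.0 * wd
        se_mean = np.sqrt(var / we.n)
        se_var = np.sqrt(2 * var ** 2 / (we.n - 1)) / (2 * KB * 300.0)
        se = np.sqrt(se_mean ** 2 + se_var ** 2)
        assert np.all(np.abs(prof.deltaG[1:] - dg[1:]) < 3 * se[1:] + 1e-9)

    def test_dissipation_nonnegative(self):
        x = np.linspace(0, 1, 10)
        rng = np.random.default_rng(0)
        works = np.column_stack([np.zeros(50), rng.normal(5, 1, (50, 9))])
        prof = free_energy(WorkEnsemble(x, works, 300.0))
        assert np.all(prof.deltaG <= prof.mean_work + 1e-12)
        assert np.all(prof.dissipative_work >= 0)

    def test_order_invariance(self):
        x = np.linspace(0, 1, 8)
        rng = np.random.default_rng(3)
        works = np.column_stack([np.zeros(20), rng.normal(2, 1, (20, 7))])
        p1 = free_energy(WorkEnsemble(x, works, 300.0))
        p2 = free_energy(WorkEnsemble(x, works[::-1], 300.0))
        np.testing.assert_allclose(p1.deltaG, p2.deltaG, atol=1e-12)

    def test_single_curve_rejected(self):
        x = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="at least 2"):
            free_energy(WorkEnsemble(x, np.zeros((1, 2)), 300.0))


class TestPathwiseFreeEnergy:
    def make_two_population(self, n_each=150, seed=5):
        x = np.linspace(0, 2, 15)
        dg1 = 5.0 * x / x[-1]
        dg2 = 12.0 * x / x[-1]
        wd1 = 3.0 * x / x[-1]
        wd2 = 9.0 * x / x[-1]
        w1 = generate_work_ensemble(dg1, wd1, 300.0, n_each, x, seed=seed)
        w2 = generate_work_ensemble(dg2, wd2, 300.0, n_each, x, seed=seed + 1)
        works = WorkEnsemble(x, np.vstack([w1.works, w2.works]), 300.0)
        part = Partition(np.array([0] * n_each + [1] * n_each), gamma=0.5)
        return works, part, (dg1, dg2), (wd1, wd2)

    def test_one_qualifying_cluster(self):
        works, part, _, _ = self.make_two_population(n_each=150)
        part = Partition(np.array([0] * 150 + [1] * 50 + [0] * 100), gamma=0.5)
        profiles = pathwise_free_energy(works, part, min_cluster_size=100)
        assert list(profiles) == [0]
        assert profiles[0].n_used == 250

    def test_two_population_recovery(self):
        works, part, (dg1, dg2), (wd1, wd2) = self.make_two_population()
        profiles = pathwise_free_energy(works, part, min_cluster_size=100)
        for cid, dg, wd in ((0, dg1, wd1), (1, dg2, wd2)):
            var = 2 * KB * 300.0 * wd
            se = np.sqrt(var / 150 + 2 * var ** 2 / 149 / (2 * KB * 300.0) ** 2)
            assert np.all(np.abs(profiles[cid].deltaG[1:] - dg[1:]) < 4 * se[1:] + 1e-9)

    def test_merged_pathways_inflate_dissipation(self):
        works, part, _, (wd1, wd2) = self.make_two_population()
        separate = pathwise_free_energy(works, part, min_cluster_size=100)
        merged = free_energy(works)
        w_within = (separate[0].dissipative_work + separate[1].dissipative_work) / 2
        # beyond the shared-x0 point the merge must dissipate more than the
        # size-weighted within-cluster average
        assert np.all(merged.dissipative_work[5:] >= w_within[5:])
        assert merged.dissipative_work[-1] > max(separate[0].dissipative_work[-1],
                                                 separate[1].dissipative_work[-1])

    def test_min_size_above_n_gives_empty(self):
        works, part, _, _ = self.make_two_population(n_each=20)
        assert pathwise_free_energy(works, part, min_cluster_size=1000) == {}

    def test_question_cluster_skipped(self):
        works, part, _, _ = self.make_two_population(n_each=150)
        assignment = part.assignment.copy()
        assignment[:150] = QUESTION_CLUSTER
        profiles = pathwise_free_energy(works, Partition(assignment, gamma=0.5),
                                        min_cluster_size=100)
        assert list(profiles) == [1]


class TestNormalityDiagnostics:
    def test_gaussian_pvalues_not_extreme(self):
        x = np.linspace(0, 1, 5)
        pvals = []
        for seed in range(40):
            we = generate_work_ensemble(np.zeros(5), 2.0 * x, 300.0, 100, x, seed=seed)
            rec = work_normality_diagnostics(we, [1.0])[0]
            pvals.append(rec["pvalue"])
        # under H0 p-values are ~uniform: mean near 0.5, few tiny values
        assert 0.3 < np.mean(pvals) < 0.7
        assert np.mean(np.array(pvals) < 0.01) < 0.15

    def test_power_against_exponential(self):
        x = np.array([0.0, 1.0])
        rejected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            works = np.column_stack([np.zeros(200), rng.exponential(5.0, 200)])
            we = WorkEnsemble(x, works, 300.0)
            if work_normality_diagnostics(we, [1.0])[0]["pvalue"] < 0.01:
                rejected += 1
        assert rejected >= 0.95 * n_seeds

    def test_qq_near_identity_for_gaussian(self):
        x = np.array([0.0, 1.0])
        rng = np.random.default_rng(11)
        works = np.column_stack([np.zeros(5000), rng.normal(10, 2, 5000)])
        rec = work_normality_diagnostics(WorkEnsemble(x, works, 300.0), [1.0])[0]
        resid = rec["sample_quantiles"] - rec["normal_quantiles"]
        # DKW-type bound on the bulk (extreme order statistics excluded)
        assert np.max(np.abs(resid[50:-50])) < 0.3

    def test_too_few_curves_rejected(self):
        we = WorkEnsemble(np.array([0.0, 1.0]), np.zeros((4, 2)), 300.0)
        with pytest.raises(ValueError, match="at least 8"):
            work_normality_diagnostics(we, [1.0])


class TestResample:
    def test_linear_resampling_preserves_values_on_subgrid(self):
        x = np.linspace(0, 1, 11)
        works = np.tile(x * 3.0, (3, 1))
        we = WorkEnsemble(x, works, 300.0)
        out = resample_works(x[::2], we)
        np.testing.assert_allclose(out.works, works[:, ::2], atol=1e-12)

    def test_extrapolation_rejected(self):
        we = WorkEnsemble(np.linspace(0, 1, 5), np.zeros((2, 5)), 300.0)
        with pytest.raises(ValueError, match="beyond"):
            resample_works(np.linspace(0, 2, 5), we)
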