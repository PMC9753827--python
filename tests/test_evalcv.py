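"""Fold plans, accuracy/bias arithmetic, paired tests, CV orchestration."""

import numpy as np
import pytest

from haplogp.evalcv import (
    accuracy,
    bias,
    kfold_split,
    paired_onesided_ttest,
    percent_change,
    run_cv,
)
from haplogp.grm import vanraden_grm
from haplogp.simdata import SimConfig, simulate_panel, simulate_phenotypes


class TestKFold:
    def test_ten_ids_five_folds(self):
        plan = kfold_split([f"s{i}" for i in range(10)], k=5, repeats=2, seed=1)
        for groups in plan.assignments:
            assert all(len(g) == 2 for g in groups)
            union = sorted(np.concatenate(groups).tolist())
            assert union == sorted(f"s{i}" for i in range(10))

    def test_same_seed_identical_plan(self):
        ids = [f"s{i}" for i in range(23)]
        p1 = kfold_split(ids, seed=9)
        p2 = kfold_split(ids, seed=9)
        for g1, g2 in zip(p1.assignments, p2.assignments):
            for a, b in zip(g1, g2):
                np.testing.assert_array_equal(a, b)

    def test_1387_ids_balanced(self):
        plan = kfold_split([f"s{i}" for i in range(1387)], k=5, repeats=1, seed=0)
        sizes = sorted(len(g) for g in plan.assignments[0])
        assert sizes == [277, 277, 277, 278, 278]

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=5)


class TestAccuracyBias:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_correlation(self):
        assert accuracy([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_flagged(self):
        assert np.isnan(accuracy([1, 2, 3], [5, 5, 5]))

    def test_bias_identity_and_scaling(self):
        g = np.array([1.0, 2.0, 3.0])
        assert bias(g, g) == pytest.approx(1.0)
        assert bias(2 * g, g) == pytest.approx(2.0)

    def test_bias_hand_value(self):
        assert bias(np.array([2.0, 2.0, 5.0]), np.array([1.0, 2.0, 3.0])) == pytest.approx(1.5)

    def test_bias_zero_variance_flagged(self):
        assert np.isnan(bias([1.0, 2.0, 3.0], [1.0, 1.0, 1.0]))

    def test_shift_invariance_and_scale_behaviour(self, rng):
        y = rng.standard_normal(50)
        g = 0.5 * y + rng.standard_normal(50) * 0.3
        assert accuracy(y + 3, g + 3) == pytest.approx(accuracy(y, g))
        assert bias(y + 3, g + 3) == pytest.approx(bias(y, g))
        assert accuracy(y, 2.5 * g) == pytest.approx(accuracy(y, g))
        assert bias(y, 2.5 * g) == pytest.approx(bias(y, g) / 2.5)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, df, p = paired_onesided_ttest([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (t, p) == (0.0, 0.5)

    def test_textbook_closed_form(self):
        d = np.array([0.02, 0.01, 0.03, 0.00, 0.02])
        a = 0.5 + d
        b = np.full(5, 0.5)
        t, df, p = paired_onesided_ttest(a, b)
        # closed form: t = mean(d)/(sd(d)/sqrt(n))
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        from scipy import stats

        assert df == 4
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(float(stats.t.sf(t_exp, 4)), abs=1e-12)

    def test_swap_maps_p_to_one_minus_p(self, rng):
        a = rng.standard_normal(8)
        b = a + rng.standard_normal(8) * 0.1
        _, _, p1 = paired_onesided_ttest(a, b)
        _, _, p2 = paired_onesided_ttest(b, a)
        assert p1 + p2 == pytest.approx(1.0)

    def test_degenerate_nonzero_differences(self):
        with pytest.warns(UserWarning):
            t, df, p = paired_onesided_ttest([1.0, 1.0], [0.5, 0.5])
        assert p == 0.0


class TestPercentChange:
    def test_identical_gives_zero(self):
        pc, se = percent_change([0.5, 0.4], [0.5, 0.4])
        assert pc == 0.0 and se == 0.0

    def test_constant_gain(self):
        pc, se = percent_change([0.54] * 6, [0.50] * 6)
        assert pc == pytest.approx(8.0)
        assert se == pytest.approx(0.0)

    def test_matches_spreadsheet_recount(self, rng):
        h = rng.uniform(0.3, 0.6, size=10)
        s = rng.uniform(0.3, 0.6, size=10)
        pc, se = percent_change(h, s)
        vals = [100 * (hi - si) / si for hi, si in zip(h, s)]
        assert pc == pytest.approx(np.mean(vals))
        assert se == pytest.approx(np.std(vals, ddof=1) / np.sqrt(10))

    def test_nonpositive_baseline_excluded(self):
        with pytest.warns(UserWarning):
            pc, _ = percent_change([0.5, 0.5], [-0.1, 0.5])
        assert pc == pytest.approx(0.0)


class TestRunCV:
    @pytest.fixture(scope="class")
    @staticmethod
    def bundle():
        cfg = SimConfig(n_individuals=200, n_chromosomes=2, markers_per_chrom=150,
                        n_qtl=30, h2_target=0.5, seed=70)
        panel = simulate_panel(cfg)
        pheno, truth = simulate_phenotypes(panel, cfg)
        M = panel.genotypes().astype(float)
        p = M.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        g = vanraden_grm(M[:, ok], p[ok], sample_ids=panel.sample_ids)
        return panel, pheno, truth, g, (M[:, ok], p[ok])

    def test_determinism(self, bundle):
        panel, pheno, _, g, _ = bundle
        y = pheno.trait_values()
        plan = kfold_split(panel.sample_ids, k=5, repeats=1, seed=3)
        r1 = run_cv(y, panel.sample_ids, "GBLUP", plan, grms=[g])
        r2 = run_cv(y, panel.sample_ids, "GBLUP", plan, grms=[g])
        assert r1.records.equals(r2.records)

    def test_near_perfect_heritability_high_accuracy(self):
        # training records exceed the marker count so the marker effects are
        # fully estimable and accuracy is limited only by the tiny residual
        cfg = SimConfig(n_individuals=300, n_chromosomes=2, markers_per_chrom=75,
                        n_qtl=30, h2_target=0.99, seed=71)
        panel = simulate_panel(cfg)
        pheno, _ = simulate_phenotypes(panel, cfg)
        M = panel.genotypes().astype(float)
        p = M.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        g = vanraden_grm(M[:, ok], p[ok], sample_ids=panel.sample_ids)
        plan = kfold_split(panel.sample_ids, k=5, repeats=1, seed=4)
        res = run_cv(pheno.trait_values(), panel.sample_ids, "GBLUP", plan, grms=[g])
        assert res.summary()["mean_accuracy"] > 0.9

    def test_no_leakage_of_validation_phenotypes(self, bundle):
        """Permuting a validation individual's phenotype must not move its
        GEBV: the fold fit never sees validation records."""
        panel, pheno, _, g, _ = bundle
        y = pheno.trait_values().copy()
        plan = kfold_split(panel.sample_ids, k=5, repeats=1, seed=5)
        val_ids = plan.assignments[0][0]
        pos = {s: i for i, s in enumerate(panel.sample_ids)}
        val_idx = [pos[s] for s in val_ids]

        from haplogp.mixedmodel import GBLUP

        train_ids = [s for s in panel.sample_ids if s not in set(val_ids)]
        train_idx = [pos[s] for s in train_ids]

        res1 = GBLUP(y[train_idx], [g], train_ids=train_ids).fit()
        y2 = y.copy()
        y2[val_idx] = y2[val_idx][::-1] + 100.0  # scramble validation records
        res2 = GBLUP(y2[train_idx], [g], train_ids=train_ids).fit()
        np.testing.assert_allclose(
            res1.gebv.loc[list(val_ids)], res2.gebv.loc[list(val_ids)], atol=1e-10
        )

    def test_failed_fold_recorded_not_fatal(self, bundle):
        panel, pheno, _, g, _ = bundle
        y = pheno.trait_values()
        plan = kfold_split(panel.sample_ids, k=5, repeats=1, seed=6)
        bad = np.full_like(g.matrix, np.nan)

        class BadG:
            matrix = bad
            sample_ids = g.sample_ids
            source = "snp"

        with pytest.warns(UserWarning, match="failed"):
            res = run_cv(y, panel.sample_ids, "GBLUP", plan, grms=[BadG()])
        assert res.summary()["n_failed"] == 5

    def test_bayes_model_runs_through_cv(self, bundle):
        panel, pheno, _, _, cols = bundle
        from haplogp.bayesb import BayesBConfig

        M, p = cols
        plan = kfold_split(panel.sample_ids, k=4, repeats=1, seed=8)
        res = run_cv(
            pheno.trait_values(), panel.sample_ids, "BayesB", plan,
            design_columns=(M, p),
            bayes_cfg=BayesBConfig(pi=0.9, chain_length=800, burn_in=200, seed=1),
        )
        s = res.summary()
        assert s["n_failed"] == 0
        assert -1 <= s["mean_accuracy"] <= 1
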