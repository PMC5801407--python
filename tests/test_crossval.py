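"""Fold construction, leakage-free CV metrics, and calibration."""

import numpy as np
import pytest

from granos.crossval import (
    bias_slope,
    plan_folds,
    predictive_ability,
    run_cv,
)
from granos.io import GranosError, PhenotypeTable, design_matrix
from conftest import structured_population


class TestPlanFolds:
    def test_loo_singletons(self):
        plan = plan_folds("loo", [f"L{i}" for i in range(5)])
        assert len(plan.units) == 5
        for unit in plan.units:
            assert len(unit.val_idx) == 1
            assert len(unit.train_idx) == 4

    def test_kfold_sizes_near_equal_and_seeded(self):
        lines = [f"L{i}" for i in range(635)]
        plan = plan_folds("kfold", lines, k=2, seed=0)
        sizes = sorted(len(u.train_idx) for u in plan.units)
        assert sizes == [317, 318]  # training sets of ~318 lines
        plan2 = plan_folds("kfold", lines, k=2, seed=0)
        np.testing.assert_array_equal(
            plan.units[0].val_idx, plan2.units[0].val_idx
        )
        for k, train_size in [(5, 508), (10, 571)]:
            plan_k = plan_folds("kfold", lines, k=k, seed=0)
            trains = {len(u.train_idx) for u in plan_k.units}
            assert min(trains) >= train_size

    def test_kfold_with_k_equal_n_is_loo(self):
        lines = [f"L{i}" for i in range(8)]
        loo = plan_folds("loo", lines)
        kf = plan_folds("kfold", lines, k=8, seed=1)
        loo_vals = sorted(int(u.val_idx[0]) for u in loo.units)
        kf_vals = sorted(int(u.val_idx[0]) for u in kf.units)
        assert loo_vals == kf_vals
        assert all(len(u.val_idx) == 1 for u in kf.units)

    def test_lfo_fullsib_excludes_parent_sharers(self):
        # families AxB (3 lines), CxD (2), AxC (2), ExF (2): validating
        # the AxB cross drops the AxC lines from training too (shared
        # parent A), leaving CxD and ExF
        lines = [f"L{i}" for i in range(9)]
        mother = ["A", "A", "A", "C", "C", "A", "A", "E", "E"]
        father = ["B", "B", "B", "D", "D", "C", "C", "F", "F"]
        ped = PhenotypeTable(lines, "t", np.zeros(9), ["s"] * 9, mother,
                            father)
        plan = plan_folds("lfo", lines, pedigree=ped, family_unit="fullsib")
        unit_ab = next(u for u in plan.units if u.name == "AxB")
        assert sorted(unit_ab.val_idx) == [0, 1, 2]
        assert sorted(unit_ab.train_idx) == [3, 4, 7, 8]
        assert plan.family_key["L0"] == "AxB"

    def test_lfo_halfsib_units_span_both_parents(self):
        # half-sib unit of parent C covers CxD and AxC lines; training
        # must then exclude everything sharing A, C or D -- here nothing
        # remains, which the plan reports as an error for that unit
        lines = [f"L{i}" for i in range(7)]
        mother = ["A", "A", "A", "C", "C", "A", "A"]
        father = ["B", "B", "B", "D", "D", "C", "C"]
        ped = PhenotypeTable(lines, "t", np.zeros(7), ["s"] * 7, mother,
                            father)
        with pytest.raises(GranosError, match="no training"):
            plan_folds("lfo", lines, pedigree=ped, family_unit="halfsib")

    def test_lfo_without_pedigree_refuses(self):
        lines = ["L0", "L1"]
        ped = PhenotypeTable(lines, "t", np.zeros(2), ["s"] * 2)
        with pytest.raises(GranosError, match="mother/father"):
            plan_folds("lfo", lines, pedigree=ped)

    def test_lfo_single_shared_parent_errors(self):
        lines = ["L0", "L1"]
        ped = PhenotypeTable(lines, "t", np.zeros(2), ["s"] * 2,
                            ["A", "A"], ["B", "C"])
        with pytest.raises(GranosError, match="no training"):
            plan_folds("lfo", lines, pedigree=ped)

    def test_lso_one_fold_per_set(self):
        lines = [f"L{i}" for i in range(6)]
        sets = ["a", "a", "b", "b", "b", "a"]
        plan = plan_folds("lso", lines, set_factor=sets)
        assert {u.name for u in plan.units} == {"a", "b"}
        unit_b = next(u for u in plan.units if u.name == "b")
        assert sorted(unit_b.val_idx) == [2, 3, 4]

    def test_lso_single_level_refuses(self):
        with pytest.raises(GranosError, match="two set levels"):
            plan_folds("lso", ["L0", "L1"], set_factor=["a", "a"])

    def test_k_larger_than_n_refuses(self):
        with pytest.raises(GranosError, match="exceeds"):
            plan_folds("kfold", ["L0", "L1"], k=5, seed=0)

    def test_every_line_predicted_at_least_once(self, tiny_pop):
        g, pheno, _, _ = tiny_pop
        for scheme, kw in [
            ("loo", {}),
            ("kfold", {"k": 5, "seed": 0}),
            ("lso", {"set_factor": pheno.set_factor}),
            ("lfo", {"pedigree": pheno}),
        ]:
            plan = plan_folds(scheme, g.line_ids, **kw)
            covered = set()
            for u in plan.units:
                covered.update(u.val_idx.tolist())
            assert covered == set(range(g.n_lines))


class TestMetrics:
    def test_perfect_agreement(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictive_ability(v, v) == pytest.approx(1.0)
        slope, se = bias_slope(v, v)
        assert slope == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert predictive_ability(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        r = predictive_ability(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 3.0, 2.0, 4.0])
        )
        assert r == pytest.approx(0.8)

    def test_double_scale_gebv(self):
        rng = np.random.default_rng(0)
        gebv = rng.standard_normal(30)
        y = gebv + 0.3 * rng.standard_normal(30)
        r1 = predictive_ability(y, gebv)
        r2 = predictive_ability(y, 2 * gebv)
        assert r1 == pytest.approx(r2)
        s1, _ = bias_slope(y, gebv)
        s2, _ = bias_slope(y, 2 * gebv)
        assert s2 == pytest.approx(s1 / 2)

    def test_constant_gebv_rejected_for_slope(self):
        with pytest.raises(GranosError, match="constant"):
            bias_slope(np.array([1.0, 2.0, 3.0]), np.ones(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(GranosError, match="length"):
            predictive_ability(np.zeros(4), np.zeros(5))

    def test_under_dispersed_gebvs_inflate_slope(self):
        # over-shrunken predictions (scaled-down GEBVs) give slope > 1
        rng = np.random.default_rng(1)
        slopes = []
        for _ in range(10):
            u = rng.standard_normal(100)
            y = u + 0.5 * rng.standard_normal(100)
            slopes.append(bias_slope(y, 0.5 * u)[0])
        assert np.mean(slopes) > 1.2


class TestRunCv:
    def test_calibrated_h2_gives_high_r_and_unit_slope(self, medium_pop):
        g, pheno, _, _ = medium_pop
        X, _ = design_matrix(pheno.set_factor)
        plan = plan_folds("loo", g.line_ids)
        res = run_cv(plan, "gblup", pheno.y, X, g)
        assert 0.6 <= res.predictive_ability <= 0.95
        assert res.bias_slope == pytest.approx(1.0, abs=0.15)
        assert res.predictive_ability <= res.h_max + 0.05

    def test_pure_noise_r_near_zero(self):
        rs = []
        for seed in range(6):
            g, pheno, _, _ = structured_population(
                1000 + seed, h2=0.0, n_families=20, fam_size=5, m=150
            )
            X, _ = design_matrix(pheno.set_factor)
            plan = plan_folds("kfold", g.line_ids, k=5, seed=seed)
            res = run_cv(plan, "gblup", pheno.y, X, g)
            # boundary fits predict a constant 0: no detectable association
            rs.append(0.0 if np.isnan(res.predictive_ability)
                      else res.predictive_ability)
        assert abs(np.mean(rs)) < 0.15

    def test_loo_beats_lfo_on_average(self):
        # losing relatives from training costs accuracy (GxE-free data)
        diffs = []
        for seed in range(8):
            g, pheno, _, _ = structured_population(2000 + seed)
            X, _ = design_matrix(pheno.set_factor)
            loo = run_cv(plan_folds("loo", g.line_ids), "gblup", pheno.y,
                         X, g)
            lfo = run_cv(
                plan_folds("lfo", g.line_ids, pedigree=pheno), "gblup",
                pheno.y, X, g, min_train=5,
            )
            diffs.append(loo.predictive_ability - lfo.predictive_ability)
        assert np.mean(diffs) >= 0.0

    def test_r_non_decreasing_in_k(self):
        means = {k: [] for k in (2, 5, 10)}
        for seed in range(8):
            g, pheno, _, _ = structured_population(3000 + seed)
            X, _ = design_matrix(pheno.set_factor)
            for k in (2, 5, 10):
                plan = plan_folds("kfold", g.line_ids, k=k, seed=seed)
                res = run_cv(plan, "gblup", pheno.y, X, g)
                means[k].append(res.predictive_ability)
        assert np.mean(means[2]) <= np.mean(means[5]) + 0.02
        assert np.mean(means[5]) <= np.mean(means[10]) + 0.02

    def test_no_leakage_from_validation_phenotypes(self, tiny_pop):
        # permuting validation-fold phenotypes leaves that fold's
        # predictions untouched
        g, pheno, _, _ = tiny_pop
        X, _ = design_matrix(pheno.set_factor)
        plan = plan_folds("kfold", g.line_ids, k=5, seed=2)
        res = run_cv(plan, "gblup", pheno.y, X, g)
        val_idx = plan.units[0].val_idx
        y_perm = pheno.y.copy()
        y_perm[val_idx] = np.random.default_rng(0).permutation(y_perm[val_idx])
        res_perm = run_cv(plan, "gblup", y_perm, X, g)
        fold_name = plan.units[0].name
        a = res.predictions.query("fold == @fold_name").set_index("line")
        b = res_perm.predictions.query("fold == @fold_name").set_index("line")
        np.testing.assert_allclose(
            a["gebv"].to_numpy(), b.loc[a.index, "gebv"].to_numpy(),
            atol=1e-10,
        )

    def test_power_lasso_predictor_runs(self, tiny_pop):
        from granos.powerlasso import ChainConfig

        g, pheno, _, _ = tiny_pop
        X, _ = design_matrix(pheno.set_factor)
        plan = plan_folds("kfold", g.line_ids, k=3, seed=1)
        res = run_cv(
            plan, "power_lasso", pheno.y, X, g,
            chain_cfg=ChainConfig(1_500, 500), seed=4,
        )
        assert np.isfinite(res.predictive_ability)
        assert len(res.predictions) == g.n_lines

    def test_small_training_folds_skipped(self, tiny_pop):
        g, pheno, _, _ = tiny_pop
        X, _ = design_matrix(pheno.set_factor)
        plan = plan_folds("kfold", g.line_ids, k=2, seed=0)
        res = run_cv(plan, "gblup", pheno.y, X, g, min_train=20)
        assert res.n_skipped_folds == 0  # 25-line training folds all pass
        # demanding more training lines than any fold has skips them all
        with pytest.raises(GranosError, match="no fold"):
            run_cv(plan, "gblup", pheno.y, X, g, min_train=1_000)

    def test_unknown_scheme_and_predictor_rejected(self, tiny_pop):
        g, pheno, _, _ = tiny_pop
        with pytest.raises(GranosError, match="unknown scheme"):
            plan_folds("bootstrap", g.line_ids)
        X, _ = design_matrix(pheno.set_factor)
        plan = plan_folds("loo", g.line_ids)
        with pytest.raises(GranosError, match="unknown predictor"):
            run_cv(plan, "magic", pheno.y, X, g)
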