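import numpy as np
import pandas as pd
import pytest

from battery_ontology.battery import BatteryError, DVMatrix
from battery_ontology.efa import (
    EFAError,
    align_factors,
    apply_weights,
    bootstrap_loadings,
    drop_measure_robustness,
    factor_score_reliability,
    factor_scores,
    fit_efa,
    fit_efa_from_corr,
    select_dimensionality,
    tucker_congruence,
)
from battery_ontology.synthetic import generate_battery, generate_retest

from conftest import small_config


def _dvm(X, prefix="dv"):
    names = [f"{prefix}{j}" for j in range(X.shape[1])]
    meta = pd.DataFrame({"measure": "m", "category": "task"},
                        index=pd.Index(names, name="dv_name"))
    return DVMatrix(pd.DataFrame(X, index=[f"p{i}" for i in range(X.shape[0])],
                                 columns=names), meta)


class TestMLFit:
    def test_spearman_closed_form(self):
        # one-factor loadings lambda_1 = sqrt(r12 * r13 / r23) etc.
        R = np.array([[1.0, 0.72, 0.63], [0.72, 1.0, 0.56], [0.63, 0.56, 1.0]])
        model = fit_efa_from_corr(R, 1, n_obs=500)
        assert np.allclose(
            model.loadings.to_numpy().ravel(), [0.9, 0.8, 0.7], atol=1e-3
        )

    def test_identity_correlation_gives_null_loadings(self):
        model = fit_efa_from_corr(np.eye(6), 1, n_obs=500)
        assert np.abs(model.loadings.to_numpy()).max() < 1e-6
        assert model.communality.max() < 1e-6

    def test_reconstruction_of_model_implied_correlations(self):
        # exact low-rank-plus-diagonal input must be reproduced
        rng = np.random.default_rng(0)
        L = np.zeros((10, 2))
        L[:5, 0] = rng.uniform(0.5, 0.8, 5)
        L[5:, 1] = rng.uniform(0.5, 0.8, 5)
        Phi = np.array([[1.0, 0.3], [0.3, 1.0]])
        R = L @ Phi @ L.T
        np.fill_diagonal(R, 1.0)
        model = fit_efa_from_corr(R, 2, n_obs=1000)
        Lh, Ph = model.loadings.to_numpy(), model.phi
        Rhat = Lh @ Ph @ Lh.T + np.diag(model.uniqueness.to_numpy())
        assert np.abs(Rhat - R).max() < 1e-4

    def test_too_many_factors_rejected(self):
        with pytest.raises(EFAError):
            fit_efa_from_corr(np.eye(4), 4, n_obs=100)


class TestRotation:
    def test_rotation_preserves_fit_and_communality(self, small_world):
        sub = small_world["battery"].select_category("task")
        rot = fit_efa(sub, 3, seed=0, rotate=True)
        unrot = fit_efa(sub, 3, seed=0, rotate=False)
        assert rot.fit["chi2"] == pytest.approx(unrot.fit["chi2"], abs=1e-6)
        assert np.allclose(
            rot.communality.to_numpy(), unrot.communality.to_numpy(), atol=1e-6
        )

    def test_communality_plus_uniqueness_is_one(self, small_world):
        sub = small_world["battery"].select_category("survey")
        model = fit_efa(sub, 4, seed=0)
        total = model.communality.to_numpy() + model.uniqueness.to_numpy()
        assert np.abs(total - 1.0).max() < 1e-5

    def test_phi_unit_diagonal_and_pd(self, small_world):
        model = fit_efa(small_world["battery"].select_category("survey"), 4, seed=0)
        assert np.allclose(np.diag(model.phi), 1.0, atol=1e-8)
        assert np.linalg.eigvalsh(model.phi).min() > 0


class TestDimensionality:
    def test_one_factor_data(self):
        cfg = small_config(seed=21)
        cfg.task.n_factors = 1
        cfg.task.n_dvs = 8
        battery, _ = generate_battery(cfg)
        sweep = select_dimensionality(
            battery.select_category("task"), range(1, 4), seed=0
        )
        assert sweep.best_f == 1

    def test_planted_factor_counts_recovered(self, small_world):
        b = small_world["battery"]
        assert select_dimensionality(
            b.select_category("task"), range(1, 7), seed=0).best_f == 3
        assert select_dimensionality(
            b.select_category("survey"), range(1, 8), seed=0).best_f == 4

    def test_sweep_reproducible(self, small_world):
        sub = small_world["battery"].select_category("task")
        s1 = select_dimensionality(sub, range(1, 5), seed=7)
        s2 = select_dimensionality(sub, range(1, 5), seed=7)
        pd.testing.assert_frame_equal(s1.sweep, s2.sweep)

    def test_empty_candidates_rejected(self, small_world):
        with pytest.raises(EFAError):
            select_dimensionality(
                small_world["battery"].select_category("task"), [], seed=0
            )


class TestScores:
    def test_tenberge_scores_reproduce_phi(self):
        cfg = small_config(seed=33, n_participants=2000)
        battery, _ = generate_battery(cfg)
        sub = battery.select_category("survey")
        model = fit_efa(sub, 4, seed=0)
        sc = factor_scores(model, sub)
        assert np.abs(np.corrcoef(sc.values, rowvar=False) - model.phi).max() < 0.02

    def test_scores_track_true_factors(self):
        cfg = small_config(seed=34, n_participants=1500)
        cfg.task.primary_range = (0.8, 0.9)
        cfg.task.cross_range = (0.0, 0.0)
        cfg.task.reliability_mean = 0.95
        cfg.task.reliability_sd = 0.0
        cfg.task.reliability_clip = (0.9, 0.99)
        battery, gt = generate_battery(cfg)
        sub = battery.select_category("task")
        model = fit_efa(sub, 3, seed=0)
        sc = factor_scores(model, sub).values
        true = gt.task_factor_scores().to_numpy()
        order, signs = align_factors(sc, true)
        aligned = sc[:, order] * signs
        rs = [np.corrcoef(aligned[:, j], true[:, j])[0, 1] for j in range(3)]
        assert min(rs) > 0.9

    def test_apply_weights_consistent_on_training_data(self, small_world):
        sub = small_world["battery"].select_category("task")
        model = fit_efa(sub, 3, seed=0)
        s1 = factor_scores(model, sub).values
        s2 = apply_weights(model, sub).values
        assert np.allclose(s1, s2, atol=1e-10)

    def test_apply_weights_column_mismatch_errors(self, small_world):
        sub = small_world["battery"].select_category("task")
        model = fit_efa(sub, 3, seed=0)
        missing = sub.select_dvs(sub.dv_names[:-1])
        with pytest.raises(BatteryError, match=sub.dv_names[-1]):
            apply_weights(model, missing)


class TestRobustness:
    def test_bootstrap_sd_small_when_structure_strong(self):
        cfg = small_config(seed=40, n_participants=800)
        cfg.task.primary_range = (0.85, 0.95)
        cfg.task.cross_range = (0.0, 0.0)
        cfg.task.reliability_mean = 0.97
        cfg.task.reliability_sd = 0.0
        cfg.task.reliability_clip = (0.95, 0.999)
        cfg.max_communality_frac = 0.99
        battery, _ = generate_battery(cfg)
        boot = bootstrap_loadings(
            battery.select_category("task"), 3, n_boot=30, seed=0
        )
        assert boot["sd"].to_numpy().max() < 0.05

    def test_bootstrap_alignment_invariant_to_dv_order(self, small_world):
        sub = small_world["battery"].select_category("task")
        rng = np.random.default_rng(0)
        perm = rng.permutation(sub.n_dvs)
        shuffled = sub.select_dvs([sub.dv_names[i] for i in perm])
        b1 = bootstrap_loadings(sub, 3, n_boot=20, seed=5)
        b2 = bootstrap_loadings(shuffled, 3, n_boot=20, seed=5)
        m1 = b1["mean"].loc[sub.dv_names]
        m2 = b2["mean"].loc[sub.dv_names]
        # refits see identical participant subsamples; factors realign
        order, signs = align_factors(m2.to_numpy(), m1.to_numpy())
        assert np.allclose(m1.to_numpy(), m2.to_numpy()[:, order] * signs,
                           atol=1e-6)

    def test_drop_measure_detects_planted_dependency(self):
        # one measure per factor block: dropping a measure removes its factor
        cfg = small_config(seed=41, n_participants=600)
        cfg.task.dvs_per_measure = 99
        battery, _ = generate_battery(cfg)
        sub = battery.select_category("task")
        table = drop_measure_robustness(sub, 3, seed=0)
        assert len(table) == 3
        for meas in table.index:
            row = np.sort(table.loc[meas].to_numpy())
            assert row[-1] > 0.9       # unaffected factors stay congruent
            assert row[0] < 0.8        # the factor this measure defined degrades


class TestScoreReliability:
    def test_identical_sessions_unit_r(self, small_world):
        sub = small_world["battery"].select_category("survey")
        model = fit_efa(sub, 4, seed=0)
        sc = factor_scores(model, sub)
        res = factor_score_reliability(sc, sc)
        assert np.allclose(res["table"]["pearson_r"], 1.0)
        assert np.allclose(res["table"]["icc3k"], 1.0)

    def test_pca_variance_matches_eigenvalues(self, small_world):
        sub = small_world["battery"].select_category("survey")
        model = fit_efa(sub, 4, seed=0)
        pair = small_world["retest"]
        s1 = apply_weights(model, pair.t1.select_dvs(sub.dv_names))
        s2 = apply_weights(model, pair.t2.select_dvs(sub.dv_names))
        res = factor_score_reliability(s1, s2)
        stacked = np.vstack([s1.values, s2.values])
        w = np.linalg.eigvalsh(np.cov(stacked, rowvar=False))[::-1]
        assert np.allclose(
            res["pca_variance_explained"], w[:2] / w.sum(), atol=1e-8
        )

    def test_retest_factor_scores_more_reliable_than_dvs(self, small_world):
        # factor scores integrate noisy DVs into a stabler trait measure
        from battery_ontology.reliability import reliability_table

        sub = small_world["battery"].select_category("task")
        model = fit_efa(sub, 3, seed=0)
        pair = small_world["retest"]
        s1 = apply_weights(model, pair.t1.select_dvs(sub.dv_names))
        s2 = apply_weights(model, pair.t2.select_dvs(sub.dv_names))
        res = factor_score_reliability(s1, s2)
        dv_rel = reliability_table(pair).table.loc[sub.dv_names, "pearson_r"]
        assert res["table"]["pearson_r"].mean() > dv_rel.mean()


class TestCongruence:
    def test_tucker_congruence_bounds_and_sign(self):
        a = np.array([0.5, 0.4, 0.1])
        assert tucker_congruence(a, a) == pytest.approx(1.0)
        assert tucker_congruence(a, -a) == pytest.approx(-1.0)
        assert tucker_congruence(a, np.zeros(3)) == 0.0

    def test_alignment_recovers_permutation(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(12, 4))
        perm = [2, 0, 3, 1]
        signs = np.array([1.0, -1.0, 1.0, -1.0])
        L = ref[:, perm] * signs
        order, sg = align_factors(L, ref)
        assert np.allclose(L[:, order] * sg, ref)
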