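import numpy as np
import pandas as pd
import pytest

from cpgclock.clock import (
    ClockModel,
    clock_objective,
    evaluate_feature_set,
    external_validate,
    fit_clock,
    load_clock,
    nonzero_features,
    predict_age,
    save_clock,
    transfer_fit,
)
from cpgclock.data_io import FeatureSet, MethylationMatrix

from conftest import planted_dataset


def all_features(m):
    return FeatureSet(tuple(m.cpg_ids))


class TestFitClock:
    def test_unpenalized_fit_matches_closed_form_least_squares(self):
        # noiseless, well-posed: one CpG exactly affine in age, the rest
        # random fillers, so the least-squares solution is unique and the
        # generating coefficients are recoverable by hand
        rng = np.random.default_rng(0)
        ages = rng.uniform(20, 90, size=50)
        X = rng.uniform(0.05, 0.95, size=(50, 5))
        X[:, 0] = 0.2 + 0.004 * (ages - 55.0)
        betas = pd.DataFrame(X, index=[f"s{i}" for i in range(50)],
                             columns=[f"cg{i}" for i in range(5)])
        m = MethylationMatrix(betas, pd.Series(ages, index=betas.index))
        clock = fit_clock(m, all_features(m), penalty_grid=[(0.0, 0.0)])
        # oracle 1: normal equations solved directly
        X1 = np.column_stack([X, np.ones(50)])
        coef, *_ = np.linalg.lstsq(X1, ages, rcond=None)
        np.testing.assert_allclose(clock.beta, coef[:-1], atol=1e-6)
        assert clock.intercept == pytest.approx(coef[-1], abs=1e-6)
        # oracle 2: invert the generating map age = 55 + (x0 - 0.2)/0.004
        expected = np.array([1 / 0.004, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(clock.beta, expected, atol=1e-6)
        assert clock.intercept == pytest.approx(55.0 - 0.2 / 0.004, abs=1e-6)

    def test_huge_l1_shrinks_everything_to_zero(self):
        m, _ = planted_dataset(1, n_cpgs=20)
        clock = fit_clock(m, all_features(m), penalty_grid=[(1e9, 0.0)])
        assert (clock.beta == 0).all()
        pred = predict_age(clock, m)
        np.testing.assert_allclose(pred, m.y.mean(), atol=1e-8)

    def test_ground_truth_features_give_accurate_held_out_clock(self):
        r2s = []
        for seed in range(5):
            m, truth = planted_dataset(seed)
            m_new, _ = planted_dataset(seed + 100)
            clock = fit_clock(m, truth, seed=seed)
            r2s.append(external_validate(clock, m_new).mean_r2)
        assert np.mean(r2s) >= 0.9

    def test_objective_never_worse_than_null_model(self):
        m, _ = planted_dataset(2, n_cpgs=15)
        fs = all_features(m)
        for pair in [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0), (5.0, 5.0)]:
            clock = fit_clock(m, fs, penalty_grid=[pair])
            null = ClockModel(clock.cpg_ids, np.zeros(len(fs)),
                              float(m.y.mean()), *pair)
            assert clock_objective(clock, m) <= clock_objective(null, m) + 1e-6

    def test_l1_monotonically_thins_the_clock(self):
        m, _ = planted_dataset(3, n_cpgs=30)
        fs = all_features(m)
        nnz = [
            len(nonzero_features(fit_clock(m, fs, penalty_grid=[(l1, 0.0)])))
            for l1 in [0.0, 10.0, 100.0, 1000.0, 1e6]
        ]
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))

    def test_training_r2_non_negative_with_zero_in_grid(self):
        m, _ = planted_dataset(4, n_cpgs=10)
        fs = all_features(m)
        clock = fit_clock(m, fs, penalty_grid=[(0.0, 0.0), (100.0, 100.0)])
        pred = predict_age(clock, m).to_numpy()
        ss_res = ((m.y - pred) ** 2).sum()
        ss_tot = ((m.y - m.y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0

    def test_single_sample_rejected(self):
        m, _ = planted_dataset(5, n_cpgs=5)
        one = m.take_samples([0])
        with pytest.raises(ValueError):
            fit_clock(one, all_features(m), penalty_grid=[(0.0, 0.0)])


class TestPredictAge:
    def hand_clock(self):
        return ClockModel(("cgA", "cgB"), np.array([10.0, -5.0]), 40.0, 0.0, 0.0)

    def test_two_feature_hand_arithmetic(self):
        clock = self.hand_clock()
        betas = pd.DataFrame({"cgA": [0.2, 0.8], "cgB": [0.4, 0.1]},
                             index=["s1", "s2"])
        m = MethylationMatrix(betas)
        # 40 + 10*0.2 - 5*0.4 = 40.0 ; 40 + 10*0.8 - 5*0.1 = 47.5
        assert predict_age(clock, m).tolist() == [40.0, 47.5]

    def test_all_zero_beta_predicts_intercept(self):
        clock = ClockModel(("cgA",), np.zeros(1), 33.0, 0.0, 0.0)
        m = MethylationMatrix(pd.DataFrame({"cgA": [0.1, 0.9]}, index=["a", "b"]))
        assert predict_age(clock, m).tolist() == [33.0, 33.0]

    def test_prediction_is_linear_in_the_betas(self):
        clock = self.hand_clock()
        x1 = pd.DataFrame({"cgA": [0.2], "cgB": [0.6]}, index=["a"])
        x2 = pd.DataFrame({"cgA": [0.8], "cgB": [0.2]}, index=["a"])
        alpha = 0.3
        mix = MethylationMatrix(alpha * x1 + (1 - alpha) * x2)
        p1 = predict_age(clock, MethylationMatrix(x1)).iloc[0]
        p2 = predict_age(clock, MethylationMatrix(x2)).iloc[0]
        assert predict_age(clock, mix).iloc[0] == pytest.approx(
            alpha * p1 + (1 - alpha) * p2
        )

    def test_missing_clock_cpgs_listed(self):
        clock = self.hand_clock()
        m = MethylationMatrix(pd.DataFrame({"cgA": [0.5]}, index=["a"]))
        with pytest.raises(KeyError, match="cgB"):
            predict_age(clock, m)


class TestNonzeroFeatures:
    def test_all_zero_clock_gives_empty_set(self):
        clock = ClockModel(("cgA", "cgB"), np.zeros(2), 50.0, 1.0, 0.0)
        assert len(nonzero_features(clock)) == 0

    def test_small_l1_on_noiseless_single_signal_selects_exactly_it(self):
        m, truth = planted_dataset(6, n_cpgs=15, n_informative=1, noise_sd=0.0)
        clock = fit_clock(m, all_features(m), penalty_grid=[(50.0, 0.0)])
        assert nonzero_features(clock).cpg_ids == truth.cpg_ids

    def test_output_subset_of_clock_features(self):
        m, _ = planted_dataset(7, n_cpgs=12)
        clock = fit_clock(m, all_features(m), seed=1)
        assert set(nonzero_features(clock)) <= set(clock.cpg_ids)


class TestExternalValidate:
    def test_self_validation_reproduces_in_sample_metrics(self):
        m, truth = planted_dataset(8)
        clock = fit_clock(m, truth, seed=0)
        rep = external_validate(clock, m)
        pred = predict_age(clock, m).to_numpy()
        err = np.abs(m.y - pred)
        assert rep.mae_years == pytest.approx(err.mean())
        assert rep.median_ae_years == pytest.approx(np.median(err))

    def test_independent_draw_scores_close_to_in_sample(self):
        for seed in range(3):
            m, truth = planted_dataset(seed)
            m_ext, _ = planted_dataset(seed + 50)
            clock = fit_clock(m, truth, seed=seed)
            assert abs(
                external_validate(clock, m).mean_r2
                - external_validate(clock, m_ext).mean_r2
            ) <= 0.1

    def test_constant_age_external_set_reports_nan_r2_with_mae(self):
        m, truth = planted_dataset(9)
        clock = fit_clock(m, truth, seed=0)
        betas = m.betas.iloc[:5]
        const = MethylationMatrix(betas, pd.Series(50.0, index=betas.index))
        rep = external_validate(clock, const)
        assert np.isnan(rep.mean_r2)
        assert np.isfinite(rep.mae_years)


class TestTransferFit:
    def test_transferred_truth_builds_accurate_clock_in_new_cohort(self):
        r2s = []
        for seed in range(5):
            m_a, truth = planted_dataset(seed)
            m_b, _ = planted_dataset(seed + 200)
            r2s.append(transfer_fit(truth, m_b, repeats=5, seed=seed).mean_r2)
        assert np.mean(r2s) >= 0.85

    def test_disjoint_features_fail_to_transfer(self):
        r2s = []
        for seed in range(5):
            m, truth = planted_dataset(seed)
            nulls = [c for c in m.cpg_ids if c not in set(truth)][:5]
            r2s.append(transfer_fit(FeatureSet(tuple(nulls)), m,
                                    repeats=5, seed=seed).mean_r2)
        assert np.mean(r2s) <= 0.2

    def test_transfer_on_same_matrix_is_evaluate_feature_set(self):
        m, truth = planted_dataset(10)
        a = transfer_fit(truth, m, repeats=4, seed=3)
        b = evaluate_feature_set(m, truth, repeats=4, seed=3)
        assert a.mean_r2 == b.mean_r2 and a.mae_years == b.mae_years


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path):
        m, truth = planted_dataset(11)
        clock = fit_clock(m, truth, seed=2)
        p1, p2 = tmp_path / "c1.tsv", tmp_path / "c2.tsv"
        save_clock(clock, p1)
        loaded = load_clock(p1)
        assert loaded.cpg_ids == clock.cpg_ids
        assert (loaded.beta == clock.beta).all()
        assert loaded.intercept == clock.intercept
        assert (loaded.lambda_l1, loaded.lambda_l2) == (clock.lambda_l1, clock.lambda_l2)
        save_clock(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
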