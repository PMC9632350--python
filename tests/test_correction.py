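"""The input-space gradient-descent age correction and the linear baseline."""

import numpy as np
import pandas as pd
import pytest

import tractage as ta
from tractage.correction import _step_cached
from tractage.errors import ParameterError


def _scalar_system(w=1.4, v=0.6, age_mean=50.0, age_sd=15.0):
    """One-tract network + scaler for closed-form checks."""
    ann = ta.ANNModel(W=np.array([[w]]), b_h=np.zeros(1), v=np.array([v]), c=0.0)
    scaler = ta.Scaler(
        fa_mean=pd.Series({"CST": 0.5}),
        fa_sd=pd.Series({"CST": 0.03}),
        age_mean=age_mean,
        age_sd=age_sd,
    )
    return ann, scaler


class TestCorrectionTarget:
    def test_zero_shift(self):
        assert ta.correction_target(61.0, 55.0, 55.0) == 61.0

    def test_arithmetic(self):
        assert ta.correction_target(60.0, 70.0, 50.0) == 40.0

    def test_shift_independent_of_prediction(self):
        s1 = ta.correction_target(60.0, 70.0, 50.0) - 60.0
        s2 = ta.correction_target(10.0, 70.0, 50.0) - 10.0
        assert s1 == s2 == -20.0


class TestCorrectionStep:
    def test_converged_point_is_fixed(self, rng):
        ann, _ = _scalar_system()
        x = np.array([0.8])
        y = float(ann.forward(x)[0])
        out = ta.correction_step(ann, x, y_target=y, lr=0.01)
        np.testing.assert_array_equal(out, x)

    def test_scalar_closed_form(self):
        # 1-tract network, w > 0, x > 0: x' = x (1 - lr E v x / w)
        w, v, lr = 1.4, 0.6, 0.005
        ann, _ = _scalar_system(w=w, v=v)
        x = 0.9
        y_target = 0.1
        E = max(x * w, 0.0) * v - y_target
        expected = x * (1 - lr * E * v * x / w)
        got = ta.correction_step(ann, np.array([x]), y_target, lr)[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        # dL/dW for L = (forward(x) - y_t)^2 / 2 on a 3-tract fixture
        W = np.eye(3) + rng.normal(scale=0.1, size=(3, 3))
        ann = ta.ANNModel(W=W, b_h=rng.normal(scale=0.1, size=3),
                          v=rng.normal(size=3), c=0.2)
        x = rng.normal(size=3)
        y_t = 1.5
        lr = 0.01
        x_prop = ta.correction_step(ann, x, y_t, lr)
        # recover the applied gradient: W' = W - lr G  =>  G from x' = x W' W^-1
        pre = x @ W + ann.b_h
        active = pre > 0
        E = float(np.maximum(pre, 0) @ ann.v + ann.c) - y_t
        G_analytic = E * np.outer(x, ann.v * active)
        eps = 1e-6
        for i in range(3):
            for j in range(3):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps

                def loss(Wq):
                    return 0.5 * (
                        float(np.maximum(x @ Wq + ann.b_h, 0) @ ann.v + ann.c)
                        - y_t
                    ) ** 2

                num = (loss(Wp) - loss(Wm)) / (2 * eps)
                assert num == pytest.approx(
                    G_analytic[i, j], rel=1e-5, abs=1e-10
                )
        # and the proposed input is exactly x (W - lr G) W^-1
        np.testing.assert_allclose(
            x_prop, x @ (W - lr * G_analytic) @ np.linalg.inv(W), rtol=1e-12
        )

    def test_model_not_mutated(self, rng):
        ann, _ = _scalar_system()
        W0 = ann.W.copy()
        ta.correction_step(ann, np.array([0.5]), 2.0, 0.01)
        np.testing.assert_array_equal(ann.W, W0)


class TestApplyConstraints:
    def test_frozen_always_original(self, rng):
        x0 = rng.normal(size=5)
        prop = rng.normal(size=5)
        out, rev = ta.apply_constraints(prop, x0, delta_sign=1.0,
                                        frozen_indices=[1, 3])
        assert out[1] == x0[1] and out[3] == x0[3]
        assert rev[1] and rev[3]

    def test_decreases_pass_when_target_older(self):
        x0 = np.array([1.0, 2.0, 3.0])
        prop = np.array([0.5, 1.5, 2.5])  # all decreased
        out, rev = ta.apply_constraints(prop, x0, 1.0, [])
        np.testing.assert_array_equal(out, prop)
        assert not rev.any()

    def test_single_violation_reverted_when_target_younger(self):
        x0 = np.array([1.0, 2.0, 3.0])
        prop = np.array([1.2, 1.9, 3.4])  # middle entry decreased
        out, rev = ta.apply_constraints(prop, x0, -1.0, [])
        assert out[1] == 2.0 and rev[1]
        assert out[0] == 1.2 and out[2] == 3.4
        assert not rev[0] and not rev[2]


class TestAnnAgeCorrect:
    def test_zero_shift_terminates_immediately(self, trained):
        sample = trained.split.test.iloc[0]
        cfg = ta.CorrectionConfig(global_target_age=float(sample["age"]))
        res = ta.ann_age_correct(trained.ann, trained.scaler, sample, cfg)
        assert res.iterations == 0
        for t in ta.TRACT_NAMES:
            assert res.corrected_fa[t] == sample[t]

    def test_termination_criterion_one_month(self, corrected_test_set, trained):
        _, _, log = corrected_test_set
        ok = log[log["converged"]]
        assert len(ok) > 0
        assert (ok["final_error"].abs() <= 1.0 / 12.0 + 1e-12).all()

    def test_frozen_tracts_bit_equal(self, corrected_test_set, trained):
        ann_fa, _, log = corrected_test_set
        ok = log["converged"].to_numpy()
        for t in ta.AGE_INVARIANT_TRACTS:
            np.testing.assert_array_equal(
                ann_fa.loc[ok, t].to_numpy(),
                trained.split.test.loc[ok, t].to_numpy(),
            )

    def test_sign_constraints_hold(self, corrected_test_set, trained):
        ann_fa, _, log = corrected_test_set
        target = trained.test_mean_age()
        test = trained.split.test
        for i in np.flatnonzero(log["converged"].to_numpy()):
            delta = target - float(test["age"].iloc[i])
            diff = ann_fa.iloc[i].to_numpy() - test.iloc[i][
                list(ta.TRACT_NAMES)
            ].to_numpy(dtype=float)
            if delta > 0:
                assert np.all(diff <= 1e-12)
            elif delta < 0:
                assert np.all(diff >= -1e-12)

    def test_prediction_shift_property(self, corrected_test_set, trained):
        ann_fa, _, log = corrected_test_set
        ok = log["converged"].to_numpy()
        target = trained.test_mean_age()
        pred_corr = ta.predict_age(trained.ann, ann_fa[ok], trained.scaler)
        pred_orig = trained.predict(trained.split.test)[ok]
        shift = target - trained.split.test["age"].to_numpy()[ok]
        np.testing.assert_allclose(
            pred_corr - pred_orig, shift, atol=1.0 / 12.0 + 1e-9
        )

    def test_gap_preserved(self, corrected_test_set, trained):
        # correlation of the post-correction residual with the generator's
        # latent gap stays comparable to the uncorrected gap correlation
        ann_fa, _, log = corrected_test_set
        ok = log["converged"].to_numpy()
        target = trained.test_mean_age()
        pred_corr = ta.predict_age(trained.ann, ann_fa[ok], trained.scaler)
        true_gap = trained.split.test["true_gap"].to_numpy()[ok]
        pred_orig = trained.predict(trained.split.test)[ok]
        ages = trained.split.test["age"].to_numpy()[ok]
        r_corr = np.corrcoef(pred_corr - target, true_gap)[0, 1]
        r_orig = np.corrcoef(pred_orig - ages, true_gap)[0, 1]
        assert r_corr > 0
        assert r_corr > 0.5 * r_orig

    def test_scalar_recursion_oracle(self):
        # noiseless 1-tract system: the loop must reproduce the scalar
        # recursion x <- x (1 - lr E v x / w) exactly (to 1e-10).
        # v < 0 encodes the physiological direction (lower FA, older
        # prediction), so correcting to a younger target raises FA and the
        # sign constraint never blocks the trajectory.
        w, v, lr = 1.2, -0.5, 0.01
        ann, scaler = _scalar_system(w=w, v=v)
        age = 70.0
        fa = 0.53
        target = 55.0
        sample = pd.Series({"age": age, "CST": fa})
        cfg = ta.CorrectionConfig(
            global_target_age=target, learning_rate=lr, frozen_tracts=()
        )
        res = ta.ann_age_correct(ann, scaler, sample, cfg)

        # independent scalar recursion
        x = (fa - 0.5) / 0.03
        y0 = max(x * w, 0.0) * v
        y_t = y0 + (target - age) / scaler.age_sd
        tol = cfg.tolerance / scaler.age_sd
        x0 = x
        it = 0
        while abs(max(x * w, 0.0) * v - y_t) > tol:
            E = max(x * w, 0.0) * v - y_t
            x_new = x * (1 - lr * E * v * x / w)
            # target younger => delta_sign < 0 => x must not decrease
            x = x0 if x_new < x0 else x_new
            it += 1
        assert res.iterations == it
        got_z = (res.corrected_fa["CST"] - 0.5) / 0.03
        assert got_z == pytest.approx(x, abs=1e-10)


class TestLinearCorrection:
    def test_age_invariant_tract_is_noop(self, trained):
        model = trained.linear_correction_model()
        for t in ta.AGE_INVARIANT_TRACTS:
            assert model.beta[t] == 0.0
        out = ta.correct_cohort_linear(model, trained.split.test, 47.0)
        for t in ta.AGE_INVARIANT_TRACTS:
            np.testing.assert_array_equal(
                out[t].to_numpy(),
                trained.split.test[t].to_numpy(),
            )

    def test_noiseless_slope_recovered_exactly(self):
        ages = np.linspace(20, 80, 40)
        train = pd.DataFrame({"age": ages})
        for t in ta.TRACT_NAMES:
            train[t] = 0.5 - 0.001 * ages
        model = ta.fit_linear_correction(
            train, age_dependent={t: True for t in ta.TRACT_NAMES}
        )
        assert model.beta["CST"] == pytest.approx(-0.001, abs=1e-10)

    def test_noiseless_correction_constant_at_target(self):
        ages = np.linspace(20, 80, 25)
        cohort = pd.DataFrame({"age": ages})
        for t in ta.TRACT_NAMES:
            cohort[t] = 0.5 - 0.001 * ages
        model = ta.fit_linear_correction(
            cohort, age_dependent={t: True for t in ta.TRACT_NAMES}
        )
        out = ta.correct_cohort_linear(model, cohort, 50.0)
        expected = 0.5 - 0.001 * 50.0
        np.testing.assert_allclose(out["SLF"].to_numpy(), expected, atol=1e-10)

    def test_slope_invariant_to_mean_shift(self, default_cohort):
        m1 = ta.fit_linear_correction(default_cohort)
        shifted = default_cohort.copy()
        shifted["CST"] = shifted["CST"] + 0.2
        m2 = ta.fit_linear_correction(shifted)
        assert m1.beta["CST"] == pytest.approx(m2.beta["CST"], abs=1e-12)

    def test_identity_at_own_age(self, trained):
        model = trained.linear_correction_model()
        sample = trained.split.test.iloc[2]
        out = ta.linear_age_correct(model, sample, float(sample["age"]))
        for t in ta.TRACT_NAMES:
            assert out[t] == pytest.approx(sample[t], abs=1e-15)

    def test_constant_age_rejected(self):
        cohort = pd.DataFrame({"age": [50.0] * 10})
        for t in ta.TRACT_NAMES:
            cohort[t] = np.linspace(0.4, 0.5, 10)
        with pytest.raises(ParameterError):
            ta.fit_linear_correction(cohort)
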