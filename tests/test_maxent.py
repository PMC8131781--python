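"""Maximum-entropy core: solver correctness against an independent
optimizer, normalization, regularization behavior, and derived outputs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from invaniche import maxent
from invaniche.maxent import FeatureMap, fit, penalized_nll, replicate_fit


def _toy_data(rng, n_pres=12, n_bg=30, effect=1.0):
    bg = pd.DataFrame(rng.standard_normal((n_bg, 2)), columns=["a", "b"])
    pres = pd.DataFrame(
        rng.standard_normal((n_pres, 2)) * 0.5 + [effect, 0.0], columns=["a", "b"]
    )
    return pres, bg


def brute_force_coefficients(f_pres, f_bg, rho, n_sweeps=400):
    """Cyclic coordinate descent with exact 1-D golden-section minimization
    of the penalized objective — an optimizer sharing no code with the
    package's L-BFGS-B path."""

    def objective(lam):
        eta = f_bg @ lam
        m = eta.max()
        log_z = m + np.log(np.exp(eta - m).mean())
        return -(f_pres @ lam).mean() + log_z + rho @ np.abs(lam)

    lam = np.zeros(f_bg.shape[1])
    for _ in range(n_sweeps):
        for j in range(lam.size):
            def along(t, j=j):
                trial = lam.copy()
                trial[j] = t
                return objective(trial)

            res = minimize_scalar(along, bracket=(lam[j] - 1.0, lam[j] + 1.0),
                                  method="brent", options={"xtol": 1e-12})
            lam[j] = res.x
    return lam


class TestFitCorrectness:
    def test_matches_independent_optimizer_on_tiny_instance(self, rng):
        pres, bg = _toy_data(rng)
        model = fit(pres, bg, beta=1.0)
        f_pres = model.feature_map.transform(pres)
        f_bg = model.feature_map.transform(bg, clamp=False)
        lam_oracle = brute_force_coefficients(f_pres, f_bg, model.reg_scale)
        assert np.allclose(model.coef, lam_oracle, atol=1e-3)

    def test_gibbs_normalization(self, rng):
        pres, bg = _toy_data(rng, n_pres=20, n_bg=100)
        model = fit(pres, bg)
        f_bg = model.feature_map.transform(bg, clamp=False)
        total = np.exp(f_bg @ model.coef - model.log_z).mean()
        # uniform weights: sum of w_i * exp(eta_i - logZ) with w_i = 1/n
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_objective_at_solution_beats_perturbations(self, rng):
        pres, bg = _toy_data(rng)
        model = fit(pres, bg)
        f_pres = model.feature_map.transform(pres)
        f_bg = model.feature_map.transform(bg, clamp=False)
        log_w = np.full(len(bg), -np.log(len(bg)))
        val = penalized_nll(model.coef, f_pres, f_bg, log_w, model.reg_scale)
        for _ in range(100):
            perturbed = model.coef + rng.standard_normal(model.coef.size) * 0.05
            assert penalized_nll(
                perturbed, f_pres, f_bg, log_w, model.reg_scale
            ) >= val - 1e-9

    def test_beta_monotonicity_of_coefficient_norm(self, rng):
        pres, bg = _toy_data(rng, n_pres=50, n_bg=400, effect=1.5)
        norms = [
            np.abs(fit(pres, bg, beta=b).coef).sum() for b in (0.5, 1.0, 3.0, 10.0)
        ]
        assert all(norms[i] >= norms[i + 1] - 1e-9 for i in range(3))

    def test_null_data_shrinks_to_flat_prediction(self):
        rng = np.random.default_rng(42)
        bg = pd.DataFrame(rng.standard_normal((10000, 3)), columns=list("abc"))
        pres = bg.sample(500, random_state=7).reset_index(drop=True)
        model = fit(pres, bg, beta=3.0)
        preds = model.predict(bg)
        assert preds.std() < 0.02

    def test_informative_variable_gets_positive_linear_weight(self, rng):
        pres, bg = _toy_data(rng, n_pres=100, n_bg=1000, effect=1.5)
        model = fit(pres, bg, beta=1.0)
        idx = model.feature_map.feature_names.index("a")
        assert model.coef[idx] > 0

    def test_weight_validation(self, rng):
        pres, bg = _toy_data(rng)
        with pytest.raises(ValueError, match="zero"):
            fit(pres, bg, weights=np.zeros(len(bg)))
        with pytest.raises(ValueError, match="non-negative"):
            fit(pres, bg, weights=-np.ones(len(bg)))

    def test_minimum_presence_count_enforced(self, rng):
        pres, bg = _toy_data(rng, n_pres=5)
        with pytest.raises(ValueError, match="10 presences"):
            fit(pres, bg)


class TestPredict:
    def test_all_zero_coefficients_constant_output(self, rng):
        pres, bg = _toy_data(rng, n_pres=15, n_bg=40)
        model = fit(pres, bg, beta=1e6)  # huge penalty: all coefficients zero
        assert np.allclose(model.coef, 0.0)
        preds = model.predict(bg)
        assert np.allclose(preds, preds[0])
        # flat model maps to 1 - 1/e on the cloglog scale
        assert preds[0] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-9)

    def test_monotone_in_positive_linear_variable(self, rng):
        pres, bg = _toy_data(rng, n_pres=100, n_bg=1000, effect=1.5)
        model = fit(pres, bg, beta=1.0)
        # keep only the positive linear term on "a"
        idx = model.feature_map.feature_names.index("a")
        coef = np.zeros_like(model.coef)
        coef[idx] = 1.0
        model.coef = coef
        sweep = pd.DataFrame(
            {"a": np.linspace(bg["a"].min(), bg["a"].max(), 50), "b": 0.0}
        )
        preds = model.predict(sweep)
        assert np.all(np.diff(preds) > 0)

    def test_missing_variable_named(self, rng):
        pres, bg = _toy_data(rng)
        model = fit(pres, bg)
        with pytest.raises(KeyError, match="b"):
            model.predict(pd.DataFrame({"a": [0.0]}))

    def test_serialization_round_trip(self, tmp_path, rng):
        pres, bg = _toy_data(rng)
        model = fit(pres, bg)
        path = tmp_path / "model.json"
        model.save(path)
        back = maxent.MaxentModel.load(path)
        assert np.allclose(back.predict(bg), model.predict(bg))


class TestReplicates:
    def test_single_replicate_full_fraction_equals_plain_fit(self, rng):
        pres, bg = _toy_data(rng, n_pres=30, n_bg=200)
        ens, reports = replicate_fit(pres, bg, n_replicates=1, train_fraction=1.0)
        single = fit(pres, bg)
        assert np.allclose(ens.models[0].coef, single.coef)
        assert reports == []

    def test_same_seed_identical_average(self, rng):
        pres, bg = _toy_data(rng, n_pres=40, n_bg=300)
        e1, _ = replicate_fit(pres, bg, n_replicates=3, seed=5)
        e2, _ = replicate_fit(pres, bg, n_replicates=3, seed=5)
        assert np.array_equal(e1.predict(bg), e2.predict(bg))

    def test_average_bounded_by_replicate_envelope(self, rng):
        pres, bg = _toy_data(rng, n_pres=40, n_bg=300)
        ens, _ = replicate_fit(pres, bg, n_replicates=5, seed=3)
        preds = np.array([m.predict(bg) for m in ens.models])
        avg = ens.predict(bg)
        assert np.all(avg <= preds.max(axis=0) + 1e-12)
        assert np.all(avg >= preds.min(axis=0) - 1e-12)

    def test_too_few_presences_to_split(self, rng):
        pres, bg = _toy_data(rng, n_pres=3, n_bg=30)
        with pytest.raises(ValueError, match="too few|at least"):
            replicate_fit(pres, bg, n_replicates=2)


class TestDerivedOutputs:
    def test_single_variable_contribution_is_100(self, rng):
        bg = pd.DataFrame({"a": rng.standard_normal(200)})
        pres = pd.DataFrame({"a": rng.standard_normal(20) + 1.0})
        model = fit(pres, bg, beta=1.0)
        contrib = maxent.variable_contribution(model, pres, bg)
        assert contrib["a"] == pytest.approx(100.0)

    def test_informative_beats_noise_variable(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bg = pd.DataFrame(rng.standard_normal((800, 2)), columns=["sig", "noise"])
            pres = pd.DataFrame(
                {
                    "sig": rng.standard_normal(80) * 0.5 + 1.2,
                    "noise": rng.standard_normal(80),
                }
            )
            model = fit(pres, bg, beta=1.0)
            contrib = maxent.variable_contribution(model, pres, bg, seed=seed)
            wins += contrib["sig"] > contrib["noise"]
        assert wins >= 19

    def test_contributions_sum_to_100(self, rng):
        pres, bg = _toy_data(rng, n_pres=60, n_bg=400, effect=1.0)
        model = fit(pres, bg, beta=1.0)
        contrib = maxent.variable_contribution(model, pres, bg)
        assert contrib.sum() == pytest.approx(100.0)

    def test_response_curve_of_pure_quadratic_peaks_at_background_mean(self, rng):
        bg = pd.DataFrame({"a": rng.standard_normal(2000)})
        pres = pd.DataFrame({"a": rng.standard_normal(300) * 0.3})
        model = fit(pres, bg, beta=1.0)
        values, curve = maxent.response_curve(model, "a", n_points=301)
        peak = values[np.argmax(curve)]
        assert abs(peak - bg["a"].mean()) < 0.25

    def test_flat_model_flat_curve(self, rng):
        pres, bg = _toy_data(rng)
        model = fit(pres, bg, beta=1e6)
        _, curve = maxent.response_curve(model, "a")
        assert np.allclose(curve, curve[0])

    def test_categorical_one_hot_round_trip(self, rng):
        bg = pd.DataFrame(
            {"a": rng.standard_normal(300),
             "cat": rng.choice([1.0, 2.0, 3.0, 4.0], 300)}
        )
        pres = pd.DataFrame(
            {"a": rng.standard_normal(40) + 1.0,
             "cat": rng.choice([1.0, 2.0], 40)}
        )
        model = fit(pres, bg, beta=1.0, categoricals={"cat": [1.0, 2.0, 3.0, 4.0]})
        levels, response = maxent.response_curve(model, "cat")
        assert len(levels) == 4
        assert np.all(np.isfinite(response))
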