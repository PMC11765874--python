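import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrt_irt as m
from mrt_irt.rasch import RaschFit, _cml_ll, _prepare_cml, fit_statistics
from oracles import brute_force_delta, enumerated_esf


def _rm(values, group=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return m.ResponseMatrix(values, [f"p{i}" for i in range(n)],
                            [f"i{j}" for j in range(k)], group)


def _simulate(delta, theta, seed):
    rng = np.random.default_rng(seed)
    p = 1 / (1 + np.exp(-(theta[:, None] - delta[None, :])))
    return _rm((rng.random(p.shape) < p).astype(float))


# ---------------------------------------------------------------------------
# elementary symmetric functions
# ---------------------------------------------------------------------------


class TestEsf:
    def test_unit_easiness_gives_binomial_coefficients(self):
        np.testing.assert_allclose(m.esf(np.ones(4)).gamma, [1, 4, 6, 4, 1])

    def test_matches_exhaustive_enumeration(self):
        eps = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(m.esf(eps).gamma, [1, 6, 11, 6])
        np.testing.assert_allclose(m.esf(eps).gamma, enumerated_esf(eps))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.05, 20.0), min_size=1, max_size=8))
    def test_boundary_identities(self, eps):
        eps = np.array(eps)
        table = m.esf(eps)
        assert table.gamma[0] == pytest.approx(1.0)
        assert table.gamma[-1] == pytest.approx(np.prod(eps), rel=1e-10)
        assert table.gamma[1] == pytest.approx(eps.sum(), rel=1e-10)

    def test_log_space_stability_for_long_tests(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 3, 60)
        lg = m.esf(np.exp(beta)).log_gamma
        assert np.isfinite(lg).all()
        # order-1 ESF is just the sum of easiness values
        assert lg[1] == pytest.approx(np.log(np.exp(beta).sum()))

    def test_nonpositive_easiness_rejected(self):
        with pytest.raises(ValueError):
            m.esf(np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# CML calibration
# ---------------------------------------------------------------------------


class TestFitRaschCml:
    def test_symmetric_two_item_data_forces_equal_difficulties(self):
        values = [[1, 0], [0, 1], [1, 0], [0, 1], [1, 1], [0, 0]]
        fit = m.fit_rasch_cml(_rm(values))
        np.testing.assert_allclose(fit.delta, [0.0, 0.0], atol=1e-10)

    def test_matches_bruteforce_oracle_on_small_dataset(self):
        rng = np.random.default_rng(2)
        rm = _simulate(np.array([-0.8, 0.2, 0.9]), rng.normal(0, 1, 30), seed=2)
        fit = m.fit_rasch_cml(rm)
        assert fit.excluded_items == []
        oracle = brute_force_delta(rm.values)
        np.testing.assert_allclose(fit.delta, oracle, atol=1e-4)

    def test_sum_zero_normalization(self, rasch2000):
        assert abs(rasch2000.delta.sum()) < 1e-8

    def test_invariant_to_person_permutation(self):
        rng = np.random.default_rng(4)
        rm = _simulate(np.array([-1.0, 0.0, 1.0, 0.5]), rng.normal(0, 1, 80), seed=4)
        fit = m.fit_rasch_cml(rm)
        perm = rng.permutation(80)
        fit2 = m.fit_rasch_cml(rm.subset_persons(perm))
        np.testing.assert_allclose(fit.delta, fit2.delta, atol=1e-6)

    def test_item_relabelling_permutes_estimates(self):
        rng = np.random.default_rng(5)
        rm = _simulate(np.array([-1.0, 0.0, 1.0]), rng.normal(0, 1, 100), seed=5)
        fit = m.fit_rasch_cml(rm)
        order = ["i2", "i0", "i1"]
        fit2 = m.fit_rasch_cml(rm.subset_items(order))
        lookup = dict(zip(fit.item_ids, fit.delta))
        np.testing.assert_allclose(fit2.delta, [lookup[i] for i in order], atol=1e-8)

    def test_conditional_likelihood_invariant_to_location_shift(self, tiny_matrix):
        data = _prepare_cml(tiny_matrix.values)
        beta = np.array([0.3, -0.1, 0.6])
        assert _cml_ll(beta, data) == pytest.approx(_cml_ll(beta + 1.7, data))

    def test_degenerate_item_excluded_with_warning(self, caplog):
        values = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1], [1, 0, 0]], dtype=float)
        fit = m.fit_rasch_cml(_rm(values))
        assert fit.excluded_items == ["i0"]
        assert fit.item_ids == ["i1", "i2"]

    def test_standard_errors_scale_with_sample_size(self, instrument):
        q, eta, _ = instrument
        small = m.simulate_responses(m.SimulationDesign(q=q, eta=eta, n_persons=200, seed=9))
        big = m.simulate_responses(m.SimulationDesign(q=q, eta=eta, n_persons=1800, seed=9))
        fs, fb = m.fit_rasch_cml(small), m.fit_rasch_cml(big)
        shared = [i for i in fs.item_ids if i in fb.item_ids]
        se_s = dict(zip(fs.item_ids, fs.se_delta))
        se_b = dict(zip(fb.item_ids, fb.se_delta))
        assert np.median([se_s[i] / se_b[i] for i in shared]) == pytest.approx(3.0, abs=0.8)


# ---------------------------------------------------------------------------
# person abilities
# ---------------------------------------------------------------------------


class TestAbilities:
    def test_balanced_items_give_zero_ability_at_half_score(self):
        rng = np.random.default_rng(6)
        rm = _simulate(np.array([-1.2, 1.2]), rng.normal(0, 1, 200), seed=6)
        fit = m.fit_rasch_cml(rm)
        # symmetric difficulties: raw score 1 of 2 pins theta at their midpoint
        half = rm.raw_scores() == 1
        np.testing.assert_allclose(fit.theta[half], -fit.delta.mean(), atol=0.05)

    def test_theta_strictly_increasing_in_raw_score(self, rasch2000, sim2000):
        scores = sim2000.raw_scores()
        nonext = ~rasch2000.extreme_person
        for r in range(1, 14):
            lo = rasch2000.theta[nonext & (scores == r)]
            hi = rasch2000.theta[nonext & (scores == r + 1)]
            if lo.size and hi.size:
                assert lo.max() < hi.min() + 1e-9

    def test_extreme_scores_get_flagged_finite_proxies(self):
        values = np.array([[1, 1, 1], [0, 0, 0], [1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        fit = m.fit_rasch_cml(_rm(values))
        assert fit.extreme_person[:2].all() and not fit.extreme_person[2:].any()
        assert np.isfinite(fit.theta).all()
        assert fit.theta[0] > fit.theta[2] > fit.theta[1]

    def test_ability_error_shrinks_with_test_length(self, instrument):
        q, eta, _ = instrument
        rng = np.random.default_rng(7)
        theta = rng.normal(0, 1, 1000)
        delta14 = q.weights[:14] @ eta
        delta14 = delta14 - delta14.mean()
        maes = {}
        for k in (7, 14):
            d = delta14[:k] - delta14[:k].mean()
            rm = _simulate(d, theta, seed=70 + k)
            fit = m.fit_rasch_cml(rm)
            use = ~fit.extreme_person
            maes[k] = np.mean(np.abs(fit.theta[use] - theta[use]))
        assert maes[14] < maes[7]


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def _manual_fit(values, expected, theta=None):
    n, k = values.shape
    residuals = (values - expected) / np.sqrt(expected * (1 - expected))
    return RaschFit(
        item_ids=[f"i{j}" for j in range(k)],
        delta=np.zeros(k), se_delta=np.ones(k), cov_delta=np.eye(k),
        minus2ll=0.0, n_iter=0,
        person_ids=[f"p{i}" for i in range(n)],
        theta=np.zeros(n) if theta is None else theta,
        se_theta=np.ones(n),
        extreme_person=np.zeros(n, dtype=bool),
        expected=expected, residuals=residuals,
    )


class TestFitStatistics:
    def test_even_odds_force_unit_mean_squares(self):
        # with every model probability 1/2, each squared standardized
        # residual is exactly 1 whatever the data
        rng = np.random.default_rng(8)
        values = (rng.random((20, 4)) < 0.5).astype(float)
        fit = _manual_fit(values, np.full((20, 4), 0.5))
        item_fit, person_fit = fit_statistics(fit, _rm(values))
        np.testing.assert_allclose(item_fit["outfit_msq"], 1.0)
        np.testing.assert_allclose(item_fit["infit_msq"], 1.0)
        np.testing.assert_allclose(person_fit["outfit_msq"], 1.0)

    def test_guttman_pattern_underfits(self):
        # deterministic data against probabilistic expectations: mean squares < 1
        values = np.array(
            [[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0]], dtype=float
        )
        theta = np.array([-1.5, -0.5, 0.5, 1.5])
        delta = np.array([-1.2, -0.4, 0.4, 1.2])
        expected = 1 / (1 + np.exp(-(theta[:, None] - delta[None, :])))
        fit = _manual_fit(values, expected, theta)
        item_fit, _ = fit_statistics(fit, _rm(values))
        assert (item_fit["outfit_msq"] < 1).all()
        assert (item_fit["infit_msq"] < 1).all()

    def test_randomized_item_is_flagged_as_misfit(self, instrument):
        q, eta, _ = instrument
        rng = np.random.default_rng(13)
        rm = m.simulate_responses(m.SimulationDesign(q=q, eta=eta, n_persons=1000, seed=13))
        noisy = rm.values.copy()
        noisy[:, 7] = (rng.random(1000) < 0.5).astype(float)  # sever item 8 from theta
        fit = m.fit_rasch_cml(_rm(noisy))
        flagged = m.flag_misfit_items(fit, m.AnalysisConfig(misfit_z_threshold=2.0))
        assert "i7" in flagged

    def test_all_calm_z_flags_nothing(self):
        import pandas as pd
        fit = _manual_fit(np.zeros((2, 2)), np.full((2, 2), 0.5))
        fit.item_fit = pd.DataFrame(
            {"item": ["i0", "i1"], "outfit_msq": [1.0, 1.0], "infit_msq": [1.0, 1.0],
             "outfit_z": [0.3, -1.9], "infit_z": [1.2, -0.7]}
        )
        assert m.flag_misfit_items(fit) == set()


# ---------------------------------------------------------------------------
# global fit diagnostics
# ---------------------------------------------------------------------------


class TestAndersen:
    def test_identical_subgroups_give_zero_statistic(self):
        rng = np.random.default_rng(14)
        block = (rng.random((40, 4)) < 1 / (1 + np.exp(-rng.normal(0, 1, (40, 1))))).astype(float)
        values = np.vstack([block, block])
        labels = ["a"] * 40 + ["b"] * 40
        res = m.andersen_lr_test(_rm(values), split=labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_median_split_type_one_error_near_nominal(self, instrument):
        q, eta, _ = instrument
        q8 = q.subset_items([str(i) for i in range(2, 10)])
        rejections = 0
        used = 0
        for s in range(60):
            rm = m.simulate_responses(m.SimulationDesign(q=q8, eta=eta, n_persons=300, seed=500 + s))
            try:
                res = m.andersen_lr_test(rm)
            except ValueError:
                continue
            used += 1
            rejections += int(res.p_value < 0.05)
        # 99% binomial envelope around 0.05 for ~60 draws
        assert used > 50
        assert rejections / used < 0.15

    def test_df_counts_estimated_parameters(self, sim2000):
        res = m.andersen_lr_test(sim2000)
        expected_df = sum(v - 1 for v in res.subgroup_items.values()) - (
            len(m.fit_rasch_cml(sim2000).item_ids) - 1
        )
        assert res.df == expected_df

    def test_degenerate_split_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            m.andersen_lr_test(tiny_matrix, split=["a"] * 4)


class TestResidualStructure:
    def test_unidimensional_data_has_small_leading_eigenvalue(self, rasch2000):
        eig, unidim = m.residual_pca(rasch2000)
        assert eig[0] < 2.0
        assert unidim

    def test_planted_second_dimension_is_detected(self, instrument):
        q, eta, _ = instrument
        rng = np.random.default_rng(15)
        n, k = 2000, 16
        theta1, theta2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        load = np.array([0] * (k // 2) + [1] * (k // 2))
        theta = np.where(load[None, :] == 0, theta1[:, None], theta2[:, None])
        values = (rng.random((n, k)) < 1 / (1 + np.exp(-theta))).astype(float)
        fit = m.fit_rasch_cml(_rm(values))
        eig, unidim = m.residual_pca(fit)
        assert eig[0] > 2.0
        assert not unidim

    def test_duplicated_item_shows_local_dependence(self, instrument):
        q, eta, _ = instrument
        rm = m.simulate_responses(m.SimulationDesign(q=q, eta=eta, n_persons=1500, seed=16))
        values = np.hstack([rm.values, rm.values[:, [6]]])  # clone one item
        fit = m.fit_rasch_cml(_rm(values))
        res = fit.residuals[~fit.extreme_person]
        j1, j2 = fit.item_ids.index("i6"), fit.item_ids.index("i15")
        r = np.corrcoef(res[:, j1], res[:, j2])[0, 1]
        assert r > 0.8
        summary = m.residual_correlation_summary(fit)
        assert summary["sd"] > 0

    def test_independent_residuals_average_near_zero(self, rasch2000):
        # off-diagonal residual correlations carry a small negative bias of
        # about -1/(k-1) under the model; "near zero" means within that band
        summary = m.residual_correlation_summary(rasch2000)
        k = len(rasch2000.item_ids)
        assert -1.0 / (k - 1) - 0.05 < summary["mean"] < 0.02


class TestVarianceExplained:
    def test_null_model_explains_nothing(self):
        values = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=float)
        fit = _manual_fit(values, np.full((4, 2), values.mean()))
        assert m.variance_explained(fit, _rm(values)) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_explains_everything(self):
        values = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=float)
        eps = 1e-9
        fit = _manual_fit(values, np.clip(values, eps, 1 - eps))
        assert m.variance_explained(fit, _rm(values)) == pytest.approx(1.0, abs=1e-6)

    def test_model_data_in_plausible_range(self, rasch2000, sim2000):
        ve = m.variance_explained(rasch2000, sim2000)
        assert 0.2 < ve < 0.6
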