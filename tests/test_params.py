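"""Moment-matching distribution constructors, table loading and PSA draws."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from her2cea.params import (
    InfeasibleMomentsError,
    Parameter,
    ParameterTable,
    ParameterValidationError,
    beta_from_moments,
    gamma_from_moments,
    lognormal_from_point,
    sample_parameter_set,
)


class TestBetaFromMoments:
    def test_zero_se_degenerates_to_point(self):
        spec = beta_from_moments(0.5, 0.0)
        assert spec.family == "fixed" and spec.args == (0.5,)

    @pytest.mark.parametrize(
        "mean, se, alpha, beta",
        [
            # hand-applied method of moments on two published rows
            (0.0053, 0.0024, 4.845589409722, 909.416563368),
            (0.15, 0.0153, 81.549346405, 462.112962963),
        ],
    )
    def test_method_of_moments(self, mean, se, alpha, beta):
        spec = beta_from_moments(mean, se)
        assert spec.args[0] == pytest.approx(alpha, rel=1e-9)
        assert spec.args[1] == pytest.approx(beta, rel=1e-9)
        assert spec.args[0] / sum(spec.args) == pytest.approx(mean, rel=1e-12)

    def test_sample_moments_match_inputs(self, rng):
        spec = beta_from_moments(0.0053, 0.0024)
        draws = spec.draw(rng, size=1_000_000)
        assert draws.mean() == pytest.approx(0.0053, rel=0.01)
        assert draws.std() == pytest.approx(0.0024, rel=0.01)

    def test_infeasible_moments_named(self):
        with pytest.raises(InfeasibleMomentsError, match="tp_bad"):
            beta_from_moments(0.01, 0.2, name="tp_bad")


class TestGammaFromMoments:
    def test_zero_se_degenerates_to_point(self):
        assert gamma_from_moments(194900, 0).args == (194900,)

    @pytest.mark.parametrize(
        "mean, se, shape",
        [(1076607, 54929, 384.159000893), (3400, 1602, 4.504357069)],
    )
    def test_shape_is_squared_cv_inverse(self, mean, se, shape):
        spec = gamma_from_moments(mean, se)
        assert spec.args[0] == pytest.approx(shape, rel=1e-9)
        assert spec.mean() == pytest.approx(mean, rel=1e-12)

    def test_sample_moments_match_inputs(self, rng):
        spec = gamma_from_moments(3400, 1602)
        draws = spec.draw(rng, size=1_000_000)
        assert draws.mean() == pytest.approx(3400, rel=0.01)
        assert draws.std() == pytest.approx(1602, rel=0.01)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            gamma_from_moments(-5, 1)


class TestLognormalFromPoint:
    def test_zero_se_degenerates_to_point(self):
        assert lognormal_from_point(1.0, 0).args == (1.0,)

    @pytest.mark.parametrize(
        "ratio, se, mu, sigma",
        [
            (0.65, 0.0825, -0.430782916092, 0.126923076923),
            (3.97, 0.2240, math.log(3.97), 0.056423173804),
        ],
    )
    def test_delta_method_parameters(self, ratio, se, mu, sigma):
        spec = lognormal_from_point(ratio, se)
        assert spec.args[0] == pytest.approx(mu, rel=1e-9)
        assert spec.args[1] == pytest.approx(sigma, rel=1e-9)
        assert spec.median() == pytest.approx(ratio, rel=1e-12)

    def test_sampling_median_is_point_estimate(self, rng):
        draws = lognormal_from_point(0.65, 0.0825).draw(rng, size=1_000_000)
        assert np.median(draws) == pytest.approx(0.65, rel=0.01)

    def test_moment_matched_mode_matches_mean(self, rng):
        spec = lognormal_from_point(0.65, 0.0825, moment_matched=True)
        assert spec.mean() == pytest.approx(0.65, rel=1e-12)
        assert spec.sd() == pytest.approx(0.0825, rel=1e-12)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            lognormal_from_point(0.0, 0.1)


@given(
    mean=st.floats(0.01, 0.99),
    cv=st.floats(0.01, 0.5),
)
def test_moment_round_trip(mean, cv):
    """Beta and gamma analytic moments reproduce any feasible input pair."""
    se = min(mean * cv, 0.9 * math.sqrt(mean * (1 - mean)))
    b = beta_from_moments(mean, se)
    assert b.mean() == pytest.approx(mean, abs=1e-9)
    assert b.sd() == pytest.approx(se, abs=1e-9)
    g = gamma_from_moments(mean * 1e5, se * 1e5)
    assert g.mean() == pytest.approx(mean * 1e5, rel=1e-9)
    assert g.sd() == pytest.approx(se * 1e5, rel=1e-9)


class TestLoader:
    def test_fixture_values(self, table):
        assert table["tp_dfs_met"].mean == 0.0785
        assert table["tp_dfs_met"].se == 0.0140
        assert table.settings.discount_rate == 0.035
        assert table.settings.horizon_cycles == 49

    def test_round_trip(self, table, tmp_path):
        path = tmp_path / "roundtrip.yaml"
        table.save(path)
        again = ParameterTable.load(path)
        assert again.parameters == table.parameters
        assert again.settings == table.settings

    def test_out_of_range_utility_rejected(self, table, tmp_path):
        bad = dict(table.parameters)
        bad["u_dfs"] = Parameter("u_dfs", 1.2, 0.01, "beta", "utility")
        with pytest.raises(ParameterValidationError, match="u_dfs"):
            ParameterTable(bad, table.settings)

    def test_missing_symbol_named(self, table):
        incomplete = {k: v for k, v in table.parameters.items() if k != "hr_os"}
        with pytest.raises(ParameterValidationError, match="hr_os"):
            ParameterTable(incomplete, table.settings)

    def test_all_failures_reported(self, table):
        bad = {k: v for k, v in table.parameters.items() if k != "hr_os"}
        bad["u_dfs"] = Parameter("u_dfs", 1.2, 0.01, "beta", "utility")
        with pytest.raises(ParameterValidationError) as err:
            ParameterTable(bad, table.settings)
        assert len(err.value.failures) >= 2

    def test_role_distribution_consistency_enforced(self, table):
        bad = dict(table.parameters)
        bad["dmc_dfs"] = Parameter("dmc_dfs", 9493, 484, "beta", "cost_dmc")
        with pytest.raises(ParameterValidationError, match="inconsistent"):
            ParameterTable(bad, table.settings)


class TestSampleParameterSet:
    def test_zero_se_table_is_identity_on_means(self, table, rng):
        fixed = ParameterTable(
            {n: Parameter(n, p.mean, 0.0, "fixed", p.role) for n, p in table.parameters.items()},
            table.settings,
        )
        ps = sample_parameter_set(fixed, rng)
        assert ps.values == {n: p.mean for n, p in table.parameters.items()}

    def test_same_seed_bit_identical(self, table):
        a = sample_parameter_set(table, np.random.default_rng(2019))
        b = sample_parameter_set(table, np.random.default_rng(2019))
        assert a.values == b.values

    def test_draws_respect_range_invariants(self, table):
        rng = np.random.default_rng(11)
        for _ in range(200):
            ps = sample_parameter_set(table, rng)
            for name, p in table.parameters.items():
                v = ps[name]
                if p.role in ("transition_prob", "utility"):
                    assert 0 <= v <= 1
                elif p.role in ("cost_dmc", "cost_dnmc"):
                    assert v >= 0
                elif p.role == "relative_effect":
                    assert v > 0

    def test_sample_means_approach_table_means(self, table):
        """Monte Carlo oracle: empirical mean per parameter ~ its input mean
        (lognormal parameters: the median matches the point estimate)."""
        rng = np.random.default_rng(5)
        n = 100_000
        draws = {n_: np.empty(n) for n_ in table.parameters}
        for i in range(n):
            ps = sample_parameter_set(table, rng)
            for name in draws:
                draws[name][i] = ps[name]
        for name, p in table.parameters.items():
            if p.role == "relative_effect" and p.se > 0:
                assert np.median(draws[name]) == pytest.approx(p.mean, rel=0.01), name
            else:
                assert draws[name].mean() == pytest.approx(p.mean, rel=0.01, abs=1e-12), name
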