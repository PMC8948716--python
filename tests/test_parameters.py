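"""Parameter definitions, distribution fits and probability conversions."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from skincost.parameters import (
    Distribution,
    Kind,
    ParameterError,
    ParameterSet,
    ParameterSpec,
    annual_to_multi_period_probability,
    fit_beta,
    fit_gamma,
    impute_nz_unit_cost,
    multi_period_to_annual_probability,
    sample_parameter,
    se_from_quartiles,
    survival_to_annual_transition,
)


class TestRateConversions:
    @pytest.mark.parametrize(
        "p_multi, years, expected",
        [
            # 5-year KC multiplicity -> annual; 1 - 0.491**0.2 frozen to 7 dp
            (0.509, 5, 0.1326062),
            (0.0, 5, 0.0),
            (0.3, 1, 0.3),
        ],
    )
    def test_multi_period_to_annual(self, p_multi, years, expected):
        annual = multi_period_to_annual_probability(p_multi, years)
        assert annual == pytest.approx(expected, abs=1e-6)
        # round trip recovers the multi-period probability to machine precision
        assert 1 - (1 - annual) ** years == pytest.approx(p_multi, abs=1e-14)

    @pytest.mark.parametrize(
        "surviving, years, expected",
        [
            (0.40, 5, 0.1674468),  # 1 - 0.4**0.2, frozen to 7 dp
            (1.0, 4, 0.0),
            (0.25, 4, 0.2928932),  # 1 - 1/sqrt(2)
        ],
    )
    def test_survival_to_annual(self, surviving, years, expected):
        assert survival_to_annual_transition(surviving, years) == pytest.approx(
            expected, abs=1e-6
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_multi_period_domain(self, bad):
        with pytest.raises(ParameterError):
            multi_period_to_annual_probability(bad, 5)

    def test_survival_zero_is_infinite_hazard(self):
        with pytest.raises(ParameterError):
            survival_to_annual_transition(0.0, 5)

    @settings(derandomize=True, max_examples=200)
    @given(
        p=st.floats(min_value=0.0, max_value=0.999, allow_nan=False),
        years=st.integers(min_value=1, max_value=10),
    )
    def test_conversion_round_trip(self, p, years):
        annual = multi_period_to_annual_probability(p, years)
        assert annual_to_multi_period_probability(annual, years) == pytest.approx(
            p, abs=1e-12
        )
        assert annual <= p + 1e-15


class TestMomentFits:
    def test_beta_uniform(self):
        a, b = fit_beta(0.5, 0.288675)
        assert (a, b) == (pytest.approx(1.0, abs=1e-4), pytest.approx(1.0, abs=1e-4))

    def test_beta_example(self):
        a, b = fit_beta(0.604, 0.1)
        assert a == pytest.approx(13.84, abs=0.01)
        assert b == pytest.approx(9.08, abs=0.01)
        assert a / (a + b) == pytest.approx(0.604, abs=1e-12)

    def test_gamma_examples(self):
        assert fit_gamma(100, 10) == (pytest.approx(100.0), pytest.approx(1.0))
        shape, scale = fit_gamma(644, 64.4)
        assert shape == pytest.approx(100.0)
        assert scale == pytest.approx(6.44)

    def test_beta_infeasible_dispersion(self):
        with pytest.raises(ParameterError, match="infeasible"):
            fit_beta(0.5, 0.6)

    def test_gamma_domain(self):
        with pytest.raises(ParameterError):
            fit_gamma(-1.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        mean=st.floats(min_value=0.05, max_value=0.95),
        se_frac=st.floats(min_value=0.01, max_value=0.5),
    )
    def test_beta_moments_recovered(self, mean, se_frac):
        se = se_frac * min(mean, 1 - mean)
        a, b = fit_beta(mean, se)
        dist = stats.beta(a, b)
        assert dist.mean() == pytest.approx(mean, rel=1e-12)
        assert dist.std() == pytest.approx(se, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        mean=st.floats(min_value=1.0, max_value=1e6),
        se_frac=st.floats(min_value=0.01, max_value=2.0),
    )
    def test_gamma_moments_recovered(self, mean, se_frac):
        shape, scale = fit_gamma(mean, mean * se_frac)
        dist = stats.gamma(shape, scale=scale)
        assert dist.mean() == pytest.approx(mean, rel=1e-12)
        assert dist.std() == pytest.approx(mean * se_frac, rel=1e-9)


class TestImputation:
    @pytest.mark.parametrize(
        "au, ratio, expected",
        [(100.0, 1.91, 191.0), (0.0, 1.91, 0.0), (644.0, 1.91, 1230.04)],
    )
    def test_price_ratio(self, au, ratio, expected):
        assert impute_nz_unit_cost(au, ratio) == pytest.approx(expected)

    def test_negative_cost_rejected(self):
        with pytest.raises(ParameterError):
            impute_nz_unit_cost(-1.0)


class TestSampling:
    def test_fixed_returns_point(self):
        spec = ParameterSpec("p", Kind.PROBABILITY, 0.604)
        rng = np.random.default_rng(0)
        assert all(sample_parameter(spec, rng) == 0.604 for _ in range(10))

    def test_beta_mean_within_clt_bound(self):
        spec = ParameterSpec(
            "p", Kind.PROBABILITY, 0.5, Distribution.BETA, se=0.05
        )
        rng = np.random.default_rng(42)
        draws = np.array([spec.sample(rng) for _ in range(100_000)])
        assert abs(draws.mean() - 0.5) < 3 * 0.05 / np.sqrt(100_000)

    def test_gamma_support_positive(self):
        spec = ParameterSpec("c", Kind.COST, 525.0, Distribution.GAMMA, se=50.0)
        rng = np.random.default_rng(1)
        assert all(spec.sample(rng) > 0 for _ in range(1000))

    def test_bit_reproducible_given_seed(self):
        ps = ParameterSet.from_specs(
            [
                ParameterSpec("a", Kind.PROBABILITY, 0.3, Distribution.BETA, se=0.03),
                ParameterSpec("b", Kind.COST, 100.0, Distribution.GAMMA, se=10.0),
                ParameterSpec("c", Kind.COST, 50.0),
            ]
        )
        one = ps.sample_values(np.random.default_rng(7))
        two = ps.sample_values(np.random.default_rng(7))
        assert one == two

    def test_invalid_spec_combinations_rejected(self):
        with pytest.raises(ParameterError):
            ParameterSpec("p", Kind.PROBABILITY, 1.2)
        with pytest.raises(ParameterError):
            ParameterSpec("p", Kind.PROBABILITY, 0.5, Distribution.GAMMA, se=0.1)
        with pytest.raises(ParameterError):
            ParameterSpec("c", Kind.COST, 100.0, Distribution.GAMMA)  # no dispersion


class TestQuartileInversion:
    @pytest.mark.parametrize(
        "kind, mean, se",
        [(Kind.PROBABILITY, 0.3, 0.05), (Kind.COST, 500.0, 75.0)],
    )
    def test_iqr_inversion_recovers_se(self, kind, mean, se):
        spec = ParameterSpec(
            "x",
            kind,
            mean,
            Distribution.BETA if kind is Kind.PROBABILITY else Distribution.GAMMA,
            se=se,
        )
        q25, q75 = spec.quantile(0.25), spec.quantile(0.75)
        assert se_from_quartiles(kind, mean, q25, q75) == pytest.approx(se, rel=1e-6)

    def test_quartile_only_spec_usable(self):
        base = ParameterSpec("c", Kind.COST, 500.0, Distribution.GAMMA, se=75.0)
        spec = ParameterSpec(
            "c",
            Kind.COST,
            500.0,
            Distribution.GAMMA,
            q25=base.quantile(0.25),
            q75=base.quantile(0.75),
        )
        assert spec.effective_se() == pytest.approx(75.0, rel=1e-6)


class TestSerialisation:
    def _example_set(self):
        return ParameterSet.from_specs(
            [
                ParameterSpec("p_a", Kind.PROBABILITY, 0.604),
                ParameterSpec("p_b", Kind.PROBABILITY, 0.3, Distribution.BETA, se=0.03),
                ParameterSpec("cost_x", Kind.COST, 97.0, Distribution.GAMMA, se=9.7,
                              source_tag="assumption"),
            ]
        )

    def test_csv_round_trip(self, tmp_path):
        ps = self._example_set()
        path = tmp_path / "params.csv"
        ps.to_csv(path)
        back = ParameterSet.from_csv(path)
        assert back.names == ps.names
        for name in ps.names:
            assert back[name].point_estimate == ps[name].point_estimate
            assert back[name].distribution == ps[name].distribution

    def test_yaml_round_trip(self):
        ps = self._example_set()
        back = ParameterSet.from_yaml(io.StringIO(ps.to_yaml()))
        assert back.point_values() == ps.point_values()

    def test_duplicate_names_rejected(self):
        ps = self._example_set()
        with pytest.raises(ParameterError, match="duplicate"):
            ps.add(ParameterSpec("p_a", Kind.PROBABILITY, 0.1))
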