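"""Monte Carlo PSA and one-way (tornado) sensitivity analysis."""

import itertools

import numpy as np
import pytest

from skincost.model_graph import PathwayModel, Terminal
from skincost.parameters import Distribution, Kind, ParameterSet, ParameterSpec
from skincost.uncertainty import (
    ModelCost,
    StageWeightedCost,
    one_way_sensitivity,
    percentile_interval,
    run_psa,
)


def _identity_cost_model(cost_ref="c"):
    """One terminal charging a single cost reference, no Markov part."""
    return PathwayModel(
        name="identity", root=Terminal("only", costs=[cost_ref]), horizon_years=1
    )


class TestPercentileInterval:
    def test_integers_1_to_100(self):
        # linear-interpolation order statistics: 1 + 0.025*99, 1 + 0.975*99
        low, high = percentile_interval(list(range(1, 101)))
        assert low == pytest.approx(3.475)
        assert high == pytest.approx(97.525)

    def test_constant_samples(self):
        assert percentile_interval([7.0] * 50) == (7.0, 7.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(size=200)
        shuffled = rng.permutation(samples)
        assert percentile_interval(samples) == percentile_interval(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_interval([])


class TestRunPsa:
    def test_all_fixed_parameters_degenerate(self):
        params = ParameterSet.from_specs([ParameterSpec("c", Kind.COST, 123.0)])
        summary = run_psa(_identity_cost_model(), params, n=50, seed=0)
        assert summary.mean == summary.ui_low == summary.ui_high == 123.0

    def test_gamma_mean_within_clt_bound(self):
        params = ParameterSet.from_specs(
            [ParameterSpec("c", Kind.COST, 100.0, Distribution.GAMMA, se=10.0)]
        )
        summary = run_psa(_identity_cost_model(), params, n=100_000, seed=11)
        assert abs(summary.mean - 100.0) < 3 * 10.0 / np.sqrt(100_000)
        assert summary.ui_low < summary.ui_high

    def test_same_seed_bit_identical(self, au_params, au_kc_model):
        one = run_psa(au_kc_model, au_params, n=200, seed=5)
        two = run_psa(au_kc_model, au_params, n=200, seed=5)
        assert (one.mean, one.ui_low, one.ui_high) == (two.mean, two.ui_low, two.ui_high)

    def test_psa_mean_converges_to_deterministic_for_multilinear_model(
        self, au_params, au_kc_model
    ):
        """Parameters enter multilinearly, so the PSA mean is unbiased."""
        summary = run_psa(au_kc_model, au_params, n=4000, seed=2, keep_samples=True)
        deterministic = ModelCost(au_kc_model).evaluate(au_params.point_values())
        mc_se = summary.samples.std(ddof=1) / np.sqrt(summary.n_iterations)
        assert abs(summary.mean - deterministic) < 3 * mc_se

    def test_ui_narrows_when_dispersion_shrinks(self):
        def width(se):
            params = ParameterSet.from_specs(
                [ParameterSpec("c", Kind.COST, 100.0, Distribution.GAMMA, se=se)]
            )
            s = run_psa(_identity_cost_model(), params, n=3000, seed=9)
            return s.ui_high - s.ui_low

        assert width(5.0) < width(20.0)

    def test_invalid_iteration_count(self, au_params, au_kc_model):
        with pytest.raises(ValueError):
            run_psa(au_kc_model, au_params, n=0, seed=0)


class TestOneWaySensitivity:
    def _linear_model_params(self):
        from skincost.model_graph import Branch, Chance, COMPLEMENT

        model = PathwayModel(
            name="linear",
            root=Chance(
                "event",
                branches=[
                    Branch("p", Terminal("hit", costs=["c"])),
                    Branch(COMPLEMENT, Terminal("miss")),
                ],
            ),
            horizon_years=1,
        )
        params = ParameterSet.from_specs(
            [
                ParameterSpec("p", Kind.PROBABILITY, 0.5, Distribution.BETA, se=0.05),
                ParameterSpec("c", Kind.COST, 100.0, Distribution.GAMMA, se=10.0),
            ]
        )
        return model, params

    def test_linear_cost_margin_range(self):
        model, params = self._linear_model_params()
        result = one_way_sensitivity(model, params, margin=0.2)
        entry = {e.parameter: e for e in result.entries}["c"]
        assert entry.range == pytest.approx(0.5 * (120 - 80))
        assert result.base_cost == pytest.approx(50.0)

    def test_unreferenced_parameter_has_zero_range(self):
        model, params = self._linear_model_params()
        params.add(ParameterSpec("c_unused", Kind.COST, 999.0, Distribution.GAMMA, se=9.0))
        result = one_way_sensitivity(model, params, margin=0.2, parameters=["c_unused"])
        assert result.entries[0].range == 0.0

    def test_ranking_matches_brute_force_oracle(self):
        """Three-parameter toy: ranking equals exhaustive recomputation."""
        from skincost.model_graph import Branch, Chance, COMPLEMENT

        model = PathwayModel(
            name="toy",
            root=Chance(
                "split",
                branches=[
                    Branch("p1", Terminal("a", costs=["c1"])),
                    Branch(COMPLEMENT, Terminal("b", costs=["c2"])),
                ],
            ),
            horizon_years=1,
        )
        params = ParameterSet.from_specs(
            [
                ParameterSpec("p1", Kind.PROBABILITY, 0.3, Distribution.BETA, se=0.03),
                ParameterSpec("c1", Kind.COST, 500.0, Distribution.GAMMA, se=50.0),
                ParameterSpec("c2", Kind.COST, 80.0, Distribution.GAMMA, se=8.0),
            ]
        )
        margin = 0.2
        result = one_way_sensitivity(model, params, margin=margin)

        def cost(p1, c1, c2):
            return p1 * c1 + (1 - p1) * c2

        base = params.point_values()
        oracle_ranges = {}
        for name in ("p1", "c1", "c2"):
            lo, hi = base[name] * (1 - margin), base[name] * (1 + margin)
            values = dict(base)
            values[name] = lo
            lo_cost = cost(**values)
            values[name] = hi
            hi_cost = cost(**values)
            oracle_ranges[name] = abs(hi_cost - lo_cost)
        oracle_ranking = sorted(oracle_ranges, key=lambda k: -oracle_ranges[k])
        assert result.ranking() == oracle_ranking
        for entry in result.entries:
            assert entry.range == pytest.approx(oracle_ranges[entry.parameter])

    def test_margin_outside_stated_band_rejected(self, au_params, au_kc_model):
        with pytest.raises(ValueError):
            one_way_sensitivity(au_kc_model, au_params, margin=0.01)

    def test_quartile_mode_uses_fitted_percentiles(self):
        model, params = self._linear_model_params()
        result = one_way_sensitivity(model, params, mode="quartiles")
        entry = {e.parameter: e for e in result.entries}["c"]
        assert entry.low_setting == pytest.approx(params["c"].quantile(0.25))
        assert entry.high_setting == pytest.approx(params["c"].quantile(0.75))

    def test_headline_tornado_led_by_stage_probabilities_and_therapy_costs(
        self, au_params, au_melanoma_models
    ):
        """Cost drivers of the all-stage mean: stage mix and high-cost therapies."""
        evaluator = StageWeightedCost(au_melanoma_models)
        result = one_way_sensitivity(evaluator, au_params, margin=0.15)
        drivers = {
            n
            for n in result.ranking()
            if n.startswith("p_stage_") or n.startswith("cost_course_")
        }
        top = result.ranking()[:8]
        assert sum(name in drivers for name in top) >= 5
        assert any(name.startswith("cost_course_") for name in top)
        assert any(name.startswith("p_stage_") for name in result.ranking()[:3])
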