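"""Probabilistic and univariate sensitivity analysis."""

import numpy as np
import pytest

from earlycea import CANDIDATE_TESTS
from earlycea.economics import compare_strategies, run_strategy
from earlycea.parameters import psa_distributions
from earlycea.strategy import DiagnosticTest, StrategyMode, StrategySpec, TestAccuracy
from earlycea.uncertainty import (
    PsaDraws,
    ce_plane_summary,
    ceac,
    default_owsa_ranges,
    run_owsa,
    run_psa,
)


@pytest.fixture(scope="module")
def base_comparison(cohort, params, bcell_intermediate):
    cur = run_strategy(cohort, StrategySpec(StrategyMode.CURRENT), params, seed=5)
    new = run_strategy(cohort, bcell_intermediate, params, seed=5)
    return compare_strategies(cur, new, params)


@pytest.fixture(scope="module")
def small_psa(cohort, params, bcell_intermediate):
    dists = psa_distributions(params)
    return run_psa(cohort, bcell_intermediate, params, dists, n_sims=200, seed=5)


class TestRunPsa:
    def test_degenerate_distributions_reproduce_base_case(
        self, cohort, params, bcell_intermediate, base_comparison
    ):
        frozen = params.replace(
            psa_beta_concentration=float("inf"), psa_gamma_cv=0.0
        )
        draws = run_psa(
            cohort, bcell_intermediate, frozen, psa_distributions(frozen),
            n_sims=5, seed=5,
        )
        assert np.ptp(draws.delta_cost) == 0.0
        assert np.ptp(draws.delta_qaly) == 0.0
        assert draws.delta_cost[0] == pytest.approx(base_comparison.delta_cost)
        assert draws.delta_qaly[0] == pytest.approx(base_comparison.delta_qaly)

    def test_degenerate_psa_with_common_sim_seed_equals_base_case_exactly(
        self, cohort, params, bcell_intermediate, base_comparison
    ):
        """Zero parameter variance + a fixed simulation seed gives exactly
        the base-case deltas (and zero variance across repeated draws)."""
        frozen = params.replace(
            psa_beta_concentration=float("inf"), psa_gamma_cv=0.0
        )
        dists = psa_distributions(frozen)
        rng = np.random.default_rng(0)
        dc = []
        de = []
        for _ in range(3):
            p_i = dists.sample(rng)
            cur = run_strategy(cohort, StrategySpec(StrategyMode.CURRENT), p_i, seed=5)
            new = run_strategy(cohort, bcell_intermediate, p_i, seed=5)
            dc.append(new.mean_cost - cur.mean_cost)
            de.append(new.mean_qaly - cur.mean_qaly)
        assert np.var(dc) == 0.0 and np.var(de) == 0.0
        assert dc[0] == pytest.approx(base_comparison.delta_cost)
        assert de[0] == pytest.approx(base_comparison.delta_qaly)

    def test_same_seed_identical_draws(self, cohort, params, bcell_intermediate):
        dists = psa_distributions(params)
        a = run_psa(cohort, bcell_intermediate, params, dists, n_sims=20, seed=9)
        b = run_psa(cohort, bcell_intermediate, params, dists, n_sims=20, seed=9)
        assert (a.delta_cost == b.delta_cost).all()
        assert (a.delta_qaly == b.delta_qaly).all()

    def test_mean_effect_within_monte_carlo_error_of_base_case(
        self, small_psa, base_comparison
    ):
        de = small_psa.delta_qaly
        se = de.std(ddof=1) / np.sqrt(len(de))
        assert abs(de.mean() - base_comparison.delta_qaly) < 3 * se


class TestCePlane:
    def test_quadrant_fractions_sum_to_one(self, small_psa):
        quad = ce_plane_summary(small_psa)
        assert sum(quad.values()) == pytest.approx(1.0)

    def test_all_northeast(self):
        draws = PsaDraws("x", np.ones(10), np.ones(10), seed=0)
        assert ce_plane_summary(draws)["NE"] == 1.0

    def test_mirrored_draws_fill_opposite_quadrants_equally(self):
        rng = np.random.default_rng(3)
        dc = rng.normal(size=500) + 0.3
        de = rng.normal(size=500) + 0.1
        draws = PsaDraws(
            "x", np.concatenate([dc, -dc]), np.concatenate([de, -de]), seed=0
        )
        quad = ce_plane_summary(draws)
        assert quad["NE"] == pytest.approx(quad["SW"], abs=1e-12)
        assert quad["SE"] == pytest.approx(quad["NW"], abs=1e-12)

    def test_dominant_configuration_concentrates_southeast(self):
        """A strategy that is cheaper and better in expectation puts the
        majority of symmetric-noise draws in the southeast quadrant."""
        rng = np.random.default_rng(4)
        draws = PsaDraws(
            "x",
            rng.normal(-50, 20, size=1000),
            rng.normal(0.02, 0.005, size=1000),
            seed=0,
        )
        quad = ce_plane_summary(draws)
        assert quad["SE"] > 0.5
        grid = np.linspace(0, 100000, 41)
        assert (ceac(draws, grid) >= 0.5).all()


class TestCeac:
    def test_at_zero_wtp_equals_fraction_of_cost_saving_draws(self, small_psa):
        frac = (small_psa.delta_cost <= 0).mean()
        assert ceac(small_psa, [0.0])[0] == pytest.approx(frac)

    def test_limit_is_one_when_all_draws_gain_qalys(self, small_psa):
        if (small_psa.delta_qaly > 0).all():
            assert ceac(small_psa, [1e12])[0] == 1.0

    def test_monotone_in_wtp_when_all_effects_positive(self, small_psa):
        mask = small_psa.delta_qaly > 0
        positive = PsaDraws(
            "x", small_psa.delta_cost[mask], small_psa.delta_qaly[mask], seed=0
        )
        grid = np.linspace(0, 120000, 49)
        curve = ceac(positive, grid)
        assert (np.diff(curve) >= 0).all()

    def test_double_counting_oracle(self, small_psa):
        """Counting nmb >= 0 equals counting dominant draws plus
        ICER-below-threshold draws among effect-gaining ones."""
        wtp = 20000.0
        dc, de = small_psa.delta_cost, small_psa.delta_qaly
        via_nmb = (wtp * de - dc >= 0).sum()
        pos = de > 0
        via_icer = ((dc[pos] / de[pos]) <= wtp).sum() + ((de <= 0) & (dc <= -wtp * np.abs(de))).sum()
        assert via_nmb == via_icer


class TestPlots:
    def test_plot_helpers_render(self, small_psa, cohort, params, bcell_intermediate):
        import matplotlib

        matplotlib.use("Agg")
        from earlycea.plots import plot_ce_plane, plot_ceac, plot_tornado

        assert plot_ce_plane(small_psa, wtp=20000.0) is not None
        assert plot_ceac(small_psa, np.linspace(0, 1e5, 11)) is not None
        entries = run_owsa(
            cohort, bcell_intermediate, params, seed=5,
            ranges={"das28_benefit": (0.0, 0.6)},
        )
        assert plot_tornado(entries) is not None


class TestOwsa:
    def test_das28_benefit_monotonically_improves_icer(
        self, cohort, params, bcell_intermediate
    ):
        entries = run_owsa(
            cohort, bcell_intermediate, params, seed=5,
            ranges={"das28_benefit": (0.0, 0.6)},
        )
        e = entries[0]
        assert e.raw_high < e.raw_low  # larger benefit, lower ICER

    def test_specificity_never_raises_icer(self, cohort, params):
        spec = StrategySpec(
            StrategyMode.ADD_ON_INTERMEDIATE,
            DiagnosticTest("t", TestAccuracy(0.60, 0.70), 150.0),
        )
        entries = run_owsa(
            cohort, spec, params, seed=5, ranges={"specificity": (0.55, 0.95)}
        )
        e = entries[0]
        assert e.raw_high <= e.raw_low

    def test_degenerate_range_has_zero_span(self, cohort, params, bcell_intermediate):
        benefit = params.das28_benefit
        entries = run_owsa(
            cohort, bcell_intermediate, params, seed=5,
            ranges={"das28_benefit": (benefit, benefit)},
        )
        assert entries[0].span == 0.0

    def test_entries_sorted_by_span(self, cohort, params, bcell_intermediate):
        entries = run_owsa(cohort, bcell_intermediate, params, seed=5)
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)
        assert {e.parameter for e in entries} == set(
            default_owsa_ranges(bcell_intermediate, params)
        )

    def test_inverted_range_rejected(self, cohort, params, bcell_intermediate):
        with pytest.raises(ValueError):
            run_owsa(
                cohort, bcell_intermediate, params, seed=5,
                ranges={"das28_benefit": (0.6, 0.0)},
            )
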