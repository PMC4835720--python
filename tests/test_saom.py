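"""SAOM engine: statistics, micro-steps, simulation, estimation, GOF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flynet import (
    EFFECT_NAMES,
    EffectSpec,
    ModelSpec,
    MoMSettings,
    NetworkPanel,
    effect_statistic,
    evaluation_function,
    fit_mom,
    generate_panel,
    gof,
    micro_step_probabilities,
    multi_group_fit,
    observed_targets,
    simulate_period,
    stepwise_select,
)
from flynet.saom import hamming


# ---------------------------------------------------------------------------
# independent brute-force oracles (loops over the definitions)

def oracle_statistic(name, x, v, i):
    n = x.shape[0]
    out = 0.0
    if name == "density":
        for j in range(n):
            out += x[i, j]
    elif name == "recip":
        for j in range(n):
            out += x[i, j] * x[j, i]
    elif name == "inPop":
        for j in range(n):
            if x[i, j]:
                for h in range(n):
                    out += x[h, j]
    elif name == "outAct":
        d = sum(x[i, j] for j in range(n))
        out = d * d
    elif name == "altX":
        for j in range(n):
            out += x[i, j] * v[j]
    elif name == "egoX":
        out = v[i] * sum(x[i, j] for j in range(n))
    elif name == "sameX":
        for j in range(n):
            if j != i and v[j] == v[i]:
                out += x[i, j]
    return float(out)


def random_digraph(rng, n, p=0.4):
    x = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(x, 0)
    return x


# ---------------------------------------------------------------------------
# effect statistics and the evaluation function

class TestEffectStatistics:
    def test_mutual_dyad_reciprocity(self):
        x = np.zeros((3, 3), dtype=np.int8)
        x[0, 1] = x[1, 0] = 1
        v = np.zeros(3, dtype=np.int8)
        assert effect_statistic("recip", x, v, 0) == 1.0

    def test_star_density_and_outdegree_activity(self):
        x = np.zeros((4, 4), dtype=np.int8)
        x[0, 1] = x[0, 2] = x[0, 3] = 1
        v = np.zeros(4, dtype=np.int8)
        assert effect_statistic("density", x, v, 0) == 3.0
        assert effect_statistic("outAct", x, v, 0) == 9.0

    def test_covariate_effects_single_tie(self):
        x = np.zeros((2, 2), dtype=np.int8)
        x[0, 1] = 1
        v = np.array([0, 1], dtype=np.int8)
        assert effect_statistic("altX", x, v, 0) == 1.0
        assert effect_statistic("egoX", x, v, 0) == 0.0
        assert effect_statistic("sameX", x, v, 0) == 0.0

    def test_unknown_effect_raises(self):
        with pytest.raises(ValueError):
            effect_statistic("transTrip", np.zeros((2, 2)), np.zeros(2), 0)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**30))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        x = random_digraph(rng, n)
        v = rng.integers(0, 2, n).astype(np.int8)
        i = int(rng.integers(0, n))
        for name in EFFECT_NAMES:
            assert effect_statistic(name, x, v, i) == oracle_statistic(name, x, v, i)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**30))
    def test_structural_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = random_digraph(rng, 6)
        v = rng.integers(0, 2, 6).astype(np.int8)
        for i in range(6):
            dens = effect_statistic("density", x, v, i)
            assert 0 <= effect_statistic("recip", x, v, i) <= dens
            assert effect_statistic("outAct", x, v, i) == dens**2
            alt = effect_statistic("altX", x, v, i)
            assert alt + (dens - alt) == dens


class TestEvaluationFunction:
    def test_null_model_is_zero(self):
        model = ModelSpec([EffectSpec("density", 0.0), EffectSpec("recip", 0.0)])
        x = random_digraph(np.random.default_rng(0), 5)
        assert evaluation_function(x, np.zeros(5), 2, model) == 0.0

    def test_single_density_effect(self):
        model = ModelSpec([EffectSpec("density", -1.0)])
        x = np.zeros((4, 4), dtype=np.int8)
        x[1, 0] = x[1, 2] = x[1, 3] = 1
        assert evaluation_function(x, np.zeros(4), 1, model) == -3.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**30))
    def test_is_dot_product_of_statistics(self, seed):
        rng = np.random.default_rng(seed)
        x = random_digraph(rng, 5)
        v = rng.integers(0, 2, 5).astype(np.int8)
        weights = rng.normal(0, 1, len(EFFECT_NAMES))
        model = ModelSpec([EffectSpec(n, w) for n, w in zip(EFFECT_NAMES, weights)])
        i = int(rng.integers(0, 5))
        expected = float(
            np.dot(weights, [effect_statistic(n, x, v, i) for n in EFFECT_NAMES])
        )
        assert evaluation_function(x, v, i, model) == pytest.approx(expected)


class TestMicroStepProbabilities:
    def test_null_model_uniform(self):
        model = ModelSpec([EffectSpec("density", 0.0)])
        x = random_digraph(np.random.default_rng(1), 4)
        p = micro_step_probabilities(x, np.zeros(4), 0, model)
        assert np.allclose(p, 0.25)

    def test_strongly_negative_density_dissolves(self):
        model = ModelSpec([EffectSpec("density", -30.0)])
        x = np.zeros((4, 4), dtype=np.int8)
        x[0, 1] = 1
        p = micro_step_probabilities(x, np.zeros(4), 0, model)
        # dissolving 0->1 dominates; creating any tie is negligible
        assert p[1] > 0.999
        assert p[2] < 1e-6 and p[3] < 1e-6

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**30))
    def test_matches_full_evaluation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        x = random_digraph(rng, n)
        v = rng.integers(0, 2, n).astype(np.int8)
        weights = rng.normal(0, 0.8, len(EFFECT_NAMES))
        model = ModelSpec([EffectSpec(nm, w) for nm, w in zip(EFFECT_NAMES, weights)])
        i = int(rng.integers(0, n))
        f = np.empty(n)
        for j in range(n):
            if j == i:
                f[j] = evaluation_function(x, v, i, model)
            else:
                alt = x.copy()
                alt[i, j] = 1 - alt[i, j]
                f[j] = evaluation_function(alt, v, i, model)
        expected = np.exp(f - f.max())
        expected /= expected.sum()
        p = micro_step_probabilities(x, v, i, model)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p.sum() == pytest.approx(1.0)


class TestSimulatePeriod:
    def test_zero_rate_is_identity(self):
        model = ModelSpec([EffectSpec("density", -1.0)])
        x0 = random_digraph(np.random.default_rng(2), 6)
        out = simulate_period(x0, np.zeros(6), model, 0.0, rng_seed=5)
        assert np.array_equal(out, x0)

    def test_fixed_seed_reproducible(self):
        model = ModelSpec([EffectSpec("density", -0.5), EffectSpec("recip", 0.5)])
        x0 = random_digraph(np.random.default_rng(3), 8)
        v = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.int8)
        a = simulate_period(x0, v, model, 3.0, rng_seed=42)
        b = simulate_period(x0, v, model, 3.0, rng_seed=42)
        assert np.array_equal(a, b)
        c = simulate_period(x0, v, model, 3.0, rng_seed=43)
        assert not np.array_equal(a, c)  # overwhelmingly likely

    def test_null_model_change_rate_matches_closed_form(self):
        # at beta=0 each specific tie is toggled at Poisson rate lam/n per
        # period (uniform actor x uniform alternative), so
        # E[hamming] = n(n-1) * P(odd toggles) = n(n-1)(1-exp(-2*lam/n))/2,
        # which approaches the opportunity count n*lam*(n-1)/n for small lam
        n, lam = 6, 0.5
        model = ModelSpec([EffectSpec("density", 0.0)])
        x0 = np.zeros((n, n), dtype=np.int8)
        total = 0
        reps = 3000
        for r in range(reps):
            out = simulate_period(x0, np.zeros(n), model, lam, rng_seed=(1000 + r))
            total += hamming(x0, out)
        p_odd = (1 - np.exp(-2 * lam / n)) / 2
        expected = n * (n - 1) * p_odd
        se = np.sqrt(n * (n - 1) * p_odd * (1 - p_odd) / reps)
        assert abs(total / reps - expected) < 4 * se
        assert expected == pytest.approx(n * lam * (n - 1) / n, rel=0.1)

    def test_density_only_two_actor_stationary_matches_logistic(self):
        # long-run tie probability for n=2 is exp(b)/(1+exp(b))
        beta = -0.7
        model = ModelSpec([EffectSpec("density", beta)])
        x0 = np.zeros((2, 2), dtype=np.int8)
        reps = 1500
        ties = 0
        for r in range(reps):
            out = simulate_period(x0, np.zeros(2), model, 25.0, rng_seed=(7000 + r))
            ties += int(out[0, 1]) + int(out[1, 0])
        p_hat = ties / (2 * reps)
        p_true = np.exp(beta) / (1 + np.exp(beta))
        se = np.sqrt(p_true * (1 - p_true) / (2 * reps))
        assert abs(p_hat - p_true) < 3 * se


class TestObservedTargets:
    def test_identical_observations_zero_rate_targets(self):
        x = random_digraph(np.random.default_rng(4), 5)
        panel = NetworkPanel("g", np.stack([x, x, x]), np.zeros(5, dtype=np.int8))
        model = ModelSpec([EffectSpec("density")])
        _, rates = observed_targets(panel, model)
        assert np.array_equal(rates, [0.0, 0.0])

    def test_single_tie_density_target(self):
        a = np.zeros((4, 4), dtype=np.int8)
        b = np.zeros((4, 4), dtype=np.int8)
        b[2, 3] = 1
        panel = NetworkPanel("g", np.stack([a, b]), np.zeros(4, dtype=np.int8))
        ev, rates = observed_targets(panel, ModelSpec([EffectSpec("density")]))
        assert ev[0] == 1.0
        assert rates[0] == 1.0

    def test_random_panel_matches_summation_oracle(self):
        rng = np.random.default_rng(6)
        obs = np.stack([random_digraph(rng, 6) for _ in range(4)])
        v = rng.integers(0, 2, 6).astype(np.int8)
        panel = NetworkPanel("g", obs, v)
        model = ModelSpec([EffectSpec(n) for n in EFFECT_NAMES])
        ev, rates = observed_targets(panel, model)
        expected_ev = np.zeros(len(EFFECT_NAMES))
        for m in range(1, 4):
            for i in range(6):
                for k, name in enumerate(EFFECT_NAMES):
                    expected_ev[k] += oracle_statistic(name, obs[m], v, i)
        assert ev == pytest.approx(expected_ev)
        for m in range(3):
            diff = sum(
                obs[m, i, j] != obs[m + 1, i, j]
                for i in range(6) for j in range(6) if i != j
            )
            assert rates[m] == diff


# ---------------------------------------------------------------------------
# estimation

RECOVERY_MODEL = ModelSpec(
    [EffectSpec("density", -1.5), EffectSpec("recip", 0.8), EffectSpec("egoX", -0.5)]
)


class TestFitMoM:
    def test_zero_change_panel_flagged_unidentifiable(self, light_settings):
        x = random_digraph(np.random.default_rng(8), 6)
        panel = NetworkPanel("g", np.stack([x, x, x]), np.zeros(6, dtype=np.int8))
        fit = fit_mom(panel, ModelSpec([EffectSpec("density")]), light_settings())
        assert not fit.converged
        assert "unidentifiable" in fit.message
        assert np.isnan(fit.estimates).all()
        assert all(np.allclose(r, 0.0) for _, r in fit.rate_estimates)

    def test_refit_identical_seed_bit_identical(self, light_settings):
        panel = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=21)
        f1 = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=9))
        f2 = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=9))
        assert np.array_equal(f1.estimates, f2.estimates)
        assert np.array_equal(f1.standard_errors, f2.standard_errors)
        assert np.array_equal(f1.conv_t_ratios, f2.conv_t_ratios)

    def test_collinear_effect_raises_singularity_error(self, light_settings):
        # with every actor informed, sameX duplicates density exactly
        model = ModelSpec([EffectSpec("density"), EffectSpec("sameX")])
        panel = generate_panel(8, (8, 0), 4, ModelSpec([EffectSpec("density", -1.0)]),
                               3.0, seed=2)
        with pytest.raises(ValueError, match="singular"):
            fit_mom(panel, model, light_settings())

    def test_estimates_track_truth_on_one_panel(self, light_settings):
        panel = generate_panel(12, (8, 4), 5, RECOVERY_MODEL, 4.0, seed=77)
        fit = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=3, n3=400))
        k = fit.effect_index("density")
        assert abs(fit.estimates[k] - (-1.5)) < 3 * fit.standard_errors[k]
        assert fit.standard_errors.min() > 0

    def test_result_serialization(self, light_settings, tmp_path):
        panel = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=21)
        fit = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=9))
        fit.to_json(tmp_path / "fit.json")
        import json

        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["effects"] == ["density", "recip", "egoX"]
        assert len(d["rate_estimates"][0]["rates"]) == 3


class TestMultiGroup:
    def test_single_group_reduces_to_fit_mom(self, light_settings):
        panel = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=30)
        f1 = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=1))
        f2 = multi_group_fit([panel], RECOVERY_MODEL, light_settings(seed=1))
        assert np.array_equal(f1.estimates, f2.estimates)

    def test_duplicated_panel_consistent_with_single_fit(self, light_settings):
        panel = generate_panel(12, (8, 4), 5, RECOVERY_MODEL, 4.0, seed=31)
        single = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=2, n3=400))
        twin = NetworkPanel(
            "copy", panel.observations.copy(), panel.covariate.copy(),
            interval_minutes=panel.interval_minutes,
        )
        double = multi_group_fit([panel, twin], RECOVERY_MODEL, light_settings(seed=2, n3=400))
        # same moment information twice: estimates agree within MC error
        se = np.maximum(single.standard_errors, 1e-3)
        assert np.all(np.abs(single.estimates - double.estimates) < 3 * se)
        assert len(double.rate_estimates) == 2

    def test_group_order_invariance(self, light_settings):
        p1 = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=41, group_id="a")
        p2 = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=42, group_id="b")
        f_ab = multi_group_fit([p1, p2], RECOVERY_MODEL, light_settings(seed=5))
        f_ba = multi_group_fit([p2, p1], RECOVERY_MODEL, light_settings(seed=5))
        assert np.array_equal(f_ab.estimates, f_ba.estimates)
        assert dict((g, tuple(r)) for g, r in f_ab.rate_estimates) == dict(
            (g, tuple(r)) for g, r in f_ba.rate_estimates
        )


class TestStepwise:
    def test_density_only_candidates_returns_density_model(self, light_settings):
        panel = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=50)
        selected = stepwise_select(panel, ["density"], light_settings(seed=6))
        assert selected.effect_names == ["density"]

    def test_candidates_must_include_density(self, light_settings):
        panel = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=50)
        with pytest.raises(ValueError, match="density"):
            stepwise_select(panel, ["recip"], light_settings())

    def test_active_reciprocity_retained(self, light_settings):
        # strong reciprocity in the generator; covariate effects inactive.
        # moderate turnover (rate 2.5, start near stationarity) keeps the
        # rate moment conditions solvable so screening fits converge
        gen = ModelSpec([EffectSpec("density", -1.4), EffectSpec("recip", 1.4)])
        panels = [
            generate_panel(12, (8, 4), 6, gen, 2.5, seed=60 + g,
                           x0_density=0.18, group_id=f"g{g}")
            for g in range(3)
        ]
        selected, details = stepwise_select(
            panels, ["density", "recip", "egoX", "altX"],
            light_settings(seed=8, n1=40, n2_iterations=30, n2_subphases=4,
                           n3=600, max_restarts=1),
            return_details=True,
        )
        assert "recip" in selected.effect_names
        assert details["per_effect"]["recip"]["p_value"] < 0.05
        assert details["per_effect"]["recip"]["converged"]


class TestGof:
    def _converged_fit(self, light_settings):
        panels = [
            generate_panel(12, (8, 4), 5, RECOVERY_MODEL, 4.0, seed=80 + g, group_id=f"g{g}")
            for g in range(2)
        ]
        fit = fit_mom(
            panels, RECOVERY_MODEL,
            light_settings(seed=4, n1=40, n2_iterations=30, n2_subphases=4,
                           n3=800, max_restarts=2),
        )
        assert fit.converged
        return fit, panels

    def test_seeded_p_value_reproducible(self, light_settings):
        fit, panels = self._converged_fit(light_settings)
        r1 = gof(fit, panels, "indegree_distribution", n_sim=50, seed=3)
        r2 = gof(fit, panels, "indegree_distribution", n_sim=50, seed=3)
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_gross_mismatch_rejected_at_floor(self, light_settings):
        fit, panels = self._converged_fit(light_settings)
        dense = np.ones((12, 12), dtype=np.int8)
        np.fill_diagonal(dense, 0)
        bogus = NetworkPanel(
            panels[0].group_id,
            np.stack([panels[0].observations[0]] + [dense] * 4),
            panels[0].covariate,
        )
        n_sim = 99
        res = gof(fit, [bogus, panels[1]], "indegree_distribution", n_sim=n_sim, seed=5)
        assert res.p_value <= 1 / (n_sim + 1) + 1e-12

    def test_requires_converged_fit(self, light_settings):
        panel = generate_panel(8, (5, 3), 4, RECOVERY_MODEL, 3.0, seed=90)
        fit = fit_mom(panel, RECOVERY_MODEL, light_settings(seed=1, n3=100))
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            gof(fit, panel)
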