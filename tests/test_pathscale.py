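"""SSF pipeline: step resampling, pools, random steps, the conditional-logit
likelihood (vs grid-search and statsmodels oracles), AICc ranking and the
second-stage regression."""

import math

import numpy as np
import pandas as pd
import pytest

from trapliner.landscape import FOREST, PASTURE, LandCoverMap, StreamNetwork
from trapliner.pathscale import (
    MODEL_REGISTRY,
    EmpiricalMoveDistributions,
    Step,
    StratumDropped,
    aicc,
    assemble_design,
    fit_conditional_logit,
    generate_random_steps,
    loo_distributions,
    odds_ratio,
    parse_model_spec,
    rank_models,
    resample_to_steps,
    second_stage,
    wald_ci,
)


def make_fixes(xy, bird="b1", dt_min=1.0, t0="2012-03-01"):
    xy = np.asarray(xy, float)
    return pd.DataFrame(
        {
            "bird_id": bird,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "timestamp": pd.date_range(t0, periods=len(xy), freq=f"{dt_min}min"),
            "obs_dist_class": "0-10",
        }
    )


class TestResampleToSteps:
    def test_straight_line_five_meter_fixes_give_ten_meter_steps(self):
        xy = [(5 * i, 0.0) for i in range(21)]
        steps = resample_to_steps(make_fixes(xy))
        assert len(steps) == 10
        assert all(s.length == pytest.approx(10.0) for s in steps)

    def test_time_gap_starts_new_bout(self):
        fixes = make_fixes([(0, 0), (20, 0), (40, 0), (60, 0)], dt_min=1.0)
        fixes.loc[2:, "timestamp"] += pd.Timedelta(minutes=25)
        steps = resample_to_steps(fixes)
        # the 20-min+ gap between fix 1 and 2 produces no step; bout restarts
        assert len(steps) == 2
        assert math.isnan(steps[1].turn)  # first step of the new bout

    def test_turning_angle_relative_to_previous_step(self):
        steps = resample_to_steps(make_fixes([(0, 0), (20, 0), (20, 20)]))
        assert math.isnan(steps[0].turn)
        assert steps[1].turn == pytest.approx(math.pi / 2)

    def test_step_count_order_of_magnitude_at_study_sampling_intensity(self):
        """~1561 usable fixes resampled at >=10 m / <=15 min give a used-step
        count on the order of the observed 903."""
        from trapliner.synthetic import SimulationConfig, gen_landscape, simulate_fixes
        from trapliner.pointscale import filter_and_dedupe

        cfg = SimulationConfig(seed=2, map_size=1200, n_birds=6, total_fixes=972)
        lcmap, streams = gen_landscape(cfg)
        fixes, _ = simulate_fixes(cfg, lcmap, streams)
        kept = filter_and_dedupe(fixes)
        steps = resample_to_steps(kept)
        per_fix = len(steps) / len(kept)
        assert 0.2 <= per_fix <= 1.0  # 903/1561 = 0.58 observed


class TestLooDistributions:
    def make_steps(self):
        steps = []
        for b, n in (("a", 5), ("b", 7), ("c", 3)):
            for i in range(n):
                steps.append(
                    Step(bird_id=b, origin=(0, 0), dest=(10 + i, 0), dt_min=5.0, turn=0.1 * i)
                )
        return steps

    def test_pool_excludes_focal_bird(self):
        steps = self.make_steps()
        pools = loo_distributions(steps, "a")
        assert len(pools.lengths) == 10
        assert "a" not in pools.source_birds

    def test_pool_size_conservation(self):
        steps = self.make_steps()
        for b, n in (("a", 5), ("b", 7), ("c", 3)):
            assert len(loo_distributions(steps, b).lengths) == 15 - n

    def test_single_bird_rejected(self):
        steps = [Step(bird_id="a", origin=(0, 0), dest=(5, 0), dt_min=5.0)]
        with pytest.raises(ValueError):
            loo_distributions(steps, "a")

    def test_bootstrap_reproduces_pool_mean(self):
        steps = self.make_steps()
        pool = loo_distributions(steps, "c")
        rng = np.random.default_rng(0)
        draws = rng.choice(pool.lengths, size=20000)
        assert draws.mean() == pytest.approx(pool.lengths.mean(), rel=0.02)


class TestGenerateRandomSteps:
    def pool(self, rng):
        return EmpiricalMoveDistributions(
            lengths=rng.gamma(2, 40, 2000), turns=rng.vonmises(0, 0.5, 2000), source_birds=("x",)
        )

    def test_all_forest_accepts_immediately_with_pool_lengths(self, all_forest_map):
        rng = np.random.default_rng(0)
        pool = EmpiricalMoveDistributions(
            lengths=np.array([12.0, 17.0]), turns=np.array([0.0, 0.5]), source_birds=("x",)
        )
        step = Step(bird_id="a", origin=(100.0, 100.0), dest=(110.0, 100.0), dt_min=5.0, turn=0.2)
        out = generate_random_steps(step, pool, all_forest_map, rng, n=20)
        assert len(out) == 20
        assert all(round(s.length, 6) in (12.0, 17.0) for s in out)
        assert all(s.origin == step.origin and not s.used for s in out)

    def test_tiny_islet_drops_stratum(self):
        g = np.full((60, 60), PASTURE)
        g[30, 30] = FOREST
        m = LandCoverMap(grid=g, resolution=5.0)
        rng = np.random.default_rng(1)
        pool = EmpiricalMoveDistributions(
            lengths=np.full(100, 200.0), turns=np.zeros(100), source_birds=("x",)
        )
        step = Step(bird_id="a", origin=(152.5, 152.5), dest=(152.5, 160.0), dt_min=5.0, turn=0.0)
        with pytest.raises(StratumDropped):
            generate_random_steps(step, pool, m, rng, n=20, max_rejections=2000)

    def test_deterministic_given_seed(self, half_forest_map):
        step = Step(bird_id="a", origin=(100.0, 250.0), dest=(110.0, 250.0), dt_min=5.0, turn=0.3)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            pool = self.pool(np.random.default_rng(5))
            outs.append(generate_random_steps(step, pool, half_forest_map, rng, n=20))
        assert [(s.dest, s.turn) for s in outs[0]] == [(s.dest, s.turn) for s in outs[1]]

    def test_random_step_lengths_exchangeable_with_pool(self):
        """On a huge all-forest map (essentially) no rejection occurs, so
        accepted lengths are draws from the pool (two-sample KS, alpha=0.01)."""
        from scipy.stats import ks_2samp

        big = LandCoverMap(grid=np.full((400, 400), FOREST), resolution=5.0)
        rng = np.random.default_rng(2)
        pool = self.pool(np.random.default_rng(9))
        step = Step(bird_id="a", origin=(1000.0, 1000.0), dest=(1012.0, 1000.0), dt_min=5.0, turn=0.1)
        lens = []
        for _ in range(40):
            lens += [s.length for s in generate_random_steps(step, pool, big, rng, n=20)]
        assert ks_2samp(lens, pool.lengths).pvalue > 0.01


class TestAssembleDesign:
    def strata(self):
        rng = np.random.default_rng(0)
        n = 42
        return pd.DataFrame(
            {
                "stratum": np.repeat(np.arange(2), 21),
                "used": np.tile([True] + [False] * 20, 2),
                "Stream": rng.uniform(0, 100, n),
                "TotGap": rng.uniform(0, 50, n),
                "MeanGap": rng.uniform(0, 30, n),
                "NumGap": rng.integers(0, 4, n).astype(float),
                "PropInFor": rng.uniform(0, 1, n),
                "ForAm": rng.uniform(0, 1, n),
                "Pasture": rng.uniform(0, 1, n),
            }
        )

    def test_two_column_model(self):
        d = assemble_design(self.strata(), "Stream + TotGap")
        assert list(d.columns) == ["Stream", "TotGap"]

    def test_interaction_model_has_three_columns(self):
        d = assemble_design(self.strata(), "Stream + TotGap * Pasture")
        assert list(d.columns) == ["Stream", "TotGap", "TotGap:Pasture"]
        st = self.strata()
        np.testing.assert_allclose(
            d["TotGap:Pasture"], st["TotGap"].to_numpy() * st["Pasture"].to_numpy()
        )

    def test_registry_contains_the_candidate_set(self):
        assert len(MODEL_REGISTRY) == 14
        assert "Stream + TotGap" in MODEL_REGISTRY
        # 5 univariate exposures, 5 exposure+Stream, 3 pasture interactions, Stream
        assert sum("*" in m for m in MODEL_REGISTRY) == 3
        assert parse_model_spec("A * B + C") == ["A", "A:B", "C"]

    def test_unknown_covariate_rejected(self):
        with pytest.raises(KeyError):
            assemble_design(self.strata(), "Stream + Slope")


def simulate_strata(rng, n_strata, beta, n_avail=20, n_cov=None, bird_ids=None):
    """Direct conditional-logit data generator (independent of the fitter):
    covariates N(0,1) scaled, used step drawn with softmax probabilities."""
    beta = np.atleast_1d(np.asarray(beta, float))
    k = len(beta)
    rows = []
    for s in range(n_strata):
        X = rng.normal(0, 1, size=(n_avail + 1, k)) * 10.0
        w = np.exp(X @ beta - (X @ beta).max())
        used = rng.choice(n_avail + 1, p=w / w.sum())
        for j in range(n_avail + 1):
            rows.append(
                {
                    "stratum": s,
                    "used": j == used,
                    "bird_id": (bird_ids[s % len(bird_ids)] if bird_ids else "b"),
                    **{f"x{i}": X[j, i] for i in range(k)},
                }
            )
    return pd.DataFrame(rows)


class TestConditionalLogit:
    def test_constant_strata_unidentifiable(self):
        rows = []
        for s in range(4):
            for j in range(21):
                rows.append({"stratum": s, "used": j == 0, "bird_id": "b", "x0": float(s)})
        strata = pd.DataFrame(rows)
        fit = fit_conditional_logit(strata[["x0"]], strata, model="x0")
        assert fit.status == "unidentifiable"
        # per-stratum choice probability is 1/21
        assert fit.loglik == pytest.approx(4 * math.log(1 / 21))

    def test_matches_grid_search_oracle(self):
        strata = pd.DataFrame(
            {
                "stratum": [0, 0, 0, 1, 1, 1, 2, 2, 2],
                "used": [True, False, False, True, False, False, True, False, False],
                "bird_id": "b",
                "x0": [1.0, 0.5, -0.2, 0.3, 1.1, 0.0, -0.5, 0.2, 0.4],
            }
        )
        fit = fit_conditional_logit(strata[["x0"]], strata, model="x0")
        grid = np.linspace(-6, 6, 120001)
        X = strata["x0"].to_numpy()
        ll = np.empty_like(grid)
        for g, b in enumerate(grid):
            eta = b * X
            tot = 0.0
            for s in range(3):
                sel = strata["stratum"] == s
                e = eta[sel.to_numpy()]
                tot += e[0] - np.log(np.exp(e).sum())
            ll[g] = tot
        assert fit.coef("x0") == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_invariant_to_stratum_constant_shifts(self):
        rng = np.random.default_rng(4)
        strata = simulate_strata(rng, 30, [0.15])
        f1 = fit_conditional_logit(strata[["x0"]], strata, model="m")
        shifted = strata.copy()
        shifted["x0"] = shifted["x0"] + shifted["stratum"] * 1000.0
        f2 = fit_conditional_logit(shifted[["x0"]], shifted, model="m")
        assert f1.coef("x0") == pytest.approx(f2.coef("x0"), abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_matches_statsmodels_conditional_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        strata = simulate_strata(rng, 60, [0.12, -0.08])
        fit = fit_conditional_logit(strata[["x0", "x1"]], strata, model="m")
        ref = sm.ConditionalLogit(
            strata["used"].astype(int), strata[["x0", "x1"]], groups=strata["stratum"]
        ).fit(disp=0)
        np.testing.assert_allclose(fit.params["coef"], ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.params["se"], ref.bse, rtol=1e-3)

    def test_or_and_ci_arithmetic_exact(self):
        rng = np.random.default_rng(1)
        strata = simulate_strata(rng, 40, [0.1])
        fit = fit_conditional_logit(strata[["x0"]], strata, model="m")
        b, se = fit.coef("x0"), fit.se("x0")
        assert fit.params.loc["x0", "or"] == odds_ratio(b)
        lo, hi = wald_ci(b, se)
        assert fit.params.loc["x0", "ci_low"] == pytest.approx(lo)
        assert fit.params.loc["x0", "ci_high"] == pytest.approx(hi)

    def test_random_coefficients_variance_zero_limit(self):
        """With tiny per-bird variance the simulated-ML fit reproduces the
        fixed-effects coefficients."""
        rng = np.random.default_rng(3)
        strata = simulate_strata(rng, 40, [0.12], bird_ids=["a", "b", "c", "d"])
        fixed = fit_conditional_logit(strata[["x0"]], strata, model="m")
        mixed = fit_conditional_logit(
            strata[["x0"]], strata, model="m", random_coefs=True, n_draws=64, seed=9
        )
        assert mixed.coef("x0") == pytest.approx(fixed.coef("x0"), abs=5e-3)
        assert mixed.random_sd is not None


class TestRanking:
    def test_single_model_delta_zero(self):
        rng = np.random.default_rng(0)
        strata = simulate_strata(rng, 20, [0.1])
        fit = fit_conditional_logit(strata[["x0"]], strata, model="m")
        tab = rank_models([fit])
        assert tab["delta_aicc"].iloc[0] == 0.0

    def test_aicc_formula(self):
        assert aicc(-100.0, 2, 50) == pytest.approx(200 + 4 + 2 * 2 * 3 / 47)
        # identical lnL, k differing by one
        d = aicc(-100.0, 3, 50) - aicc(-100.0, 2, 50)
        assert d == pytest.approx(2 + (2 * 3 * 4 / 46 - 2 * 2 * 3 / 47))

    def test_simpler_model_preferred_on_null_data(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            strata = simulate_strata(rng, 60, [0.2, 0.0])
            f1 = fit_conditional_logit(strata[["x0"]], strata, model="x0")
            f2 = fit_conditional_logit(strata[["x0", "x1"]], strata, model="x0+x1")
            tab = rank_models([f1, f2])
            wins += tab["model"].iloc[0] == "x0"
        assert wins >= 8


class TestSecondStage:
    def covs(self, n=12):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "forest_amount": rng.uniform(16, 78, n),
                "connectivity": rng.uniform(0, 60, n),
                "sex": rng.choice(["M", "F"], n),
            },
            index=[f"b{i}" for i in range(n)],
        )

    def test_constant_coefficients_give_zero_slopes(self):
        covs = self.covs()
        coefs = pd.Series(0.5, index=covs.index)
        tab = second_stage(coefs, covs)
        assert np.allclose(tab.loc[["forest_amount", "connectivity", "sex"], "coef"], 0.0, atol=1e-10)
        assert tab.loc["intercept", "coef"] == pytest.approx(0.5)

    def test_connectivity_slope_recovered(self):
        """Coefficients built as -0.0005 * CON + noise recover the slope."""
        covs = self.covs(20)
        rng = np.random.default_rng(5)
        coefs = pd.Series(
            -0.0005 * covs["connectivity"].to_numpy() + rng.normal(0, 0.002, 20), index=covs.index
        )
        tab = second_stage(coefs, covs)
        assert abs(tab.loc["connectivity", "coef"] - (-0.0005)) <= 2 * tab.loc["connectivity", "se"]

    def test_matches_normal_equations_oracle(self):
        covs = self.covs(8)
        rng = np.random.default_rng(2)
        coefs = pd.Series(rng.normal(0, 1, 8), index=covs.index)
        tab = second_stage(coefs, covs)
        X = np.column_stack(
            [
                np.ones(8),
                covs["forest_amount"],
                covs["connectivity"],
                pd.factorize(covs["sex"])[0].astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ coefs.to_numpy())
        np.testing.assert_allclose(tab["coef"].to_numpy(), beta, atol=1e-10)

    def test_too_few_birds_rejected(self):
        covs = self.covs(3)
        with pytest.raises(ValueError):
            second_stage(pd.Series(0.1, index=covs.index), covs)


class TestWaldCoverage:
    def test_null_coverage_of_wald_intervals(self):
        """Under beta=0, 95% Wald CIs cover zero at the nominal rate."""
        hits = 0
        n = 60
        for s in range(n):
            rng = np.random.default_rng(1000 + s)
            strata = simulate_strata(rng, 50, [0.0])
            fit = fit_conditional_logit(strata[["x0"]], strata, model="m")
            hits += abs(fit.coef("x0")) <= 1.96 * fit.se("x0")
        assert hits / n == pytest.approx(0.95, abs=0.08)
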