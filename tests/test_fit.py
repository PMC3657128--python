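"""Sampler correctness: grid oracle, Gaussian conditioning, shrinkage."""

import warnings

import numpy as np
import pandas as pd
import pytest

import forestvar as fv
from forestvar.demography import vector_rates
from forestvar.effects import FitConfig, fit_region


def _survival_tables(n_dead: int, n_live: int, dbh: float = 22.0) -> fv.InventoryTables:
    """One plot of large recent-period trees with survival data only."""
    plots = pd.DataFrame(
        {
            "plot_id": [1],
            "region": ["r1"],
            "mat": [12.0],
            "map": [1100.0],
            "period": ["recent"],
            "meas_year": [2004],
            "interval_yr": [5.0],
            "forestland": [True],
            "harvested": [False],
            "cond_boundary": [False],
        }
    )
    n = n_dead + n_live
    trees = pd.DataFrame(
        {
            "plot_id": 1,
            "subplot_id": 1,
            "size_class": "large",
            "pft": "north_temperate_hardwood",
            "dbh_t0": dbh,
            "dbh_t1": np.nan,
            "status_t1": ["dead"] * n_dead + ["live"] * n_live,
            "period": "recent",
            "shading_cai": 1.0,
        }
    )
    return fv.InventoryTables(trees=trees, plots=plots)


def _grid_posterior(tables, params, prior_mean, prior_sd):
    """Brute-force 1-D posterior of the large-tree recent mortality effect."""
    tr = tables.trees
    meta = tables.plots.iloc[0]
    _, m = vector_rates(
        tr["dbh_t0"].to_numpy(),
        tr["shading_cai"].to_numpy(),
        meta["mat"],
        meta["map"],
        "north_temperate_hardwood",
        params,
    )
    dt = float(meta["interval_yr"])
    died = (tr["status_t1"] == "dead").to_numpy()
    from scipy.special import expit, logit

    grid = np.linspace(prior_mean - 8 * prior_sd, prior_mean + 8 * prior_sd, 20001)
    log_post = -0.5 * ((grid - prior_mean) / prior_sd) ** 2
    for i in range(len(tr)):
        m_adj = expit(logit(m[i]) + grid)
        q = 1.0 - (1.0 - m_adj) ** dt
        log_post += np.log(q) if died[i] else dt * np.log(1.0 - m_adj)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    mean = float((grid * w).sum())
    sd = float(np.sqrt(((grid - mean) ** 2 * w).sum()))
    return mean, sd


class TestSingleEffectGridOracle:
    def test_posterior_matches_grid_integration(self, single_plot_tables, params):
        # independent prior: the marginal posterior of the informed
        # component is exactly 1-D and can be integrated on a grid
        sigma = np.eye(6) * 0.25
        cfg = FitConfig(
            chains=2,
            draws=15000,
            burn=2000,
            seed=7,
            fix_hyper=(np.zeros(6), sigma, 0.15),
            store_plot_draws=[1],
        )
        summ = fit_region(single_plot_tables, "r1", cfg, params)
        draws = summ.effect_draws[1][:, 5]
        g_mean, g_sd = _grid_posterior(single_plot_tables, params, 0.0, 0.5)
        assert draws.mean() == pytest.approx(g_mean, abs=0.01)
        assert draws.std() == pytest.approx(g_sd, abs=0.01)

    def test_uninformed_component_follows_prior(self, single_plot_tables, params):
        # no small trees and no growth observations: those components must
        # reproduce their (independent) prior
        sigma = np.eye(6) * 0.25
        cfg = FitConfig(
            chains=2,
            draws=8000,
            burn=1000,
            seed=3,
            fix_hyper=(np.zeros(6), sigma, 0.15),
            store_plot_draws=[1],
        )
        summ = fit_region(single_plot_tables, "r1", cfg, params)
        small = summ.effect_draws[1][:, 4]
        assert small.mean() == pytest.approx(0.0, abs=0.02)
        assert small.std() == pytest.approx(0.5, abs=0.02)


class TestMissingBlockConditioning:
    def test_small_effect_equals_gaussian_conditional_mean(self, truth, params):
        # a plot with zero small trees: its small-tree effect posterior must
        # equal the MVN conditional expectation given its other effects
        tables = _survival_tables(3, 17)
        dist = truth.regions["southern_mixed"]
        cfg = FitConfig(
            chains=2,
            draws=6000,
            burn=1000,
            seed=5,
            fix_hyper=(dist.mu, dist.sigma_mat, 0.15),
            store_plot_draws=[1],
        )
        summ = fit_region(tables, "r1", cfg, params)
        draws = summ.effect_draws[1]
        c = 4  # mort_small_recent
        others = [i for i in range(6) if i != c]
        sig = dist.sigma_mat
        w = np.linalg.solve(sig[np.ix_(others, others)], sig[np.ix_(others, [c])])
        cond = dist.mu[c] + (draws[:, others] - dist.mu[others]) @ w[:, 0]
        # sampled small-tree effects and their conditional means agree in
        # expectation (and the residual variance matches the Schur complement)
        se = draws[:, c].std() / np.sqrt(len(draws) / 10.0)  # crude ESS deflation
        assert draws[:, c].mean() == pytest.approx(cond.mean(), abs=3 * se)
        schur = sig[c, c] - float(sig[c, others] @ w[:, 0])
        assert np.var(draws[:, c] - cond) == pytest.approx(schur, rel=0.1)


class TestShrinkage:
    def test_posterior_sd_decreases_with_trees_per_plot(self, params):
        sds = []
        for n in (4, 16, 64):
            tables = _survival_tables(max(1, n // 10), n - max(1, n // 10))
            cfg = FitConfig(
                chains=1,
                draws=4000,
                burn=800,
                seed=2,
                fix_hyper=(np.zeros(6), np.eye(6) * 0.25, 0.15),
                store_plot_draws=[1],
            )
            summ = fit_region(tables, "r1", cfg, params)
            sds.append(summ.effect_draws[1][:, 5].std())
        assert sds[0] > sds[1] > sds[2]


class TestFitRegionContracts:
    def test_missing_region_rejected(self, single_plot_tables, params):
        with pytest.raises(ValueError, match="region"):
            fit_region(single_plot_tables, "atlantis", FitConfig(), params)

    def test_too_few_plots_rejected_without_fixed_hyper(self, single_plot_tables, params):
        with pytest.raises(ValueError, match="2 plots"):
            fit_region(single_plot_tables, "r1", FitConfig(), params)

    def test_nonconvergence_is_flagged_loudly(self, truth):
        # absurdly short chains on real hierarchical data cannot converge;
        # the summary must say so and warn rather than stay silent
        tables = fv.generate_inventory(truth, n_plots=30, mean_trees_per_plot=10, seed=6)
        cfg = FitConfig(chains=2, draws=40, burn=5, seed=0, rhat_threshold=1.001)
        with pytest.warns(RuntimeWarning, match="convergence"):
            summ = fit_region(tables, "northern_hardwoods_hemlock", cfg, truth.params)
        assert not summ.converged
        assert summ.warning


class TestCoverage:
    def test_hyperparameter_interval_coverage(self):
        # repeated reduced-scale fits: nominal 90% intervals for the six mu
        # components should cover truth at roughly the nominal rate
        hits = 0
        total = 0
        for rep in range(20):
            truth = fv.generate_truth(n_regions=1, seed=0)
            tables = fv.generate_inventory(
                truth, n_plots=60, mean_trees_per_plot=10, seed=100 + rep,
                frac_both_periods=1.0,
            )
            cfg = FitConfig(chains=1, draws=400, burn=400, seed=rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summ = fit_region(
                    tables, "northern_hardwoods_hemlock", cfg, truth.params
                )
            ci = summ.mu_interval(0.90)
            mu = truth.regions["northern_hardwoods_hemlock"].mu
            hits += int(((ci[:, 0] <= mu) & (mu <= ci[:, 1])).sum())
            total += 6
        coverage = hits / total
        assert 0.75 <= coverage <= 1.0
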