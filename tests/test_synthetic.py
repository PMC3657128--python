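"""Synthetic truth and inventory generation."""

import numpy as np
import pytest

import forestvar as fv
from forestvar.demography import PFTS
from forestvar.effects import COMPONENTS
from forestvar.simulator import stand_biomass, step_stand, EffectProcess


class TestGenerateTruth:
    def test_deterministic_given_arguments(self):
        t1 = fv.generate_truth(seed=5)
        t2 = fv.generate_truth(seed=5)
        for name in t1.regions:
            assert np.array_equal(t1.regions[name].mu, t2.regions[name].mu)
            assert np.array_equal(t1.regions[name].sigma_mat, t2.regions[name].sigma_mat)

    def test_all_covariances_positive_definite(self, truth):
        for dist in truth.regions.values():
            assert np.linalg.eigvalsh(dist.sigma_mat).min() > 0

    def test_configured_correlations_read_back(self, truth):
        for dist in truth.regions.values():
            corr = dist.correlation()
            assert corr[1, 2] == pytest.approx(0.47, abs=1e-12)
            assert corr[0, 3] == pytest.approx(0.70, abs=1e-12)
            assert corr[1, 4] == pytest.approx(0.25, abs=1e-12)
            assert corr[2, 5] == pytest.approx(0.45, abs=1e-12)

    def test_mean_centered_for_unit_mean_multiplier(self, truth):
        for dist in truth.regions.values():
            var = np.diag(dist.sigma_mat)
            assert np.allclose(dist.mu, -var / 2)

    def test_region_count_validated(self):
        with pytest.raises(ValueError):
            fv.generate_truth(n_regions=0)


class TestGenerateInventory:
    def test_reproducible(self, truth):
        a = fv.generate_inventory(truth, n_plots=30, seed=9)
        b = fv.generate_inventory(truth, n_plots=30, seed=9)
        assert a.trees.equals(b.trees)
        assert a.plots.equals(b.plots)

    def test_schema_and_referential_integrity(self, small_inventory):
        _, tables = small_inventory
        assert set(tables.trees["plot_id"]).issubset(set(tables.plots["plot_id"]))
        assert tables.trees.loc[tables.trees["status_t1"] == "dead", "dbh_t1"].isna().all()
        assert tables.plots["interval_yr"].between(3, 8).all()
        small = tables.trees["size_class"] == "small"
        assert (tables.trees.loc[small, "dbh_t0"] < 12.7).all()
        assert (tables.trees.loc[~small, "dbh_t0"] >= 12.7).all()
        # period labels consistent with measurement year
        early = tables.plots["period"] == "earlier"
        assert (tables.plots.loc[early, "meas_year"] < 2003).all()
        assert (tables.plots.loc[~early, "meas_year"] >= 2003).all()

    def test_effect_draws_stored_with_truth(self, truth):
        tables = fv.generate_inventory(truth, n_plots=25, seed=2)
        pe = truth.plot_effects
        assert pe is not None
        assert len(pe) == 25
        assert list(pe.columns[:6]) == list(COMPONENTS)

    def test_no_flags_when_fraction_zero(self, small_inventory):
        _, tables = small_inventory
        assert tables.plots["forestland"].all()
        assert not tables.plots["harvested"].any()
        assert not tables.plots["cond_boundary"].any()

    def test_flag_fractions_produce_flags(self, truth):
        tables = fv.generate_inventory(
            truth, n_plots=200, seed=3, flag_fracs=(0.2, 0.2, 0.2)
        )
        assert (tables.plots["forestland"] == 0).sum() > 10
        assert (tables.plots["harvested"] == 1).sum() > 10

    def test_death_fraction_matches_background_when_effects_off(self):
        # with ~zero effect variance and zero mean the population death
        # fraction must match the background model's analytic expectation
        truth = fv.generate_truth(
            n_regions=1, growth_sd=1e-6, mort_sd_scale=1e-6, center_mean=False, seed=0
        )
        tables = fv.generate_inventory(truth, n_plots=400, mean_trees_per_plot=25, seed=8)
        from forestvar.demography import vector_rates

        t = tables.trees.merge(
            tables.plots[["plot_id", "period", "mat", "map", "interval_yr"]],
            on=["plot_id", "period"],
        )
        q = np.empty(len(t))
        for pft, grp in t.groupby("pft", sort=False):
            _, m = vector_rates(
                grp["dbh_t0"].to_numpy(),
                grp["shading_cai"].to_numpy(),
                grp["mat"].to_numpy(),
                grp["map"].to_numpy(),
                str(pft),
                truth.params,
            )
            q[grp.index.to_numpy()] = 1.0 - (1.0 - m) ** grp["interval_yr"].to_numpy()
        observed = (t["status_t1"] == "dead").mean()
        expected = q.mean()
        se = np.sqrt((q * (1 - q)).sum()) / len(t)
        assert abs(observed - expected) < 3 * se

    def test_fourfold_effect_quadruples_expected_mortality(self, params, climate):
        # a stored large-tree effect of ln 4 implies ~4x the background
        # annual rate in the small-rate regime
        m = float(
            fv.background_mortality(25.0, 1.0, climate, "north_temperate_hardwood", params)
        )
        adj = float(fv.apply_mortality_effect(m, np.log(4.0)))
        assert adj / m == pytest.approx(4.0, rel=0.05)

    def test_invalid_tree_count_rejected(self, truth):
        with pytest.raises(ValueError):
            fv.generate_inventory(truth, n_plots=10, mean_trees_per_plot=0.0)


class TestInitialStands:
    def test_bare_ground_is_empty(self, params):
        stand = fv.generate_initial_stand("bare_ground", params)
        assert stand.cohorts == []
        assert stand_biomass(stand, params)["total"] == 0.0

    def test_bare_ground_first_step_recruits_every_viable_pft(self, params, climate, truth):
        stand = fv.generate_initial_stand("bare_ground", params, climate=climate)
        proc = EffectProcess(
            mu=np.zeros(3), a_mat=np.zeros((3, 3)), q_mat=np.zeros((3, 3))
        )
        after = step_stand(stand, params, proc, np.random.default_rng(0))
        expected = sum(
            1 for p in PFTS if float(fv.recruitment(p, 0.0, climate, params)) >= 1e-3
        )
        assert len(after.cohorts) == expected

    def test_random_stand_reproducible(self, params):
        a = fv.generate_initial_stand("random", params, seed=4)
        b = fv.generate_initial_stand("random", params, seed=4)
        assert [(c.pft, c.dbh, c.density) for c in a.cohorts] == [
            (c.pft, c.dbh, c.density) for c in b.cohorts
        ]
        assert sum(c.density for c in a.cohorts) > 0

    def test_unknown_kind_rejected(self, params):
        with pytest.raises(ValueError, match="kind"):
            fv.generate_initial_stand("plantation", params)
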