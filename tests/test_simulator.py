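"""VAR-1 effect process and cohort stand dynamics."""

import numpy as np
import pytest

import forestvar as fv
from forestvar.simulator import (
    EffectProcess,
    StandState,
    effect_process,
    simulate_stand,
    step_effects,
    step_stand,
    var1_from_blocks,
)


class TestVar1FromBlocks:
    def test_white_noise_limit(self):
        c0 = np.diag([0.1, 0.4, 0.36])
        a, q = var1_from_blocks(c0, np.zeros((3, 3)))
        assert np.allclose(a, 0.0)
        assert np.allclose(q, c0)

    def test_scalar_ar1_identities(self):
        a, q = var1_from_blocks(np.array([[1.0]]), np.array([[0.5]]))
        assert a[0, 0] == pytest.approx(0.5)
        assert q[0, 0] == pytest.approx(0.75)

    def test_perfect_persistence_flagged_degenerate(self):
        c0 = np.diag([0.2, 0.2, 0.2])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            a, q = var1_from_blocks(c0, c0)
        assert np.allclose(q, 0.0, atol=1e-10)

    def test_inconsistent_blocks_rejected_with_hint(self):
        c0 = np.diag([0.1, 0.1, 0.1])
        c1 = np.array([[0.0, 0.1, 0.0], [0.1, 0.0, 0.1], [0.0, 0.1, 0.0]])
        with pytest.raises(ValueError, match="shrink"):
            var1_from_blocks(c0, c1)

    def test_stationary_moments_match_blocks(self, truth):
        dist = truth.regions["southern_mixed"]
        from forestvar.effects import derive_blocks

        c0, c1 = derive_blocks(dist)
        a, q = var1_from_blocks(c0, c1)
        proc = EffectProcess(mu=np.zeros(3), a_mat=a, q_mat=q)
        rng = np.random.default_rng(1)
        n = 100_000
        x = np.empty((n, 3))
        e = np.zeros(3)
        for i in range(n):
            e = step_effects(e, proc, rng)
            x[i] = e
        emp_c0 = np.cov(x.T)
        emp_c1 = (x[1:] - x.mean(0)).T @ (x[:-1] - x.mean(0)) / (n - 1)
        emp_c1 = 0.5 * (emp_c1 + emp_c1.T)
        assert np.linalg.norm(emp_c0 - c0) / np.linalg.norm(c0) < 0.05
        assert np.linalg.norm(emp_c1 - c1) / np.linalg.norm(c1) < 0.05


class TestStepEffects:
    def test_degenerate_process_returns_mean(self):
        mu = np.array([0.1, -0.2, 0.3])
        proc = EffectProcess(mu=mu, a_mat=np.zeros((3, 3)), q_mat=np.zeros((3, 3)))
        rng = np.random.default_rng(0)
        out = step_effects(np.array([5.0, 5.0, 5.0]), proc, rng)
        assert np.allclose(out, mu)

    def test_fixed_mode_pins_mortality_components(self, truth):
        proc = effect_process(truth.regions["prairie"], mode="fixed")
        rng = np.random.default_rng(3)
        e = proc.mu.copy()
        growth_values = []
        for _ in range(50):
            e = step_effects(e, proc, rng)
            assert e[1] == proc.pin[1]
            assert e[2] == proc.pin[2]
            growth_values.append(e[0])
        assert np.std(growth_values) > 0  # growth still evolves

    def test_effect_scale_pinning_uses_process_mean(self, truth):
        proc = effect_process(truth.regions["prairie"], mode="fixed", pin_scale="effect")
        rng = np.random.default_rng(3)
        e = step_effects(proc.mu.copy(), proc, rng)
        assert e[1] == proc.mu[1]
        assert e[2] == proc.mu[2]

    def test_matched_growth_noise_across_modes(self, truth):
        dist = truth.regions["prairie"]
        va = effect_process(dist, mode="variable")
        fx = effect_process(dist, mode="fixed")
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        e1 = e2 = va.mu.copy()
        for _ in range(20):
            e1 = step_effects(e1, va, r1)
            e2 = step_effects(e2, fx, r2)
            assert e1[0] == e2[0]  # identical growth trajectory

    def test_stationarity_of_long_runs(self, truth):
        proc = effect_process(truth.regions["oak_hickory"])
        rng = np.random.default_rng(2)
        e = proc.mu.copy()
        xs = np.empty((40_000, 3))
        for i in range(len(xs)):
            e = step_effects(e, proc, rng)
            xs[i] = e
        from forestvar.effects import derive_blocks

        c0, _ = derive_blocks(truth.regions["oak_hickory"])
        se = np.sqrt(np.diag(c0) / len(xs)) * np.sqrt(
            (1 + np.diag(proc.a_mat)) / (1 - np.diag(proc.a_mat))
        )
        assert np.all(np.abs(xs.mean(0) - proc.mu) < 4 * se)


class TestStepStand:
    def test_empty_stand_gets_open_canopy_recruits(self, params, climate):
        proc = EffectProcess(mu=np.zeros(3), a_mat=np.zeros((3, 3)), q_mat=np.zeros((3, 3)))
        stand = StandState(cohorts=[], effects=np.zeros(3), time=0.0, climate=climate)
        out = step_stand(stand, params, proc, np.random.default_rng(0))
        for c in out.cohorts:
            assert c.dbh == pytest.approx(2.54)
            assert c.density == pytest.approx(
                float(fv.recruitment(c.pft, 0.0, climate, params))
            )

    def test_extreme_mortality_effect_wipes_existing_cohorts(self, params, climate):
        mu = np.array([0.0, 12.0, 12.0])  # ~e^12-fold mortality odds
        proc = EffectProcess(mu=mu, a_mat=np.zeros((3, 3)), q_mat=np.zeros((3, 3)))
        stand = fv.generate_initial_stand("random", params, seed=1, climate=climate)
        out = step_stand(stand, params, proc, np.random.default_rng(0))
        survivors = [c for c in out.cohorts if c.dbh != pytest.approx(2.54)]
        assert survivors == []

    def test_zero_effects_match_background_update(self, params, climate):
        proc = EffectProcess(mu=np.zeros(3), a_mat=np.zeros((3, 3)), q_mat=np.zeros((3, 3)))
        stand = fv.generate_initial_stand("random", params, seed=2, climate=climate)
        out = step_stand(stand, params, proc, np.random.default_rng(0))
        # survival of the tallest (unshaded) cohort equals the background rate
        tallest = max(stand.cohorts, key=lambda c: float(fv.demography.tree_height(c.dbh, c.pft, params)))
        m = float(fv.background_mortality(tallest.dbh, 0.0, climate, tallest.pft, params))
        g = float(fv.background_growth(tallest.dbh, 0.0, climate, tallest.pft, params))
        new_dbh = tallest.dbh + 5.0 * g
        match = [c for c in out.cohorts if abs(c.dbh - new_dbh) < 0.51]
        assert match
        assert match[0].density <= tallest.density * (1 - m) ** 5 + 1e-9

    def test_density_never_increases_for_surviving_cohorts(self, params, climate, truth):
        proc = effect_process(truth.regions["mesophytic"])
        stand = fv.generate_initial_stand("random", params, seed=3, climate=climate)
        rng = np.random.default_rng(1)
        total_before = sum(c.density for c in stand.cohorts)
        out = step_stand(stand, params, proc, rng)
        veterans = [c for c in out.cohorts if c.dbh > 2.6]
        assert sum(c.density for c in veterans) <= total_before + 1e-9


class TestSimulateStand:
    def test_zero_years_returns_initial_state_only(self, params, climate, truth):
        proc = effect_process(truth.regions["prairie"])
        init = fv.generate_initial_stand("bare_ground", params, climate=climate)
        traj = simulate_stand(init, 0, "fixed", params, proc, seed=0)
        assert len(traj) == 1
        assert traj["total"].iloc[0] == 0.0

    def test_reproducible_and_correct_length(self, params, climate, truth):
        proc = effect_process(truth.regions["prairie"])
        init = fv.generate_initial_stand("bare_ground", params, climate=climate)
        a = simulate_stand(init, 200, "variable", params, proc, seed=5)
        b = simulate_stand(init, 200, "variable", params, proc, seed=5)
        assert len(a) == 41
        assert a.equals(b)

    def test_deterministic_run_grows_to_plateau(self, params, climate, truth):
        # no growth noise, fixed mortality: bare ground climbs monotonically
        # to a quasi-equilibrium
        from forestvar.effects import derive_blocks

        c0, _ = derive_blocks(truth.regions["prairie"])
        mu3 = np.zeros(3)
        proc = EffectProcess(mu=mu3, a_mat=np.zeros((3, 3)), q_mat=np.zeros((3, 3)))
        init = fv.generate_initial_stand("bare_ground", params, climate=climate)
        traj = simulate_stand(init, 600, "fixed", params, proc, seed=0)
        total = traj["total"].to_numpy()
        rise = total[:40]
        assert np.all(np.diff(rise) > -1e-9)
        late = total[total > 0][-40:]
        assert late.std() / late.mean() < 0.05
        assert 120 < late.mean() < 400

    def test_biomass_finite_under_default_dynamics(self, params, climate, truth):
        proc = effect_process(truth.regions["subtropical_evergreen"])
        init = fv.generate_initial_stand("bare_ground", params, climate=climate)
        traj = simulate_stand(init, 400, "variable", params, proc, seed=11)
        assert np.all(np.isfinite(traj["total"]))

    def test_invalid_years_rejected(self, params, climate, truth):
        proc = effect_process(truth.regions["prairie"])
        init = fv.generate_initial_stand("bare_ground", params, climate=climate)
        with pytest.raises(ValueError):
            simulate_stand(init, 12, "fixed", params, proc, seed=0)
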