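import numpy as np
import pytest

import photoclock as pc
from photoclock.fitting import (FitSpec, fit, integrate_target,
                                pif_activity_trajectory,
                                target_residual_builder)

FREE5 = ("v0_athb2", "v_athb2", "k_athb2", "h_athb2", "d_athb2")


@pytest.fixture(scope="module")
def activities(params):
    """Frozen PIF-activity trajectories for the two standard photoperiods."""
    return {
        "SD": pif_activity_trajectory(params, pc.Environment.make(8)),
        "LD": pif_activity_trajectory(params, pc.Environment.make(16)),
    }


def make_datasets(params, activities, sigma=0.0, seed=0, truth_scale=None):
    """Target-gene observations generated at (optionally perturbed) truth."""
    q = params.copy()
    if truth_scale:
        for nm, f in truth_scale.items():
            q.set(nm, q[nm] * f)
    rng = np.random.default_rng(seed)
    out = {}
    for key, act in activities.items():
        m = integrate_target(act, q["v0_athb2"], q["v_athb2"], q["k_athb2"],
                             q["h_athb2"], q["d_athb2"])
        grid = np.arange(0.0, 24.1, 2.0)
        vals = np.interp(grid, m.zt, m.value)
        if sigma > 0:
            vals = vals * rng.lognormal(0.0, sigma, size=vals.shape)
        out[key] = pc.Timeseries(grid, vals, label=key)
    return out, q


class TestTargetSubmodel:
    def test_periodic_solution_matches_full_simulation(self, params, sims):
        act = pif_activity_trajectory(params, pc.Environment.make(8))
        m = integrate_target(act, params["v0_athb2"], params["v_athb2"],
                             params["k_athb2"], params["h_athb2"],
                             params["d_athb2"])
        full = sims.series("ATHB2_m", hours=8)
        assert np.max(np.abs(m.value - full.value)) / full.value.max() < 1e-3

    def test_periodic_boundary(self, params, activities):
        m = integrate_target(activities["SD"], 0.1, 1.0, 1.0, 2.0, 0.4)
        assert m.value[0] == pytest.approx(m.value[-1], rel=1e-9)


class TestFit:
    def test_zero_free_parameters_returns_input(self, params, activities):
        data, _ = make_datasets(params, activities)
        resid = target_residual_builder("athb2", activities, data, params)
        spec = FitSpec(free={}, datasets=data, seed=1)
        res = fit(params, spec, residual=resid)
        assert res.parameters.diff(params) == {}
        assert res.cost == res.cost0

    def test_final_cost_never_exceeds_initial(self, params, activities):
        data, _ = make_datasets(params, activities, sigma=0.05, seed=5)
        resid = target_residual_builder("athb2", activities, data, params)
        spec = FitSpec.around(params, FREE5, factor=5.0, datasets=data,
                              multi_start=3, seed=2)
        res = fit(params, spec, residual=resid)
        assert res.cost <= res.cost0

    def test_deterministic_given_seed(self, params, activities):
        data, _ = make_datasets(params, activities, sigma=0.05, seed=5)
        resid = target_residual_builder("athb2", activities, data, params)
        spec = FitSpec.around(params, FREE5, factor=5.0, datasets=data,
                              multi_start=3, seed=7)
        r1 = fit(params, spec, residual=resid)
        r2 = fit(params, spec, residual=resid)
        assert all(r1.parameters[nm] == r2.parameters[nm] for nm in FREE5)

    def test_noiseless_recovery_of_five_target_parameters(self, params,
                                                          activities):
        truth_scale = {"v0_athb2": 1.8, "v_athb2": 0.7, "k_athb2": 1.4,
                       "h_athb2": 0.8, "d_athb2": 1.3}
        data, q_true = make_datasets(params, activities,
                                     truth_scale=truth_scale)
        resid = target_residual_builder("athb2", activities, data, params)
        spec = FitSpec.around(params, FREE5, factor=10.0, datasets=data,
                              multi_start=8, seed=3)
        res = fit(params, spec, residual=resid)
        for nm in FREE5:
            assert res.parameters[nm] == pytest.approx(q_true[nm], rel=0.01), nm

    def test_noisy_recovery_median_within_20_percent(self, params, activities):
        # 5% multiplicative noise, median error over 10 seeds; the synthetic
        # truth keeps the half-saturation inside the PIF-activity range so
        # that v and k are separately identifiable
        truth_scale = {"v0_athb2": 1.5, "v_athb2": 0.8, "k_athb2": 0.5,
                       "h_athb2": 0.8, "d_athb2": 1.2}
        errors = {nm: [] for nm in FREE5}
        for seed in range(10):
            data, q_true = make_datasets(params, activities, sigma=0.05,
                                         seed=seed, truth_scale=truth_scale)
            resid = target_residual_builder("athb2", activities, data, params)
            spec = FitSpec.around(params, FREE5, factor=10.0, datasets=data,
                                  multi_start=4, seed=seed)
            res = fit(params, spec, residual=resid)
            for nm in FREE5:
                errors[nm].append(abs(res.parameters[nm] / q_true[nm] - 1.0))
        for nm, errs in errors.items():
            assert np.median(errs) <= 0.20, (nm, errs)

    def test_recovery_degrades_monotonically_with_noise(self, params,
                                                        activities):
        # median total parameter error grows along the noise ladder
        truth_scale = {"v_athb2": 0.8, "k_athb2": 1.3}
        med = []
        for sigma in (0.0, 0.02, 0.05, 0.10):
            errs = []
            for seed in range(5):
                data, q_true = make_datasets(params, activities, sigma=sigma,
                                             seed=seed, truth_scale=truth_scale)
                resid = target_residual_builder("athb2", activities, data,
                                                params)
                spec = FitSpec.around(params, ("v_athb2", "k_athb2"),
                                      factor=10.0, datasets=data,
                                      multi_start=3, seed=seed)
                res = fit(params, spec, residual=resid)
                errs.append(sum(abs(res.parameters[nm] / q_true[nm] - 1.0)
                                for nm in ("v_athb2", "k_athb2")))
            med.append(float(np.median(errs)))
        assert med == sorted(med), med

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FitSpec(free={"v_athb2": (2.0, 1.0)}, datasets={})

    def test_missing_residual_rejected(self, params):
        spec = FitSpec(free={"v_athb2": (0.1, 10.0)}, datasets={})
        with pytest.raises(ValueError):
            fit(params, spec)
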