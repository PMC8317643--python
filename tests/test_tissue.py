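import numpy as np
import pytest

from restforge import _kernels
from restforge.cell import default_stim_amplitude
from restforge.params import make_base_params, resting_state
from restforge.tissue import (
    TissueConfig,
    inducibility_sweep,
    measure_cv,
    prepace_state,
    s1s2_crossfield,
    step_monodomain,
)


class TestPrepace:
    def test_uniform_broadcast_stays_uniform(self, base_params, tissue_cfg):
        state = prepace_state(base_params)
        n = 16
        grids = tuple(np.full((n, n), x) for x in state)
        out = step_monodomain(grids, base_params, D=1e-4, dt=0.02, dx=0.025, n_steps=200)
        for g in out:
            assert np.ptp(g) == 0.0  # diffusion of a uniform state is zero

    def test_prepace_converged_at_100_beats(self, base_params):
        a = prepace_state(base_params, beats=100)
        b = prepace_state(base_params, beats=150)
        assert np.max(np.abs(a - b)) < 1e-3

    def test_cache_hit_identical(self, base_params):
        a = prepace_state(base_params)
        b = prepace_state(base_params)
        assert np.array_equal(a, b)


class TestMonodomainStep:
    def test_d_zero_equals_single_cell(self, base_params):
        # with D = 0 every node follows the exact single-cell trajectory
        vec = base_params.to_vector()
        tab = _kernels.make_gate_table(vec)
        amp = default_stim_amplitude()
        n_steps = 10000  # 200 ms at dt 0.02
        dt = 0.02

        trace, cell_final, ok = _kernels.integrate_trace(
            vec, tab, resting_state(base_params), dt, n_steps, np.array([0.0]), 1.0, amp
        )
        assert ok

        n = 5
        state = resting_state(base_params)
        grids = tuple(np.full((n, n), x) for x in state)
        mask = np.ones((n, n), dtype=bool)
        # stimulus window: 1 ms of drive, then free running
        mid = step_monodomain(grids, base_params, 0.0, dt, 0.025, int(1.0 / dt), mask, amp)
        out = step_monodomain(mid, base_params, 0.0, dt, 0.025, n_steps - int(1.0 / dt))
        for g, ref in zip(out, cell_final):
            assert np.all(g == ref)  # exact to floating point

    def test_total_u_changes_only_via_reaction(self, base_params, rng):
        # no-flux Laplacian sums to zero: tissue-summed du equals the sum
        # of per-node reaction terms
        vec = base_params.to_vector()
        tab = _kernels.make_gate_table(vec)
        n = 12
        u = rng.uniform(0.0, 1.2, (n, n))
        v = rng.uniform(0.2, 1.0, (n, n))
        w = rng.uniform(0.2, 1.0, (n, n))
        s = rng.uniform(0.0, 0.8, (n, n))
        dt, dx, D = 0.02, 0.025, 2e-4
        reaction = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                du, _, _, _ = _kernels._derivs_tab(u[i, j], v[i, j], w[i, j], s[i, j], vec, tab, 0.0)
                reaction[i, j] = du
        out = step_monodomain((u, v, w, s), base_params, D, dt, dx, 1)
        total_change = out[0].sum() - u.sum()
        assert total_change == pytest.approx(dt * reaction.sum(), rel=1e-10)


class TestConductionVelocity:
    def test_cv_monotone_in_conductivity(self, base_params, tissue_cfg):
        cvs = [measure_cv(base_params, s, tissue_cfg) for s in (0.002, 0.006, 0.012)]
        assert cvs[0] < cvs[1] < cvs[2]

    def test_sqrt_conductivity_scaling(self, base_params, tissue_cfg):
        cv1 = measure_cv(base_params, 0.003, tissue_cfg)
        cv2 = measure_cv(base_params, 0.012, tissue_cfg)
        assert cv2 / cv1 == pytest.approx(2.0, rel=0.15)

    def test_spatial_convergence_at_reference_conductivity(self, base_params, tissue_cfg):
        # halve dx at fixed dt so only the spatial error is refined
        from dataclasses import replace

        ref = replace(tissue_cfg, dt=0.01)  # dx = 0.0125 strip
        fine = replace(tissue_cfg, dx=0.00625, dt=0.01)
        cv_ref = measure_cv(base_params, 0.009, ref)
        cv_fine = measure_cv(base_params, 0.009, fine)
        assert abs(cv_fine - cv_ref) / cv_ref < 0.05


class TestS1S2:
    def test_long_coupling_interval_no_reentry(self, base_params, tissue_cfg):
        out = s1s2_crossfield(base_params, 0.009, 500.0, tissue_cfg)
        assert not out.induced and not out.sustained
        assert out.activity_ms < 200.0  # planar S2 wave transits and dies

    def test_empty_ci_grid(self, base_params, tissue_cfg):
        m = inducibility_sweep(base_params, sigmas=(0.009,), cis=(), cfg=tissue_cfg)
        assert m.sustained.shape == (1, 0)
        assert all(m.ci_window(0) is None for _ in [0])


def test_stability_bound_enforced(tissue_cfg):
    from dataclasses import replace

    bad = replace(tissue_cfg, dt=5.0)
    with pytest.raises(ValueError, match="stability"):
        bad.check_stability(0.012)
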