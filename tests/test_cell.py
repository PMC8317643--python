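import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restforge import _kernels
from restforge.cell import (
    MapCell,
    alternans_scan,
    default_stim_amplitude,
    derivatives,
    dynamic_restitution,
    extract_biomarkers,
    rescale_voltage,
    rested_biomarkers,
    simulate_train,
    unscale_voltage,
)
from restforge.params import make_base_params, resting_state


class TestDerivatives:
    def test_stimulus_at_rest_drives_du_exactly(self, base_params):
        # all three currents vanish at the resting potential
        rates, currents = derivatives(resting_state(base_params), base_params, 0.3)
        assert rates[0] == pytest.approx(0.3, abs=0.0)
        assert currents == (0.0, 0.0, 0.0)

    @given(
        st.floats(min_value=-0.1, max_value=1.6),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=-0.5, max_value=0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_current_decomposition_identity(self, u, v, w, s, istim):
        # du/dt + J_fi + J_so + J_si - i_stim == 0 by construction
        base = make_base_params()
        rates, (jfi, jso, jsi) = derivatives([u, v, w, s], base, istim)
        assert rates[0] + jfi + jso + jsi - istim == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_state_rejected(self, base_params):
        with pytest.raises(ValueError):
            derivatives([np.nan, 1, 1, 0], base_params)


class TestRescale:
    def test_rest_maps_to_published_rmp(self):
        assert rescale_voltage(0.0) == pytest.approx(-84.0)

    def test_affine_and_invertible(self, rng):
        u = rng.uniform(-1, 2, 20)
        v = rescale_voltage(u)
        # affine: differences proportional
        assert np.allclose(np.diff(v), 85.7 * np.diff(u))
        assert np.allclose(unscale_voltage(v), u)


class TestSimulateTrain:
    def test_zero_stimulus_stays_at_rest(self, base_params):
        tr = simulate_train(base_params, 400, 2, stim_amp=0.0)
        assert np.all(np.abs(tr.voltage - tr.voltage[0]) < 0.5)

    def test_trace_time_axis(self, base_params):
        tr = simulate_train(base_params, 300, 2, dt=0.05)
        assert tr.time[0] == 0.0
        assert np.allclose(np.diff(tr.time), 0.05)

    def test_dt_refinement_changes_apd90_below_half_ms(self, base_params):
        coarse = extract_biomarkers(simulate_train(base_params, 500, 5, dt=0.04))
        fine = extract_biomarkers(simulate_train(base_params, 500, 5, dt=0.02))
        assert abs(coarse.APD90 - fine.APD90) < 0.5


class TestBiomarkers:
    def test_triangulation_identities(self, base_params):
        b = rested_biomarkers(base_params)
        assert b.Tri_90_30 == b.APD90 - b.APD30
        assert b.Tri_30_90 == b.APD30 / b.APD90
        assert b.Tri_90_50 == b.APD90 - b.APD50
        assert b.Tri_50_90 == b.APD50 / b.APD90
        assert b.APD30 < b.APD50 < b.APD90

    def test_no_action_potential_detected(self, base_params):
        from restforge.cell import NoActionPotentialError

        tr = simulate_train(base_params, 400, 1, stim_amp=0.0)
        with pytest.raises(NoActionPotentialError):
            extract_biomarkers(tr)


class TestDynamicRestitution:
    def test_protocol_identity_and_monotonicity(self, base_params):
        res = dynamic_restitution(base_params, dt=0.05)
        b = res.beats
        # APD + next DI = CL for steady in-block beat pairs
        for i in range(len(b) - 1):
            if (
                b.included[i]
                and b.captured[i]
                and b.captured[i + 1]
                and b.cl[i] == b.cl[i + 1]
            ):
                assert b.apd90[i] + b.di[i + 1] == pytest.approx(b.cl[i], abs=0.1)
        mean_apd = res.points().groupby("cl")["apd90"].mean()
        assert mean_apd.is_monotonic_increasing  # APD shrinks with CL

    def test_exclusion_mask_counts(self, base_params):
        res = dynamic_restitution(base_params, cls=(500, 400), beats_per_cl=20, dt=0.05)
        per_cl = res.points().groupby("cl").size()
        # 16 of 20 kept; the first included beat of the first block has no DI
        assert per_cl[400.0] == 16
        assert per_cl[500.0] in (15, 16)

    def test_single_cl_matches_simulate_train(self, base_params):
        res = dynamic_restitution(
            base_params, cls=(500.0,), beats_per_cl=8, dt=0.02, exclude_first=0, exclude_last=0
        )
        apd_last = res.beats["apd90"].iloc[-1]
        b = extract_biomarkers(simulate_train(base_params, 500, 8, dt=0.02))
        assert apd_last == pytest.approx(b.APD90, abs=0.5)

    def test_descending_cls_required(self, base_params):
        with pytest.raises(ValueError):
            dynamic_restitution(base_params, cls=(400, 500))


class TestAdaptiveIntegrator:
    def test_matches_fixed_step_apd_within_a_millisecond(self, base_params):
        vec = base_params.to_vector()
        tab = _kernels.make_gate_table(vec)
        amp = default_stim_amplitude()
        stims = np.arange(12, dtype=float) * 450.0
        total = 13 * 450.0
        st0 = resting_state(base_params)
        _, _, apd_fix, _, _, ok1 = _kernels.paced_beats(
            vec, tab, st0.copy(), stims, total, 0.02, 1.0, amp
        )
        _, _, apd_ad, _, _, ok2 = _kernels.paced_beats_adaptive(
            vec, tab, st0.copy(), stims, total, 1.0, amp, 0.02, 0.1, 0.002
        )
        assert ok1 and ok2
        assert np.nanmax(np.abs(apd_fix - apd_ad)) < 1.0


class TestAlternansScan:
    def test_constant_apd_cell_never_alternates(self):
        scan = alternans_scan(MapCell(lambda di: 200.0))
        assert scan.onset_cl is None

    def test_map_cell_onset_matches_map_iteration_oracle(self):
        # memoryless log-restitution cell: the scan must agree with direct
        # 1-D map iteration under the identical protocol and rule
        # saturating exponential restitution: APD = a (1 - b e^{-DI/tau});
        # steep (slope > 1) below DI ~ 75 ms, rested APD below the scan floor
        a, b, tau = 250.0, 0.9, 50.0
        fn = lambda di: a * (1.0 - b * np.exp(-max(di, 1.0) / tau))
        scan = alternans_scan(MapCell(fn, di0=400.0))

        def oracle_onset():
            cls = np.arange(620.0, 259.0, -5.0)
            deltas = []
            for cl in cls:
                di = 400.0
                apds = []
                for _ in range(10):
                    apd = fn(di)
                    apds.append(apd)
                    di = cl - apd
                    if di <= 1.0:
                        return None
                deltas.append(abs(apds[-1] - apds[-2]))
            for i in range(len(deltas) - 1):
                if deltas[i] >= 2.0 and deltas[i + 1] >= 2.0:
                    return cls[i]
            return None

        expected = oracle_onset()
        assert expected is not None
        assert scan.onset_cl == pytest.approx(expected, abs=20.0)

    def test_base_model_scan_runs_and_reports_grid(self, base_params):
        scan = alternans_scan(base_params, cl_hi=500, cl_lo=400, step=20, dt=0.05)
        assert scan.cls[0] == 500.0 and scan.cls[-1] == 400.0
        assert np.all(np.isfinite(scan.apd_pairs))

    def test_loss_of_capture_terminates_grid(self):
        # a cell whose APD exceeds short CLs loses 1:1 capture
        scan = alternans_scan(MapCell(lambda di: 350.0, di0=300.0), cl_hi=620, cl_lo=260)
        assert scan.lost_capture_cl is not None
        assert scan.onset_cl is None
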