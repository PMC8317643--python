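"""Numba kernels for the minimal ventricular model.

All kernels take the parameter set as a flat float64 vector in the
canonical order of :data:`restforge.params.PARAM_NAMES` and integrate the
four-variable system with explicit forward Euler.

The three smooth u-dependent nonlinearities of the model — the
tanh-shaped gate time constants tau_w^- and tau_so and the s-gate steady
state — are pre-tabulated per parameter set on a fine uniform u grid and
evaluated by linear interpolation inside the integrators
(:func:`make_gate_table`).  At the default resolution (16384 points over
u in [-2, 4]) the interpolation error is far below the time-stepping
error while removing the three libm tanh calls that otherwise dominate
the cost of every node update.

The pacing kernels measure activation times, APD90 and diastolic
intervals online with a small finite-state machine so that long protocols
never materialize a full voltage trace:

* ``u_base``   — u at stimulus onset (diastolic baseline of the beat)
* activation   — time of maximum du/dt between stimulus onset and the peak
* capture      — the beat reaches ``u_base + CAPTURE_AMP``
* repolarization — first downward crossing of
  ``u_base + 0.1 * (u_peak - u_base)`` after the peak (APD90 endpoint),
  linearly interpolated between steps; this may occur after the next
  stimulus (spill-over beats at fast pacing are handled correctly).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Minimum dimensionless excursion above the diastolic baseline for a beat
# to count as captured (a full action potential rises ~1.5 units).
CAPTURE_AMP = 0.5
# |u| beyond this signals numerical blow-up.
U_BLOWUP = 25.0

U_TAB_MIN = -2.0
U_TAB_MAX = 4.0
N_TAB = 16384


@njit(cache=True, fastmath=True)
def derivs(u, v, w, s, p, istim):
    """Exact time derivatives and currents at one state point.

    Returns (du, dv, dw, ds, j_fi, j_so, j_si).  This is the reference
    right-hand side; the integrators use the table-accelerated variant.
    """
    u_o = p[0]
    u_u = p[1]
    theta_v = p[2]
    theta_w = p[3]
    theta_vm = p[4]
    theta_o = p[5]
    tau_v1m = p[6]
    tau_v2m = p[7]
    tau_vp = p[8]
    tau_w1m = p[9]
    tau_w2m = p[10]
    k_wm = p[11]
    u_wm = p[12]
    tau_wp = p[13]
    tau_fi = p[14]
    tau_o1 = p[15]
    tau_o2 = p[16]
    tau_so1 = p[17]
    tau_so2 = p[18]
    k_so = p[19]
    u_so = p[20]
    tau_s1 = p[21]
    tau_s2 = p[22]
    k_s = p[23]
    u_s = p[24]
    tau_si = p[25]
    tau_w_inf = p[26]
    w_inf_star = p[27]

    h_v = 1.0 if u >= theta_v else 0.0
    h_w = 1.0 if u >= theta_w else 0.0
    h_vm = 1.0 if u >= theta_vm else 0.0
    h_o = 1.0 if u >= theta_o else 0.0

    tau_vm = (1.0 - h_vm) * tau_v1m + h_vm * tau_v2m
    tau_wm = tau_w1m + (tau_w2m - tau_w1m) * (1.0 + np.tanh(k_wm * (u - u_wm))) / 2.0
    tau_so = tau_so1 + (tau_so2 - tau_so1) * (1.0 + np.tanh(k_so * (u - u_so))) / 2.0
    tau_s = (1.0 - h_w) * tau_s1 + h_w * tau_s2
    tau_o = (1.0 - h_o) * tau_o1 + h_o * tau_o2

    v_inf = 1.0 if u < theta_vm else 0.0
    w_inf = (1.0 - h_o) * (1.0 - u / tau_w_inf) + h_o * w_inf_star

    j_fi = -v * h_v * (u - theta_v) * (u_u - u) / tau_fi
    j_so = (u - u_o) * (1.0 - h_w) / tau_o + h_w / tau_so
    j_si = -h_w * w * s / tau_si

    du = -(j_fi + j_so + j_si) + istim
    dv = (1.0 - h_v) * (v_inf - v) / tau_vm - h_v * v / tau_vp
    dw = (1.0 - h_w) * (w_inf - w) / tau_wm - h_w * w / tau_wp
    ds = ((1.0 + np.tanh(k_s * (u - u_s))) / 2.0 - s) / tau_s
    return du, dv, dw, ds, j_fi, j_so, j_si


@njit(cache=True, fastmath=True)
def make_gate_table(p):
    """Tabulate tau_w^-(u), 1/tau_so(u) and s_inf(u) for one parameter set.

    Returns a (N_TAB, 3) array over the uniform grid
    [U_TAB_MIN, U_TAB_MAX]; integrators interpolate linearly (values are
    clamped to the table ends, which only matters en route to blow-up).
    """
    tab = np.empty((N_TAB, 3))
    tau_w1m = p[9]
    tau_w2m = p[10]
    k_wm = p[11]
    u_wm = p[12]
    tau_so1 = p[17]
    tau_so2 = p[18]
    k_so = p[19]
    u_so = p[20]
    k_s = p[23]
    u_s = p[24]
    du = (U_TAB_MAX - U_TAB_MIN) / (N_TAB - 1)
    for i in range(N_TAB):
        u = U_TAB_MIN + i * du
        tab[i, 0] = tau_w1m + (tau_w2m - tau_w1m) * (1.0 + np.tanh(k_wm * (u - u_wm))) / 2.0
        tab[i, 1] = 1.0 / (tau_so1 + (tau_so2 - tau_so1) * (1.0 + np.tanh(k_so * (u - u_so))) / 2.0)
        tab[i, 2] = (1.0 + np.tanh(k_s * (u - u_s))) / 2.0
    return tab


_TAB_SCALE = (N_TAB - 1) / (U_TAB_MAX - U_TAB_MIN)


@njit(cache=True, fastmath=True, inline="always")
def _derivs_tab(u, v, w, s, p, tab, istim):
    """Table-accelerated right-hand side (du, dv, dw, ds)."""
    x = (u - U_TAB_MIN) * _TAB_SCALE
    if x < 0.0:
        x = 0.0
    elif x > N_TAB - 1.0001:
        x = N_TAB - 1.0001
    i0 = int(x)
    f = x - i0
    tau_wm = tab[i0, 0] + f * (tab[i0 + 1, 0] - tab[i0, 0])
    inv_tau_so = tab[i0, 1] + f * (tab[i0 + 1, 1] - tab[i0, 1])
    s_inf = tab[i0, 2] + f * (tab[i0 + 1, 2] - tab[i0, 2])

    h_v = 1.0 if u >= p[2] else 0.0
    h_w = 1.0 if u >= p[3] else 0.0
    h_vm = 1.0 if u >= p[4] else 0.0
    h_o = 1.0 if u >= p[5] else 0.0

    tau_vm = (1.0 - h_vm) * p[6] + h_vm * p[7]
    tau_s = (1.0 - h_w) * p[21] + h_w * p[22]
    tau_o = (1.0 - h_o) * p[15] + h_o * p[16]

    v_inf = 1.0 if u < p[4] else 0.0
    w_inf = (1.0 - h_o) * (1.0 - u / p[26]) + h_o * p[27]

    j_fi = -v * h_v * (u - p[2]) * (p[1] - u) / p[14]
    j_so = (u - p[0]) * (1.0 - h_w) / tau_o + h_w * inv_tau_so
    j_si = -h_w * w * s / p[25]

    du = -(j_fi + j_so + j_si) + istim
    dv = (1.0 - h_v) * (v_inf - v) / tau_vm - h_v * v / p[8]
    dw = (1.0 - h_w) * (w_inf - w) / tau_wm - h_w * w / p[13]
    ds = (s_inf - s) / tau_s
    return du, dv, dw, ds


@njit(cache=True, fastmath=True)
def integrate_trace(p, tab, state, dt, n_steps, stim_times, stim_dur, stim_amp):
    """Integrate recording u at every step.

    Returns (u_trace[n_steps+1], final_state[4], ok).  ``ok`` is False on
    numerical blow-up.
    """
    u = state[0]
    v = state[1]
    w = state[2]
    s = state[3]
    trace = np.empty(n_steps + 1, dtype=np.float64)
    trace[0] = u
    k = 0
    n_stim = stim_times.shape[0]
    for i in range(n_steps):
        t = i * dt
        while k < n_stim and t >= stim_times[k] + stim_dur:
            k += 1
        istim = stim_amp if (k < n_stim and stim_times[k] <= t) else 0.0
        du, dv, dw, ds = _derivs_tab(u, v, w, s, p, tab, istim)
        u += dt * du
        v += dt * dv
        w += dt * dw
        s += dt * ds
        trace[i + 1] = u
        if abs(u) > U_BLOWUP:
            out = np.empty(4, dtype=np.float64)
            out[0] = u
            out[1] = v
            out[2] = w
            out[3] = s
            return trace[: i + 2], out, False
    out = np.empty(4, dtype=np.float64)
    out[0] = u
    out[1] = v
    out[2] = w
    out[3] = s
    return trace, out, True


@njit(cache=True, fastmath=True)
def paced_beats(p, tab, state, stim_times, total_ms, dt, stim_dur, stim_amp):
    """Pace with an arbitrary stimulus-time train; measure beats online.

    Returns per-stimulus arrays
    ``(t_act, t_end90, apd90, captured, final_state, ok)``:

    * ``t_act``   activation time (ms; max-du/dt point), NaN if not captured
    * ``t_end90`` APD90 repolarization endpoint (ms), NaN if not reached
    * ``apd90``   t_end90 - t_act (ms)
    * ``captured`` 1.0/0.0 per stimulus
    """
    n_stim = stim_times.shape[0]
    t_act = np.full(n_stim, np.nan)
    t_end = np.full(n_stim, np.nan)
    apd = np.full(n_stim, np.nan)
    captured = np.zeros(n_stim)

    u = state[0]
    v = state[1]
    w = state[2]
    s = state[3]

    n_steps = int(total_ms / dt)
    k = 0  # next stimulus to fire
    cur = -1  # beat being watched for activation/peak
    rep = -1  # beat awaiting repolarization crossing
    u_base = 0.0
    max_du = -1.0e30
    t_max_du = 0.0
    u_peak = -1.0e30
    past_peak = False
    thresh = 0.0

    for i in range(n_steps):
        t = i * dt
        if k < n_stim and t >= stim_times[k]:
            cur = k
            u_base = u
            max_du = -1.0e30
            u_peak = u
            past_peak = False
            k += 1
        in_stim = cur >= 0 and stim_times[cur] <= t < stim_times[cur] + stim_dur
        istim = stim_amp if in_stim else 0.0
        du, dv, dw, ds = _derivs_tab(u, v, w, s, p, tab, istim)
        u_new = u + dt * du
        v += dt * dv
        w += dt * dw
        s += dt * ds
        if abs(u_new) > U_BLOWUP:
            out = np.empty(4, dtype=np.float64)
            out[0] = u_new
            out[1] = v
            out[2] = w
            out[3] = s
            return t_act, t_end, apd, captured, out, False

        if cur >= 0 and not past_peak:
            if du > max_du:
                max_du = du
                t_max_du = t
            if u_new > u_peak:
                u_peak = u_new
            if captured[cur] == 0.0 and u_new > u_base + CAPTURE_AMP:
                captured[cur] = 1.0
            if captured[cur] == 1.0 and u_new < u - 1.0e-12:
                # peak passed: freeze activation, arm repolarization watch
                past_peak = True
                t_act[cur] = t_max_du
                thresh = u_base + 0.1 * (u_peak - u_base)
                rep = cur
        if rep >= 0 and u_new < u and u_new <= thresh < u:
            # downward crossing of the APD90 level, linear interpolation
            frac = (u - thresh) / (u - u_new)
            tc = t + frac * dt
            t_end[rep] = tc
            apd[rep] = tc - t_act[rep]
            rep = -1

        u = u_new

    out = np.empty(4, dtype=np.float64)
    out[0] = u
    out[1] = v
    out[2] = w
    out[3] = s
    return t_act, t_end, apd, captured, out, True


@njit(cache=True, fastmath=True)
def paced_beats_adaptive(
    p, tab, state, stim_times, total_ms, stim_dur, stim_amp, dt_min, dt_max, err_tol
):
    """Adaptive-step variant of :func:`paced_beats`.

    Step size is ``clip(err_tol / |du/dt|, dt_min, dt_max)`` so the stiff
    upstroke is resolved at ``dt_min`` while plateau and diastole take
    large steps; steps are clipped to stimulus on/off boundaries so the
    rectangular pulse is integrated exactly.  Used inside the genetic
    algorithm where tens of thousands of restitution protocols are run;
    per-beat APD90 agrees with the fixed-step kernel to a few tenths of a
    millisecond (validated in the test suite).
    """
    n_stim = stim_times.shape[0]
    t_act = np.full(n_stim, np.nan)
    t_end = np.full(n_stim, np.nan)
    apd = np.full(n_stim, np.nan)
    captured = np.zeros(n_stim)

    u = state[0]
    v = state[1]
    w = state[2]
    s = state[3]

    k = 0
    cur = -1
    rep = -1
    u_base = 0.0
    max_du = -1.0e30
    t_max_du = 0.0
    u_peak = -1.0e30
    past_peak = False
    thresh = 0.0

    t = 0.0
    while t < total_ms:
        if k < n_stim and t >= stim_times[k] - 1.0e-12:
            cur = k
            u_base = u
            max_du = -1.0e30
            u_peak = u
            past_peak = False
            k += 1
        in_stim = cur >= 0 and stim_times[cur] - 1.0e-12 <= t < stim_times[cur] + stim_dur - 1.0e-12
        istim = stim_amp if in_stim else 0.0
        du, dv, dw, ds = _derivs_tab(u, v, w, s, p, tab, istim)

        h = err_tol / (abs(du) + 1.0e-12)
        if h > dt_max:
            h = dt_max
        if h < dt_min:
            h = dt_min
        # clip to event boundaries: next stimulus onset, active stimulus end
        if k < n_stim:
            gap = stim_times[k] - t
            if 1.0e-9 < gap < h:
                h = gap
        if in_stim:
            gap = stim_times[cur] + stim_dur - t
            if 1.0e-9 < gap < h:
                h = gap
        if t + h > total_ms:
            h = total_ms - t

        u_new = u + h * du
        v += h * dv
        w += h * dw
        s += h * ds
        if abs(u_new) > U_BLOWUP:
            out = np.empty(4, dtype=np.float64)
            out[0] = u_new
            out[1] = v
            out[2] = w
            out[3] = s
            return t_act, t_end, apd, captured, out, False

        if cur >= 0 and not past_peak:
            if du > max_du:
                max_du = du
                t_max_du = t
            if u_new > u_peak:
                u_peak = u_new
            if captured[cur] == 0.0 and u_new > u_base + CAPTURE_AMP:
                captured[cur] = 1.0
            if captured[cur] == 1.0 and u_new < u - 1.0e-12:
                past_peak = True
                t_act[cur] = t_max_du
                thresh = u_base + 0.1 * (u_peak - u_base)
                rep = cur
        if rep >= 0 and u_new < u and u_new <= thresh < u:
            frac = (u - thresh) / (u - u_new)
            tc = t + frac * h
            t_end[rep] = tc
            apd[rep] = tc - t_act[rep]
            rep = -1

        u = u_new
        t += h

    out = np.empty(4, dtype=np.float64)
    out[0] = u
    out[1] = v
    out[2] = w
    out[3] = s
    return t_act, t_end, apd, captured, out, True


@njit(cache=True, fastmath=True)
def tissue_run(
    p,
    tab,
    u,
    v,
    w,
    s,
    D,
    dx,
    dt,
    n_steps,
    mask1,
    on1,
    dur1,
    mask2,
    on2,
    dur2,
    amp,
    u_thresh,
    deadtime,
    quiesc_u,
    check_every,
    idle_stop_ms,
):
    """Isotropic monodomain slab: forward Euler + 5-point Laplacian.

    No-flux boundaries via mirrored edge neighbors.  Two rectangular
    stimulus events (masks with onset/duration; a negative onset disables
    the event).  Per-node upward crossings of ``u_thresh`` are logged as
    activations with a refractory ``deadtime``.  Activation times use a
    sentinel of -1 for "never" (avoids NaN flow under fastmath).

    Early stopping, once both stimuli are over and checked every
    ``check_every`` steps: (a) the whole slab is below ``quiesc_u``, or
    (b) no node has activated for ``idle_stop_ms`` (0 disables) — a slab
    with no activation for several hundred ms cannot be re-entrant.

    Returns (t_last_act, first_act, last_act, n_act, ok, t_stop); state
    arrays are updated in place.
    """
    ny, nx = u.shape
    first_act = np.full((ny, nx), -1.0)
    last_act = np.full((ny, nx), -1.0)
    n_act = np.zeros((ny, nx), dtype=np.int64)
    armed = np.ones((ny, nx), dtype=np.uint8)
    t_arm = np.zeros((ny, nx))
    t_last_global = -1.0

    r = D * dt / (dx * dx)
    un = np.empty_like(u)

    for step in range(n_steps):
        t = step * dt
        s1 = 1.0 if (on1 >= 0.0 and on1 <= t < on1 + dur1) else 0.0
        s2 = 1.0 if (on2 >= 0.0 and on2 <= t < on2 + dur2) else 0.0
        for i in range(ny):
            # flux-form no-flux boundary: a missing neighbor contributes no
            # flux (ghost node = center), so the Laplacian sums to zero
            im = i - 1 if i > 0 else i
            ip = i + 1 if i < ny - 1 else i
            for j in range(nx):
                jm = j - 1 if j > 0 else j
                jp = j + 1 if j < nx - 1 else j
                uc = u[i, j]
                istim = 0.0
                if s1 == 1.0 and mask1[i, j]:
                    istim += amp
                if s2 == 1.0 and mask2[i, j]:
                    istim += amp
                du, dv, dw, ds = _derivs_tab(uc, v[i, j], w[i, j], s[i, j], p, tab, istim)
                lap = u[im, j] + u[ip, j] + u[i, jm] + u[i, jp] - 4.0 * uc
                unew = uc + dt * du + r * lap
                v[i, j] += dt * dv
                w[i, j] += dt * dw
                s[i, j] += dt * ds
                if abs(unew) > U_BLOWUP:
                    return t_last_global, first_act, last_act, n_act, False, t
                un[i, j] = unew
                if armed[i, j] == 1:
                    if uc < u_thresh <= unew:
                        if first_act[i, j] < 0.0:
                            first_act[i, j] = t
                        last_act[i, j] = t
                        n_act[i, j] += 1
                        t_last_global = t
                        armed[i, j] = 0
                        t_arm[i, j] = t + deadtime
                elif unew < u_thresh and t >= t_arm[i, j]:
                    armed[i, j] = 1
        for i in range(ny):
            for j in range(nx):
                u[i, j] = un[i, j]
        if check_every > 0 and step % check_every == 0:
            done1 = (on1 < 0.0) or (t > on1 + dur1)
            done2 = (on2 < 0.0) or (t > on2 + dur2)
            if done1 and done2:
                if idle_stop_ms > 0.0 and t_last_global >= 0.0 and t - t_last_global > idle_stop_ms:
                    return t_last_global, first_act, last_act, n_act, True, t
                umax = u[0, 0]
                for i in range(ny):
                    for j in range(nx):
                        if u[i, j] > umax:
                            umax = u[i, j]
                if umax < quiesc_u:
                    return t_last_global, first_act, last_act, n_act, True, t
    return t_last_global, first_act, last_act, n_act, True, n_steps * dt
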