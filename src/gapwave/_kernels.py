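"""Compiled numerical core.

All hot loops live here as numba kernels operating on packed arrays:

* parameter rows ``p`` of length :data:`NPAR` (see layout below),
* state rows ``y`` of length :data:`NSTATE`
  (``V, m, h, n, p, dI_ex, I_ex, dI_in, I_in``),
* per-neuron gap-input reductions ``gbar`` (summed conductance, nS) and
  ``gt`` (conductance-weighted interpolation coefficients, nS*mV), laid out
  as ``(order + 1)`` values per computation step of the current interval.

The Python modules wrap these kernels; they never reimplement the maths, so
the wrapped and the vectorized paths are bitwise identical.
"""

import numpy as np
from numba import njit

# parameter packing order
P_CM, P_GNA, P_GKV1, P_GKV3, P_GL, P_ENA, P_EK, P_EL = 0, 1, 2, 3, 4, 5, 6, 7
P_TAUEX, P_TAUIN, P_THETA, P_TAUR, P_ICONST = 8, 9, 10, 11, 12
NPAR = 13
NSTATE = 9


@njit(cache=True)
def _xdexp(x, k):
    # x / (1 - exp(-x/k)); removable singularity at x = 0 with limit k
    if abs(x) < 1e-7 * k:
        return k + 0.5 * x
    return x / (1.0 - np.exp(-x / k))


@njit(cache=True)
def channel_rates(V):
    """Voltage-dependent opening/closing rates (1/ms) of the four gates."""
    alpha_m = 40.0 * _xdexp(V - 75.5, 13.5)
    beta_m = 1.2262 * np.exp(-V / 42.248)
    alpha_h = 0.0035 * np.exp(-V / 24.186)
    beta_h = 0.017 * _xdexp(-(51.25 + V), 5.2)
    alpha_n = 0.014 * _xdexp(V + 44.0, 2.3)
    beta_n = 0.0043 * np.exp(-(V + 44.0) / 34.0)
    alpha_p = _xdexp(V - 95.0, 11.8)
    beta_p = 0.025 * np.exp(-V / 22.222)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, alpha_p, beta_p


@njit(cache=True)
def rhs(y, p, gbar, gts, order, x, dy):
    """Right-hand side of the 9-ODE neuron system.

    The gap current is evaluated from the receiver's own instantaneous V and
    the reduced coupling polynomial: I_gap = -gbar*V + sum_m gts[m] * x**m,
    with x the fraction of the current computation step.
    """
    V = y[0]
    m = y[1]
    hg = y[2]
    n = y[3]
    pg = y[4]
    am, bm, ah, bh, an, bn, ap, bp = channel_rates(V)
    I_Na = p[P_GNA] * m * m * m * hg * (V - p[P_ENA])
    I_K = (p[P_GKV3] * pg * pg + p[P_GKV1] * n * n * n * n) * (V - p[P_EK])
    I_L = p[P_GL] * (V - p[P_EL])
    I_gap = -gbar * V
    xp = 1.0
    for mm in range(order + 1):
        I_gap += gts[mm] * xp
        xp *= x
    dy[0] = (-(I_Na + I_K + I_L) + y[6] + y[8] + p[P_ICONST] + I_gap) / p[P_CM]
    dy[1] = am * (1.0 - m) - bm * m
    dy[2] = ah * (1.0 - hg) - bh * hg
    dy[3] = an * (1.0 - n) - bn * n
    dy[4] = ap * (1.0 - pg) - bp * pg
    dy[5] = -y[5] / p[P_TAUEX]
    dy[6] = y[5] - y[6] / p[P_TAUEX]
    dy[7] = -y[7] / p[P_TAUIN]
    dy[8] = y[7] - y[8] / p[P_TAUIN]


@njit(cache=True)
def vdot(y, p, gbar, gts, order, x):
    """dV/dt alone (no gate kinetics); used for waveform derivatives."""
    V = y[0]
    m = y[1]
    hg = y[2]
    n = y[3]
    pg = y[4]
    I_Na = p[P_GNA] * m * m * m * hg * (V - p[P_ENA])
    I_K = (p[P_GKV3] * pg * pg + p[P_GKV1] * n * n * n * n) * (V - p[P_EK])
    I_L = p[P_GL] * (V - p[P_EL])
    I_gap = -gbar * V
    xp = 1.0
    for mm in range(order + 1):
        I_gap += gts[mm] * xp
        xp *= x
    return (-(I_Na + I_K + I_L) + y[6] + y[8] + p[P_ICONST] + I_gap) / p[P_CM]


@njit(cache=True)
def rkf45_propagate(y, p, gbar, gts, order, h, abs_tol, min_substep, dt_init):
    """Advance one neuron by one computation step h (in place).

    Embedded Runge-Kutta-Fehlberg 4(5) with adaptive internal sub-stepping:
    absolute error control (max component norm), safety factor 0.9, step
    change clipped to [0.2, 5]. The first sub-step is ``dt_init`` (clipped
    to h); the controller's final sub-step proposal is returned so the
    caller can seed the next step, avoiding a rejected trial at every grid
    step during fast dynamics. Returns (status, dt_next); status 1 on
    sub-step underflow.
    """
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    k5 = np.empty(NSTATE)
    k6 = np.empty(NSTATE)
    yt = np.empty(NSTATE)
    y5 = np.empty(NSTATE)
    t = 0.0
    dt = dt_init
    if dt > h or not dt > 0.0:
        dt = h
    dt_next = dt
    while t < h * (1.0 - 1e-14):
        if dt > h - t:
            dt = h - t
        rhs(y, p, gbar, gts, order, t / h, k1)
        for i in range(NSTATE):
            yt[i] = y[i] + dt * 0.25 * k1[i]
        rhs(yt, p, gbar, gts, order, (t + 0.25 * dt) / h, k2)
        for i in range(NSTATE):
            yt[i] = y[i] + dt * (3.0 / 32.0 * k1[i] + 9.0 / 32.0 * k2[i])
        rhs(yt, p, gbar, gts, order, (t + 0.375 * dt) / h, k3)
        for i in range(NSTATE):
            yt[i] = y[i] + dt * (
                1932.0 / 2197.0 * k1[i]
                - 7200.0 / 2197.0 * k2[i]
                + 7296.0 / 2197.0 * k3[i]
            )
        rhs(yt, p, gbar, gts, order, (t + 12.0 / 13.0 * dt) / h, k4)
        for i in range(NSTATE):
            yt[i] = y[i] + dt * (
                439.0 / 216.0 * k1[i]
                - 8.0 * k2[i]
                + 3680.0 / 513.0 * k3[i]
                - 845.0 / 4104.0 * k4[i]
            )
        rhs(yt, p, gbar, gts, order, (t + dt) / h, k5)
        for i in range(NSTATE):
            yt[i] = y[i] + dt * (
                -8.0 / 27.0 * k1[i]
                + 2.0 * k2[i]
                - 3544.0 / 2565.0 * k3[i]
                + 1859.0 / 4104.0 * k4[i]
                - 11.0 / 40.0 * k5[i]
            )
        rhs(yt, p, gbar, gts, order, (t + 0.5 * dt) / h, k6)
        err = 0.0
        for i in range(NSTATE):
            y5[i] = y[i] + dt * (
                16.0 / 135.0 * k1[i]
                + 6656.0 / 12825.0 * k3[i]
                + 28561.0 / 56430.0 * k4[i]
                - 9.0 / 50.0 * k5[i]
                + 2.0 / 55.0 * k6[i]
            )
            y4 = y[i] + dt * (
                25.0 / 216.0 * k1[i]
                + 1408.0 / 2565.0 * k3[i]
                + 2197.0 / 4104.0 * k4[i]
                - 0.2 * k5[i]
            )
            e = abs(y5[i] - y4)
            if not np.isfinite(e):
                # a trial stage left the stability region; force rejection
                e = 1.0e300
            if e > err:
                err = e
        if err <= abs_tol:
            for i in range(NSTATE):
                y[i] = y5[i]
            t += dt
        if err == 0.0:
            fac = 5.0
        else:
            fac = 0.9 * (abs_tol / err) ** 0.2
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
        dt *= fac
        dt_next = dt
        if dt < min_substep and t < h * (1.0 - 1e-14):
            return 1, dt_next
    return 0, dt_next


@njit(cache=True)
def update_interval(
    prelim,
    y,
    params,
    prelim_mask,
    r,
    order,
    h,
    abs_tol,
    min_substep,
    k0,
    L,
    gbar,
    gt,
    kick_ex,
    kick_in,
    V_last,
    prelim_tol,
    v_last_reset_to_current,
    coeffs,
    refr,
    crossed,
    vprev,
    refr_steps,
    spike_flags,
    vtrace,
    done_out,
    dt_carry,
):
    """One (preliminary or final) update of all neurons over one interval.

    Implements the per-neuron update semantics of the scheduler: propagate
    the state over the r computation steps of the interval, add buffered
    synaptic kicks at the right grid point of every step, and either

    * preliminary: collect interpolation coefficients of the membrane
      potential per step and test the stopping criterion against V_last
      (violation when |V_last - V| >= prelim_tol); the neuron state ``y``
      is left untouched, or
    * final: write the state back, record the voltage trace, detect spikes
      (first grid point after the post-threshold maximum, suppressed while
      refractory) and broadcast the constant extrapolation for the next
      interval; V_last is reset.

    Returns 0 on success, 1 if any neuron's solver underflowed.
    """
    N = y.shape[0]
    nc = order + 1
    status = 0
    yl = np.empty(NSTATE)
    for nn in range(N):
        if prelim and not prelim_mask[nn]:
            done_out[nn] = True
            continue
        for q in range(NSTATE):
            yl[q] = y[nn, q]
        pl = params[nn]
        gb = gbar[nn]
        done_n = True
        dtl = dt_carry[nn]
        for s in range(1, r + 1):
            base = (s - 1) * nc
            gts = gt[nn, base : base + nc]
            V0 = yl[0]
            d0 = 0.0
            d1 = 0.0
            if prelim and order == 3:
                d0 = vdot(yl, pl, gb, gts, order, 0.0)
            st, dtl = rkf45_propagate(
                yl, pl, gb, gts, order, h, abs_tol, min_substep, dtl
            )
            if st != 0:
                status = 1
            V1 = yl[0]
            if prelim and order == 3:
                d1 = vdot(yl, pl, gb, gts, order, 1.0)
            idx = (k0 + s) % L
            yl[5] += kick_ex[nn, idx]
            yl[7] += kick_in[nn, idx]
            if prelim:
                coeffs[nn, base] = V0
                if order == 1:
                    coeffs[nn, base + 1] = V1 - V0
                elif order == 3:
                    coeffs[nn, base + 1] = h * d0
                    coeffs[nn, base + 2] = -3.0 * V0 + 3.0 * V1 - h * (2.0 * d0 + d1)
                    coeffs[nn, base + 3] = 2.0 * V0 - 2.0 * V1 + h * (d0 + d1)
                if abs(V_last[nn, s - 1] - V1) >= prelim_tol:
                    done_n = False
                V_last[nn, s - 1] = V1
            else:
                vtrace[nn, s - 1] = V1
                if refr[nn] > 0:
                    refr[nn] -= 1
                else:
                    if (not crossed[nn]) and V1 > pl[P_THETA]:
                        crossed[nn] = True
                    if crossed[nn] and V1 < vprev[nn]:
                        spike_flags[nn, s - 1] = 1
                        crossed[nn] = False
                        refr[nn] = refr_steps[nn]
                vprev[nn] = V1
        dt_carry[nn] = dtl
        if prelim:
            done_out[nn] = done_n
        else:
            for q in range(NSTATE):
                y[nn, q] = yl[q]
            for s in range(1, r + 1):
                base = (s - 1) * nc
                coeffs[nn, base] = yl[0]  # constant extrapolation
                for j in range(1, nc):
                    coeffs[nn, base + j] = 0.0
                if v_last_reset_to_current:
                    V_last[nn, s - 1] = vtrace[nn, s - 1]
                else:
                    V_last[nn, s - 1] = 0.0
            done_out[nn] = True
    return status


@njit(cache=True)
def csr_exchange(indptr, indices, data, coeffs, gt):
    """gt[i] = sum_j g_ij * coeffs[j]  (Jacobi waveform accumulation)."""
    N, nc = gt.shape
    for i in range(N):
        for c in range(nc):
            gt[i, c] = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            gv = data[ptr]
            for c in range(nc):
                gt[i, c] += gv * coeffs[j, c]


@njit(cache=True)
def run_chunk(
    y,
    params,
    prelim_mask,
    has_gaps,
    single_step,
    rp,
    order,
    h,
    abs_tol,
    min_substep,
    k0_start,
    n_intervals,
    L,
    gbar,
    gt,
    coeffs,
    V_last,
    prelim_tol,
    v_last_reset_to_current,
    adaptive,
    cap,
    kick_ex,
    kick_in,
    G_indptr,
    G_indices,
    G_data,
    refr,
    crossed,
    vprev,
    refr_steps,
    dt_carry,
    syn_indptr,
    syn_tgt,
    syn_dsteps,
    syn_amp,
    syn_exc,
    pois_tgt,
    pois_arrive,
    pois_amp,
    pois_exc,
    pois_ptr,
    vtrace_chunk,
    spike_n,
    spike_step,
    iterations_out,
):
    """Scheduler loop over ``n_intervals`` consecutive intervals.

    Per interval: insert pending external kicks, run the preliminary
    Jacobi iterations with waveform exchange until converged or capped,
    run the final update, deliver emitted spikes into the targets' ring
    buffers, and clear the consumed buffer slots. Fills ``vtrace_chunk``
    (all neurons, all grid points of the chunk) and the spike arrays.

    Returns (status, new_pois_ptr, n_spikes, cap_warnings); status 1
    signals solver sub-step underflow, 2 a spike-buffer overflow.
    """
    N = y.shape[0]
    nc = order + 1
    spike_flags = np.zeros((N, rp), dtype=np.int8)
    vtr = np.empty((N, rp))
    done = np.zeros(N, dtype=np.bool_)
    n_spikes = 0
    cap_warnings = 0
    n_pois = pois_arrive.shape[0]
    for interval in range(n_intervals):
        k0 = k0_start + interval * rp
        while pois_ptr < n_pois and pois_arrive[pois_ptr] <= k0 + rp:
            slot = pois_arrive[pois_ptr] % L
            tgt = pois_tgt[pois_ptr]
            if pois_exc[pois_ptr]:
                kick_ex[tgt, slot] += pois_amp[pois_ptr]
            else:
                kick_in[tgt, slot] += pois_amp[pois_ptr]
            pois_ptr += 1

        used = 0
        if has_gaps and not single_step:
            used = cap
            converged = not adaptive
            for i in range(1, cap + 1):
                st = update_interval(
                    True, y, params, prelim_mask, rp, order, h, abs_tol,
                    min_substep, k0, L, gbar, gt, kick_ex, kick_in,
                    V_last, prelim_tol, v_last_reset_to_current,
                    coeffs, refr, crossed, vprev, refr_steps,
                    spike_flags, vtr, done, dt_carry,
                )
                if st != 0:
                    return 1, pois_ptr, n_spikes, cap_warnings
                csr_exchange(G_indptr, G_indices, G_data, coeffs, gt)
                if adaptive and done.all():
                    used = i
                    converged = True
                    break
            if adaptive and not converged:
                cap_warnings += 1
        iterations_out[interval] = used

        for nn in range(N):
            for s in range(rp):
                spike_flags[nn, s] = 0
        st = update_interval(
            False, y, params, prelim_mask, rp, order, h, abs_tol,
            min_substep, k0, L, gbar, gt, kick_ex, kick_in,
            V_last, prelim_tol, v_last_reset_to_current,
            coeffs, refr, crossed, vprev, refr_steps,
            spike_flags, vtr, done, dt_carry,
        )
        if st != 0:
            return 1, pois_ptr, n_spikes, cap_warnings
        if has_gaps:
            csr_exchange(G_indptr, G_indices, G_data, coeffs, gt)

        col0 = interval * rp
        for nn in range(N):
            for s in range(rp):
                vtrace_chunk[nn, col0 + s] = vtr[nn, s]

        for nn in range(N):
            for s in range(rp):
                if spike_flags[nn, s]:
                    step = k0 + 1 + s
                    if n_spikes >= spike_n.shape[0]:
                        return 2, pois_ptr, n_spikes, cap_warnings
                    spike_n[n_spikes] = nn
                    spike_step[n_spikes] = step
                    n_spikes += 1
                    for ptr in range(syn_indptr[nn], syn_indptr[nn + 1]):
                        slot = (step + syn_dsteps[ptr]) % L
                        if syn_exc[ptr]:
                            kick_ex[syn_tgt[ptr], slot] += syn_amp[ptr]
                        else:
                            kick_in[syn_tgt[ptr], slot] += syn_amp[ptr]

        for s in range(1, rp + 1):
            slot = (k0 + s) % L
            for nn in range(N):
                kick_ex[nn, slot] = 0.0
                kick_in[nn, slot] = 0.0
    return 0, pois_ptr, n_spikes, cap_warnings
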