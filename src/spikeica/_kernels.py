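"""Numba inner loops for the simulation engine.

Scalar math here intentionally mirrors `neuron.gain`, `intrinsic.ip_update`
and the event rules in `plasticity`; consistency between the two code paths
is pinned by tests.  All times are in ms, rates in Hz.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e300  # "never spiked" sentinel usable inside njit


@njit(cache=True, inline="always")
def _softplus(z):
    if z > 30.0:
        return z
    if z < -30.0:
        return np.exp(z)
    return np.log1p(np.exp(z))


@njit(cache=True, inline="always")
def _sigmoid(z):
    if z > 30.0:
        return 1.0
    if z < -30.0:
        return np.exp(z)
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True, inline="always")
def _gain(u, r0, u0, ua):
    return r0 * _softplus((u - u0) / ua)


@njit(cache=True, inline="always")
def _refractory(delta, tau_abs, tau_refr):
    x = delta - tau_abs
    if x <= 0.0:
        return 0.0
    return x / (tau_refr + x)


@njit(cache=True, inline="always")
def _ip_step(gp, u, eta, mu_goal, r0_floor, ua_floor):
    """In-place IP gradient step on gp = [r0, u0, u_alpha]."""
    r0 = gp[0]
    ua = gp[2]
    z = (u - gp[1]) / ua
    s = _softplus(z)
    sig = _sigmoid(z)
    d_r0 = -1.0 / r0 + s / mu_goal
    d_u0 = (1.0 - sig) / ua - r0 * sig / (ua * mu_goal)
    d_ua = ((1.0 - sig) * z + 1.0) / ua - r0 * sig * z / (ua * mu_goal)
    r0n = r0 - eta * d_r0
    uan = ua - eta * d_ua
    gp[0] = r0n if r0n > r0_floor else r0_floor
    gp[1] = gp[1] - eta * d_u0
    gp[2] = uan if uan > ua_floor else ua_floor


@njit(cache=True)
def present_sample_kernel(
    rng,
    pre,            # (n_steps, n_syn) uint8 presynaptic spikes
    w,              # (n_neur, n_syn) excitatory weights, in place
    winh,           # (n_neur, n_neur) inhibitory weights (zero diag), in place
    psp,            # (n_syn,) shared excitatory PSP traces, in place
    inh_trace,      # (n_neur,) PSP traces of each neuron's output spikes
    gp,             # (n_neur, 3) gain parameters, in place
    t_post,         # (n_neur,) last spike times (NEG_INF if never)
    ltp,            # (n_neur, n_syn) nearest-mode LTP traces
    pre_trace,      # (n_syn,) all-to-all pre traces (shared)
    post_trace,     # (n_neur,) all-to-all post traces
    y_trace,        # (n_neur,) triplet slow post traces
    inh_ltp,        # (n_neur, n_neur) LTP traces for lateral synapses
    neuron_c,       # [u_rest, tau_m, tau_gaba, psp_amp, tau_abs, tau_refr, dt]
    stdp_c,         # [A_plus, A_minus, tau_plus, tau_minus, A3_plus, tau_y]
    inh_stdp_c,     # [A_plus, A_minus, tau_plus, tau_minus]
    mode,           # 0 nearest, 1 all_to_all, 2 triplet
    same_bin_causal,  # sub-bin pairing convention (see below)
    ip_mode,        # 0 fixed gain, 1 full IP, 2 mean-rate IP
    eta_ip,
    mu_goal,
    ip_floors,      # (n_neur, 2): r0 and u_alpha floors
    mr,             # [r_bar, eta_mr, r_goal, tau_r], in place
    plastic,        # 0/1: apply STDP
    t0,             # time at the start of the sample (ms)
    g_out,          # (n_rec, n_neur) instantaneous-rate log
    g_stride,       # record every g_stride steps (0: never)
    spike_counts,   # (n_neur,) incremented in place
):
    n_steps, n_syn = pre.shape
    n_neur = w.shape[0]
    u_rest, tau_m, tau_gaba, amp, tau_abs, tau_refr, dt = (
        neuron_c[0], neuron_c[1], neuron_c[2], neuron_c[3],
        neuron_c[4], neuron_c[5], neuron_c[6])
    ap, am, tp, tm, a3, ty = (stdp_c[0], stdp_c[1], stdp_c[2], stdp_c[3],
                              stdp_c[4], stdp_c[5])
    iap, iam, itp, itm = inh_stdp_c[0], inh_stdp_c[1], inh_stdp_c[2], inh_stdp_c[3]
    dm = np.exp(-dt / tau_m)
    dg = np.exp(-dt / tau_gaba)
    dltp = np.exp(-dt / tp)
    dpost = np.exp(-dt / tm)
    dy = np.exp(-dt / ty)
    diltp = np.exp(-dt / itp)
    diltd = np.exp(-dt / itm)
    spiked = np.zeros(n_neur, np.uint8)
    # incremental exp(-(t - t_post)/tau) factors (avoid transcendentals in
    # the inner loop): ltd_fac for nearest-mode depression, ltp_fac for the
    # snapshot representation of the consumable potentiation trace
    #   ltp[k, i](t) = pre_trace[i](t) - snap[k, i] * ltp_fac[k],
    # where snap is the value of pre_trace at neuron k's last spike (stored
    # in the `ltp` array) and ltp_fac = exp(-(t - t_post_k)/tau_plus).
    ltd_fac = np.zeros(n_neur)
    iltd_fac = np.zeros(n_neur)
    ltp_fac = np.zeros(n_neur)
    for k in range(n_neur):
        if t_post[k] > NEG_INF:
            ltd_fac[k] = np.exp(-(t0 - t_post[k]) / tm)
            iltd_fac[k] = np.exp(-(t0 - t_post[k]) / itm)
            ltp_fac[k] = np.exp(-(t0 - t_post[k]) / tp)
    rec = 0
    for s in range(n_steps):
        t = t0 + (s + 1) * dt
        # 1. decay traces, apply presynaptic spikes to the membrane
        for i in range(n_syn):
            psp[i] *= dm
            if pre[s, i]:
                psp[i] += amp
        for k in range(n_neur):
            inh_trace[k] *= dg
        # 2-4. membrane potential, gain, IP, postsynaptic draw.  The
        # softplus and sigmoid of z share a single exponential; the IP
        # gradient step is inlined for the same reason.
        draws = rng.random(n_neur)
        for k in range(n_neur):
            u = u_rest
            for i in range(n_syn):
                u += w[k, i] * psp[i]
            if n_neur > 1:
                for j in range(n_neur):
                    u -= winh[k, j] * inh_trace[j]
            r0 = gp[k, 0]
            ua = gp[k, 2]
            z = (u - gp[k, 1]) / ua
            if z > 30.0:
                sp_z = z
                sig = 1.0
            elif z < -30.0:
                ez = np.exp(z)
                sp_z = ez
                sig = ez
            else:
                ez = np.exp(z)
                sp_z = np.log1p(ez)
                sig = ez / (1.0 + ez)
            g = r0 * sp_z
            if g_stride > 0 and s % g_stride == g_stride - 1 and rec < g_out.shape[0]:
                g_out[rec, k] = g
            if ip_mode == 1 and eta_ip > 0.0:
                d_r0 = -1.0 / r0 + sp_z / mu_goal
                d_u0 = (1.0 - sig) / ua - r0 * sig / (ua * mu_goal)
                d_ua = ((1.0 - sig) * z + 1.0) / ua - r0 * sig * z / (ua * mu_goal)
                r0n = r0 - eta_ip * d_r0
                uan = ua - eta_ip * d_ua
                gp[k, 0] = r0n if r0n > ip_floors[k, 0] else ip_floors[k, 0]
                gp[k, 1] = gp[k, 1] - eta_ip * d_u0
                gp[k, 2] = uan if uan > ip_floors[k, 1] else ip_floors[k, 1]
            delta = t - t_post[k]
            r = 1.0 if t_post[k] <= NEG_INF else _refractory(delta, tau_abs, tau_refr)
            p_fire = -np.expm1(-r * g * dt / 1000.0)
            sp = 1 if draws[k] < p_fire else 0
            spiked[k] = sp
            if ip_mode == 2:
                mr[0] += (dt / mr[3]) * (sp * 1000.0 / dt - mr[0])
                gp[k, 1] += mr[1] * (mr[0] - mr[2])
        if g_stride > 0 and s % g_stride == g_stride - 1 and rec < g_out.shape[0]:
            rec += 1
        if plastic:
            # decay STDP traces (the per-neuron LTP rows decay implicitly
            # through pre_trace and ltp_fac)
            for k in range(n_neur):
                post_trace[k] *= dpost
                y_trace[k] *= dy
                ltd_fac[k] *= dpost
                iltd_fac[k] *= diltd
                ltp_fac[k] *= dltp
                if n_neur > 1:
                    for j in range(n_neur):
                        inh_ltp[k, j] *= diltp
            for i in range(n_syn):
                pre_trace[i] *= dltp
            # depression: each presynaptic spike pairs with the most recent
            # post (ltd_fac carries exp(-(t - t_post)/tau_minus), which is
            # zero while no post has occurred; same-bin posts commit later,
            # so the pairing always uses the previous postsynaptic spike)
            for i in range(n_syn):
                if pre[s, i]:
                    for k in range(n_neur):
                        dwn = w[k, i] - am * (post_trace[k] if mode == 1
                                              else ltd_fac[k])
                        w[k, i] = dwn if dwn > 0.0 else 0.0
            # potentiation: postsynaptic spike consumes the LTP trace.
            # same_bin_causal selects the sub-bin convention: 0 treats
            # same-bin pre/post pairs as simultaneous (contributing nothing),
            # 1 treats presynaptic spikes as acting at the bin start and the
            # postsynaptic draw at the bin end, so the volley that fires the
            # neuron is potentiated at lag dt (needed for correlation coding).
            for k in range(n_neur):
                if spiked[k]:
                    sb = dltp if same_bin_causal else 0.0
                    if mode == 1:
                        for i in range(n_syn):
                            w[k, i] += ap * (pre_trace[i]
                                             + (sb if pre[s, i] else 0.0))
                    else:
                        a_eff = ap + (a3 * y_trace[k] if mode == 2 else 0.0)
                        fk = ltp_fac[k]
                        for i in range(n_syn):
                            v = pre_trace[i] - ltp[k, i] * fk
                            if v < 0.0:
                                v = 0.0
                            w[k, i] += a_eff * (v + (sb if pre[s, i] else 0.0))
            # lateral inhibitory STDP (nearest): pre = other neuron's spike
            if n_neur > 1:
                for j in range(n_neur):
                    if spiked[j]:
                        for k in range(n_neur):
                            if k != j:
                                dwn = winh[k, j] - iam * iltd_fac[k]
                                winh[k, j] = dwn if dwn > 0.0 else 0.0
                for k in range(n_neur):
                    if spiked[k]:
                        for j in range(n_neur):
                            if j != k:
                                winh[k, j] += iap * inh_ltp[k, j]
                            inh_ltp[k, j] = 0.0
            # register this step's presynaptic spikes
            for i in range(n_syn):
                if pre[s, i]:
                    pre_trace[i] += 1.0
            if n_neur > 1:
                for j in range(n_neur):
                    if spiked[j]:
                        for k in range(n_neur):
                            if k != j:
                                inh_ltp[k, j] += 1.0
        # 5. commit postsynaptic spikes; reset the consumed LTP row by
        # snapshotting pre_trace (under the simultaneity convention this
        # step's unconsumed presynaptic spikes stay in the row)
        for k in range(n_neur):
            if spiked[k]:
                t_post[k] = t
                post_trace[k] += 1.0
                y_trace[k] += 1.0
                ltd_fac[k] = 1.0
                iltd_fac[k] = 1.0
                ltp_fac[k] = 1.0
                for i in range(n_syn):
                    keep = 0.0 if same_bin_causal else (
                        1.0 if pre[s, i] else 0.0)
                    ltp[k, i] = pre_trace[i] - keep
                inh_trace[k] += amp
                spike_counts[k] += 1
    return rec


@njit(cache=True)
def ip_gaussian_kernel(rng, n_steps, u_mean, u_std, gp, eta, mu_goal,
                       r0_floor, ua_floor, g_out, g_stride):
    """Closed-loop IP on a stationary Gaussian membrane-potential drive."""
    rec = 0
    for s in range(n_steps):
        u = u_mean + u_std * rng.standard_normal()
        g = _gain(u, gp[0], gp[1], gp[2])
        _ip_step(gp, u, eta, mu_goal, r0_floor, ua_floor)
        if g_stride > 0 and s % g_stride == g_stride - 1 and rec < g_out.shape[0]:
            g_out[rec] = g
            rec += 1
    return rec


@njit(cache=True)
def stdp_drift_kernel(rng, rho_pre, rho_post, duration_s, ap, am, tp, tm):
    """Monte-Carlo expected drift: independent continuous-time Poisson
    pre/post trains under nearest-neighbor STDP (no clipping), returning the
    summed weight change over duration_s seconds.  Event-driven with exact
    exponential inter-arrival times, so the only error is Monte-Carlo."""
    t_end = duration_s * 1000.0  # ms
    t_pre = rng.exponential(1000.0 / rho_pre) if rho_pre > 0 else t_end + 1.0
    t_post_next = rng.exponential(1000.0 / rho_post) if rho_post > 0 else t_end + 1.0
    t_post = NEG_INF
    ltp = 0.0      # potentiation trace value ...
    t_ltp = 0.0    # ... last updated at this time
    dw = 0.0
    while True:
        if t_pre < t_post_next:
            t = t_pre
            if t > t_end:
                break
            if t_post > NEG_INF:
                dw -= am * np.exp(-(t - t_post) / tm)
            ltp = ltp * np.exp(-(t - t_ltp) / tp) + 1.0
            t_ltp = t
            t_pre = t + rng.exponential(1000.0 / rho_pre)
        else:
            t = t_post_next
            if t > t_end:
                break
            dw += ap * ltp * np.exp(-(t - t_ltp) / tp)
            ltp = 0.0
            t_ltp = t
            t_post = t
            t_post_next = t + rng.exponential(1000.0 / rho_post)
    return dw


@njit(cache=True, inline="always")
def _laplace(rng, scale):
    v = rng.random() - 0.5
    a = abs(v)
    if a >= 0.5:
        a = 0.5 - 1e-16
    x = -scale * np.log(1.0 - 2.0 * a)
    return -x if v < 0.0 else x


@njit(cache=True)
def rate_demix_kernel(rng, n_steps, theta, source_kinds, eta_hebb, eta_ip,
                      gp, w, k_scale, u_rest, mu_goal, r0_floor, ua_floor,
                      norm_order, log_every, w_log, gp_log, nu_log):
    """Rate-based demixing: Laplacian (or Gaussian) sources, rotation mix,
    shared gain function, per-step IP and Hebbian learning with L1 or L2
    weight normalization.

    source_kinds: per-source 0 = unit-variance Laplace, 1 = unit Gaussian.
    norm_order: 0 = L1 with nonnegative weights, 1 = L2 (signed weights).
    """
    ct = np.cos(theta)
    st = np.sin(theta)
    b = 1.0 / np.sqrt(2.0)
    rec = 0
    for s in range(n_steps):
        s0 = _laplace(rng, b) if source_kinds[0] == 0 else rng.standard_normal()
        s1 = _laplace(rng, b) if source_kinds[1] == 0 else rng.standard_normal()
        x0 = ct * s0 - st * s1
        x1 = st * s0 + ct * s1
        drive = w[0] * x0 + w[1] * x1
        u = u_rest + k_scale * drive
        nu = _gain(u, gp[0], gp[1], gp[2])
        if eta_ip > 0.0:
            _ip_step(gp, u, eta_ip, mu_goal, r0_floor, ua_floor)
        w[0] += eta_hebb * nu * x0
        w[1] += eta_hebb * nu * x1
        if norm_order == 0:
            if w[0] < 0.0:
                w[0] = 0.0
            if w[1] < 0.0:
                w[1] = 0.0
            nrm = w[0] + w[1]
        else:
            nrm = np.sqrt(w[0] * w[0] + w[1] * w[1])
        if nrm == 0.0:
            return -1  # dead weight vector
        w[0] /= nrm
        w[1] /= nrm
        if log_every > 0 and s % log_every == log_every - 1 and rec < nu_log.shape[0]:
            w_log[rec, 0] = w[0]
            w_log[rec, 1] = w[1]
            gp_log[rec, 0] = gp[0]
            gp_log[rec, 1] = gp[1]
            gp_log[rec, 2] = gp[2]
            nu_log[rec] = nu
            rec += 1
    return rec
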