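"""Intrinsic plasticity (IP): homeostatic adaptation of the gain function.

The full rule performs stochastic gradient descent, in the three gain
parameters (r0, u0, u_alpha), on the Kullback-Leibler divergence between the
distribution of the neuron's instantaneous firing rate g(u) and an
exponential distribution with mean mu_goal.  The exponential target is the
maximum-entropy distribution for a fixed mean rate (a fixed energy budget),
so the rule maximizes information transmission per spike.

Per sample of the membrane potential u, the divergence is estimated (up to a
parameter-independent constant) by

    F(u; r0, u0, u_alpha) = -ln g'(u) + g(u) / mu_goal,

where g' = dg/du: the first term is the negative log-density of g(u) under a
change of variables (entropy ascent), the second penalizes mean rate above
the budget.  One IP step moves each parameter by -eta_ip * dF/dparam.

A simplified control rule (`ip_mean_rate_update`) adjusts only the threshold
u0 to hold a low-pass estimate of the mean firing rate at a set point; it
constrains the mean but not the shape of the output distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .neuron import GainParams

__all__ = [
    "IPConfig",
    "MeanRateIPConfig",
    "ip_sample_objective",
    "ip_gradients",
    "ip_update",
    "lowpass_rate",
    "ip_mean_rate_update",
    "calibrate_eta_mr",
]


@dataclass
class IPConfig:
    """Full (distribution-matching) IP rule settings."""

    eta_ip: float = 1e-4     # learning rate per update
    mu_goal: float = 5.0     # target mean rate (Hz)
    update_every: int = 1    # steps between IP updates
    # floors keeping r0, u_alpha positive, as fractions of their initial values
    floor_frac: float = 1e-6

    def __post_init__(self) -> None:
        if self.eta_ip < 0:
            raise ValueError("eta_ip must be >= 0")
        if self.update_every < 1:
            raise ValueError("update_every must be >= 1")
        if self.mu_goal <= 0:
            raise ValueError("mu_goal must be positive")


@dataclass
class MeanRateIPConfig:
    """Simplified mean-rate-only rule (threshold regulation)."""

    eta_mr: float = 2e-4     # mV per Hz of rate error, per update
    r_goal: float = 5.0      # target mean rate (Hz)
    tau_r: float = 1000.0    # low-pass time constant of the rate estimate (ms)
    r_bar: float = 0.0       # current rate estimate (Hz)

    def __post_init__(self) -> None:
        for name in ("eta_mr", "r_goal", "tau_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ip_sample_objective(u: float, p: GainParams, mu_goal: float) -> float:
    """Per-sample stochastic objective F(u) = -ln g'(u) + g(u)/mu_goal.

    Its expectation over the stationary distribution of u equals
    KL(p_g || Exp(mu_goal)) up to a parameter-independent constant
    (the entropy of u plus ln mu_goal).
    """
    z = (u - p.u0) / p.u_alpha
    s = np.logaddexp(0.0, z)
    g = p.r0 * s
    # ln g' = ln r0 + ln sigmoid(z) - ln u_alpha ; ln sigmoid(z) = -softplus(-z)
    log_gprime = np.log(p.r0) - np.logaddexp(0.0, -z) - np.log(p.u_alpha)
    if not np.isfinite(log_gprime) or log_gprime < -745.0:
        # g'(u) is numerically zero in double precision
        raise FloatingPointError("gain derivative underflowed to zero at this u")
    return float(-log_gprime + g / mu_goal)


def ip_gradients(u: float, p: GainParams, mu_goal: float) -> np.ndarray:
    """Analytic gradient of the per-sample objective in (r0, u0, u_alpha)."""
    a = p.u_alpha
    z = (u - p.u0) / a
    s = np.logaddexp(0.0, z)
    sig = expit(z)
    dF_dr0 = -1.0 / p.r0 + s / mu_goal
    dF_du0 = (1.0 - sig) / a - p.r0 * sig / (a * mu_goal)
    dF_dualpha = ((1.0 - sig) * z + 1.0) / a - p.r0 * sig * z / (a * mu_goal)
    return np.array([dF_dr0, dF_du0, dF_dualpha])


def ip_update(p: GainParams, u: float, cfg: IPConfig,
              floors: tuple[float, float] | None = None) -> GainParams:
    """One stochastic-gradient-descent step of the IP objective.

    Updates that would drive r0 or u_alpha non-positive are clamped at a
    small positive floor (floor_frac of the pre-update value unless explicit
    floors are given).
    """
    if cfg.eta_ip == 0.0:
        return p.copy()
    grad = ip_gradients(u, p, cfg.mu_goal)
    r0 = p.r0 - cfg.eta_ip * grad[0]
    u0 = p.u0 - cfg.eta_ip * grad[1]
    ua = p.u_alpha - cfg.eta_ip * grad[2]
    f_r0, f_ua = floors if floors is not None else (
        cfg.floor_frac * p.r0, cfg.floor_frac * p.u_alpha)
    if r0 <= f_r0:
        r0 = f_r0
    if ua <= f_ua:
        ua = f_ua
    return GainParams(r0=r0, u0=u0, u_alpha=ua)


def lowpass_rate(mr: MeanRateIPConfig, spike: int, dt: float) -> float:
    """Exponential low-pass of the spike train as a rate estimate (Hz).

    r_bar <- r_bar + (dt/tau_r) * (spike * 1000/dt - r_bar); unbiased for a
    constant-rate Poisson train in steady state.  Returns the new r_bar and
    stores it on `mr`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    inst = spike * 1000.0 / dt
    mr.r_bar = mr.r_bar + (dt / mr.tau_r) * (inst - mr.r_bar)
    return mr.r_bar


def ip_mean_rate_update(p: GainParams, mr: MeanRateIPConfig) -> GainParams:
    """Mean-rate-only control: u0 <- u0 + eta_mr * (r_bar - r_goal).

    Firing above target raises the threshold (lowers excitability); firing
    below lowers it.  r0 and u_alpha are frozen.
    """
    return GainParams(r0=p.r0, u0=p.u0 + mr.eta_mr * (mr.r_bar - mr.r_goal),
                      u_alpha=p.u_alpha)


def _settling_time(traj: np.ndarray, frac: float = 0.1) -> int:
    """First index after which the trajectory stays within frac of its final value."""
    final = traj[-1]
    tol = frac * max(abs(final), 1e-12)
    outside = np.abs(traj - final) > tol
    if not outside.any():
        return 0
    return int(np.max(np.nonzero(outside)) + 1)


def calibrate_eta_mr(
    p0: GainParams,
    ip_cfg: IPConfig,
    u_mean: float = -60.0,
    u_std: float = 3.0,
    n_steps: int = 200_000,
    seed: int = 0,
) -> float:
    """Pick eta_mr so the mean-rate rule settles about as fast as full IP.

    Runs the full IP rule on a fixed Gaussian drive, measures the settling
    time of the mean rate, then scales eta_mr so the linearized time constant
    of the threshold-only loop matches it.  Returns the calibrated eta_mr.
    """
    rng = np.random.default_rng(seed)
    p = p0.copy()
    us = u_mean + u_std * rng.standard_normal(n_steps)
    from .neuron import gain

    means = np.empty(n_steps // 1000)
    acc = 0.0
    for i, u in enumerate(us):
        p = ip_update(p, float(u), ip_cfg)
        acc += gain(float(u), p)
        if (i + 1) % 1000 == 0:
            means[i // 1000] = acc / 1000.0
            acc = 0.0
    t_ip = max(_settling_time(means) * 1000, 1000)  # steps
    # threshold-only loop: d u0/dstep ~ eta_mr * (r - r_goal); rate sensitivity
    # dr/du0 ~ -r0*sigma/u_alpha ~ -r0/(2*u_alpha) near threshold -> time constant
    # 1/(eta_mr * r0/(2 u_alpha)) steps; match it to t_ip.
    eta_mr = 2.0 * p0.u_alpha / (p0.r0 * t_ip)
    return float(eta_mr)
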