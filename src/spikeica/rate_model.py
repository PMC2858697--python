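"""Rate-based reference neuron for the two-source demixing problem.

The neuron shares the spiking model's gain function: a 2-D input sample x
(a rotated pair of unit-variance sources) drives the rate
nu = g(u_rest + k * w.x), intrinsic plasticity adapts the gain parameters
every step, and the weights follow classic Hebbian learning
w <- w + eta_hebb * nu * x with either L1 (nonnegative weights) or L2
(signed weights) renormalization.  With a heavy-tailed source pair the
weight vector rotates onto an independent component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .neuron import GainParams, gain

__all__ = ["RateModelConfig", "RateTrajectory", "rate_response", "hebb_step",
           "run_rate_demixing"]


@dataclass
class RateModelConfig:
    """Learning rates and conventions of the rate experiments."""

    eta_hebb: float = 1e-5
    eta_ip: float = 1e-3
    norm_order: str = "L2"          # L1 (positive weights) | L2 (signed)
    n_steps: int = 400_000
    seed: int = 0
    k_scale: float = 10.0           # mV of drive per unit w.x
    u_rest: float = -70.0
    mu_goal: float = 5.0
    init_gain: GainParams = field(default_factory=GainParams)
    source_kinds: tuple = (0, 0)    # per source: 0 Laplace, 1 Gaussian
    log_every: int = 1000

    def __post_init__(self) -> None:
        if self.eta_hebb < 0 or self.eta_ip < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.norm_order not in ("L1", "L2"):
            raise ValueError("norm_order must be 'L1' or 'L2'")


@dataclass
class RateTrajectory:
    w: np.ndarray          # (n_logs, 2)
    gain: np.ndarray       # (n_logs, 3)
    nu: np.ndarray         # (n_logs,) instantaneous rate at log points
    w_final: np.ndarray
    gain_final: GainParams


def rate_response(x: np.ndarray, w: np.ndarray, p: GainParams,
                  k_scale: float = 10.0, u_rest: float = -70.0) -> float:
    """Firing rate g(u_rest + k * w.x), the same gain as the spiking model."""
    return gain(u_rest + k_scale * float(np.dot(w, x)), p)


def hebb_step(w: np.ndarray, x: np.ndarray, nu: float,
              cfg: RateModelConfig) -> np.ndarray:
    """One Hebbian update followed by the configured renormalization."""
    w = np.asarray(w, dtype=float) + cfg.eta_hebb * nu * np.asarray(x, dtype=float)
    if cfg.norm_order == "L1":
        w = np.maximum(w, 0.0)
        nrm = np.abs(w).sum()
    else:
        nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ZeroDivisionError("weight vector collapsed to zero norm")
    return w / nrm


def run_rate_demixing(theta: float, cfg: RateModelConfig,
                      w0: np.ndarray | None = None) -> RateTrajectory:
    """Full demixing run: sample sources, rotate, respond, adapt, renormalize."""
    rng = np.random.default_rng(cfg.seed)
    if w0 is None:
        v = rng.uniform(0.0, 1.0, 2) if cfg.norm_order == "L1" \
            else rng.standard_normal(2)
        w0 = v / (np.abs(v).sum() if cfg.norm_order == "L1" else np.linalg.norm(v))
    w = np.asarray(w0, dtype=float).copy()
    gp = cfg.init_gain.as_array().copy()
    n_logs = cfg.n_steps // cfg.log_every
    w_log = np.zeros((n_logs, 2))
    gp_log = np.zeros((n_logs, 3))
    nu_log = np.zeros(n_logs)
    rc = _kernels.rate_demix_kernel(
        rng, cfg.n_steps, theta, np.asarray(cfg.source_kinds, np.int64),
        cfg.eta_hebb, cfg.eta_ip, gp, w, cfg.k_scale, cfg.u_rest, cfg.mu_goal,
        1e-6 * gp[0], 1e-6 * gp[2],
        0 if cfg.norm_order == "L1" else 1, cfg.log_every,
        w_log, gp_log, nu_log)
    if rc < 0:
        raise ZeroDivisionError("weight vector collapsed to zero norm")
    return RateTrajectory(w=w_log[:rc], gain=gp_log[:rc], nu=nu_log[:rc],
                          w_final=w, gain_final=GainParams(*gp))
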