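"""Stochastically spiking neuron with refractoriness.

The neuron fires as an inhomogeneous Poisson process whose instantaneous
rate is a parametric *gain function* of the membrane potential,

    g(u) = r0 * ln(1 + exp((u - u0) / u_alpha)),

multiplied by a refractory recovery factor R in [0, 1].  The membrane
potential is the linear sum of exponentially decaying post-synaptic
potentials (PSPs) evoked by incoming spikes.  The three gain parameters
(r0, u0, u_alpha) are the substrate of intrinsic plasticity: r0 sets the
slope / rate scale, u0 shifts the curve along the membrane-potential axis,
and u_alpha rescales that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "GainParams",
    "NeuronConfig",
    "NeuronState",
    "gain",
    "gain_gradients",
    "refractory_factor",
    "membrane_update",
    "spike_draw",
]

NEVER = -np.inf  # sentinel for "has never spiked"


@dataclass
class GainParams:
    """Adaptable transfer-function parameters.

    r0 : rate scale (Hz), > 0
    u0 : threshold shift (mV)
    u_alpha : membrane-axis scale (mV), > 0
    """

    r0: float = 10.0
    u0: float = -55.0
    u_alpha: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (np.isfinite(self.r0) and self.r0 > 0):
            raise ValueError(f"r0 must be positive and finite, got {self.r0}")
        if not (np.isfinite(self.u_alpha) and self.u_alpha > 0):
            raise ValueError(f"u_alpha must be positive and finite, got {self.u_alpha}")
        if not np.isfinite(self.u0):
            raise ValueError(f"u0 must be finite, got {self.u0}")

    def copy(self) -> "GainParams":
        return replace(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.r0, self.u0, self.u_alpha], dtype=float)


@dataclass
class NeuronConfig:
    """Fixed neuron parameters (times in ms, rates in Hz).

    mu_goal is the intrinsic-plasticity target mean rate; the exponential
    target distribution is only a good approximation of the refractoriness-
    truncated optimum when mu_goal is far below the maximal rate 1/tau_abs,
    so mu_goal <= 0.1 / tau_abs is enforced.
    """

    u_rest: float = -70.0
    tau_m: float = 10.0
    tau_gaba: float = 10.0
    psp_amplitude: float = 1.0
    tau_abs: float = 3.0
    tau_refr: float = 10.0
    dt: float = 1.0
    mu_goal: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_gaba", "tau_abs", "tau_refr", "dt"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.tau_abs < self.dt:
            raise ValueError("tau_abs must be >= dt")
        if self.mu_goal <= 0:
            raise ValueError("mu_goal must be positive")
        # mu_goal << 1/tau_abs keeps the untruncated exponential target valid
        max_rate = 1000.0 / self.tau_abs  # Hz
        if self.mu_goal > 0.1 * max_rate:
            raise ValueError(
                f"mu_goal={self.mu_goal} Hz violates mu_goal <= 0.1/tau_abs "
                f"({0.1 * max_rate:.1f} Hz)"
            )


@dataclass
class NeuronState:
    """Dynamic state: PSP traces, last spike time, membrane potential."""

    psp_exc: np.ndarray
    psp_inh: np.ndarray = field(default_factory=lambda: np.zeros(0))
    t_last_spike: float = NEVER
    u: float = -70.0

    @classmethod
    def initial(cls, n_exc: int, n_inh: int = 0, cfg: NeuronConfig | None = None) -> "NeuronState":
        u_rest = cfg.u_rest if cfg is not None else -70.0
        return cls(psp_exc=np.zeros(n_exc), psp_inh=np.zeros(n_inh), u=u_rest)


def _z(u, p: GainParams):
    return (np.asarray(u, dtype=float) - p.u0) / p.u_alpha


def gain(u, p: GainParams):
    """Instantaneous firing rate g(u) = r0 * softplus((u - u0)/u_alpha), in Hz.

    Strictly increasing and continuous in u; g -> 0 as u -> -inf and
    asymptotic slope r0/u_alpha for u >> u0.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("membrane potential must be finite")
    z = _z(u, p)
    # stable softplus
    out = p.r0 * (np.logaddexp(0.0, z))
    return out if out.ndim else float(out)


def gain_gradients(u, p: GainParams):
    """Analytic partials of the gain.

    Returns a dict with dg/dr0, dg/du0, dg/du_alpha, dg/du and the mixed
    second derivatives d2g/du dr0, d2g/du du0, d2g/du du_alpha, d2g/du2
    (needed by the intrinsic-plasticity gradient).
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("membrane potential must be finite")
    z = _z(u, p)
    s = np.logaddexp(0.0, z)          # softplus(z)
    sig = expit(z)                     # softplus'(z)
    dsig = sig * (1.0 - sig)           # softplus''(z)
    a = p.u_alpha
    grads = {
        "dg_dr0": s,
        "dg_du0": -p.r0 * sig / a,
        "dg_dualpha": -p.r0 * sig * z / a,
        "dg_du": p.r0 * sig / a,
        "d2g_du_dr0": sig / a,
        "d2g_du_du0": -p.r0 * dsig / a**2,
        "d2g_du_dualpha": -p.r0 * (dsig * z + sig) / a**2,
        "d2g_du2": p.r0 * dsig / a**2,
    }
    if np.ndim(u) == 0:
        grads = {k: float(v) for k, v in grads.items()}
    return grads


def refractory_factor(t_since_spike, cfg: NeuronConfig):
    """Refractory recovery R in [0, 1].

    Zero throughout the absolute refractory period tau_abs, then recovers as
    x / (tau_refr + x) with x the time since the end of the absolute period;
    tau_refr sets the relative-refractory half-recovery time.  A neuron that
    has never spiked (t_since_spike = +inf or NEVER sentinel handled by the
    caller) gets R = 1.
    """
    d = np.asarray(t_since_spike, dtype=float)
    if np.any(d < 0):
        raise ValueError("time since spike must be nonnegative")
    x = d - cfg.tau_abs
    with np.errstate(invalid="ignore"):
        r = np.where(x <= 0, 0.0, x / (cfg.tau_refr + x))
    r = np.where(np.isposinf(d), 1.0, r)
    return float(r) if r.ndim == 0 else r


def membrane_update(
    state: NeuronState,
    exc_spikes: np.ndarray,
    inh_spikes: np.ndarray,
    w_exc: np.ndarray,
    w_inh: np.ndarray,
    cfg: NeuronConfig,
) -> NeuronState:
    """Advance the PSP traces one time step and recompute u.

    Each excitatory trace decays by exp(-dt/tau_m), each inhibitory trace by
    exp(-dt/tau_gaba); a presynaptic spike adds psp_amplitude to its trace.
    u = u_rest + w_exc . psp_exc - w_inh . psp_inh.
    """
    exc_spikes = np.asarray(exc_spikes)
    inh_spikes = np.asarray(inh_spikes)
    w_exc = np.asarray(w_exc, dtype=float)
    w_inh = np.asarray(w_inh, dtype=float)
    if exc_spikes.shape != w_exc.shape or inh_spikes.shape != w_inh.shape:
        raise ValueError("spike indicator and weight vectors must have matching shapes")
    if np.any(w_exc < 0) or np.any(w_inh < 0):
        raise ValueError("weights must be nonnegative")
    psp_exc = state.psp_exc * np.exp(-cfg.dt / cfg.tau_m) + cfg.psp_amplitude * exc_spikes
    psp_inh = state.psp_inh * np.exp(-cfg.dt / cfg.tau_gaba) + cfg.psp_amplitude * inh_spikes
    u = cfg.u_rest + float(w_exc @ psp_exc) - float(w_inh @ psp_inh)
    return NeuronState(psp_exc=psp_exc, psp_inh=psp_inh, t_last_spike=state.t_last_spike, u=u)


def spike_probability(g_hz: float, refractory: float, dt_ms: float) -> float:
    """Per-step firing probability P = 1 - exp(-R * g * dt).

    The exact exponential of the inhomogeneous-Poisson intensity is used
    rather than the linearization R*g*dt, so P never exceeds 1.
    """
    return -np.expm1(-refractory * g_hz * dt_ms / 1000.0)


def spike_draw(
    u: float,
    state: NeuronState,
    p: GainParams,
    cfg: NeuronConfig,
    rng: np.random.Generator,
    t_now: float = 0.0,
) -> int:
    """Bernoulli spike draw at the current step; updates t_last_spike on spike."""
    g = gain(u, p)
    if g * cfg.dt / 1000.0 > 0.2:
        import warnings

        warnings.warn("g*dt > 0.2: time step too coarse for the Poisson approximation")
    delta = t_now - state.t_last_spike if state.t_last_spike != NEVER else np.inf
    r = refractory_factor(delta, cfg)
    spike = int(rng.random() < spike_probability(g, r, cfg.dt))
    if spike:
        state.t_last_spike = t_now
    return spike
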