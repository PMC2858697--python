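"""Synaptic plasticity: STDP variants, synaptic scaling, BCM correspondence.

The default rule is nearest-neighbor STDP in the Izhikevich-Desai sense:
every presynaptic spike is paired with its nearest *preceding* postsynaptic
spike (depression, amplitude A_minus, time constant tau_minus) and its
nearest *following* postsynaptic spike (potentiation, A_plus, tau_plus);
each pairing is used exactly once.  Operationally this is realized with a
per-synapse potentiation trace that accumulates presynaptic spikes (decay
tau_plus) and is consumed — read out and reset — at each postsynaptic spike.

Under independent Poisson pre/post trains this scheme yields an expected
weight drift of BCM form,

    dw/dt = rho_pre * rho_post * [ A+ tau+ / (1 + rho_post tau+)
                                 - A- tau- / (1 + rho_post tau-) ],

linear in the presynaptic rate, with a fixed sign-change threshold

    theta = (A- tau- - A+ tau+) / (tau+ tau- (A+ - A-))

that is positive exactly when potentiation dominates on the short time
scale (A+ > A-) while overall depression dominates (A- tau- > A+ tau+).

Weights are kept nonnegative by clipping and homeostatically normalized by
multiplicative synaptic scaling after every sample presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPParams",
    "ScalingConfig",
    "PairingState",
    "DeadScopeError",
    "stdp_on_pre",
    "stdp_on_post",
    "clip_nonnegative",
    "scale_weights",
    "expected_drift_nn",
    "bcm_threshold",
]


@dataclass
class STDPParams:
    """STDP kernel parameters (amplitudes in weight units, taus in ms)."""

    A_plus: float = 0.005
    A_minus: float = 0.0035
    tau_plus: float = 17.0
    tau_minus: float = 34.0
    mode: str = "nearest"          # nearest | all_to_all | triplet
    A3_plus: float = 0.0           # triplet LTP amplitude
    tau_y: float = 100.0           # slow postsynaptic trace (triplet), ms
    # sub-bin convention of the discrete-time engine: False treats same-bin
    # pre/post spikes as simultaneous (no pairing, the Delta t = 0 tie-break);
    # True places presynaptic spikes at the bin start and the postsynaptic
    # draw at the bin end, so the spikes that fire the neuron are potentiated
    # at lag dt.  Correlation-coded tasks need True: their information lives
    # in single-bin synchrony.
    same_bin_causal: bool = False

    def __post_init__(self) -> None:
        if self.A_plus < 0 or self.A_minus < 0 or self.A3_plus < 0:
            raise ValueError("STDP amplitudes must be nonnegative")
        if self.tau_plus <= 0 or self.tau_minus <= 0 or self.tau_y <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.mode not in ("nearest", "all_to_all", "triplet"):
            raise ValueError(f"unknown STDP mode {self.mode!r}")

    @property
    def bcm_regime(self) -> bool:
        """True iff potentiation wins at short lags but depression overall."""
        return (self.A_plus > self.A_minus
                and self.A_minus * self.tau_minus > self.A_plus * self.tau_plus)

    def scaled(self, factor: float) -> "STDPParams":
        """Same kernel with amplitudes multiplied by `factor` (e.g. faster
        learning on lateral inhibitory connections)."""
        return STDPParams(A_plus=self.A_plus * factor, A_minus=self.A_minus * factor,
                          tau_plus=self.tau_plus, tau_minus=self.tau_minus,
                          mode=self.mode, A3_plus=self.A3_plus * factor,
                          tau_y=self.tau_y, same_bin_causal=self.same_bin_causal)


@dataclass
class ScalingConfig:
    """Multiplicative synaptic scaling to a fixed total weight."""

    W_total: float = 80.0
    norm_order: str = "L1"         # L1 | L2
    scope: str = "all"             # all | per_population

    def __post_init__(self) -> None:
        if self.W_total <= 0:
            raise ValueError("W_total must be positive")
        if self.norm_order not in ("L1", "L2"):
            raise ValueError("norm_order must be 'L1' or 'L2'")


class DeadScopeError(RuntimeError):
    """All weights in a scaling scope are zero — the scope is dead."""


@dataclass
class PairingState:
    """Bookkeeping for event-driven STDP on one neuron's afferents.

    ltp_trace accumulates presynaptic spikes (decay tau_plus) and is reset
    when consumed by a postsynaptic spike, realizing pair-each-pre-with-its-
    next-post semantics.  t_pre / t_post record most recent spike times for
    the depression branch and for the all-to-all / triplet traces.
    """

    n_syn: int
    t_pre: np.ndarray = field(init=False)
    t_post: float = field(default=-np.inf, init=False)
    ltp_trace: np.ndarray = field(init=False)      # nearest mode, tau_plus decay
    ltp_trace_t: float = field(default=-np.inf, init=False)
    pre_trace: np.ndarray = field(init=False)      # all-to-all, tau_plus decay
    post_trace: float = field(default=0.0, init=False)  # all-to-all, tau_minus
    y_trace: float = field(default=0.0, init=False)     # triplet slow post trace
    y_trace_t: float = field(default=-np.inf, init=False)
    post_trace_t: float = field(default=-np.inf, init=False)
    pre_trace_t: float = field(default=-np.inf, init=False)

    def __post_init__(self) -> None:
        self.t_pre = np.full(self.n_syn, -np.inf)
        self.ltp_trace = np.zeros(self.n_syn)
        self.pre_trace = np.zeros(self.n_syn)

    def _check_time(self, t: float) -> None:
        latest = max(self.t_post, float(np.max(self.t_pre)) if self.n_syn else -np.inf)
        if t < latest:
            raise ValueError(f"spike time {t} precedes a recorded spike at {latest}")

    def _decay_to(self, t: float, p: STDPParams) -> None:
        if np.isfinite(self.ltp_trace_t):
            self.ltp_trace *= np.exp(-(t - self.ltp_trace_t) / p.tau_plus)
        self.ltp_trace_t = t
        if np.isfinite(self.pre_trace_t):
            self.pre_trace *= np.exp(-(t - self.pre_trace_t) / p.tau_plus)
        self.pre_trace_t = t
        if np.isfinite(self.post_trace_t):
            self.post_trace *= np.exp(-(t - self.post_trace_t) / p.tau_minus)
        self.post_trace_t = t


def stdp_on_pre(s: PairingState, synapse_id, t: float, p: STDPParams) -> np.ndarray:
    """Register presynaptic spike(s) at time t; return per-synapse weight deltas.

    Depression pairs each presynaptic spike with the most recent postsynaptic
    spike; exact coincidence (delta t = 0) contributes nothing.
    """
    s._check_time(t)
    s._decay_to(t, p)
    ids = np.atleast_1d(np.asarray(synapse_id, dtype=int))
    dw = np.zeros(s.n_syn)
    if p.mode == "all_to_all":
        if t > s.t_post:  # delta t = 0 pairings contribute nothing
            dw[ids] = -p.A_minus * s.post_trace
    elif np.isfinite(s.t_post) and t > s.t_post:
        dw[ids] = -p.A_minus * np.exp(-(t - s.t_post) / p.tau_minus)
    s.t_pre[ids] = t
    s.ltp_trace[ids] += 1.0
    s.pre_trace[ids] += 1.0
    return dw


def stdp_on_post(s: PairingState, t: float, p: STDPParams) -> np.ndarray:
    """Register a postsynaptic spike at time t; return per-synapse weight deltas.

    Nearest mode: potentiation consumes the LTP trace (all presynaptic spikes
    since the previous postsynaptic spike, each weighted by exp(-dt/tau_plus))
    and resets it.  All-to-all: reads the running pre traces without reset.
    Triplet: the pair term is amplified by A3_plus times the slow post trace
    evaluated just before this spike.
    """
    s._check_time(t)
    # decay slow trace to just before this spike
    if p.mode == "triplet" and np.isfinite(s.y_trace_t):
        s.y_trace *= np.exp(-(t - s.y_trace_t) / p.tau_y)
    s._decay_to(t, p)
    # a pre spike recorded at this same t added exactly 1.0 to its trace;
    # exact-coincidence pairings contribute nothing
    coincident = (s.t_pre == t).astype(float)
    if p.mode == "all_to_all":
        dw = p.A_plus * (s.pre_trace - coincident)
    else:
        amp = p.A_plus + (p.A3_plus * s.y_trace if p.mode == "triplet" else 0.0)
        dw = amp * (s.ltp_trace - coincident)
        s.ltp_trace[:] = 0.0
    if p.mode == "triplet":
        s.y_trace += 1.0
        s.y_trace_t = t
    s.post_trace += 1.0
    s.t_post = t
    return dw


def clip_nonnegative(w: np.ndarray) -> np.ndarray:
    """Clip weights at zero from below (weights never change sign)."""
    return np.maximum(np.asarray(w, dtype=float), 0.0)


def scale_weights(
    w: np.ndarray,
    cfg: ScalingConfig,
    population_masks: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Multiplicatively rescale each scope to the target norm W_total.

    L1: scope sums to W_total; L2: Euclidean norm equals W_total.  With
    `population_masks` (e.g. on/off populations) each mask is normalized
    independently.  An all-zero scope aborts with DeadScopeError.
    """
    w = np.asarray(w, dtype=float).copy()
    masks = population_masks if population_masks is not None else [np.ones(w.shape, bool)]
    for m in masks:
        sub = w[m]
        norm = np.abs(sub).sum() if cfg.norm_order == "L1" else np.sqrt((sub**2).sum())
        if norm == 0:
            raise DeadScopeError("all weights in a scaling scope are zero")
        w[m] = sub * (cfg.W_total / norm)
    return w


def expected_drift_nn(rho_pre: float, rho_post: float, p: STDPParams) -> float:
    """Expected weight drift dw/dt (weight units per second) for independent
    Poisson pre/post trains under nearest-neighbor STDP.

    Each presynaptic spike pairs once with its nearest following post spike
    (forward waiting time ~ Exp(rho_post)) and once with its nearest
    preceding post spike (backward waiting time ~ Exp(rho_post)), giving

        dw/dt = rho_pre * rho_post * [A+ tau+/(1 + rho_post tau+)
                                      - A- tau-/(1 + rho_post tau-)].
    """
    if rho_pre < 0 or rho_post < 0:
        raise ValueError("rates must be nonnegative")
    tp = p.tau_plus / 1000.0   # s
    tm = p.tau_minus / 1000.0
    ltp = p.A_plus * tp / (1.0 + rho_post * tp)
    ltd = p.A_minus * tm / (1.0 + rho_post * tm)
    return rho_pre * rho_post * (ltp - ltd)


def bcm_threshold(p: STDPParams) -> float:
    """Fixed BCM threshold: the unique positive postsynaptic rate at which
    the expected nearest-neighbor drift changes sign.

    Requires the BCM regime: A+ > A- (potentiation dominates at short lags)
    and A- tau- > A+ tau+ (depression dominates overall).
    """
    if p.A_plus <= p.A_minus:
        raise ValueError("not in BCM regime: requires A_plus > A_minus")
    if p.A_minus * p.tau_minus < p.A_plus * p.tau_plus:
        raise ValueError("not in BCM regime: requires A_minus*tau_minus > A_plus*tau_plus")
    tp = p.tau_plus / 1000.0
    tm = p.tau_minus / 1000.0
    return (p.A_minus * tm - p.A_plus * tp) / (tp * tm * (p.A_plus - p.A_minus))
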