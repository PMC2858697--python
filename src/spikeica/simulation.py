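"""Experiment engine: sample-presentation loop coupling neuron, IP, STDP
and synaptic scaling; single neurons and laterally inhibited populations.

Each stimulus sample is presented for `sample_duration` ms of dt-resolution
simulation; within the presentation the membrane, intrinsic plasticity and
STDP evolve every step, and after each sample the weights are clipped and
multiplicatively rescaled (synaptic scaling).  In a population, every
postsynaptic spike feeds the other neurons' inhibitory PSP traces, and the
all-to-all inhibitory weights learn with the same STDP kernel at a higher
amplitude (inhibitory adaptation must outpace the feedforward weights for
efficient decorrelation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import _kernels
from .intrinsic import IPConfig, MeanRateIPConfig
from .neuron import GainParams, NeuronConfig
from .plasticity import DeadScopeError, STDPParams, ScalingConfig, scale_weights
from .stimuli import (BarsConfig, CorrelationSpec, DemixConfig, bars_sample,
                      bars_to_rates, mix_rotate, onoff_encode,
                      sample_laplace_pair)

__all__ = [
    "ExperimentConfig",
    "ExperimentTrace",
    "default_config",
    "present_sample",
    "run_experiment",
    "run_population",
]

_STDP_MODES = {"nearest": 0, "all_to_all": 1, "triplet": 2}
_IP_MODES = {"fixed_gain": 0, "full_ip": 1, "mean_rate_ip": 2}


@dataclass
class ExperimentConfig:
    """Complete description of one experiment; traces are a pure function of
    (config, seed)."""

    task: str = "bars"                   # bars | bars-corr | demix-spike
    n_samples: int = 3000
    seed: int = 0
    neuron: NeuronConfig = field(default_factory=NeuronConfig)
    ip: IPConfig = field(default_factory=IPConfig)
    stdp: STDPParams = field(default_factory=STDPParams)
    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    bars: BarsConfig | None = None
    demix: DemixConfig | None = None
    corr_nu: float = 20.0                # bars-corr mean rate (Hz)
    corr_c: float = 0.5                  # bars-corr pairwise correlation
    ip_mode: str = "full_ip"             # full_ip | fixed_gain | mean_rate_ip
    init_gain: GainParams = field(default_factory=GainParams)
    fixed_gain: GainParams | None = None
    mean_rate: MeanRateIPConfig | None = None
    # population
    n_neurons: int = 1
    inh_W_total: float = 30.0            # per-row inhibitory norm
    inhibitory_stdp_gain: float = 5.0    # lateral STDP amplitude factor
    init_jitter: tuple = (0.1, 5.0, 0.2)  # variances for (r0, u0, u_alpha)
    snapshot_every: int = 0              # samples between weight snapshots

    def __post_init__(self) -> None:
        if self.task not in ("bars", "bars-corr", "demix-spike"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.ip_mode not in _IP_MODES:
            raise ValueError(f"unknown ip_mode {self.ip_mode!r}")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.ip_mode == "fixed_gain" and self.fixed_gain is None:
            raise ValueError("fixed_gain mode requires fixed_gain parameters")
        if self.ip_mode == "mean_rate_ip" and self.mean_rate is None:
            self.mean_rate = MeanRateIPConfig(r_goal=self.neuron.mu_goal)
        if self.task.startswith("bars") and self.bars is None:
            raise ValueError("bars tasks require a bars section")
        if self.task == "demix-spike" and self.demix is None:
            raise ValueError("demix-spike requires a demix section")
        if self.ip.update_every != 1:
            raise ValueError("the engine applies IP every step (update_every must be 1)")

    @property
    def n_synapses(self) -> int:
        if self.task.startswith("bars"):
            return self.bars.n_pixels
        return 4 * self.demix.synapses_per_channel

    @property
    def sample_duration(self) -> float:
        return (self.bars if self.task.startswith("bars") else self.demix).sample_duration

    def to_yaml(self) -> str:
        d = asdict(self)
        d["init_jitter"] = list(self.init_jitter)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        for key, typ in (("neuron", NeuronConfig), ("ip", IPConfig),
                         ("stdp", STDPParams), ("scaling", ScalingConfig),
                         ("bars", BarsConfig), ("demix", DemixConfig),
                         ("init_gain", GainParams), ("fixed_gain", GainParams),
                         ("mean_rate", MeanRateIPConfig)):
            if d.get(key) is not None:
                d[key] = typ(**d[key])
        if "init_jitter" in d:
            d["init_jitter"] = tuple(d["init_jitter"])
        return cls(**d)


@dataclass
class ExperimentTrace:
    """Logged time series of one run."""

    config: ExperimentConfig
    sample_rate: np.ndarray      # (n_samples, n_neurons) per-sample mean rate, Hz
    g_inst: np.ndarray           # (n_samples, n_neurons) instantaneous rate at sample end
    gain_history: np.ndarray     # (n_samples, n_neurons, 3)
    w_final: np.ndarray          # (n_neurons, n_synapses)
    winh_final: np.ndarray       # (n_neurons, n_neurons)
    gain_final: np.ndarray       # (n_neurons, 3)
    spike_total: np.ndarray      # (n_neurons,)
    snapshots: list = field(default_factory=list)   # (sample_idx, weights copy)

    def to_frame(self):
        """Tidy long-format trace (t_ms, neuron, variable, value)."""
        import pandas as pd

        dur = self.config.sample_duration
        rows = []
        t = (np.arange(self.sample_rate.shape[0]) + 1) * dur
        for k in range(self.sample_rate.shape[1]):
            for name, arr in (("rate_hz", self.sample_rate[:, k]),
                              ("g_inst_hz", self.g_inst[:, k]),
                              ("r0_hz", self.gain_history[:, k, 0]),
                              ("u0_mv", self.gain_history[:, k, 1]),
                              ("ualpha_mv", self.gain_history[:, k, 2])):
                rows.append(pd.DataFrame(
                    {"t_ms": t, "neuron": k, "variable": name, "value": arr}))
        return pd.concat(rows, ignore_index=True)


def default_config(task: str, **overrides) -> ExperimentConfig:
    """Canonical configurations for the study tasks.

    bars          : 5x5 grid, 1-px bars, exactly-4-bars variant, rate code.
    bars-corr     : 10x10 grid, 2-px bars, always two bars, correlation code
                    (equal mean rates; STDP taus symmetric at 20 ms, causal
                    same-bin pairing).
    bars-population: 10 neurons, 10x10 grid, 2-px bars (10-bar basis,
                    three bars per sample), rate code, plastic lateral
                    inhibition.
    demix-spike   : rotated Laplacian pair, on/off channels x 25 synapses.
    """
    if task == "bars":
        base = dict(task="bars", n_samples=300_000,
                    bars=BarsConfig(grid=5, bar_width=1, mode="exactly_k", k=4,
                                    nu_max=120.0),
                    scaling=ScalingConfig(W_total=40.0),
                    neuron=NeuronConfig(mu_goal=10.0),
                    ip=IPConfig(mu_goal=10.0),
                    stdp=STDPParams(A_plus=0.0064, A_minus=0.0035))
    elif task == "bars-corr":
        base = dict(task="bars-corr", n_samples=100_000,
                    bars=BarsConfig(grid=10, bar_width=2, mode="exactly_k", k=2),
                    scaling=ScalingConfig(W_total=70.0),
                    stdp=STDPParams(A_plus=0.0192, A_minus=0.0105,
                                    tau_plus=20.0, tau_minus=20.0,
                                    same_bin_causal=True),
                    corr_nu=20.0, corr_c=0.5)
    elif task == "bars-population":
        # slower feedforward STDP than the single-neuron task: lateral
        # inhibition must decorrelate the neurons before they commit to a
        # bar, or duplicates are locked in
        # slow (GABA_B-like) inhibitory integration: lateral decorrelation
        # needs inhibition integrated over a longer window than the
        # excitatory PSPs, or duplicate receptive fields persist
        base = dict(task="bars", n_samples=220_000, n_neurons=10,
                    bars=BarsConfig(grid=10, bar_width=2, mode="exactly_k",
                                    k=3, nu_max=120.0),
                    scaling=ScalingConfig(W_total=100.0), inh_W_total=30.0,
                    neuron=NeuronConfig(mu_goal=10.0, tau_gaba=50.0),
                    ip=IPConfig(mu_goal=10.0),
                    stdp=STDPParams(A_plus=0.0051, A_minus=0.0028))
    elif task == "demix-spike":
        base = dict(task="demix-spike", n_samples=100_000,
                    demix=DemixConfig(),
                    scaling=ScalingConfig(W_total=200.0),
                    neuron=NeuronConfig(mu_goal=10.0),
                    ip=IPConfig(mu_goal=10.0),
                    stdp=STDPParams(A_plus=0.0064, A_minus=0.0035))
    else:
        raise ValueError(f"no default configuration for task {task!r}")
    base.update(overrides)
    return ExperimentConfig(**base)


class _Engine:
    """Mutable run state shared by present_sample / run_experiment."""

    def __init__(self, cfg: ExperimentConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        n, m = cfg.n_neurons, cfg.n_synapses
        w = rng.uniform(0.0, 1.0, size=(n, m))
        for k in range(n):
            w[k] = scale_weights(w[k], cfg.scaling)
        self.w = w
        winh = np.zeros((n, n))
        if n > 1:
            winh = rng.uniform(0.0, 1.0, size=(n, n))
            np.fill_diagonal(winh, 0.0)
            inh_cfg = ScalingConfig(W_total=cfg.inh_W_total,
                                    norm_order=cfg.scaling.norm_order)
            for k in range(n):
                winh[k] = scale_weights(winh[k], inh_cfg)
            self.inh_cfg = inh_cfg
        self.winh = winh
        # gain parameters (jittered in a population)
        gp0 = cfg.init_gain if cfg.ip_mode != "fixed_gain" else cfg.fixed_gain
        gp = np.tile(gp0.as_array(), (n, 1))
        if n > 1:
            half = np.sqrt(3.0 * np.asarray(cfg.init_jitter))
            gp += rng.uniform(-half, half, size=(n, 3))
            gp[:, 0] = np.maximum(gp[:, 0], 0.1)
            gp[:, 2] = np.maximum(gp[:, 2], 0.1)
        self.gp = gp
        self.ip_floors = np.column_stack([1e-6 * gp[:, 0], 1e-6 * gp[:, 2]])
        # dynamic state
        self.psp = np.zeros(m)
        self.inh_trace = np.zeros(n)
        self.t_post = np.full(n, _kernels.NEG_INF)
        self.ltp = np.zeros((n, m))
        self.pre_trace = np.zeros(m)
        self.post_trace = np.zeros(n)
        self.y_trace = np.zeros(n)
        self.inh_ltp = np.zeros((n, n))
        self.t_now = 0.0
        self.mr = np.array([
            cfg.mean_rate.r_bar if cfg.mean_rate else 0.0,
            cfg.mean_rate.eta_mr if cfg.mean_rate else 0.0,
            cfg.mean_rate.r_goal if cfg.mean_rate else 0.0,
            cfg.mean_rate.tau_r if cfg.mean_rate else 1.0,
        ])
        nc = cfg.neuron
        self.neuron_c = np.array([nc.u_rest, nc.tau_m, nc.tau_gaba,
                                  nc.psp_amplitude, nc.tau_abs, nc.tau_refr, nc.dt])
        st = cfg.stdp
        self.stdp_c = np.array([st.A_plus, st.A_minus, st.tau_plus, st.tau_minus,
                                st.A3_plus, st.tau_y])
        ist = st.scaled(cfg.inhibitory_stdp_gain)
        self.inh_stdp_c = np.array([ist.A_plus, ist.A_minus, ist.tau_plus,
                                    ist.tau_minus])
        self.mode = _STDP_MODES[st.mode]
        self.same_bin_causal = 1 if st.same_bin_causal else 0
        self.ip_mode = _IP_MODES[cfg.ip_mode]
        # per-(nu, c) latent solution for the correlation encoding
        if cfg.task == "bars-corr":
            self.corr_spec = CorrelationSpec(nu=cfg.corr_nu, c=cfg.corr_c,
                                             dt=nc.dt).solve()

    # -- stimulus generation -------------------------------------------------
    def draw_pre_spikes(self, n_steps: int):
        cfg = self.cfg
        dt = cfg.neuron.dt
        if cfg.task == "bars":
            grid, _ = bars_sample(cfg.bars, self.rng)
            rates = bars_to_rates(grid, cfg.bars)
            return self.rng.random((n_steps, rates.size)) < rates * dt / 1000.0
        if cfg.task == "bars-corr":
            grid, _ = bars_sample(cfg.bars, self.rng)
            members = np.nonzero(grid.ravel())[0]
            spec = self.corr_spec
            n_px = cfg.bars.n_pixels
            z = self.rng.standard_normal((n_steps, n_px))
            if members.size:
                common = self.rng.standard_normal(n_steps)
                z[:, members] = (np.sqrt(spec.lam) * common[:, None]
                                 + np.sqrt(1.0 - spec.lam) * z[:, members])
            return z > spec.gamma
        # demix-spike
        s = sample_laplace_pair(self.rng)
        x = onoff_encode(mix_rotate(s, cfg.demix.theta)) * cfg.demix.rate_scale
        rates = np.repeat(x, cfg.demix.synapses_per_channel)
        p = np.minimum(rates * dt / 1000.0, 1.0)
        return self.rng.random((n_steps, rates.size)) < p


def present_sample(engine: _Engine, pre_spikes: np.ndarray,
                   plastic: bool = True):
    """Present one stimulus sample; returns (mean rates Hz, g at sample end).

    Runs the per-step loop (PSP decay + input spikes, membrane potential,
    IP update, postsynaptic draw, STDP events), then clips and rescales the
    weights — the synaptic-scaling step that follows every presentation.
    A zero-length sample leaves all state untouched.
    """
    cfg = engine.cfg
    n_steps = pre_spikes.shape[0]
    n = cfg.n_neurons
    if n_steps == 0:
        return np.zeros(n), np.zeros(n)
    dt = cfg.neuron.dt
    g_out = np.zeros((1, n))
    counts = np.zeros(n, np.int64)
    eta = cfg.ip.eta_ip if cfg.ip_mode == "full_ip" else 0.0
    _kernels.present_sample_kernel(
        engine.rng, pre_spikes.astype(np.uint8), engine.w, engine.winh,
        engine.psp, engine.inh_trace, engine.gp, engine.t_post, engine.ltp,
        engine.pre_trace, engine.post_trace, engine.y_trace, engine.inh_ltp,
        engine.neuron_c, engine.stdp_c, engine.inh_stdp_c, engine.mode,
        engine.same_bin_causal,
        engine.ip_mode, eta, cfg.ip.mu_goal, engine.ip_floors, engine.mr,
        1 if plastic else 0, engine.t_now, g_out, n_steps, counts)
    engine.t_now += n_steps * dt
    if plastic:
        try:
            for k in range(n):
                engine.w[k] = scale_weights(np.maximum(engine.w[k], 0.0),
                                            cfg.scaling)
        except DeadScopeError as e:
            raise DeadScopeError(f"{e} (at t={engine.t_now:.0f} ms)") from e
        if n > 1:
            # no self-connections: force the diagonal to zero at each scaling
            np.fill_diagonal(engine.winh, 0.0)
            for k in range(n):
                engine.winh[k] = scale_weights(np.maximum(engine.winh[k], 0.0),
                                               engine.inh_cfg)
    rates = counts * 1000.0 / (n_steps * dt)
    return rates, g_out[0]


def run_experiment(cfg: ExperimentConfig) -> ExperimentTrace:
    """Run a full experiment; the trace is reproducible from (config, seed)."""
    rng = np.random.default_rng(cfg.seed)
    engine = _Engine(cfg, rng)
    n_steps = int(round(cfg.sample_duration / cfg.neuron.dt))
    n = cfg.n_neurons
    sample_rate = np.zeros((cfg.n_samples, n))
    g_inst = np.zeros((cfg.n_samples, n))
    gain_history = np.zeros((cfg.n_samples, n, 3))
    spike_total = np.zeros(n)
    snapshots = []
    for i in range(cfg.n_samples):
        pre = engine.draw_pre_spikes(n_steps)
        rates, g = present_sample(engine, pre)
        sample_rate[i] = rates
        g_inst[i] = g
        gain_history[i] = engine.gp
        spike_total += rates * cfg.sample_duration / 1000.0
        if cfg.snapshot_every and (i + 1) % cfg.snapshot_every == 0:
            snapshots.append((i + 1, engine.w.copy()))
    return ExperimentTrace(
        config=cfg, sample_rate=sample_rate, g_inst=g_inst,
        gain_history=gain_history, w_final=engine.w.copy(),
        winh_final=engine.winh.copy(), gain_final=engine.gp.copy(),
        spike_total=spike_total, snapshots=snapshots)


def run_population(cfg: ExperimentConfig) -> ExperimentTrace:
    """Population run with all-to-all plastic lateral inhibition.

    Degenerates exactly to `run_experiment` for n_neurons = 1.  Warns when
    the inhibitory STDP is not faster than the feedforward STDP, since
    efficient decorrelation requires faster inhibitory adaptation.
    """
    if cfg.n_neurons > 1 and cfg.inhibitory_stdp_gain <= 1.0:
        warnings.warn("inhibitory adaptation should be faster than feedforward "
                      "(inhibitory_stdp_gain > 1) for efficient decorrelation")
    return run_experiment(cfg)
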