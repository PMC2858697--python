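"""Receptive-field estimation and quantitative readouts.

Covers back-projection of on/off demixing weights to the 2-D source space,
angle recovery, bar counting and matching, output-distribution diagnostics
(mean, CV, kurtosis, KL to the exponential target), population
decorrelation metrics (pairwise Pearson correlation and normalized mutual
information over time windows), and spike-triggered averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .stimuli import BarsConfig, bar_templates

__all__ = [
    "ReceptiveField",
    "project_demix_weights",
    "estimate_angle",
    "rf_from_onoff",
    "count_bars",
    "output_stats",
    "decorrelation_metrics",
    "reverse_correlation",
]


@dataclass
class ReceptiveField:
    """Signed per-pixel (or per-dimension) weight map with provenance."""

    map: np.ndarray
    provenance: str = "onoff_difference"

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if not np.all(np.isfinite(self.map)):
            raise ValueError("receptive field must be finite")


def project_demix_weights(w: np.ndarray) -> np.ndarray:
    """Back-project 4-channel summed weights (on1, off1, on2, off2) to 2-D.

    Minimum-error projection onto the rectified-encoding constraint set
    (on_i * off_i = 0): per dimension the magnitude is max(W_on, W_off) and
    the sign is that of the channel with the larger weight (ties toward +).
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (4,):
        raise ValueError("expected 4 channel sums (on1, off1, on2, off2)")
    if np.any(w < 0):
        raise ValueError("channel sums must be nonnegative")
    if np.all(w == 0):
        raise ValueError("all-zero weight vector cannot be projected")
    out = np.empty(2)
    for i in range(2):
        on, off = w[2 * i], w[2 * i + 1]
        out[i] = on if on >= off else -off
    return out


def estimate_angle(v: np.ndarray, modulus: float = np.pi / 2) -> float:
    """Orientation of a 2-D vector folded into [0, modulus)."""
    v = np.asarray(v, dtype=float)
    if np.allclose(v, 0):
        raise ValueError("cannot estimate the angle of a zero vector")
    return float(np.arctan2(v[1], v[0]) % modulus)


def rf_from_onoff(w_on: np.ndarray, w_off: np.ndarray) -> ReceptiveField:
    """Receptive field as the difference of on- and off-population weights."""
    w_on = np.asarray(w_on, dtype=float)
    w_off = np.asarray(w_off, dtype=float)
    if w_on.shape != w_off.shape:
        raise ValueError("on/off weight maps must have the same shape")
    return ReceptiveField(w_on - w_off, provenance="onoff_difference")


def count_bars(rf, cfg: BarsConfig, frac: float = 0.5, stray_frac: float = 0.1):
    """Count whole bars present in a weight map.

    The map is binarized at frac * max(weights).  A bar counts as present iff
    all of its pixels are above threshold; the match is accepted only if the
    above-threshold set equals the union of the matched bars up to
    grid * stray_frac stray pixels.  Returns (count, matched bar ids); an
    all-zero (or all-nonpositive) field gives (0, []).
    """
    w = rf.map if isinstance(rf, ReceptiveField) else np.asarray(rf, dtype=float)
    w = w.reshape(cfg.grid, cfg.grid)
    mx = w.max()
    if mx <= 0:
        return 0, []
    above = w >= frac * mx
    if above.all():
        return 0, []  # unselective (e.g. uniform) map: the threshold excludes nothing
    templates = bar_templates(cfg)
    matched = [i for i, t in enumerate(templates) if np.all(above[t])]
    union = np.zeros_like(above)
    for i in matched:
        union |= templates[i]
    stray = np.count_nonzero(above & ~union)
    if stray > cfg.grid * stray_frac:
        return 0, []
    return len(matched), matched


def best_matching_bar(rf, cfg: BarsConfig) -> int:
    """Index of the bar template with the highest cosine similarity to the map."""
    w = rf.map if isinstance(rf, ReceptiveField) else np.asarray(rf, dtype=float)
    w = w.reshape(-1)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("zero receptive field")
    t = bar_templates(cfg).reshape(cfg.n_bars, -1).astype(float)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return int(np.argmax(t @ w / nrm))


def output_stats(g_samples: np.ndarray, mu_goal: float, n_bins: int = 50) -> dict:
    """Moments of an instantaneous-rate sample and its KL to Exp(mu_goal).

    KL uses a histogram over n_bins equal-probability bins of the target
    exponential (last bin open-ended), so a perfectly matched sample gives
    uniform counts and KL near zero.  A constant sequence has no spread to
    histogram; its KL is reported as NaN with a flag.
    """
    g = np.asarray(g_samples, dtype=float)
    mean = float(g.mean())
    sd = float(g.std())
    cv = sd / mean if mean > 0 else np.nan
    kurt = float(stats.kurtosis(g, fisher=True)) if sd > 0 else np.nan
    out = {"mean": mean, "cv": cv, "excess_kurtosis": kurt, "kl": np.nan,
           "degenerate": sd == 0}
    if sd == 0 or g.size < 1000:
        return out
    qs = np.arange(1, n_bins) / n_bins
    edges = np.concatenate([[0.0], -mu_goal * np.log1p(-qs), [np.inf]])
    counts, _ = np.histogram(g, bins=edges)
    phat = counts / counts.sum()
    nz = phat > 0
    out["kl"] = float(np.sum(phat[nz] * np.log(phat[nz] * n_bins)))
    return out


def _nmi(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Mutual information of equal-width-binned values, normalized by the
    smaller marginal entropy."""
    cx = np.histogram_bin_edges(x, bins=n_bins)
    cy = np.histogram_bin_edges(y, bins=n_bins)
    joint, _, _ = np.histogram2d(x, y, bins=[cx, cy])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nzx, nzy = px > 0, py > 0
    hx = -np.sum(px[nzx] * np.log(px[nzx]))
    hy = -np.sum(py[nzy] * np.log(py[nzy]))
    nz = pxy > 0
    hxy = -np.sum(pxy[nz] * np.log(pxy[nz]))
    mi = hx + hy - hxy
    denom = min(hx, hy)
    if denom <= 0:
        return np.nan
    return float(mi / denom)


def decorrelation_metrics(
    rates: np.ndarray,
    window: int,
    n_bins: int = 10,
) -> dict:
    """Windowed population-dependence metrics.

    rates: array (n_neurons, n_samples) of per-sample mean rates.  For each
    non-overlapping window of `window` samples, computes the mean over
    neuron pairs of |Pearson r| and of normalized mutual information
    (equal-width bins, normalized by the min marginal entropy).  Pairs with
    a zero-variance member in a window are skipped.
    """
    rates = np.asarray(rates, dtype=float)
    n_neurons, n_samples = rates.shape
    if n_neurons < 2:
        raise ValueError("need at least two neurons")
    if window < 100:
        raise ValueError("window must span at least 100 samples")
    n_win = n_samples // window
    out = {"t": [], "mean_abs_r": [], "mean_nmi": []}
    for k in range(n_win):
        sl = slice(k * window, (k + 1) * window)
        block = rates[:, sl]
        var = block.var(axis=1)
        rs, nmis = [], []
        for i in range(n_neurons):
            for j in range(i + 1, n_neurons):
                if var[i] == 0 or var[j] == 0:
                    continue
                rs.append(abs(np.corrcoef(block[i], block[j])[0, 1]))
                nmis.append(_nmi(block[i], block[j], n_bins))
        out["t"].append(k)
        out["mean_abs_r"].append(float(np.mean(rs)) if rs else np.nan)
        out["mean_nmi"].append(float(np.nanmean(nmis)) if nmis else np.nan)
    return {k: np.asarray(v) for k, v in out.items()}


def reverse_correlation(stimuli: np.ndarray, spikes: np.ndarray) -> ReceptiveField:
    """Spike-triggered average of per-sample stimulus vectors, mean-subtracted.

    stimuli: (n_samples, n_dims) zero-mean white stimulus values;
    spikes: per-sample spike counts.  Requires >= 100 spikes.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    if spikes.sum() == 0:
        raise ValueError("no spikes recorded")
    if spikes.sum() < 100:
        raise ValueError("need at least 100 spikes for a stable STA")
    if np.allclose(stimuli.std(axis=0), 0):
        raise ValueError("constant stimulus carries no information")
    sta = (spikes @ stimuli) / spikes.sum() - stimuli.mean(axis=0)
    return ReceptiveField(sta, provenance="reverse_correlation")
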