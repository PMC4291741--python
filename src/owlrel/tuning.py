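"""Tuning-curve feature extraction for midbrain auditory neurons.

All features derive from a `RateCurve`: per-trial spike counts against
one stimulus axis (ITD in microseconds, tone frequency in Hz, or
speaker azimuth in degrees) with the stimulus duration and spontaneous
rate.  The features are the standard ones for space-map neurons: best
ITD (half-height center of the main peak), best frequency and frequency
edges (threshold crossings of the rate-frequency curve), vector-strength
IPD synchrony, Fano factors, and spatial-tuning similarity under
concurrent sounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

__all__ = [
    "RateCurve",
    "IPDCurve",
    "PeriodicGaussianFit",
    "mean_rate_curve",
    "best_itd",
    "frequency_tuning_features",
    "fold_itd_to_ipd",
    "fit_periodic_gaussian",
    "synchronization_coefficient",
    "fano_factor",
    "fano_factor_per_stimulus",
    "spatial_similarity",
    "smooth_curve",
    "save_rate_curve",
    "load_rate_curve",
]


@dataclass
class RateCurve:
    """Per-trial spike counts along one stimulus axis."""

    axis_name: str            # "itd_us" | "frequency_hz" | "azimuth_deg"
    stimulus: np.ndarray      # strictly monotone grid
    counts: np.ndarray        # (n_trials, n_stimuli) non-negative ints
    duration_s: float
    spontaneous_rate_hz: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise ValueError("counts must be a (trials, stimuli) matrix")
        if self.counts.shape[1] != self.stimulus.size:
            raise ValueError("counts do not match the stimulus grid")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        d = np.diff(self.stimulus)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("stimulus grid must be strictly monotone")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class IPDCurve:
    """Mean rate against interaural phase at a single tone frequency."""

    ipd_cycles: np.ndarray    # in [0, 1)
    mean_rate_hz: np.ndarray
    stim_freq_hz: float


def mean_rate_curve(rc: RateCurve) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate minus the spontaneous rate, floored at 0."""
    rates = rc.counts.mean(axis=0) / rc.duration_s - rc.spontaneous_rate_hz
    return rc.stimulus.copy(), np.maximum(rates, 0.0)


def _cross_up(x0, y0, x1, y1, level):
    """Linear interpolation of the crossing of `level` between two points."""
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def best_itd(itds_us, rates) -> dict:
    """Half-height center of the main peak of an ITD tuning curve.

    The main peak is the global maximum; the half-height level is
    ``min + 0.5 (max - min)``.  The contiguous region around the peak
    at or above that level is delimited by linear interpolation, and the
    best ITD is the midpoint of the region.  Returns signed and absolute
    values plus the region edges.
    """
    itds_us = np.asarray(itds_us, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if itds_us.size < 5:
        raise ValueError("need at least 5 ITD points")
    if np.ptp(rates) == 0:
        raise ValueError("flat ITD curve: best ITD undefined")
    level = rates.min() + 0.5 * (rates.max() - rates.min())
    ipk = int(np.argmax(rates))
    lo = ipk
    while lo > 0 and rates[lo - 1] >= level:
        lo -= 1
    hi = ipk
    while hi < rates.size - 1 and rates[hi + 1] >= level:
        hi += 1
    left = (
        itds_us[lo]
        if lo == 0
        else _cross_up(itds_us[lo - 1], rates[lo - 1], itds_us[lo], rates[lo], level)
    )
    right = (
        itds_us[hi]
        if hi == rates.size - 1
        else _cross_up(itds_us[hi], rates[hi], itds_us[hi + 1], rates[hi + 1], level)
    )
    center = 0.5 * (left + right)
    return {
        "best_itd_us": float(center),
        "abs_best_itd_us": float(abs(center)),
        "half_height_range_us": (float(left), float(right)),
    }


def frequency_tuning_features(freqs_hz, rates, threshold: float = 0.5) -> dict:
    """Frequency response area edges and best frequency (BF).

    The response area is the frequency range exceeding
    ``threshold * max`` (edges by linear interpolation between grid
    points); BF is the center of that range.  A center-of-mass BF is
    also returned.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    if rates.max() <= 0:
        raise ValueError("all-zero frequency tuning curve")
    level = threshold * rates.max()
    above = np.nonzero(rates > level)[0]
    i0, i1 = above[0], above[-1]
    f_low = (
        freqs_hz[i0]
        if i0 == 0
        else _cross_up(freqs_hz[i0 - 1], rates[i0 - 1], freqs_hz[i0], rates[i0], level)
    )
    f_high = (
        freqs_hz[i1]
        if i1 == rates.size - 1
        else _cross_up(freqs_hz[i1], rates[i1], freqs_hz[i1 + 1], rates[i1 + 1], level)
    )
    return {
        "f_low_hz": float(f_low),
        "f_high_hz": float(f_high),
        "bf_hz": float(0.5 * (f_low + f_high)),
        "bf_center_of_mass_hz": float(np.sum(freqs_hz * rates) / np.sum(rates)),
    }


def fold_itd_to_ipd(itds_us, rates, f_stim_hz: float, decimals: int = 9) -> IPDCurve:
    """Fold a tonal ITD curve into one period of the stimulating frequency.

    ``ipd = (itd * f) mod 1``; rates landing on coincident IPDs are
    averaged.  Requires the ITD span to cover at least one period.
    """
    if f_stim_hz <= 0:
        raise ValueError("stimulating frequency must be positive")
    itds_us = np.asarray(itds_us, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.ptp(itds_us) * 1e-6 * f_stim_hz < 1.0 - 1e-9:
        raise ValueError("ITD span must cover at least one stimulus period")
    ipd = np.round((itds_us * 1e-6 * f_stim_hz) % 1.0, decimals) % 1.0
    uniq, inv = np.unique(ipd, return_inverse=True)
    mean = np.zeros(uniq.size)
    for i in range(uniq.size):
        mean[i] = rates[inv == i].mean()
    return IPDCurve(ipd_cycles=uniq, mean_rate_hz=mean, stim_freq_hz=float(f_stim_hz))


@dataclass
class PeriodicGaussianFit:
    baseline: float
    amplitude: float
    mu_cycles: float
    sigma_cycles: float
    grid_cycles: np.ndarray
    fitted_rate_hz: np.ndarray
    converged: bool


def _wrapped_gaussian(phi, mu, sigma):
    k = np.arange(-3, 4)
    return np.exp(-((phi[..., None] - mu + k) ** 2) / (2.0 * sigma**2)).sum(axis=-1)


def fit_periodic_gaussian(curve: IPDCurve, n_grid: int = 64) -> PeriodicGaussianFit:
    """Least-squares wrapped-Gaussian fit of an IPD curve.

    Fits ``baseline + amplitude * G(phi; mu, sigma)`` with ``G`` a
    period-1 wrapped Gaussian, then evaluates the fit on a uniform IPD
    grid (this is what gives a uniform sampling of IPD over one period
    for the synchronization coefficient).  On failure the raw curve is
    interpolated periodically and flagged unconverged.
    """
    phi = np.asarray(curve.ipd_cycles, dtype=float)
    r = np.asarray(curve.mean_rate_hz, dtype=float)
    if np.unique(phi).size < 7:
        raise ValueError("need at least 7 distinct IPD points")
    grid = np.arange(n_grid) / n_grid

    def model(p, b, a, mu, sigma):
        return b + a * _wrapped_gaussian(p, mu, sigma)

    p0 = (float(r.min()), float(max(r.max() - r.min(), 1e-6)), float(phi[np.argmax(r)]), 0.15)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                phi,
                r,
                p0=p0,
                bounds=([0.0, 0.0, -0.5, 0.01], [np.inf, np.inf, 1.5, 2.0]),
                maxfev=20000,
            )
        fitted = model(grid, *popt)
        return PeriodicGaussianFit(
            baseline=float(popt[0]),
            amplitude=float(popt[1]),
            mu_cycles=float(popt[2] % 1.0),
            sigma_cycles=float(popt[3]),
            grid_cycles=grid,
            fitted_rate_hz=np.maximum(fitted, 0.0),
            converged=True,
        )
    except RuntimeError:
        order = np.argsort(phi)
        px = np.concatenate([phi[order] - 1.0, phi[order], phi[order] + 1.0])
        py = np.tile(r[order], 3)
        fitted = np.interp(grid, px, py)
        return PeriodicGaussianFit(
            baseline=float(r.min()),
            amplitude=float(r.max() - r.min()),
            mu_cycles=float(phi[np.argmax(r)]),
            sigma_cycles=float("nan"),
            grid_cycles=grid,
            fitted_rate_hz=np.maximum(fitted, 0.0),
            converged=False,
        )


def synchronization_coefficient(ipd_cycles, rates) -> float:
    """Vector strength of an IPD tuning curve.

    Each IPD contributes a vector with direction ``2 pi ipd`` and length
    equal to its mean rate; the coefficient is the resultant amplitude
    divided by the summed rates: 0 for no IPD selectivity, 1 for perfect
    phase synchrony.  Assumes uniform IPD sampling over one period.
    """
    ipd_cycles = np.asarray(ipd_cycles, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    total = rates.sum()
    if total <= 0:
        raise ValueError("zero total rate")
    return float(np.abs(np.sum(rates * np.exp(2j * np.pi * ipd_cycles))) / total)


def fano_factor_per_stimulus(rc: RateCurve) -> np.ndarray:
    """Variance/mean of raw spike counts at each stimulus (NaN where the
    mean count is zero).  Spontaneous rate is not subtracted."""
    if rc.counts.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    mean = rc.counts.mean(axis=0)
    var = rc.counts.var(axis=0, ddof=1)
    out = np.full(mean.size, np.nan)
    ok = mean > 0
    out[ok] = var[ok] / mean[ok]
    return out

def fano_factor(rc: RateCurve) -> float:
    """Fano factor of a tuning curve: the per-stimulus variance-to-mean
    ratios of the spike count averaged across stimuli (zero-mean
    stimuli skipped)."""
    per = fano_factor_per_stimulus(rc)
    ok = np.isfinite(per)
    if not ok.any():
        raise ValueError("all stimuli have zero mean count")
    return float(per[ok].mean())


def _minmax01(y: np.ndarray) -> np.ndarray:
    rng = np.ptp(y)
    return (y - y.min()) / rng if rng > 0 else np.zeros_like(y)


def spatial_similarity(single_rates, concurrent_rates_list) -> dict:
    """Mean Pearson correlation between single-source and
    concurrent-sound spatial tuning curves (each normalized to [0, 1]).

    Constant curves are skipped with a warning.  Returns the per-
    condition coefficients and their mean.
    """
    single = _minmax01(np.asarray(single_rates, dtype=float))
    if np.ptp(single) == 0:
        raise ValueError("single-source curve is constant")
    rs = []
    for y in concurrent_rates_list:
        y = np.asarray(y, dtype=float)
        if y.size != single.size:
            raise ValueError("curves must share the azimuth grid")
        if np.ptp(y) == 0:
            warnings.warn("constant concurrent curve skipped", stacklevel=2)
            continue
        r, _ = pearsonr(single, _minmax01(y))
        rs.append(float(r))
    return {"per_condition_r": rs, "mean_r": float(np.mean(rs)) if rs else float("nan")}


def smooth_curve(y, window: int = 3) -> np.ndarray:
    """Centered moving average with edge-aware normalization."""
    y = np.asarray(y, dtype=float)
    if window <= 1:
        return y.copy()
    kernel = np.ones(window)
    return np.convolve(y, kernel, mode="same") / np.convolve(
        np.ones_like(y), kernel, mode="same"
    )


def save_rate_curve(rc: RateCurve, csv_path) -> None:
    """Long-format CSV (trial, stimulus, count) plus a JSON sidecar."""
    csv_path = Path(csv_path)
    trials, stims = np.meshgrid(
        np.arange(rc.counts.shape[0]), rc.stimulus, indexing="ij"
    )
    pd.DataFrame(
        {"trial": trials.ravel(), "stimulus": stims.ravel(), "count": rc.counts.ravel()}
    ).to_csv(csv_path, index=False)
    sidecar = {
        "axis_name": rc.axis_name,
        "duration_s": rc.duration_s,
        "spontaneous_rate_hz": rc.spontaneous_rate_hz,
        "meta": rc.meta,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_rate_curve(csv_path) -> RateCurve:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    table = df.pivot(index="trial", columns="stimulus", values="count")
    return RateCurve(
        axis_name=sidecar["axis_name"],
        stimulus=table.columns.to_numpy(dtype=float),
        counts=table.to_numpy(dtype=int),
        duration_s=sidecar["duration_s"],
        spontaneous_rate_hz=sidecar["spontaneous_rate_hz"],
        meta=sidecar.get("meta", {}),
    )
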