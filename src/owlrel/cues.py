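"""Interaural cue statistics over concurrent-source ensembles.

The central quantity is the interaural phase difference (IPD) in a
narrow frequency channel: the delay maximising the normalized
cross-correlation of the left and right gammatone outputs, restricted to
half a period of the channel center frequency and expressed in cycles.

For a target direction, an ensemble of scenes is rendered in which a
second (or third) independent equal-level noise source is placed at each
position of a distractor grid spanning the frontal hemisphere.  The
circular standard deviation of the per-channel IPD over that ensemble
measures how badly concurrent sounds corrupt the cue; its inverse
variance is the cue's *reliability*.  Companion maps collect the
head-filter intensity gain and the mean interaural correlation at the
target's delay under the same ensembles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .binaural import (
    BinauralWave,
    GammatoneBank,
    NoiseStimulus,
    filter_binaural,
    make_flat_noise,
    render_binaural,
)
from .hrtf import HRIRSet, analysis_elevation, monaural_gain_map

__all__ = [
    "ZeroEnergyError",
    "extract_ipd",
    "interaural_correlation_at",
    "circular_std",
    "circular_mean",
    "ipd_distractor_ensemble",
    "single_source_channel_cues",
    "ReliabilityMap",
    "GainMap",
    "IACMap",
    "build_reliability_map",
    "build_reliability_map_three_sources",
    "build_iac_map",
    "build_cue_maps",
    "build_gain_map",
    "band_edges",
    "DEFAULT_TARGET_GRID",
    "DEFAULT_DISTRACTOR_GRID",
]

DEFAULT_TARGET_GRID = np.arange(-90.0, 90.0 + 1e-9, 5.0)
DEFAULT_DISTRACTOR_GRID = np.arange(-90.0, 90.0 + 1e-9, 5.0)  # 37 positions
DEFAULT_BAND_HZ = (500.0, 9000.0)
# steady-state analysis window: skips onset ramp plus filter transients,
# stops before the offset ramp
_WINDOW_START_S = 0.030
_WINDOW_END_TRIM_S = 0.005
# circular SD floor (percent of cycle) used when inverting variance
RELIABILITY_SD_CAP_PCT = 0.1


class ZeroEnergyError(ValueError):
    """A channel carried no energy; its IPD is undefined."""


def _restricted_xcorr(left: np.ndarray, right: np.ndarray, max_lag: int):
    """Normalized cross-correlation for lags -max_lag..max_lag.

    Positive lag means the right signal lags the left (right = delayed
    left peaks at a positive lag).
    """
    el = float(np.dot(left, left))
    er = float(np.dot(right, right))
    if el <= 0 or er <= 0:
        raise ZeroEnergyError("silent channel: IPD/correlation undefined")
    c_full = fftconvolve(right, left[::-1])
    center = left.size - 1
    lo = max(center - max_lag, 0)
    hi = min(center + max_lag, c_full.size - 1)
    lags = np.arange(lo - center, hi - center + 1)
    return c_full[lo : hi + 1] / np.sqrt(el * er), lags


def _cosine_peak_interp(c: np.ndarray, i: int, omega: float) -> tuple[float, float]:
    """Sub-sample peak location/height assuming a locally cosine-shaped
    correlation function with carrier ``omega`` rad/sample.

    Exact for pure tones; falls back to no refinement at array edges or
    a vanishing peak sample.
    """
    if i <= 0 or i >= c.size - 1 or abs(c[i]) < 1e-12:
        return 0.0, float(c[i])
    theta = np.arctan2(c[i + 1] - c[i - 1], 2.0 * np.sin(omega) * c[i])
    delta = float(np.clip(theta / omega, -1.0, 1.0))
    height = float(c[i] / max(np.cos(theta), 1e-6))
    return delta, height


def extract_ipd(
    left: np.ndarray,
    right: np.ndarray,
    fc_hz: float,
    fs_hz: float,
    return_corr: bool = False,
):
    """IPD of one narrowband channel pair, in cycles of ``fc_hz``.

    The normalized cross-correlation is maximised over lags restricted
    to +/- half a period of the channel center frequency (phase delays
    are cyclic-ambiguous beyond that), refined to sub-sample precision,
    and converted to a principal-value phase ``lag * fc`` in
    ``(-0.5, 0.5]`` cycles.

    With ``return_corr=True`` also returns the peak lag in seconds and
    the peak normalized correlation.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.size != right.size:
        raise ValueError("channel signals must have equal length")
    if left.size < 3 * fs_hz / fc_hz:
        raise ValueError("signals must span at least 3 periods of fc")
    max_lag = int(np.floor(0.5 * fs_hz / fc_hz)) + 1
    c, lags = _restricted_xcorr(left, right, max_lag)
    i = int(np.argmax(c))
    omega = 2.0 * np.pi * fc_hz / fs_hz
    delta, height = _cosine_peak_interp(c, i, omega)
    lag_s = (lags[i] + delta) / fs_hz
    ipd = lag_s * fc_hz
    ipd = -((0.5 - ipd) % 1.0) + 0.5  # wrap into (-0.5, 0.5]
    if return_corr:
        return float(ipd), float(lag_s), float(min(height, 1.0))
    return float(ipd)


def interaural_correlation_at(
    left: np.ndarray, right: np.ndarray, lag_s: float, fs_hz: float
) -> float:
    """Normalized interaural correlation evaluated at a given delay.

    The correlation function is computed at the integer lags bracketing
    ``lag_s`` and interpolated quadratically.
    """
    lag = lag_s * fs_hz
    k0 = int(round(lag))
    max_lag = abs(k0) + 2
    c, lags = _restricted_xcorr(
        np.asarray(left, dtype=float), np.asarray(right, dtype=float), max_lag
    )
    i = int(np.searchsorted(lags, k0))
    if i <= 0 or i >= c.size - 1:
        return float(c[np.argmin(np.abs(lags - lag))])
    x = lag - k0  # in [-0.5, 0.5]
    y0, y1, y2 = c[i - 1], c[i], c[i + 1]
    val = y1 + 0.5 * x * (y2 - y0) + 0.5 * x * x * (y2 - 2 * y1 + y0)
    return float(np.clip(val, -1.0, 1.0))


def circular_mean(ipds_cycles) -> float:
    """Circular mean of phases given in cycles, principal value."""
    x = np.asarray(ipds_cycles, dtype=float)
    ang = np.angle(np.mean(np.exp(2j * np.pi * x))) / (2.0 * np.pi)
    return float(-((0.5 - ang) % 1.0) + 0.5)


def circular_std(ipds_cycles) -> float:
    """Circular standard deviation of IPD samples, percent of cycle.

    With ``R`` the mean resultant length of the unit phasors,
    ``SD = sqrt(-2 ln R)`` radians, reported as ``100 * SD / (2 pi)``
    percent of a cycle.  ``R`` is capped away from 0 and 1 so the value
    is always finite.
    """
    x = np.asarray(ipds_cycles, dtype=float)
    if x.size == 0:
        raise ValueError("circular_std of an empty sample")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    r = np.abs(np.mean(np.exp(2j * np.pi * x)))
    r = float(np.clip(r, 1e-12, 1.0 - 1e-12))
    sd_rad = np.sqrt(-2.0 * np.log(r))
    return float(100.0 * sd_rad / (2.0 * np.pi))


def _steady_window(n_render: int, fs_hz: float, duration_s: float) -> slice:
    start = int(_WINDOW_START_S * fs_hz)
    stop = int((duration_s - _WINDOW_END_TRIM_S) * fs_hz)
    stop = min(stop, n_render)
    if stop - start < 64:
        raise ValueError("stimulus too short for the steady-state analysis window")
    return slice(start, stop)


def _filtered_channels(wave: BinauralWave, bank: GammatoneBank, window: slice):
    ch_l, ch_r = filter_binaural(wave, bank)
    return ch_l[:, window], ch_r[:, window]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def single_source_channel_cues(
    target_az: float,
    h: HRIRSet,
    bank: GammatoneBank,
    elevation: float | None = None,
    seed: int = 0,
    duration_s: float = 0.1,
):
    """Per-channel (ipd, lag_s, corr) for a lone target source."""
    if elevation is None:
        elevation = analysis_elevation(h)
    stim = make_flat_noise(DEFAULT_BAND_HZ, duration_s, h.fs_hz, seed=seed)
    wave = render_binaural([(target_az, elevation, stim)], h)
    window = _steady_window(wave.left.size, h.fs_hz, duration_s)
    ch_l, ch_r = _filtered_channels(wave, bank, window)
    out = [
        extract_ipd(ch_l[k], ch_r[k], bank.center_freqs_hz[k], bank.fs_hz, return_corr=True)
        for k in range(bank.n_channels)
    ]
    ipd, lag, corr = map(np.array, zip(*out))
    return ipd, lag, corr


def _ensemble_cues(
    target_az: float,
    h: HRIRSet,
    bank: GammatoneBank,
    configs,
    elevation: float,
    seed: int,
    duration_s: float,
    n_realizations: int,
    target_lags_s: np.ndarray | None = None,
):
    """IPD matrix (channels x configs) and, if ``target_lags_s`` given,
    the matching interaural-correlation matrix evaluated at those lags.

    ``configs`` is a sequence of tuples of distractor azimuths (possibly
    empty).  Target and distractor tokens are independent equal-level
    noises; with ``n_realizations > 1`` the per-config IPD is the
    circular mean over fresh noise draws (correlations are averaged).
    """
    n_ch = bank.n_channels
    n_cfg = len(configs)
    fs = h.fs_hz
    seeds = _child_seeds(seed, n_realizations * (1 + sum(len(c) for c in configs)))
    seed_iter = iter(seeds.tolist())

    ipd_acc = np.zeros((n_ch, n_cfg), dtype=complex)
    iac_acc = np.zeros((n_ch, n_cfg))
    for _ in range(n_realizations):
        t_stim = make_flat_noise(DEFAULT_BAND_HZ, duration_s, fs, seed=next(seed_iter))
        t_wave = render_binaural([(target_az, elevation, t_stim)], h)
        window = _steady_window(t_wave.left.size, fs, duration_s)
        t_l, t_r = _filtered_channels(t_wave, bank, window)
        for j, cfg in enumerate(configs):
            sum_l, sum_r = t_l.copy(), t_r.copy()
            for d_az in cfg:
                d_stim = make_flat_noise(DEFAULT_BAND_HZ, duration_s, fs, seed=next(seed_iter))
                d_wave = render_binaural([(d_az, elevation, d_stim)], h)
                d_l, d_r = _filtered_channels(d_wave, bank, window)
                sum_l += d_l
                sum_r += d_r
            for k in range(n_ch):
                ipd = extract_ipd(sum_l[k], sum_r[k], bank.center_freqs_hz[k], fs)
                ipd_acc[k, j] += np.exp(2j * np.pi * ipd)
                if target_lags_s is not None:
                    iac_acc[k, j] += interaural_correlation_at(
                        sum_l[k], sum_r[k], target_lags_s[k], fs
                    )
    ipd = np.angle(ipd_acc) / (2.0 * np.pi)
    ipd = -((0.5 - ipd) % 1.0) + 0.5
    if target_lags_s is None:
        return ipd, None
    return ipd, iac_acc / n_realizations


def ipd_distractor_ensemble(
    target_az: float,
    h: HRIRSet,
    bank: GammatoneBank,
    distractor_azimuths=None,
    elevation: float | None = None,
    seed: int = 0,
    duration_s: float = 0.1,
    n_realizations: int = 1,
) -> np.ndarray:
    """IPD estimates under a second source at each distractor position.

    Returns a ``(n_channels, n_configs)`` matrix; the default distractor
    grid spans the frontal hemisphere, -90..90 deg in 5 deg steps
    (37 positions) at the analysis elevation.
    """
    if distractor_azimuths is None:
        distractor_azimuths = DEFAULT_DISTRACTOR_GRID
    if elevation is None:
        elevation = analysis_elevation(h)
    configs = [(float(d),) for d in np.asarray(distractor_azimuths, dtype=float)]
    ipd, _ = _ensemble_cues(
        target_az, h, bank, configs, elevation, seed, duration_s, n_realizations
    )
    return ipd


@dataclass
class ReliabilityMap:
    """Circular IPD spread and its inverse-variance reliability,
    target location x frequency channel."""

    target_azimuths_deg: np.ndarray
    channel_fcs_hz: np.ndarray
    circ_std_pct_cycle: np.ndarray  # (n_targets, n_channels)
    reliability_norm: np.ndarray    # max over channels = 1 per target
    meta: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name, mat in (
            ("circ_std_pct_cycle", self.circ_std_pct_cycle),
            ("reliability_norm", self.reliability_norm),
        ):
            t, c = np.meshgrid(self.target_azimuths_deg, self.channel_fcs_hz, indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "target_azimuth": t.ravel(),
                        "channel_fc": c.ravel(),
                        "statistic": name,
                        "value": mat.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def profile_at(self, target_az: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.target_azimuths_deg - target_az)))
        return self.reliability_norm[i]


@dataclass
class GainMap:
    """Head-filter intensity gain (mean of the two ears, dB) and its
    two normalized variants."""

    target_azimuths_deg: np.ndarray
    channel_fcs_hz: np.ndarray
    gain_db: np.ndarray
    gain_norm_per_location: np.ndarray
    gain_norm_freq_then_location: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        t, c = np.meshgrid(self.target_azimuths_deg, self.channel_fcs_hz, indexing="ij")
        frames = []
        for name, mat in (
            ("gain_db", self.gain_db),
            ("gain_norm_per_location", self.gain_norm_per_location),
            ("gain_norm_freq_then_location", self.gain_norm_freq_then_location),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "target_azimuth": t.ravel(),
                        "channel_fc": c.ravel(),
                        "statistic": name,
                        "value": mat.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class IACMap:
    """Mean interaural correlation at the target's delay under
    concurrent-source ensembles."""

    target_azimuths_deg: np.ndarray
    channel_fcs_hz: np.ndarray
    mean_iac: np.ndarray
    single_source_iac: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        t, c = np.meshgrid(self.target_azimuths_deg, self.channel_fcs_hz, indexing="ij")
        return pd.DataFrame(
            {
                "target_azimuth": t.ravel(),
                "channel_fc": c.ravel(),
                "statistic": "mean_iac",
                "value": self.mean_iac.ravel(),
            }
        )


def _reliability_from_sd(sd_pct: np.ndarray, cap_pct: float = RELIABILITY_SD_CAP_PCT):
    """1/variance reliability with the SD floored at ``cap_pct`` % cycle
    (keeps zero-variance cells finite without reordering others)."""
    raw = 1.0 / np.maximum(sd_pct, cap_pct) ** 2
    norm = raw / raw.max(axis=1, keepdims=True)
    return raw, norm


def build_cue_maps(
    h: HRIRSet,
    bank: GammatoneBank,
    target_azimuths=None,
    distractor_azimuths=None,
    seed: int = 0,
    elevation: float | None = None,
    duration_s: float = 0.1,
    n_realizations: int = 1,
) -> tuple[ReliabilityMap, IACMap]:
    """Reliability and interaural-correlation maps from one shared
    concurrent-source ensemble (the expensive renders are reused)."""
    if target_azimuths is None:
        target_azimuths = DEFAULT_TARGET_GRID
    if distractor_azimuths is None:
        distractor_azimuths = DEFAULT_DISTRACTOR_GRID
    target_azimuths = np.asarray(target_azimuths, dtype=float)
    distractor_azimuths = np.asarray(distractor_azimuths, dtype=float)
    if elevation is None:
        elevation = analysis_elevation(h)

    n_t = target_azimuths.size
    n_ch = bank.n_channels
    sd = np.empty((n_t, n_ch))
    iac = np.empty((n_t, n_ch))
    iac0 = np.empty((n_t, n_ch))
    seeds = _child_seeds(seed, 2 * n_t)
    configs = [(float(d),) for d in distractor_azimuths]
    for i, az in enumerate(target_azimuths):
        _, lag0, corr0 = single_source_channel_cues(
            az, h, bank, elevation, seed=int(seeds[2 * i]), duration_s=duration_s
        )
        iac0[i] = corr0
        ipd, iac_i = _ensemble_cues(
            az,
            h,
            bank,
            configs,
            elevation,
            int(seeds[2 * i + 1]),
            duration_s,
            n_realizations,
            target_lags_s=lag0,
        )
        sd[i] = [circular_std(ipd[k]) for k in range(n_ch)]
        iac[i] = iac_i.mean(axis=1)

    _, norm = _reliability_from_sd(sd)
    meta = {
        "seed": int(seed),
        "elevation_deg": float(elevation),
        "n_configs": len(configs),
        "n_realizations": int(n_realizations),
    }
    rmap = ReliabilityMap(target_azimuths, bank.center_freqs_hz.copy(), sd, norm, meta)
    imap = IACMap(target_azimuths, bank.center_freqs_hz.copy(), iac, iac0, dict(meta))
    return rmap, imap


def build_reliability_map(
    h: HRIRSet,
    bank: GammatoneBank,
    target_azimuths=None,
    distractor_azimuths=None,
    seed: int = 0,
    elevation: float | None = None,
    duration_s: float = 0.1,
    n_realizations: int = 1,
) -> ReliabilityMap:
    """IPD reliability (inverse circular variance, normalized within
    each target location) over the two-source ensemble."""
    rmap, _ = build_cue_maps(
        h,
        bank,
        target_azimuths,
        distractor_azimuths,
        seed,
        elevation,
        duration_s,
        n_realizations,
    )
    return rmap


def build_iac_map(
    h: HRIRSet,
    bank: GammatoneBank,
    target_azimuths=None,
    distractor_azimuths=None,
    seed: int = 0,
    elevation: float | None = None,
    duration_s: float = 0.1,
) -> IACMap:
    """Mean interaural correlation at the target's single-source delay,
    averaged over distractor positions."""
    _, imap = build_cue_maps(
        h, bank, target_azimuths, distractor_azimuths, seed, elevation, duration_s
    )
    return imap


def default_distractor_pairs(step_deg: float = 15.0):
    """All unordered pairs from a coarse -90..90 grid (78 pairs at the
    default 15 deg spacing)."""
    grid = np.arange(-90.0, 90.0 + 1e-9, step_deg)
    return [tuple(p) for p in itertools.combinations(grid.tolist(), 2)]


def build_reliability_map_three_sources(
    h: HRIRSet,
    bank: GammatoneBank,
    target_azimuths=None,
    distractor_pairs=None,
    seed: int = 0,
    elevation: float | None = None,
    duration_s: float = 0.1,
) -> ReliabilityMap:
    """IPD reliability with two concurrent distractors per scene."""
    if target_azimuths is None:
        target_azimuths = DEFAULT_TARGET_GRID
    if distractor_pairs is None:
        distractor_pairs = default_distractor_pairs()
    target_azimuths = np.asarray(target_azimuths, dtype=float)
    if elevation is None:
        elevation = analysis_elevation(h)
    n_t = target_azimuths.size
    n_ch = bank.n_channels
    sd = np.empty((n_t, n_ch))
    seeds = _child_seeds(seed, n_t)
    for i, az in enumerate(target_azimuths):
        ipd, _ = _ensemble_cues(
            az, h, bank, list(distractor_pairs), elevation, int(seeds[i]), duration_s, 1
        )
        sd[i] = [circular_std(ipd[k]) for k in range(n_ch)]
    _, norm = _reliability_from_sd(sd)
    meta = {"seed": int(seed), "elevation_deg": float(elevation), "n_configs": len(distractor_pairs)}
    return ReliabilityMap(target_azimuths, bank.center_freqs_hz.copy(), sd, norm, meta)


def _minmax(x: np.ndarray, axis: int) -> np.ndarray:
    lo = x.min(axis=axis, keepdims=True)
    rng = x.max(axis=axis, keepdims=True) - lo
    return (x - lo) / np.where(rng > 0, rng, 1.0)


def gain_normalizations(gain_db: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two gain scalings used as tuning predictors.

    ``per_location``: min-max over frequency at each location (axis 1).
    ``freq_then_location``: min-max over locations at each frequency,
    then over frequency at each location — the relative-gain cue.
    Input is (n_locations, n_frequencies) in dB.
    """
    gain_db = np.asarray(gain_db, dtype=float)
    per_location = _minmax(gain_db, axis=1)
    freq_then_location = _minmax(_minmax(gain_db, axis=0), axis=1)
    return per_location, freq_then_location


def build_gain_map(
    h: HRIRSet,
    freqs_hz=None,
    target_azimuths=None,
    elevation: float | None = None,
) -> GainMap:
    """Average-of-ears intensity gain map with both normalizations.

    ``gain_norm_per_location`` is min-max scaled over frequency at each
    location; ``gain_norm_freq_then_location`` is first min-max scaled
    over locations at each frequency, then over frequency at each
    location (relative-gain cue).
    """
    if freqs_hz is None:
        freqs_hz = np.arange(1000.0, 8000.0 + 1e-9, 200.0)
    if target_azimuths is None:
        target_azimuths = DEFAULT_TARGET_GRID
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    target_azimuths = np.asarray(target_azimuths, dtype=float)
    if elevation is None:
        elevation = analysis_elevation(h)
    gl, gr = monaural_gain_map(h, freqs_hz)
    ie = int(np.argmin(np.abs(h.elevations_deg - elevation)))
    rows = [int(np.argmin(np.abs(h.azimuths_deg - az))) for az in target_azimuths]
    gain_db = 0.5 * (gl[rows, ie, :] + gr[rows, ie, :])
    per_loc, freq_then_loc = gain_normalizations(gain_db)
    return GainMap(
        target_azimuths,
        freqs_hz,
        gain_db,
        per_loc,
        freq_then_loc,
        meta={"elevation_deg": float(elevation)},
    )


def save_maps_h5(path, **maps) -> None:
    """Write any of the map objects as HDF5 matrices, one group per
    keyword (grids as `/targets`, `/channels`; matrices by field name)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, m in maps.items():
            g = f.create_group(name)
            g.create_dataset("targets", data=m.target_azimuths_deg)
            g.create_dataset("channels", data=m.channel_fcs_hz)
            for field_name in (
                "circ_std_pct_cycle",
                "reliability_norm",
                "gain_db",
                "gain_norm_per_location",
                "gain_norm_freq_then_location",
                "mean_iac",
                "single_source_iac",
            ):
                if hasattr(m, field_name):
                    g.create_dataset(field_name, data=getattr(m, field_name))


def band_edges(freqs_hz, profile, threshold_fraction: float = 0.5) -> tuple[float, float]:
    """Lowest/highest grid frequency whose value exceeds
    ``threshold_fraction`` of the profile maximum (no interpolation)."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if np.any(profile < 0):
        raise ValueError("profile must be non-negative")
    if profile.max() <= 0:
        raise ValueError("profile has no positive values")
    if threshold_fraction >= 1.0:
        raise ValueError("threshold_fraction must be < 1")
    mask = profile > threshold_fraction * profile.max()
    idx = np.nonzero(mask)[0]
    return float(freqs_hz[idx[0]]), float(freqs_hz[idx[-1]])
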