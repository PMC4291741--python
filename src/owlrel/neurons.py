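"""Synthetic ICx / ICCc neurons and the stimulation protocols.

This module is a test harness, not a mechanistic claim: it generates
spike-count data with known ground truth so the analysis stages can be
validated end to end.  An ICx cell is modelled as a weighted sum of
narrowband cross-correlator inputs — channel ``k`` contributes
``w_k cos(2 pi f_k (ITD - best_itd))`` — half-wave rectified and scaled
to a peak rate; side peaks emerge naturally from partial channel
convergence.  Setting the channel weights to the IPD-reliability
profile at the neuron's preferred direction embodies the
weighting-by-reliability hypothesis, and recovering that structure with
the analysis code is the package's closed-loop check.  An ICCc cell is
a single narrowband channel with von-Mises IPD tuning, driven by the
IPD actually extracted from rendered free-field scenes.

Spike counts are Poisson in every protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binaural import GammatoneBank, make_flat_noise, render_binaural
from .cues import DEFAULT_BAND_HZ, _steady_window, extract_ipd, single_source_channel_cues
from .hrtf import HeadModelParams, HRIRSet, analysis_elevation, itd_us_to_azimuth
from .binaural import filter_binaural
from .tuning import RateCurve

__all__ = [
    "SimNeuronParams",
    "PROTOCOLS",
    "simulate_icx_rate",
    "simulate_counts",
    "simulate_population",
    "simulate_iccc_spatial_tuning",
]

STIM_DURATION_S = 0.1  # spike-count window = stimulus duration


@dataclass
class SimNeuronParams:
    """Generative description of one synthetic midbrain neuron."""

    best_itd_us: float
    channel_weights: np.ndarray  # non-negative, sums to 1 (ICx)
    peak_rate_hz: float = 100.0
    baseline_rate_hz: float = 5.0
    trials: int = 20
    seed: int = 0
    kind: str = "ICx"            # "ICx" | "ICCc"
    bf_hz: float | None = None   # ICCc only
    ipd_kappa: float = 4.0       # ICCc von-Mises concentration
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        if np.any(self.channel_weights < 0):
            raise ValueError("channel weights must be non-negative")
        s = self.channel_weights.sum()
        if s <= 0:
            raise ValueError("channel weights must not be all zero")
        self.channel_weights = self.channel_weights / s
        if self.peak_rate_hz < 0 or self.baseline_rate_hz < 0:
            raise ValueError("rates must be non-negative")


def _broadband_itd_rate(p: SimNeuronParams, fcs_hz: np.ndarray, itd_us: np.ndarray) -> np.ndarray:
    dt = (itd_us - p.best_itd_us) * 1e-6
    drive = np.sum(
        p.channel_weights[None, :] * np.cos(2 * np.pi * fcs_hz[None, :] * dt[:, None]),
        axis=1,
    )
    return p.baseline_rate_hz + p.peak_rate_hz * np.maximum(drive, 0.0)


def _tone_weight(p: SimNeuronParams, fcs_hz: np.ndarray, freq_hz: np.ndarray) -> np.ndarray:
    w = np.interp(freq_hz, fcs_hz, p.channel_weights, left=0.0, right=0.0)
    return w / p.channel_weights.max()


def simulate_icx_rate(p: SimNeuronParams, fcs_hz, stimulus: dict) -> np.ndarray:
    """Expected (noise-free) firing rate of an ICx cell.

    ``stimulus`` is ``{"kind": ..., ...}`` with kinds:

    * ``broadband_itd``: key ``itd_us`` — the cross-correlator sum.
    * ``tone_frequency``: key ``freq_hz`` — rate follows the channel
      weight at the stimulating frequency (tones at the best ITD).
    * ``tonal_itd``: keys ``itd_us``, ``freq_hz`` — single-channel
      cosine ITD tuning at the stimulating frequency.
    """
    fcs_hz = np.asarray(fcs_hz, dtype=float)
    kind = stimulus.get("kind")
    if kind == "broadband_itd":
        return _broadband_itd_rate(p, fcs_hz, np.atleast_1d(np.asarray(stimulus["itd_us"], float)))
    if kind == "tone_frequency":
        w = _tone_weight(p, fcs_hz, np.atleast_1d(np.asarray(stimulus["freq_hz"], float)))
        return p.baseline_rate_hz + p.peak_rate_hz * w
    if kind == "tonal_itd":
        f0 = float(stimulus["freq_hz"])
        itd = np.atleast_1d(np.asarray(stimulus["itd_us"], float))
        w = float(_tone_weight(p, fcs_hz, np.array([f0]))[0])
        drive = np.maximum(np.cos(2 * np.pi * f0 * (itd - p.best_itd_us) * 1e-6), 0.0)
        return p.baseline_rate_hz + p.peak_rate_hz * w * drive
    raise ValueError(f"unknown stimulus kind: {kind!r}")


def _protocol_grid(protocol: str, f0_hz: float | None, fcs_hz=None):
    if protocol == "broadband_itd":
        return "itd_us", np.arange(-300.0, 300.0 + 1e-9, 30.0), 5
    if protocol == "tone_frequency":
        # tones presented at each filterbank channel frequency
        return "frequency_hz", np.asarray(fcs_hz, dtype=float).copy(), 20
    if protocol == "tonal_itd":
        if f0_hz is None:
            raise ValueError("tonal_itd protocol needs a stimulating frequency")
        period_us = 1e6 / f0_hz
        return "itd_us", np.linspace(-1.5 * period_us, 1.5 * period_us, 21), 20
    raise ValueError(f"unknown protocol: {protocol!r}")


PROTOCOLS = ("broadband_itd", "tone_frequency", "tonal_itd")


def simulate_counts(
    p: SimNeuronParams,
    protocol: str,
    fcs_hz,
    f0_hz: float | None = None,
    trials: int | None = None,
) -> RateCurve:
    """Poisson spike counts under one of the standard protocols.

    Broadband ITD: -300..300 us in 30 us steps, 5 trials.  Tones at the
    best ITD: one tone per filterbank channel (1-8 kHz in 200 Hz steps
    with the default bank), 20 trials.  Tonal ITD: three periods of the
    stimulating frequency over 21 ITDs, 20 trials.  Deterministic in
    ``p.seed``.
    """
    axis, grid, default_trials = _protocol_grid(protocol, f0_hz, fcs_hz)
    trials = int(trials if trials is not None else (p.trials or default_trials))
    stim = {"kind": protocol}
    if axis == "itd_us":
        stim["itd_us"] = grid
    else:
        stim["freq_hz"] = grid
    if protocol == "tonal_itd":
        stim["freq_hz"] = f0_hz
    rates = simulate_icx_rate(p, fcs_hz, stim)
    rng = np.random.default_rng(p.seed)
    counts = rng.poisson(rates * STIM_DURATION_S, size=(trials, grid.size))
    return RateCurve(
        axis_name=axis,
        stimulus=grid,
        counts=counts,
        duration_s=STIM_DURATION_S,
        spontaneous_rate_hz=p.baseline_rate_hz,
        meta={"protocol": protocol, "f0_hz": f0_hz, "kind": p.kind},
    )


def simulate_population(
    reliability_map,
    head_params: HeadModelParams,
    n_neurons: int = 100,
    trials: int = 20,
    seed: int = 0,
    shuffle_locations: bool = False,
):
    """A population of ICx cells weighted by the reliability map.

    Best ITDs are sampled uniformly over 0-250 us; each neuron's
    preferred azimuth follows from the head model's own delay law, and
    its channel weights are the normalized reliability profile at that
    azimuth.  ``shuffle_locations=True`` breaks the ITD-to-profile
    pairing (a null model in which frequency weighting is unrelated to
    preferred direction).

    Returns a list of ``(SimNeuronParams, {"tone_frequency": RateCurve,
    "broadband_itd": RateCurve})``.
    """
    if n_neurons < 10:
        raise ValueError("population needs at least 10 neurons")
    rng = np.random.default_rng(seed)
    best_itds = rng.uniform(0.0, 250.0, size=n_neurons)
    azimuths = itd_us_to_azimuth(head_params, best_itds)
    loc_idx = np.array(
        [
            int(np.argmin(np.abs(reliability_map.target_azimuths_deg - az)))
            for az in azimuths
        ]
    )
    if shuffle_locations:
        loc_idx = rng.permutation(loc_idx)
    fcs = reliability_map.channel_fcs_hz
    population = []
    for i in range(n_neurons):
        weights = reliability_map.reliability_norm[loc_idx[i]]
        p = SimNeuronParams(
            best_itd_us=float(best_itds[i]),
            channel_weights=weights,
            trials=trials,
            seed=int(rng.integers(0, 2**31 - 1)),
            meta={
                "azimuth_deg": float(azimuths[i]),
                "map_location_index": int(loc_idx[i]),
            },
        )
        curves = {
            "tone_frequency": simulate_counts(p, "tone_frequency", fcs, trials=trials),
            "broadband_itd": simulate_counts(p, "broadband_itd", fcs, trials=5),
        }
        population.append((p, curves))
    return population


def simulate_iccc_spatial_tuning(
    p: SimNeuronParams,
    h: HRIRSet,
    bank: GammatoneBank,
    preferred_azimuth_deg: float,
    speaker_azimuths=None,
    concurrent_offsets_deg=None,
    seed: int = 0,
    trials: int = 20,
):
    """Free-field spatial tuning of a narrowband ICCc cell, alone and
    with one concurrent broadband source.

    The cell reads the IPD extracted from the rendered scene in its
    single best-frequency channel and responds with von-Mises IPD
    tuning centred on the IPD of its preferred direction.  The speaker
    array covers +/-100 deg in 10 deg steps (21 speakers); concurrent
    sources sit within +/-90 deg of the preferred location in 20 deg
    steps.

    Returns ``(single RateCurve, list of concurrent RateCurves)``.
    """
    if p.bf_hz is None:
        raise ValueError("ICCc simulation needs bf_hz")
    if not bank.center_freqs_hz[0] <= p.bf_hz <= bank.center_freqs_hz[-1]:
        raise ValueError("bf_hz outside the filterbank range")
    if speaker_azimuths is None:
        speaker_azimuths = np.arange(-100.0, 100.0 + 1e-9, 10.0)
    if concurrent_offsets_deg is None:
        concurrent_offsets_deg = np.arange(-90.0, 90.0 + 1e-9, 20.0)
    speaker_azimuths = np.asarray(speaker_azimuths, dtype=float)
    elevation = analysis_elevation(h)
    k = int(np.argmin(np.abs(bank.center_freqs_hz - p.bf_hz)))
    fc = bank.center_freqs_hz[k]

    rng = np.random.default_rng(seed)
    ipd0, _, _ = single_source_channel_cues(
        preferred_azimuth_deg, h, bank, elevation, seed=int(rng.integers(2**31))
    )
    pref_ipd = ipd0[k]

    def channel_ipd(sources) -> float:
        wave = render_binaural(sources, h)
        window = _steady_window(wave.left.size, h.fs_hz, STIM_DURATION_S)
        ch_l, ch_r = filter_binaural(wave, bank, channels=[k])
        return extract_ipd(ch_l[0, window], ch_r[0, window], fc, bank.fs_hz)

    def rate_from_ipd(ipd: float) -> float:
        tune = np.exp(p.ipd_kappa * (np.cos(2 * np.pi * (ipd - pref_ipd)) - 1.0))
        return p.baseline_rate_hz + p.peak_rate_hz * tune

    def curve(concurrent_az: float | None) -> RateCurve:
        rates = np.empty(speaker_azimuths.size)
        for i, az in enumerate(speaker_azimuths):
            sources = [
                (az, elevation, make_flat_noise(DEFAULT_BAND_HZ, STIM_DURATION_S, h.fs_hz, seed=int(rng.integers(2**31))))
            ]
            if concurrent_az is not None:
                sources.append(
                    (
                        concurrent_az,
                        elevation,
                        make_flat_noise(DEFAULT_BAND_HZ, STIM_DURATION_S, h.fs_hz, seed=int(rng.integers(2**31))),
                    )
                )
            rates[i] = rate_from_ipd(channel_ipd(sources))
        counts = rng.poisson(rates * STIM_DURATION_S, size=(trials, rates.size))
        return RateCurve(
            axis_name="azimuth_deg",
            stimulus=speaker_azimuths,
            counts=counts,
            duration_s=STIM_DURATION_S,
            spontaneous_rate_hz=p.baseline_rate_hz,
            meta={"concurrent_az": concurrent_az, "bf_hz": float(fc)},
        )

    single = curve(None)
    az_lo, az_hi = speaker_azimuths[0], speaker_azimuths[-1]
    concurrent = [
        curve(float(np.clip(preferred_azimuth_deg + off, az_lo, az_hi)))
        for off in np.asarray(concurrent_offsets_deg, dtype=float)
    ]
    return single, concurrent
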