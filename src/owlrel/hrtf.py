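"""Parametric owl head-filter (HRIR) sets.

Real owl head-related transfer functions are direction-dependent linear
filters produced by the facial ruff and ear canals.  Two of their gross
properties drive everything downstream in this package:

* the interaural delay grows monotonically with source azimuth, up to
  roughly a quarter of a millisecond at the most lateral directions;
* the frontal-vs-peripheral intensity-gain contrast grows with
  frequency (directionality is weak near 1 kHz and strong near 8 kHz,
  where the facial ruff forms a narrow frontal beam); and
* the *direction* of maximal gain migrates with frequency: only the
  highest frequencies are boosted straight ahead, while at middle
  frequencies the gain maximum sits at progressively more lateral
  azimuths.  This migration is what makes the most reliable interaural
  phase channel slide from high frequencies for frontal targets toward
  low frequencies for peripheral targets.

This module generates impulse-response grids with exactly those
properties from a handful of interpretable parameters, and provides the
per-location monaural gain and acoustic-axis computations used to align
and analyse them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "HeadModelParams",
    "HRIRSet",
    "generate_hrir_set",
    "monaural_gain_map",
    "compute_acoustic_axis",
    "analysis_elevation",
    "azimuth_to_itd_us",
    "itd_us_to_azimuth",
    "save_hrir_set",
    "load_hrir_set",
    "load_sofa",
    "AmbiguousAxisError",
]

# reference frequencies anchoring the gain model (Hz)
_F_LOBE_REF = 1000.0   # lobe width is specified at this frequency
_F_BOOST_REF = 8000.0  # frontal boost reaches its full value here
_F_LOBE_FLOOR = 500.0  # below this the lobe stops widening (near-omni)


@dataclass(frozen=True)
class HeadModelParams:
    """Generative parameters of the synthetic owl head.

    Parameters
    ----------
    max_itd_us:
        Interaural delay magnitude at +/-90 deg azimuth, microseconds.
    frontal_boost_db:
        On-axis vs far-off-axis gain contrast at 8 kHz (the lobe depth
        scales linearly with frequency, ~0 dB at very low frequencies).
    lobe_width_deg_at_1khz:
        Half-width at half-depth of the gain lobe at 1 kHz, degrees.
    lobe_narrowing_exponent:
        The lobe half-width shrinks as ``(f / 1 kHz) ** -exponent``.
    gain_ring_azimuth_deg_at_1khz:
        Azimuth of the gain maximum at 1 kHz, degrees.  The maximum
        migrates toward the midline as
        ``ring(f) = ring_1khz * (1 kHz / f) ** migration_exponent``,
        reaching the frontal beam at the top of the hearing range.
    gain_ring_migration_exponent:
        Exponent of the ring migration law above.
    jitter_fraction:
        Relative scale of multiplicative inter-individual parameter
        jitter; 0 gives the canonical head, ~0.1 emulates the spread
        between individual owls.
    axis_elevation_offset_deg:
        Vertical displacement of the two ear axes (left up, right down),
        mimicking the owl's vertically asymmetric ears.
    """

    max_itd_us: float = 250.0
    frontal_boost_db: float = 20.0
    lobe_width_deg_at_1khz: float = 120.0
    lobe_narrowing_exponent: float = 0.9
    gain_ring_azimuth_deg_at_1khz: float = 60.0
    gain_ring_migration_exponent: float = 1.0
    sample_rate_hz: float = 48000.0
    hrir_length_samples: int = 256
    jitter_fraction: float = 0.0
    axis_elevation_offset_deg: float = 7.0

    def __post_init__(self) -> None:
        if not self.max_itd_us > 0:
            raise ValueError("max_itd_us must be positive")
        if self.hrir_length_samples < 64:
            raise ValueError("hrir_length_samples must be >= 64")
        if not 0.0 <= self.jitter_fraction <= 1.0:
            raise ValueError("jitter_fraction must lie in [0, 1]")
        if not self.lobe_width_deg_at_1khz > 0:
            raise ValueError("lobe widths must be positive")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample rate must be positive")


@dataclass
class HRIRSet:
    """A grid of left/right head-related impulse responses.

    ``left`` and ``right`` have shape ``(n_azimuths, n_elevations,
    n_taps)``; azimuth/elevation grids are strictly increasing, degrees.
    """

    azimuths_deg: np.ndarray
    elevations_deg: np.ndarray
    fs_hz: float
    left: np.ndarray
    right: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.azimuths_deg = np.asarray(self.azimuths_deg, dtype=float)
        self.elevations_deg = np.asarray(self.elevations_deg, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if np.any(np.diff(self.azimuths_deg) <= 0) or np.any(
            np.diff(self.elevations_deg) <= 0
        ):
            raise ValueError("grids must be strictly increasing")
        expected = (
            self.azimuths_deg.size,
            self.elevations_deg.size,
            self.left.shape[-1],
        )
        if self.left.shape != expected or self.right.shape != expected:
            raise ValueError("impulse-response arrays do not match grids")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("impulse responses must be finite")

    @property
    def n_taps(self) -> int:
        return self.left.shape[-1]

    def nearest_index(self, azimuth_deg: float, elevation_deg: float) -> tuple[int, int]:
        """Indices of the grid node nearest to a requested direction.

        Raises ``ValueError`` if the direction falls outside the grid
        hull (beyond half a grid step past either end).
        """
        for value, grid, name in (
            (azimuth_deg, self.azimuths_deg, "azimuth"),
            (elevation_deg, self.elevations_deg, "elevation"),
        ):
            step = np.max(np.diff(grid)) if grid.size > 1 else 0.0
            if value < grid[0] - step / 2 or value > grid[-1] + step / 2:
                raise ValueError(
                    f"{name} {value} deg outside HRIR grid "
                    f"[{grid[0]}, {grid[-1]}]"
                )
        ia = int(np.argmin(np.abs(self.azimuths_deg - azimuth_deg)))
        ie = int(np.argmin(np.abs(self.elevations_deg - elevation_deg)))
        return ia, ie

    def ir_pair(self, azimuth_deg: float, elevation_deg: float) -> tuple[np.ndarray, np.ndarray]:
        ia, ie = self.nearest_index(azimuth_deg, elevation_deg)
        return self.left[ia, ie], self.right[ia, ie]


class AmbiguousAxisError(ValueError):
    """Raised when a gain surface is flat and has no acoustic axis."""


def azimuth_to_itd_us(params: HeadModelParams, azimuth_deg) -> np.ndarray:
    """Interaural delay law of the head model: ``ITD = max_itd * sin(az)``.

    Positive azimuth (owl's right) gives positive ITD (right ear leads).
    """
    return params.max_itd_us * np.sin(np.deg2rad(np.asarray(azimuth_deg, dtype=float)))


def itd_us_to_azimuth(params: HeadModelParams, itd_us) -> np.ndarray:
    """Inverse of the delay law, clipped to +/-90 deg."""
    x = np.clip(np.asarray(itd_us, dtype=float) / params.max_itd_us, -1.0, 1.0)
    return np.rad2deg(np.arcsin(x))


def _jittered(params: HeadModelParams, rng: np.random.Generator) -> HeadModelParams:
    if params.jitter_fraction == 0:
        return params
    j = params.jitter_fraction

    def mul(x: float) -> float:
        return float(x * (1.0 + j * rng.uniform(-1.0, 1.0)))

    return dataclasses.replace(
        params,
        max_itd_us=mul(params.max_itd_us),
        frontal_boost_db=mul(params.frontal_boost_db),
        lobe_width_deg_at_1khz=mul(params.lobe_width_deg_at_1khz),
        lobe_narrowing_exponent=mul(params.lobe_narrowing_exponent),
        gain_ring_azimuth_deg_at_1khz=mul(params.gain_ring_azimuth_deg_at_1khz),
        axis_elevation_offset_deg=mul(params.axis_elevation_offset_deg),
    )


def _gain_linear(
    params: HeadModelParams,
    freqs_hz: np.ndarray,
    az_deg: np.ndarray,
    el_deg: np.ndarray,
    ear: str,
) -> np.ndarray:
    """Linear gain surface, shape (n_az, n_el, n_freq).

    The gain maximum of each frequency sits on a ring of azimuths
    ``+/- ring(f)`` that migrates from lateral directions at low
    frequencies to the frontal beam at high frequencies; gain is 0 dB
    on the ring and falls to ``-D(f)`` far off it, with a von-Mises-
    like profile whose half-width narrows as a power law of frequency.
    ``D(f)`` ramps linearly with frequency up to ``frontal_boost_db``
    at 8 kHz.  The ears share the azimuthal pattern but their axes are
    displaced vertically in opposite directions.
    """
    f = np.asarray(freqs_hz, dtype=float)
    depth_db = params.frontal_boost_db * np.clip(f / _F_BOOST_REF, 0.0, 1.0)
    width_deg = params.lobe_width_deg_at_1khz * (
        np.maximum(f, _F_LOBE_FLOOR) / _F_LOBE_REF
    ) ** (-params.lobe_narrowing_exponent)
    width_rad = np.deg2rad(np.clip(width_deg, 1.0, 179.0))
    kappa = np.log(2.0) / (1.0 - np.cos(width_rad))  # half depth at half width
    ring_deg = params.gain_ring_azimuth_deg_at_1khz * (
        _F_LOBE_REF / np.maximum(f, _F_LOBE_FLOOR)
    ) ** params.gain_ring_migration_exponent

    el_axis = params.axis_elevation_offset_deg * (1 if ear == "left" else -1)
    # angular distance to the nearest ring point, small-angle composition
    # of the azimuthal offset from the ring and the elevation offset
    d_az = np.abs(np.abs(az_deg)[:, None, None] - ring_deg[None, None, :])
    d_el = np.abs(el_deg - el_axis)[None, :, None]
    delta = np.deg2rad(np.minimum(np.sqrt(d_az**2 + d_el**2), 180.0))

    lobe = np.exp(kappa[None, None, :] * (np.cos(delta) - 1.0))
    gain_db = depth_db[None, None, :] * (lobe - 1.0)
    return 10.0 ** (gain_db / 20.0)


def generate_hrir_set(
    params: HeadModelParams,
    seed: int,
    azimuths_deg: np.ndarray | None = None,
    elevations_deg: np.ndarray | None = None,
) -> HRIRSet:
    """Generate a synthetic HRIR grid.

    Impulse responses are synthesised in the frequency domain as a
    smooth direction- and frequency-dependent magnitude times a linear
    phase encoding a fractional-sample interaural delay (band-limited,
    so delays are not quantised to the sample grid), then inverted to a
    common-length FIR pair per location.  A bulk delay of a quarter of
    the IR length keeps the responses causal.

    The same ``seed`` always returns a bit-identical set; with
    ``jitter_fraction > 0`` the seed selects the individual "owl".
    """
    if azimuths_deg is None:
        azimuths_deg = np.arange(-160.0, 160.0 + 1e-9, 5.0)
    if elevations_deg is None:
        elevations_deg = np.arange(-40.0, 40.0 + 1e-9, 10.0)
    azimuths_deg = np.asarray(azimuths_deg, dtype=float)
    elevations_deg = np.asarray(elevations_deg, dtype=float)
    if azimuths_deg[0] > -100.0 or azimuths_deg[-1] < 100.0:
        raise ValueError("azimuth grid must cover at least -100..+100 deg")

    rng = np.random.default_rng(seed)
    p = _jittered(params, rng)

    n = params.hrir_length_samples
    fs = params.sample_rate_hz
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    itd_s = azimuth_to_itd_us(p, azimuths_deg) * 1e-6
    t0 = (n // 4) / fs
    # right ear leads for positive azimuth
    tau_left = t0 + itd_s / 2.0
    tau_right = t0 - itd_s / 2.0

    irs = {}
    for ear, tau in (("left", tau_left), ("right", tau_right)):
        mag = _gain_linear(p, freqs, azimuths_deg, elevations_deg, ear)
        phase = np.exp(-2j * np.pi * freqs[None, None, :] * tau[:, None, None])
        irs[ear] = np.fft.irfft(mag * phase, n=n, axis=-1)

    meta = {"seed": int(seed), "params": dataclasses.asdict(params)}
    return HRIRSet(
        azimuths_deg=azimuths_deg,
        elevations_deg=elevations_deg,
        fs_hz=fs,
        left=irs["left"],
        right=irs["right"],
        meta=meta,
    )


def monaural_gain_map(h: HRIRSet, freqs_hz) -> tuple[np.ndarray, np.ndarray]:
    """Per-location, per-ear transfer magnitude in dB.

    Returns ``(gain_left_db, gain_right_db)`` of shape
    ``(n_az, n_el, n_freq)``: the magnitude of each ear's transfer
    function evaluated at the requested frequencies (the relative
    attenuation of sound level by the head filter at that ear).
    """
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs_hz <= 0) or np.any(freqs_hz >= h.fs_hz / 2):
        raise ValueError("frequencies must lie strictly within (0, fs/2)")
    t = np.arange(h.n_taps) / h.fs_hz
    basis = np.exp(-2j * np.pi * freqs_hz[:, None] * t[None, :])  # (n_freq, taps)
    out = []
    for ir in (h.left, h.right):
        tf = np.tensordot(ir, basis, axes=([-1], [-1]))  # (n_az, n_el, n_freq)
        out.append(20.0 * np.log10(np.maximum(np.abs(tf), 1e-300)))
    return out[0], out[1]


def compute_acoustic_axis(
    h: HRIRSet,
    ear: str,
    freqs_hz=None,
) -> tuple[float, float]:
    """Direction of maximal gain for one ear.

    The gain surface is the median across frequencies of the ear's
    monaural gain; the axis is the intensity-weighted centroid of the
    grid locations whose median gain lies in the top 10 % (at or above
    the 90th percentile).  Weights are linear power.
    """
    if ear not in ("left", "right"):
        raise ValueError("ear must be 'left' or 'right'")
    if h.elevations_deg.size < 2:
        raise ValueError("need at least 2 elevations to locate an axis")
    if freqs_hz is None:
        freqs_hz = np.arange(1000.0, 8000.0 + 1e-9, 200.0)
    gl, gr = monaural_gain_map(h, freqs_hz)
    surface = np.median(gl if ear == "left" else gr, axis=-1)  # (n_az, n_el)
    if np.ptp(surface) < 1e-9:
        raise AmbiguousAxisError("gain surface is flat; acoustic axis undefined")
    threshold = np.percentile(surface, 90.0)
    mask = surface >= threshold
    weights = 10.0 ** (surface[mask] / 10.0)
    az_grid, el_grid = np.meshgrid(h.azimuths_deg, h.elevations_deg, indexing="ij")
    az = float(np.average(az_grid[mask], weights=weights))
    el = float(np.average(el_grid[mask], weights=weights))
    return az, el


def analysis_elevation(h: HRIRSet) -> float:
    """Grid elevation nearest the midpoint of the two acoustic axes.

    The cue-statistics analyses are run at an elevation centred between
    the left and right acoustic axes, which compensates for vertical
    ear-axis asymmetry (and, with real heads, for head-placement
    differences between individuals).
    """
    _, el_l = compute_acoustic_axis(h, "left")
    _, el_r = compute_acoustic_axis(h, "right")
    mid = 0.5 * (el_l + el_r)
    return float(h.elevations_deg[np.argmin(np.abs(h.elevations_deg - mid))])


def save_hrir_set(h: HRIRSet, path) -> None:
    """Write an HRIRSet to HDF5 (`/azimuths`, `/elevations`, `/fs`, `/left`, `/right`)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("azimuths", data=h.azimuths_deg)
        f.create_dataset("elevations", data=h.elevations_deg)
        f.create_dataset("fs", data=float(h.fs_hz))
        f.create_dataset("left", data=h.left)
        f.create_dataset("right", data=h.right)
        f.attrs["meta"] = json.dumps(h.meta)


def load_hrir_set(path) -> HRIRSet:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs.get("meta", "{}"))
        return HRIRSet(
            azimuths_deg=f["azimuths"][...],
            elevations_deg=f["elevations"][...],
            fs_hz=float(f["fs"][()]),
            left=f["left"][...],
            right=f["right"][...],
            meta=meta,
        )


def load_sofa(path) -> HRIRSet:
    """Best-effort read of a SOFA (HDF5) HRIR container.

    Expects the SimpleFreeFieldHRIR convention: ``Data.IR`` of shape
    (n_measurements, 2, n_taps), ``SourcePosition`` (azimuth, elevation,
    distance) and ``Data.SamplingRate``.  Measurements are arranged onto
    a rectangular azimuth x elevation grid; a measurement missing from
    the grid raises ``ValueError``.  Read-only convenience.
    """
    with h5py.File(path, "r") as f:
        ir = np.asarray(f["Data.IR"][...], dtype=float)
        pos = np.asarray(f["SourcePosition"][...], dtype=float)
        fs = float(np.ravel(f["Data.SamplingRate"][...])[0])
    # SOFA azimuths are often 0..360; map to -180..180
    az = (pos[:, 0] + 180.0) % 360.0 - 180.0
    el = pos[:, 1]
    azs = np.unique(np.round(az, 6))
    els = np.unique(np.round(el, 6))
    n_taps = ir.shape[-1]
    left = np.full((azs.size, els.size, n_taps), np.nan)
    right = np.full_like(left, np.nan)
    for m in range(ir.shape[0]):
        ia = int(np.argmin(np.abs(azs - az[m])))
        ie = int(np.argmin(np.abs(els - el[m])))
        left[ia, ie] = ir[m, 0]
        right[ia, ie] = ir[m, 1]
    if np.any(np.isnan(left)) or np.any(np.isnan(right)):
        raise ValueError("SOFA measurements do not form a full azimuth x elevation grid")
    return HRIRSet(azs, els, fs, left, right, meta={"source": "sofa"})
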