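"""MUAP synthesis, interference EMG, signal features and profile maps.

A fiber's extracellular potential at an electrode is the lead field
(weighting function) evaluated along the fiber, combined with the
charge-balanced source train: at each instant the potential equals the sum
over sources of current times h at the source's arc position — the
discrete form of phi(x, t) = i0(t) * h(x, t).  Motor-unit action
potentials (MUAPs) superpose the fibers of a unit; interference EMG
convolves each unit's spike train with its MUAP, adds white Gaussian
noise, and band-pass filters 20-2000 Hz (zero phase).

The electrode array is the five-contact montage: 0.5 mm contacts at the
corners and center of a 5 x 5 mm square; the four recorded channels are
corner minus center ("double differential" in the recording system's
nomenclature; a true longitudinal double difference is available as an
option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .ap_source import SourceTrain
from .volume_conductor import LeadField

__all__ = [
    "MUAP",
    "EMGRecord",
    "ProfileMap",
    "DEFAULT_FS",
    "NOISE_SIGMA_V",
    "fiber_potential",
    "compose_muap",
    "apply_montage",
    "synthesize_emg",
    "signal_features",
    "spike_triggered_average",
    "electrical_profile",
    "pickup_radius",
]

DEFAULT_FS = 20_000.0
BAND_HZ = (20.0, 2000.0)
#: white-noise level: power -107.5 dBW into 1 ohm -> sigma ~ 4.217 uV
NOISE_SIGMA_V = 10.0 ** (-107.5 / 20.0)


@dataclass
class MUAP:
    """Per-electrode sampled waveforms of one motor unit (V at fs)."""

    waveforms: np.ndarray  # (n_electrodes, n_samples)
    fs: float
    unit_index: int = 0

    @property
    def peak_to_peak(self) -> np.ndarray:
        return self.waveforms.max(axis=1) - self.waveforms.min(axis=1)


@dataclass
class EMGRecord:
    """Multichannel sampled EMG with montage and noise metadata."""

    channels: np.ndarray  # (n_channels, n_samples), V
    fs: float
    montage: str = "corner_minus_center"
    noise_sigma_v: float = 0.0
    times: np.ndarray | None = None

    @property
    def duration_s(self) -> float:
        return self.channels.shape[1] / self.fs


@dataclass
class ProfileMap:
    """Normalized array-mean lead field over the reference cross-section."""

    grid_points_mm: np.ndarray  # (n, 2) in-plane coordinates
    values: np.ndarray  # normalized to Vmax across compared states
    vmax: float
    array_center_mm: np.ndarray  # in-plane projection of the array


def fiber_potential(
    train: SourceTrain, lead: LeadField, dt: float | None = None
) -> np.ndarray:
    """Extracellular potential waveform of one fiber at one electrode.

    ``lead`` must be sampled along the fiber polyline (arc_mm set); h is
    linearly interpolated in arc length at the source positions, and the
    potential at each instant is sum(current * h).  Zero-sum sources make
    the result invariant to any constant offset in h.
    """
    if lead.arc_mm is None:
        raise ValueError("lead field must be sampled along the fiber polyline")
    arc = lead.arc_mm
    if abs(arc[-1] - train.fiber_length_mm) > max(
        0.2, 1e-3 * train.fiber_length_mm
    ):
        raise ValueError(
            "lead-field arc length does not match the fiber "
            f"({arc[-1]:.2f} vs {train.fiber_length_mm:.2f} mm)"
        )
    h = np.interp(train.positions_mm, arc, lead.values)
    return train.currents @ h


def compose_muap(
    fiber_trains: list[SourceTrain],
    fiber_leads: list[list[LeadField]],
    fs: float = DEFAULT_FS,
    unit_index: int = 0,
) -> MUAP:
    """Superpose the fibers of one unit into its per-electrode MUAP.

    ``fiber_leads[i][e]`` is the lead field of electrode ``e`` along fiber
    ``i``.  Waveforms are accumulated on a common time base sized to the
    slowest fiber's full transit plus a 5 ms guard.
    """
    if not fiber_trains:
        raise ValueError("unit has no fibers")
    n_el = len(fiber_leads[0])
    dt = 1.0 / fs
    dur = max(t.times[-1] for t in fiber_trains) + 5e-3
    n_s = int(np.ceil(dur / dt)) + 1
    out = np.zeros((n_el, n_s))
    tgrid = np.arange(n_s) * dt
    for train, leads in zip(fiber_trains, fiber_leads):
        for e in range(n_el):
            w = fiber_potential(train, leads[e])
            out[e] += np.interp(tgrid, train.times, w, left=0.0, right=0.0)
    return MUAP(waveforms=out, fs=fs, unit_index=unit_index)


def apply_montage(monopolar: np.ndarray, scheme: str = "corner_minus_center"):
    """Combine 5 monopolar electrode waveforms into 4 channels.

    Electrode order: 4 corners then center.  ``corner_minus_center`` is
    the recording system's montage (each corner referenced to the center
    contact); ``double_differential`` forms the two true second
    differences along the square's diagonals.
    """
    monopolar = np.asarray(monopolar)
    if monopolar.shape[0] != 5:
        raise ValueError("montage expects exactly 5 electrode waveforms")
    corners, center = monopolar[:4], monopolar[4]
    if scheme == "corner_minus_center":
        return corners - center[None, :]
    if scheme == "double_differential":
        # corners 0-2 and 1-3 are diagonal pairs through the center
        return np.stack(
            [
                corners[0] - 2 * center + corners[2],
                corners[1] - 2 * center + corners[3],
            ]
        )
    raise ValueError(f"unknown montage scheme {scheme!r}")


def synthesize_emg(
    muaps: dict[int, MUAP],
    firings,
    duration_s: float | None = None,
    fs: float = DEFAULT_FS,
    noise_sigma_v: float = NOISE_SIGMA_V,
    band_hz: tuple[float, float] | None = BAND_HZ,
    seed: int = 0,
) -> EMGRecord:
    """Interference EMG: spike trains convolved with MUAPs, noise, filter.

    ``muaps`` maps unit index -> MUAP (all on the same channel layout);
    ``firings`` is a FiringTrain (or dict unit -> spike times).  White
    Gaussian noise of the configured sigma is added per channel, then a
    zero-phase 4th-order Butterworth band-pass is applied.
    """
    spikes = firings.spikes if hasattr(firings, "spikes") else firings
    if duration_s is None:
        cfg = getattr(firings, "config", None)
        duration_s = cfg.duration_s if cfg is not None else (
            max((s[-1] for s in spikes.values() if len(s)), default=0.0) + 0.1
        )
    if band_hz is not None and fs < 2 * band_hz[1]:
        raise ValueError("sampling rate below Nyquist for the band top")
    n_ch = next(iter(muaps.values())).waveforms.shape[0]
    n_s = int(round(duration_s * fs))
    chans = np.zeros((n_ch, n_s))
    for unit, times in spikes.items():
        if unit not in muaps or len(times) == 0:
            continue
        w = muaps[unit].waveforms
        pulse = np.zeros(n_s)
        idx = np.round(np.asarray(times) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n_s)]
        np.add.at(pulse, idx, 1.0)
        for c in range(n_ch):
            chans[c] += sps.fftconvolve(pulse, w[c])[:n_s]
    if noise_sigma_v > 0:
        rng = np.random.default_rng(seed)
        chans = chans + rng.normal(0.0, noise_sigma_v, size=chans.shape)
    if band_hz is not None:
        sos = sps.butter(4, band_hz, btype="bandpass", fs=fs, output="sos")
        chans = sps.sosfiltfilt(sos, chans, axis=1)
    return EMGRecord(
        channels=chans,
        fs=fs,
        noise_sigma_v=noise_sigma_v,
        times=np.arange(n_s) / fs,
    )


def signal_features(
    record: EMGRecord,
    window_s: tuple[float, float] | None = None,
    channel: int = 0,
) -> dict[str, float]:
    """RMS, median frequency, skewness and kurtosis of one channel.

    The analysis window defaults to the full record; pass the plateau
    window to exclude the ramps.  Median frequency splits the Welch power
    spectrum (1 s Hann segments, 50% overlap) into equal-power halves;
    kurtosis is the non-excess standardized fourth moment (Gaussian -> 3).
    """
    x = record.channels[channel]
    if window_s is not None:
        i0, i1 = (int(round(w * record.fs)) for w in window_s)
        x = x[i0:i1]
    if len(x) < record.fs:
        raise ValueError("need at least 1 s of signal for features")
    rms = float(np.sqrt(np.mean(x**2)))
    nper = int(min(record.fs, len(x)))
    f, p = sps.welch(x, fs=record.fs, window="hann", nperseg=nper)
    cum = np.cumsum(p)
    mf = float(np.interp(0.5 * cum[-1], cum, f))
    return {
        "rms_v": rms,
        "median_frequency_hz": mf,
        "skewness": float(spst.skew(x)),
        "kurtosis": float(spst.kurtosis(x, fisher=False)),
    }


def spike_triggered_average(
    record: EMGRecord,
    firings,
    unit: int,
    window_s: tuple[float, float],
    min_spikes: int = 10,
) -> np.ndarray:
    """Mean of record segments aligned on one unit's spikes.

    ``window_s = (pre, post)`` in seconds around each spike.  Returns
    (n_channels, n_window) — the unit's MUAP estimate.
    """
    if hasattr(firings, "spikes"):
        spikes = firings.spikes[unit]
    elif isinstance(firings, dict):
        spikes = firings[unit]
    else:
        spikes = firings
    spikes = np.asarray(spikes)
    n_pre = int(round(window_s[0] * record.fs))
    n_post = int(round(window_s[1] * record.fs))
    n_s = record.channels.shape[1]
    segs = []
    for t in spikes:
        i = int(round(t * record.fs))
        if i - n_pre < 0 or i + n_post > n_s:
            continue
        segs.append(record.channels[:, i - n_pre : i + n_post])
    if len(segs) < min_spikes:
        raise ValueError(
            f"spike-triggered averaging needs >= {min_spikes} usable "
            f"spikes, got {len(segs)}"
        )
    return np.mean(segs, axis=0)


def electrical_profile(
    leads: list[LeadField],
    grid_points_mm: np.ndarray,
    array_center_mm: np.ndarray,
    vmax: float | None = None,
) -> ProfileMap:
    """Array-mean pick-up profile over the muscle cross-section.

    ``leads`` are the electrode lead fields evaluated at the grid points
    (one reciprocal solve per electrode, no extra solves here): the
    profile at a grid point is the mean over electrodes of h_e, i.e. the
    potential the array would average for a unit point source there.
    ``vmax`` normalizes across compared states (defaults to this map's
    maximum).
    """
    vals = np.mean([ld.values for ld in leads], axis=0)
    vmax_eff = float(vals.max()) if vmax is None else float(vmax)
    return ProfileMap(
        grid_points_mm=np.asarray(grid_points_mm, float),
        values=vals / vmax_eff,
        vmax=vmax_eff,
        array_center_mm=np.asarray(array_center_mm, float),
    )


def pickup_radius(pmap: ProfileMap, level: float = 0.30) -> float:
    """Radius of the region where the profile stays >= level * Vmax (mm).

    Measured as the maximum in-plane distance from the array's projection
    at which the normalized profile still reaches the level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    above = pmap.values >= level
    if not np.any(above):
        return 0.0
    d = np.linalg.norm(
        pmap.grid_points_mm[above] - pmap.array_center_mm[None, :], axis=1
    )
    return float(d.max())
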