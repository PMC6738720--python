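"""Motor-unit firing times for trapezoidal isometric contractions.

The drive profile is a ramp-plateau-ramp trapezoid (5 %MVC/s up to a 25
%MVC plateau over a 25 s contraction).  Recruitment thresholds follow an
exponential ladder across the pool, rescaled so that a configurable number
of units (90 of 120 by default) are recruited at the plateau drive.  Above
threshold, firing rate grows linearly with excess drive from a minimum
rate toward a peak rate; inter-spike intervals are Gaussian-jittered with
a configurable coefficient of variation and floored at an absolute
refractory interval.

This is a standard Fuglevand-style pool: the pinned constraints are the
pool size, the 90-unit recruitment at 25 %MVC and the trapezoid protocol;
minimum/peak rates, the rate-drive gain and the ISI variability are
free parameters with defaults documented as modelling choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PoolConfig", "FiringTrain", "excitation_profile", "generate_firings"]


@dataclass(frozen=True)
class PoolConfig:
    n_units: int = 120
    recruited_at_plateau: int = 90
    ramp_rate_pct_s: float = 5.0
    plateau_pct: float = 25.0
    duration_s: float = 25.0
    min_rate_hz: float = 8.0
    peak_rate_hz: float = 35.0
    isi_cv: float = 0.15
    #: threshold ratio across the full pool (last/first threshold)
    threshold_range: float = 30.0
    #: rate gain in Hz per %MVC of excess drive
    rate_gain_hz_per_pct: float = 2.0
    #: "onion" — earlier units reach higher peak rates; "ahp" — later do
    rate_scheme: str = "onion"
    refractory_s: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.recruited_at_plateau <= self.n_units:
            raise ValueError("recruited_at_plateau must be within the pool")
        ramp = self.plateau_pct / self.ramp_rate_pct_s
        if self.duration_s <= 2 * ramp:
            raise ValueError("duration must exceed the two ramps")
        if self.rate_scheme not in ("onion", "ahp"):
            raise ValueError("rate_scheme must be 'onion' or 'ahp'")

    @property
    def ramp_s(self) -> float:
        return self.plateau_pct / self.ramp_rate_pct_s

    def thresholds(self) -> np.ndarray:
        """Exponential recruitment-threshold ladder, %MVC.

        theta_i = a * exp(b i) with b = ln(threshold_range)/n, and a
        rescaled so theta_{recruited_at_plateau} equals the plateau drive
        exactly (units above it stay silent at the plateau).
        """
        i = np.arange(1, self.n_units + 1)
        b = np.log(self.threshold_range) / self.n_units
        theta = np.exp(b * i)
        return theta * (self.plateau_pct / theta[self.recruited_at_plateau - 1])


@dataclass
class FiringTrain:
    """Per-unit sorted spike times (s); 1-based unit indices as keys."""

    spikes: dict[int, np.ndarray]
    config: PoolConfig

    def __getitem__(self, unit: int) -> np.ndarray:
        return self.spikes[unit]

    def active_units(self) -> list[int]:
        return sorted(u for u, s in self.spikes.items() if len(s))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("unit,spike_time_s\n")
            for u in sorted(self.spikes):
                for t in self.spikes[u]:
                    fh.write(f"{u},{t:.6f}\n")


def excitation_profile(t, cfg: PoolConfig = PoolConfig()):
    """Trapezoidal drive in %MVC at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > cfg.duration_s)):
        raise ValueError("time outside the contraction window")
    up = cfg.ramp_rate_pct_s * t
    down = cfg.ramp_rate_pct_s * (cfg.duration_s - t)
    e = np.minimum(np.minimum(up, down), cfg.plateau_pct)
    return e if e.ndim else float(e)


def generate_firings(cfg: PoolConfig = PoolConfig()) -> FiringTrain:
    """Simulate spike trains for the whole pool.

    Each unit fires while the drive exceeds its threshold, at a rate
    linear in the excess drive (clipped to [min_rate, unit peak rate]).
    ISIs are jittered by a Gaussian factor of the configured CV and floored
    at the refractory interval.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = cfg.thresholds()
    n = cfg.n_units
    frac = np.arange(n) / max(n - 1, 1)
    if cfg.rate_scheme == "onion":
        peak = cfg.peak_rate_hz - (cfg.peak_rate_hz - cfg.min_rate_hz) * 0.5 * frac
    else:
        peak = cfg.min_rate_hz + (cfg.peak_rate_hz - cfg.min_rate_hz) * (
            0.5 + 0.5 * frac
        )

    spikes: dict[int, np.ndarray] = {}
    for k in range(n):
        th = theta[k]
        if th > cfg.plateau_pct:
            spikes[k + 1] = np.array([])
            continue
        t_on = th / cfg.ramp_rate_pct_s  # first crossing on the up ramp
        eps = 1e-9 * cfg.plateau_pct  # guard against 1-ulp drive deficits
        out = []
        t = t_on
        while t < cfg.duration_s:
            e = excitation_profile(min(t, cfg.duration_s), cfg)
            if e < th - eps:
                break
            rate = cfg.min_rate_hz + cfg.rate_gain_hz_per_pct * (e - th)
            rate = min(rate, peak[k])
            isi = (1.0 / rate) * (1.0 + cfg.isi_cv * rng.standard_normal())
            isi = max(isi, cfg.refractory_s)
            t = t + isi
            e_next = excitation_profile(min(t, cfg.duration_s), cfg)
            if t >= cfg.duration_s or e_next < th - eps:
                break
            out.append(t)
        spikes[k + 1] = np.asarray(out)
    return FiringTrain(spikes=spikes, config=cfg)
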