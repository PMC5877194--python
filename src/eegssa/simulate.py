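"""Markov-Process-Amplitude (MPA) EEG simulator.

Spontaneous EEG is modelled as a superposition of sinusoidal rhythms whose
instantaneous amplitudes follow first-order Markov (AR(1)) processes:

    s(n dt)     = sum_i a_i(n dt) sin(2 pi f_i n dt + theta_i) + v_art + v_n
    a_i((n+1)dt) = gamma_i a_i(n dt) + xi_i(n dt),     0 < gamma_i < 1

where xi_i is zero-mean Gaussian with standard deviation sigma_xi_i.  The
stationary amplitude variance is sigma_xi^2 / (1 - gamma^2); amplitudes are
initialized from that stationary law so short records carry no burn-in
transient.

Default parameters (the standard simulation conditions):

==========  ======  =======  =========
rhythm      f (Hz)  gamma    sigma_xi
==========  ======  =======  =========
delta        2.50    0.99     2.26
theta        6.00    0.97     2.78
alpha       10.50    0.99     2.35
beta        21.50    0.99     0.36
==========  ======  =======  =========

sampled at 200 Hz for 8 s.  Artifacts are periodic triangular EOG pulses
(50 uV peak, 3 s period, 0.3 s base width) and a sinusoidal baseline drift
(10 uV, 0.5 Hz); measurement noise is Gaussian and white with power 1 dB,
interpreted as 10*log10(variance in uV^2) — i.e. variance 10^0.1 uV^2.
Initial phases default to 0 (none are specified by the model) and are
configurable.

An "eyes-open" record is emulated by scaling the alpha innovation
sigma_xi by 0.3, since the resting alpha rhythm is much stronger with eyes
closed than open; all other parameters are shared between the two states.

Every stream (each rhythm, the noise) draws from an independent generator
whose sub-seed is derived deterministically from the master seed and the
stream's name, so runs are bit-reproducible and rhythm order is immaterial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .series import TimeSeries

__all__ = [
    "RhythmParams",
    "ArtifactParams",
    "MPAConfig",
    "SimulatedEEG",
    "DEFAULT_RHYTHMS",
    "DEFAULT_ARTIFACTS",
    "OPEN_ALPHA_SCALE",
    "markov_amplitude",
    "simulate_rhythm",
    "simulate_spontaneous",
    "eog_waveform",
    "baseline_drift",
    "white_noise",
    "simulate_eeg",
    "preset_config",
]


@dataclass(frozen=True)
class RhythmParams:
    """One amplitude-modulated sinusoidal rhythm."""

    name: str
    f: float  # oscillation frequency, Hz
    gamma: float  # AR(1) amplitude correlation, in (0, 1)
    sigma_xi: float  # innovation standard deviation, uV
    theta: float = 0.0  # initial phase, rad

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError(
                f"gamma={self.gamma} violates the Markov-amplitude constraint 0 < gamma < 1"
            )
        if self.sigma_xi < 0:
            raise ValueError(f"sigma_xi must be non-negative, got {self.sigma_xi}")
        if self.f <= 0:
            raise ValueError(f"oscillation frequency must be positive, got {self.f}")

    @property
    def stationary_std(self) -> float:
        """Stationary amplitude s.d. sigma_xi / sqrt(1 - gamma^2)."""
        return self.sigma_xi / np.sqrt(1 - self.gamma**2)


@dataclass(frozen=True)
class ArtifactParams:
    """EOG pulse train and sinusoidal baseline drift parameters."""

    v_eog: float = 50.0  # EOG peak amplitude, uV
    t_eog: float = 3.0  # EOG pulse period, s
    w_eog: float = 0.3  # EOG pulse base width, s
    v_bd: float = 10.0  # baseline-drift amplitude, uV
    f_bd: float = 0.5  # baseline-drift frequency, Hz

    def __post_init__(self) -> None:
        for name in ("v_eog", "t_eog", "w_eog", "v_bd", "f_bd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.w_eog >= self.t_eog:
            raise ValueError(
                f"EOG pulse width {self.w_eog}s must be smaller than its period {self.t_eog}s"
            )


DEFAULT_RHYTHMS: tuple[RhythmParams, ...] = (
    RhythmParams("delta", 2.50, 0.99, 2.26),
    RhythmParams("theta", 6.00, 0.97, 2.78),
    RhythmParams("alpha", 10.50, 0.99, 2.35),
    RhythmParams("beta", 21.50, 0.99, 0.36),
)
DEFAULT_ARTIFACTS = ArtifactParams()

# eyes-open records scale the alpha innovation s.d. by this factor
OPEN_ALPHA_SCALE = 0.3


@dataclass(frozen=True)
class MPAConfig:
    """Full simulator parameter set.

    ``artifacts=None`` and ``noise_power_db=None`` switch those terms off,
    yielding the pure spontaneous signal.
    """

    rhythms: tuple[RhythmParams, ...] = DEFAULT_RHYTHMS
    artifacts: ArtifactParams | None = DEFAULT_ARTIFACTS
    noise_power_db: float | None = 1.0
    fs: float = 200.0
    duration: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rhythms:
            raise ValueError("at least one rhythm is required")
        names = [r.name for r in self.rhythms]
        if len(set(names)) != len(names):
            raise ValueError(f"rhythm names must be unique, got {names}")
        fmax = max(r.f for r in self.rhythms)
        if self.fs <= 2 * fmax:
            raise ValueError(
                f"sampling rate {self.fs} Hz must exceed twice the fastest rhythm ({fmax} Hz)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def preset_config(name: str, seed: int = 0) -> MPAConfig:
    """Named study conditions.

    ``spontaneous``  — four rhythms only, no artifacts or noise;
    ``full``         — rhythms + EOG + drift + white noise;
    ``eyes-closed``  — alias of ``full`` (resting alpha at its default level);
    ``eyes-open``    — ``full`` with the alpha innovation scaled by 0.3.
    """
    key = name.strip().lower().replace("_", "-")
    if key == "spontaneous":
        return MPAConfig(artifacts=None, noise_power_db=None, seed=seed)
    if key in ("full", "eyes-closed"):
        return MPAConfig(seed=seed)
    if key == "eyes-open":
        rhythms = tuple(
            replace(r, sigma_xi=r.sigma_xi * OPEN_ALPHA_SCALE) if r.name == "alpha" else r
            for r in DEFAULT_RHYTHMS
        )
        return MPAConfig(rhythms=rhythms, seed=seed)
    raise ValueError(
        f"unknown preset {name!r}: use spontaneous, full, eyes-open or eyes-closed"
    )


def _stream_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator keyed by (master seed, stream name)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def markov_amplitude(
    gamma: float,
    sigma_xi: float,
    n_samples: int,
    rng: np.random.Generator | int,
    a0: float | None = None,
) -> np.ndarray:
    """First-order Markov (AR(1)) amplitude sequence.

    ``a[k+1] = gamma * a[k] + xi[k]`` with xi ~ N(0, sigma_xi^2).  When
    ``a0`` is None the start value is drawn from the stationary law
    N(0, sigma_xi^2 / (1 - gamma^2)), so the sequence is stationary from
    sample 0.
    """
    if not 0 < gamma < 1:
        raise ValueError(f"gamma={gamma} violates the constraint 0 < gamma < 1")
    if sigma_xi < 0:
        raise ValueError(f"sigma_xi must be non-negative, got {sigma_xi}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if a0 is None:
        a0 = float(rng.normal(0.0, sigma_xi / np.sqrt(1 - gamma**2))) if sigma_xi else 0.0
    a = np.empty(n_samples)
    a[0] = a0
    if n_samples > 1:
        xi = rng.normal(0.0, sigma_xi, size=n_samples - 1)
        # recursive filter y[n] = x[n] + gamma*y[n-1], seeded with y[-1] = a0
        a[1:], _ = scipy.signal.lfilter(
            [1.0], [1.0, -gamma], xi, zi=np.array([gamma * a0])
        )
    return a


def simulate_rhythm(
    p: RhythmParams,
    fs: float,
    duration: float,
    rng: np.random.Generator | int,
    a0: float | None = None,
) -> TimeSeries:
    """One rhythm: the AR(1) amplitude times the sinusoid sin(2 pi f t + theta)."""
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    a = markov_amplitude(p.gamma, p.sigma_xi, n, rng, a0=a0)
    return TimeSeries(a * np.sin(2 * np.pi * p.f * t + p.theta), fs)


def _rhythm_streams(cfg: MPAConfig) -> dict[str, TimeSeries]:
    return {
        r.name: simulate_rhythm(r, cfg.fs, cfg.duration, _stream_rng(cfg.seed, r.name))
        for r in cfg.rhythms
    }


def _sum_streams(streams: dict[str, TimeSeries]) -> np.ndarray:
    # fixed (name-sorted) summation order keeps output bit-identical
    # regardless of the order rhythms were configured in
    return np.sum([streams[k].values for k in sorted(streams)], axis=0)


def simulate_spontaneous(cfg: MPAConfig) -> TimeSeries:
    """Superposition of the configured rhythms (no artifacts, no noise)."""
    return TimeSeries(_sum_streams(_rhythm_streams(cfg)), cfg.fs)


def eog_waveform(a: ArtifactParams, fs: float, duration: float) -> TimeSeries:
    """Periodic isosceles-triangular EOG pulses, zero between pulses.

    The first apex sits at t = t_eog / 2 and apexes repeat every t_eog
    seconds; each pulse rises and falls linearly over a base of width
    w_eog centred on the apex.
    """
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    if a.v_eog == 0 or a.w_eog == 0:
        return TimeSeries(np.zeros(n), fs)
    offset = np.mod(t, a.t_eog) - a.t_eog / 2  # distance to nearest apex
    v = a.v_eog * np.maximum(0.0, 1.0 - np.abs(offset) / (a.w_eog / 2))
    return TimeSeries(v, fs)


def baseline_drift(a: ArtifactParams, fs: float, duration: float) -> TimeSeries:
    """Low-frequency sinusoidal baseline wander v_bd * sin(2 pi f_bd t)."""
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    return TimeSeries(a.v_bd * np.sin(2 * np.pi * a.f_bd * t), fs)


def white_noise(
    power_db: float, fs: float, duration: float, rng: np.random.Generator | int
) -> TimeSeries:
    """Gaussian white measurement noise with variance 10^(power_db/10) uV^2."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = int(round(fs * duration))
    sd = np.sqrt(10 ** (power_db / 10))
    return TimeSeries(rng.normal(0.0, sd, size=n), fs)


@dataclass(frozen=True)
class SimulatedEEG:
    """A simulated record with its full component breakdown.

    Keeping the clean per-rhythm channels alongside the composite signal is
    what makes reconstruction error measurable against ground truth.
    """

    eeg: TimeSeries
    spontaneous: TimeSeries
    rhythms: dict[str, TimeSeries] = field(repr=False)
    artifacts: TimeSeries = field(repr=False)
    noise: TimeSeries = field(repr=False)
    config: MPAConfig = field(repr=False)

    @property
    def alpha(self) -> TimeSeries:
        return self.rhythms["alpha"]


def simulate_eeg(cfg: MPAConfig) -> SimulatedEEG:
    """Full simulated EEG: spontaneous rhythms + EOG + drift + white noise."""
    streams = _rhythm_streams(cfg)
    fs, dur = cfg.fs, cfg.duration
    n = cfg.n_samples
    spont = TimeSeries(_sum_streams(streams), fs)
    if cfg.artifacts is not None:
        art_values = eog_waveform(cfg.artifacts, fs, dur).values + baseline_drift(
            cfg.artifacts, fs, dur
        ).values
    else:
        art_values = np.zeros(n)
    artifacts = TimeSeries(art_values, fs)
    if cfg.noise_power_db is not None:
        noise = white_noise(cfg.noise_power_db, fs, dur, _stream_rng(cfg.seed, "noise"))
    else:
        noise = TimeSeries(np.zeros(n), fs)
    eeg = TimeSeries(spont.values + artifacts.values + noise.values, fs)
    return SimulatedEEG(
        eeg=eeg,
        spontaneous=spont,
        rhythms=streams,
        artifacts=artifacts,
        noise=noise,
        config=cfg,
    )
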