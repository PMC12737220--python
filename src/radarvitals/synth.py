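"""Synthetic radar scenes and raw IF data cubes.

Generates the signals the processing chain assumes: chest-wall displacement
(a respiration tone with harmonics plus a much weaker heartbeat tone) is
embedded in the phase of each target's IF beat tone, targets are summed over
an ideal TDM-MIMO virtual uniform linear array, static clutter is added as
motionless reflectors, and circular white Gaussian noise sets the SNR.
The module also provides the plain two-tone-in-noise signals used by the
frequency-estimator benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

from .config import RadarConfig

__all__ = [
    "VitalProfile", "TargetTruth", "SceneDescription", "DataCube",
    "chest_displacement", "simulate_cube", "two_tone", "add_awgn",
]


@dataclass(frozen=True)
class VitalProfile:
    """Chest-displacement model of one subject.

    Displacement (m):

        s(t) = sum_h a_r * w_h * sin(2 pi h f_r t + phi_r)
             + a_h * sin(2 pi f_h t + phi_h)

    with respiration fundamental ``f_r`` (typically 0.1-0.5 Hz), harmonic
    multiples/relative weights ``(h, w_h)``, and heartbeat tone ``f_h``
    (0.5-3 Hz) roughly two orders of magnitude weaker than respiration.
    """

    respiration_frequency: float = 0.3        # Hz
    respiration_amplitude: float = 4e-3       # m
    respiration_harmonics: tuple = ((1, 1.0), (2, 0.2), (3, 0.03))
    heartbeat_frequency: float = 1.233        # Hz
    heartbeat_amplitude: float = 0.15e-3      # m
    respiration_phase: float = 0.0            # rad
    heartbeat_phase: float = 0.0              # rad

    def __post_init__(self) -> None:
        if self.respiration_amplitude < 0 or self.heartbeat_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.heartbeat_amplitude > 0 and not 0.5 < self.heartbeat_frequency < 3.0:
            raise ValueError("heartbeat frequency must lie in (0.5, 3.0) Hz")


@dataclass(frozen=True)
class TargetTruth:
    """Ground-truth target: nominal range, azimuth and vital profile."""

    range_m: float
    azimuth_deg: float = 0.0
    vital: VitalProfile = field(default_factory=VitalProfile)
    reflectivity: float = 1.0

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ValueError("target range must be positive")
        if not -90.0 < self.azimuth_deg < 90.0:
            raise ValueError("azimuth must lie in (-90, 90) degrees")


@dataclass(frozen=True)
class SceneDescription:
    """A complete synthetic scene: targets, clutter, noise level, duration."""

    targets: tuple = ()
    static_clutter: tuple = ()   # (range_m, amplitude) pairs
    snr_db: float | None = 20.0  # None -> noiseless
    duration: float = 32.0       # s
    seed: int = 0

    def n_frames(self, config: RadarConfig) -> int:
        n = self.duration * config.slow_sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer number of frames")
        return int(round(n))


@dataclass
class DataCube:
    """Raw complex IF samples indexed (fast m, slow n, channel i)."""

    samples: np.ndarray
    config: RadarConfig

    def __post_init__(self) -> None:
        if self.samples.ndim != 3:
            raise ValueError("cube must be 3-D (fast, slow, channel)")
        if self.samples.shape[0] != self.config.samples_per_chirp:
            raise ValueError("fast-time extent must equal samples_per_chirp")
        if self.samples.shape[2] != self.config.n_channels:
            raise ValueError("channel extent must equal n_tx * n_rx")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("cube contains non-finite samples")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[1]

    @property
    def shape(self) -> tuple:
        return self.samples.shape


def chest_displacement(vital: VitalProfile, times: np.ndarray) -> np.ndarray:
    """Chest-wall displacement series s(t) in m for uniformly spaced times."""
    times = np.asarray(times, dtype=float)
    if times.size > 1:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
    s = np.zeros_like(times)
    for mult, rel in vital.respiration_harmonics:
        s += (vital.respiration_amplitude * rel
              * np.sin(2 * np.pi * mult * vital.respiration_frequency * times
                       + vital.respiration_phase))
    s += vital.heartbeat_amplitude * np.sin(
        2 * np.pi * vital.heartbeat_frequency * times + vital.heartbeat_phase)
    return s


def simulate_cube(scene: SceneDescription, config: RadarConfig | None = None) -> DataCube:
    """Simulate the raw M x N x I IF data cube for a scene.

    Per target l, chirp n and channel i the IF sample at fast-time index m is

        a_l * exp(j [2 pi f_IF,l m Ts + 4 pi fc (d_l + s_l(t_n)) / c
                     + 2 pi d_i sin(theta_l) / lambda])

    with beat frequency f_IF,l = 2 S d_l / c.  Static clutter enters as
    motionless unit-phase targets; circular white Gaussian noise is scaled so
    that the strongest target tone's per-sample power over the noise variance
    equals ``scene.snr_db``.
    """
    config = config or RadarConfig()
    n_frames = scene.n_frames(config)
    m_idx = np.arange(config.samples_per_chirp)
    t_fast = m_idx / config.fast_sampling_rate
    t_slow = np.arange(n_frames) / config.slow_sampling_rate
    d_i = np.arange(config.n_channels) * config.spacing
    lam = config.wavelength

    cube = np.zeros((config.samples_per_chirp, n_frames, config.n_channels),
                    dtype=np.complex128)
    peak_amplitude = 0.0

    def add_reflector(rng_m, azimuth_deg, amplitude, displacement):
        nonlocal cube
        f_if = config.beat_frequency(rng_m)
        if f_if >= config.fast_sampling_rate / 2:
            raise ValueError(
                f"target at {rng_m} m is beyond the unambiguous range "
                f"({config.max_unambiguous_range:.2f} m)")
        fast_phase = 2 * np.pi * f_if * t_fast                       # (M,)
        slow_phase = (4 * np.pi * config.carrier_frequency
                      * (rng_m + displacement) / SPEED_OF_LIGHT)      # (N,)
        spatial_phase = 2 * np.pi * d_i * np.sin(np.deg2rad(azimuth_deg)) / lam
        cube += amplitude * np.exp(1j * (fast_phase[:, None, None]
                                         + slow_phase[None, :, None]
                                         + spatial_phase[None, None, :]))

    for tgt in scene.targets:
        s_t = chest_displacement(tgt.vital, t_slow)
        add_reflector(tgt.range_m, tgt.azimuth_deg, tgt.reflectivity, s_t)
        peak_amplitude = max(peak_amplitude, tgt.reflectivity)

    for rng_m, amp in scene.static_clutter:
        add_reflector(rng_m, 0.0, amp, np.zeros(n_frames))

    if scene.snr_db is not None and peak_amplitude > 0:
        rng = np.random.default_rng(scene.seed)
        noise_var = peak_amplitude**2 / 10 ** (scene.snr_db / 10)
        noise = rng.normal(scale=np.sqrt(noise_var / 2), size=cube.shape + (2,))
        cube += noise[..., 0] + 1j * noise[..., 1]

    return DataCube(samples=cube, config=config)


def two_tone(a1: float, a2: float, f1: float, f2: float,
             fs: float, ns: int) -> np.ndarray:
    """Real two-tone test signal A1 sin(2 pi f1 n/fs) + A2 sin(2 pi f2 n/fs)."""
    if ns <= 0:
        raise ValueError("number of samples must be positive")
    if not (f1 < fs / 2 and f2 < fs / 2):
        raise ValueError("tone frequencies must be below Nyquist")
    n = np.arange(ns)
    return (a1 * np.sin(2 * np.pi * f1 * n / fs)
            + a2 * np.sin(2 * np.pi * f2 * n / fs))


def add_awgn(x: np.ndarray, snr_db: float,
             seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add white Gaussian noise at a given SNR (dB).

    SNR is defined against the *mean* signal power ``mean(|x|^2)``.  Complex
    input receives circular complex noise; real input receives real noise.
    Reproducible for a given seed.
    """
    x = np.asarray(x)
    power = float(np.mean(np.abs(x) ** 2))
    if power == 0 and np.isfinite(snr_db):
        raise ValueError("cannot set a finite SNR on a zero-power signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise_var = power / 10 ** (snr_db / 10)
    if np.iscomplexobj(x):
        w = rng.normal(scale=np.sqrt(noise_var / 2), size=x.shape + (2,))
        return x + w[..., 0] + 1j * w[..., 1]
    return x + rng.normal(scale=np.sqrt(noise_var), size=x.shape)
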