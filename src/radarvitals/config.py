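"""Radar waveform and array configuration.

The default configuration mirrors a 77 GHz automotive-band FMCW MIMO sensor
(2 TX x 4 RX, time-division multiplexed into an 8-element virtual uniform
linear array at half-wavelength spacing): 70 MHz/us sweep slope, 50 us ADC
window sampled at 4 MHz (200 fast-time samples per chirp), one chirp frame
every 50 ms (20 Hz slow-time rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from scipy.constants import c as SPEED_OF_LIGHT


@dataclass(frozen=True)
class RadarConfig:
    """Chirp, sampling and array-geometry parameters of an FMCW MIMO radar.

    Parameters
    ----------
    carrier_frequency : float
        Chirp start frequency fc in Hz.
    bandwidth : float
        Total sweep bandwidth B in Hz.
    chirp_duration : float
        Duration of the sampled ADC window in s (the IF tone is modelled
        only over this window; chirp edges are ignored).
    sweep_slope : float
        Chirp slope S in Hz/s.
    fast_sampling_rate : float
        ADC (fast-time) sampling rate in Hz.
    samples_per_chirp : int
        Fast-time samples per chirp, M.
    slow_sampling_rate : float
        Chirp/frame repetition rate in Hz (slow-time rate).
    n_tx, n_rx : int
        Physical transmit / receive element counts; the virtual array has
        ``n_tx * n_rx`` channels.
    element_spacing : float or None
        Virtual-array element spacing in m; ``None`` selects lambda/2.
    """

    carrier_frequency: float = 77e9
    bandwidth: float = 3.99e9
    chirp_duration: float = 50e-6
    sweep_slope: float = 70e12          # 70 MHz/us
    fast_sampling_rate: float = 4e6
    samples_per_chirp: int = 200
    slow_sampling_rate: float = 20.0
    n_tx: int = 2
    n_rx: int = 4
    element_spacing: float | None = None

    def __post_init__(self) -> None:
        if min(self.carrier_frequency, self.bandwidth, self.fast_sampling_rate,
               self.slow_sampling_rate, self.sweep_slope) <= 0:
            raise ValueError("all rates and the sweep slope must be positive")
        if self.n_tx < 1 or self.n_rx < 1 or self.samples_per_chirp < 1:
            raise ValueError("counts must be positive")
        swept = self.sweep_slope * self.samples_per_chirp / self.fast_sampling_rate
        if swept > self.bandwidth * (1 + 1e-9):
            raise ValueError(
                f"sweep over the ADC window ({swept:.3g} Hz) exceeds the "
                f"bandwidth ({self.bandwidth:.3g} Hz)")

    # ---- derived quantities -------------------------------------------------

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / fc in m."""
        return SPEED_OF_LIGHT / self.carrier_frequency

    @property
    def n_channels(self) -> int:
        """Virtual channel count I = n_tx * n_rx."""
        return self.n_tx * self.n_rx

    @property
    def spacing(self) -> float:
        """Virtual-element spacing in m (lambda/2 unless overridden)."""
        return self.wavelength / 2 if self.element_spacing is None else self.element_spacing

    @property
    def frame_period(self) -> float:
        return 1.0 / self.slow_sampling_rate

    @property
    def range_bin_width(self) -> float:
        """Range per fast-time DFT bin: c * fs_fast / (2 S M) in m."""
        return (SPEED_OF_LIGHT * self.fast_sampling_rate
                / (2 * self.sweep_slope * self.samples_per_chirp))

    @property
    def max_unambiguous_range(self) -> float:
        """Range at which the beat frequency reaches fs_fast / 2."""
        return SPEED_OF_LIGHT * self.fast_sampling_rate / (4 * self.sweep_slope)

    def beat_frequency(self, rng: float) -> float:
        """IF beat frequency 2 S r / c of a target at range ``rng`` (Hz)."""
        return 2 * self.sweep_slope * rng / SPEED_OF_LIGHT

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        return cls(**d)
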