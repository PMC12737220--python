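"""Angle-domain processing: Doppler accumulation, Root-MUSIC, MVDR separation.

For each detected range bin the slow-time x channel slice is Doppler-FFT'd
per channel; the Doppler bins with the highest channel-summed power serve as
high-SNR spatial snapshots for subspace direction finding.  Root-MUSIC
replaces the spectral search of MUSIC with polynomial rooting on the noise
subspace; co-range targets are then separated by MVDR (Capon) beamforming,
which passes the steered direction with unit gain while minimizing total
output power.

Angle convention: boresight is 0 deg, positive toward increasing virtual
element index; the root phase maps to sin(theta) through the element spacing
in wavelengths (default half-wavelength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelSlice", "DOAResult", "doppler_accumulate", "estimate_n_sources",
    "root_music", "mvdr_separate", "steering_vector",
]


@dataclass
class ChannelSlice:
    """Slow-time x channel samples at one range bin (shape N x I)."""

    samples: np.ndarray
    range_bin: int

    def __post_init__(self):
        if self.samples.ndim != 2:
            raise ValueError("channel slice must be 2-D (slow, channel)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class DOAResult:
    """Estimated directions of arrival for one range bin / segment."""

    angles_deg: np.ndarray
    n_sources: int
    segment_index: int = 0
    degenerate: bool = False


def steering_vector(theta_deg: float, n_channels: int,
                    d_over_lambda: float = 0.5) -> np.ndarray:
    """Array response a(theta), a_i = exp(j 2 pi i d sin(theta) / lambda)."""
    i = np.arange(n_channels)
    return np.exp(2j * np.pi * i * d_over_lambda
                  * np.sin(np.deg2rad(theta_deg)))


def doppler_accumulate(sl: ChannelSlice, n_snapshots: int = 8) -> np.ndarray:
    """High-SNR spatial snapshots from the strongest Doppler bins.

    Doppler-FFT along slow time per channel, then keep the ``n_snapshots``
    Doppler bins with the largest channel-summed power; returns an
    (n_snapshots, I) snapshot matrix.  Each retained bin concentrates the
    accumulation gain of the whole slow-time extent.
    """
    x = sl.samples
    if not np.any(x):
        raise ValueError("all-zero channel slice")
    dopp = np.fft.fft(x, axis=0)                       # N x I
    power = np.sum(np.abs(dopp) ** 2, axis=1)
    n_keep = min(n_snapshots, power.size)
    top = np.argsort(power)[::-1][:n_keep]
    return dopp[top, :]


def _covariance(snapshots: np.ndarray, loading: float = 1e-3) -> np.ndarray:
    """Sample covariance E[x x^H] over snapshot rows plus diagonal loading."""
    r = snapshots.T @ snapshots.conj() / snapshots.shape[0]
    i = r.shape[0]
    return r + loading * np.trace(r).real / i * np.eye(i)


def estimate_n_sources(snapshots: np.ndarray, max_sources: int = 3) -> int:
    """Model-order estimate from the largest eigenvalue-gap ratio."""
    r = _covariance(snapshots, loading=0.0)
    w = np.linalg.eigvalsh(r)[::-1]
    w = np.maximum(w, 1e-30)
    k = min(max_sources, w.size - 1)
    ratios = w[:k] / w[1:k + 1]
    return int(np.argmax(ratios)) + 1


def root_music(snapshots: np.ndarray, n_sources: int,
               d_over_lambda: float = 0.5, loading: float = 1e-3,
               segment_index: int = 0) -> DOAResult:
    """Root-MUSIC direction finding on a snapshot matrix.

    Eigendecomposes the (diagonally loaded) sample covariance, forms the
    noise-subspace polynomial sum_k diag_k(E_n E_n^H) z^k, roots it, keeps
    the ``n_sources`` roots inside and nearest the unit circle, and maps
    each root phase to sin(theta).
    """
    n_chan = snapshots.shape[1]
    if n_sources >= n_chan:
        raise ValueError("n_sources must be below the channel count")
    r = _covariance(snapshots, loading)
    w, v = np.linalg.eigh(r)                 # ascending
    degenerate = False
    signal_rank = int(np.sum(w > w[-1] * 1e-10))
    if signal_rank < n_sources:
        degenerate = True
        warnings.warn("covariance rank below the requested source count",
                      stacklevel=2)
    noise = v[:, : n_chan - n_sources]
    c = noise @ noise.conj().T
    # polynomial coefficients, degree 2(I-1), from the diagonal sums of C
    coeffs = np.array([np.trace(c, offset=k)
                       for k in range(n_chan - 1, -n_chan, -1)])
    roots = np.roots(coeffs)
    inside = roots[np.abs(roots) < 1.0]
    order = np.argsort(np.abs(np.abs(inside) - 1.0))
    angles = []
    for z in inside[order]:
        sin_theta = np.angle(z) / (2 * np.pi * d_over_lambda)
        if abs(sin_theta) <= 1.0:
            angles.append(np.rad2deg(np.arcsin(sin_theta)))
        if len(angles) == n_sources:
            break
    return DOAResult(angles_deg=np.sort(np.array(angles)),
                     n_sources=n_sources, segment_index=segment_index,
                     degenerate=degenerate)


def mvdr_separate(sl: ChannelSlice, theta_deg: float,
                  d_over_lambda: float = 0.5,
                  loading: float = 1e-3) -> np.ndarray:
    """MVDR (Capon) beamformed slow-time series toward ``theta_deg``.

    Weights w = R^-1 a / (a^H R^-1 a) satisfy the distortionless constraint
    w^H a = 1 exactly while minimizing total output power, which places
    adaptive nulls on co-range interferers.  The covariance is the slow-time
    sample average of the slice with diagonal loading; a singular covariance
    is flagged and re-loaded more heavily.
    """
    x = sl.samples
    a = steering_vector(theta_deg, sl.n_channels, d_over_lambda)
    if sl.n_channels == 1:
        return x[:, 0].copy()
    r = _covariance(x, loading)
    try:
        r_inv_a = np.linalg.solve(r, a)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; applying heavier diagonal loading",
                      stacklevel=2)
        r = _covariance(x, 1e-1)
        r_inv_a = np.linalg.solve(r, a)
    w = r_inv_a / (a.conj() @ r_inv_a)
    return x @ w.conj()
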