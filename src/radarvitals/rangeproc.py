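"""Range-domain processing: range-FFT, clutter removal, accumulation, HDBS.

The raw cube is transformed to a range-time map by a fast-time DFT; static
(zero-Doppler) clutter is removed by subtracting the slow-time mean per range
bin.  Slow time is split into segments of K chirps; within each segment a
two-stage accumulation (channels, then groups of P columns) raises the SNR
before detection.  Target range bins are then selected by HDBS: OS-CFAR
thresholding column by column, DBSCAN clustering of the threshold crossings
in (range bin, column) space, and, per cluster, selection of the member bin
with the largest slow-time energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from sklearn.cluster import DBSCAN

from .synth import DataCube

__all__ = [
    "RangeTimeMap", "SegmentMatrix", "TargetCluster", "DetectionResult",
    "range_fft", "remove_clutter", "two_stage_accumulate",
    "os_cfar_threshold_factor", "os_cfar", "hdbs", "detect_segment",
]


@dataclass
class RangeTimeMap:
    """Complex range-FFT coefficients indexed (range bin m, chirp n, channel i).

    All M bins are kept; targets are constrained below the fast-time Nyquist
    so only bins < M/2 carry physical ranges (one-sided interpretation).
    """

    coefficients: np.ndarray
    bin_width: float   # m of range per bin

    def __post_init__(self):
        if self.coefficients.ndim != 3:
            raise ValueError("range-time map must be 3-D (bin, chirp, channel)")

    @property
    def n_bins(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_chirps(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class SegmentMatrix:
    """Accumulated M x K/P matrix of one time segment."""

    values: np.ndarray
    segment_index: int
    k_chirps: int
    p_accumulation: int

    def __post_init__(self):
        if self.values.shape[1] != self.k_chirps // self.p_accumulation:
            raise ValueError("column count must equal K/P")


@dataclass
class TargetCluster:
    """One DBSCAN cluster of CFAR detections and its selected range bin."""

    members: np.ndarray          # (n, 2) array of (bin, column) cells
    selected_bin: int
    energy: float
    range_m: float


@dataclass
class DetectionResult:
    """HDBS output for one time segment."""

    segment_index: int
    candidates: np.ndarray       # (n, 2) (bin, column) CFAR crossings
    clusters: list = field(default_factory=list)

    @property
    def ranges(self) -> np.ndarray:
        return np.array([c.range_m for c in self.clusters])

    @property
    def bins(self) -> np.ndarray:
        return np.array([c.selected_bin for c in self.clusters], dtype=int)


# ---------------------------------------------------------------------------

def range_fft(cube: DataCube) -> RangeTimeMap:
    """Fast-time DFT of the raw cube, one length-M transform per (chirp, channel)."""
    coeff = np.fft.fft(cube.samples, axis=0)
    return RangeTimeMap(coefficients=coeff,
                        bin_width=cube.config.range_bin_width)


def remove_clutter(rtm: RangeTimeMap) -> RangeTimeMap:
    """Static clutter removal: subtract the slow-time mean per (bin, channel).

    Removes zero-Doppler echoes of motionless reflectors; the output's
    slow-time mean is exactly zero for every bin and channel, which also
    makes the operation idempotent.
    """
    coeff = rtm.coefficients
    if coeff.shape[1] < 2:
        raise ValueError("need at least two chirps to estimate the clutter mean")
    cleaned = coeff - coeff.mean(axis=1, keepdims=True)
    return RangeTimeMap(coefficients=cleaned, bin_width=rtm.bin_width)


def two_stage_accumulate(segment: np.ndarray, p_accumulation: int,
                         segment_index: int = 0,
                         coherent: bool = True) -> SegmentMatrix:
    """Two-stage accumulation of an M x K x I segment into M x K/P.

    Stage 1 sums the I channels element-wise; stage 2 sums every P
    consecutive slow-time columns.  ``coherent=True`` sums complex values
    (full 10 log10(I P) gain when the signal is phase-aligned across channels
    and columns); ``coherent=False`` accumulates magnitudes instead, which is
    robust to the inter-channel phase progression of off-boresight targets
    and to large slow-time phase excursions.
    """
    if segment.ndim != 3:
        raise ValueError("segment must be M x K x I")
    m, k, _ = segment.shape
    if k % p_accumulation != 0:
        raise ValueError(f"segment length {k} not divisible by P={p_accumulation}")
    data = segment if coherent else np.abs(segment)
    stage1 = data.sum(axis=2)                                     # M x K
    stage2 = stage1.reshape(m, k // p_accumulation, p_accumulation).sum(axis=2)
    return SegmentMatrix(values=stage2, segment_index=segment_index,
                         k_chirps=k, p_accumulation=p_accumulation)


# ---------------------------------------------------------------------------
# OS-CFAR
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def os_cfar_threshold_factor(pfa: float, n_train: int, rank: int) -> float:
    """Threshold factor alpha of an OS-CFAR square-law detector.

    For exponentially distributed cell powers the false-alarm probability of
    the rank-k order-statistic test ``z > alpha * x_(k)`` is

        Pfa(alpha) = prod_{i=0}^{k-1} (N - i) / (N - i + alpha),

    solved here for alpha by bisection.
    """
    if not 0 < pfa < 1:
        raise ValueError("pfa must lie in (0, 1)")
    if rank > n_train or rank < 1:
        raise ValueError("rank must lie in [1, n_train]")

    def log_pfa(alpha):
        i = np.arange(rank)
        return np.sum(np.log(n_train - i) - np.log(n_train - i + alpha))

    f = lambda a: log_pfa(a) - np.log(pfa)
    hi = 10.0
    while f(hi) > 0:
        hi *= 2
    return float(brentq(f, 1e-9, hi, xtol=1e-10))


def os_cfar(column: np.ndarray, n_train: int = 16, n_guard: int = 2,
            rank: int = 12, pfa: float = 1e-3,
            scale: float | None = None) -> np.ndarray:
    """Detected cell indices of one column via ordered-statistics CFAR.

    ``column`` holds cell magnitudes; the test operates on powers
    (squared magnitudes, the square-law convention under which the
    false-alarm calibration is exact for Rayleigh noise).  ``n_train`` is the
    total training-cell count (split across the two sides), ``n_guard`` the
    guard cells per side, ``rank`` the order statistic used.  ``scale``
    overrides the threshold factor; otherwise it is derived from ``pfa``.
    Near the column edges the truncated training window renormalizes the
    rank proportionally and re-derives the factor for the same ``pfa``.
    """
    column = np.asarray(column, dtype=float)
    power = column ** 2
    m = column.size
    half = n_train // 2
    if n_train + 2 * n_guard + 1 > m:
        raise ValueError("CFAR window does not fit within the column")
    if rank > n_train:
        raise ValueError("rank exceeds the number of training cells")

    detected = []
    for cell in range(m):
        lo = np.arange(max(0, cell - n_guard - half), max(0, cell - n_guard))
        hi = np.arange(min(m, cell + n_guard + 1),
                       min(m, cell + n_guard + 1 + half))
        train = np.concatenate([power[lo], power[hi]])
        n_avail = train.size
        if n_avail == 0:
            continue
        k_eff = min(n_avail, max(1, int(round(rank * n_avail / n_train))))
        alpha = (scale if scale is not None
                 else os_cfar_threshold_factor(pfa, n_avail, k_eff))
        stat = np.partition(train, k_eff - 1)[k_eff - 1]
        if power[cell] > alpha * stat:
            detected.append(cell)
    return np.array(detected, dtype=int)


# ---------------------------------------------------------------------------
# HDBS
# ---------------------------------------------------------------------------

def hdbs(candidates: np.ndarray, energy: np.ndarray, bin_width: float,
         segment_index: int = 0, eps: float = 6.0,
         min_samples: int = 5) -> DetectionResult:
    """Cluster CFAR crossings and select one range bin per cluster.

    ``candidates`` is an (n, 2) array of (range bin, column) cells from one
    segment; ``energy`` maps range bin -> summed slow-time energy
    sum_n |R[m, n]|^2 of the clutter-removed range-time map.  DBSCAN runs on
    the raw (bin, column) coordinates (Euclidean metric, eps in range-bin
    units, unit column weight); noise points are discarded, and within each
    cluster the member bin with the maximum energy is the target bin.  An
    empty candidate set yields an empty result.
    """
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 2)
    result = DetectionResult(segment_index=segment_index,
                             candidates=candidates.astype(int))
    if candidates.shape[0] == 0:
        return result
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(candidates)
    for lab in sorted(set(labels) - {-1}):
        members = candidates[labels == lab].astype(int)
        bins = np.unique(members[:, 0])
        best = bins[np.argmax(energy[bins])]
        result.clusters.append(TargetCluster(
            members=members, selected_bin=int(best),
            energy=float(energy[best]), range_m=float(best * bin_width)))
    result.clusters.sort(key=lambda c: c.selected_bin)
    return result


def detect_segment(segment: np.ndarray, bin_width: float,
                   segment_index: int = 0, p_accumulation: int = 8,
                   coherent: bool = True, n_train: int = 16, n_guard: int = 2,
                   rank: int = 12, pfa: float = 1e-3, eps: float = 6.0,
                   min_samples: int = 5,
                   max_range_bin: int | None = None) -> DetectionResult:
    """Full HDBS detection on one clutter-removed M x K x I segment."""
    seg_mat = two_stage_accumulate(segment, p_accumulation,
                                   segment_index, coherent=coherent)
    mags = np.abs(seg_mat.values)
    limit = mags.shape[0] // 2 if max_range_bin is None else max_range_bin
    cells = []
    for col in range(mags.shape[1]):
        for b in os_cfar(mags[:limit, col], n_train, n_guard, rank, pfa):
            cells.append((b, col))
    energy = np.sum(np.abs(segment) ** 2, axis=(1, 2))
    return hdbs(np.array(cells, dtype=float).reshape(-1, 2), energy,
                bin_width, segment_index, eps, min_samples)
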