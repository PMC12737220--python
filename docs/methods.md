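# Methods

## Signal model and simulator

The simulator produces the raw complex IF data cube X[m, n, i] (fast time ×
slow time × virtual channel) of an FMCW MIMO radar observing one or more
breathing subjects plus motionless clutter:

    X[m,n,i] = Σ_l a_l exp(j[2π f_IF,l m Ts + 4π fc (d_l + s_l(t_n))/c
                            + 2π d_i sin(θ_l)/λ]) + w[m,n,i]

* f_IF,l = 2 S d_l / c is the beat frequency of target l (sweep slope S),
  sampled over the ADC window only; chirp edges are not modelled.
* s_l(t) is chest displacement: a respiration fundamental with a decaying
  harmonic series plus a much weaker heartbeat tone.
* The channel term is an ideal I-element virtual uniform linear array at
  λ/2 spacing.  TDM-MIMO is idealized: no inter-chirp motion within a frame
  and no transmitter phase errors, so no phase-compensation step exists or
  is needed.
* w is circular white Gaussian noise.  **SNR convention:** the per-sample
  power of the strongest target's IF tone divided by the complex noise
  variance.  For 1-D signal fixtures (`add_awgn`) the convention is mean
  signal power over noise variance.  Both are documented rather than
  universal — any comparison across SNR conventions must rescale.

Radar defaults follow a 77 GHz automotive-band sensor: 3.99 GHz bandwidth,
70 MHz/µs slope, 50 µs ADC window at 4 MHz (M = 200 samples), 20 Hz frame
rate, 2×4 TDM-MIMO (I = 8).  Range-bin width is c·fs/(2SM) ≈ 4.29 cm and the
unambiguous range ≈ 4.3 m.

Default vital profile (the study conditions): respiration 0.3 Hz with 4 mm
amplitude and harmonic weights (2nd: 0.20, 3rd: 0.03); heartbeat 1.233 Hz at
0.15 mm; initial phases zero (overridable).  The harmonic series decays fast
enough that the strongest in-band respiratory product (3rd harmonic,
0.9 Hz, 0.12 mm) competes with but does not exceed the heartbeat — the
regime the method is designed for.  A slowly decaying series (e.g. 1/h²
with a 0.4 mm third harmonic) would dominate every in-band selection rule
and no strongest-component method could recover the heartbeat.

### What the simulator does not emulate

Antenna patterns, multipath and ghost targets, body motion other than the
two tones (no posture shifts, no respiratory irregularity), RCS fluctuation,
TDM phase errors, and mutual shadowing (an "occluded" rear subject is
attenuated only via its reflectivity).  Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
robustness to real-world artifacts.

## Range processing

* **Clutter removal** subtracts the slow-time mean per (bin, channel)
  within each K-chirp segment, making segments independent processing units;
  the operation is exactly idempotent.
* **Two-stage accumulation** (K = 128 chirps per segment, P = 8 columns)
  defaults to coherent complex sums, which carries the full 10·log10(I)
  = 9 dB channel gain for boresight targets.  The end-to-end pipeline uses
  the documented non-coherent (magnitude) switch instead: the coherent
  channel sum has *zero* gain at ±30° azimuth (the inter-element phase
  progression of π/2 per element sums to zero over 8 elements), and the
  ~13 rad slow-time respiration phase excursion likewise cancels coherent
  column sums.  Magnitude accumulation trades some gain for uniform
  behaviour across the field of view.
* **OS-CFAR** runs on cell powers (square-law detector), 16 training cells,
  2 guard cells per side, rank k = 12, with the threshold factor α solved
  from Pfa = Π_{i<k} (N−i)/(N−i+α) at a design false-alarm rate of 1e-3 —
  exact for exponential cell powers and verified by Monte Carlo.  Near
  column edges the truncated training window renormalizes the rank
  proportionally and re-solves α.  These detector parameters are this
  package's choices; only the method itself is prescribed upstream.
* **HDBS**: DBSCAN over the (range bin, column) threshold crossings of one
  segment (Euclidean metric, eps = 6 range bins, min_samples = 5, unit
  column weight); noise points are dropped; per cluster, the member bin
  with the largest slow-time energy is the target bin and the reported
  range is bin × bin-width.  Consequence of eps = 6: subjects closer than
  ~6 bins (≈26 cm) merge into a single range cluster and are separated in
  angle only, both inheriting the cluster's selected bin.

## Angle processing

* **Doppler accumulation** keeps the 8 Doppler bins with the largest
  channel-summed power as spatial snapshots.  Respiration phase modulation
  spreads energy over roughly (β+1)·f_r ≈ 4 Hz (Carson's rule, β ≈ 13 rad),
  so the retained bins cover the vital-motion sidebands.
* **Model order** comes from the largest eigenvalue-gap ratio of the
  snapshot covariance (capped at 3 sources); the covariance always receives
  diagonal loading of 1e-3·trace/I.
* **Root-MUSIC** roots the noise-subspace polynomial Σ_k diag_k(E_n E_nᴴ) z^k
  and keeps the n roots inside and nearest the unit circle; root phase maps
  to sin θ through d/λ.  Verified against a fine-grid spectral MUSIC oracle
  to 0.1°.
* **MVDR separation** uses the slow-time sample covariance of the slice per
  segment (a full-recording covariance is available by concatenating
  segments before the call).  The distortionless constraint wᴴa = 1 holds
  exactly by construction.

## VLW heartbeat extraction

Cascade: VMD → heartbeat-mode selection → LMD → correlation gating →
wavelet denoising → summation of the kept, denoised product functions.

* **VMD** (ADMM): K = 6 modes, bandwidth penalty α = 2000, dual step τ = 0
  (no exact-reconstruction enforcement; robust under noise), tolerance 1e-6,
  500-iteration cap, uniform centre-frequency initialization, mirror
  extension.  Modes are canonicalized by ascending centre frequency.
* **Mode selection**: the mode centred in the heartbeat band [0.8, 2.0] Hz
  (48–120 bpm); ties broken by in-band energy; nearest-centre fallback with
  a flag.  Because an over-specified K splits a single physical component
  across near-duplicate modes, modes centred within 0.1 Hz of the winner are
  absorbed into it — without this, a clean heartbeat loses ~half its energy
  to its own duplicates.
* **LMD** extracts product functions highest-frequency-first with
  moving-average smoothing of the extrema-pair local mean and envelope.
  Signals are mirror-extended about their first/last interior extremum
  (even reflection at an extremum is slope-free; endpoint reflection kinks
  mid-slope and corrupts the envelope).  Sifting stops when the residual
  envelope is within 5 % of unity; PF extraction stops when fewer than five
  extrema remain or the residual drops below 5 % of the input scale.
* **Correlation gating** keeps PFs with Pearson r strictly above 0.35.  The
  reference is the VMD-selected heartbeat mode (switchable to the raw
  phase).  Rationale: with respiration ~25× the heartbeat, a perfect
  heartbeat PF correlates with the raw phase at only r ≈ 0.04, so a
  raw-phase reference would discard every PF; referencing the signal LMD
  actually decomposed keeps heartbeat-carrying PFs and rejects noise.
  When nothing passes, the best-correlated PF is kept and flagged.
* **Wavelet thresholding**: db4, depth 2, hard universal threshold
  σ√(2 ln n) with σ from the MAD of the finest details.  Depth 2 keeps the
  whole heartbeat band inside the approximation at the 20 Hz rate, so
  thresholding removes only out-of-band noise (~6 dB gain on a 0 dB tone);
  a 4-level soft-threshold variant measurably attenuates the tone itself
  (negative gain), which is why both defaults differ from the more common
  textbook choice.

Operating envelope: on directly synthesized phase signals the cascade is
reliable for phase-domain SNR ≳ 28 dB (heartbeat above the in-band noise
floor).  This is the regime the radar chain actually delivers — range-FFT
(×200) and beamforming (×8) processing gain put cube-level SNRs of ~20 dB
far above it.

## FIIB frequency estimation

Model x[n] = Σ_l A_l e^{j2πf_l n}, l = 1..L, leakage kernel
S_i(f) = (1 − e^{j2πNS(f̂_i − f)})/(1 − e^{j2π(f̂_i − f)}).

* **Coarse stage** (first iteration only): L times, pick the strongest
  residual FFT bin, set f̂ to the bin centre and Â to the leakage-corrected
  bin value / NS, subtract the component's kernel from the residual.
  Ties break toward the lowest bin index.
* **Fine stage** (Q = 10 iterations): for each component, evaluate the
  leakage-corrected DTFT at f̂ ± 0.5/NS (all other components' leakage
  subtracted) and apply the two-point interpolated-DFT correction
  δ = ½·Re{(X₊ + X₋)/(X₊ − X₋)} (clipped to ±1 bin as a noise guard);
  then refresh amplitudes with two passes of Â_l = (X(f̂_l) −
  Σ_{i≠l} Â_i S_i(f̂_l))/NS.  All updates within an iteration are computed
  simultaneously from the previous iteration's state rather than swept
  sequentially: simultaneous updates preserve the exact conjugate symmetry
  of the component set on real inputs, which is what makes the real-valued
  variant *identical* (to machine precision) rather than merely close.
* **Real-valued variant**: searches bins 0..NS/2−1 and refines L/2
  components.  The leakage of a conjugate pair is subtracted exactly as
  Â_i S_i(f) + conj(Â_i S_i(−f)) — including the refined component's own
  negative-frequency partner — and the mirrored half is reconstructed as
  f_{L−l+1} = 1 − f_l, Â_{L−l+1} = Â_l*.  Per fine iteration this costs
  exactly half the leakage-kernel evaluations of the full-band variant at
  any L (counted, not estimated).  Because the two variants are
  algebraically equivalent, their convergence-iteration counts under the
  0.001 stopping rule coincide at every SNR.
* Default L = 4 (two positive-frequency components: heartbeat plus the
  strongest interferer); heart-rate readout picks the largest-amplitude
  in-band component and returns 60·f̂ bpm, with a flagged FFT-peak fallback.

Baselines: FFT peak-picking is deliberately uninterpolated (the grid-
quantization floor for f1 = 1.05 Hz on the 0.1 Hz grid is (0.05)² =
2.5e-3 Hz²); the MUSIC baseline uses forward–backward temporal smoothing
with subarray length NS/2 and a 0.001-normalized-frequency grid, and two
signal-subspace dimensions per real tone.  The plotted reference is the
single-complex-tone frequency CRB 6fs²/((2π)²·SNR·NS(NS²−1)).

## Pipeline and evaluation

Per 128-chirp segment the pipeline detects ranges and angles once and
reuses the (bin, angle) solution for every 1 s window hop inside it;
detections are associated across segments greedily (±3 bins, ±10°) and
tracks supported in at least half the segments survive.  Windows are 25.6 s
(512 samples) hopping 20 samples.  Evaluation matches estimates to truth by
nearest range+angle and reports HR MAE, the SD of per-target MAEs, relative
range error |d̂−d₀|/d₀·100, DOA deviation, and Bland–Altman bias with
±1.96·SD limits.

## Problem sizes

End-to-end study scenes use 32 s recordings (640 frames → 5 segments,
7 sliding windows) and cube-level SNR 20 dB; Monte-Carlo benchmarks use
1000–2000 repetitions per operating point (2000 in the acceptance script);
convergence studies use 500 repetitions per SNR.  These sizes were chosen so
the full suite runs in about a minute on one CPU while keeping Monte-Carlo
standard errors a small fraction of the quantities measured.

## Known limitations

* Subjects closer than the DBSCAN radius (~26 cm) in range share a range
  bin; their ranges are reported at the cluster's energy-argmax bin.
* Range readout is bin-quantized (±2.1 cm); no sub-bin interpolation.
* The eigenvalue-gap model-order rule assumes well-separated source powers;
  heavily correlated co-range sources with identical respiration rates can
  under-count.
* LMD stopping criteria are heuristic (the upstream literature leaves them
  open); very long windows may fragment a noisy mode into many PFs.
* Heart rates outside [0.8, 2.0] Hz (48–120 bpm) are rejected by the band
  selection; the band is configurable.
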