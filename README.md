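# radarvitals

Non-contact, multi-person heart-rate estimation from raw FMCW radar data.

A 77 GHz frequency-modulated continuous-wave (FMCW) radar measures chest-wall
micro-motion: the beat (IF) frequency of each echo encodes a subject's range,
and the slow-time phase at that range encodes displacement through
φ(t) = 4π(d₀ + s(t))/λ, where s(t) mixes a millimetre-scale respiration
movement with a heartbeat movement roughly two orders of magnitude weaker.
With several people in the scene the challenges compound: echoes overlap in
range, subjects sit at the same distance and must be separated in angle, and
respiration harmonics crowd the heartbeat's spectral neighbourhood.

`radarvitals` implements a complete processing chain for this problem,
exercised end to end on a bundled scene simulator:

1. **Range domain** — fast-time FFT, static-clutter removal (slow-time mean
   subtraction), two-stage accumulation over the virtual-array channels and
   slow-time columns, then *HDBS* range detection: OS-CFAR adaptive
   thresholding, DBSCAN clustering of the threshold crossings, and per-cluster
   selection of the bin maximizing the slow-time energy Σₙ|R̂[m,n]|².
2. **Angle domain** — Doppler-FFT accumulation into high-SNR spatial
   snapshots, Root-MUSIC direction finding on the 8-channel TDM-MIMO virtual
   array, and MVDR (Capon) beamforming with weights
   w = R⁻¹a(θ)/(aᴴR⁻¹a(θ)) to separate co-range subjects.
3. **Heartbeat extraction (VLW)** — variational mode decomposition of the
   unwrapped phase, selection of the heartbeat-band mode, local mean
   decomposition into product functions, Pearson-correlation gating
   (r > 0.35), and wavelet-threshold denoising.
4. **Heart-rate estimation (FIIB)** — the signal is modelled as
   x[n] = Σₗ Aₗ e^{j2πfₗn} and fitted by fast iterative interpolated
   beamforming: iterative strongest-bin picking with Dirichlet-kernel leakage
   subtraction, ±half-bin interpolated-DFT frequency refinement, and
   amplitude correction.  The real-valued variant exploits the conjugate
   symmetry X[n] = X*[NS−n] of real signals to estimate only the L/2
   positive-frequency components, halving the leakage-evaluation count while
   producing identical estimates.

Heart rates are tracked with 25.6 s sliding windows hopping every 1 s, and
scored with MAE/RMSE, relative range error, DOA deviation and Bland–Altman
agreement.

## Worked example

Two subjects in line with the radar (0.8 m and 1.5 m, rear subject occluded),
heartbeats at 1.233 Hz and 1.5 Hz, a strong static reflector at 2.5 m,
SNR 20 dB:

```python
from radarvitals import (HeartRateModel, SceneDescription, TargetTruth,
                         VitalProfile)

scene = SceneDescription(
    targets=(TargetTruth(0.8, 0.0, VitalProfile(heartbeat_frequency=1.233)),
             TargetTruth(1.5, 0.0, VitalProfile(heartbeat_frequency=1.5,
                                                respiration_frequency=0.25),
                         reflectivity=0.8)),
    static_clutter=((2.5, 2.0),), snr_db=20, duration=32.0, seed=1)
res = HeartRateModel.from_scene(scene).fit()
print(res.summary())
```

```
Multi-target heart-rate estimate
  cube: (200, 640, 8) (fast x slow x channel), 5 segments of 128 chirps
  targets detected: 2
  id   range (m)   azimuth (deg)   median HR (bpm)   windows
   0       0.814            0.00             73.85         7
   1       1.499           -0.00             89.99         7
```

Both subjects are found at their true ranges (range-bin width 4.3 cm) and
their median heart rates land within 0.2 bpm of the ground truth (73.98 and
90 bpm).  `res.evaluate(scene)` scores the fit against the scene:

```
HR MAE 0.19 bpm | range error 0.89 % | DOA deviation 0.001 deg
```

The frequency estimator is usable on any 1-D series through the model
interface.  On the two-tone test signal (amplitudes 1 and 0.8 at 1.05 and
1.25 Hz — two FFT bins apart at 200 samples / 20 Hz — with 25 dB noise):

```python
from radarvitals import SinusoidModel, add_awgn, two_tone
x = add_awgn(two_tone(1.0, 0.8, 1.05, 1.25, 20.0, 200), 25, seed=0)
print(SinusoidModel(x, fs=20.0).fit(4).summary())
```

```
Sum-of-sinusoids fit (FIIB, real variant)
  samples: 200   fs: 20 Hz   iterations: 10
  fit R^2: 0.997268
  component   freq (Hz)      |A|        phase (rad)
          1     1.05025     0.50383    -1.57231
          2    18.94975     0.50383    +1.57231
          3     1.24934     0.40335    -1.56026
          4    18.75066     0.40335    +1.56026
```

Each real tone appears as a conjugate pair (|A| = amplitude/2); the off-grid
frequencies are recovered to a few 10⁻⁴ Hz, far below the 0.1 Hz FFT
resolution.

## Command line

```bash
radarvitals simulate scene.yaml cube.h5      # scene description -> IF cube
radarvitals detect cube.h5 detections.csv    # HDBS range detections
radarvitals estimate-hr cube.h5 --out-prefix run1
radarvitals benchmark --snr 5 --snr 25 --reps 1000 bench.csv
radarvitals vlw-demo vlw_spectra.csv         # stage-wise cascade spectra
```

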