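# Methods

## Problem and pipeline

`camoxy` estimates peripheral oxygen saturation (SpO2) from multimodal facial
video without skin contact. The measurement principle is the same as in a
fingertip pulse oximeter: oxygenated and deoxygenated hemoglobin absorb red
and near-infrared light differently, so the relative strength of the cardiac
pulsation (AC) against the static reflectance (DC) at two wavelengths — the
*ratio of ratios* RR = (AC/DC)_red / (AC/DC)_nir — maps monotonically to SpO2,
classically via the linear calibration S = A − B·RR.

The pipeline turns raw multi-camera recordings into model inputs in four
stages:

1. **Multimodal registration (geometry).** Disparity maps of a rectified
   active-stereo pair are back-projected to a 3D point cloud
   (z = f·b/d). Any 3D point projects into a 2D camera c as
   s·[u,v,1]ᵀ = K_c·(R_c·R_rect⁻¹·p + T_c); gray values at fractional pixel
   positions are obtained by 4-neighbour bilinear interpolation. A forehead
   rectangle selected on the reference image becomes an h×w grid of 3D
   points carrying one gray value per modality (R, G, B, NIR 780 nm,
   NIR 940 nm).
2. **Rigid 3D ROI tracking.** Up to 468 indexed face-mesh landmarks per
   frame are lifted into the cloud; the 6-DoF transform (R_k, t_k) minimising
   Σᵢ‖R·p_1i + t − p_ki‖² between frame 1 and frame k is solved in closed form
   (SVD of the centred cross-covariance with determinant-sign correction).
   Frames are always matched to frame 1, never chained, so tracking error
   does not accumulate. The frame-1 ROI grid is carried through the video and
   re-projected into every modality, yielding registered fixed-size crops of
   the *same skin patch*. Crop stability is scored by SSIM (7×7 uniform
   window, K1=0.01, K2=0.03, dynamic range from the container bit depth).
3. **Blockwise cubic detrending (preprocess).** The 5-channel ROI video is
   partitioned into m×n equal blocks (floor-sized, residual margins
   discarded; default 5×5). Per block, channel and time segment, an OLS cubic
   P(t)=a·t³+b·t²+c·t+d is fitted to the block's spatial-mean series and the
   video decomposes exactly into a trend part (the DC analogue, spatially
   constant within a block) and a detrended part (the pulsatile AC analogue).
   Fitting a single cubic to a multi-minute recording is a weak trend model,
   so the fit runs on consecutive segments (default 30 s); `segment_s=None`
   restores the whole-recording reading. Holes are excluded from block means;
   blocks that are >50 % holes are dropped and masked.
4. **Observations and regression (model).** Both parts are sliced into
   non-overlapping 1-s, 15-frame windows; detrended-then-trend concatenation
   gives a 10×15×h′×w′ volume labelled with the 1 Hz reference value at the
   window start. The regressor is a 3-d ResNet: [7,7,7] stem convolution,
   four residual stages of [3,3,3] kernels with standard channel doubling,
   global average pooling over all spatio-temporal axes, and an FC 512→64→1
   head with dropout 0.3 and a sigmoid output mapped linearly onto a
   configurable SpO2 range. Training minimises MSE with Adam; early stopping
   monitors a validation split and the best-validation weights are restored.
   Rounding to integer percent is the only post-processing (references from
   clinical oximeters are integers). A channel-selection switch runs the
   identical code path on RGB-only or NIR-only observations (780/940 nm),
   the NIR mode being what overnight monitoring would use.

Because the facial circulation leads the fingertip by roughly 20 s, training
labels apply a fixed 20 s advance to the reference, and evaluation re-aligns
the reference within 20 ± 5 s (integer-second scan maximising Pearson
correlation; ties resolve toward the nominal lag, then the smaller shift).
Agreement is summarised by MAE, Pearson ρ, Bland–Altman bias with 95 % limits
of agreement (bias ± 1.96 × sample SD of paired differences, n−1), and PERC —
the percentage of 1-s time points with |error| ≤ k.

## Networks in NumPy

All networks (the 3-d ResNets, the tiny test variant, and the five baseline
feature-extraction strategies A–E with their 1-d/2-d CNN and LSTM extractors)
are built on a small reverse-mode autodiff engine over NumPy arrays written
for this package: im2col-based N-d convolution, fused batch normalisation,
LSTM assembled from primitive ops, Adam. Gradients of every operation are
verified against central finite differences in the test suite. All randomness
(initialisation, shuffling, dropout) flows from explicit seeds, so training
histories are bit-reproducible on a fixed machine.

Two deliberate input-handling choices matter for trainability: inputs are
divided by the sensor full scale, and each network starts with a
parameter-free per-channel standardisation (`InputNorm`, batch statistics at
training time, running statistics at inference). The detrended channels are
two orders of magnitude smaller than the trend channels; without per-channel
balancing the early convolutions are dominated by the DC channels and the
pulsatile signal — which carries essentially all the SpO2 information — takes
implausibly long to surface.

`tiny3d` is a width-reduced two-stage instance of the same
stem/residual/pool/head pattern (stem (3,5,5) kernel with stride (2,5,5),
width 8, two residual blocks, FC 16→16→1). It exists so that CPU-only test
runs finish in minutes; the full-width ResNet 10/18/34 variants are built by
the same code and their parameter counts (14.6 M / 33.4 M / 63.7 M) increase
strictly with depth. The model config optionally average-pools the input
volume spatially (`input_pool`, default 1) before the network; the synthetic
experiment uses a factor of 2. Besides cutting compute roughly fourfold, the
pre-smoothing removes most of the fine spatial texture, which on synthetic
data is pure nuisance: without it the optimizer spends a long, init-dependent
plateau fitting per-recording texture shortcuts before discovering the
pulsatile-amplitude features that actually generalise.

## The synthetic study

No public recordings exist for this modality combination, so the package
ships a simulator that emulates the acquisition end to end and serves as the
ground-truth authority for every test:

* **Scene.** A curved, textured forehead-like surface (paraboloid patch,
  curvature radius 0.15 m, extent 0.20 × 0.16 m at 1.5 m) imaged by a
  calibrated rig: an RGB reference camera mounted as the rectified stereo
  reference, and two off-axis NIR cameras boresighted at the surface centre.
  Rendering is exact per-pixel ray/paraboloid intersection (closed-form
  quadratic), so disparity maps, landmark positions and surface coordinates
  all have analytic oracles. A flat-surface mode (`curvature_radius_m=inf`)
  makes bilinear cloud interpolation exact for the tightest tests.
* **Radiance.** I_c(x,y,t) = G_c(t)·DC_c(x,y)·(1 − α_c(S(t))·p(t)) + ε, with
  DC_c a smooth random reflectance field (rms contrast 10 %) plus
  high-contrast marker blobs (for SSIM tests), G_c a ±2 % sinusoidal
  illumination drift, p(t) a unit-amplitude cardiac waveform (70 bpm sinusoid
  plus 0.3-amplitude second harmonic), and ε Gaussian sensor noise (σ = 1
  gray at 8 bit). The NIR 940 modulation depth is a0 = 0.05; the red depth is
  a0·RR(S) with RR(S) = (A−S)/B, A = 110, B = 25 (the classic empirical
  calibration line); G, B and 780 nm interpolate between the red and 940 nm
  endpoints by wavelength. Consequently the AC/DC ratio-of-ratios computed
  from the rendered video inverts *exactly* to S — the property the physics
  oracle tests exploit. a0 = 0.05 is the clean-encoding regime; real skin
  sits nearer 1–2 %, so passing tests demonstrate pipeline correctness, not
  robustness at clinical signal-to-noise.
* **Protocol.** 15 Hz frame rate, breath-hold SpO2 traces (plateau 98 %,
  ramps at 0.7 %/s down and 2 %/s up to nadirs in 80–92 %, integer-rounded at
  1 Hz, range 80–99 %), rigid head motion of 2° / 3 mm amplitude at
  ~0.08 Hz, landmark jitter 0.2 px, and a fingertip-style reference exported
  as the facial trace delayed by 20 s. Frame geometry is scaled down
  (96×80 px images, 40×40 px ROI) so complete recordings stay comfortably in
  memory; all temporal and physiological constants are at protocol scale.

What the simulator does *not* emulate: facial expressions (the head is
perfectly rigid), specular reflections and shadows, melanin diversity,
ballistocardiac micro-motion, camera rolling shutter, and the weak real-world
modulation depths. Results on it are a correctness statement about the
pipeline, not a clinical validation.

## The end-to-end experiment

`camoxy.pipeline.synthetic_experiment` simulates recordings with distinct
textures, pose trajectories, noise streams, drift phases and nadirs, trains
`tiny3d` on one subset and scores held-out recordings against their
ground-truth facial traces. The default experiment uses 20 recordings of
60 s (16 train / 4 test, 640 labelled training observations) with ROI 40×40,
2×2 input pooling, learning rate 3·10⁻³, batch 32, weight decay 10⁻⁴,
dropout 0.2, and 300 epochs with patience 100 — sizes chosen so the whole
experiment runs on a single CPU core in well under ten minutes. Two aspects
proved essential for generalisation and are worth knowing when adapting the
experiment. First, training-set diversity: with only a handful of training
recordings the network learns per-recording texture shortcuts and produces
systematic offsets on unseen recordings; sixteen distinct textures suffice
to suppress this. Second, full convergence: the optimisation passes through
a long plateau in which validation loss stalls while the network fits
texture features, and only later discovers the pulsatile-amplitude features;
a model stopped in the plateau regresses toward the label mean on held-out
data. Input pooling shortens this plateau dramatically, and with it every
initialisation we tested converges within the epoch budget.

## Numerical choices and edge cases

* Pixel convention: 0-based indices, (u, v) = (column, row), pixel centres at
  integers. Bilinear samples needing an out-of-image neighbour are invalid
  (no clamping); invalidity is propagated as masks, never interpolated away.
* Projections with non-positive homogeneous depth, or landing outside the
  image, are invalid per modality; a tracked frame with >20 % invalid ROI
  projections is QC-flagged.
* The rigid-transform solver refuses <3 correspondences and collinear
  configurations (second singular value ≤ 1e−12 relative); the
  determinant-sign correction guarantees det(R) = +1 even for
  reflection-degenerate noisy inputs.
* Detrending reconstructs the input exactly (machine precision) on the
  block-covered region; a trailing segment shorter than 4 frames is absorbed
  into its predecessor.
* Pearson correlation of a constant series raises; the aggregate report
  stores an explicit NaN in that case rather than a silent zero.
* Ratio-of-ratios windows with non-positive DC or (numerically) zero NIR AC
  are flagged invalid, not extrapolated.
* LoA use the sample (n−1) standard deviation, the Bland–Altman convention.
* Reference alignment scans integer-second shifts only, matching the 1 Hz
  reference sampling.

## Known limitations

* The NumPy networks are CPU-bound and two to three orders of magnitude
  slower than a GPU framework; the full-width 3-d ResNets are buildable and
  differentiable but practical training at package scale is limited to
  `tiny3d` and the strategy baselines.
* The linear ratio-of-ratios calibration is the simulator's encoding choice;
  a real system learns a subject-dependent, nonlinear mapping.
* The simulator's reference series differs from the facial trace only by a
  pure delay; real fingertip references also low-pass the waveform.
* Landmark detection itself (face-mesh inference) is out of scope; landmarks
  are consumed from the container or synthesised.
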