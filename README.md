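# camoxy

**Contactless pulse oximetry from multimodal facial video.**

`camoxy` estimates peripheral oxygen saturation (SpO2) from calibrated
VIS–NIR multi-camera recordings of a face — no finger clip, no skin contact.
It is aimed at researchers in camera-based vital-sign monitoring who need a
complete, testable reference pipeline: 3D-information-based registration of
RGB / NIR 780 nm / NIR 940 nm streams, rigid 3D tracking of a forehead region
of interest, blockwise cubic detrending into pulsatile (AC) and quasi-static
(DC) components, a spatio-temporal 3D-CNN regressor, and the standard
agreement-evaluation stack. Because no public dataset covers this modality
combination, the package ships a physics-based simulator that renders
complete synthetic recordings with known SpO2 ground truth, so every stage is
exercised end to end without downloads.

## The method in brief

Pulse oximetry rests on the ratio of ratios: with AC the cardiac-pulsatile
and DC the static part of the skin intensity signal at a red and a
near-infrared wavelength,

```
RR = (AC_red / DC_red) / (AC_nir / DC_nir),        S = A − B·RR
```

maps linearly to SpO2. camoxy realises the AC/DC split spatially and
temporally: disparity maps of a rectified stereo pair are back-projected to a
3D point cloud (`z = f·b/d`); any 3D point lands in camera *c* at

```
s·[u, v, 1]ᵀ = K_c · (R_c · R_rect⁻¹ · p + T_c)
```

so a forehead ROI selected once is sampled consistently in every modality.
Per-frame rigid head pose is the closed-form minimiser of
`Σᵢ ‖R·p_1i + t − p_ki‖²` over lifted 3D facial landmarks (Kabsch/Umeyama).
The tracked 5-channel ROI video is split into m×n blocks, each block's
spatial-mean series is fitted with a cubic `P(t) = a·t³ + b·t² + c·t + d`,
and the video decomposes exactly into a trend part (DC analogue) and a
detrended part (AC analogue). One second of both parts — a 10-channel ×
15-frame volume — forms an *observation*; a 3D ResNet with a sigmoid-scaled
scalar head regresses SpO2 from it. Agreement with a reference oximeter is
reported as MAE, Pearson ρ, Bland–Altman bias with 95 % limits of agreement,
and PERC (fraction of 1-s windows within ±k %), after aligning the reference
within 20 ± 5 s to account for the face-to-fingertip circulatory delay.

## Worked example

`examples/03_detrend_and_rr_estimate.py` simulates a clean breath-hold
recording (one desaturation from 98 % to 85 %), runs registration → tracking
→ detrending, and recovers SpO2 with the classical ratio-of-ratios estimator
— no learning involved:

```
trend + detrended reconstructs the ROI video to 0.00e+00 gray (exact)
window  RR      estimated  true (window mean)
  2.5 s  0.480     98.01 %     98.00 %
  7.5 s  0.480     98.00 %     98.00 %
 12.5 s  0.480     98.00 %     98.00 %
 17.5 s  0.480     98.00 %     98.00 %
 22.5 s  0.554     96.14 %     96.23 %
 27.5 s  0.693     92.67 %     92.72 %
 32.5 s  0.829     89.26 %     89.32 %
 37.5 s  0.963     85.93 %     85.92 %
 42.5 s  0.982     85.46 %     85.48 %
 47.5 s  0.691     92.73 %     92.93 %
 52.5 s  0.480     98.00 %     98.00 %
 57.5 s  0.481     97.97 %     98.00 %
max error 0.20 % — the registration/tracking/detrending chain preserves the oximetry signal
```

The RR column rises as saturation falls (more pulsatile red absorption), and
inverting it through the linear calibration recovers the true trace to within
0.2 % in every 5-s window: the geometric and temporal preprocessing preserve
the oximetry signal essentially losslessly.

The other examples cover simulation (`01`), registration + SSIM-scored ROI
tracking (`02`), training the small 3D CNN on several synthetic recordings
(`04`), and the agreement metrics in isolation (`05`). A thin CLI wraps the
same library calls:

```bash
camoxy simulate --seed 7 --out rec.h5
camoxy run-all rec.h5 --out report.json
```

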