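"""Blockwise cubic detrending and the classical ratio-of-ratios estimate.

Decomposes the tracked ROI video into trend (DC) and detrended (AC) parts,
then recovers SpO2 without any learning: the AC/DC ratio of the red channel
over the NIR 940 nm channel maps linearly to SpO2.
"""

import numpy as np

from camoxy.evaluate import ratio_of_ratios_estimate
from camoxy.pipeline import PipelineConfig, process_recording
from camoxy.simulate import SimConfig, simulate_recording

cfg = SimConfig(duration_s=60.0, breath_cycles=1, breath_nadirs=(85.0,),
                breath_start_s=20.0, noise_sigma=0.0, pose_amplitude_deg=0.0,
                pose_amplitude_mm=0.0, landmark_noise_px=0.0, seed=5)
container, gt = simulate_recording(cfg)
proc = process_recording(container, PipelineConfig(segment_s=20.0))

dec = proc.decomposed
recon_err = np.abs(dec.trend + dec.detrended
                   - proc.crops.data[:, :, :dec.trend.shape[2], :dec.trend.shape[3]]).max()
print(f"trend + detrended reconstructs the ROI video to {recon_err:.2e} gray (exact)")

est = ratio_of_ratios_estimate(dec, window_s=5.0, A=cfg.calib_A, B=cfg.calib_B)
wlen = int(5.0 * 15)
print("window  RR      estimated  true (window mean)")
for i, (t, v, r) in enumerate(zip(est.times, est.values, est.rr)):
    truth = gt.spo2_at_frames[i * wlen:(i + 1) * wlen].mean()
    print(f"{t:5.1f} s  {r:.3f}  {v:8.2f} %  {truth:8.2f} %")
errs = [abs(v - gt.spo2_at_frames[i * wlen:(i + 1) * wlen].mean())
        for i, v in enumerate(est.values)]
print(f"max error {max(errs):.2f} % — the registration/tracking/detrending chain "
      f"preserves the oximetry signal")
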