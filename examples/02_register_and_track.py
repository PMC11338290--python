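"""Register the multimodal streams in 3D and track the forehead ROI.

Back-projects a disparity map into a point cloud, lifts the facial landmarks
to 3D, estimates per-frame 6-DoF rigid head poses, carries the frame-1 ROI
through the video, and scores the tracked crops with SSIM against frame 1.
"""

import numpy as np

from camoxy.geometry import disparity_to_pointcloud, roi_grid_from_rect
from camoxy.simulate import SimConfig, simulate_recording
from camoxy.tracking import crop_roi_video, lift_landmarks, track_roi, tracking_ssim

cfg = SimConfig(duration_s=10.0, breath_cycles=0, seed=11)
container, gt = simulate_recording(cfg)
cameras, rig, _ = container.cameras()

landmark_sets = []
roi = None
for k in range(container.n_frames):
    cloud = disparity_to_pointcloud(container.disparity[k], rig)
    landmark_sets.append(
        lift_landmarks(container.landmarks2d[k], container.landmark_indices, cloud))
    if k == 0:
        roi = roi_grid_from_rect(gt.roi_rect, cloud)

track = track_roi(roi, landmark_sets)
angles = [np.degrees(np.arccos(np.clip((np.trace(t.rotation) - 1) / 2, -1, 1)))
          for t in track.transforms]
print(f"estimated head rotation range: {min(angles):.2f}–{max(angles):.2f} deg "
      f"(simulated amplitude {cfg.pose_amplitude_deg} deg)")
print(f"mean fit residual: {np.mean([t.residual_rms for t in track.transforms]) * 1e3:.3f} mm "
      f"(driven by the {cfg.landmark_noise_px} px landmark jitter)")

crops = crop_roi_video(container, track, cameras, rig.rectification_rotation)
ssim = tracking_ssim(crops)
print(f"tracking SSIM vs frame 1: mean {ssim.mean():.4f}, min {ssim.min():.4f} "
      f"(1.0 = the crop follows the same skin patch perfectly)")
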