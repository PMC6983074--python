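"""Generate a synthetic 9-point calibration session and inspect it.

The generator emulates webcam capture: for each of the 9 on-screen
calibration points it produces 40 frames of eye landmarks whose pupil
displacement is an affine function of the gaze target.
"""

import icpcv

protocol = icpcv.default_train_protocol(screen_size=(1920.0, 1080.0))
params = icpcv.GazeModelParams(landmark_noise_sd=0.5)
session = icpcv.generate_session(protocol, params, seed=42)

print(f"calibration points : {len(protocol.grid_points)}")
print(f"frames per point   : {protocol.frames_per_point}")
print(f"session samples    : {len(session)}")
obs = session[0]
print(f"first target       : {obs.target}")
print(f"left pupil center  : {obs.left.pupil_center.round(2)}")
print(f"left inner corner  : {obs.left.inner_corner.round(2)}")
# 9 x 40 = 360 samples; the pupil sits near its rest position offset
# toward the top-left target, plus 0.5 px landmark noise.
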