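"""Calibrate gaze regressors and score them on the 36-point test grid.

Trains one scalar network per screen coordinate on a 360-sample
calibration session and reports per-coordinate mean absolute error and
mean Euclidean error distance in screen pixels, for all three model
families plus the quadratic polynomial baseline.
"""

import numpy as np

import icpcv
from icpcv import features as feat
from icpcv import regressors as reg

params = icpcv.GazeModelParams(landmark_noise_sd=0.5)
train = icpcv.generate_session(icpcv.default_train_protocol(), params, seed=1)
test = icpcv.generate_session(icpcv.default_test_protocol(), params, seed=2)
ftr = icpcv.featurize_session(train, "icpcv8")
fte = icpcv.featurize_session(test, "icpcv8")

for family in ("mlp", "rbfn", "dnn"):
    mx, my = reg.train_pair(reg.RegressorConfig(family=family, seed=0), ftr)
    r = reg.evaluate(mx, my, fte)
    print(f"{family:5s} avg_x={r.avg_error_x:7.2f}  avg_y={r.avg_error_y:7.2f}  "
          f"dist={r.mean_error_distance:7.2f} px")

ptr = icpcv.featurize_session(train, "pcecv")
pte = icpcv.featurize_session(test, "pcecv")
M = feat.fit_polynomial_mapping(
    list(zip(ptr.iloc[:, :6].to_numpy(), ptr[["target_x", "target_y"]].to_numpy()))
)
errs = [np.linalg.norm(M.predict(f) - y)
        for f, y in zip(pte.iloc[:, :6].to_numpy(),
                        pte[["target_x", "target_y"]].to_numpy())]
print(f"poly  mean error distance = {np.mean(errs):7.2f} px")
# Errors are in pixels of the 1920x1080 screen; tens of pixels is around
# 1-3 degrees of visual angle at typical webcam viewing distance.
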