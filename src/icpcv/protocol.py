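"""Calibration and evaluation protocols.

* Training: a 3x3 grid of 9 points (10% screen margins, even spacing),
  visited row-major, 40 frames per point — 360 calibration samples.
* Testing: each of the 9 points expanded into a 2x2 cluster spaced
  80 px, visited top-to-bottom within columns and columns left-to-right
  — 36 distinct points, 10 frames each, 360 samples.
* Trajectory: a left-to-right diamond sweep; the gaze estimate at each
  point is the mean of 10 per-frame predictions, scored by Euclidean
  distance to the true point.
* Yaw sweep: eye-detection success fraction as the face rotates
  in-plane away from frontal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import segmentation as seg
from . import synth
from .features import feature_vector
from .regressors import predict_point


@dataclass
class ProtocolConfig:
    kind: str  # train_grid | test_grid | trajectory | yaw_sweep
    screen_size: tuple[float, float] = (1920.0, 1080.0)
    grid_points: list = field(default_factory=list)
    frames_per_point: int = 1
    dwell_seconds: float = 1.5  # metadata only; no real-time capture
    trajectory_points: list = field(default_factory=list)
    frames_per_trajectory_point: int = 10
    yaw_angles: list = field(default_factory=list)

    def __post_init__(self):
        if self.frames_per_point < 1:
            raise ValueError("frames_per_point must be >= 1")
        w, h = self.screen_size
        for p in list(self.grid_points) + list(self.trajectory_points):
            x, y = p
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(f"protocol point {p} outside screen {self.screen_size}")


def _grid9(screen_size, margin: float = 0.10):
    w, h = screen_size
    xs = np.linspace(margin * w, (1 - margin) * w, 3)
    ys = np.linspace(margin * h, (1 - margin) * h, 3)
    return [np.array([x, y]) for y in ys for x in xs]  # row-major


def default_train_protocol(screen_size=(1920.0, 1080.0)) -> ProtocolConfig:
    """9-point calibration grid, 40 frames per point (360 samples)."""
    return ProtocolConfig(
        kind="train_grid",
        screen_size=screen_size,
        grid_points=_grid9(screen_size),
        frames_per_point=40,
    )


def default_test_protocol(
    screen_size=(1920.0, 1080.0), cluster_spacing: float = 80.0
) -> ProtocolConfig:
    """36-point test grid: each calibration point becomes a 2x2 cluster
    spaced ``cluster_spacing`` px, visited top-to-bottom then
    left-to-right; 10 frames per point (360 samples)."""
    w, h = screen_size
    half = cluster_spacing / 2.0
    pts = []
    for p in _grid9(screen_size):
        for dx in (-half, half):
            for dy in (-half, half):
                q = p + np.array([dx, dy])
                if not (0 <= q[0] <= w and 0 <= q[1] <= h):
                    raise ValueError(
                        f"cluster offset pushes point {q} off-screen {screen_size}"
                    )
                pts.append(q)
    pts.sort(key=lambda q: (q[0], q[1]))  # columns left-to-right, top-to-bottom within
    return ProtocolConfig(
        kind="test_grid",
        screen_size=screen_size,
        grid_points=pts,
        frames_per_point=10,
    )


def default_trajectory(screen_size=(1920.0, 1080.0), n_points: int = 9) -> ProtocolConfig:
    """Diamond trajectory: points sweep left to right across the screen
    mid-band, alternating below / above the midline."""
    w, h = screen_size
    xs = np.linspace(0.1 * w, 0.9 * w, n_points)
    offsets = [0.0, -1.0, 0.0, 1.0]  # one diamond period, repeated
    pts = [
        np.array([x, 0.5 * h + 0.25 * h * offsets[i % 4]]) for i, x in enumerate(xs)
    ]
    return ProtocolConfig(
        kind="trajectory",
        screen_size=screen_size,
        trajectory_points=pts,
        frames_per_trajectory_point=10,
    )


@dataclass
class TrajectoryResult:
    """Per-point averaged gaze estimates and error distances (px)."""

    points: np.ndarray  # (n, 2) ground truth
    estimates: np.ndarray  # (n, 2) 10-frame-averaged predictions
    per_point_error: np.ndarray  # (n,)
    mean_error_distance: float


def regressor_predictor(model_x, model_y, variant: str):
    """Adapt a trained model pair into an observation -> point predictor."""

    def _predict(obs: synth.GazeObservation) -> np.ndarray:
        return np.asarray(predict_point(model_x, model_y, feature_vector(obs, variant)))

    return _predict


def run_trajectory(
    predict,
    params: synth.GazeModelParams,
    cfg: ProtocolConfig,
    seed: int = 0,
) -> TrajectoryResult:
    """Run the trajectory experiment: simulate ``frames_per_trajectory_point``
    frames per point, predict each, average the predictions, and report
    per-point and mean Euclidean error distance.

    ``predict`` maps a :class:`~icpcv.synth.GazeObservation` to a screen
    point; use :func:`regressor_predictor` for trained model pairs.
    """
    if not len(cfg.trajectory_points):
        raise ValueError("trajectory protocol has no points")
    rng = np.random.default_rng(seed)
    truths, estimates = [], []
    for p in cfg.trajectory_points:
        preds = []
        for _ in range(cfg.frames_per_trajectory_point):
            obs = synth.simulate_observation(
                p, params, seed=int(rng.integers(0, 2**31 - 1))
            )
            preds.append(np.asarray(predict(obs), dtype=float))
        truths.append(np.asarray(p, dtype=float))
        estimates.append(np.mean(preds, axis=0))
    truths = np.asarray(truths)
    estimates = np.asarray(estimates)
    err = np.linalg.norm(estimates - truths, axis=1)
    return TrajectoryResult(truths, estimates, err, float(err.mean()))


def run_yaw_sweep(
    detector=None,
    angles=None,
    n_per_angle: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Detection success fraction per in-plane face rotation angle.

    Renders ``n_per_angle`` synthetic faces at each angle (seeded) and
    runs the eye-presence gate on each; returns {angle: fraction}.
    """
    if angles is None:
        angles = [a * 2.5 for a in range(-4, 5)]  # -10 .. +10 deg
    if not len(angles):
        raise ValueError("angle list is empty")
    rng = np.random.default_rng(seed)
    out = {}
    for ang in angles:
        hits = 0
        for _ in range(n_per_angle):
            frame, _truth = synth.render_face(
                yaw=ang, noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1))
            )
            ok, _box = seg.detect_eyes_present(frame, detector)
            hits += bool(ok)
        out[float(ang)] = hits / n_per_angle
    return out
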