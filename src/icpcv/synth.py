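"""Synthetic eye images and gaze observations with known ground truth.

This module stands in for live webcam capture: it renders simplified eye
regions (bright sclera ellipse, dark pupil disk, optional eyebrow band)
and simulates per-frame landmark observations whose pupil displacement is
a smooth affine function of the normalized gaze target, with optional
rigid head translation / in-plane rotation and additive Gaussian landmark
noise.  Every generated quantity carries exact ground truth, so each
downstream stage (segmentation, features, regression) can be tested
offline against known answers.

Conventions: image origin top-left, x rightward, y downward, pixel units.
"left"/"right" label the eye's position in the image (upright,
non-mirrored frontal view), so the image-left eye has its inner (nasal)
corner on its right side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw as _draw

Point = np.ndarray  # shape (2,), float, (x, y)

EYES = ("left", "right")


def _as_point(p) -> Point:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected an (x, y) point, got shape {a.shape}")
    return a


@dataclass
class EyeGeometry:
    """Geometric ground truth for one rendered eye region (pixels).

    The eye is a bright axis-aligned sclera ellipse on skin background;
    the pupil is a dark disk; the corners are the ellipse's horizontal
    extremes.
    """

    eye_center: Point
    eye_half_width: float
    eye_half_height: float
    pupil_center: Point
    pupil_radius: float
    iris_intensity: int = 20
    sclera_intensity: int = 230
    skin_intensity: int = 180
    eyebrow: bool = False
    eyebrow_intensity: int = 60

    def __post_init__(self):
        self.eye_center = _as_point(self.eye_center)
        self.pupil_center = _as_point(self.pupil_center)
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be > 0")
        if self.eye_half_width <= 0 or self.eye_half_height <= 0:
            raise ValueError("eye semi-axes must be > 0")
        dx, dy = self.pupil_center - self.eye_center
        if (dx / self.eye_half_width) ** 2 + (dy / self.eye_half_height) ** 2 > 1.0:
            raise ValueError("pupil_center lies outside the eye ellipse")

    @property
    def inner_corner(self) -> Point:
        """Rightmost ellipse extreme (nasal side for an image-left eye)."""
        return self.eye_center + np.array([self.eye_half_width, 0.0])

    @property
    def outer_corner(self) -> Point:
        return self.eye_center - np.array([self.eye_half_width, 0.0])


def render_eye_region(
    geom: EyeGeometry,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render one eye region as an 8-bit grayscale frame.

    Parameters
    ----------
    geom : EyeGeometry
        Eye geometry; corners sit at the ellipse's horizontal extremes.
    noise_sd : float
        Additive Gaussian pixel noise (grayscale levels), >= 0.
    seed : int
        Noise seed; rendering is bit-identical for a fixed seed.
    frame_shape : (height, width), optional
        Defaults to a frame just enclosing the eye (and eyebrow) with a
        10 px margin.

    Raises
    ------
    ValueError
        If the geometry does not fit inside the frame bounds.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cx, cy = geom.eye_center
    hw, hh = geom.eye_half_width, geom.eye_half_height
    brow_h = int(round(hh)) if geom.eyebrow else 0
    if frame_shape is None:
        frame_shape = (
            int(np.ceil(cy + hh)) + 10,
            int(np.ceil(cx + hw)) + 10,
        )
    h, w = frame_shape
    if cx - hw < 0 or cy - hh - (brow_h + 4 if geom.eyebrow else 0) < 0:
        raise ValueError("eye geometry extends outside the frame bounds")
    if cx + hw >= w or cy + hh >= h:
        raise ValueError("eye geometry extends outside the frame bounds")

    img = np.full((h, w), geom.skin_intensity, dtype=float)
    rr, cc = _draw.ellipse(cy, cx, hh, hw, shape=(h, w))
    img[rr, cc] = geom.sclera_intensity
    rr, cc = _draw.disk(
        (geom.pupil_center[1], geom.pupil_center[0]), geom.pupil_radius, shape=(h, w)
    )
    img[rr, cc] = geom.iris_intensity
    if geom.eyebrow:
        top = int(round(cy - hh)) - 4 - brow_h
        rr, cc = _draw.rectangle(
            (max(top, 0), int(round(cx - hw))),
            extent=(brow_h, int(round(2 * hw))),
            shape=(h, w),
        )
        img[rr, cc] = geom.eyebrow_intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class GazeModelParams:
    """Parameters of the affine-plus-noise synthetic gaze model.

    Pupil displacement from its rest position is ``gaze_gain * (t - 0.5)``
    where ``t`` is the target in normalized screen coordinates; head pose
    is a rigid 2-D translation plus an in-plane rotation (``head_yaw``,
    degrees) of all landmarks about the face center.  When ``free_head``
    is set, session generation draws an independent head pose per
    calibration point (uniform translation within
    ``+/- head_translation_range`` px per axis and rotation within
    ``+/- head_rotation_range`` deg), emulating unconstrained capture.
    """

    screen_size: tuple[float, float] = (1920.0, 1080.0)
    eye_base_positions: tuple = ((270.0, 210.0), (370.0, 210.0))
    eye_half_width: float = 30.0
    gaze_gain: tuple[float, float] = (24.0, 16.0)
    head_translation: tuple[float, float] = (0.0, 0.0)
    head_yaw: float = 0.0
    landmark_noise_sd: float = 0.0
    free_head: bool = False
    head_translation_range: float = 20.0
    head_rotation_range: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.screen_size[0] <= 0 or self.screen_size[1] <= 0:
            raise ValueError("screen_size components must be > 0")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be >= 0")

    @property
    def face_center(self) -> Point:
        bases = np.asarray(self.eye_base_positions, dtype=float)
        return bases.mean(axis=0)


@dataclass
class EyePoints:
    """Landmarks of a single eye, frame coordinates (px)."""

    pupil_center: Point
    inner_corner: Point
    outer_corner: Point


@dataclass
class GazeObservation:
    """Per-frame landmark set paired with its ground-truth screen target."""

    left: EyePoints
    right: EyePoints
    target: Point
    frame_index: int = 0


def free_head_params(landmark_noise_sd: float = 1.0, **overrides) -> GazeModelParams:
    """Study conditions for free-head capture: per-point rigid head pose
    (translation up to +/-20 px, rotation up to +/-3 deg) plus 1 px
    landmark noise by default."""
    return GazeModelParams(
        free_head=True, landmark_noise_sd=landmark_noise_sd, **overrides
    )


def _rotate_about(p: Point, center: Point, degrees: float) -> Point:
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    d = p - center
    return center + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def simulate_observation(
    target,
    params: GazeModelParams,
    seed: int = 0,
    frame_index: int = 0,
    head_translation=None,
    head_yaw: float | None = None,
) -> GazeObservation:
    """Simulate one frame's landmarks for a gaze at ``target`` (screen px).

    Corners and rest pupil positions are the base eye geometry under the
    rigid head pose (rotation about the face center, then translation);
    each pupil is then displaced by ``gaze_gain * (normalized target -
    0.5)``, and iid Gaussian noise of sd ``landmark_noise_sd`` is added
    to every landmark coordinate.  Deterministic for a fixed seed.
    """
    target = _as_point(target)
    w, h = params.screen_size
    if not (0 <= target[0] <= w and 0 <= target[1] <= h):
        raise ValueError(f"target {target} outside screen bounds {params.screen_size}")
    trans = np.asarray(
        params.head_translation if head_translation is None else head_translation,
        dtype=float,
    )
    yaw = params.head_yaw if head_yaw is None else head_yaw
    rng = np.random.default_rng(seed)

    norm = target / np.array([w, h])
    shift = np.asarray(params.gaze_gain, dtype=float) * (norm - 0.5)
    center = params.face_center
    eyes = {}
    for name, base in zip(EYES, params.eye_base_positions):
        base = np.asarray(base, dtype=float)
        sign = 1.0 if name == "left" else -1.0  # nasal corner side in the image
        inner = base + np.array([sign * params.eye_half_width, 0.0])
        outer = base - np.array([sign * params.eye_half_width, 0.0])
        pts = [base + shift, inner, outer]  # pupil = rest + gaze displacement
        pts = [_rotate_about(p, center, yaw) + trans for p in pts]
        if params.landmark_noise_sd > 0:
            pts = [p + rng.normal(0.0, params.landmark_noise_sd, 2) for p in pts]
        eyes[name] = EyePoints(*pts)
    return GazeObservation(eyes["left"], eyes["right"], target, frame_index)


def generate_session(protocol, params: GazeModelParams, seed: int = 0):
    """Generate one calibration/test session: ``frames_per_point``
    observations per protocol target point, in the protocol's order.

    Under ``params.free_head`` a fresh head pose is drawn per point (the
    user settles into a new posture for each fixation) and held for that
    point's frames.

    Returns a list of :class:`GazeObservation` of length
    ``len(points) * frames_per_point``.
    """
    points = list(protocol.grid_points)
    if not points or protocol.frames_per_point < 1:
        raise ValueError("protocol needs >= 1 target point and >= 1 frame per point")
    rng = np.random.default_rng(seed)
    out = []
    idx = 0
    for p in points:
        if params.free_head:
            trans = rng.uniform(
                -params.head_translation_range, params.head_translation_range, 2
            )
            yaw = rng.uniform(-params.head_rotation_range, params.head_rotation_range)
        else:
            trans, yaw = params.head_translation, params.head_yaw
        for _ in range(protocol.frames_per_point):
            out.append(
                simulate_observation(
                    p,
                    params,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    frame_index=idx,
                    head_translation=trans,
                    head_yaw=yaw,
                )
            )
            idx += 1
    return out


# ---------------------------------------------------------------------------
# Full-face rendering (for the eye-presence gate and yaw sweep)


@dataclass
class FaceGroundTruth:
    """Metadata accompanying a rendered synthetic face frame."""

    face_box: tuple[int, int, int, int]  # x0, y0, x1, y1, half-open
    yaw: float
    left: EyePoints
    right: EyePoints


def render_face(
    yaw: float = 0.0,
    frame_shape: tuple[int, int] = (480, 640),
    face_size: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, FaceGroundTruth]:
    """Render a frontal synthetic face with two eyes, rotated in-plane by
    ``yaw`` degrees about the face center.

    The eyes sit where the 4-row / 5-column face partition expects them:
    vertically at the second quarter's center, horizontally at the
    centers of the second and fourth fifths.  Eye ellipses stay
    axis-aligned (only their positions rotate), which is adequate for the
    small-angle sweeps this fixture serves.
    """
    h, w = frame_shape
    x0 = (w - face_size) // 2
    y0 = (h - face_size) // 2
    face_box = (x0, y0, x0 + face_size, y0 + face_size)
    eye_y = y0 + 0.375 * face_size
    centers = {
        "left": np.array([x0 + 0.30 * face_size, eye_y]),
        "right": np.array([x0 + 0.70 * face_size, eye_y]),
    }
    face_center = np.array([x0 + face_size / 2.0, y0 + face_size / 2.0])
    hw_eye, hh_eye, pr = face_size * 0.09, face_size * 0.04, face_size * 0.025

    img = np.full((h, w), 120, dtype=float)  # background
    rr, cc = _draw.rectangle((y0, x0), extent=(face_size, face_size), shape=(h, w))
    img[rr, cc] = 180  # skin
    truth = {}
    for name, c in centers.items():
        c_rot = _rotate_about(c, face_center, yaw)
        sign = 1.0 if name == "left" else -1.0
        inner = _rotate_about(c + np.array([sign * hw_eye, 0.0]), face_center, yaw)
        outer = _rotate_about(c - np.array([sign * hw_eye, 0.0]), face_center, yaw)
        rr, cc = _draw.ellipse(c_rot[1], c_rot[0], hh_eye, hw_eye, shape=(h, w))
        img[rr, cc] = 230  # sclera
        rr, cc = _draw.disk((c_rot[1], c_rot[0]), pr, shape=(h, w))
        img[rr, cc] = 20  # pupil
        # eyebrow band above the (rotated) eye
        top = c_rot[1] - hh_eye - 6 - hh_eye
        rr, cc = _draw.rectangle(
            (int(round(top)), int(round(c_rot[0] - hw_eye))),
            extent=(int(round(hh_eye)), int(round(2 * hw_eye))),
            shape=(h, w),
        )
        img[rr, cc] = 60
        truth[name] = EyePoints(c_rot, inner, outer)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    frame = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return frame, FaceGroundTruth(face_box, yaw, truth["left"], truth["right"])


# ---------------------------------------------------------------------------
# Session CSV I/O

SESSION_COLUMNS = [
    "frame_index",
    "eye",
    "pupil_x",
    "pupil_y",
    "inner_x",
    "inner_y",
    "outer_x",
    "outer_y",
    "target_x",
    "target_y",
]


def session_to_frame(session) -> pd.DataFrame:
    """Flatten observations to the session table: one row per eye per frame."""
    rows = []
    for obs in session:
        for eye in EYES:
            pts: EyePoints = getattr(obs, eye)
            rows.append(
                {
                    "frame_index": obs.frame_index,
                    "eye": eye,
                    "pupil_x": pts.pupil_center[0],
                    "pupil_y": pts.pupil_center[1],
                    "inner_x": pts.inner_corner[0],
                    "inner_y": pts.inner_corner[1],
                    "outer_x": pts.outer_corner[0],
                    "outer_y": pts.outer_corner[1],
                    "target_x": obs.target[0],
                    "target_y": obs.target[1],
                }
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session_csv(session, path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def read_session_csv(path) -> list[GazeObservation]:
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session file missing columns: {sorted(missing)}")
    out = []
    for idx, grp in df.groupby("frame_index", sort=True):
        eyes = {}
        for _, row in grp.iterrows():
            eyes[row["eye"]] = EyePoints(
                np.array([row["pupil_x"], row["pupil_y"]]),
                np.array([row["inner_x"], row["inner_y"]]),
                np.array([row["outer_x"], row["outer_y"]]),
            )
        if set(eyes) != set(EYES):
            raise ValueError(f"frame {idx} does not have both eyes")
        tgt = np.array([grp["target_x"].iloc[0], grp["target_y"].iloc[0]])
        out.append(GazeObservation(eyes["left"], eyes["right"], tgt, int(idx)))
    return out
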