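"""Eye localization, pupil segmentation and corner extraction.

Pipeline: a face box (from a pluggable detector) is partitioned into a
4-row / 5-column grid to locate the two eye ROIs; each eye ROI drops its
top third to exclude the eyebrow; the Value channel is binarized (dark
pixels foreground), cleaned with erosion + dilation, and the largest
connected component is kept as the pupil, whose center of gravity

    Cx = sum(x * B(x, y)) / sum(B),   Cy = sum(y * B(x, y)) / sum(B)

is the pupil-center estimate.  Eye corners are the leftmost / rightmost
points of the Canny edge contour of the eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as _color
from skimage import feature as _feature
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import dilation, erosion, footprint_rectangle

from .synth import FaceGroundTruth


class NoPupilError(ValueError):
    """Segmentation produced an empty pupil mask; skip the frame."""


class NoCornerError(ValueError):
    """No eye contour found in the ROI."""


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel box [x0, x1) x [y0, y1) in frame coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def crop(self, frame: np.ndarray) -> np.ndarray:
        h, w = frame.shape[:2]
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise ValueError(f"{self} outside frame of shape {frame.shape}")
        return frame[self.y0 : self.y1, self.x0 : self.x1]

    def shift(self, dx: int, dy: int) -> "RoiBox":
        return RoiBox(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)


@dataclass
class PupilMask:
    """Binary pupil mask aligned to its ROI; offset locates it in the frame."""

    mask: np.ndarray  # bool, shape (roi_height, roi_width)
    offset: tuple[int, int]  # (x0, y0) of the ROI in frame coordinates


@dataclass
class Landmarks:
    """Per-eye pupil center (subpixel) and inner/outer corners, frame px."""

    pupil_center: dict
    inner_corner: dict
    outer_corner: dict


@dataclass
class SegmentationConfig:
    threshold_method: str = "multiotsu"  # multiotsu | otsu | fixed
    threshold_value: float = 128.0
    morphology_kernel: int = 3  # square structuring element side
    morphology_iterations: int = 1
    canny_sigma: float = 1.0
    mirror_view: bool = False  # True for mirrored webcam images


# ---------------------------------------------------------------------------
# Eye presence gate


@dataclass
class FixtureDetector:
    """Detector backend that returns a known ground-truth face box when the
    frame contains any structure (non-uniform pixels)."""

    truth: FaceGroundTruth

    def __call__(self, frame: np.ndarray):
        if frame.size == 0 or int(frame.max()) == int(frame.min()):
            return False, None
        x0, y0, x1, y1 = self.truth.face_box
        return True, RoiBox(x0, y0, x1, y1)


@dataclass
class PupilPairDetector:
    """Eye-presence detector for synthetic frames: finds dark blobs and
    accepts when two similar blobs lie on a near-horizontal line.

    The face box is inferred by inverting the 4-row / 5-column layout
    (eye centers at 0.3 / 0.7 of the face width and 0.375 of its height).
    ``max_tilt_deg`` bounds the inter-pupil line's angle to the
    horizontal; frames from a rolled head beyond it are rejected, which
    is what makes the yaw sweep lose detection away from frontal pose.
    """

    dark_threshold: float = 60.0
    min_area: int = 20
    max_tilt_deg: float = 4.0
    area_ratio: float = 3.0

    def __call__(self, frame: np.ndarray):
        gray = value_channel(frame)
        binary = gray < self.dark_threshold
        labels, n = ndi.label(binary)
        if n < 2:
            return False, None
        areas = ndi.sum_labels(np.ones_like(gray), labels, index=np.arange(1, n + 1))
        order = np.argsort(areas)[::-1]
        # candidate pupils: two largest blobs of comparable area and near-round
        cand = []
        for i in order[:6]:
            if areas[i] < self.min_area:
                continue
            ys, xs = np.nonzero(labels == i + 1)
            hext, wext = np.ptp(ys) + 1, np.ptp(xs) + 1
            if max(hext, wext) > 2.0 * min(hext, wext):  # elongated: eyebrow bar
                continue
            cand.append((areas[i], xs.mean(), ys.mean()))
            if len(cand) == 2:
                break
        if len(cand) < 2:
            return False, None
        (a1, x1, y1), (a2, x2, y2) = cand
        if max(a1, a2) > self.area_ratio * min(a1, a2):
            return False, None
        if x2 < x1:
            x1, y1, x2, y2 = x2, y2, x1, y1
        sep = x2 - x1
        if sep <= 0:
            return False, None
        tilt = np.degrees(np.arctan2(abs(y2 - y1), sep))
        if tilt > self.max_tilt_deg:
            return False, None
        face_w = sep / 0.40
        fx0 = x1 - 0.30 * face_w
        fy0 = (y1 + y2) / 2.0 - 0.375 * face_w  # square face box
        box = RoiBox(
            int(round(fx0)),
            int(round(fy0)),
            int(round(fx0 + face_w)),
            int(round(fy0 + face_w)),
        )
        return True, box


def detect_eyes_present(frame: np.ndarray, detector=None):
    """Gate the pipeline: ``(True, face_box)`` when both eyes are found,
    ``(False, None)`` otherwise.  Absence is a valid result, not an error;
    the caller halts processing until detection succeeds."""
    if detector is None:
        detector = PupilPairDetector()
    return detector(frame)


# ---------------------------------------------------------------------------
# ROI geometry


def _partition(lo: int, hi: int, n: int):
    """Split [lo, hi) into n bands by floor division; the last band
    absorbs the remainder."""
    size = (hi - lo) // n
    bounds = [lo + i * size for i in range(n)] + [hi]
    return [(bounds[i], bounds[i + 1]) for i in range(n)]


def partition_face_rois(face: RoiBox) -> tuple[RoiBox, RoiBox]:
    """4-row / 5-column face partition: the eye band is the 2nd of 4 equal
    rows; the left eye is the 2nd of 5 equal columns in that band, the
    right eye the 4th."""
    if face.width < 5 or face.height < 4:
        raise ValueError(f"face box {face} too small to partition (needs 5x4 px)")
    rows = _partition(face.y0, face.y1, 4)
    cols = _partition(face.x0, face.x1, 5)
    band_y0, band_y1 = rows[1]
    left = RoiBox(cols[1][0], band_y0, cols[1][1], band_y1)
    right = RoiBox(cols[3][0], band_y0, cols[3][1], band_y1)
    return left, right


def crop_eyebrow(eye_roi: RoiBox) -> RoiBox:
    """Keep the middle of 3 equal horizontal bands of the eye ROI,
    excluding the eyebrow above."""
    if eye_roi.height < 3:
        raise ValueError(f"eye ROI {eye_roi} too short to crop (needs 3 px)")
    bands = _partition(eye_roi.y0, eye_roi.y1, 3)
    return RoiBox(eye_roi.x0, bands[1][0], eye_roi.x1, bands[1][1])


# ---------------------------------------------------------------------------
# Pupil segmentation


def value_channel(frame: np.ndarray) -> np.ndarray:
    """HSV Value channel for color frames; identity for grayscale."""
    if frame.ndim == 2:
        return frame.astype(float)
    return _color.rgb2hsv(frame)[..., 2] * 255.0


def segment_pupil(
    frame: np.ndarray, roi: RoiBox, cfg: SegmentationConfig | None = None
) -> PupilMask:
    """Binarize the ROI's Value channel (dark -> foreground), apply erosion
    then dilation, and keep the largest 8-connected component.

    Raises :class:`NoPupilError` when nothing remains — the caller skips
    the frame.
    """
    cfg = cfg or SegmentationConfig()
    patch = value_channel(roi.crop(frame))
    if cfg.threshold_method in ("multiotsu", "otsu"):
        if np.ptp(patch) == 0:
            raise NoPupilError("uniform ROI: nothing dark to segment")
        if cfg.threshold_method == "multiotsu" and np.unique(patch).size > 2:
            # eye ROIs are trimodal (pupil / skin / sclera); the darkest
            # class boundary isolates the pupil even when it is small
            thr = threshold_multiotsu(patch, classes=3)[0]
        else:
            thr = threshold_otsu(patch)
    elif cfg.threshold_method == "fixed":
        thr = cfg.threshold_value
    else:
        raise ValueError(f"unknown threshold method {cfg.threshold_method!r}")
    binary = patch < thr
    foot = footprint_rectangle((cfg.morphology_kernel, cfg.morphology_kernel))
    for _ in range(cfg.morphology_iterations):
        binary = erosion(binary, foot)
    for _ in range(cfg.morphology_iterations):
        binary = dilation(binary, foot)
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoPupilError("empty mask after morphology")
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1  # argmax keeps the first (row-major) label on ties
    return PupilMask(labels == best, (roi.x0, roi.y0))


def pupil_centroid(mask: PupilMask) -> np.ndarray:
    """Center of gravity of the pupil mask, subpixel, frame coordinates."""
    ys, xs = np.nonzero(mask.mask)
    if xs.size == 0:
        raise NoPupilError("empty pupil mask")
    return np.array(
        [xs.mean() + mask.offset[0], ys.mean() + mask.offset[1]], dtype=float
    )


# ---------------------------------------------------------------------------
# Corner extraction


def detect_eye_corners(
    frame: np.ndarray, roi: RoiBox, cfg: SegmentationConfig | None = None
):
    """Extract the eye contour by Canny edge detection and return its
    leftmost and rightmost points, frame px.

    When several contour pixels share the extreme column (the contour
    runs vertically through an ellipse's horizontal extreme), the
    corner is the vertical midpoint of that run, which lands on the
    true extreme of a symmetric eye outline; the topmost of the two
    middle rows breaks even-length runs.
    """
    cfg = cfg or SegmentationConfig()
    patch = value_channel(roi.crop(frame))
    edges = _feature.canny(patch / 255.0, sigma=cfg.canny_sigma)
    ys, xs = np.nonzero(edges)
    if xs.size == 0:
        raise NoCornerError("no eye contour found in ROI")

    def extreme(target_x):
        col = np.sort(ys[xs == target_x])
        y = col[(len(col) - 1) // 2]
        return np.array([target_x + roi.x0, y + roi.y0], dtype=float)

    return extreme(xs.min()), extreme(xs.max())


# ---------------------------------------------------------------------------
# Full landmark extraction


def extract_landmarks(
    frame: np.ndarray,
    face: RoiBox,
    cfg: SegmentationConfig | None = None,
) -> Landmarks:
    """Run the full per-frame chain: partition the face, crop eyebrows,
    segment pupils, locate corners, and assign inner/outer sides.

    In an upright non-mirrored view the image-left eye's inner (nasal)
    corner is its rightmost corner; ``cfg.mirror_view`` flips the
    assignment for mirrored webcams.
    """
    cfg = cfg or SegmentationConfig()
    left_roi, right_roi = partition_face_rois(face)
    pupil, inner, outer = {}, {}, {}
    for eye, roi in (("left", left_roi), ("right", right_roi)):
        band = crop_eyebrow(roi)
        pupil[eye] = pupil_centroid(segment_pupil(frame, band, cfg))
        leftmost, rightmost = detect_eye_corners(frame, band, cfg)
        nasal_is_right = (eye == "left") ^ cfg.mirror_view
        if nasal_is_right:
            inner[eye], outer[eye] = rightmost, leftmost
        else:
            inner[eye], outer[eye] = leftmost, rightmost
    return Landmarks(pupil, inner, outer)
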