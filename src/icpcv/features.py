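"""Gaze features: PCECV and ICPCV vectors, and the polynomial mapping.

PCECV (pupil center-eye corner vector): per eye and corner,

    theta0 = (PC - EC_i) / ECD

with ECD the inner-to-outer corner distance of that eye; theta0 values
are averaged over the two corners of an eye and then over the two eyes
to give theta (a 2-vector), which is expanded to the quadratic design
vector (1, tx, ty, tx^2, ty^2, tx*ty) and mapped to the screen point of
regard by a 2x6 coefficient matrix C fit by least squares.

ICPCV (inner corner-pupil center vector): per eye, the raw pixel vector
PC - IC from the inner corner to the pupil center, assembled with three
head-pose proxies — CES (midpoint of the inner corners), DES (distance
between them) and TA (tilt of the inter-inner-corner line, degrees) —
into the 8-vector (CESx, CESy, DES, TA, ICPCVx_l, ICPCVy_l, ICPCVx_r,
ICPCVy_r).  The reduced 6-vector variant drops DES and TA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import GazeObservation

FULL8_NAMES = ("ces_x", "ces_y", "des", "ta", "icpcv_lx", "icpcv_ly", "icpcv_rx", "icpcv_ry")
REDUCED6_NAMES = ("ces_x", "ces_y", "icpcv_lx", "icpcv_ly", "icpcv_rx", "icpcv_ry")
VARIANTS = ("icpcv8", "icpcv6d", "pcecv")


class DegenerateEyeError(ValueError):
    """Inner and outer corner coincide (zero corner distance)."""


@dataclass
class PcecvFeature:
    theta: np.ndarray  # 2-vector, dimensionless
    expanded: np.ndarray  # 6-vector (1, tx, ty, tx^2, ty^2, tx*ty)


@dataclass
class IcpcvFeature:
    ces: np.ndarray  # 2-vector, px
    des: float  # px, >= 0
    ta: float  # degrees, (-90, 90]
    icpcv_left: np.ndarray
    icpcv_right: np.ndarray

    @property
    def full8(self) -> np.ndarray:
        return np.concatenate(
            [self.ces, [self.des, self.ta], self.icpcv_left, self.icpcv_right]
        )

    @property
    def reduced6(self) -> np.ndarray:
        return np.concatenate([self.ces, self.icpcv_left, self.icpcv_right])


@dataclass
class MappingMatrix:
    """2x6 coefficient matrix C mapping the expanded PCECV vector to
    (PoR_x, PoR_y) via C @ f."""

    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (2, 6) or not np.all(np.isfinite(self.C)):
            raise ValueError("mapping matrix must be a finite 2x6 array")

    def predict(self, expanded: np.ndarray) -> np.ndarray:
        return self.C @ np.asarray(expanded, dtype=float)


# ---------------------------------------------------------------------------
# PCECV


def pcecv_theta0(pc, corner, ecd: float) -> np.ndarray:
    """Corner-to-pupil vector normalized by that eye's corner distance."""
    if ecd <= 0:
        raise DegenerateEyeError("eye corner distance must be > 0")
    return (np.asarray(pc, dtype=float) - np.asarray(corner, dtype=float)) / ecd


def pcecv_combine(t_inner_left, t_outer_left, t_inner_right, t_outer_right) -> np.ndarray:
    """Average per eye over its two corners, then over the two eyes;
    algebraically the mean of the four normalized vectors."""
    vs = [np.asarray(v, dtype=float) for v in
          (t_inner_left, t_outer_left, t_inner_right, t_outer_right)]
    if not all(np.all(np.isfinite(v)) for v in vs):
        raise ValueError("non-finite theta0 input")
    left = 0.5 * (vs[0] + vs[1])
    right = 0.5 * (vs[2] + vs[3])
    return 0.5 * (left + right)


def pcecv_expand(theta) -> np.ndarray:
    tx, ty = np.asarray(theta, dtype=float)
    return np.array([1.0, tx, ty, tx * tx, ty * ty, tx * ty])


def pcecv_feature(obs: GazeObservation) -> PcecvFeature:
    """Compute the PCECV feature for one observation's landmarks."""
    thetas = []
    for eye in (obs.left, obs.right):
        ecd = float(np.linalg.norm(eye.inner_corner - eye.outer_corner))
        thetas.append(pcecv_theta0(eye.pupil_center, eye.inner_corner, ecd))
        thetas.append(pcecv_theta0(eye.pupil_center, eye.outer_corner, ecd))
    theta = pcecv_combine(thetas[0], thetas[1], thetas[2], thetas[3])
    return PcecvFeature(theta, pcecv_expand(theta))


def fit_polynomial_mapping(samples) -> MappingMatrix:
    """Least-squares fit of the 2x6 mapping C from (expanded 6-vector,
    screen point) pairs, minimizing sum ||C f - PoR||^2."""
    F = np.asarray([np.asarray(f, dtype=float) for f, _ in samples])
    Y = np.asarray([np.asarray(y, dtype=float) for _, y in samples])
    if F.ndim != 2 or F.shape[1] != 6:
        raise ValueError("features must be expanded 6-vectors")
    if F.shape[0] < 6 or np.linalg.matrix_rank(F) < 6:
        raise np.linalg.LinAlgError(
            "rank-deficient design: need >= 6 samples with distinct thetas"
        )
    coef, *_ = np.linalg.lstsq(F, Y, rcond=None)
    return MappingMatrix(coef.T)


# ---------------------------------------------------------------------------
# ICPCV


def icpcv(pc, inner_corner) -> np.ndarray:
    """Inner corner-pupil center vector: PC - IC, raw pixels."""
    return np.asarray(pc, dtype=float) - np.asarray(inner_corner, dtype=float)


def _tilt_angle(vec: np.ndarray) -> float:
    """Angle between a vector and the image horizontal, degrees in
    (-90, 90], y-down image convention."""
    ang = np.degrees(np.arctan2(vec[1], vec[0]))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return float(ang)


def assemble_icpcv(obs: GazeObservation, normalize_by_des: bool = False) -> IcpcvFeature:
    """Assemble the ICPCV feature set from both eyes' landmarks.

    CES = midpoint of the two inner corners; DES = their Euclidean
    distance; TA = tilt of the left-inner -> right-inner vector.
    ``normalize_by_des`` divides the per-eye vectors by DES (an
    experimental scale-invariant variant; the canonical feature keeps
    raw pixels).
    """
    for eye in ("left", "right"):
        if getattr(obs, eye) is None:
            raise ValueError(f"incomplete landmarks: missing {eye} eye")
    il, ir = obs.left.inner_corner, obs.right.inner_corner
    span = np.asarray(ir, dtype=float) - np.asarray(il, dtype=float)
    des = float(np.linalg.norm(span))
    scale = des if (normalize_by_des and des > 0) else 1.0
    return IcpcvFeature(
        ces=0.5 * (np.asarray(il, dtype=float) + np.asarray(ir, dtype=float)),
        des=des,
        ta=_tilt_angle(span),
        icpcv_left=icpcv(obs.left.pupil_center, il) / scale,
        icpcv_right=icpcv(obs.right.pupil_center, ir) / scale,
    )


# ---------------------------------------------------------------------------
# Session featurization


def feature_vector(obs: GazeObservation, variant: str) -> np.ndarray:
    """One observation's feature vector for the chosen variant
    (``icpcv8``, ``icpcv6d`` or ``pcecv``)."""
    if variant == "icpcv8":
        return assemble_icpcv(obs).full8
    if variant == "icpcv6d":
        return assemble_icpcv(obs).reduced6
    if variant == "pcecv":
        return pcecv_feature(obs).expanded
    raise ValueError(f"unknown feature variant {variant!r}; choose from {VARIANTS}")


def feature_names(variant: str) -> tuple[str, ...]:
    if variant == "icpcv8":
        return FULL8_NAMES
    if variant == "icpcv6d":
        return REDUCED6_NAMES
    if variant == "pcecv":
        return ("one", "theta_x", "theta_y", "theta_x2", "theta_y2", "theta_xy")
    raise ValueError(f"unknown feature variant {variant!r}")


def featurize_session(session, variant: str) -> pd.DataFrame:
    """Featurize a session: one row per frame with the variant's feature
    columns plus target_x, target_y; the variant is recorded in the
    DataFrame's attrs and recoverable from the column set."""
    names = feature_names(variant)
    rows = []
    for obs in session:
        f = feature_vector(obs, variant)
        row = dict(zip(names, f))
        row["target_x"], row["target_y"] = obs.target
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(names) + ["target_x", "target_y"])
    df.attrs["variant"] = variant
    return df
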