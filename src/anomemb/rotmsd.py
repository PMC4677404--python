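"""Rotational TAMSD via accumulated rotation vectors.

The orientation of the protein (a unit quaternion per frame, or a tracked
body-fixed unit vector such as a COM-to-residue direction) is converted to
per-frame axis-angle increments whose cumulative sum phi(t) is an unbounded
rotation path; the rotational TAMSD is then the ordinary TAMSD estimator
applied to phi.  For rotational diffusion phi behaves like a 3D Brownian
path; transient rotational subdiffusion shows up as TAMSD ~ Delta^alpha
with alpha < 1 at short lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from anomemb.tamsd import TamsdCurve, Trajectory, tamsd

__all__ = [
    "OrientationSeries",
    "RotationPath",
    "accumulate_rotation",
    "rotational_tamsd",
    "quat_multiply",
    "quat_conjugate",
]

_UNIT_TOL = 1e-6
_NORM_WARN = 1e-3


@dataclass
class OrientationSeries:
    """Orientations per frame: unit quaternions (w, x, y, z) or unit
    body-fixed vectors (x, y, z)."""

    times: np.ndarray
    orientations: np.ndarray
    mode: str = "quat"  # "quat" | "vector"
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.mode not in ("quat", "vector"):
            raise ValueError("mode must be 'quat' or 'vector'")
        want = 4 if self.mode == "quat" else 3
        if self.orientations.ndim != 2 or self.orientations.shape[1] != want:
            raise ValueError(f"{self.mode} mode expects shape (n, {want})")
        if len(self.times) != len(self.orientations):
            raise ValueError("times and orientations must have equal length")
        d = np.diff(self.times)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=0, atol=1e-6 * d[0]):
            raise ValueError("times must be uniform and increasing")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > _NORM_WARN):
            warnings.warn("orientations deviate from unit norm; renormalizing",
                          RuntimeWarning)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            self.orientations = self.orientations / norms[:, None]


@dataclass
class RotationPath:
    """Cumulative (unwrapped) rotation vector phi(t) in radians."""

    times: np.ndarray
    phi: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (len(self.times), 3):
            raise ValueError("phi must have shape (n, 3)")
        if np.any(np.abs(self.phi[0]) > 1e-12):
            raise ValueError("phi must start at zero")


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product, scalar-first convention."""
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    out = np.asarray(q, dtype=float).copy()
    out[..., 1:] *= -1.0
    return out


def _quat_increments(q: np.ndarray) -> np.ndarray:
    """Axis-angle vector of the relative rotation between frames."""
    rel = quat_multiply(quat_conjugate(q[:-1]), q[1:])
    # resolve double cover: keep the short arc
    flip = rel[:, 0] < 0
    rel[flip] *= -1.0
    w = np.clip(rel[:, 0], -1.0, 1.0)
    angle = 2.0 * np.arccos(w)
    if np.any(angle >= np.pi - 1e-9):
        raise ValueError("antipodal consecutive frames: rotation axis ambiguous")
    axis = rel[:, 1:]
    norm = np.linalg.norm(axis, axis=1)
    inc = np.zeros_like(axis)
    nz = norm > 1e-15
    inc[nz] = axis[nz] / norm[nz, None] * angle[nz, None]
    return inc


def _vector_increments(u: np.ndarray) -> np.ndarray:
    """Increment axis = u_i x u_{i+1} normalised; magnitude = arc angle."""
    dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    angle = np.arccos(dots)
    if np.any(angle >= np.pi - 1e-9):
        raise ValueError("antipodal consecutive frames: rotation axis ambiguous")
    cross = np.cross(u[:-1], u[1:])
    norm = np.linalg.norm(cross, axis=1)
    inc = np.zeros_like(cross)
    nz = norm > 1e-15
    inc[nz] = cross[nz] / norm[nz, None] * angle[nz, None]
    return inc


def accumulate_rotation(series: OrientationSeries) -> RotationPath:
    """Accumulate per-frame rotation increments into the unbounded
    rotation vector phi(t); phi(t0) = 0."""
    if series.mode == "quat":
        inc = _quat_increments(series.orientations)
    else:
        inc = _vector_increments(series.orientations)
    phi = np.vstack([np.zeros(3), np.cumsum(inc, axis=0)])
    return RotationPath(times=series.times, phi=phi, label=series.label)


def rotational_tamsd(path: RotationPath, lags=None) -> TamsdCurve:
    """TAMSD of the accumulated rotation vector: the translational
    estimator applied to phi(t) (units rad^2)."""
    traj = Trajectory(times=path.times, positions=path.phi, label=path.label)
    curve = tamsd(traj, lags)
    curve.label = f"rot:{path.label}" if path.label else "rot"
    return curve
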