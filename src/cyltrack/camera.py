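"""Pinhole camera model, lens distortion and rigid marker poses.

Conventions: camera frame has x right, y down, z along the optical axis;
pixel coordinates are 0-based with the origin at the top-left pixel
centre.  A :class:`Pose` maps cylinder-local marker coordinates (mm) into
the camera frame, ``P_cam = R @ P_local + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = ["CameraIntrinsics", "Pose", "BehindCameraError", "project_points"]


class BehindCameraError(ValueError):
    """Raised when points to be projected have non-positive depth."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"points behind the camera at indices {self.indices}")


@dataclass(frozen=True)
class CameraIntrinsics:
    """Focal lengths / principal point in px plus radial-tangential
    distortion coefficients ``(k1, k2, p1, p2[, k3])`` (may be empty)."""

    fx: float = 1000.0
    fy: float = 1000.0
    cx: float = 480.0
    cy: float = 270.0
    distortion: tuple[float, ...] = ()
    image_size: tuple[int, int] = (960, 540)   # (width, height)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        w, h = self.image_size
        if not (0 <= self.cx < w and 0 <= self.cy < h):
            raise ValueError("principal point outside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    def distort(self, xy: np.ndarray) -> np.ndarray:
        """Apply the distortion model to normalised coordinates."""
        if not self.distortion:
            return xy
        d = list(self.distortion) + [0.0] * (5 - len(self.distortion))
        k1, k2, p1, p2, k3 = d[:5]
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
        xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        return np.stack([xd, yd], axis=-1)

    def undistort(self, xy: np.ndarray, iters: int = 8) -> np.ndarray:
        """Invert :meth:`distort` by fixed-point iteration."""
        if not self.distortion:
            return xy
        und = np.array(xy, dtype=float, copy=True)
        for _ in range(iters):
            delta = self.distort(und) - und
            und = xy - delta
        return und

    def pixels_to_normalized(self, uv: np.ndarray) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        xy = np.stack([(uv[..., 0] - self.cx) / self.fx,
                       (uv[..., 1] - self.cy) / self.fy], axis=-1)
        return self.undistort(xy)

    def normalized_to_pixels(self, xy: np.ndarray) -> np.ndarray:
        xy = self.distort(np.asarray(xy, dtype=float))
        return np.stack([xy[..., 0] * self.fx + self.cx,
                         xy[..., 1] * self.fy + self.cy], axis=-1)

    # -- serialisation ----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        doc = yaml.safe_dump({"camera": asdict(self)}, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_yaml(cls, source) -> "CameraIntrinsics":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        elif "\n" in str(source) or ":" in str(source):
            data = yaml.safe_load(str(source))
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        fields = data.get("camera", data)
        fields["distortion"] = tuple(fields.get("distortion", ()))
        fields["image_size"] = tuple(fields["image_size"])
        return cls(**fields)


@dataclass(frozen=True)
class Pose:
    """Rigid transform from marker-local to camera coordinates (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "Pose":
        T = np.asarray(T, dtype=float).reshape(4, 4)
        return cls(T[:3, :3], T[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "Pose":
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   translation)

    def matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    def inverse(self) -> "Pose":
        return Pose(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "Pose") -> "Pose":
        """Return ``self @ other`` (apply ``other`` first)."""
        return Pose(self.rotation @ other.rotation,
                    self.rotation @ other.translation + self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()


def project_points(K: CameraIntrinsics, pose: Pose, points) -> np.ndarray:
    """Project 3D marker-local points (mm) to pixel coordinates.

    Raises :class:`BehindCameraError` listing offending indices if any
    transformed point has non-positive depth.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cam = pose.apply(pts)
    bad = np.nonzero(cam[:, 2] <= 0)[0]
    if bad.size:
        raise BehindCameraError(bad)
    xy = cam[:, :2] / cam[:, 2:3]
    uv = K.normalized_to_pixels(xy)
    return uv if np.asarray(points).ndim > 1 else uv[0]


def rot_x(a: float) -> np.ndarray:
    return Rotation.from_euler("x", a).as_matrix()


def rot_y(a: float) -> np.ndarray:
    return Rotation.from_euler("y", a).as_matrix()


def rot_z(a: float) -> np.ndarray:
    return Rotation.from_euler("z", a).as_matrix()
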