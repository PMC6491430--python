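"""Small planar-geometry helpers shared by the simulator and the correction stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AffineMap2D:
    """A 2D affine transform ``p -> linear @ p + translation`` (nm in, nm out).

    Used both to inject anisotropic-magnification distortions in the simulator
    and to represent the estimated UAF<->EPI registration. The linear part is
    dimensionless; the translation is in nm.
    """

    linear: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        if np.linalg.det(self.linear) <= 0:
            raise ValueError("AffineMap2D must be orientation preserving (det > 0)")

    @classmethod
    def identity(cls) -> "AffineMap2D":
        return cls()

    @classmethod
    def from_params(cls, scale_x: float = 1.0, scale_y: float = 1.0,
                    rotation_deg: float = 0.0, tx: float = 0.0, ty: float = 0.0) -> "AffineMap2D":
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(rot @ np.diag([scale_x, scale_y]), np.array([tx, ty]))

    def apply(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xn = self.linear[0, 0] * x + self.linear[0, 1] * y + self.translation[0]
        yn = self.linear[1, 0] * x + self.linear[1, 1] * y + self.translation[1]
        return xn, yn

    def inverse(self) -> "AffineMap2D":
        inv = np.linalg.inv(self.linear)
        return AffineMap2D(inv, -inv @ self.translation)

    def compose(self, other: "AffineMap2D") -> "AffineMap2D":
        """Return the map ``self o other`` (apply `other` first)."""
        return AffineMap2D(self.linear @ other.linear,
                           self.linear @ other.translation + self.translation)

    @property
    def singular_values(self) -> np.ndarray:
        return np.linalg.svd(self.linear, compute_uv=False)

    @property
    def anisotropy(self) -> float:
        """Magnification difference between the two principal axes, |s1/s2 - 1|."""
        s = self.singular_values
        return float(s[0] / s[1] - 1.0)

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the polar decomposition of the linear part."""
        u, _, vt = np.linalg.svd(self.linear)
        rot = u @ vt
        return float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))

    def to_dict(self) -> dict:
        return {"linear": self.linear.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineMap2D":
        return cls(np.asarray(d["linear"]), np.asarray(d["translation"]))
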