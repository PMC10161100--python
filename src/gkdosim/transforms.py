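"""Rigid (rotation + translation) transforms in mm, no scale or shear."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class RigidTransform:
    """x ↦ R x + t with R a proper rotation (det +1, orthonormal)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1); reflections rejected")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_z(cls, angle_deg: float, translation=(0.0, 0.0, 0.0), center=None) -> "RigidTransform":
        """Rotation about the z axis (optionally about ``center``) plus a shift."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = np.asarray(translation, dtype=float)
        if center is not None:
            ctr = np.asarray(center, dtype=float)
            t = t + ctr - rot @ ctr
        return cls(rot, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    # JSON persistence (row-major rotation + translation)
    def to_json(self, path: str | Path) -> None:
        payload = {
            "rotation": self.rotation.ravel().tolist(),
            "translation": self.translation.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["rotation"]).reshape(3, 3),
            np.array(payload["translation"]),
        )
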