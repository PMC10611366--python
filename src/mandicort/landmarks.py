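"""The seven-landmark container shared by the regression stage and the
phantom ground truth.

Coordinates are (x, y) pixels with the origin at the top-left of the axial
slice, x = column, y = row, 0-based. The flattening order is a fixed
contract: (x1, y1, ..., x7, y7), the five bone-line points first (ordered
left to right along the mandibular arch), then the left and right canal
points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_BONE = 5
N_CANAL = 2
N_POINTS = N_BONE + N_CANAL
N_COORDS = 2 * N_POINTS  # 14 regression outputs


@dataclass(frozen=True)
class LandmarkSet:
    bone_line: np.ndarray  # (5, 2) float, (x, y) px
    canal: np.ndarray      # (2, 2) float, (x, y) px: left then right

    def __post_init__(self):
        bl = np.asarray(self.bone_line, dtype=np.float64)
        ca = np.asarray(self.canal, dtype=np.float64)
        if bl.shape != (N_BONE, 2) or ca.shape != (N_CANAL, 2):
            raise ValueError(
                f"expected {N_BONE} bone-line and {N_CANAL} canal (x, y) points, "
                f"got shapes {bl.shape} and {ca.shape}")
        object.__setattr__(self, "bone_line", bl)
        object.__setattr__(self, "canal", ca)

    def to_vector(self) -> np.ndarray:
        """Flatten to the 14-vector (x1, y1, ..., x7, y7)."""
        return np.concatenate([self.bone_line, self.canal]).reshape(N_COORDS)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "LandmarkSet":
        vec = np.asarray(vec, dtype=np.float64).reshape(N_COORDS)
        pts = vec.reshape(N_POINTS, 2)
        return cls(bone_line=pts[:N_BONE], canal=pts[N_BONE:])

    @property
    def points(self) -> np.ndarray:
        """All 7 points as a (7, 2) array, bone-line first."""
        return np.concatenate([self.bone_line, self.canal])

    def clipped(self, width: int, height: int) -> "LandmarkSet":
        """Clip coordinates into image bounds [0, width-1] x [0, height-1]."""
        pts = self.points.copy()
        pts[:, 0] = np.clip(pts[:, 0], 0, width - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, height - 1)
        return LandmarkSet(bone_line=pts[:N_BONE], canal=pts[N_BONE:])

    def to_dict(self) -> dict:
        return {"bone_line": self.bone_line.tolist(), "canal": self.canal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(bone_line=np.asarray(d["bone_line"]), canal=np.asarray(d["canal"]))
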