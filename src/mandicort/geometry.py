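"""Bone-line construction and orthogonal cross-section extraction.

The five bone-line landmarks define a piecewise-linear polyline with an
arc-length parameterization. A cut frame at a station along the line gives
the local tangent and the normal (tangent rotated +90 deg), and the
cross-section sampler reads the volume along that normal — bilinear in the
axial plane, nearest-neighbour across slices, zero fill outside the volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .landmarks import LandmarkSet
from .volume import CTVolume


@dataclass(frozen=True)
class BoneLine:
    points: np.ndarray       # (5, 2) px, ordered left -> right
    seg_lengths: np.ndarray  # (4,)
    cum_lengths: np.ndarray  # (5,), starts at 0

    @property
    def total_length(self) -> float:
        return float(self.cum_lengths[-1])


@dataclass(frozen=True)
class CutFrame:
    anchor: np.ndarray   # (2,) px
    tangent: np.ndarray  # unit 2-vector
    normal: np.ndarray   # unit 2-vector, tangent rotated +90 deg
    half_extent_px: float


@dataclass(frozen=True)
class CrossSection:
    image: np.ndarray       # (along-normal, along-slice-axis)
    px_spacing_mm: float
    offsets_px: np.ndarray  # signed offsets along the normal


def fit_bone_line(points) -> BoneLine:
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape != (5, 2):
        raise ValueError(f"bone line needs exactly 5 (x, y) points, got shape {pts.shape}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("consecutive bone-line points coincide")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return BoneLine(points=pts, seg_lengths=seg, cum_lengths=cum)


def point_at(line: BoneLine, station: float) -> np.ndarray:
    """Point at arc-length fraction ``station`` in [0, 1]."""
    if not 0.0 <= station <= 1.0:
        raise ValueError(f"station must lie in [0, 1], got {station}")
    s = station * line.total_length
    i = int(np.searchsorted(line.cum_lengths[1:-1], s, side="right"))
    f = (s - line.cum_lengths[i]) / line.seg_lengths[i]
    return line.points[i] + f * (line.points[i + 1] - line.points[i])


def tangent_at(line: BoneLine, station: float) -> np.ndarray:
    """Unit tangent; at interior vertices, the mean of adjacent segments."""
    if not 0.0 <= station <= 1.0:
        raise ValueError(f"station must lie in [0, 1], got {station}")
    s = station * line.total_length
    dirs = np.diff(line.points, axis=0) / line.seg_lengths[:, None]
    # on a vertex (within tolerance): average the two adjacent directions
    at_vertex = np.isclose(s, line.cum_lengths, atol=1e-9)
    if at_vertex.any():
        i = int(np.argmax(at_vertex))
        if 0 < i < len(line.points) - 1:
            t = dirs[i - 1] + dirs[i]
        else:
            t = dirs[0] if i == 0 else dirs[-1]
    else:
        i = int(np.searchsorted(line.cum_lengths[1:-1], s, side="right"))
        t = dirs[i]
    return t / np.linalg.norm(t)


def compute_cut_frame(line: BoneLine, station: float, half_extent_px: float = 30.0) -> CutFrame:
    """Orthogonal cut frame at an arc-length fraction of the bone line."""
    anchor = point_at(line, station)
    tangent = tangent_at(line, station)
    normal = np.array([-tangent[1], tangent[0]])
    return CutFrame(anchor=anchor, tangent=tangent, normal=normal,
                    half_extent_px=float(half_extent_px))


def project_station(line: BoneLine, point) -> float:
    """Arc-length fraction of the polyline point closest to ``point``."""
    p = np.asarray(point, dtype=np.float64)
    best_d, best_s = np.inf, 0.0
    for i in range(len(line.points) - 1):
        a, b = line.points[i], line.points[i + 1]
        ab = b - a
        t = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
        q = a + t * ab
        d = float(np.linalg.norm(p - q))
        if d < best_d:
            best_d = d
            best_s = (line.cum_lengths[i] + t * line.seg_lengths[i]) / line.total_length
    return best_s


def default_stations(line: BoneLine, landmarks: LandmarkSet,
                     offset_px: float = 6.0) -> list[float]:
    """Cut stations anchored at the canal (foramen) projections.

    Each canal point is projected onto the bone line and the station is
    shifted ``offset_px`` along the arc toward the midline, mirroring the
    clinical practice of measuring in the premolar/molar regions next to
    the foramen rather than through it (a cut through the foramen void
    would not cross intact cortical bone).
    """
    df = offset_px / line.total_length
    s_left = project_station(line, landmarks.canal[0])
    s_right = project_station(line, landmarks.canal[1])
    return [float(np.clip(s_left + df, 0.0, 1.0)),
            float(np.clip(s_right - df, 0.0, 1.0))]


def extract_cross_section(vol: CTVolume, slice_index: int, frame: CutFrame,
                          depth_extent: int = 1, fill: float = 0.0) -> CrossSection:
    """Sample the volume on a regular grid along the cut frame's normal.

    Returns an image of shape (2*floor(half_extent)+1, depth_extent):
    bilinear interpolation within each axial slice, nearest (exact index)
    across slices, ``fill`` outside the volume.
    """
    if depth_extent < 1:
        raise ValueError("depth_extent must be >= 1")
    if not 0 <= slice_index < vol.n_slices:
        raise ValueError(f"slice index {slice_index} outside volume of {vol.n_slices} slices")
    h = np.floor(frame.half_extent_px)
    if h < 0:
        raise ValueError("half extent must be non-negative")
    offsets = np.arange(-h, h + 1)
    xs = frame.anchor[0] + offsets * frame.normal[0]
    ys = frame.anchor[1] + offsets * frame.normal[1]
    n_rows, n_cols = vol.data.shape[1:]
    image = np.full((len(offsets), depth_extent), fill, dtype=np.float64)
    z0 = slice_index - (depth_extent - 1) // 2
    for k in range(depth_extent):
        z = z0 + k
        if not 0 <= z < vol.n_slices:
            continue
        image[:, k] = map_coordinates(vol.data[z], np.array([ys, xs]),
                                      order=1, mode="constant", cval=fill)
    inside = ((xs >= 0) & (xs <= n_cols - 1) & (ys >= 0) & (ys <= n_rows - 1))
    if not inside.any():
        warnings.warn("cut frame lies entirely outside the volume; section is all fill",
                      stacklevel=2)
    return CrossSection(image=image, px_spacing_mm=float(vol.spacing_mm[2]),
                        offsets_px=offsets)
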