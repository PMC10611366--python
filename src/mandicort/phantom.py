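"""Synthetic CBCT-like mandible phantoms with known ground truth.

A phantom emulates the features the three-stage pipeline depends on, in an
axial stack:

* a horseshoe-shaped (open-ring) cortical shell — two concentric cortical
  walls of known radial thickness enclosing a lower-intensity trabecular
  band — present on every slice;
* two circular canal voids piercing the outer cortical wall (the geometric
  stand-in for the mental foramina) on, and only on, the narrow band of
  "valid" slices around the labelled correct slice;
* additive Gaussian noise.

Ground truth records the valid band, the five bone-line points (equally
spaced along the outer cortical wall midline, left to right), the two canal
centers, and the cortical wall thickness, so every stage of the pipeline
can be scored without manual labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np

from .landmarks import LandmarkSet
from .volume import CTVolume, write_nrrd

# horseshoe geometry (angles measured from "straight down" in image coords)
SPAN_DEG = 120.0        # half-span of the open ring
BONE_LINE_DEG = 100.0   # half-span of the 5 bone-line points
CANAL_DEG = 62.0        # canal voids sit at +/- this angle, clear of bone-line points


class GeometryError(ValueError):
    """Raised when the requested shell does not fit the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mandible volume."""

    grid: tuple[int, int, int] = (20, 64, 64)  # (slices, rows, cols)
    arch_radius_px: float = 19.0
    cortical_thickness_px: float = 4.0
    trabecular_width_px: float = 6.0
    background_intensity: float = 0.0
    trabecular_intensity: float = 0.35
    cortical_intensity: float = 1.0
    canal_radius_px: float = 2.0
    valid_band_halfwidth: int = 1
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (1.0 <= self.cortical_thickness_px < self.arch_radius_px):
            raise ValueError("cortical thickness must be >= 1 px and below the arch radius")
        if not (self.background_intensity < self.trabecular_intensity
                < self.cortical_intensity):
            raise ValueError("intensities must be ordered background < trabecular < cortical")
        if self.valid_band_halfwidth < 0 or self.noise_sd < 0:
            raise ValueError("valid_band_halfwidth and noise_sd must be non-negative")

    @property
    def outer_radius_px(self) -> float:
        return self.arch_radius_px + self.trabecular_width_px / 2 + self.cortical_thickness_px

    @property
    def inner_radius_px(self) -> float:
        return self.arch_radius_px - self.trabecular_width_px / 2 - self.cortical_thickness_px


@dataclass(frozen=True)
class PhantomTruth:
    correct_slice: int
    valid_slices: tuple[int, ...]
    landmarks: LandmarkSet
    cortical_thickness_px: float

    def to_dict(self) -> dict:
        return {
            "correct_slice": self.correct_slice,
            "valid_slices": list(self.valid_slices),
            "landmarks": self.landmarks.to_dict(),
            "cortical_thickness_px": self.cortical_thickness_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        return cls(d["correct_slice"], tuple(d["valid_slices"]),
                   LandmarkSet.from_dict(d["landmarks"]), d["cortical_thickness_px"])


def _center(spec: PhantomSpec) -> tuple[float, float]:
    _, n_rows, n_cols = spec.grid
    return n_cols / 2.0, 0.42 * n_rows  # (cx, cy)


def _check_fit(spec: PhantomSpec) -> None:
    n_slices, n_rows, n_cols = spec.grid
    cx, cy = _center(spec)
    ro = spec.outer_radius_px
    if spec.inner_radius_px <= 0:
        raise GeometryError("inner cortical wall collapses through the arch center")
    if ro > min(cx, n_cols - 1 - cx, n_rows - 1 - cy) - 1:
        raise GeometryError(
            f"shell outer radius {ro:.1f} px does not fit a {n_rows}x{n_cols} slice")
    if cy - 0.5 * ro < 1:
        raise GeometryError("shell extends above the top edge of the slice")


def _arc_point(spec: PhantomSpec, angle_rad: float, radius: float) -> tuple[float, float]:
    cx, cy = _center(spec)
    return cx + radius * np.sin(angle_rad), cy + radius * np.cos(angle_rad)


def _render_slice(spec: PhantomSpec, radius_scale: float, with_canals: bool) -> np.ndarray:
    """Rasterize one axial slice (no noise)."""
    _, n_rows, n_cols = spec.grid
    cx, cy = _center(spec)
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    ang = np.arctan2(dx, dy)  # 0 == straight down, +/-pi straight up
    in_span = np.abs(ang) <= np.deg2rad(SPAN_DEG)

    t = spec.cortical_thickness_px
    ro = spec.outer_radius_px * radius_scale
    ri = spec.inner_radius_px * radius_scale
    img = np.full((n_rows, n_cols), spec.background_intensity, dtype=np.float64)
    trab = in_span & (r > ri + t) & (r < ro - t)
    cort = in_span & (((r >= ro - t) & (r <= ro)) | ((r >= ri) & (r <= ri + t)))
    img[trab] = spec.trabecular_intensity
    img[cort] = spec.cortical_intensity
    if with_canals:
        wall_mid = ro - t / 2
        for sign in (-1.0, 1.0):
            px, py = _arc_point(spec, sign * np.deg2rad(CANAL_DEG), wall_mid)
            void = (xx - px) ** 2 + (yy - py) ** 2 <= spec.canal_radius_px ** 2
            img[void] = spec.background_intensity
    return img


def _truth_landmarks(spec: PhantomSpec) -> LandmarkSet:
    wall_mid = spec.outer_radius_px - spec.cortical_thickness_px / 2
    angles = np.deg2rad(np.linspace(-BONE_LINE_DEG, BONE_LINE_DEG, 5))
    bone = np.array([_arc_point(spec, a, wall_mid) for a in angles])
    canal = np.array([_arc_point(spec, s * np.deg2rad(CANAL_DEG), wall_mid)
                      for s in (-1.0, 1.0)])
    return LandmarkSet(bone_line=bone, canal=canal)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Build one phantom volume and its ground truth.

    The arch radius tapers slightly away from the correct slice (1.5% per
    slice) so the stack looks like a narrowing anatomical structure rather
    than an extruded cylinder; the canal voids exist only inside the valid
    band, which is what makes the slice-labelling criterion discriminative.
    """
    _check_fit(spec)
    n_slices = spec.grid[0]
    correct = n_slices // 2
    band = range(max(0, correct - spec.valid_band_halfwidth),
                 min(n_slices - 1, correct + spec.valid_band_halfwidth) + 1)
    rng = np.random.default_rng(spec.seed)
    data = np.empty(spec.grid, dtype=np.float64)
    for z in range(n_slices):
        scale = 1.0 - 0.015 * abs(z - correct)
        data[z] = _render_slice(spec, scale, with_canals=z in band)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    truth = PhantomTruth(
        correct_slice=correct,
        valid_slices=tuple(band),
        landmarks=_truth_landmarks(spec),
        cortical_thickness_px=spec.cortical_thickness_px,
    )
    vol = CTVolume(data=data, spacing_mm=(0.3, 0.3, 0.3), normalized=False)
    return vol, truth


DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    "arch_radius_px": (17.0, 21.0),
    "cortical_thickness_px": (2.0, 6.0),
    "canal_radius_px": (1.5, 2.5),
}


def generate_dataset(n: int, spec_ranges: dict | None = None, seed: int = 0,
                     base_spec: PhantomSpec | None = None,
                     ) -> list[tuple[CTVolume, PhantomTruth]]:
    """Draw ``n`` phantoms with spec fields sampled uniformly from ranges.

    ``spec_ranges`` maps PhantomSpec field names to (low, high) tuples;
    unlisted fields keep the value from ``base_spec`` (or the defaults).
    Reproducible: per-item seeds are derived from ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one phantom")
    ranges = dict(DEFAULT_SPEC_RANGES if spec_ranges is None else spec_ranges)
    base = base_spec or PhantomSpec()
    valid_fields = set(PhantomSpec.__dataclass_fields__)
    for name, rng_pair in ranges.items():
        if name not in valid_fields:
            raise ValueError(f"unknown PhantomSpec field in ranges: {name!r}")
        lo, hi = rng_pair
        if hi < lo:
            raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
        spec = replace(base, seed=int(rng.integers(2 ** 31)), **draws)
        items.append(generate_phantom(spec))
    return items


def split_dataset(items: list, train_fraction: float, seed: int = 0) -> tuple[list, list]:
    """Random disjoint train/validation partition (default study ratio 70:30)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    return train, val


def normalized_midpoint_threshold(spec: PhantomSpec) -> float:
    """Fixed binarization threshold halfway between the trabecular and
    cortical intensities after volume normalization (exact when noise-free,
    since the global extrema are then background and cortical)."""
    lo, hi = spec.background_intensity, spec.cortical_intensity
    trab_n = (spec.trabecular_intensity - lo) / (hi - lo) - 0.5
    return (trab_n + 0.5) / 2


def save_phantom(vol: CTVolume, truth: PhantomTruth, stem: str | Path) -> tuple[Path, Path]:
    """Write a phantom as NRRD plus a JSON truth file."""
    stem = Path(stem)
    vol_path = write_nrrd(vol, stem.with_suffix(".nrrd"))
    truth_path = stem.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2))
    return vol_path, truth_path


def load_phantom_dir(directory: str | Path) -> list[tuple[CTVolume, PhantomTruth]]:
    """Load every NRRD + .truth.json pair written by :func:`save_phantom`."""
    from .volume import read_nrrd

    directory = Path(directory)
    items = []
    for vol_path in sorted(directory.glob("*.nrrd")):
        truth_path = vol_path.with_suffix(".truth.json")
        if not truth_path.exists():
            continue
        items.append((read_nrrd(vol_path),
                      PhantomTruth.from_dict(json.loads(truth_path.read_text()))))
    if not items:
        raise FileNotFoundError(f"no phantom NRRD/truth pairs found in {directory}")
    return items
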