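"""End-to-end orchestration of the three stages.

``run_pipeline`` takes one volume through normalize -> slice scoring ->
slice selection -> landmark regression -> cut-frame construction ->
cross-section extraction -> binarization -> boundary scan, and returns a
structured report. Any failure is re-raised as a :class:`StageError`
naming the stage, because in a chained design an early mistake silently
propagates into the thickness numbers otherwise.

``run_experiment`` mirrors the study protocol at phantom scale: generate a
dataset, split 70:30, train both networks, and report the per-stage
metrics (classification accuracy/precision/recall and slice-hit rate,
landmark L1 in px, thickness MSE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classifier as clf
from . import regressor as reg
from .geometry import compute_cut_frame, default_stations, extract_cross_section, fit_bone_line
from .landmarks import LandmarkSet
from .nn import Network, load_network
from .phantom import (PhantomSpec, PhantomTruth, generate_dataset, generate_phantom,
                      normalized_midpoint_threshold, split_dataset)
from .thickness import evaluate_thickness, measure_section
from .volume import CTVolume, normalize_volume

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    stage1_weights: str | None = None
    stage2_weights: str | None = None
    binarize_method: str = "multiotsu"   # "fixed" needs `threshold`
    threshold: float | None = None
    half_extent_px: float = 30.0
    depth_extent: int = 1
    station_offset_px: float = 6.0
    mm_per_px: float | None = None       # default: in-plane voxel spacing
    seed: int = 0
    output_dir: str | None = None


@dataclass
class PipelineReport:
    selected_slice: int
    slice_probability: float
    landmarks: LandmarkSet
    stations: list[float]
    profiles: list[dict]
    thickness_px: float
    thickness_mm: float
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected_slice": self.selected_slice,
            "slice_probability": self.slice_probability,
            "landmarks": self.landmarks.to_dict(),
            "stations": self.stations,
            "profiles": self.profiles,
            "thickness_px": self.thickness_px,
            "thickness_mm": self.thickness_mm,
            "metrics": self.metrics,
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _load(weights: str | None, stage: str) -> Network:
    if weights is None:
        raise StageError(stage, "no model given and no weights path configured")
    try:
        return load_network(weights)
    except FileNotFoundError as exc:
        raise StageError(stage, str(exc)) from exc


def measure_cortical_thickness(vol: CTVolume, slice_index: int, landmarks: LandmarkSet,
                               cfg: PipelineConfig) -> tuple[list[float], list[dict], float]:
    """Stage 3 given a slice and landmarks: stations, per-station profiles,
    and the point estimate (median thickness across all measured columns)."""
    line = fit_bone_line(landmarks.bone_line)
    stations = default_stations(line, landmarks, offset_px=cfg.station_offset_px)
    mm_per_px = cfg.mm_per_px if cfg.mm_per_px is not None else vol.spacing_mm[2]
    profiles, all_px = [], []
    for s in stations:
        frame = compute_cut_frame(line, s, half_extent_px=cfg.half_extent_px)
        section = extract_cross_section(vol, slice_index, frame,
                                        depth_extent=cfg.depth_extent)
        prof = measure_section(section, method=cfg.binarize_method,
                               threshold=cfg.threshold, mm_per_px=mm_per_px)
        profiles.append({
            "station": s,
            "columns": prof.columns.tolist(),
            "thickness_px": prof.thickness_px.tolist(),
            "thickness_mm": prof.thickness_mm.tolist(),
            "thinnest_px": prof.thinnest_px,
            "thickest_px": prof.thickest_px,
        })
        all_px.extend(prof.thickness_px.tolist())
    estimate_px = float(np.median(all_px))
    return stations, profiles, estimate_px


def run_pipeline(vol: CTVolume, cfg: PipelineConfig, truth: PhantomTruth | None = None,
                 stage1_model: Network | None = None,
                 stage2_model: Network | None = None) -> PipelineReport:
    """Run all three stages on one volume; attach truth metrics if given."""
    with _stage("preprocess"):
        nv = vol if vol.normalized else normalize_volume(vol)
    if stage1_model is None:
        stage1_model = _load(cfg.stage1_weights, "stage1")
    if stage2_model is None:
        stage2_model = _load(cfg.stage2_weights, "stage2")
    with _stage("stage1"):
        scores = clf.score_slices(stage1_model, nv)
        chosen = clf.select_optimal_slice(scores)
        prob = scores[chosen].probability
    with _stage("stage2"):
        landmarks = reg.predict_keypoints(stage2_model, nv.slice(chosen))
    with _stage("stage3"):
        stations, profiles, est_px = measure_cortical_thickness(nv, chosen, landmarks, cfg)
    mm_per_px = cfg.mm_per_px if cfg.mm_per_px is not None else nv.spacing_mm[2]
    report = PipelineReport(
        selected_slice=chosen, slice_probability=prob, landmarks=landmarks,
        stations=stations, profiles=profiles, thickness_px=est_px,
        thickness_mm=est_px * mm_per_px,
    )
    if truth is not None:
        report.metrics = {
            "slice_hit": chosen in truth.valid_slices,
            "landmark_mae_px": reg.evaluate_regressor(
                [landmarks], [truth.landmarks])["mae_px"],
            "thickness_error_px": est_px - truth.cortical_thickness_px,
        }
    return report


# -- desk-scale experiment -------------------------------------------------

#: study conditions of the scaled-down experiment: 200 noise-free phantoms
#: with 64x64 slices, split 70:30.
EXPERIMENT_N = 200
TRAIN_FRACTION = 0.7


def train_models(train_items, val_items, seed: int = 0,
                 classifier_epochs: int = 24, regressor_epochs: int = 60,
                 backbone_depth: str = "small"):
    """Train both networks on phantom items; returns models and histories."""
    c_cfg = clf.ClassifierConfig(backbone_depth=backbone_depth, epochs=classifier_epochs,
                                 seed=seed)
    model1 = clf.build_slice_classifier(c_cfg)
    model1, c_metrics = clf.train_classifier(
        model1, clf.slices_from_phantoms(train_items),
        clf.slices_from_phantoms(val_items), c_cfg)
    r_cfg = reg.RegressorConfig(backbone_depth=backbone_depth, epochs=regressor_epochs,
                                seed=seed + 1)
    model2 = reg.build_keypoint_regressor(r_cfg)
    model2, r_hist = reg.train_regressor(
        model2, reg.keypoint_pairs_from_phantoms(train_items),
        reg.keypoint_pairs_from_phantoms(val_items), r_cfg)
    return model1, c_metrics, model2, r_hist


def thickness_recovery_experiment(thicknesses=(2.0, 3.0, 4.0, 6.0, 8.0),
                                  per_thickness: int = 10, seed: int = 0) -> dict:
    """Stage-3 parameter recovery: measure noise-free phantoms of known
    cortical thickness from their truth landmarks.

    The arch radius is drawn from 16-18 px so the thickest shell still fits
    the 64x64 grid. Returns per-phantom errors and their summary.
    """
    rng = np.random.default_rng(seed)
    measured, truths = [], []
    for t in thicknesses:
        for _ in range(per_thickness):
            spec = PhantomSpec(
                noise_sd=0.0, cortical_thickness_px=float(t),
                arch_radius_px=float(rng.uniform(16.0, 18.0)),
                canal_radius_px=float(rng.uniform(1.5, 2.5)),
                seed=int(rng.integers(2 ** 31)))
            vol, truth = generate_phantom(spec)
            nv = normalize_volume(vol)
            cfg = PipelineConfig(binarize_method="fixed",
                                 threshold=normalized_midpoint_threshold(spec),
                                 mm_per_px=0.3)
            _, _, est = measure_cortical_thickness(
                nv, truth.correct_slice, truth.landmarks, cfg)
            measured.append(est)
            truths.append(float(t))
    out = evaluate_thickness(measured, truths, units="px")
    out["measured"] = measured
    out["truth"] = truths
    return out


def run_experiment(n: int = EXPERIMENT_N, seed: int = 0,
                   classifier_epochs: int = 24, regressor_epochs: int = 60,
                   spec_ranges: dict | None = None) -> dict:
    """Generate phantoms, train both stages on the 70:30 split, and report
    all three stages' aggregate metrics."""
    if n < 1:
        raise ValueError("need at least one phantom")
    if n < 10:
        logger.warning("n=%d is small; aggregate metrics will be unstable", n)
    base = PhantomSpec(noise_sd=0.0)
    items = generate_dataset(n, spec_ranges=spec_ranges, seed=seed, base_spec=base)
    train_items, val_items = split_dataset(items, TRAIN_FRACTION, seed=seed + 1)
    model1, c_metrics, model2, r_hist = train_models(
        train_items, val_items, seed=seed,
        classifier_epochs=classifier_epochs, regressor_epochs=regressor_epochs)

    hit = clf.slice_hit_accuracy(model1, val_items)
    cfg = PipelineConfig(binarize_method="fixed",
                         threshold=normalized_midpoint_threshold(base),
                         mm_per_px=0.3, seed=seed)
    measured, truths, n_failed = [], [], 0
    for vol, truth in val_items:
        try:
            rep = run_pipeline(vol, cfg, truth=truth,
                               stage1_model=model1, stage2_model=model2)
        except StageError as exc:
            logger.warning("pipeline failed on a validation phantom: %s", exc)
            n_failed += 1
            continue
        measured.append(rep.thickness_px)
        truths.append(truth.cortical_thickness_px)
    thick = (evaluate_thickness(measured, truths, units="px")
             if measured else {"units": "px", "n": 0})
    thick["n_failed"] = n_failed
    return {
        "n": n,
        "split": {"train": len(train_items), "val": len(val_items)},
        "stage1": {
            "val_accuracy": c_metrics.accuracy,
            "val_precision": c_metrics.precision,
            "val_recall": c_metrics.recall,
            "val_slice_hit_accuracy": hit,
            "train_accuracy_history": c_metrics.train_accuracy,
            "val_accuracy_history": c_metrics.val_accuracy,
        },
        "stage2": {
            "val_mae_px": min(r_hist.val_l1) if r_hist.val_l1 else None,
            "train_l1_history": r_hist.train_l1,
            "val_l1_history": r_hist.val_l1,
        },
        "stage3": thick,
    }
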