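"""End-to-end orchestration: simulate, normalize, segment, extract
features, embed, train and predict, with reproducible artifacts on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.optimize import linear_sum_assignment

from . import phantom as ph
from .embedding import (FEATURE_SUBSETS, fit_pca, fit_scaler, project,
                        subset_columns)
from .features import features_table, write_features_csv
from .preprocessing import AttenuationImage, Radiograph, normalize, write_radiograph
from .segmentation import label_image, segment_grains
from . import trait_models as tm

log = logging.getLogger("grainray")

__all__ = [
    "RunConfig",
    "SceneAnalysis",
    "analyze_scene",
    "match_segments",
    "write_matched_truth",
    "train_chaffy",
    "train_crk",
    "train_hrr",
    "predict_traits",
    "run_pipeline",
    "make_fixture_suite",
]


# ---------------------------------------------------------------------------
# scene analysis: image -> per-grain feature table with matched truth
# ---------------------------------------------------------------------------

@dataclass
class SceneAnalysis:
    """Measured per-grain quantities from one rendered scene."""

    segments: list
    att: AttenuationImage
    labels: list[int]
    features: np.ndarray            # n x 8, f1..f8
    truth: Optional[list] = None    # matched GrainSpec per segment (same order)


def analyze_scene(scene: ph.PhantomScene, min_area_px: int = 50,
                  match_truth: bool = True) -> SceneAnalysis:
    """Render, normalize, segment and featurize one phantom scene."""
    counts = ph.render_radiograph(scene)
    att = normalize(Radiograph(pixels=counts), "auto")
    segments = segment_grains(att, min_area_px=min_area_px)
    labels, table = features_table(segments, att)
    truth = match_segments(segments, scene) if match_truth else None
    return SceneAnalysis(segments, att, labels, table, truth)


def match_segments(segments, scene: ph.PhantomScene):
    """Bijectively match segments to true grains by centroid distance.

    Returns one GrainSpec per segment (order follows segments).  Raises if
    counts differ or any matched pair is further apart than half a pitch.
    """
    if len(segments) != len(scene.grains):
        raise ValueError(
            f"segment count {len(segments)} != true grain count {len(scene.grains)}"
        )
    seg_centers = np.array([s.centroid for s in segments])
    true_centers = np.array([g.center_px for g in scene.grains])
    cost = np.linalg.norm(seg_centers[:, None] - true_centers[None], axis=2)
    rows, cols = linear_sum_assignment(cost)
    limit = scene.grid_layout[2] / 2
    if np.any(cost[rows, cols] > limit):
        raise ValueError("matched segment further than half a grid pitch from truth")
    order = np.empty(len(segments), dtype=int)
    order[rows] = cols
    return [scene.grains[i] for i in order]


def write_matched_truth(analysis: SceneAnalysis, path) -> None:
    """Per-segment truth labels (aligned with the feature table rows)."""
    import csv

    if analysis.truth is None:
        raise ValueError("analysis carries no matched truth")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "chaffy", "chalky", "hrr_class"])
        for label, g in zip(analysis.labels, analysis.truth):
            w.writerow([
                label,
                str(g.chaffy).lower(),
                str(g.is_chalky).lower(),
                "" if g.hrr_class is None else g.hrr_class,
            ])


# ---------------------------------------------------------------------------
# trait-specific training on phantom scenes
# ---------------------------------------------------------------------------

def train_chaffy(analysis: SceneAnalysis, theta: float = tm.DEFAULT_THETA_CHAFFY):
    """Fit embedding on all grains and the cluster on non-chaffy grains."""
    X = subset_columns(analysis.features, "chaffiness")
    scaler = fit_scaler(X, FEATURE_SUBSETS["chaffiness"])
    pca = fit_pca(scaler.transform(X), feature_names=FEATURE_SUBSETS["chaffiness"])
    coords = project(scaler, pca, X)
    non_chaffy = np.array([not g.chaffy for g in analysis.truth])
    model = tm.fit_chaffy_cluster(coords[non_chaffy], theta=theta)
    return scaler, pca, model


def train_crk(grain_scene: ph.PhantomScene, min_area_px: int = 50):
    """Train the chalky hyperplane on de-husked kernels of the same scene.

    The de-husked render of the training scene stands in for the manually
    de-husked, re-imaged ground-truth grains; the stored shift maps
    whole-grain features onto the kernel population.
    """
    kernel_analysis = analyze_scene(ph.dehusked(grain_scene), min_area_px)
    grain_analysis = analyze_scene(grain_scene, min_area_px)

    Xk = subset_columns(kernel_analysis.features, "crk")
    Xg = subset_columns(grain_analysis.features, "crk")
    scaler = fit_scaler(Xk, FEATURE_SUBSETS["crk"])
    pca = fit_pca(scaler.transform(Xk), feature_names=FEATURE_SUBSETS["crk"])
    coords = project(scaler, pca, Xk)
    chalky = [g.is_chalky for g in kernel_analysis.truth]
    shift = Xg.mean(axis=0) - Xk.mean(axis=0)
    model = tm.fit_chalky_hyperplane(coords, chalky, dehusk_shift=shift)
    return scaler, pca, model


def train_hrr(analysis: SceneAnalysis):
    """Fit embedding and the 5-class decision functions on labeled grains."""
    X = subset_columns(analysis.features, "hrr")
    scaler = fit_scaler(X, FEATURE_SUBSETS["hrr"])
    pca = fit_pca(scaler.transform(X), feature_names=FEATURE_SUBSETS["hrr"])
    coords = project(scaler, pca, X)
    labels = [g.hrr_class for g in analysis.truth]
    keep = [i for i, c in enumerate(labels) if c is not None]
    model = tm.fit_hrr_model(coords[keep], [labels[i] for i in keep])
    return scaler, pca, model


def predict_traits(
    analysis: SceneAnalysis,
    chaffy_bundle=None,
    crk_bundle=None,
    hrr_bundle=None,
) -> tm.SampleTraitReport:
    """Apply any subset of fitted trait models to a measured scene."""
    n = len(analysis.labels)
    per_grain = [{"label": lab} for lab in analysis.labels]
    chaffy_count = 0
    crk_percent = 0.0
    hrr_percent = float("nan")

    if chaffy_bundle is not None:
        scaler, pca, model = chaffy_bundle
        coords = project(scaler, pca, subset_columns(analysis.features, "chaffiness"))
        flags, dists = tm.classify_chaffy(coords, model)
        chaffy_count = int(flags.sum())
        for rec, f, d in zip(per_grain, flags, dists):
            rec["chaffy"] = bool(f)
            rec["mahalanobis"] = float(d)

    if crk_bundle is not None:
        scaler, pca, model = crk_bundle
        X = subset_columns(analysis.features, "crk")
        flags, crk_percent = tm.classify_chalky(X, model, scaler, pca, dehusk=True)
        for rec, f in zip(per_grain, flags):
            rec["chalky"] = bool(f)

    if hrr_bundle is not None:
        scaler, pca, model = hrr_bundle
        coords = project(scaler, pca, subset_columns(analysis.features, "hrr"))
        probs = tm.predict_hrr_probabilities(coords, model)
        classes = []
        for rec, p in zip(per_grain, probs):
            cls, rel = tm.predict_grain_hrr(p)
            rec["hrr_class"] = cls
            rec["hrr_reliability"] = rel
            classes.append(cls)
        hrr_percent = tm.aggregate_sample_hrr(classes) if classes else float("nan")

    return tm.SampleTraitReport(
        n_grains=n,
        chaffy_count=chaffy_count,
        crk_percent=crk_percent,
        hrr_percent_predicted=hrr_percent,
        per_grain=per_grain,
    )


# ---------------------------------------------------------------------------
# full runs from a config
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters of one end-to-end phantom run."""

    out_dir: str
    seed: int = 0
    n_grains: int = 100
    detector_shape: tuple[int, int] = (420, 640)
    i0: int = 12000
    noise_sd: float = 30.0
    chaffy_proportion: float = 0.15
    chalky_proportion: float = 0.3
    hrr_mix: dict = field(
        default_factory=lambda: {100: 0.2, 80: 0.2, 60: 0.2, 40: 0.2, 20: 0.2}
    )
    theta_chaffy: float = tm.DEFAULT_THETA_CHAFFY
    min_area_px: int = 50
    struct_radius: int = 1
    traits: tuple[str, ...] = ("chaffy", "crk", "hrr")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "hrr_mix" in raw:
            raw["hrr_mix"] = {int(k): float(v) for k, v in raw["hrr_mix"].items()}
        if "detector_shape" in raw:
            raw["detector_shape"] = tuple(raw["detector_shape"])
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["detector_shape"] = list(self.detector_shape)
        data["traits"] = list(self.traits)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def run_pipeline(config: RunConfig) -> tm.SampleTraitReport:
    """Simulate, train on one scene, predict on a second, write artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    log.info("run_pipeline: %s", dataclasses.asdict(config))

    acq = ph.AcquisitionModel(
        background_intensity_I0=config.i0,
        detector_shape=config.detector_shape,
        noise_sd=config.noise_sd,
        rng_seed=config.seed,
    )
    mix = ph.TraitMix(
        chaffy=config.chaffy_proportion,
        chalky=config.chalky_proportion,
        hrr=config.hrr_mix,
    )
    train_scene = ph.build_scene(config.n_grains, mix, acq, seed=config.seed)
    eval_acq = dataclasses.replace(acq, rng_seed=config.seed + 1)
    eval_scene = ph.build_scene(config.n_grains, mix, eval_acq, seed=config.seed + 1)

    ph.write_truth_table(train_scene, out / "train_truth.csv")
    ph.write_truth_table(eval_scene, out / "eval_truth.csv")
    write_radiograph(out / "eval_radiograph.tif", ph.render_radiograph(eval_scene))

    train_analysis = analyze_scene(train_scene, config.min_area_px)
    write_matched_truth(train_analysis, out / "train_matched_truth.csv")
    eval_analysis = analyze_scene(eval_scene, config.min_area_px, match_truth=False)
    write_features_csv(out / "eval_features.csv", eval_analysis.labels,
                       eval_analysis.features)
    write_radiograph(
        out / "eval_labels.tif",
        label_image(eval_analysis.segments, config.detector_shape),
    )

    chaffy_bundle = crk_bundle = hrr_bundle = None
    if "chaffy" in config.traits:
        chaffy_bundle = train_chaffy(train_analysis, theta=config.theta_chaffy)
    if "crk" in config.traits:
        # chalky training must see filled grains only (kernels vanish on chaffy)
        crk_mix = ph.TraitMix(chaffy=0.0, chalky=0.5, hrr=config.hrr_mix)
        crk_scene = ph.build_scene(config.n_grains, crk_mix, acq, seed=config.seed + 2)
        crk_bundle = train_crk(crk_scene, config.min_area_px)
    if "hrr" in config.traits:
        hrr_bundle = train_hrr(train_analysis)

    tm.save_models(
        out / "models.json",
        chaffy=chaffy_bundle[2] if chaffy_bundle else None,
        chalky=crk_bundle[2] if crk_bundle else None,
        hrr=hrr_bundle[2] if hrr_bundle else None,
    )
    report = predict_traits(eval_analysis, chaffy_bundle, crk_bundle, hrr_bundle)
    (out / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# canonical test fixtures
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def touching_pair_attenuation(shape: tuple[int, int] = (80, 120)) -> np.ndarray:
    """Two overlapping ellipses with distinct distance peaks, for watershed tests."""
    grains = [
        ph.GrainSpec(1, (40.0, 40.0), (16.0, 10.0), 8.0, 0.0, 1.5, 0.01, 0.08),
        ph.GrainSpec(2, (40.0, 66.0), (16.0, 10.0), 8.0, 0.0, 1.5, 0.01, 0.08),
    ]
    return ph.grains_attenuation(grains, shape)


def make_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Emit the canonical fixtures and a checksum manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    acq = ph.AcquisitionModel(
        background_intensity_I0=12000, detector_shape=(420, 640),
        noise_sd=0.0, rng_seed=seed,
    )

    files: dict[str, str] = {}

    blank = ph.render_radiograph(ph.PhantomScene((), acq, (0, 0, 1.0)))
    write_radiograph(out / "blank.tif", blank)
    files["blank.tif"] = _sha256(out / "blank.tif")

    single = ph.build_scene(1, ph.TraitMix(), acq, seed=seed)
    write_radiograph(out / "single_grain.tif", ph.render_radiograph(single))
    ph.write_truth_table(single, out / "single_grain_truth.csv")
    files["single_grain.tif"] = _sha256(out / "single_grain.tif")
    files["single_grain_truth.csv"] = _sha256(out / "single_grain_truth.csv")

    pair = touching_pair_attenuation()
    counts = np.clip(np.round(12000 * np.exp(-pair)), 0, 16383).astype(np.uint16)
    write_radiograph(out / "touching_pair.tif", counts)
    files["touching_pair.tif"] = _sha256(out / "touching_pair.tif")

    mixes = {
        "chaffy": ph.TraitMix(chaffy=0.3),
        "crk": ph.TraitMix(chalky=0.4),
        "hrr": ph.TraitMix(hrr={100: 0.2, 80: 0.2, 60: 0.2, 40: 0.2, 20: 0.2}),
    }
    for offset, (trait, mix) in enumerate(mixes.items(), start=1):
        scene = ph.build_scene(100, mix, acq, seed=seed + offset)
        write_radiograph(out / f"scene_{trait}.tif", ph.render_radiograph(scene))
        ph.write_truth_table(scene, out / f"scene_{trait}_truth.csv")
        files[f"scene_{trait}.tif"] = _sha256(out / f"scene_{trait}.tif")
        files[f"scene_{trait}_truth.csv"] = _sha256(out / f"scene_{trait}_truth.csv")

    manifest = {"seed": seed, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
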