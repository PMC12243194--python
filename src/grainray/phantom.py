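"""Synthetic radiograph generator for husked-grain scenes.

Produces parallel-beam transmission images of ellipsoidal grains (low
attenuation husk shell around a denser kernel) laid out on a fixed
non-touching grid, together with exact per-grain ground truth.  Every
downstream stage of the pipeline is tested against these phantoms.

The forward model is Lambert-Beer: ``counts = I0 * exp(-sum(mu * t))``
with additive Gaussian noise on counts, rounded and clipped to the
detector bit depth.  Projection is parallel-beam; magnification is folded
into the pixel scale, so all geometry is expressed in pixels.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GrainSpec",
    "AcquisitionModel",
    "PhantomScene",
    "TraitMix",
    "CHALKY_FRACTION_THRESHOLD",
    "HRR_CLASS_VALUES",
    "build_scene",
    "projected_thickness",
    "grains_attenuation",
    "attenuation_map",
    "render_radiograph",
    "write_truth_table",
    "dehusked",
]

#: chalk area fraction above which a kernel counts as chalky (strict >).
CHALKY_FRACTION_THRESHOLD = 0.20

#: the five head-rice-recovery class values, in percent.
HRR_CLASS_VALUES = (100, 80, 60, 40, 20)

MAX_COUNT_BITS = 14


@dataclass(frozen=True)
class GrainSpec:
    """Geometry and material description of a single ellipsoidal grain."""

    id: int
    center_px: tuple[float, float]          # (row, col)
    semi_axes_px: tuple[float, float]       # in-plane (a, b); a along orientation
    depth_semi_axis_px: float               # c, along the beam
    orientation_rad: float
    husk_thickness_px: float
    mu_husk: float
    mu_kernel: float
    chaffy: bool = False
    chalk_fraction: float = 0.0
    chalk_factor: float = 0.85
    hrr_class: Optional[int] = None
    # chalk inclusion center, as a fraction of the available in-kernel
    # offset in the grain frame (set by build_scene; (0, 0) = concentric)
    chalk_center_frac: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        a, b = self.semi_axes_px
        if a <= 0 or b <= 0 or self.depth_semi_axis_px <= 0:
            raise ValueError("semi-axes must be strictly positive")
        if not 0 < self.husk_thickness_px < min(a, b):
            raise ValueError("husk_thickness_px must lie in (0, min(a, b))")
        if self.mu_husk < 0 or self.mu_kernel < 0:
            raise ValueError("attenuation coefficients must be >= 0")
        if not 0.0 <= self.chalk_fraction <= 1.0:
            raise ValueError("chalk_fraction must be in [0, 1]")
        if self.chalk_factor <= 0:
            raise ValueError("chalk_factor must be > 0")
        if self.chaffy and self.chalk_fraction != 0.0:
            raise ValueError("chaffy grains carry no kernel, chalk_fraction must be 0")
        if self.hrr_class is not None and self.hrr_class not in HRR_CLASS_VALUES:
            raise ValueError(f"hrr_class must be one of {HRR_CLASS_VALUES}")

    @property
    def is_chalky(self) -> bool:
        """True when the chalk inclusion exceeds the 20 % area threshold."""
        return self.chalk_fraction > CHALKY_FRACTION_THRESHOLD

    @property
    def outer_radius_px(self) -> float:
        return max(self.semi_axes_px)


@dataclass(frozen=True)
class AcquisitionModel:
    """Detector and exposure parameters of the virtual scanner."""

    background_intensity_I0: int = 12000
    detector_shape: tuple[int, int] = (1300, 2304)
    bit_depth: int = MAX_COUNT_BITS
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_intensity_I0 <= 2 ** self.bit_depth - 1:
            raise ValueError("I0 must be in (0, 2^bit_depth - 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class TraitMix:
    """Per-class proportions used to assign ground-truth trait labels.

    ``chaffy`` grains carry no kernel; ``chalky`` applies to the remaining
    filled grains; ``hrr`` gives proportions over the five HRR classes for
    filled grains (defaults to all 100 %).
    """

    chaffy: float = 0.0
    chalky: float = 0.0
    hrr: dict[int, float] = field(default_factory=lambda: {100: 1.0})

    def __post_init__(self) -> None:
        if not 0.0 <= self.chaffy <= 1.0 or not 0.0 <= self.chalky <= 1.0:
            raise ValueError("proportions must be in [0, 1]")
        total = sum(self.hrr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("hrr class proportions must sum to 1 within 1e-9")
        for cls in self.hrr:
            if cls not in HRR_CLASS_VALUES:
                raise ValueError(f"unknown hrr class {cls}")


@dataclass(frozen=True)
class PhantomScene:
    grains: tuple[GrainSpec, ...]
    acquisition: AcquisitionModel
    grid_layout: tuple[int, int, float]     # (n_rows, n_cols, pitch_px)

    def __post_init__(self) -> None:
        rows, cols = self.acquisition.detector_shape
        for g in self.grains:
            r, c = g.center_px
            rad = g.outer_radius_px
            if not (rad <= r <= rows - 1 - rad and rad <= c <= cols - 1 - rad):
                raise ValueError(f"grain {g.id} footprint outside detector")
        # pairwise disjoint outer footprints (bounding-circle check)
        centers = np.array([g.center_px for g in self.grains], float)
        radii = np.array([g.outer_radius_px for g in self.grains], float)
        for i in range(len(self.grains)):
            d = np.hypot(*(centers[i] - centers[i + 1:]).T)
            if np.any(d < radii[i] + radii[i + 1:]):
                raise ValueError("grain footprints overlap")


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer counts summing to n, matching proportions up to rounding."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


# monotone map from HRR class value to geometry scaling: lower recovery
# classes get smaller kernels (thicker husk), more elongated outlines and a
# weaker kernel; a documented modelling choice, not a measured relation.
_HRR_GEOMETRY = {
    100: dict(size=1.00, elong=1.00, husk=1.00, mu=1.00),
    80: dict(size=0.95, elong=1.12, husk=1.25, mu=0.93),
    60: dict(size=0.90, elong=1.24, husk=1.50, mu=0.86),
    40: dict(size=0.85, elong=1.36, husk=1.75, mu=0.79),
    20: dict(size=0.80, elong=1.48, husk=2.00, mu=0.72),
}


def build_scene(
    n_grains: int,
    trait_mix: TraitMix,
    acquisition: AcquisitionModel,
    seed: int,
    *,
    base_semi_axes: tuple[float, float] = (14.0, 8.0),
    depth_semi_axis: float = 7.0,
    husk_thickness: float = 1.6,
    mu_husk: float = 0.012,
    mu_kernel: float = 0.085,
    pitch_factor: float = 2.4,   # covers worst-case elongation + jitter + placement
    margin_px: float = 4.0,
    jitter: float = 0.04,
) -> PhantomScene:
    """Lay out ``n_grains`` on a fixed grid and assign trait labels.

    Deterministic given ``seed``.  Raises ``ValueError`` when the detector
    grid cannot hold the requested number of grains.
    """
    rng = np.random.default_rng(seed)
    a0, b0 = base_semi_axes
    pitch = pitch_factor * max(a0, b0)
    det_rows, det_cols = acquisition.detector_shape
    n_rows = int((det_rows - 2 * margin_px) // pitch)
    n_cols = int((det_cols - 2 * margin_px) // pitch)
    capacity = n_rows * n_cols
    if n_grains > capacity:
        raise ValueError(
            f"requested {n_grains} grains but grid capacity is {capacity} "
            f"({n_rows} x {n_cols} at pitch {pitch:.1f} px)"
        )

    n_chaffy = _largest_remainder_counts(n_grains, [trait_mix.chaffy, 1 - trait_mix.chaffy])[0]
    n_filled = n_grains - n_chaffy
    n_chalky = _largest_remainder_counts(n_filled, [trait_mix.chalky, 1 - trait_mix.chalky])[0]
    hrr_classes = sorted(trait_mix.hrr)
    hrr_counts = _largest_remainder_counts(n_filled, [trait_mix.hrr[c] for c in hrr_classes])

    # labels in deterministic order, then shuffled onto grid positions
    chaffy_flags = [True] * n_chaffy + [False] * n_filled
    chalk_fracs = [0.0] * n_chaffy
    hrr_labels: list[Optional[int]] = [None] * n_chaffy
    per_class = [c for c, k in zip(hrr_classes, hrr_counts) for _ in range(k)]
    per_class = [per_class[i] for i in rng.permutation(n_filled)]  # decouple from chalk
    for i in range(n_filled):
        chalk_fracs.append(float(rng.uniform(0.35, 0.65)) if i < n_chalky else 0.0)
        hrr_labels.append(per_class[i])
    order = rng.permutation(n_grains)

    grains = []
    for slot, src in enumerate(order):
        gr, gc = divmod(slot, n_cols)
        hrr = hrr_labels[src]
        geo = _HRR_GEOMETRY[hrr] if hrr is not None else _HRR_GEOMETRY[100]
        scale = geo["size"] * (1.0 + rng.uniform(-jitter, jitter))
        elong = geo["elong"] * (1.0 + rng.uniform(-jitter, jitter))
        a = a0 * scale * math.sqrt(elong)
        b = b0 * scale / math.sqrt(elong)
        grains.append(
            GrainSpec(
                id=slot + 1,
                center_px=(
                    margin_px + (gr + 0.5) * pitch + rng.uniform(-1.0, 1.0),
                    margin_px + (gc + 0.5) * pitch + rng.uniform(-1.0, 1.0),
                ),
                semi_axes_px=(a, b),
                depth_semi_axis_px=depth_semi_axis * scale,
                orientation_rad=float(rng.uniform(0, math.pi)),
                husk_thickness_px=min(husk_thickness * geo["husk"], 0.45 * min(a, b)),
                mu_husk=mu_husk,
                mu_kernel=mu_kernel * geo["mu"] * (1.0 + rng.uniform(-jitter, jitter)),
                chaffy=chaffy_flags[src],
                chalk_fraction=chalk_fracs[src],
                hrr_class=hrr,
                chalk_center_frac=(float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1))),
            )
        )
    return PhantomScene(tuple(grains), acquisition, (n_rows, n_cols, pitch))


def dehusked(scene: PhantomScene) -> PhantomScene:
    """Return the scene with every husk made X-ray transparent.

    Emulates imaging manually de-husked kernels in the same holder
    positions; the kernel geometry is unchanged.
    """
    return replace(
        scene,
        grains=tuple(replace(g, mu_husk=0.0) for g in scene.grains),
    )


# ---------------------------------------------------------------------------
# forward projection
# ---------------------------------------------------------------------------

def _grain_frame(spec: GrainSpec, rows: np.ndarray, cols: np.ndarray):
    """Rotate pixel coordinates into the grain's principal frame."""
    r0, c0 = spec.center_px
    phi = spec.orientation_rad
    dr, dc = rows - r0, cols - c0
    x = math.cos(phi) * dc + math.sin(phi) * dr
    y = -math.sin(phi) * dc + math.cos(phi) * dr
    return x, y


def _ellipsoid_thickness(x, y, a: float, b: float, c: float):
    """Through-thickness 2c*sqrt(1 - x^2/a^2 - y^2/b^2), zero outside."""
    s = 1.0 - (x / a) ** 2 - (y / b) ** 2
    return 2.0 * c * np.sqrt(np.maximum(s, 0.0))


def _thickness_maps(spec: GrainSpec, rows: np.ndarray, cols: np.ndarray):
    """(t_husk, t_kernel, chalk_mask) for pixel arrays, vectorized."""
    x, y = _grain_frame(spec, rows, cols)
    a, b = spec.semi_axes_px
    c = spec.depth_semi_axis_px
    h = spec.husk_thickness_px
    t_outer = _ellipsoid_thickness(x, y, a, b, c)
    ai, bi, ci = a - h, b - h, c - h
    if min(ai, bi, ci) > 0:
        t_inner = _ellipsoid_thickness(x, y, ai, bi, ci)
    else:
        t_inner = np.zeros_like(t_outer)
    t_husk = t_outer - t_inner
    t_kernel = np.zeros_like(t_inner) if spec.chaffy else t_inner

    chalk = np.zeros(np.shape(x), dtype=bool)
    if spec.chalk_fraction > 0 and not spec.chaffy and min(ai, bi) > 0:
        # sub-ellipse of the kernel footprint with matching area fraction
        f = math.sqrt(spec.chalk_fraction)
        ux, uy = spec.chalk_center_frac
        cx, cy = ux * (1 - f) * ai, uy * (1 - f) * bi
        chalk = ((x - cx) / (f * ai)) ** 2 + ((y - cy) / (f * bi)) ** 2 <= 1.0
        chalk &= t_inner > 0
    return t_husk, t_kernel, chalk


def projected_thickness(spec: GrainSpec, pixel: tuple[float, float]) -> tuple[float, float]:
    """Husk and kernel through-thickness at one pixel, in pixel lengths."""
    r, c = pixel
    t_h, t_k, _ = _thickness_maps(spec, np.float64(r), np.float64(c))
    return float(t_h), float(t_k)


def grains_attenuation(
    grains: Sequence[GrainSpec], shape: tuple[int, int]
) -> np.ndarray:
    """Summed attenuation line integrals of arbitrary grains (no layout checks)."""
    det_rows, det_cols = shape
    att = np.zeros((det_rows, det_cols), dtype=np.float64)
    for g in grains:
        r0, c0 = g.center_px
        rad = g.outer_radius_px + 1.0
        r_lo, r_hi = max(0, int(r0 - rad)), min(det_rows, int(r0 + rad) + 2)
        c_lo, c_hi = max(0, int(c0 - rad)), min(det_cols, int(c0 + rad) + 2)
        rr, cc = np.meshgrid(
            np.arange(r_lo, r_hi, dtype=np.float64),
            np.arange(c_lo, c_hi, dtype=np.float64),
            indexing="ij",
        )
        t_husk, t_kernel, chalk = _thickness_maps(g, rr, cc)
        mu_eff = np.where(chalk, g.mu_kernel * g.chalk_factor, g.mu_kernel)
        att[r_lo:r_hi, c_lo:c_hi] += g.mu_husk * t_husk + mu_eff * t_kernel
    return att


def attenuation_map(scene: PhantomScene) -> np.ndarray:
    """Noise-free summed attenuation line integrals over the detector."""
    return grains_attenuation(scene.grains, scene.acquisition.detector_shape)


def render_radiograph(scene: PhantomScene) -> np.ndarray:
    """Render detector counts as uint16; deterministic given rng_seed."""
    acq = scene.acquisition
    counts = acq.background_intensity_I0 * np.exp(-attenuation_map(scene))
    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.rng_seed)
        counts = counts + rng.normal(0.0, acq.noise_sd, counts.shape)
    counts = np.clip(np.round(counts), 0, acq.max_count)
    return counts.astype(np.uint16)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ("id", "center_row", "center_col", "chaffy", "chalky", "hrr_class")


def write_truth_table(scene: PhantomScene, path) -> None:
    """Write per-grain ground truth as an RFC-4180 CSV with header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRUTH_COLUMNS)
        for g in scene.grains:
            writer.writerow(
                [
                    g.id,
                    f"{g.center_px[0]:.3f}",
                    f"{g.center_px[1]:.3f}",
                    str(g.chaffy).lower(),
                    str(g.is_chalky).lower(),
                    "" if g.hrr_class is None else g.hrr_class,
                ]
            )
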