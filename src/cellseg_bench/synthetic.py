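"""Seeded generators for cell-like scenes, degraded predictions and count series.

These emulate dense 2D-culture phase-contrast scenes: tens to thousands of
instances per image, lognormal-like pixel-area distributions, blobby outlines
(an ellipse radius modulated by low-order random harmonics, orders 2-6, which
keeps the polygon simple), and a controllable permitted overlap fraction.  The
count-series generator produces logistic growth curves whose model-based counts
track the fluorescence-based counts linearly up to a configurable breakpoint
and saturate beyond it.  Every generator is a pure function of its config and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    AnnotationSet,
    CountSeries,
    ImageRecord,
    InstanceMask,
    PredictionSet,
)
from .detection import mask_iou


@dataclass
class SceneConfig:
    seed: int = 0
    n_images: int = 10
    width_px: int = 256
    height_px: int = 256
    instances_per_image: int | list[int] = 30
    median_area_px: float = 250.0   # lognormal median of instance pixel area
    area_sigma: float = 0.5         # lognormal sigma in log px^2
    aspect_max: float = 2.5
    harmonic_amp: float = 0.15      # boundary perturbation, fraction of radius
    max_overlap: float = 0.25       # permitted fraction of an instance's area
    n_vertices: int = 28
    render: bool = False
    pixel_size_um: float | None = None
    cell_types: list[str] | None = None  # cycled over images when given


@dataclass
class DegradationConfig:
    seed: int = 0
    false_negative_rate: float = 0.0
    false_positive_rate: float = 0.0
    target_iou: float = 1.0         # mean prediction-vs-GT IoU for survivors
    score_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("false_negative_rate", "false_positive_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.target_iou <= 1.0):
            raise ValueError("target_iou must be in (0, 1]")


# ---------------------------------------------------------------------------
# blob geometry
# ---------------------------------------------------------------------------

def _blob_polygon(rng: np.random.Generator, cfg: SceneConfig, cx: float, cy: float) -> np.ndarray:
    """One simple blob polygon (n_vertices x 2) centered near (cx, cy)."""
    area = cfg.median_area_px * np.exp(rng.normal(0.0, cfg.area_sigma))
    q = rng.uniform(1.0, cfg.aspect_max)
    a = np.sqrt(area * q / np.pi)
    b = np.sqrt(area / (q * np.pi))
    phi = rng.uniform(0, 2 * np.pi)
    theta = np.linspace(0, 2 * np.pi, cfg.n_vertices, endpoint=False)
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    mod = np.ones_like(theta)
    for h in range(2, 7):
        mod += (cfg.harmonic_amp * rng.uniform(0, 1) / (h - 1)) * np.cos(
            h * theta + rng.uniform(0, 2 * np.pi)
        )
    r = r_ell * np.clip(mod, 0.3, None)
    x = cx + r * np.cos(theta + phi)
    y = cy + r * np.sin(theta + phi)
    return np.column_stack([x, y])


def generate_scenes(cfg: SceneConfig) -> tuple[AnnotationSet, dict[str, np.ndarray]]:
    """Deterministic scene set; returns the annotations and (when rendering)
    grayscale float images keyed by image_id.

    Raises RuntimeError when the requested density cannot be packed under the
    overlap limit within a bounded number of placement attempts.
    """
    rng = np.random.default_rng(cfg.seed)
    counts = (
        cfg.instances_per_image
        if isinstance(cfg.instances_per_image, list)
        else [cfg.instances_per_image] * cfg.n_images
    )
    if len(counts) != cfg.n_images:
        raise ValueError("instances_per_image schedule length != n_images")
    aset = AnnotationSet()
    renders: dict[str, np.ndarray] = {}
    w, h = cfg.width_px, cfg.height_px
    for idx, n_inst in enumerate(counts):
        image_id = f"scene{idx:04d}"
        cell_type = cfg.cell_types[idx % len(cfg.cell_types)] if cfg.cell_types else None
        rec = ImageRecord(image_id, w, h, pixel_size_um=cfg.pixel_size_um, cell_type=cell_type)
        aset.images[rec.image_id] = rec
        aset.instances[rec.image_id] = []
        occupied = np.zeros((h, w), dtype=bool)
        budget = max(200, 60 * n_inst)
        placed = 0
        while placed < n_inst:
            if budget <= 0:
                raise RuntimeError(
                    f"infeasible packing: {placed}/{n_inst} instances placed in "
                    f"{image_id} under max_overlap={cfg.max_overlap}"
                )
            budget -= 1
            # sample the outline first, then place it fully inside the frame so
            # border clipping does not bias the realized area distribution
            shape = _blob_polygon(rng, cfg, 0.0, 0.0)
            x_lo, y_lo = shape.min(axis=0)
            x_hi, y_hi = shape.max(axis=0)
            if x_hi - x_lo >= w or y_hi - y_lo >= h:
                continue  # blob larger than the frame: resample
            cx = rng.uniform(-x_lo, w - x_hi)
            cy = rng.uniform(-y_lo, h - y_hi)
            poly = shape + [cx, cy]
            inst = InstanceMask(image_id, polygons=[poly.reshape(-1)])
            m = inst.rasterize(w, h)
            area = m.sum()
            if area < 3:
                continue
            overlap = np.logical_and(m, occupied).sum() / area
            if overlap > cfg.max_overlap:
                continue
            occupied |= m
            aset.instances[image_id].append(inst)
            placed += 1
        if cfg.render:
            renders[image_id] = _render(rng, aset.instances[image_id], w, h)
    return aset, renders


def _render(rng: np.random.Generator, insts: list[InstanceMask], w: int, h: int) -> np.ndarray:
    """Flat-background grayscale render with per-cell base intensity + noise."""
    img = 0.35 + 0.02 * rng.standard_normal((h, w))
    for inst in insts:
        m = inst.rasterize(w, h)
        base = rng.uniform(0.55, 0.9)
        img[m] = base + 0.03 * rng.standard_normal(int(m.sum()))
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# prediction degradation
# ---------------------------------------------------------------------------

def _perturb_to_iou(
    rng: np.random.Generator,
    inst: InstanceMask,
    rec: ImageRecord,
    target: float,
) -> tuple[InstanceMask, float]:
    """Translate + jitter the mask, bisecting the magnitude until the realized
    IoU against the original lands near ``target``."""
    poly = np.vstack(inst.polygons)
    centroid = poly.mean(axis=0)
    r_eq = np.sqrt(
        inst.area_px(rec.width_px, rec.height_px) / np.pi
    )
    direction = rng.uniform(0, 2 * np.pi)
    jitter = rng.standard_normal(poly.shape)

    def candidate(s: float) -> InstanceMask:
        shift = s * r_eq * np.array([np.cos(direction), np.sin(direction)])
        p = poly + shift + 0.3 * s * r_eq * jitter
        return InstanceMask(inst.image_id, polygons=[p.reshape(-1)])

    lo, hi = 0.0, 2.0
    best, best_iou = inst, 1.0
    for _ in range(8):
        mid = 0.5 * (lo + hi)
        cand = candidate(mid)
        if cand.area_px(rec.width_px, rec.height_px) == 0:
            hi = mid
            continue
        iou = mask_iou(inst, cand, rec)
        best, best_iou = cand, iou
        if iou > target:
            lo = mid
        else:
            hi = mid
        if abs(iou - target) < 0.01:
            break
    return best, best_iou


def degrade(gt: AnnotationSet, cfg: DegradationConfig) -> PredictionSet:
    """Drop, perturb and pollute ground truth into a scored PredictionSet."""
    rng = np.random.default_rng(cfg.seed)
    pset = PredictionSet(images=dict(gt.images))
    all_areas = []
    for image_id, rec in gt.images.items():
        for inst in gt.instances.get(image_id, []):
            all_areas.append(inst.area_px(rec.width_px, rec.height_px))
    for image_id, rec in gt.images.items():
        w, h = rec.width_px, rec.height_px
        gts = gt.instances.get(image_id, [])
        for inst in gts:
            if rng.uniform() < cfg.false_negative_rate:
                continue
            if cfg.target_iou >= 0.999:
                pred = InstanceMask(
                    image_id,
                    polygons=[p.reshape(-1).copy() for p in inst.polygons]
                    if inst.polygons is not None
                    else None,
                    rle=inst.rle,
                )
                realized = 1.0
            else:
                pred, realized = _perturb_to_iou(rng, inst, rec, cfg.target_iou)
            pred.score = float(
                np.clip(realized + rng.normal(0.0, cfg.score_noise_sd), 0.0, 1.0)
            )
            pset.instances[image_id].append(pred)
        n_fp = rng.binomial(len(gts), cfg.false_positive_rate) if gts else 0
        for _ in range(n_fp):
            area = float(rng.choice(all_areas)) if all_areas else 100.0
            r_eq = max(2.0, np.sqrt(area / np.pi))
            cx = rng.uniform(r_eq, max(r_eq + 1, w - r_eq))
            cy = rng.uniform(r_eq, max(r_eq + 1, h - r_eq))
            scfg = SceneConfig(median_area_px=area, area_sigma=0.0)
            poly = _blob_polygon(rng, scfg, cx, cy)
            fp = InstanceMask(image_id, polygons=[poly.reshape(-1)])
            if fp.area_px(w, h) == 0:
                continue
            best_iou = 0.0
            for g in gts:
                try:
                    best_iou = max(best_iou, mask_iou(g, fp, rec))
                except ValueError:
                    continue
            fp.score = float(
                np.clip(best_iou + abs(rng.normal(0.0, cfg.score_noise_sd)), 0.0, 1.0)
            )
            pset.instances[image_id].append(fp)
    return pset


# ---------------------------------------------------------------------------
# count series
# ---------------------------------------------------------------------------

def generate_counts(
    n_images: int = 400,
    breakpoint_count: float = 1500.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    n_densities: int = 4,
    capacity_range: tuple[float, float] = (2400.0, 3200.0),
    t_max_hours: float = 96.0,
    saturation_slope: float = 0.2,
) -> CountSeries:
    """Logistic fluorescence-count growth with a model-count linearity break.

    Below the breakpoint the model count equals the fluorescence count plus
    Gaussian noise; beyond it the model saturates to
    ``breakpoint + saturation_slope * (y - breakpoint)`` plus the same noise.
    A breakpoint above every generated count yields a fully linear series.
    """
    rng = np.random.default_rng(seed)
    per = n_images // n_densities
    counts_left = n_images - per * n_densities
    rows = []
    i = 0
    for d in range(n_densities):
        n_d = per + (1 if d < counts_left else 0)
        k_cap = rng.uniform(*capacity_range)
        # seeding densities shift the growth curve in time, so the pooled
        # series covers the count range fairly evenly
        stagger = 0.3 + 0.45 * d / max(1, n_densities - 1)
        t0 = (stagger + rng.uniform(-0.03, 0.03)) * t_max_hours
        tau = rng.uniform(0.10, 0.14) * t_max_hours
        times = np.linspace(0.0, t_max_hours, n_d)
        y_f = k_cap / (1.0 + np.exp(-(times - t0) / tau))
        y_f = np.maximum(np.round(y_f), 1).astype(int)
        lin = y_f + rng.normal(0.0, noise_sd, n_d)
        sat = breakpoint_count + saturation_slope * (y_f - breakpoint_count) + rng.normal(
            0.0, noise_sd, n_d
        )
        y_m = np.where(y_f <= breakpoint_count, lin, sat)
        y_m = np.maximum(np.round(y_m), 0).astype(int)
        for t, f, m in zip(times, y_f, y_m):
            rows.append(
                {
                    "image_id": f"img{i:04d}",
                    "time_hours": round(float(t), 3),
                    "density": f"D{d + 1}",
                    "fluorescence_count": int(f),
                    "model_count": int(m),
                }
            )
            i += 1
    return CountSeries(pd.DataFrame(rows))
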