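"""Per-cell morphology metrics, image-wise averaging and two-component PCA.

The 17 metrics per cell cover size (area, perimeter, Feret's diameter),
phase-contrast intensity (mean, min, max, 5th and 95th percentiles), intensity
distribution (skewness, kurtosis, normalized weighted centroid NWC), texture
(standard deviation of intensity) and shape (eccentricity, roundness,
circularity, solidity, aspect ratio).  Formulas the field leaves to convention:

* perimeter: Crofton 4-direction estimator (unbiased for smooth outlines,
  unlike the chain-code length which overestimates digital disks by ~4%),
* circularity = 4*pi*A / P^2,
* roundness   = 4*A / (pi * major_axis^2),
* AR          = major / minor axis of the second-moment ellipse,
* solidity    = A / convex-hull area,
* Feret's diameter = maximum caliper distance,
* NWC = distance between the intensity-weighted and geometric centroids,
  normalized by Feret's diameter (see :func:`normalized_weighted_centroid`).

Image-wise metric means are standard-scaled (mean 0, unit variance) before a
two-component PCA whose scores and loadings profile dataset diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .datamodel import AnnotationSet, ImageRecord, InstanceMask

METRIC_NAMES: tuple[str, ...] = (
    "area",
    "perimeter",
    "feret_diameter",
    "mean_intensity",
    "min_intensity",
    "max_intensity",
    "p5_intensity",
    "p95_intensity",
    "skewness",
    "kurtosis",
    "nwc",
    "std_intensity",
    "eccentricity",
    "roundness",
    "circularity",
    "solidity",
    "aspect_ratio",
)


class DegenerateShapeError(ValueError):
    """Mask too small or thin for shape fitting."""


def normalized_weighted_centroid(
    centroid: np.ndarray, weighted_centroid: np.ndarray, feret_diameter: float
) -> float:
    """Euclidean centroid displacement normalized by Feret's diameter.

    The sole place the NWC normalization choice lives: swap here to change it.
    """
    return float(np.linalg.norm(weighted_centroid - centroid) / feret_diameter)


def cell_metrics(
    mask: InstanceMask,
    image: np.ndarray,
    record: ImageRecord,
    pixel_size_um: float | None = None,
) -> dict[str, float]:
    """All 17 morphology metrics for one cell.

    ``image`` is a grayscale array matching the record's dimensions; intensity
    metrics use masked pixels only.  Lengths scale by ``pixel_size_um`` (areas
    by its square) when given, else stay in pixels.
    """
    w, h = record.width_px, record.height_px
    if image.shape != (h, w):
        raise ValueError(f"image shape {image.shape} != record {h}x{w}")
    m = mask.rasterize(w, h)
    if m.sum() < 3:
        raise DegenerateShapeError("mask has fewer than 3 pixels")
    props = regionprops(m.astype(np.uint8), intensity_image=image.astype(float))[0]
    if props.axis_minor_length == 0:
        raise DegenerateShapeError("degenerate (zero minor axis) mask")
    s = pixel_size_um if pixel_size_um is not None else (record.pixel_size_um or 1.0)
    vals = image[m].astype(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite intensities under the mask")
    area_px = float(props.area)
    perim_px = float(props.perimeter_crofton)
    feret_px = float(props.feret_diameter_max)
    if vals.min() < 0:
        raise ValueError("negative intensities: weighted centroid undefined")
    if vals.sum() > 0:
        wc = np.asarray(props.centroid_weighted)
    else:
        wc = np.asarray(props.centroid)  # all-zero intensity: no displacement
    # constant intensity: higher moments degenerate, reported as 0 by convention
    if vals.std() == 0:
        skew_val = kurt_val = 0.0
    else:
        skew_val = float(stats.skew(vals))
        kurt_val = float(stats.kurtosis(vals))
    return {
        "area": area_px * s * s,
        "perimeter": perim_px * s,
        "feret_diameter": feret_px * s,
        "mean_intensity": float(vals.mean()),
        "min_intensity": float(vals.min()),
        "max_intensity": float(vals.max()),
        "p5_intensity": float(np.percentile(vals, 5)),
        "p95_intensity": float(np.percentile(vals, 95)),
        "skewness": skew_val,
        "kurtosis": kurt_val,
        "nwc": normalized_weighted_centroid(
            np.asarray(props.centroid), wc, feret_px
        ),
        "std_intensity": float(vals.std()),
        "eccentricity": float(props.eccentricity),
        "roundness": 4.0 * area_px / (np.pi * props.axis_major_length**2),
        "circularity": 4.0 * np.pi * area_px / perim_px**2,
        "solidity": float(props.solidity),
        "aspect_ratio": float(props.axis_major_length / props.axis_minor_length),
    }


def dataset_metrics(
    gt: AnnotationSet,
    images: dict[int | str, np.ndarray],
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """One metric row per cell over every annotated image with pixel data."""
    rows = []
    for image_id, rec in gt.images.items():
        if image_id not in images:
            continue
        for inst in gt.instances.get(image_id, []):
            row = cell_metrics(inst, images[image_id], rec, pixel_size_um)
            row["image_id"] = image_id
            rows.append(row)
    return pd.DataFrame(rows, columns=["image_id", *METRIC_NAMES])


def imagewise_average(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic per-image mean of each metric (cell count in ``n_cells``).

    Images with zero cells are absent from the per-cell table and therefore
    excluded here by construction.
    """
    if cell_table.empty:
        raise ValueError("no cells to average")
    grouped = cell_table.groupby("image_id", sort=False)
    out = grouped[list(METRIC_NAMES)].mean()
    out["n_cells"] = grouped.size()
    return out


@dataclass
class PCAModel:
    """Standard-scaling parameters plus two-component scores and loadings."""

    means: pd.Series
    scales: pd.Series
    loadings: pd.DataFrame           # (2, n_metrics)
    scores: pd.DataFrame             # (n_images, 2), columns PC1/PC2
    explained_variance: np.ndarray   # variances of the two components
    explained_variance_ratio: np.ndarray
    log_transformed: tuple[str, ...] = ()

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.means.index
        x = table[cols].to_numpy(dtype=float)
        if self.log_transformed:
            x = x.copy()
            for name in self.log_transformed:
                j = list(cols).index(name)
                x[:, j] = np.log(x[:, j])
        z = (x - self.means.to_numpy()) / self.scales.to_numpy()
        s = z @ self.loadings.to_numpy().T
        return pd.DataFrame(s, index=table.index, columns=["PC1", "PC2"])


def fit_pca(
    table: pd.DataFrame, log_transform: tuple[str, ...] = ()
) -> PCAModel:
    """Two-component PCA of the standard-scaled per-image metric table.

    ``log_transform`` optionally lists right-skewed (size) metrics to log
    before scaling; the default applies no transformation.  Component signs
    are fixed so each loading vector's largest-magnitude element is positive.
    """
    cols = [c for c in table.columns if c in METRIC_NAMES]
    if len(table) < 3:
        raise ValueError("PCA requires at least 3 images")
    x = table[cols].to_numpy(dtype=float).copy()
    for name in log_transform:
        j = cols.index(name)
        if np.any(x[:, j] <= 0):
            raise ValueError(f"log transform of non-positive values in {name!r}")
        x[:, j] = np.log(x[:, j])
    stds = x.std(axis=0)
    constant = [c for c, sd in zip(cols, stds) if sd == 0]
    if constant:
        raise ValueError(f"constant metric column(s): {', '.join(constant)}")
    scaler = StandardScaler()
    z = scaler.fit_transform(x)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(z)
    loadings = pca.components_
    for i in range(2):  # sign convention for reproducible plots
        jmax = np.argmax(np.abs(loadings[i]))
        if loadings[i, jmax] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAModel(
        means=pd.Series(scaler.mean_, index=cols),
        scales=pd.Series(scaler.scale_, index=cols),
        loadings=pd.DataFrame(loadings, index=["PC1", "PC2"], columns=cols),
        scores=pd.DataFrame(scores, index=table.index, columns=["PC1", "PC2"]),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        log_transformed=tuple(log_transform),
    )
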