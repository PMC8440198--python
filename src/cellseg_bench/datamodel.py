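"""Core data types and I/O for instance annotations, predictions and count tables.

Masks are stored as COCO-style polygons (flat ``[x1, y1, x2, y2, ...]`` vertex
lists in pixel coordinates, origin top-left) or as run-length encodings over the
column-major flattened image grid.  Rasterization uses an even-odd scanline fill
sampled at pixel centers on the half-open grid ``[0, W) x [0, H)`` with polygon
vertices interpreted as pixel-corner coordinates, so a unit square from (0, 0)
to (1, 1) covers exactly pixel (row 0, col 0).  Both the uncompressed
(list-of-ints) and compressed (LEB128-style string) RLE dialects are supported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Default microns-per-pixel for Incucyte-style phase-contrast images
# (704 px spanning 0.875 mm).  Overridable per dataset.
DEFAULT_PIXEL_SIZE_UM = 0.875e3 / 704.0


class ValidationError(ValueError):
    """Input fails a structural or referential-integrity check."""


class SchemaError(ValueError):
    """A delimited table is missing required columns or is unreadable."""


# ---------------------------------------------------------------------------
# rasterization and RLE primitives
# ---------------------------------------------------------------------------

def rasterize_polygon(xs: np.ndarray, ys: np.ndarray, width: int, height: int) -> np.ndarray:
    """Even-odd scanline fill of one simple (possibly self-intersecting) polygon.

    A pixel (r, c) is inside when its center (c + 0.5, r + 0.5) is inside the
    polygon under the even-odd rule.  Returns a boolean (height, width) array.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3:
        return np.zeros((height, width), dtype=bool)
    mask = np.zeros((height, width), dtype=bool)
    x1, y1 = xs, ys
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    r_lo = max(0, int(np.floor(ys.min() - 0.5)))
    r_hi = min(height - 1, int(np.ceil(ys.max())))
    for r in range(r_lo, r_hi + 1):
        yc = r + 0.5
        # edges straddling the scanline (half-open in y avoids double counting)
        crosses = ((y1 <= yc) & (y2 > yc)) | ((y2 <= yc) & (y1 > yc))
        if not crosses.any():
            continue
        xa, ya = x1[crosses], y1[crosses]
        xb, yb = x2[crosses], y2[crosses]
        xc = np.sort(xa + (yc - ya) * (xb - xa) / (yb - ya))
        for xl, xr in zip(xc[0::2], xc[1::2]):
            c_lo = max(0, int(np.ceil(xl - 0.5)))
            c_hi = min(width, int(np.ceil(xr - 0.5)))
            if c_hi > c_lo:
                mask[r, c_lo:c_hi] = True
    return mask


def rle_encode(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed column-major RLE.

    Counts alternate background/foreground runs starting with background, over
    the Fortran-order flattened grid; ``size`` is ``[height, width]``.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.flatten(order="F")
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:  # runs must start with a (possibly empty) background run
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def rle_decode(rle: Mapping) -> np.ndarray:
    """Decode uncompressed or compressed RLE to a boolean (height, width) mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    if isinstance(counts, (bytes, str)):
        counts = rle_string_to_counts(counts)
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() != h * w:
        raise ValidationError(
            f"RLE counts sum to {counts.sum()}, expected {h * w} for size {h}x{w}"
        )
    vals = np.zeros(len(counts), dtype=bool)
    vals[1::2] = True
    flat = np.repeat(vals, counts)
    return flat.reshape((h, w), order="F")


def counts_to_rle_string(counts: Sequence[int]) -> str:
    """Compress RLE counts with the COCO-style LEB128 variant (6-bit chunks,
    printable offset 48, runs after the second delta-coded)."""
    out = []
    counts = list(counts)
    for i, x in enumerate(counts):
        if i > 2:  # canonical COCO string coding delta-codes from the 4th run on
            x -= counts[i - 2]
        more = True
        while more:
            c = x & 0x1F
            x >>= 5
            more = (x != -1) if (c & 0x10) else (x != 0)
            if more:
                c |= 0x20
            out.append(chr(c + 48))
    return "".join(out)


def rle_string_to_counts(s: bytes | str) -> list[int]:
    """Inverse of :func:`counts_to_rle_string`."""
    if isinstance(s, bytes):
        s = s.decode("ascii")
    counts: list[int] = []
    i = 0
    while i < len(s):
        x = 0
        k = 0
        more = True
        while more:
            c = ord(s[i]) - 48
            x |= (c & 0x1F) << (5 * k)
            more = bool(c & 0x20)
            if not more and (c & 0x10):
                x |= -1 << (5 * (k + 1))  # sign-extend
            i += 1
            k += 1
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageRecord:
    """One image: identity, geometry and optional grouping labels."""

    image_id: int | str
    width_px: int
    height_px: int
    pixel_size_um: float | None = None
    cell_type: str | None = None
    well: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError(
                f"image {self.image_id}: non-positive dimensions "
                f"{self.width_px}x{self.height_px}"
            )
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValidationError(f"image {self.image_id}: pixel_size_um must be > 0")


class InstanceMask:
    """One instance mask: polygons (union of parts) or an RLE, plus an optional
    prediction score.  Rasterization is lazy and cached."""

    __slots__ = ("image_id", "polygons", "rle", "score", "_raster", "_bbox")

    def __init__(
        self,
        image_id: int | str,
        polygons: Sequence[Sequence[float]] | None = None,
        rle: Mapping | None = None,
        score: float | None = None,
    ) -> None:
        if (polygons is None) == (rle is None):
            raise ValidationError("exactly one of polygons / rle must be given")
        if score is not None and not (0.0 <= score <= 1.0):
            raise ValidationError(f"score {score} outside [0, 1]")
        self.image_id = image_id
        self.polygons = (
            None
            if polygons is None
            else [np.asarray(p, dtype=float).reshape(-1, 2) for p in polygons]
        )
        self.rle = dict(rle) if rle is not None else None
        self.score = score
        self._raster: np.ndarray | None = None
        self._bbox: tuple[int, int, int, int] | None = None

    def rasterize(self, width: int, height: int) -> np.ndarray:
        """Boolean (height, width) mask, clipped to image bounds."""
        if self._raster is not None and self._raster.shape == (height, width):
            return self._raster
        if self.rle is not None:
            m = rle_decode(self.rle)
            if m.shape != (height, width):
                raise ValidationError(
                    f"RLE size {m.shape} does not match image {height}x{width}"
                )
        else:
            m = np.zeros((height, width), dtype=bool)
            for poly in self.polygons:
                m |= rasterize_polygon(poly[:, 0], poly[:, 1], width, height)
        self._raster = m
        return m

    def area_px(self, width: int, height: int) -> int:
        return int(self.rasterize(width, height).sum())

    def bbox(self, width: int, height: int) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open bounds of the rasterized mask."""
        if self._bbox is None:
            m = self.rasterize(width, height)
            rows = np.flatnonzero(m.any(axis=1))
            cols = np.flatnonzero(m.any(axis=0))
            if rows.size == 0:
                self._bbox = (0, 0, 0, 0)
            else:
                self._bbox = (rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)
        return self._bbox


@dataclass
class AnnotationSet:
    """Ground-truth instances grouped by image (insertion order preserved)."""

    images: dict[int | str, ImageRecord] = field(default_factory=dict)
    instances: dict[int | str, list[InstanceMask]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for image_id in self.instances:
            if image_id not in self.images:
                raise ValidationError(f"instances reference unknown image {image_id!r}")
        for image_id in self.images:
            self.instances.setdefault(image_id, [])

    def add(self, inst: InstanceMask) -> None:
        if inst.image_id not in self.images:
            raise ValidationError(f"instance references unknown image {inst.image_id!r}")
        self.instances.setdefault(inst.image_id, []).append(inst)

    @property
    def n_instances(self) -> int:
        return sum(len(v) for v in self.instances.values())

    def all_instances(self) -> Iterable[InstanceMask]:
        for image_id in self.images:
            yield from self.instances.get(image_id, [])


class PredictionSet(AnnotationSet):
    """Scored predicted instances; every instance must carry a score."""

    def add(self, inst: InstanceMask) -> None:
        if inst.score is None:
            raise ValidationError("prediction instance missing score")
        super().add(inst)


@dataclass
class CountSeries:
    """Paired fluorescence-based and model-based per-image object counts."""

    table: pd.DataFrame

    REQUIRED = ("image_id", "time_hours", "density", "fluorescence_count", "model_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"count table missing column(s): {', '.join(missing)}")
        t = self.table
        for col in ("fluorescence_count", "model_count"):
            vals = pd.to_numeric(t[col], errors="coerce")
            if vals.isna().any():
                raise ValidationError(f"non-numeric values in {col}")
            if (vals < 0).any():
                raise ValidationError(f"negative counts in {col}")
            rounded = vals.round()
            if not np.allclose(vals, rounded):
                raise ValidationError(f"non-integer counts in {col}")
            t[col] = rounded.astype(int)
        if t["image_id"].duplicated().any():
            dupes = t.loc[t["image_id"].duplicated(), "image_id"].tolist()
            raise ValidationError(f"duplicate image_id(s): {dupes[:5]}")

    @property
    def y_fluorescence(self) -> np.ndarray:
        return self.table["fluorescence_count"].to_numpy()

    @property
    def y_model(self) -> np.ndarray:
        return self.table["model_count"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_images(blob: Mapping, pixel_size_um: float | None) -> dict:
    images: dict = {}
    for im in blob.get("images", []):
        for key in ("id", "width", "height"):
            if key not in im:
                raise ValidationError(f"images entry missing key {key!r}")
        rec = ImageRecord(
            image_id=im["id"],
            width_px=im["width"],
            height_px=im["height"],
            pixel_size_um=im.get("pixel_size_um", pixel_size_um),
            cell_type=im.get("cell_type"),
            well=im.get("well"),
            timestamp=im.get("timestamp"),
        )
        images[rec.image_id] = rec
    return images


def _segmentation_to_mask(image_id, seg, score=None) -> InstanceMask:
    if isinstance(seg, Mapping):
        return InstanceMask(image_id, rle=seg, score=score)
    if isinstance(seg, Sequence) and seg and isinstance(seg[0], (list, tuple)):
        return InstanceMask(image_id, polygons=seg, score=score)
    raise ValidationError(f"unrecognized segmentation for image {image_id!r}")


def read_ground_truth(path, pixel_size_um: float | None = None) -> AnnotationSet:
    """Read COCO-format instance annotations (images/annotations/categories)."""
    try:
        with open(path) as fh:
            blob = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in {path}: {exc}") from exc
    for key in ("images", "annotations"):
        if key not in blob:
            raise ValidationError(f"annotation file missing key {key!r}")
    cats = blob.get("categories", [])
    if len(cats) > 1:
        warnings.warn(
            f"{len(cats)} categories found; a single 'cell' category is expected — "
            "instances will be evaluated jointly",
            stacklevel=2,
        )
    aset = AnnotationSet(images=_parse_images(blob, pixel_size_um))
    for ann in blob["annotations"]:
        if "segmentation" not in ann:
            raise ValidationError(f"annotation {ann.get('id')} missing key 'segmentation'")
        aset.add(_segmentation_to_mask(ann["image_id"], ann["segmentation"]))
    return aset


def read_predictions(path, images: AnnotationSet | Mapping | None = None) -> PredictionSet:
    """Read COCO-results-style scored instances.

    A bare results list needs image geometry from ``images`` (an AnnotationSet
    or image_id -> ImageRecord mapping); a full dict with an images block is
    self-contained.
    """
    try:
        with open(path) as fh:
            blob = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in {path}: {exc}") from exc
    if isinstance(blob, Mapping):
        image_map = _parse_images(blob, None)
        results = blob.get("annotations", blob.get("results", []))
    else:
        if images is None:
            raise ValidationError("results list requires an images source")
        image_map = dict(images.images if isinstance(images, AnnotationSet) else images)
        results = blob
    pset = PredictionSet(images=image_map)
    for res in results:
        if "score" not in res:
            raise ValidationError(f"prediction for image {res.get('image_id')!r} missing score")
        pset.add(_segmentation_to_mask(res["image_id"], res["segmentation"], score=res["score"]))
    return pset


def _mask_to_coco(inst: InstanceMask, rec: ImageRecord) -> dict:
    if inst.polygons is not None:
        seg = [p.reshape(-1).tolist() for p in inst.polygons]
    else:
        seg = inst.rle
    return {
        "image_id": inst.image_id,
        "segmentation": seg,
        "area": inst.area_px(rec.width_px, rec.height_px),
    }


def write_annotations(aset: AnnotationSet, path) -> None:
    """Write an AnnotationSet or PredictionSet back to COCO-format JSON."""
    images = [
        {
            "id": rec.image_id,
            "width": rec.width_px,
            "height": rec.height_px,
            **({"pixel_size_um": rec.pixel_size_um} if rec.pixel_size_um else {}),
            **({"cell_type": rec.cell_type} if rec.cell_type else {}),
            **({"well": rec.well} if rec.well else {}),
            **({"timestamp": rec.timestamp} if rec.timestamp else {}),
        }
        for rec in aset.images.values()
    ]
    annotations = []
    for image_id, insts in aset.instances.items():
        rec = aset.images[image_id]
        for i, inst in enumerate(insts):
            entry = _mask_to_coco(inst, rec)
            entry["id"] = len(annotations) + 1
            entry["category_id"] = 1
            if inst.score is not None:
                entry["score"] = inst.score
            annotations.append(entry)
    blob = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "cell"}],
    }
    with open(path, "w") as fh:
        json.dump(blob, fh)


def read_count_series(path) -> CountSeries:
    """Read a per-image count table (CSV with the CountSeries columns)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"count table {path} is empty") from exc
    return CountSeries(table)


def write_count_series(series: CountSeries, path) -> None:
    series.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------

def take_every_nth(aset: AnnotationSet, n: int) -> AnnotationSet:
    """Keep images at positions 0, n, 2n, ... of the stable image ordering
    (ascending image_id, ties broken by insertion order) plus their instances.

    n in {50, 25, 20, 4, 2, 1} yields 2/4/5/25/50/100% of the image count.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    order = sorted(aset.images, key=lambda k: (_sort_key(k),))
    kept = order[::n]
    out = type(aset)(images={k: aset.images[k] for k in kept})
    for k in kept:
        for inst in aset.instances.get(k, []):
            out.instances[k].append(inst)
    return out


def _sort_key(image_id):
    # numeric ids sort numerically, strings lexically; mixed sets sort by repr class
    if isinstance(image_id, (int, float)):
        return (0, image_id, "")
    return (1, 0, str(image_id))
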