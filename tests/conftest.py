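import json

import numpy as np
import pytest

from cellseg_bench import (
    AnnotationSet,
    ImageRecord,
    InstanceMask,
    PredictionSet,
)


def square_poly(x0, y0, side):
    """Flat COCO-style vertex list for an axis-aligned square."""
    return [x0, y0, x0 + side, y0, x0 + side, y0 + side, x0, y0 + side]


def rect_poly(x0, y0, w, h):
    return [x0, y0, x0 + w, y0, x0 + w, y0 + h, x0, y0 + h]


@pytest.fixture
def coco_fixture(tmp_path):
    """Tiny ground-truth file: 2 images, 3 polygon annotations."""
    blob = {
        "images": [
            {"id": 1, "width": 64, "height": 64, "cell_type": "A"},
            {"id": 2, "width": 64, "height": 64, "cell_type": "B"},
        ],
        "annotations": [
            {"id": 1, "image_id": 1, "category_id": 1,
             "segmentation": [square_poly(5, 5, 10)], "area": 100},
            {"id": 2, "image_id": 1, "category_id": 1,
             "segmentation": [square_poly(30, 30, 8)], "area": 64},
            {"id": 3, "image_id": 2, "category_id": 1,
             "segmentation": [square_poly(10, 20, 12)], "area": 144},
        ],
        "categories": [{"id": 1, "name": "cell"}],
    }
    path = tmp_path / "gt.json"
    path.write_text(json.dumps(blob))
    return path


@pytest.fixture
def results_fixture(tmp_path):
    """COCO-results list: 5 scored predictions across 2 images."""
    results = [
        {"image_id": 1, "segmentation": [square_poly(5, 5, 10)], "score": 0.9},
        {"image_id": 1, "segmentation": [square_poly(30, 30, 8)], "score": 0.8},
        {"image_id": 1, "segmentation": [square_poly(50, 50, 6)], "score": 0.3},
        {"image_id": 2, "segmentation": [square_poly(10, 20, 12)], "score": 0.95},
        {"image_id": 2, "segmentation": [square_poly(40, 5, 7)], "score": 0.2},
    ]
    path = tmp_path / "pred.json"
    path.write_text(json.dumps(results))
    return path


def make_set(n_images=1, width=64, height=64, cell_types=None):
    aset = AnnotationSet()
    for i in range(n_images):
        ct = cell_types[i % len(cell_types)] if cell_types else None
        rec = ImageRecord(i + 1, width, height, cell_type=ct)
        aset.images[rec.image_id] = rec
        aset.instances[rec.image_id] = []
    return aset


def add_square(aset, image_id, x0, y0, side, score=None):
    inst = InstanceMask(image_id, polygons=[square_poly(x0, y0, side)], score=score)
    aset.instances[image_id].append(inst)
    return inst


def perfect_predictions(gt: AnnotationSet) -> PredictionSet:
    """Copy every ground-truth mask as a score-1 prediction."""
    pset = PredictionSet(images=dict(gt.images))
    for image_id, insts in gt.instances.items():
        for inst in insts:
            pset.instances[image_id].append(
                InstanceMask(
                    image_id,
                    polygons=[p.reshape(-1).copy() for p in inst.polygons]
                    if inst.polygons is not None
                    else None,
                    rle=inst.rle if inst.polygons is None else None,
                    score=1.0,
                )
            )
    return pset


def random_bool_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    m = rng.uniform(size=(h, w)) < rng.uniform(0.05, 0.6)
    return m
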