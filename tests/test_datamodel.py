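import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellseg_bench import (
    AnnotationSet,
    ImageRecord,
    InstanceMask,
    SchemaError,
    ValidationError,
    read_count_series,
    read_ground_truth,
    read_predictions,
    rle_decode,
    rle_encode,
    take_every_nth,
    write_annotations,
)
from cellseg_bench.datamodel import (
    counts_to_rle_string,
    rasterize_polygon,
    rle_string_to_counts,
)
from conftest import make_set, add_square, random_bool_mask


class TestRasterization:
    def test_unit_square_covers_one_pixel(self):
        m = rasterize_polygon([0, 1, 1, 0], [0, 0, 1, 1], 4, 4)
        assert m.sum() == 1 and m[0, 0]

    def test_square_area_matches_vertex_extent(self):
        m = rasterize_polygon([2, 12, 12, 2], [3, 3, 9, 9], 20, 20)
        assert m.sum() == 10 * 6

    def test_clipping_to_image_bounds(self):
        m = rasterize_polygon([-5, 10, 10, -5], [-5, -5, 10, 10], 8, 8)
        assert m.sum() == 64  # polygon overflows; mask confined to the grid

    def test_even_odd_fill_leaves_hole(self):
        # self-intersecting bowtie: center row pixels split into two lobes
        m = rasterize_polygon([0, 10, 0, 10], [0, 10, 10, 0], 10, 10)
        # even-odd rule keeps the left and right triangles, not the full hull
        assert 0 < m.sum() < 100
        assert not m[5, 0] or not m[0, 5]  # at least one off-lobe region empty


class TestRLE:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_roundtrip_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = random_bool_mask(rng, 37, 23)
        assert (rle_decode(rle_encode(m)) == m).all()

    def test_compressed_string_roundtrip(self):
        rng = np.random.default_rng(7)
        m = random_bool_mask(rng, 40, 40)
        rle = rle_encode(m)
        s = counts_to_rle_string(rle["counts"])
        assert rle_string_to_counts(s) == list(rle["counts"])
        decoded = rle_decode({"size": rle["size"], "counts": s})
        assert (decoded == m).all()

    def test_empty_and_full_masks(self):
        empty = np.zeros((5, 4), dtype=bool)
        full = np.ones((5, 4), dtype=bool)
        assert (rle_decode(rle_encode(empty)) == empty).all()
        assert (rle_decode(rle_encode(full)) == full).all()

    def test_bad_counts_sum_rejected(self):
        with pytest.raises(ValidationError):
            rle_decode({"size": [4, 4], "counts": [3, 2]})


class TestReaders:
    def test_ground_truth_counts(self, coco_fixture):
        aset = read_ground_truth(coco_fixture)
        assert len(aset.images) == 2
        assert aset.n_instances == 3

    def test_empty_annotation_list_is_valid(self, tmp_path):
        blob = {"images": [{"id": 1, "width": 8, "height": 8}], "annotations": []}
        p = tmp_path / "gt.json"
        p.write_text(json.dumps(blob))
        aset = read_ground_truth(p)
        assert aset.n_instances == 0

    def test_unknown_image_reference_rejected(self, tmp_path):
        blob = {
            "images": [{"id": 1, "width": 8, "height": 8}],
            "annotations": [{"id": 1, "image_id": 99,
                             "segmentation": [[0, 0, 4, 0, 4, 4]]}],
        }
        p = tmp_path / "gt.json"
        p.write_text(json.dumps(blob))
        with pytest.raises(ValidationError, match="unknown image"):
            read_ground_truth(p)

    def test_malformed_json_names_problem(self, tmp_path):
        p = tmp_path / "gt.json"
        p.write_text("{not json")
        with pytest.raises(ValidationError, match="malformed JSON"):
            read_ground_truth(p)

    def test_multiple_categories_warn(self, tmp_path):
        blob = {
            "images": [{"id": 1, "width": 8, "height": 8}],
            "annotations": [],
            "categories": [{"id": 1, "name": "cell"}, {"id": 2, "name": "debris"}],
        }
        p = tmp_path / "gt.json"
        p.write_text(json.dumps(blob))
        with pytest.warns(UserWarning, match="categories"):
            read_ground_truth(p)

    def test_predictions_grouped_and_scored(self, coco_fixture, results_fixture):
        gt = read_ground_truth(coco_fixture)
        preds = read_predictions(results_fixture, images=gt)
        assert preds.n_instances == 5
        assert len(preds.instances[1]) == 3 and len(preds.instances[2]) == 2

    def test_prediction_missing_score_rejected(self, tmp_path, coco_fixture):
        gt = read_ground_truth(coco_fixture)
        p = tmp_path / "pred.json"
        p.write_text(json.dumps([{"image_id": 1, "segmentation": [[0, 0, 4, 0, 4, 4]]}]))
        with pytest.raises(ValidationError, match="score"):
            read_predictions(p, images=gt)

    def test_prediction_score_out_of_range_rejected(self, tmp_path, coco_fixture):
        gt = read_ground_truth(coco_fixture)
        p = tmp_path / "pred.json"
        p.write_text(json.dumps(
            [{"image_id": 1, "segmentation": [[0, 0, 4, 0, 4, 4]], "score": 1.5}]
        ))
        with pytest.raises(ValidationError, match="score"):
            read_predictions(p, images=gt)

    def test_rle_prediction_pixelset_roundtrip(self, tmp_path, coco_fixture):
        """decode -> encode -> decode reproduces the identical pixel set."""
        gt = read_ground_truth(coco_fixture)
        rng = np.random.default_rng(3)
        m = random_bool_mask(rng, 64, 64)
        rle = rle_encode(m)
        p = tmp_path / "pred.json"
        p.write_text(json.dumps(
            [{"image_id": 1, "segmentation": rle, "score": 0.5}]
        ))
        preds = read_predictions(p, images=gt)
        decoded = preds.instances[1][0].rasterize(64, 64)
        assert (rle_decode(rle_encode(decoded)) == m).all()


class TestRoundTrip:
    def test_read_write_read_pixel_identity(self, coco_fixture, tmp_path):
        aset = read_ground_truth(coco_fixture)
        out = tmp_path / "rt.json"
        write_annotations(aset, out)
        again = read_ground_truth(out)
        for image_id, rec in aset.images.items():
            for a, b in zip(aset.instances[image_id], again.instances[image_id]):
                ma = a.rasterize(rec.width_px, rec.height_px)
                mb = b.rasterize(rec.width_px, rec.height_px)
                assert (ma == mb).all()


class TestCountTable:
    def _write(self, tmp_path, text):
        p = tmp_path / "counts.csv"
        p.write_text(text)
        return p

    HEADER = "image_id,time_hours,density,fluorescence_count,model_count\n"

    def test_four_rows(self, tmp_path):
        p = self._write(tmp_path, self.HEADER +
                        "a,0,D1,10,11\nb,1,D1,20,19\nc,2,D1,30,33\nd,3,D1,40,38\n")
        series = read_count_series(p)
        assert len(series) == 4

    def test_blank_file_schema_error(self, tmp_path):
        with pytest.raises(SchemaError):
            read_count_series(self._write(tmp_path, ""))

    def test_missing_column_schema_error(self, tmp_path):
        with pytest.raises(SchemaError, match="model_count"):
            read_count_series(self._write(
                tmp_path, "image_id,time_hours,density,fluorescence_count\na,0,D1,5\n"))

    def test_lossless_float_coercion(self, tmp_path):
        p = self._write(tmp_path, self.HEADER + "a,0,D1,12.0,13.0\nb,1,D1,1,2\n")
        series = read_count_series(p)
        assert series.y_fluorescence[0] == 12
        assert series.table["fluorescence_count"].dtype.kind == "i"

    def test_fractional_count_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="non-integer"):
            read_count_series(self._write(tmp_path, self.HEADER + "a,0,D1,12.5,13\n"))

    def test_negative_count_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="negative"):
            read_count_series(self._write(tmp_path, self.HEADER + "a,0,D1,-1,13\n"))

    def test_duplicate_image_id_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="duplicate"):
            read_count_series(self._write(
                tmp_path, self.HEADER + "a,0,D1,1,1\na,1,D1,2,2\n"))


class TestTakeEveryNth:
    @pytest.mark.parametrize("n_images,n,expected", [
        (100, 1, 100), (100, 50, 2), (101, 50, 3), (10, 3, 4), (5, 10, 1),
    ])
    def test_image_counts(self, n_images, n, expected):
        aset = make_set(n_images=n_images)
        sub = take_every_nth(aset, n)
        assert len(sub.images) == expected

    def test_identity_preserves_instances(self):
        aset = make_set(n_images=3)
        add_square(aset, 1, 0, 0, 5)
        add_square(aset, 2, 0, 0, 5)
        sub = take_every_nth(aset, 1)
        assert list(sub.images) == list(aset.images)
        assert sub.n_instances == aset.n_instances

    def test_positions_are_multiples_of_n(self):
        aset = make_set(n_images=101)
        sub = take_every_nth(aset, 50)
        assert list(sub.images) == [1, 51, 101]  # ids are 1-based, positions 0/50/100

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            take_every_nth(make_set(2), 0)

    @given(n_images=st.integers(1, 60), n=st.integers(1, 60))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_count_is_ceil(self, n_images, n):
        sub = take_every_nth(make_set(n_images=n_images), n)
        assert len(sub.images) == -(-n_images // n)


class TestInvariants:
    def test_image_record_validation(self):
        with pytest.raises(ValidationError):
            ImageRecord("x", 0, 10)
        with pytest.raises(ValidationError):
            ImageRecord("x", 10, 10, pixel_size_um=-1)

    def test_instance_needs_exactly_one_geometry(self):
        with pytest.raises(ValidationError):
            InstanceMask("x")
        with pytest.raises(ValidationError):
            InstanceMask("x", polygons=[[0, 0, 1, 0, 1, 1]], rle={"size": [2, 2], "counts": [4]})

    def test_annotation_set_referential_integrity(self):
        aset = AnnotationSet()
        with pytest.raises(ValidationError):
            aset.add(InstanceMask("ghost", polygons=[[0, 0, 1, 0, 1, 1]]))
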