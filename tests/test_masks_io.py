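"""Annotation parsing, rasterization, ROI crop/pad and file round-trips."""

import json

import numpy as np
import pytest

from soss import (
    AnnotationParseError,
    IntegrityError,
    LabelMask,
    PolygonAnnotation,
    ProbabilityMap,
    Roi,
    Segment,
    SegmentStack,
    ValidationError,
    crop_and_pad,
    rasterize_polygons,
    read_label_mask,
    read_polygon_annotations,
    read_probability_map,
    read_segment_stack,
    write_label_mask,
    write_probability_map,
    write_segment_stack,
)
from _oracles import rasterize_naive

from conftest import random_probmap


# ---------------------------------------------------------------------------
# annotations


def _labelstudio_doc(points, label="tube", ow=10, oh=10):
    return [
        {
            "id": 1,
            "data": {"image": "img_001.png"},
            "annotations": [
                {
                    "result": [
                        {
                            "type": "polygonlabels",
                            "original_width": ow,
                            "original_height": oh,
                            "value": {"points": points, "polygonlabels": [label]},
                        }
                    ]
                }
            ],
        }
    ]


def test_labelstudio_percent_coordinates_become_pixels(tmp_path):
    """A one-polygon export parses into absolute pixel vertices."""
    doc = _labelstudio_doc([[10, 10], [40, 10], [40, 40], [10, 40]])
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(doc))
    anns = read_polygon_annotations(path, "labelstudio", {"tube": 1})
    assert len(anns) == 1
    assert anns[0].class_id == 1
    assert anns[0].image_id == "img_001.png"
    np.testing.assert_allclose(anns[0].vertices, [[1, 1], [4, 1], [4, 4], [1, 4]])


def test_empty_annotation_list_parses_to_empty(tmp_path):
    path = tmp_path / "ann.json"
    path.write_text("[]")
    assert read_polygon_annotations(path, "labelstudio", {}) == []


def test_two_vertex_polygon_is_rejected(tmp_path):
    doc = _labelstudio_doc([[10, 10], [40, 40]])
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ValidationError, match="3 vertices"):
        read_polygon_annotations(path, "labelstudio", {"tube": 1})


def test_malformed_json_names_the_file(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text("{not json")
    with pytest.raises(AnnotationParseError, match="bad.json"):
        read_polygon_annotations(path, "generic_json")


def test_unknown_label_names_the_offender(tmp_path):
    doc = _labelstudio_doc([[0, 0], [50, 0], [0, 50]], label="wire")
    path = tmp_path / "ann.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ValidationError, match="wire"):
        read_polygon_annotations(path, "labelstudio", {"tube": 1})


def test_generic_dialect_roundtrip(tmp_path):
    doc = {"polygons": [{"points": [[0, 0], [3, 0], [0, 3]], "class_id": 2}]}
    path = tmp_path / "g.json"
    path.write_text(json.dumps(doc))
    (ann,) = read_polygon_annotations(path, "generic_json")
    assert ann.class_id == 2
    assert ann.vertices.shape == (3, 2)


# ---------------------------------------------------------------------------
# rasterization


def test_axis_aligned_square_covers_exactly_nine_centers():
    """Corners (1,1)-(4,4) contain the 9 pixel centers in {1.5,2.5,3.5}^2."""
    ann = PolygonAnnotation([[1, 1], [4, 1], [4, 4], [1, 4]], class_id=1)
    mask = rasterize_polygons([ann], 8, 8, 2)
    assert mask.labels.sum() == 9
    assert (mask.labels[1:4, 1:4] == 1).all()


def test_no_annotations_gives_all_background():
    assert rasterize_polygons([], 5, 7, 3).labels.sum() == 0


def test_overlap_last_polygon_wins():
    a = PolygonAnnotation([[0, 0], [6, 0], [6, 6], [0, 6]], class_id=1)
    b = PolygonAnnotation([[3, 3], [8, 3], [8, 8], [3, 8]], class_id=2)
    mask = rasterize_polygons([a, b], 8, 8, 3)
    assert mask.labels[4, 4] == 2  # overlap region
    assert mask.labels[1, 1] == 1


def test_far_out_of_frame_vertex_rejected():
    ann = PolygonAnnotation([[0, 0], [100, 0], [0, 100]], class_id=1)
    with pytest.raises(ValidationError, match="tolerance band"):
        rasterize_polygons([ann], 8, 8, 2)


def test_rasterization_matches_pointwise_oracle(rng):
    """Vectorized rasterization equals the exhaustive per-pixel-center
    even-odd oracle on random polygons."""
    for _ in range(25):
        h = int(rng.integers(4, 33))
        w = int(rng.integers(4, 33))
        anns = []
        for _ in range(int(rng.integers(1, 4))):
            k = int(rng.integers(3, 9))
            verts = np.stack(
                [rng.uniform(-2, w + 2, k), rng.uniform(-2, h + 2, k)], axis=1
            )
            anns.append(PolygonAnnotation(verts, class_id=int(rng.integers(1, 4))))
        got = rasterize_polygons(anns, h, w, 4).labels
        np.testing.assert_array_equal(got, rasterize_naive(anns, h, w))


# ---------------------------------------------------------------------------
# crop and pad


def test_crop_and_pad_centers_content_with_background_border():
    labels = np.arange(100, dtype=np.int64).reshape(10, 10) % 3
    mask = LabelMask(labels, 3)
    out = crop_and_pad(mask, Roi(2, 8, 2, 8), (8, 8))
    assert out.shape == (8, 8)
    np.testing.assert_array_equal(out.labels[1:7, 1:7], labels[2:8, 2:8])
    assert out.labels[0].sum() == 0 and out.labels[-1].sum() == 0


def test_full_extent_identity():
    labels = np.ones((4, 4), dtype=np.int64)
    out = crop_and_pad(LabelMask(labels, 2), Roi(0, 4, 0, 4), (4, 4))
    np.testing.assert_array_equal(out.labels, labels)


def test_probability_padding_is_background_one_hot(rng):
    pmap = random_probmap(rng, 6, 6, 3)
    out = crop_and_pad(pmap, Roi(1, 5, 1, 5), (8, 8))
    assert out.probs[0, 0, 0] == 1.0 and out.probs[0, 0, 1:].sum() == 0.0
    np.testing.assert_array_equal(out.probs[2:6, 2:6], pmap.probs[1:5, 1:5])


def test_inverse_crop_recovers_roi_content(rng):
    from soss.masks_io import pad_offsets

    labels = rng.integers(0, 3, size=(12, 9))
    mask = LabelMask(labels, 3)
    roi = Roi(3, 9, 2, 7)
    target = (10, 10)
    out = crop_and_pad(mask, roi, target)
    top, left = pad_offsets(roi.extent, target)
    rh, rw = roi.extent
    np.testing.assert_array_equal(
        out.labels[top : top + rh, left : left + rw],
        labels[roi.row_start : roi.row_end, roi.col_start : roi.col_end],
    )


def test_target_smaller_than_roi_rejected():
    mask = LabelMask(np.zeros((8, 8), dtype=np.int64), 2)
    with pytest.raises(ValidationError, match="smaller than ROI"):
        crop_and_pad(mask, Roi(0, 6, 0, 6), (4, 4))


# ---------------------------------------------------------------------------
# round-trips


def test_label_mask_png_roundtrip_bit_exact(tmp_path, rng):
    mask = LabelMask(rng.integers(0, 4, size=(9, 7)), 4)
    write_label_mask(mask, tmp_path / "m.png")
    back = read_label_mask(tmp_path / "m.png", 4)
    np.testing.assert_array_equal(back.labels, mask.labels)


def test_sixteen_bit_label_mask_roundtrip(tmp_path):
    labels = np.array([[0, 300], [500, 999]], dtype=np.int64)
    mask = LabelMask(labels, 1000)
    write_label_mask(mask, tmp_path / "m16.png")
    np.testing.assert_array_equal(
        read_label_mask(tmp_path / "m16.png", 1000).labels, labels
    )


def test_rgb_png_rejected_as_label_mask(tmp_path):
    from PIL import Image

    Image.new("RGB", (4, 4)).save(tmp_path / "rgb.png")
    with pytest.raises(ValidationError, match="single-channel"):
        read_label_mask(tmp_path / "rgb.png", 2)


def test_out_of_range_values_rejected_on_read(tmp_path):
    write_label_mask(LabelMask(np.full((3, 3), 5, dtype=np.int64), 6), tmp_path / "m.png")
    with pytest.raises(ValidationError, match="n_classes"):
        read_label_mask(tmp_path / "m.png", 3)


def test_segment_stack_roundtrip_bit_exact(tmp_path, rng):
    segments = []
    for _ in range(3):
        m = rng.random((6, 5)) < 0.4
        if not m.any():
            m[0, 0] = True
        segments.append(Segment(m, float(rng.uniform(0.9, 1)), float(rng.uniform(0.9, 1))))
    stack = SegmentStack(6, 5, segments)
    write_segment_stack(stack, tmp_path / "stack")
    back = read_segment_stack(tmp_path / "stack")
    assert len(back) == 3
    for a, b in zip(stack, back):
        np.testing.assert_array_equal(a.mask, b.mask)
        assert (a.predicted_confidence, a.stability, a.area) == (
            b.predicted_confidence,
            b.stability,
            b.area,
        )


def test_empty_stack_roundtrip(tmp_path):
    write_segment_stack(SegmentStack(4, 4, []), tmp_path / "empty")
    assert len(read_segment_stack(tmp_path / "empty")) == 0


def test_manifest_area_mismatch_is_integrity_error(tmp_path):
    stack = SegmentStack(4, 4, [Segment(np.eye(4, dtype=bool), 0.95, 0.9)])
    write_segment_stack(stack, tmp_path / "s")
    manifest = json.loads((tmp_path / "s" / "manifest.json").read_text())
    manifest["segments"][0]["area"] = 10
    (tmp_path / "s" / "manifest.json").write_text(json.dumps(manifest))
    with pytest.raises(IntegrityError, match="area"):
        read_segment_stack(tmp_path / "s")


def test_manifest_missing_file_is_integrity_error(tmp_path):
    stack = SegmentStack(4, 4, [Segment(np.eye(4, dtype=bool), 0.95, 0.9)])
    write_segment_stack(stack, tmp_path / "s")
    (tmp_path / "s" / "segment_0000.png").unlink()
    with pytest.raises(IntegrityError, match="missing file"):
        read_segment_stack(tmp_path / "s")


def test_probability_map_roundtrip(tmp_path, rng):
    pmap = random_probmap(rng, 5, 6, 3)
    write_probability_map(pmap, tmp_path / "p.npz")
    np.testing.assert_array_equal(
        read_probability_map(tmp_path / "p.npz").probs, pmap.probs
    )


# ---------------------------------------------------------------------------
# container validation


@pytest.mark.parametrize(
    "labels, n_classes",
    [
        (np.array([[0, 2]]), 2),  # label out of range
        (np.array([[-1, 0]]), 2),  # negative label
        (np.zeros((2, 2)), 2),  # float dtype
    ],
)
def test_label_mask_invariants(labels, n_classes):
    with pytest.raises(ValidationError):
        LabelMask(np.asarray(labels), n_classes)


def test_probability_rows_must_sum_to_one():
    bad = np.full((2, 2, 2), 0.4)
    with pytest.raises(ValidationError, match="sum to 1"):
        ProbabilityMap(bad)
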