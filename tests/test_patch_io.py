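"""Tests of VIA parsing, sliding-window extraction, augmentation and splits."""

import json

import numpy as np
import pytest
import shapely

from texfuse.patch_io import (
    AnnotationSet,
    Patch,
    ViaFormatError,
    augment,
    extract_patches,
    parse_via_annotations,
    split_dataset,
)
from texfuse.synthetic import generate_via_fixture


def brute_force_extract(image, ann, window, stride, max_foreign):
    """Independent oracle: per-window pixel-center membership by direct point tests."""
    h, w = image.shape
    polys = [shapely.geometry.Polygon(v) for v, lab in ann.polygons if lab == "HCC"]
    inside = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            pt = shapely.geometry.Point(float(c), float(r))
            inside[r, c] = any(poly.covers(pt) for poly in polys)
    out = []
    for r in range(0, h - window + 1, stride):
        for c in range(0, w - window + 1, stride):
            frac_in = inside[r : r + window, c : c + window].mean()
            if 1 - frac_in < max_foreign:
                out.append((r, c, "HCC"))
            elif frac_in < max_foreign:
                out.append((r, c, "PAR"))
    return out


class TestParseVia:
    def test_round_trip_with_fixture(self, tmp_path):
        poly = np.array([[5.0, 5.0], [30.0, 5.0], [30.0, 30.0], [5.0, 30.0]])
        path = tmp_path / "f.json"
        generate_via_fixture((64, 64), [(poly, "HCC")], path)
        ann = parse_via_annotations(path)
        np.testing.assert_array_equal(ann.polygons[0][0], poly)

    def test_rectangle_region_rejected(self, tmp_path):
        doc = {"img-1": {"filename": "img.png", "regions": [
            {"shape_attributes": {"name": "rect", "x": 1, "y": 1, "width": 5, "height": 5},
             "region_attributes": {}}]}}
        path = tmp_path / "rect.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ViaFormatError, match="region 0"):
            parse_via_annotations(path)

    def test_missing_vertex_arrays_named(self, tmp_path):
        doc = {"img-1": {"filename": "img.png", "regions": [
            {"shape_attributes": {"name": "polygon", "all_points_x": [1, 2, 3]},
             "region_attributes": {}}]}}
        path = tmp_path / "miss.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ViaFormatError, match="region 0"):
            parse_via_annotations(path)

    def test_hand_written_two_region_file(self, tmp_path):
        doc = {"img-1": {"filename": "us.png", "regions": [
            {"shape_attributes": {"name": "polygon",
                                  "all_points_x": [0, 10, 10], "all_points_y": [0, 0, 10]},
             "region_attributes": {"label": "HCC"}},
            {"shape_attributes": {"name": "polygon",
                                  "all_points_x": [20, 30, 30, 20], "all_points_y": [20, 20, 30, 30]},
             "region_attributes": {"label": "PAR"}}]}}
        path = tmp_path / "two.json"
        path.write_text(json.dumps(doc))
        ann = parse_via_annotations(path)
        assert len(ann.polygons) == 2
        assert [lab for _, lab in ann.polygons] == ["HCC", "PAR"]
        assert ann.image_id == "us.png"


def square_ann(lo, hi, image_id="img"):
    verts = np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]], dtype=float)
    return AnnotationSet(image_id, [(verts, "HCC")])


class TestExtractPatches:
    def test_window_fully_inside_polygon_is_hcc(self, rng):
        image = rng.integers(0, 256, (100, 100)).astype(np.uint8)
        ann = square_ann(10, 90)
        patches = extract_patches(image, ann, window_px=20, stride_px=20)
        labels = {p.origin_rowcol: p.label for p in patches}
        assert labels[(20, 20)] == "HCC"  # fully interior window, zero foreign fraction

    def test_boundary_window_discarded(self, rng):
        image = rng.integers(0, 256, (60, 60)).astype(np.uint8)
        ann = square_ann(0, 29.5)  # window 20 at (0, 20) straddles the boundary
        patches = extract_patches(image, ann, window_px=20, stride_px=20)
        labels = {p.origin_rowcol: p.label for p in patches}
        assert (0, 20) not in labels
        assert labels[(0, 0)] == "HCC"
        assert labels[(40, 40)] == "PAR"

    def test_matches_brute_force_on_centered_square(self, rng):
        """56-px windows over a 200x200 image with a centered 112x112 polygon
        must reproduce the exhaustive all-window oracle exactly."""
        image = rng.integers(0, 256, (200, 200)).astype(np.uint8)
        ann = square_ann(44, 156)
        got = sorted((p.origin_rowcol[0], p.origin_rowcol[1], p.label)
                     for p in extract_patches(image, ann, 56, 56, 0.001))
        expected = sorted(brute_force_extract(image, ann, 56, 56, 0.001))
        assert got == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_triangles(self, seed):
        rng = np.random.default_rng(seed)
        image = rng.integers(0, 256, (96, 96)).astype(np.uint8)
        verts = rng.uniform(5, 90, size=(3, 2))
        ann = AnnotationSet("img", [(verts, "HCC")])
        got = sorted((p.origin_rowcol[0], p.origin_rowcol[1], p.label)
                     for p in extract_patches(image, ann, 16, 8, 0.05))
        expected = sorted(brute_force_extract(image, ann, 16, 8, 0.05))
        assert got == expected

    def test_vertex_order_invariance(self, rng):
        image = rng.integers(0, 256, (120, 120)).astype(np.uint8)
        cw = np.array([[20.0, 20.0], [100.0, 20.0], [100.0, 100.0], [20.0, 100.0]])
        ccw = cw[::-1]
        a = extract_patches(image, AnnotationSet("i", [(cw, "HCC")]), 24, 24)
        b = extract_patches(image, AnnotationSet("i", [(ccw, "HCC")]), 24, 24)
        assert [(p.origin_rowcol, p.label) for p in a] == [(p.origin_rowcol, p.label) for p in b]

    def test_invalid_stride(self, rng):
        image = rng.integers(0, 256, (60, 60)).astype(np.uint8)
        with pytest.raises(ValueError, match="stride"):
            extract_patches(image, square_ann(5, 50), 20, 0)


class TestAugment:
    @pytest.fixture()
    def patch(self, rng):
        return Patch(rng.integers(0, 256, (16, 16)).astype(np.uint8), "HCC", "src", (0, 0))

    def test_hflip_is_involution(self, patch):
        once = augment(patch, ["h_flip"])[1]
        twice = augment(once, ["h_flip"])[1]
        np.testing.assert_array_equal(twice.pixels, patch.pixels)

    def test_count_and_tags(self, patch):
        out = augment(patch, ["rotation", "h_flip", "scaling"])
        assert len(out) == 4
        assert out[0].augmentation_tag == "none"
        assert {p.augmentation_tag for p in out[1:]} == {"rotation", "h_flip", "scaling"}

    def test_rot90_matches_index_remap(self):
        base = np.arange(16, dtype=np.uint8).reshape(4, 4)
        p = Patch(base, "PAR", "s", (0, 0))
        rotated = augment(p, ["rotation"], {"rotation": {"angle_deg": 90.0}})[1]
        # a +90 degree rotation maps pixel (r, c) to (side-1-c, r): one rot90 step
        np.testing.assert_array_equal(rotated.pixels, np.rot90(base, k=1))

    def test_translation_shifts_content(self, patch):
        shifted = augment(patch, ["h_translation"], {"h_translation": {"shift_px": 3}})[1]
        np.testing.assert_array_equal(shifted.pixels[:, 3:], patch.pixels[:, :-3])

    def test_unknown_transform_rejected(self, patch):
        with pytest.raises(ValueError, match="unknown transform"):
            augment(patch, ["shear"])


def make_patches(n_per_class, side=8):
    rng = np.random.default_rng(0)
    out = []
    for lab in ("HCC", "PAR"):
        for i in range(n_per_class):
            out.append(Patch(rng.integers(0, 256, (side, side)).astype(np.uint8),
                             lab, f"{lab}_{i}", (0, 0)))
    return out


class TestSplitDataset:
    def test_conventional_75_25(self):
        parts = split_dataset(make_patches(50), "conventional", seed=0)
        assert len(parts["train"]) == 75
        assert len(parts["test"]) == 25

    def test_cnn_75_8_17(self):
        parts = split_dataset(make_patches(50), "cnn", seed=0)
        assert (len(parts["train"]), len(parts["val"]), len(parts["test"])) == (75, 8, 17)

    def test_stratified_by_class(self):
        parts = split_dataset(make_patches(50), "conventional", seed=3)
        train_hcc = sum(p.label == "HCC" for p in parts["train"])
        assert 36 <= train_hcc <= 39

    def test_same_seed_identical_partition(self):
        a = split_dataset(make_patches(20), "cnn", seed=9)
        b = split_dataset(make_patches(20), "cnn", seed=9)
        for part in a:
            assert [p.source_image_id for p in a[part]] == [p.source_image_id for p in b[part]]

    def test_no_patch_in_two_partitions(self):
        parts = split_dataset(make_patches(30), "cnn", seed=1)
        ids = [id(p) for ps in parts.values() for p in ps]
        assert len(ids) == len(set(ids))

    def test_augmented_copies_stay_with_original(self):
        base = make_patches(20)
        augmented = []
        for p in base:
            augmented.extend(augment(p, ["h_flip", "rotation"]))
        parts = split_dataset(augmented, "conventional", seed=2)
        home = {}
        for part, ps in parts.items():
            for p in ps:
                key = p.base_id
                assert home.setdefault(key, part) == part

    def test_single_class_rejected(self):
        patches = [p for p in make_patches(10) if p.label == "HCC"]
        with pytest.raises(ValueError):
            split_dataset(patches, "conventional", seed=0)
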