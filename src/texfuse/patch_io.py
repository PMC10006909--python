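"""Patch input/output: VIA annotations, sliding-window extraction, augmentation, splits.

Ground truth arrives as polygonal tumor delineations drawn in the VGG Image
Annotator (VIA) on B-mode ultrasound images.  Square patches are carved out of
the annotated images with a sliding window: a window almost entirely inside
the tumor polygon becomes an HCC patch, a window almost entirely outside
becomes a parenchyma (PAR) patch, and everything near the boundary is
discarded.  "Almost entirely" means the foreign-area fraction is below
``max_foreign_fraction`` (default 0.001, i.e. 0.1% of the window area).

Area fractions are decided by pixel-center membership: a pixel belongs to the
tumor region iff its center lies inside (or on the boundary of) a tumor
polygon.  This is exact for the brute-force oracle used in the tests and is
adequate at 50-56 px window sizes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath

import numpy as np
import shapely
from scipy import ndimage

__all__ = [
    "Patch",
    "AnnotationSet",
    "ViaFormatError",
    "parse_via_annotations",
    "extract_patches",
    "augment",
    "split_dataset",
    "save_patches",
    "load_patches",
]

HCC = "HCC"
PAR = "PAR"
AUGMENT_TRANSFORMS = ("rotation", "h_translation", "v_translation", "scaling", "h_flip")


@dataclass
class Patch:
    """A square 8-bit grayscale patch with its class label and provenance."""

    pixels: np.ndarray
    label: str
    source_image_id: str = ""
    origin_rowcol: tuple[int, int] = (0, 0)
    augmentation_tag: str = "none"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"patch pixels must be square 2-D, got shape {self.pixels.shape}")
        if self.label not in (HCC, PAR):
            raise ValueError(f"label must be {HCC!r} or {PAR!r}, got {self.label!r}")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def base_id(self) -> tuple:
        """Identity of the un-augmented source patch (used to group augmented copies)."""
        return (self.source_image_id, self.origin_rowcol)


@dataclass
class AnnotationSet:
    """Polygonal annotations of one image: list of (vertices (N,2) in (x, y), label)."""

    image_id: str
    polygons: list[tuple[np.ndarray, str]] = field(default_factory=list)

    def tumor_polygons(self) -> list[np.ndarray]:
        return [v for v, lab in self.polygons if lab == HCC]


class ViaFormatError(ValueError):
    """Raised when a VIA JSON file does not conform to the polygon region dialect."""


def parse_via_annotations(file) -> AnnotationSet:
    """Parse a VIA-dialect JSON file into an :class:`AnnotationSet`.

    Accepts both a bare image-keyed mapping and a full VIA project file with a
    ``_via_img_metadata`` section.  Only ``polygon`` regions are supported;
    any other shape type raises :class:`ViaFormatError` naming the region.
    """
    with open(file) as fh:
        doc = json.load(fh)
    if "_via_img_metadata" in doc:
        doc = doc["_via_img_metadata"]
    if len(doc) != 1:
        raise ViaFormatError(f"expected exactly one image entry, found {len(doc)}")
    (key, entry), = doc.items()
    image_id = entry.get("filename", key)
    polygons: list[tuple[np.ndarray, str]] = []
    for i, region in enumerate(entry.get("regions", [])):
        shape = region.get("shape_attributes", {})
        if shape.get("name") != "polygon":
            raise ViaFormatError(
                f"region {i}: unsupported shape {shape.get('name')!r}; only 'polygon' regions are accepted"
            )
        if "all_points_x" not in shape or "all_points_y" not in shape:
            raise ViaFormatError(f"region {i}: missing vertex arrays all_points_x/all_points_y")
        xs = np.asarray(shape["all_points_x"], dtype=float)
        ys = np.asarray(shape["all_points_y"], dtype=float)
        if xs.shape != ys.shape or xs.ndim != 1:
            raise ViaFormatError(f"region {i}: vertex arrays have inconsistent shapes")
        label = region.get("region_attributes", {}).get("label", HCC)
        polygons.append((np.stack([xs, ys], axis=1), label))
    return AnnotationSet(image_id=image_id, polygons=polygons)


def region_mask(image_shape: tuple[int, int], ann: AnnotationSet) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside (or on) a tumor polygon."""
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    cols, rows = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    for verts in ann.tumor_polygons():
        poly = shapely.geometry.Polygon(verts)
        # intersects_xy is True on the boundary, so boundary pixels count as inside
        mask |= shapely.intersects_xy(poly, cols.ravel(), rows.ravel()).reshape(h, w)
    return mask


def extract_patches(
    image: np.ndarray,
    ann: AnnotationSet,
    window_px: int = 56,
    stride_px: int | None = None,
    max_foreign_fraction: float = 0.001,
) -> list[Patch]:
    """Slide a square window over the image and label windows by polygon overlap.

    A window is labeled HCC when the fraction of its area outside the tumor
    region is below ``max_foreign_fraction``, PAR when the fraction inside is
    below that threshold, and is discarded otherwise.
    """
    image = np.asarray(image)
    if stride_px is None:
        stride_px = window_px
    if stride_px <= 0:
        raise ValueError(f"stride_px must be positive, got {stride_px}")
    h, w = image.shape
    if window_px > min(h, w):
        raise ValueError(f"window {window_px} exceeds image dims {image.shape}")
    inside = region_mask((h, w), ann)
    # summed-area table for O(1) window sums
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = np.cumsum(np.cumsum(inside, axis=0), axis=1)
    area = window_px * window_px
    patches: list[Patch] = []
    for r in range(0, h - window_px + 1, stride_px):
        for c in range(0, w - window_px + 1, stride_px):
            n_in = int(
                sat[r + window_px, c + window_px]
                - sat[r, c + window_px]
                - sat[r + window_px, c]
                + sat[r, c]
            )
            frac_in = n_in / area
            if 1.0 - frac_in < max_foreign_fraction:
                label = HCC
            elif frac_in < max_foreign_fraction:
                label = PAR
            else:
                continue
            patches.append(
                Patch(
                    pixels=image[r : r + window_px, c : c + window_px].copy(),
                    label=label,
                    source_image_id=ann.image_id,
                    origin_rowcol=(r, c),
                )
            )
    return patches


def _same_size(out: np.ndarray, side: int) -> np.ndarray:
    """Center-crop or reflect-pad ``out`` back to ``side`` x ``side``."""
    h, w = out.shape
    if h > side:
        r0 = (h - side) // 2
        out = out[r0 : r0 + side, :]
    if w > side:
        c0 = (w - side) // 2
        out = out[:, c0 : c0 + side]
    h, w = out.shape
    if h < side or w < side:
        pr, pc = side - h, side - w
        out = np.pad(out, ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)), mode="reflect")
    return out


def augment(patch: Patch, transforms, params: dict | None = None) -> list[Patch]:
    """Apply geometric transforms to a patch; the original is retained.

    Supported transforms: rotation (``angle_deg``), h_translation /
    v_translation (``shift_px``), scaling (``factor``), h_flip.  Every output
    keeps the original size (rotation/scaling act about the center; borders
    are filled by reflection) and records its transform in
    ``augmentation_tag``.
    """
    params = params or {}
    side = patch.side
    px = patch.pixels.astype(np.float64)
    out = [patch]
    for name in transforms:
        if name == "rotation":
            angle = params.get("rotation", {}).get("angle_deg", 15.0)
            arr = ndimage.rotate(px, angle, reshape=False, mode="reflect", order=1)
        elif name == "h_translation":
            shift = params.get("h_translation", {}).get("shift_px", 5)
            arr = ndimage.shift(px, (0, shift), mode="reflect", order=1)
        elif name == "v_translation":
            shift = params.get("v_translation", {}).get("shift_px", 5)
            arr = ndimage.shift(px, (shift, 0), mode="reflect", order=1)
        elif name == "scaling":
            factor = params.get("scaling", {}).get("factor", 1.1)
            arr = _same_size(ndimage.zoom(px, factor, mode="reflect", order=1), side)
        elif name == "h_flip":
            arr = np.fliplr(px)
        else:
            raise ValueError(f"unknown transform {name!r}; supported: {AUGMENT_TRANSFORMS}")
        arr = np.clip(np.rint(arr), 0, 255).astype(patch.pixels.dtype)
        out.append(replace(patch, pixels=arr, augmentation_tag=name))
    return out


_MODES = {"cnn": (("train", 0.75), ("val", 0.08), ("test", 0.17)),
          "conventional": (("train", 0.75), ("test", 0.25))}


def split_dataset(patches: list[Patch], mode: str, seed: int = 0) -> dict[str, list[Patch]]:
    """Stratified partition of patches into train(/val)/test sets.

    ``cnn`` mode uses 75/8/17 train/val/test fractions, ``conventional`` mode
    75/25 train/test.  All augmented copies of a patch travel with their
    original (grouping by source image and window origin), so no augmented
    view of a test patch can leak into training.  Partition sizes follow the
    fractions exactly at the whole-dataset level (largest-remainder
    apportionment across class-by-partition cells).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    parts = _MODES[mode]
    labels = sorted({p.label for p in patches})
    if len(labels) < 2:
        raise ValueError("need patches from both classes to split")
    # group augmented copies with their base patch
    groups: dict[tuple, list[Patch]] = {}
    for p in patches:
        groups.setdefault((p.label,) + p.base_id, []).append(p)
    for lab in labels:
        if sum(1 for k in groups if k[0] == lab) < len(parts):
            raise ValueError(f"class {lab}: fewer base patches than partitions")
    n_total = len(patches)
    class_counts = {lab: sum(len(v) for k, v in groups.items() if k[0] == lab) for lab in labels}
    # largest-remainder apportionment of patch counts over (class, partition) cells,
    # breaking ties in favor of the partition furthest below its global target
    quotas = {(lab, pname): class_counts[lab] * f for lab in labels for pname, f in parts}
    alloc = {cell: int(np.floor(q)) for cell, q in quotas.items()}
    seats = n_total - sum(alloc.values())
    part_targets = {pname: n_total * f for pname, f in parts}
    for _ in range(seats):
        part_tot = {pname: sum(alloc[(lab, pname)] for lab in labels) for pname, _ in parts}
        class_tot = {lab: sum(alloc[(lab, pname)] for pname, _ in parts) for lab in labels}
        candidates = [c for c in alloc if class_tot[c[0]] < class_counts[c[0]]]
        cell = max(
            candidates,
            key=lambda c: (round(quotas[c] - alloc[c], 9),
                           round(part_targets[c[1]] - part_tot[c[1]], 9),
                           round(class_counts[c[0]] - class_tot[c[0]], 9)),
        )
        alloc[cell] += 1
    rng = np.random.default_rng(seed)
    partition: dict[str, list[Patch]] = {pname: [] for pname, _ in parts}
    for lab in labels:
        keys = sorted((k for k in groups if k[0] == lab), key=str)
        rng.shuffle(keys)
        it = iter(keys)
        for pname, _ in parts:
            want = alloc[(lab, pname)]
            got = 0
            while got < want:
                try:
                    k = next(it)
                except StopIteration:
                    break
                partition[pname].extend(groups[k])
                got += len(groups[k])
        for k in it:  # leftovers from group rounding go to train
            partition["train"].extend(groups[k])
    return partition


def save_patches(patches: list[Patch], out_dir) -> FsPath:
    """Write patches as PNG files plus a CSV manifest; returns the manifest path."""
    from PIL import Image

    out_dir = FsPath(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["patch_id,label,source_image_id,origin_row,origin_col,augmentation_tag"]
    for i, p in enumerate(patches):
        name = f"patch_{i:06d}.png"
        Image.fromarray(p.pixels.astype(np.uint8), mode="L").save(out_dir / name)
        rows.append(
            f"{name},{p.label},{p.source_image_id},{p.origin_rowcol[0]},{p.origin_rowcol[1]},{p.augmentation_tag}"
        )
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def load_patches(manifest) -> list[Patch]:
    from PIL import Image

    manifest = FsPath(manifest)
    out = []
    lines = manifest.read_text().strip().splitlines()[1:]
    for line in lines:
        name, label, src, r, c, tag = line.split(",")
        arr = np.asarray(Image.open(manifest.parent / name))
        out.append(Patch(arr, label, src, (int(r), int(c)), tag))
    return out
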