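"""Synthetic speckle-textured patch generator and VIA annotation fixtures.

B-mode ultrasound texture is dominated by speckle, the interference pattern
of coherent backscatter.  Under the fully-developed-speckle model the complex
echo amplitude has independent zero-mean Gaussian in-phase and quadrature
components, so the envelope (root of the sum of squares) follows a Rayleigh
law with scale equal to the component standard deviation.  Spatial
granularity is injected by giving both Gaussian fields an isotropic Gaussian
autocorrelation of configurable length; the Rayleigh *marginal* is unchanged.

Two synthetic tissue classes are emulated:

* ``HCC`` (tumor): coarser speckle (longer correlation length) modulated by
  smooth random "blobs" that mimic the heterogeneous, hyperechogenic aspect
  of advanced hepatocellular carcinoma;
* ``PAR`` (cirrhotic parenchyma): finer, more homogeneous speckle.

The class defaults are tuning knobs for a two-class texture benchmark, not
quantitative claims about real liver echotexture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import ndimage

from .patch_io import HCC, PAR, AnnotationSet, Patch, parse_via_annotations

__all__ = [
    "SpeckleParams",
    "HCC_DEFAULTS",
    "PAR_DEFAULTS",
    "speckle_envelope",
    "simulate_speckle_patch",
    "generate_via_fixture",
    "build_benchmark_dataset",
]


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of one synthetic speckle patch.

    correlation_length_px
        1/e radius of the Gaussian autocorrelation of the underlying fields;
        larger values give coarser speckle grain.
    heterogeneity_blob_count / heterogeneity_blob_contrast
        Number and relative amplitude (in [0, 1]) of smooth multiplicative
        brightness blobs superimposed on the speckle.
    base_scale
        Standard deviation of each Gaussian component field, i.e. the
        Rayleigh scale of the envelope before blob modulation and 8-bit
        rescaling.
    """

    class_label: str = HCC
    correlation_length_px: float = 2.5
    heterogeneity_blob_count: int = 6
    heterogeneity_blob_contrast: float = 0.45
    base_scale: float = 1.0
    patch_size_px: int = 56
    seed: int = 0

    def __post_init__(self):
        if self.correlation_length_px <= 0:
            raise ValueError(f"correlation_length_px must be positive, got {self.correlation_length_px}")
        if self.base_scale <= 0:
            raise ValueError("base_scale must be positive")
        if self.heterogeneity_blob_count < 0:
            raise ValueError("heterogeneity_blob_count must be non-negative")
        if self.patch_size_px < 16:
            raise ValueError("patch_size_px must be at least 16")


HCC_DEFAULTS = SpeckleParams(class_label=HCC, correlation_length_px=2.5,
                             heterogeneity_blob_count=6, heterogeneity_blob_contrast=0.45)
PAR_DEFAULTS = SpeckleParams(class_label=PAR, correlation_length_px=1.2,
                             heterogeneity_blob_count=1, heterogeneity_blob_contrast=0.15)


def _correlated_gaussian(rng: np.random.Generator, n: int, corr_len: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with Gaussian autocorrelation.

    Smoothing white noise with a Gaussian kernel of std sigma_f yields a field
    whose autocorrelation is Gaussian with std sigma_f * sqrt(2); we therefore
    use sigma_f = corr_len / sqrt(2) and renormalize by the exact kernel
    l2-norm so the marginal variance stays 1.
    """
    sigma_f = corr_len / np.sqrt(2.0)
    white = rng.standard_normal((n, n))
    field = ndimage.gaussian_filter(white, sigma_f, mode="wrap")
    # discrete kernel l2-norm (separable): ||g2d||_2 = ||g1d||_2 ** 2
    radius = int(4.0 * sigma_f + 0.5)
    impulse = np.zeros(max(2 * radius + 1, 1))
    impulse[len(impulse) // 2] = 1.0
    g1 = ndimage.gaussian_filter1d(impulse, sigma_f, mode="constant")
    norm = np.sum(g1 ** 2)
    return field / norm if norm > 0 else white


def _blob_modulation(rng: np.random.Generator, n: int, count: int, contrast: float) -> np.ndarray:
    """Multiplicative brightness field 1 + contrast * b with b in [0, 1]."""
    if count == 0 or contrast == 0:
        return np.ones((n, n))
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    bumps = np.zeros((n, n))
    sigma_b = n / 8.0
    for _ in range(count):
        cr, cc = rng.uniform(0, n, size=2)
        bumps += np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma_b ** 2))
    peak = bumps.max()
    if peak > 0:
        bumps /= peak
    return 1.0 + contrast * bumps


def speckle_envelope(params: SpeckleParams) -> np.ndarray:
    """Pre-quantization envelope field (float), Rayleigh-distributed when blob_count=0."""
    rng = np.random.default_rng(params.seed)
    n = params.patch_size_px
    i_field = _correlated_gaussian(rng, n, params.correlation_length_px) * params.base_scale
    q_field = _correlated_gaussian(rng, n, params.correlation_length_px) * params.base_scale
    env = np.hypot(i_field, q_field)
    env *= _blob_modulation(rng, n, params.heterogeneity_blob_count,
                            params.heterogeneity_blob_contrast)
    return env


def simulate_speckle_patch(params: SpeckleParams) -> Patch:
    """Simulate one 8-bit speckle patch; bit-identical for identical params."""
    env = speckle_envelope(params)
    lo, hi = env.min(), env.max()
    if hi > lo:
        arr = np.rint((env - lo) / (hi - lo) * 255.0)
    else:
        arr = np.zeros_like(env)
    return Patch(
        pixels=arr.astype(np.uint8),
        label=params.class_label,
        source_image_id=f"synthetic_seed{params.seed}",
    )


def generate_via_fixture(image_size_px: tuple[int, int], polygons, path) -> AnnotationSet:
    """Write a VIA-dialect JSON annotation fixture and return its parsed form.

    ``polygons`` is a list of ``(vertices, label)`` with vertices an (N, 2)
    array of (x, y) pixel coordinates.  Polygons must have at least three
    vertices, lie inside the image bounds and be simple (non-self-
    intersecting); the written file round-trips exactly through
    :func:`texfuse.patch_io.parse_via_annotations`.
    """
    w, h = image_size_px
    regions = []
    for i, (verts, label) in enumerate(polygons):
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError(f"polygon {i}: need >= 3 (x, y) vertices")
        if verts[:, 0].min() < 0 or verts[:, 0].max() >= w or verts[:, 1].min() < 0 or verts[:, 1].max() >= h:
            raise ValueError(f"polygon {i}: vertices outside image bounds {image_size_px}")
        ring = shapely.geometry.LineString(np.vstack([verts, verts[:1]]))
        if not ring.is_simple:
            raise ValueError(f"polygon {i}: self-intersecting polygon rejected")
        regions.append(
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [float(v) for v in verts[:, 0]],
                    "all_points_y": [float(v) for v in verts[:, 1]],
                },
                "region_attributes": {"label": label},
            }
        )
    doc = {
        "synthetic.png-1": {
            "filename": "synthetic.png",
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return parse_via_annotations(path)


def patch_seed(master_seed: int, index: int, class_code: int) -> int:
    """Deterministic per-patch seed derived from the master seed (kept < 2^31)."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, class_code, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_benchmark_dataset(
    n_per_class: int,
    params_hcc: SpeckleParams = HCC_DEFAULTS,
    params_par: SpeckleParams = PAR_DEFAULTS,
    seed: int = 0,
) -> list[Patch]:
    """Generate a balanced two-class benchmark of ``n_per_class`` patches per class.

    Each patch gets its own seed derived from the master seed, so the
    collection is reproducible as a whole while patches are mutually
    independent streams.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    patches: list[Patch] = []
    for code, params in ((0, params_hcc), (1, params_par)):
        for i in range(n_per_class):
            p = simulate_speckle_patch(replace(params, seed=patch_seed(seed, i, code)))
            p.source_image_id = f"synthetic_{params.class_label}_{i}"
            patches.append(p)
    return patches
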