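"""Conventional texture-analysis battery for ultrasound patches.

The battery combines classical descriptors (first-order statistics, Haralick
features of the second-order gray-level co-occurrence matrix, autocorrelation,
Hurst index, edge statistics, Laws microstructure energies, wavelet-entropy
multiresolution features, local binary patterns) with generalized
co-occurrence statistics of superior order:

* third-order GLCM over collinear and right-angle pixel triples, and
* the textural microstructure co-occurrence matrix (TMCM), a co-occurrence
  tensor whose attribute alphabet is the k-means cluster label of each
  pixel's 3x3 gray-level neighborhood (k in {250, 500}).

An order-n co-occurrence tensor counts pixel n-tuples in a fixed geometric
configuration, indexed by the attribute values of the tuple.  Counts are kept
sparse (coordinate lists), which makes 256^3-cell third-order tensors cheap.

All features are computed on the median-filtered patch (speckle reduction).
Degenerate inputs (flat patches) yield 0 for correlation-type features so
vectors stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .patch_io import Patch

__all__ = [
    "CooccurrenceTensor",
    "TextureConfig",
    "preprocess",
    "cooccurrence",
    "haralick",
    "tmcm_labels",
    "lbp_histogram",
    "laws_stats",
    "edge_features",
    "multiscale_stats",
    "texture_battery",
    "texture_feature_matrix",
    "DISPLACEMENTS_ORDER2",
    "DISPLACEMENTS_ORDER3",
]

HARALICK_NAMES = ("homogeneity", "energy", "entropy", "correlation", "contrast", "variance")


def _unit(angle_deg: int, d: int) -> tuple[int, int]:
    """(row, col) offset for a displacement at ``angle_deg`` and distance ``d``.

    Angles follow the usual image convention: 0 deg points right (+col),
    90 deg points up (-row).
    """
    a = np.deg2rad(angle_deg)
    return (-int(round(d * np.sin(a))), int(round(d * np.cos(a))))


# order-2: single displacement at 0/45/90/135 degrees
DISPLACEMENTS_ORDER2 = {"0": (0,), "45": (45,), "90": (90,), "135": (135,)}
# order-3 collinear (current pixel central) and right-angle (current pixel at the corner)
_COLLINEAR = {f"{a}_{a + 180}": (a, a + 180) for a in (0, 45, 90, 135)}
_RIGHT_ANGLE = {f"{a}_{a + 90}": (a, a + 90) for a in (0, 45, 90, 135)}
DISPLACEMENTS_ORDER3 = {**_COLLINEAR, **_RIGHT_ANGLE}


@dataclass
class CooccurrenceTensor:
    """Sparse order-n co-occurrence counts over an attribute alphabet.

    ``coords`` has shape (order_n, m) with attribute values of each distinct
    observed n-tuple; ``counts`` the corresponding non-negative tallies (or
    probabilities once normalized).
    """

    order_n: int
    attribute_domain: str
    alphabet_size: int
    displacement_config: str
    coords: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalize(self) -> "CooccurrenceTensor":
        if self.normalized:
            return self
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize an empty co-occurrence tensor")
        return CooccurrenceTensor(
            self.order_n, self.attribute_domain, self.alphabet_size,
            self.displacement_config, self.coords, self.counts / tot, normalized=True,
        )

    def to_dense(self) -> np.ndarray:
        if self.alphabet_size ** self.order_n > 2 ** 24:
            raise ValueError("dense tensor would be too large; use the sparse form")
        dense = np.zeros((self.alphabet_size,) * self.order_n,
                         dtype=float if self.normalized else np.int64)
        dense[tuple(self.coords)] = self.counts
        return dense


def preprocess(patch: Patch, median_window_px: int = 3) -> Patch:
    """Median-filter the patch for speckle reduction; window must be odd."""
    if median_window_px % 2 == 0:
        raise ValueError(f"median window must be odd, got {median_window_px}")
    filtered = ndimage.median_filter(patch.pixels, size=median_window_px, mode="reflect")
    out = Patch(filtered, patch.label, patch.source_image_id,
                patch.origin_rowcol, patch.augmentation_tag)
    return out


def cooccurrence(
    patch_or_labels: np.ndarray,
    order_n: int,
    attribute_domain: str = "gray_level",
    displacement_config: str = "0",
    levels: int | None = None,
    distance: int = 1,
) -> CooccurrenceTensor:
    """Count attribute n-tuples of pixels in the configured geometry.

    For order 2 the tuple is (current pixel, pixel at the displacement).  For
    order 3 the two named angles give the positions of the two companion
    pixels relative to the current one: collinear pairs (theta, theta+180)
    put the current pixel in the middle, right-angle pairs (theta, theta+90)
    put it at the corner of the triangle.  Displacements are signed (no
    symmetrization); tuples reaching off the image are skipped.
    """
    arr = np.asarray(patch_or_labels)
    if arr.ndim != 2:
        raise ValueError("input must be a 2-D array")
    table = DISPLACEMENTS_ORDER2 if order_n == 2 else DISPLACEMENTS_ORDER3
    if order_n not in (2, 3):
        raise ValueError(f"order_n must be 2 or 3, got {order_n}")
    if displacement_config not in table:
        raise ValueError(
            f"unknown displacement {displacement_config!r} for order {order_n}; "
            f"choose from {sorted(table)}"
        )
    if levels is None:
        levels = int(arr.max()) + 1 if arr.size else 1
    if arr.max() >= levels:
        raise ValueError(f"input has values >= levels={levels}")
    offsets = [_unit(a, distance) for a in table[displacement_config]]
    h, w = arr.shape
    # intersection of valid positions for all offsets
    r_lo = max(0, *(-dr for dr, _ in offsets), 0)
    r_hi = min(h, *(h - dr for dr, _ in offsets), h)
    c_lo = max(0, *(-dc for _, dc in offsets), 0)
    c_hi = min(w, *(w - dc for _, dc in offsets), w)
    if r_lo >= r_hi or c_lo >= c_hi:
        coords = np.zeros((order_n, 0), dtype=np.int64)
        return CooccurrenceTensor(order_n, attribute_domain, levels,
                                  displacement_config, coords, np.zeros(0, dtype=np.int64))
    tuples = [arr[r_lo:r_hi, c_lo:c_hi].ravel().astype(np.int64)]
    for dr, dc in offsets:
        tuples.append(arr[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc].ravel().astype(np.int64))
    code = tuples[0]
    for t in tuples[1:]:
        code = code * levels + t
    uniq, counts = np.unique(code, return_counts=True)
    coords = np.empty((order_n, uniq.size), dtype=np.int64)
    rem = uniq.copy()
    for k in range(order_n - 1, -1, -1):
        coords[k] = rem % levels
        rem //= levels
    return CooccurrenceTensor(order_n, attribute_domain, levels,
                              displacement_config, coords, counts.astype(np.int64))


def _pair_correlation(a: np.ndarray, b: np.ndarray, p: np.ndarray) -> float:
    """Correlation of two attribute coordinates under joint probability p; 0 if degenerate."""
    mu_a = float(np.sum(p * a))
    mu_b = float(np.sum(p * b))
    va = float(np.sum(p * (a - mu_a) ** 2))
    vb = float(np.sum(p * (b - mu_b) ** 2))
    if va <= 0 or vb <= 0:
        return 0.0
    cov = float(np.sum(p * (a - mu_a) * (b - mu_b)))
    return cov / np.sqrt(va * vb)


def haralick(tensor: CooccurrenceTensor) -> dict[str, float]:
    """Haralick-type statistics of a (normalized) co-occurrence tensor.

    Contrast and homogeneity generalize to order n through the tuple spread
    max-min, which reduces to |a1 - a2| at n=2.  Variance uses the marginal
    of the first (current-pixel) coordinate.  Order-3 correlation is the mean
    of the three pairwise order-2 correlations of the tensor's 2-D marginals;
    a zero marginal variance yields correlation 0 by contract.
    """
    if tensor.total <= 0:
        raise ValueError("empty co-occurrence tensor")
    t = tensor.normalize()
    p = t.counts
    a = t.coords.astype(float)
    spread = a.max(axis=0) - a.min(axis=0)
    energy = float(np.sum(p ** 2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    contrast = float(np.sum(p * spread ** 2))
    homogeneity = float(np.sum(p / (1.0 + spread)))
    mu1 = float(np.sum(p * a[0]))
    variance = float(np.sum(p * (a[0] - mu1) ** 2))
    if t.order_n == 2:
        correlation = _pair_correlation(a[0], a[1], p)
    else:
        correlation = float(np.mean([
            _pair_correlation(a[i], a[j], p)
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]))
    return {
        "homogeneity": homogeneity,
        "energy": energy,
        "entropy": entropy,
        "correlation": correlation,
        "contrast": contrast,
        "variance": variance,
    }


def _assign(vectors: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment via the expanded squared-distance identity."""
    d2 = (np.einsum("ij,ij->i", centers, centers)[None, :]
          - 2.0 * vectors @ centers.T)
    return np.argmin(d2, axis=1)


def _lloyd_kmeans(fit_vecs: np.ndarray, k: int, rng: np.random.Generator,
                  max_iter: int) -> np.ndarray:
    """Seeded Lloyd k-means; initial centers are k distinct observed vectors."""
    uniq = np.unique(fit_vecs, axis=0)
    k = min(k, uniq.shape[0])
    centers = uniq[rng.choice(uniq.shape[0], size=k, replace=False)].astype(float)
    labels = None
    for _ in range(max_iter):
        new_labels = _assign(fit_vecs, centers)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        sums = np.zeros_like(centers)
        np.add.at(sums, labels, fit_vecs)
        counts = np.bincount(labels, minlength=k).astype(float)
        occupied = counts > 0
        centers[occupied] = sums[occupied] / counts[occupied, None]
    return centers


def tmcm_labels(
    patch: Patch | np.ndarray,
    k: int,
    neighborhood_px: int = 3,
    seed: int = 0,
    fit_subsample: int | None = 2048,
    max_iter: int = 10,
) -> np.ndarray:
    """Per-pixel k-means labels of gray-level neighborhood vectors.

    Each pixel is described by the ``neighborhood_px`` x ``neighborhood_px``
    gray values around it (reflect-padded); the vectors are clustered with
    seeded Lloyd k-means and each pixel receives its cluster label.  The
    effective k is capped at the number of distinct neighborhood vectors.
    For speed the clustering may be fitted on a seeded subsample of the
    vectors and then applied to all of them.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    arr = np.asarray(patch.pixels if isinstance(patch, Patch) else patch, dtype=float)
    r = neighborhood_px // 2
    padded = np.pad(arr, r, mode="reflect") if r else arr
    windows = np.lib.stride_tricks.sliding_window_view(padded, (neighborhood_px, neighborhood_px))
    vectors = np.ascontiguousarray(windows.reshape(arr.size, neighborhood_px * neighborhood_px))
    rng = np.random.default_rng(seed)
    if fit_subsample is not None and vectors.shape[0] > fit_subsample:
        idx = rng.choice(vectors.shape[0], size=fit_subsample, replace=False)
        fit_vecs = vectors[idx]
    else:
        fit_vecs = vectors
    centers = _lloyd_kmeans(fit_vecs, k, rng, max_iter)
    if centers.shape[0] < 2:
        return np.zeros(arr.shape, dtype=np.int64)
    labels = _assign(vectors, centers)
    return labels.reshape(arr.shape).astype(np.int64)


def lbp_histogram(
    patch: Patch | np.ndarray,
    radius: float,
    neighbors: int,
    bins: int = 100,
) -> np.ndarray:
    """Compressed local-binary-pattern code histogram.

    For every pixel, ``neighbors`` points on the circle of the given radius
    are sampled with bilinear interpolation and thresholded strictly above
    the center value (bit 1 iff neighbor - center > 0; ties give 0, so a
    constant patch maps to code 0).  A small epsilon guards the strict
    comparison against interpolation round-off, which would otherwise flip
    bits in perfectly flat regions.  The 2^N code histogram is compressed to
    ``bins`` equal-width bins and normalized to sum 1.
    """
    if neighbors > 30:
        raise ValueError("neighbors > 30 would overflow the code integer")
    arr = np.asarray(patch.pixels if isinstance(patch, Patch) else patch, dtype=float)
    h, w = arr.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    codes = np.zeros((h, w), dtype=np.int64)
    eps = 1e-6 * max(float(np.abs(arr).max()), 1.0)
    for j in range(neighbors):
        theta = 2.0 * np.pi * j / neighbors
        dr, dc = -radius * np.sin(theta), radius * np.cos(theta)
        sample = ndimage.map_coordinates(arr, [rows + dr, cols + dc], order=1, mode="reflect")
        codes |= ((sample - arr) > eps).astype(np.int64) << j
    n_codes = 1 << neighbors
    bin_idx = (codes * bins) // n_codes
    hist = np.bincount(bin_idx.ravel(), minlength=bins).astype(float)
    return hist / hist.sum()


_LAWS_1D = {
    "level": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "edge": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "spot": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "wave": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "ripple": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}


def laws_stats(patch: Patch | np.ndarray) -> dict[str, float]:
    """Laws microstructure density and frequency per type (level/edge/spot/wave/ripple).

    Each 5x5 kernel is the outer product of the classic 1-D kernel with
    itself.  Density is the mean absolute filter response; frequency is the
    fraction of pixels whose absolute response exceeds that mean.
    """
    arr = np.asarray(patch.pixels if isinstance(patch, Patch) else patch, dtype=float)
    if min(arr.shape) < 5:
        raise ValueError("patch side must be >= 5 for the 5x5 Laws kernels")
    out: dict[str, float] = {}
    for name, v in _LAWS_1D.items():
        resp = np.abs(ndimage.convolve(arr, np.outer(v, v), mode="reflect"))
        density = float(resp.mean())
        out[f"laws_{name}_density"] = density
        out[f"laws_{name}_frequency"] = float(np.mean(resp > density))
    return out


def edge_features(patch: Patch | np.ndarray, quantile: float = 0.75) -> dict[str, float]:
    """Sobel-based edge frequency, contrast and orientation variability.

    Edge pixels are those with gradient magnitude above the given quantile of
    the magnitude image.  Orientation variability is the circular variance
    (1 - mean resultant length) of the doubled gradient orientations, folding
    the 180-degree ambiguity of edge direction.  A flat patch yields zeros.
    """
    arr = np.asarray(patch.pixels if isinstance(patch, Patch) else patch, dtype=float)
    gr = ndimage.sobel(arr, axis=0, mode="reflect")
    gc = ndimage.sobel(arr, axis=1, mode="reflect")
    mag = np.hypot(gr, gc)
    if mag.max() <= 0:
        return {"edge_frequency": 0.0, "edge_contrast": 0.0, "edge_orientation_variability": 0.0}
    thresh = np.quantile(mag, quantile)
    edges = mag > thresh
    if not edges.any():
        return {"edge_frequency": 0.0, "edge_contrast": 0.0, "edge_orientation_variability": 0.0}
    theta2 = 2.0 * np.arctan2(gr[edges], gc[edges])
    resultant = np.hypot(np.mean(np.cos(theta2)), np.mean(np.sin(theta2)))
    return {
        "edge_frequency": float(edges.mean()),
        "edge_contrast": float(mag[edges].mean()),
        "edge_orientation_variability": float(1.0 - resultant),
    }


def multiscale_stats(
    patch: Patch | np.ndarray,
    wavelet: str = "haar",
    max_lag: int = 8,
) -> dict[str, float]:
    """Hurst index, lag-(1,1) autocorrelation, and wavelet sub-band entropies.

    The Hurst index is half the log-log slope of the isotropic variogram over
    lags 1..``max_lag`` (for fractional Brownian surfaces the squared
    increments scale as h^(2H)).  The autocorrelation index is the circular
    normalized autocorrelation at lag (1, 1).  The wavelet features are
    Shannon entropies of the normalized squared-coefficient distribution of
    the six detail sub-bands of a two-level recursion plus the final
    approximation band.  Zero-variance patches give hurst = autocorr = 0.
    """
    arr = np.asarray(patch.pixels if isinstance(patch, Patch) else patch, dtype=float)
    if min(arr.shape) < 16:
        raise ValueError("patch side must be >= 16 for the two-level wavelet recursion")
    out: dict[str, float] = {}
    centered = arr - arr.mean()
    var_tot = float(np.sum(centered ** 2))
    # variogram slope -> Hurst
    if var_tot <= 0:
        out["hurst_index"] = 0.0
        out["autocorrelation_index"] = 0.0
    else:
        lags = np.arange(1, max_lag + 1)
        gamma = np.empty(len(lags))
        for i, lag in enumerate(lags):
            dh = arr[:, lag:] - arr[:, :-lag]
            dv = arr[lag:, :] - arr[:-lag, :]
            gamma[i] = 0.5 * (np.mean(dh ** 2) + np.mean(dv ** 2))
        if np.any(gamma <= 0):
            out["hurst_index"] = 0.0
        else:
            slope = np.polyfit(np.log(lags), np.log(gamma), 1)[0]
            out["hurst_index"] = float(slope / 2.0)
        shifted = np.roll(np.roll(centered, 1, axis=0), 1, axis=1)
        out["autocorrelation_index"] = float(np.sum(centered * shifted) / var_tot)

    def band_entropy(c: np.ndarray) -> float:
        e = c.astype(float) ** 2
        tot = e.sum()
        if tot <= 0:
            return 0.0
        q = (e / tot).ravel()
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    approx = arr
    for level in (1, 2):
        approx, (ch, cv, cd) = pywt.dwt2(approx, wavelet)
        out[f"wavelet_L{level}_HL_entropy"] = band_entropy(ch)
        out[f"wavelet_L{level}_LH_entropy"] = band_entropy(cv)
        out[f"wavelet_L{level}_HH_entropy"] = band_entropy(cd)
    out["wavelet_L2_LL_entropy"] = band_entropy(approx)
    return out


@dataclass
class TextureConfig:
    """Configuration of the full texture battery (defaults follow the study setup)."""

    median_window_px: int = 3
    glcm_levels: int = 256
    distance: int = 1
    tmcm_ks: tuple[int, ...] = (250, 500)
    tmcm_neighborhood_px: int = 3
    tmcm_fit_subsample: int | None = 2048
    tmcm_max_iter: int = 15
    lbp_configs: tuple[tuple[float, int], ...] = ((1, 8), (2, 16), (3, 24))
    lbp_bins: int = 100
    edge_quantile: float = 0.75
    wavelet: str = "haar"
    seed: int = 0
    order3_configs: tuple[str, ...] = tuple(DISPLACEMENTS_ORDER3)


def _haralick_block(arr, order_n, config_names, levels, distance, prefix, out):
    per_dir = {}
    for cfg in config_names:
        tensor = cooccurrence(arr, order_n, displacement_config=cfg,
                              levels=levels, distance=distance,
                              attribute_domain="gray_level" if "GLCM" in prefix else "cluster_label")
        if tensor.total <= 0:
            feats = {n: 0.0 for n in HARALICK_NAMES}
        else:
            feats = haralick(tensor)
        per_dir[cfg] = feats
        for fname in HARALICK_NAMES:
            out[f"{prefix}_{cfg}_{fname}"] = feats[fname]
    return per_dir


def texture_battery(patch: Patch, config: TextureConfig | None = None) -> dict[str, float]:
    """Run the full texture battery on one patch; returns an ordered name->value dict.

    Naming: ``GLCM_<dir>_<stat>`` for second-order gray-level features,
    ``GLCM3_<dir1>_<dir2>_<stat>`` for third order, ``TMCM<k>...`` for the
    microstructure co-occurrence features, plus direction-averaged summaries
    ``GLCM_<stat>`` and ``TMCM<k>_<stat>`` matching the field's shorthand
    (e.g. TMCM500_contrast).
    """
    config = config or TextureConfig()
    filtered = preprocess(patch, config.median_window_px)
    arr = filtered.pixels.astype(np.int64)
    out: dict[str, float] = {}
    px = filtered.pixels.astype(float)
    out["FO_mean"] = float(px.mean())
    out["FO_min"] = float(px.min())
    out["FO_max"] = float(px.max())

    glcm2 = _haralick_block(arr, 2, DISPLACEMENTS_ORDER2, config.glcm_levels,
                            config.distance, "GLCM", out)
    for fname in HARALICK_NAMES:
        out[f"GLCM_{fname}"] = float(np.mean([glcm2[c][fname] for c in glcm2]))
    _haralick_block(arr, 3, config.order3_configs, config.glcm_levels,
                    config.distance, "GLCM3", out)

    for k in config.tmcm_ks:
        labels = tmcm_labels(filtered, k, config.tmcm_neighborhood_px, seed=config.seed,
                             fit_subsample=config.tmcm_fit_subsample,
                             max_iter=config.tmcm_max_iter)
        levels = int(labels.max()) + 1
        t2 = _haralick_block(labels, 2, DISPLACEMENTS_ORDER2, levels, config.distance,
                             f"TMCM{k}", out)
        for fname in HARALICK_NAMES:
            out[f"TMCM{k}_{fname}"] = float(np.mean([t2[c][fname] for c in t2]))
        _haralick_block(labels, 3, config.order3_configs, levels, config.distance,
                        f"TMCM{k}3", out)

    out.update(multiscale_stats(filtered, wavelet=config.wavelet))
    out.update(edge_features(filtered, quantile=config.edge_quantile))
    out.update(laws_stats(filtered))
    for radius, nbrs in config.lbp_configs:
        hist = lbp_histogram(filtered, radius, nbrs, bins=config.lbp_bins)
        for b, v in enumerate(hist):
            out[f"LBP_r{radius:g}_n{nbrs}_bin{b:03d}"] = float(v)
    return out


def texture_feature_matrix(patches: list[Patch], config: TextureConfig | None = None,
                           progress: bool = False):
    """Texture battery over a patch list as a pandas DataFrame (plus label column)."""
    import pandas as pd

    config = config or TextureConfig()
    rows = []
    for i, p in enumerate(patches):
        if progress and i % 200 == 0:
            print(f"  texture battery: {i}/{len(patches)}", flush=True)
        rows.append(texture_battery(p, config))
    df = pd.DataFrame(rows)
    df["label"] = [p.label for p in patches]
    return df
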