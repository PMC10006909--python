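"""Tests of the texture battery operators.

The co-occurrence implementation is checked against a brute-force n-tuple
enumeration oracle that walks every pixel and offset combination explicitly.
"""

import numpy as np
import pytest

from texfuse.patch_io import Patch
from texfuse.texture import (
    DISPLACEMENTS_ORDER2,
    DISPLACEMENTS_ORDER3,
    TextureConfig,
    _unit,
    cooccurrence,
    edge_features,
    haralick,
    laws_stats,
    lbp_histogram,
    multiscale_stats,
    preprocess,
    texture_battery,
    tmcm_labels,
)


def brute_force_cooccurrence(arr, order_n, config, levels, distance=1):
    """Oracle: explicit loop over every pixel and its displaced companions."""
    table = DISPLACEMENTS_ORDER2 if order_n == 2 else DISPLACEMENTS_ORDER3
    offsets = [_unit(a, distance) for a in table[config]]
    h, w = arr.shape
    counts = {}
    for r in range(h):
        for c in range(w):
            tup = [int(arr[r, c])]
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    ok = False
                    break
                tup.append(int(arr[rr, cc]))
            if ok:
                counts[tuple(tup)] = counts.get(tuple(tup), 0) + 1
    return counts


def tensor_to_dict(t):
    return {tuple(int(v) for v in t.coords[:, m]): int(t.counts[m])
            for m in range(t.counts.size)}


class TestCooccurrence:
    def test_two_by_two_horizontal_pairs(self):
        t = cooccurrence(np.array([[0, 0], [1, 1]]), 2, displacement_config="0", levels=2)
        dense = t.to_dense()
        assert dense[0, 0] == 1 and dense[1, 1] == 1
        assert dense[0, 1] == 0 and dense[1, 0] == 0

    def test_constant_patch_single_cell(self):
        t = cooccurrence(np.full((5, 5), 7), 2, displacement_config="135", levels=8)
        assert t.counts.size == 1
        assert tuple(t.coords[:, 0]) == (7, 7)

    def test_collinear_triple_on_1x3(self):
        t = cooccurrence(np.array([[4, 6, 1]]), 3, displacement_config="0_180", levels=8)
        assert t.total == 1
        # tuple order: (current pixel, neighbor at 0 deg, neighbor at 180 deg)
        assert tuple(t.coords[:, 0]) == (6, 1, 4)

    def test_normalization_sums_to_one(self, rng):
        arr = rng.integers(0, 8, (10, 10))
        t = cooccurrence(arr, 3, displacement_config="45_135", levels=8).normalize()
        assert abs(t.counts.sum() - 1.0) < 1e-9

    def test_unknown_displacement_rejected(self):
        with pytest.raises(ValueError, match="displacement"):
            cooccurrence(np.zeros((4, 4), dtype=int), 2, displacement_config="30")

    @pytest.mark.parametrize("order_n,config", [
        *[(2, c) for c in DISPLACEMENTS_ORDER2],
        *[(3, c) for c in DISPLACEMENTS_ORDER3],
    ])
    def test_matches_brute_force_enumeration(self, order_n, config):
        rng = np.random.default_rng(hash((order_n, config)) % 2**31)
        for _ in range(10):
            h, w = rng.integers(3, 17, size=2)
            arr = rng.integers(0, 6, (h, w))
            t = cooccurrence(arr, order_n, displacement_config=config, levels=6)
            assert tensor_to_dict(t) == brute_force_cooccurrence(arr, order_n, config, 6)


class TestHaralick:
    def test_constant_patch_closed_forms(self):
        t = cooccurrence(np.full((6, 6), 3), 2, displacement_config="0", levels=8)
        h = haralick(t)
        assert h["energy"] == 1.0
        assert h["entropy"] == 0.0
        assert h["contrast"] == 0.0
        assert h["homogeneity"] == 1.0
        assert h["variance"] == 0.0

    def test_checkerboard_horizontal_contrast_is_one(self):
        cb = np.indices((8, 8)).sum(axis=0) % 2
        h = haralick(cooccurrence(cb, 2, displacement_config="0", levels=2))
        assert h["contrast"] == pytest.approx(1.0)

    def test_degenerate_marginal_correlation_is_zero(self):
        # vertical stripes: along direction 0 every pair is (a, b) with fixed parity,
        # and a two-level alphabet leaves the first marginal concentrated when rows repeat
        t = cooccurrence(np.full((4, 4), 1), 2, displacement_config="0", levels=4)
        assert haralick(t)["correlation"] == 0.0

    def test_entropy_zero_iff_energy_one(self, rng):
        for _ in range(10):
            arr = rng.integers(0, 4, (8, 8))
            h = haralick(cooccurrence(arr, 2, displacement_config="90", levels=4))
            assert (h["entropy"] == 0.0) == (h["energy"] == pytest.approx(1.0))

    def test_order3_correlation_is_mean_of_pair_marginals(self):
        arr = np.array([[0, 1, 2, 0], [2, 1, 0, 1], [1, 0, 2, 2], [0, 2, 1, 0]])
        t = cooccurrence(arr, 3, displacement_config="0_90", levels=3).normalize()
        # oracle: build the three 2-D marginals densely and correlate
        dense = np.zeros((3, 3, 3))
        dense[tuple(t.coords)] = t.counts

        def corr2(p):
            i = np.arange(3)
            pa, pb = p.sum(1), p.sum(0)
            mua, mub = i @ pa, i @ pb
            va = ((i - mua) ** 2) @ pa
            vb = ((i - mub) ** 2) @ pb
            if va <= 0 or vb <= 0:
                return 0.0
            return float(np.outer(i - mua, i - mub).ravel() @ p.ravel() / np.sqrt(va * vb))

        expected = np.mean([corr2(dense.sum(2)), corr2(dense.sum(1)), corr2(dense.sum(0))])
        assert haralick(t)["correlation"] == pytest.approx(expected, abs=1e-12)

    def test_empty_tensor_rejected(self):
        t = cooccurrence(np.zeros((1, 1), dtype=int), 2, displacement_config="0", levels=2)
        with pytest.raises(ValueError):
            haralick(t)


class TestPreprocess:
    def test_constant_unchanged(self):
        p = Patch(np.full((8, 8), 9, dtype=np.uint8), "HCC")
        assert np.array_equal(preprocess(p).pixels, p.pixels)

    def test_impulse_removed(self):
        arr = np.full((9, 9), 10, dtype=np.uint8)
        arr[4, 4] = 250
        out = preprocess(Patch(arr, "PAR"))
        assert out.pixels[4, 4] == 10

    def test_matches_sort_based_oracle(self, rng):
        arr = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        out = preprocess(Patch(arr, "HCC"), 3).pixels
        # scipy's "reflect" boundary duplicates the edge sample = np.pad "symmetric"
        padded = np.pad(arr, 1, mode="symmetric")
        for r in range(5):
            for c in range(5):
                window = np.sort(padded[r : r + 3, c : c + 3].ravel())
                assert out[r, c] == window[4]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            preprocess(Patch(np.zeros((4, 4), dtype=np.uint8), "HCC"), 4)


class TestTmcm:
    def test_two_valued_patch_partitions_by_gray(self):
        arr = np.zeros((16, 16), dtype=np.uint8)
        arr[:, 8:] = 200
        labels = tmcm_labels(arr, 2, neighborhood_px=1, seed=0)
        assert len(np.unique(labels[:, :8])) == 1
        assert len(np.unique(labels[:, 8:])) == 1
        assert labels[0, 0] != labels[0, 15]

    def test_determinism(self, tiny_patch_pair):
        hcc, _ = tiny_patch_pair
        a = tmcm_labels(hcc, 250, seed=3)
        b = tmcm_labels(hcc, 250, seed=3)
        assert np.array_equal(a, b)

    def test_k_capped_at_distinct_vectors(self):
        arr = np.zeros((16, 16), dtype=np.uint8)
        arr[:, 8:] = 200
        labels = tmcm_labels(arr, 500, neighborhood_px=1, seed=0)
        assert len(np.unique(labels)) == 2  # only two distinct 1x1 vectors exist

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            tmcm_labels(np.zeros((8, 8), dtype=np.uint8), 1)


class TestLbp:
    def test_constant_patch_all_mass_in_first_bin(self):
        hist = lbp_histogram(np.full((10, 10), 100, dtype=np.uint8), 1, 8)
        assert hist[0] == 1.0
        assert hist[1:].sum() == 0.0

    def test_histogram_sums_to_one(self, rng):
        hist = lbp_histogram(rng.integers(0, 256, (12, 12)).astype(np.uint8), 2, 16)
        assert hist.sum() == pytest.approx(1.0)

    def test_single_bright_center_codes(self):
        """A lone bright pixel: its own code is 0 (every sample darker).

        Hand derivation.  An axis neighbor such as (2, 1) samples the bright
        pixel exactly at its relative angle 0 (bit 0, sample = 200) and also
        through bilinear interpolation at the two adjacent 45-degree samples,
        whose footprints at (2 -+ 0.707, 1.707) put weight 0.293 * 0.707 on the
        bright pixel: code 1 + 2 + 128 = 131.  A diagonal neighbor such as
        (3, 1) samples it only at its exact relative angle 45 deg — the
        axis-angle samples land on dark grid pixels — with bilinear weight
        0.707^2: a single bit, code 2.  The other six codes follow by rotating
        the bit patterns.
        """
        arr = np.full((5, 5), 10.0)
        arr[2, 2] = 200.0
        hist = lbp_histogram(arr, 1, 8, bins=256)  # bins=2^N: one bin per code

        def code_from_bits(*bits):
            return sum(1 << (b % 8) for b in bits)

        expected = {
            (2, 1): code_from_bits(7, 0, 1),   # bright pixel at relative angle 0
            (3, 2): code_from_bits(1, 2, 3),   # at angle 90
            (2, 3): code_from_bits(3, 4, 5),   # at angle 180
            (1, 2): code_from_bits(5, 6, 7),   # at angle 270
            (3, 1): code_from_bits(1),         # at angle 45
            (1, 1): code_from_bits(7),         # at angle 315
            (1, 3): code_from_bits(5),         # at angle 225
            (3, 3): code_from_bits(3),         # at angle 135
        }
        assert expected[(2, 1)] == 131
        for code in expected.values():
            assert hist[code] == pytest.approx(1 / 25)
        assert hist[0] == pytest.approx((25 - 8) / 25)

    def test_invariant_to_affine_rescale(self, rng):
        """Thresholding the sign of sample - center makes the histogram exactly
        invariant to affine gray-level maps (gain and offset)."""
        arr = rng.integers(1, 255, (16, 16)).astype(float)
        affine = 2.5 * arr + 40.0
        for radius, nbrs in ((1, 8), (2, 16), (3, 24)):
            np.testing.assert_allclose(lbp_histogram(arr, radius, nbrs),
                                       lbp_histogram(affine, radius, nbrs))

    def test_near_invariant_to_monotone_gamma(self, rng):
        """Under a nonlinear monotone map, bilinearly interpolated samples can
        flip sign near ties, so invariance is approximate: the total-variation
        distance between histograms stays small."""
        arr = rng.integers(1, 255, (16, 16)).astype(float)
        gamma = (arr / 255.0) ** 0.5 * 255.0
        for radius, nbrs in ((1, 8), (2, 16)):
            tv = 0.5 * np.abs(lbp_histogram(arr, radius, nbrs)
                              - lbp_histogram(gamma, radius, nbrs)).sum()
            assert tv < 0.2

    def test_neighbor_overflow_guard(self):
        with pytest.raises(ValueError, match="overflow"):
            lbp_histogram(np.zeros((8, 8)), 4, 32)


class TestLawsAndEdges:
    def test_constant_patch_zero_sum_kernels(self):
        out = laws_stats(np.full((10, 10), 50, dtype=np.uint8))
        for name in ("edge", "spot", "wave", "ripple"):
            assert out[f"laws_{name}_density"] == 0.0
            assert out[f"laws_{name}_frequency"] == 0.0

    def test_impulse_response_center_coefficient(self):
        arr = np.zeros((11, 11))
        arr[5, 5] = 1.0
        from scipy import ndimage

        kern = np.outer([-1, 0, 2, 0, -1], [-1, 0, 2, 0, -1])  # spot
        resp = ndimage.convolve(arr, kern, mode="reflect")
        assert resp[5, 5] == kern[2, 2]

    def test_frequency_bounded(self, rng):
        out = laws_stats(rng.integers(0, 256, (20, 20)).astype(np.uint8))
        for name in ("level", "edge", "spot", "wave", "ripple"):
            assert 0.0 <= out[f"laws_{name}_frequency"] <= 1.0

    def test_flat_patch_edge_features_zero(self):
        out = edge_features(np.full((12, 12), 77, dtype=np.uint8))
        assert out == {"edge_frequency": 0.0, "edge_contrast": 0.0,
                       "edge_orientation_variability": 0.0}

    def test_vertical_step_zero_orientation_variability(self):
        arr = np.zeros((20, 20))
        arr[:, 10:] = 100.0
        out = edge_features(arr)
        assert out["edge_orientation_variability"] == pytest.approx(0.0, abs=1e-12)
        assert out["edge_frequency"] > 0

    def test_orthogonal_steps_match_circular_closed_form(self):
        """Equal masses at orientations 0 and 90 deg double to 0 and 180: the
        resultant vanishes and the circular variance is exactly 1."""
        arr = np.zeros((40, 40))
        arr[:, 20:] += 100.0
        arr[20:, :] += 100.0
        out = edge_features(arr, quantile=0.5)
        assert out["edge_orientation_variability"] == pytest.approx(1.0, abs=0.05)


def spectral_fbm_surface(h_exp, n, seed):
    """Independent fractional-Brownian-surface sampler via spectral synthesis."""
    rng = np.random.default_rng(seed)
    freq = np.fft.fftfreq(n)
    fx, fy = np.meshgrid(freq, freq)
    radius = np.hypot(fx, fy)
    radius[0, 0] = np.inf  # no DC power
    amplitude = radius ** (-(h_exp + 1.0))
    phase = rng.uniform(0, 2 * np.pi, (n, n))
    spectrum = amplitude * np.exp(1j * phase)
    surf = np.real(np.fft.ifft2(spectrum))
    surf = (surf - surf.min()) / (surf.max() - surf.min()) * 255.0
    return surf


class TestMultiscale:
    def test_constant_patch_detail_entropies_zero(self):
        out = multiscale_stats(np.full((32, 32), 9, dtype=np.uint8))
        for level in (1, 2):
            for band in ("HL", "LH", "HH"):
                assert out[f"wavelet_L{level}_{band}_entropy"] == 0.0
        assert out["hurst_index"] == 0.0
        assert out["autocorrelation_index"] == 0.0

    def test_diagonally_periodic_patch_autocorrelation_one(self):
        base = np.arange(16)
        # constant along the wrapped (1, 1) diagonal: arr[r+1, c+1] == arr[r, c]
        arr = (base[None, :] - base[:, None]) % 16 * 10.0
        out = multiscale_stats(arr)
        assert out["autocorrelation_index"] == pytest.approx(1.0)

    def test_hurst_recovers_fbm_exponent(self):
        """Variogram-slope estimate within +-0.15 of the synthesis exponent
        H=0.7, averaged over 20 independent spectral-synthesis surfaces."""
        estimates = [multiscale_stats(spectral_fbm_surface(0.7, 64, s))["hurst_index"]
                     for s in range(20)]
        assert abs(np.mean(estimates) - 0.7) < 0.15


class TestBattery:
    def test_schema_fixed_and_deterministic(self, tiny_patch_pair):
        hcc, _ = tiny_patch_pair
        a = texture_battery(hcc)
        b = texture_battery(hcc)
        assert list(a) == list(b)
        assert a == b
        assert len(a) == 559
        for key in ("TMCM500_contrast", "GLCM3_45_225_energy", "GLCM_homogeneity",
                    "LBP_r1_n8_bin000", "hurst_index"):
            assert key in a

    def test_difference_features_shift_invariant(self, rng):
        arr = rng.integers(30, 200, (24, 24)).astype(float)
        shifted = arr + 17.0
        a, b = laws_stats(arr), laws_stats(shifted)
        for k in a:
            if "level" in k:  # the level kernel is not zero-sum, so it tracks the mean
                continue
            assert a[k] == pytest.approx(b[k], abs=1e-9)
        a, b = edge_features(arr), edge_features(shifted)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)
        wa = multiscale_stats(arr)
        wb = multiscale_stats(shifted)
        for level in (1, 2):
            for band in ("HL", "LH", "HH"):
                key = f"wavelet_L{level}_{band}_entropy"
                assert wa[key] == pytest.approx(wb[key], abs=1e-9)

    def test_tmcm_contrast_separates_classes(self, small_benchmark):
        """TMCM500 contrast must differ between the synthetic classes with
        |t| > 2 at 100 patches per class."""
        from scipy import stats

        config = TextureConfig(lbp_configs=(), order3_configs=())
        values = {"HCC": [], "PAR": []}
        for p in small_benchmark:
            values[p.label].append(texture_battery(p, config)["TMCM500_contrast"])
        t = stats.ttest_ind(values["HCC"], values["PAR"], equal_var=False).statistic
        assert abs(t) > 2
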