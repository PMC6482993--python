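"""Otsu/Huang threshold selection against brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from oirquant.errors import DegenerateHistogramError, EmptySelectionError
from oirquant.image import Image2D
from oirquant.thresholding import (
    Histogram,
    ThresholdResult,
    apply_threshold,
    build_histogram,
    huang_threshold,
    otsu_threshold,
)

from conftest import random_histogram_counts


def hist_from(counts) -> Histogram:
    c = np.zeros(256, dtype=np.int64)
    for b, n in counts.items():
        c[b] = n
    return Histogram(counts=c)


# ---------------------------------------------------------------- oracles

def otsu_oracle(counts: np.ndarray) -> int:
    """Exhaustive exact-rational argmax of the between-class variance."""
    counts = [int(c) for c in counts]
    total = sum(counts)
    total_s = sum(g * c for g, c in enumerate(counts))
    occ = [g for g, c in enumerate(counts) if c]
    best_t, best = None, Fraction(-1)
    for t in range(occ[0], occ[-1]):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        s0 = sum(g * c for g, c in enumerate(counts[: t + 1]))
        s1 = total_s - s0
        sigma = Fraction((s0 * w1 - s1 * w0) ** 2, w0 * w1)
        if sigma > best:
            best, best_t = sigma, t
    return best_t


def huang_oracle(counts: np.ndarray) -> int:
    """Exhaustive argmin of the fuzzy Shannon entropy, plain-Python loop."""
    counts = [int(c) for c in counts]
    total = sum(counts)
    occ = [g for g, c in enumerate(counts) if c]
    c_range = occ[-1] - occ[0]

    def shannon(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0
        return -u * math.log(u) - (1 - u) * math.log(1 - u)

    best_t, best = None, math.inf
    for t in range(occ[0], occ[-1]):
        w0 = sum(counts[: t + 1])
        s0 = sum(g * c for g, c in enumerate(counts[: t + 1]))
        m0 = s0 / w0
        w1 = total - w0
        m1 = (sum(g * c for g, c in enumerate(counts)) - s0) / w1
        e = 0.0
        for g, c in enumerate(counts):
            if not c:
                continue
            m = m0 if g <= t else m1
            mu = 1.0 / (1.0 + abs(g - m) / c_range)
            e += (c / total) * shannon(mu)
        if e < best:
            best, best_t = e, t
    return best_t


# ---------------------------------------------------------------- histograms

class TestBuildHistogram:
    def test_counts_all_pixels(self, tiny_image):
        h = build_histogram(tiny_image)
        assert h.counts[0] == 2 and h.counts[255] == 2 and h.n_pixels == 4

    def test_mask_restricts_counting(self, tiny_image):
        mask = np.array([[True, True], [False, False]])
        h = build_histogram(tiny_image, mask)
        assert h.counts[0] == 2 and h.n_pixels == 2

    def test_empty_mask_raises(self, tiny_image):
        with pytest.raises(EmptySelectionError):
            build_histogram(tiny_image, np.zeros((2, 2), dtype=bool))

    def test_16bit_minmax_rescaled_to_256_bins(self):
        img = Image2D(np.array([[0, 65535]], dtype=np.uint16), bit_depth=16)
        h = build_histogram(img)
        assert h.counts[0] == 1 and h.counts[255] == 1
        assert h.bin_to_gray(255) == pytest.approx(65535)


# ---------------------------------------------------------------- otsu

class TestOtsu:
    def test_two_equal_masses_tie_break_smallest(self):
        # all t in [50, 199] are optimal; the smallest must win
        assert otsu_threshold(hist_from({50: 7, 200: 7})).t == 50

    def test_extreme_bins(self):
        assert otsu_threshold(hist_from({0: 3, 255: 3})).t == 0

    def test_single_occupied_bin_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(hist_from({100: 10}))

    def test_matches_skimage_on_bimodal(self, rng):
        """Independent cross-check against the scikit-image implementation."""
        from skimage.filters import threshold_otsu

        values = np.concatenate(
            [rng.normal(60, 8, 4000), rng.normal(180, 10, 2000)]
        ).clip(0, 255).astype(np.uint8)
        h = build_histogram(Image2D(values.reshape(60, 100)))
        t = otsu_threshold(h).t
        t_ski = int(threshold_otsu(hist=(h.counts, np.arange(256))))
        assert abs(t - t_ski) <= 1  # conventions differ by at most the bin edge

    @pytest.mark.parametrize("trial", range(120))
    def test_oracle_equivalence(self, trial):
        rng = np.random.default_rng(1000 + trial)
        counts = random_histogram_counts(rng)
        assert otsu_threshold(Histogram(counts=counts)).t == otsu_oracle(counts)


# ---------------------------------------------------------------- huang

class TestHuang:
    def test_two_equal_masses_matches_oracle(self):
        counts = np.zeros(256, dtype=np.int64)
        counts[50] = counts[200] = 5
        assert huang_threshold(Histogram(counts=counts)).t == huang_oracle(counts)

    def test_mirror_symmetric_histogram(self, rng):
        """Objective is mirror-symmetric; the smaller threshold is returned."""
        counts = np.zeros(256, dtype=np.int64)
        occ = rng.choice(120, size=10, replace=False)
        counts[occ] = rng.integers(1, 50, size=10)
        counts += counts[::-1]  # mirror about bin 127.5
        res = huang_threshold(Histogram(counts=counts))
        from oirquant.thresholding import _huang_entropy_curve

        ts, e_vals = _huang_entropy_curve(Histogram(counts=counts))
        mirror_t = 255 - res.t - 1
        e_at = dict(zip(ts.tolist(), e_vals.tolist()))
        assert e_at[res.t] == pytest.approx(e_at[mirror_t], abs=1e-9)
        assert res.t <= mirror_t

    def test_single_occupied_bin_raises(self):
        with pytest.raises(DegenerateHistogramError):
            huang_threshold(hist_from({7: 3}))

    @pytest.mark.parametrize("trial", range(120))
    def test_oracle_equivalence(self, trial):
        rng = np.random.default_rng(2000 + trial)
        counts = random_histogram_counts(rng)
        assert huang_threshold(Histogram(counts=counts)).t == huang_oracle(counts)


# ---------------------------------------------------------------- invariances

@pytest.mark.parametrize("method", [otsu_threshold, huang_threshold])
def test_count_scale_invariance(method, rng):
    for _ in range(10):
        counts = random_histogram_counts(rng)
        k = int(rng.integers(2, 9))
        assert method(Histogram(counts=counts)).t == method(Histogram(counts=counts * k)).t


@pytest.mark.parametrize("method", [otsu_threshold, huang_threshold])
def test_shift_equivariance(method, rng):
    for _ in range(10):
        counts = np.zeros(256, dtype=np.int64)
        bins = rng.choice(100, size=8, replace=False)
        counts[bins] = rng.integers(1, 100, size=8)
        c = int(rng.integers(1, 100))
        shifted = np.zeros(256, dtype=np.int64)
        shifted[bins + c] = counts[bins]
        assert method(Histogram(counts=shifted)).t == method(Histogram(counts=counts)).t + c


# ---------------------------------------------------------------- apply

class TestApplyThreshold:
    def test_polarity_above(self, tiny_image):
        mask = apply_threshold(tiny_image, 0, "above")
        assert mask.tolist() == [[False, False], [True, True]]

    def test_polarity_below_is_complement(self, tiny_image):
        above = apply_threshold(tiny_image, 0, "above")
        below = apply_threshold(tiny_image, 0, "below")
        assert (above ^ below).all()

    def test_partition_for_random_images(self, rng):
        img = Image2D(rng.integers(0, 256, (20, 20)).astype(np.uint8))
        for t in (0, 100, 254):
            a = apply_threshold(img, t, "above")
            b = apply_threshold(img, t, "below")
            assert (a | b).all() and not (a & b).any()

    def test_accepts_threshold_result(self, tiny_image):
        res = ThresholdResult(method="manual", t=0)
        assert apply_threshold(tiny_image, res, "above")[1, 0]
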