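"""Automatic threshold selection on 256-bin gray-level histograms.

Two classic global methods are implemented from scratch because they are the
core of the flatmount pipeline and their exact behaviour (objective, tie
rule) must be testable against brute-force oracles:

* **Otsu** — maximise the between-class variance
  ``sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` of the split into
  background (bins <= t) and foreground (bins > t). The decision is made in
  exact integer arithmetic, so ties are resolved deterministically at the
  smallest optimal ``t``.
* **Huang** — minimise the fuzzy Shannon entropy
  ``E(t) = sum_g p(g) * S(mu_t(g))`` with membership
  ``mu_t(g) = 1 / (1 + |g - m(t, g)| / C)``, where ``m(t, g)`` is the mean
  of the class ``g`` falls into at threshold ``t`` and ``C`` is the occupied
  gray range. ``S(u) = -u ln u - (1 - u) ln(1 - u)`` with the limit value 0
  at ``u`` in {0, 1}.

Both methods search every admissible split exhaustively (256 bins make this
cheap) and return the smallest optimiser, so repeated runs are bit-stable.
16-bit input is min–max rescaled into 256 bins before thresholding and the
affine mapping is recorded on the histogram, mirroring how histogram-based
auto-thresholds are conventionally computed on high-bit-depth images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, EmptySelectionError, FormatError
from .image import Image2D

__all__ = [
    "Histogram",
    "ThresholdResult",
    "build_histogram",
    "otsu_threshold",
    "huang_threshold",
    "apply_threshold",
]

N_BINS = 256


@dataclass(frozen=True)
class Histogram:
    """A 256-bin gray-level histogram with its bin mapping.

    ``gray = gray_min + bin * gray_scale`` recovers the original gray value
    at a bin centre; for 8-bit input the mapping is the identity.
    """

    counts: np.ndarray  # (256,) int64
    gray_min: float = 0.0
    gray_scale: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_BINS,) or (c < 0).any():
            raise ValueError("counts must be 256 nonnegative integers")
        object.__setattr__(self, "counts", c)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def occupied_bins(self) -> np.ndarray:
        return np.flatnonzero(self.counts)

    def bin_to_gray(self, b: float) -> float:
        return self.gray_min + b * self.gray_scale

    def gray_to_bin(self, g: np.ndarray) -> np.ndarray:
        if self.gray_scale == 1.0 and self.gray_min == 0.0:
            return np.asarray(g, dtype=np.int64)
        b = np.rint((np.asarray(g, dtype=np.float64) - self.gray_min) / self.gray_scale)
        return np.clip(b, 0, N_BINS - 1).astype(np.int64)


@dataclass(frozen=True)
class ThresholdResult:
    """A chosen threshold: bins <= t are background, bins > t foreground."""

    method: str  # "otsu" | "huang" | "manual"
    t: int
    objective: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "huang", "manual"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 <= self.t <= N_BINS - 2:
            raise ValueError(f"t must lie in [0, {N_BINS - 2}], got {self.t}")


def build_histogram(image: Image2D, mask: np.ndarray | None = None) -> Histogram:
    """Histogram of an image, optionally restricted to a binary mask.

    16-bit images are min–max rescaled into 256 bins (over the selected
    pixels) and the affine mapping recorded, so thresholds can be reported
    on the original gray scale.
    """
    px = image.pixels
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != px.shape:
            raise FormatError("mask shape does not match image shape")
        values = px[mask]
        if values.size == 0:
            raise EmptySelectionError("mask selects no pixels")
    else:
        values = px.ravel()

    if image.bit_depth == 8:
        counts = np.bincount(values.astype(np.int64), minlength=N_BINS)
        return Histogram(counts=counts[:N_BINS])

    gmin = float(values.min())
    gmax = float(values.max())
    scale = (gmax - gmin) / (N_BINS - 1) if gmax > gmin else 1.0
    bins = np.rint((values.astype(np.float64) - gmin) / scale).astype(np.int64)
    bins = np.clip(bins, 0, N_BINS - 1)
    counts = np.bincount(bins, minlength=N_BINS)
    return Histogram(counts=counts, gray_min=gmin, gray_scale=scale)


def _check_non_degenerate(hist: Histogram) -> np.ndarray:
    occ = hist.occupied_bins
    if occ.size < 2:
        raise DegenerateHistogramError(
            f"histogram has {occ.size} occupied bin(s); need at least 2"
        )
    return occ


def otsu_threshold(hist: Histogram) -> ThresholdResult:
    """Between-class-variance maximising threshold.

    The argmax over ``t`` is decided with exact integer arithmetic
    (``sigma_B^2`` is proportional to ``(S0*W1 - S1*W0)**2 / (W0*W1)`` for
    integer class counts ``W`` and intensity sums ``S``), so mathematically
    tied splits deterministically yield the smallest ``t``.
    """
    occ = _check_non_degenerate(hist)
    counts = [int(c) for c in hist.counts]
    total = sum(counts)
    total_sum = sum(g * c for g, c in zip(range(N_BINS), counts))

    # admissible t: both classes non-empty -> t in [first occupied, last occupied - 1]
    t_lo, t_hi = int(occ[0]), int(occ[-1]) - 1

    best_t = -1
    best_num = -1  # numerator (S0*W1 - S1*W0)^2 * denominator-cross, exact ints
    best_den = 1
    w0 = 0
    s0 = 0
    for t in range(t_lo, t_hi + 1):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        s1 = total_sum - s0
        num = (s0 * w1 - s1 * w0) ** 2
        den = w0 * w1
        # compare num/den > best_num/best_den exactly
        if num * best_den > best_num * den:
            best_num, best_den, best_t = num, den, t
    objective = best_num / best_den / total**2
    return ThresholdResult(method="otsu", t=best_t, objective=objective)


def _huang_entropy_curve(hist: Histogram) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy entropy E(t) for every admissible t. Returns (ts, E)."""
    occ = hist.occupied_bins
    counts = hist.counts.astype(np.float64)
    p = counts / counts.sum()
    g = np.arange(N_BINS, dtype=np.float64)
    c_range = float(occ[-1] - occ[0])
    if c_range == 0.0:  # unreachable past degeneracy check; keep formula total
        c_range = 1.0

    w = np.cumsum(counts)
    s = np.cumsum(g * counts)
    total_w, total_s = w[-1], s[-1]

    ts = np.arange(int(occ[0]), int(occ[-1]))
    e_vals = np.empty(ts.size, dtype=np.float64)
    for i, t in enumerate(ts):
        m0 = s[t] / w[t]
        m1 = (total_s - s[t]) / (total_w - w[t])
        m = np.where(g <= t, m0, m1)
        mu = 1.0 / (1.0 + np.abs(g - m) / c_range)
        # Shannon term with the limit value 0 at mu in {0, 1}
        with np.errstate(divide="ignore", invalid="ignore"):
            s_u = -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)
        s_u[(mu <= 0.0) | (mu >= 1.0)] = 0.0
        e_vals[i] = float(np.dot(p, s_u))
    return ts, e_vals


def huang_threshold(hist: Histogram) -> ThresholdResult:
    """Fuzzy-entropy minimising threshold (smallest minimiser on ties)."""
    _check_non_degenerate(hist)
    ts, e_vals = _huang_entropy_curve(hist)
    i = int(np.argmin(e_vals))  # first occurrence -> smallest t
    return ThresholdResult(method="huang", t=int(ts[i]), objective=float(e_vals[i]))


def apply_threshold(
    image: Image2D,
    t: ThresholdResult | int,
    polarity: str = "above",
    hist: Histogram | None = None,
) -> np.ndarray:
    """Binarise an image at a bin threshold.

    ``polarity="above"`` marks pixels whose bin exceeds ``t`` (the
    foreground convention throughout the package); ``"below"`` marks the
    complement. The histogram supplies the gray-to-bin mapping for 16-bit
    images; without one, the image's own min–max mapping is used.
    """
    if polarity not in ("above", "below"):
        raise ValueError(f"polarity must be 'above' or 'below', got {polarity!r}")
    t_bin = t.t if isinstance(t, ThresholdResult) else int(t)
    if not 0 <= t_bin <= N_BINS - 2:
        raise ValueError(f"threshold bin {t_bin} outside [0, {N_BINS - 2}]")
    if hist is None:
        hist = build_histogram(image)
    bins = hist.gray_to_bin(image.pixels)
    above = bins > t_bin
    return above if polarity == "above" else ~above
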