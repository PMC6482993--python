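"""Four-threshold OIR flatmount pipeline.

Oxygen-induced retinopathy flatmounts are quantified as three areas, each a
percentage of the total retinal area: the central **avascular** zone left by
hyperoxic capillary regression, the **neovascular** tufts (the brightest,
preretinal vessel clumps) and the remaining **normal vascular** area. The
pipeline is driven by four user-adjustable values, each auto-initialised:

1. retina threshold (Huang fuzzy entropy — separates tissue from slide),
2. vascular threshold (Otsu, restricted to retina pixels),
3. neovascular threshold (second-stage Otsu, restricted to vascular pixels),
4. a morphological closing radius that absorbs inter-capillary gaps before
   the avascular zone is taken as the complement of the closed vasculature.

Deriving avascular as a complement (rather than thresholding it directly)
guarantees ``avascular + vascular = retina``, which the subtraction formula
``normal = total vascular − neovascular`` presupposes; percentages are
computed with exact rational arithmetic on pixel counts so the three classes
always sum to exactly 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.ndimage as ndi

from .errors import (
    DegenerateHistogramError,
    EmptyRetinaError,
    MaskHierarchyError,
)
from .image import Image2D
from .thresholding import (
    Histogram,
    ThresholdResult,
    apply_threshold,
    build_histogram,
    huang_threshold,
    otsu_threshold,
)

__all__ = [
    "OirConfig",
    "OirMaskSet",
    "OirAreaReport",
    "segment_retina",
    "segment_vasculature",
    "segment_neovascular",
    "derive_avascular",
    "compute_area_report",
    "run_oir_select",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass(frozen=True)
class OirConfig:
    """The four user-adjustable values plus housekeeping parameters.

    Thresholds are 256-bin indices; ``"auto"`` selects Huang (retina) or
    Otsu (vascular, neovascular). ``closing_radius`` is the structuring-disc
    radius in pixels used to absorb inter-capillary gaps; it should exceed
    half the typical capillary spacing. ``min_tuft_contrast`` guards the
    second-stage Otsu: if the within-vessel class separation (in bins) falls
    below it, the image is declared tuft-free.
    """

    t_retina: int | str = "auto"
    t_vascular: int | str = "auto"
    t_neovascular: int | str = "auto"
    closing_radius: int = 8
    min_object_px: int = 30
    min_tuft_contrast: float = 25.0
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_retina", "t_vascular", "t_neovascular"):
            v = getattr(self, name)
            if v != "auto" and not (isinstance(v, (int, np.integer)) and 0 <= v <= 254):
                raise ValueError(f"{name} must be 'auto' or an int in [0, 254]")
        if self.closing_radius < 0 or self.min_object_px < 0:
            raise ValueError("closing_radius and min_object_px must be >= 0")


@dataclass(frozen=True)
class OirMaskSet:
    """The four masks of one flatmount; nested as NV ⊆ V ⊆ R, AV ⊆ R."""

    retina: np.ndarray
    vascular: np.ndarray
    neovascular: np.ndarray
    avascular: np.ndarray

    def validate(self) -> None:
        r, v, nv, av = self.retina, self.vascular, self.neovascular, self.avascular
        if not (r.shape == v.shape == nv.shape == av.shape):
            raise MaskHierarchyError("mask shapes differ")
        if (v & ~r).any():
            raise MaskHierarchyError("vascular not contained in retina")
        if (nv & ~v).any():
            raise MaskHierarchyError("neovascular not contained in vascular")
        if (av & ~r).any():
            raise MaskHierarchyError("avascular not contained in retina")
        if (av & v).any():
            raise MaskHierarchyError("avascular overlaps vascular")


@dataclass(frozen=True)
class OirAreaReport:
    """Percent-of-retina area accounting for one flatmount.

    The three percentages are stored as exact :class:`~fractions.Fraction`
    of pixel counts (``*_frac``) alongside float views; the fractions sum to
    exactly 100.
    """

    retina_px: int
    retina_um2: float | None
    avascular_frac: Fraction
    neovascular_frac: Fraction
    thresholds: dict = field(default_factory=dict)

    @property
    def normal_vascular_frac(self) -> Fraction:
        return Fraction(100) - self.avascular_frac - self.neovascular_frac

    @property
    def avascular_pct(self) -> float:
        return float(self.avascular_frac)

    @property
    def neovascular_pct(self) -> float:
        return float(self.neovascular_frac)

    @property
    def normal_vascular_pct(self) -> float:
        return float(self.normal_vascular_frac)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 0 or not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=_STRUCT8)
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(labels, keep)


def segment_retina(image: Image2D, cfg: OirConfig) -> tuple[np.ndarray, ThresholdResult]:
    """Whole-retina mask: Huang threshold, despeckle, hole fill, largest component.

    A radius-1 opening between thresholding and component selection kills
    isolated noise speckles; without it, near-percolating background noise
    can fuse with the retina into one giant component when the threshold
    sits at the edge of the background mode.
    """
    hist = build_histogram(image)
    if cfg.t_retina == "auto":
        thr = huang_threshold(hist)
    else:
        thr = ThresholdResult(method="manual", t=int(cfg.t_retina))
    mask = apply_threshold(image, thr, "above", hist)
    if not mask.any():
        raise EmptyRetinaError("no foreground after retina thresholding")
    mask = ndi.binary_opening(mask, structure=_STRUCT8)
    if not mask.any():
        raise EmptyRetinaError("no foreground after retina despeckling")
    mask = ndi.binary_fill_holes(mask)
    mask = _largest_component(mask)
    return mask, thr


def segment_vasculature(
    image: Image2D, retina: np.ndarray, cfg: OirConfig
) -> tuple[np.ndarray, ThresholdResult]:
    """Vascular mask: Otsu on the within-retina histogram, speck removal."""
    if not retina.any():
        raise EmptyRetinaError("retina mask is empty")
    hist = build_histogram(image, mask=retina)
    if cfg.t_vascular == "auto":
        thr = otsu_threshold(hist)
    else:
        thr = ThresholdResult(method="manual", t=int(cfg.t_vascular))
    mask = apply_threshold(image, thr, "above", hist) & retina
    mask = _remove_small(mask, cfg.min_object_px)
    return mask, thr


def segment_neovascular(
    image: Image2D, vascular: np.ndarray, cfg: OirConfig
) -> tuple[np.ndarray, ThresholdResult | None]:
    """Tuft mask: second-stage Otsu restricted to vascular pixels.

    Tufts are the brightest vascular structures; if the Otsu class
    separation within the vessels is below ``min_tuft_contrast`` bins the
    split is judged to be noise and the empty mask is returned.
    """
    if not vascular.any():
        return np.zeros_like(vascular), None
    hist = build_histogram(image, mask=vascular)
    if cfg.t_neovascular == "auto":
        try:
            thr = otsu_threshold(hist)
        except DegenerateHistogramError:
            return np.zeros_like(vascular), None
        counts = hist.counts.astype(np.float64)
        g = np.arange(counts.size)
        w0 = counts[: thr.t + 1].sum()
        w1 = counts[thr.t + 1 :].sum()
        mu0 = (g[: thr.t + 1] * counts[: thr.t + 1]).sum() / w0
        mu1 = (g[thr.t + 1 :] * counts[thr.t + 1 :]).sum() / w1
        if (mu1 - mu0) < cfg.min_tuft_contrast:
            return np.zeros_like(vascular), None
    else:
        thr = ThresholdResult(method="manual", t=int(cfg.t_neovascular))
    mask = apply_threshold(image, thr, "above", hist) & vascular
    mask = _remove_small(mask, cfg.min_object_px)
    return mask, thr


def derive_avascular(
    retina: np.ndarray, vascular: np.ndarray, cfg: OirConfig
) -> np.ndarray:
    """Avascular zone: retina minus the morphologically closed vasculature.

    Closing with a disc of ``closing_radius`` absorbs inter-capillary gaps
    so only genuinely vessel-free territory survives the complement.
    """
    if (vascular & ~retina).any():
        raise MaskHierarchyError("vascular mask extends outside retina")
    if cfg.closing_radius > 0 and vascular.any():
        r = cfg.closing_radius
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        disc = (yy * yy + xx * xx) <= r * r
        # pad so the closing stays extensive at the array border
        padded = np.pad(vascular, r, constant_values=False)
        closed = ndi.binary_closing(padded, structure=disc)[r:-r, r:-r]
    else:
        closed = vascular
    return retina & ~closed


def compute_area_report(
    masks: OirMaskSet, cfg: OirConfig, thresholds: dict | None = None
) -> OirAreaReport:
    """Exact percent-of-retina accounting from pixel counts."""
    masks.validate()
    n_r = int(masks.retina.sum())
    if n_r == 0:
        raise EmptyRetinaError("retina mask is empty")
    n_av = int(masks.avascular.sum())
    n_nv = int(masks.neovascular.sum())
    if n_av + n_nv > n_r:
        raise MaskHierarchyError("avascular + neovascular exceed retina")
    um2 = n_r * cfg.um_per_px**2 if cfg.um_per_px else None
    return OirAreaReport(
        retina_px=n_r,
        retina_um2=um2,
        avascular_frac=Fraction(100 * n_av, n_r),
        neovascular_frac=Fraction(100 * n_nv, n_r),
        thresholds=dict(thresholds or {}),
    )


def run_oir_select(image: Image2D, cfg: OirConfig | None = None) -> tuple[OirMaskSet, OirAreaReport]:
    """Full pipeline: retina → vascular → neovascular → avascular → report.

    All auto thresholds actually used are recorded in the report's
    ``thresholds`` dict, so a run can be repeated exactly with manual values.
    After the avascular complement is taken, the effective vascular area is
    redefined as ``retina − avascular`` so the three classes partition the
    retina exactly.
    """
    cfg = cfg or OirConfig()
    retina, t_ret = segment_retina(image, cfg)
    vascular_raw, t_vas = segment_vasculature(image, retina, cfg)
    neovascular, t_nv = segment_neovascular(image, vascular_raw, cfg)
    avascular = derive_avascular(retina, vascular_raw, cfg)
    vascular = retina & ~avascular  # reconciled partition
    masks = OirMaskSet(
        retina=retina, vascular=vascular, neovascular=neovascular, avascular=avascular
    )
    thresholds = {
        "t_retina": t_ret.t,
        "t_vascular": t_vas.t,
        "t_neovascular": None if t_nv is None else t_nv.t,
        "closing_radius": cfg.closing_radius,
    }
    report = compute_area_report(masks, cfg, thresholds)
    return masks, report
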