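"""Skeleton-based vascular-network metrics.

Given a binary vessel mask, three whole-network descriptors are computed
from its topology-preserving skeleton:

* **total vessel length** — chain length over skeleton adjacency: 1 per
  axial step, √2 per diagonal step, each edge counted once, times the
  μm-per-pixel calibration;
* **branching index** — junctions (skeleton pixels with ≥3 skeleton
  neighbours, 8-connected clusters merged into one junction) per mm² of
  analyzed area;
* **lacunarity** — the gliding-box statistic Λ(r) = var(M_r)/mean(M_r)²
  of foreground mass in r×r windows (stride 1), averaged over a dyadic
  ladder of box sizes, describing the gappiness of the pattern.

Note the chain-length rule is exact for axial and 45° runs but, like any
chain-code estimator, overestimates intermediate angles by up to ~8%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize

from .errors import UndefinedLacunarityError

__all__ = [
    "VesselMetrics",
    "skeletonize",
    "vessel_length",
    "junction_count",
    "junction_density",
    "lacunarity",
    "compute_vessel_metrics",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class VesselMetrics:
    total_length_um: float
    n_junctions: int
    branching_index_per_mm2: float
    lacunarity: float


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to 1-pixel-wide, 8-connected centrelines."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _skimage_skeletonize(mask)


def _edge_counts(skel: np.ndarray) -> tuple[int, int]:
    """Count axial and diagonal adjacency edges, each pair once."""
    axial = int((skel[:, :-1] & skel[:, 1:]).sum()) + int((skel[:-1, :] & skel[1:, :]).sum())
    diag = int((skel[:-1, :-1] & skel[1:, 1:]).sum()) + int((skel[:-1, 1:] & skel[1:, :-1]).sum())
    return axial, diag


def vessel_length(skel: np.ndarray, um_per_px: float = 1.0) -> float:
    """Total centreline length in μm (chain length over skeleton edges)."""
    skel = np.asarray(skel, dtype=bool)
    axial, diag = _edge_counts(skel)
    return (axial + np.sqrt(2.0) * diag) * um_per_px


def junction_count(skel: np.ndarray) -> int:
    """Number of junctions: ≥3-neighbour pixels, adjacent ones merged."""
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        return 0
    neighbours = ndi.convolve(skel.astype(np.int8), _STRUCT8.astype(np.int8), mode="constant") - skel
    junction_px = skel & (neighbours >= 3)
    _, n = ndi.label(junction_px, structure=_STRUCT8)
    return int(n)


def junction_density(skel: np.ndarray, area_mm2: float) -> float:
    """Branching index: junctions per mm² of analyzed area."""
    if not area_mm2 > 0:
        raise ValueError("area_mm2 must be strictly positive")
    return junction_count(skel) / area_mm2


def _box_masses(mask: np.ndarray, r: int) -> np.ndarray:
    """Foreground counts in every fully interior r×r window (stride 1)."""
    ii = np.pad(np.cumsum(np.cumsum(mask, axis=0), axis=1), ((1, 0), (1, 0)))
    return ii[r:, r:] - ii[:-r, r:] - ii[r:, :-r] + ii[:-r, :-r]


def lacunarity(mask: np.ndarray, box_sizes: list[int] | None = None) -> float:
    """Mean gliding-box lacunarity over a ladder of box sizes.

    Default ladder: powers of 2 from 2 up to ``min(shape) // 4``. Λ(r) is 0
    for a uniform mask (zero variance) and grows with gappiness.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UndefinedLacunarityError("lacunarity is undefined for an empty mask")
    min_dim = min(mask.shape)
    if box_sizes is None:
        box_sizes = []
        r = 2
        while r <= max(min_dim // 4, 2):
            box_sizes.append(r)
            r *= 2
    if any(r < 1 or r > min_dim for r in box_sizes):
        raise ValueError("box sizes must lie in [1, min image dimension]")
    lam = []
    for r in box_sizes:
        m = _box_masses(mask.astype(np.int64), r).ravel()
        mean = m.mean()
        lam.append(float(m.var() / mean**2) if mean > 0 else 0.0)
    return float(np.mean(lam))


def compute_vessel_metrics(
    mask: np.ndarray,
    um_per_px: float = 1.0,
    analyzed_area_px: int | None = None,
    box_sizes: list[int] | None = None,
) -> VesselMetrics:
    """All three network metrics for one vessel mask.

    ``analyzed_area_px`` defaults to the full image area; pass the retina
    mask area when available so densities are comparable across crops.
    """
    mask = np.asarray(mask, dtype=bool)
    skel = skeletonize(mask)
    area_px = analyzed_area_px if analyzed_area_px is not None else mask.size
    area_mm2 = area_px * (um_per_px / 1000.0) ** 2
    n_j = junction_count(skel)
    return VesselMetrics(
        total_length_um=vessel_length(skel, um_per_px),
        n_junctions=n_j,
        branching_index_per_mm2=n_j / area_mm2,
        lacunarity=lacunarity(mask, box_sizes),
    )
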