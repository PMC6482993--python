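"""Phospho-kinase membrane array densitometry and statistics.

Each membrane carries capture-antibody spots in duplicate (43 targets in the
default layout) plus positive-control reference spots. Quantification is:

1. per-spot integrated density = disc sum − disc area × median of a
   background annulus, floored at 0 (median resists bleed from neighbours);
2. per-target raw density = mean of the two duplicates;
3. per-membrane normalization: raw × (reference constant / this membrane's
   mean reference-spot density) — with the control membrane's reference
   mean as the constant, this cancels exposure differences between
   membranes;
4. fold change = treated / control per target;
5. per-target one-way F-test across treatment groups with Benjamini–
   Hochberg false-discovery-rate adjustment.

The arcsine (angular) transform ``asin(sqrt(p/100))`` used on percentage
endpoints before parametric testing also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, NormalizationError
from .image import Image2D

__all__ = [
    "SpotGrid",
    "ArrayResult",
    "integrate_spot",
    "quantify_membrane",
    "fold_changes",
    "per_target_test",
    "bh_adjust",
    "arcsine_transform",
    "analyze_membranes",
]


@dataclass(frozen=True)
class SpotGrid:
    """Membrane layout: duplicate spots per target plus reference spots.

    ``spots`` is a DataFrame with columns ``target``, ``spot_index`` (1|2),
    ``row_px``, ``col_px``, ``is_reference``. Geometry (integration disc
    radius, background-annulus radii) is shared by all spots.
    """

    spots: pd.DataFrame
    spot_radius: float = 10.0
    annulus_inner: float = 12.0
    annulus_outer: float = 16.0

    def __post_init__(self) -> None:
        df = self.spots
        required = {"target", "spot_index", "row_px", "col_px", "is_reference"}
        if not required.issubset(df.columns):
            raise ValueError(f"grid missing columns {required - set(df.columns)}")
        per_target = df.groupby("target")["spot_index"].count()
        if not (per_target == 2).all():
            bad = per_target[per_target != 2].index.tolist()
            raise ValueError(f"each target needs exactly 2 spots; offending: {bad}")
        if not df["is_reference"].any():
            raise ValueError("grid needs at least one reference spot")
        if not self.annulus_outer > self.annulus_inner >= self.spot_radius:
            raise ValueError("need annulus_outer > annulus_inner >= spot_radius")

    @classmethod
    def from_entries(cls, entries, **geometry) -> "SpotGrid":
        df = pd.DataFrame(
            entries, columns=["target", "spot_index", "row_px", "col_px", "is_reference"]
        )
        return cls(spots=df, **geometry)

    @classmethod
    def from_csv(cls, path, **geometry) -> "SpotGrid":
        df = pd.read_csv(path)
        df["is_reference"] = df["is_reference"].astype(bool)
        return cls(spots=df, **geometry)

    def to_csv(self, path) -> None:
        self.spots.to_csv(path, index=False)

    @property
    def targets(self) -> list[str]:
        df = self.spots
        return sorted(df.loc[~df["is_reference"], "target"].unique())


@dataclass(frozen=True)
class ArrayResult:
    """Per-target results of a multi-membrane comparison."""

    table: pd.DataFrame  # target, fold_change, p_value, p_adjusted, significant


def integrate_spot(
    image: Image2D,
    center: tuple[float, float],
    radius: float,
    annulus: tuple[float, float],
) -> float:
    """Background-subtracted integrated density of one spot.

    ``sum(disc) - disc_area * median(annulus)``, floored at 0.
    """
    r0, c0 = center
    ri, ro = annulus
    h, w = image.shape
    if not (r0 - ro >= 0 and r0 + ro < h and c0 - ro >= 0 and c0 + ro < w):
        raise FormatError(f"spot at ({r0}, {c0}) with annulus radius {ro} out of bounds")
    lo_r, hi_r = int(np.floor(r0 - ro)), int(np.ceil(r0 + ro)) + 1
    lo_c, hi_c = int(np.floor(c0 - ro)), int(np.ceil(c0 + ro)) + 1
    win = image.pixels[lo_r:hi_r, lo_c:hi_c].astype(np.float64)
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d2 = (yy - r0) ** 2 + (xx - c0) ** 2
    disc = d2 <= radius**2
    ann = (d2 >= ri**2) & (d2 <= ro**2)
    density = win[disc].sum() - disc.sum() * float(np.median(win[ann]))
    return max(density, 0.0)


def quantify_membrane(
    image: Image2D,
    grid: SpotGrid,
    reference_constant: float | None = None,
) -> pd.Series:
    """Normalized per-target densities for one membrane.

    Raw per-target density is the duplicate mean; normalization multiplies
    by ``reference_constant / reference_mean`` where ``reference_mean`` is
    this membrane's mean reference-spot density. With ``reference_constant``
    left as ``None`` the reference mean itself is used as the constant's
    stand-in (densities are then expressed relative to the references);
    pass the control membrane's reference mean to compare across membranes.
    """
    per_spot = grid.spots.apply(
        lambda s: integrate_spot(
            image,
            (float(s["row_px"]), float(s["col_px"])),
            grid.spot_radius,
            (grid.annulus_inner, grid.annulus_outer),
        ),
        axis=1,
    )
    df = grid.spots.assign(density=per_spot)
    ref_mean = float(df.loc[df["is_reference"], "density"].mean())
    if ref_mean <= 0:
        raise NormalizationError("reference spots integrate to zero; cannot normalize")
    scale = (reference_constant / ref_mean) if reference_constant is not None else (1.0 / ref_mean)
    raw = df.loc[~df["is_reference"]].groupby("target")["density"].mean()
    out = (raw * scale).sort_index()
    out.attrs["reference_mean"] = ref_mean
    return out


def fold_changes(treated: pd.Series, control: pd.Series) -> pd.Series:
    """Per-target fold change treated/control; NaN where control is 0."""
    if set(treated.index) != set(control.index):
        raise ValueError("treated and control target sets differ")
    control = control.reindex(treated.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = treated / control
    return fc.where(control > 0, np.nan)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``q(i) = min_{j >= i} min(1, p(j) * m / j)`` on the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def per_target_test(groups: dict[str, pd.DataFrame]) -> pd.Series:
    """One-way F-test per target across treatment groups.

    ``groups`` maps group name → DataFrame (replicate membranes × targets).
    Requires ≥2 groups and ≥2 replicates in each.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    frames = list(groups.values())
    targets = frames[0].columns
    for name, df in groups.items():
        if len(df) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
        if set(df.columns) != set(targets):
            raise ValueError("groups disagree on target sets")
    pvals = {}
    for t in targets:
        samples = [df[t].to_numpy(dtype=np.float64) for df in frames]
        if np.ptp(np.concatenate(samples)) == 0:  # constant target: no evidence
            pvals[t] = 1.0
            continue
        _, p = stats.f_oneway(*samples)
        pvals[t] = 1.0 if np.isnan(p) else float(p)
    return pd.Series(pvals).reindex(targets)


def arcsine_transform(pct):
    """Angular transform of a percentage: ``asin(sqrt(p/100))`` in radians."""
    p = np.asarray(pct, dtype=np.float64)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(p / 100.0))
    return float(out) if np.isscalar(pct) else out


def analyze_membranes(
    group_images: dict[str, list[Image2D]],
    grid: SpotGrid,
    control_group: str,
    alpha: float = 0.05,
) -> ArrayResult:
    """End-to-end comparison of replicate membranes across groups.

    Every membrane is normalized to the first control membrane's reference
    mean; per-target fold changes are group means relative to the control
    group; p-values come from the per-target F-test, BH-adjusted.
    """
    if control_group not in group_images:
        raise ValueError(f"control group {control_group!r} not among groups")
    ctrl0 = quantify_membrane(group_images[control_group][0], grid)
    ref_const = ctrl0.attrs["reference_mean"]
    quantified = {
        g: pd.DataFrame([quantify_membrane(im, grid, ref_const) for im in ims])
        for g, ims in group_images.items()
    }
    pvals = per_target_test(quantified)
    padj = pd.Series(bh_adjust(pvals.to_numpy()), index=pvals.index)
    ctrl_mean = quantified[control_group].mean()
    rows = []
    for g, df in quantified.items():
        if g == control_group:
            continue
        fc = fold_changes(df.mean(), ctrl_mean)
        for t in pvals.index:
            rows.append(
                {
                    "group": g,
                    "target": t,
                    "fold_change": fc[t],
                    "p_value": pvals[t],
                    "p_adjusted": padj[t],
                    "significant": padj[t] <= alpha,
                }
            )
    return ArrayResult(table=pd.DataFrame(rows))
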