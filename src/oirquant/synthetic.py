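"""Seeded synthetic phantoms with exact ground truth.

Animal images behind OIR, CNV and membrane-array experiments are never
deposited, so every pipeline in this package is validated against seeded
phantoms that emulate the geometry and intensity ordering of the real data:

* **Flatmount** — a bright retina disc with petal-cut dissection wedges on a
  dark background; a stochastic vessel tree grown outward from the edge of
  a central avascular zone (sized to a requested area fraction); bright
  neovascular tufts clustered at the ischemic border (sized to a requested
  fraction); Gaussian noise and a smooth multiplicative illumination
  gradient. Default fractions follow the typical P17 OIR control retina:
  ~40% avascular, ~20% neovascular, ~40% normal vascular.
* **CNV stack** — an ellipsoidal bright lesion inside a spherical burn
  region in a 3D stack at 1.5 μm z-spacing.
* **Array membrane** — Gaussian-profile chemiluminescent spots, 43 targets
  in duplicate plus reference (positive-control) spots, with background
  offset and noise.

Every generator takes an integer seed and is bit-reproducible; ground-truth
masks/volumes/densities are returned alongside the images.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .image import Image2D, Stack3D

__all__ = [
    "FlatmountSpec",
    "CnvStackSpec",
    "MembraneSpec",
    "FlatmountTruth",
    "CnvTruth",
    "MembraneTruth",
    "MembraneStudyTruth",
    "generate_flatmount",
    "generate_cnv_stack",
    "generate_array_membrane",
    "generate_membrane_study",
    "default_grid_layout",
]


# --------------------------------------------------------------------------
# flatmount
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FlatmountSpec:
    """Parameters of a synthetic OIR flatmount.

    Intensity levels must be ordered background < tissue < vessel < tuft
    (tuft = vessel * tuft_multiplier, clipped to the dynamic range); the
    requested area fractions must satisfy ``f_av + f_nv < 1``.
    """

    seed: int = 0
    size: tuple[int, int] = (512, 512)
    retina_radius: int = 230
    petal_count: int = 4
    petal_angle_deg: float = 18.0
    petal_depth: float = 0.55  # cuts reach inward to this fraction of the radius
    f_av: float = 0.40
    f_nv: float = 0.20
    n_trunks_per_px: float = 1 / 5.0  # vessel walkers per pixel of circumference
    vessel_width: int = 3
    tuft_radius_range: tuple[int, int] = (4, 8)
    tuft_radial_sd: float = 15.0
    background_level: int = 12
    tissue_level: int = 60
    vessel_level: int = 140
    tuft_multiplier: float = 1.6
    noise_sd: float = 4.0
    illumination_amplitude: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.f_av < 1 and 0 <= self.f_nv < 1 and self.f_av + self.f_nv < 1):
            raise ValueError("need f_av, f_nv in [0, 1) with f_av + f_nv < 1")
        lv = (self.background_level, self.tissue_level, self.vessel_level)
        if not lv[0] < lv[1] < lv[2]:
            raise ValueError("intensity levels must be ordered background < tissue < vessel")
        if self.tuft_multiplier <= 1.0:
            raise ValueError("tuft_multiplier must exceed 1")


@dataclass(frozen=True)
class FlatmountTruth:
    retina: np.ndarray
    vascular: np.ndarray
    neovascular: np.ndarray
    avascular: np.ndarray
    f_av_realized: float
    f_nv_realized: float


def _disc_stamp(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def _stamp(mask: np.ndarray, r: int, c: int, disc: np.ndarray) -> None:
    """Paint a disc into a boolean mask, clipping at borders."""
    rad = disc.shape[0] // 2
    h, w = mask.shape
    r0, r1 = max(r - rad, 0), min(r + rad + 1, h)
    c0, c1 = max(c - rad, 0), min(c + rad + 1, w)
    mask[r0:r1, c0:c1] |= disc[r0 - (r - rad) : r1 - (r - rad), c0 - (c - rad) : c1 - (c - rad)]


def _grow_vessels(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center: tuple[float, float],
    r_start: float,
    r_stop: float,
    spec: FlatmountSpec,
) -> np.ndarray:
    """Stochastic branching random walk from the avascular border outward.

    Trunks are seeded around the border circumference at roughly constant
    spacing; each walker steps outward with angular wander and may branch,
    which keeps the inter-capillary spacing roughly constant with radius —
    the feature the closing-radius step of the pipeline must absorb.
    """
    mask = np.zeros(shape, dtype=bool)
    disc = _disc_stamp(max(spec.vessel_width // 2, 1))
    # trunk count floored at the 30-px circumference so growth from a small
    # (or absent) avascular zone still fans out in all directions
    n_trunks = max(int(round(2 * np.pi * max(r_start, 30.0) * spec.n_trunks_per_px)), 8)
    cy, cx = center

    angles = (np.arange(n_trunks) + rng.uniform(0, 1, n_trunks)) * (2 * np.pi / n_trunks)
    # each walker: (y, x, direction); direction starts radial
    walkers = [(cy + r_start * np.sin(a), cx + r_start * np.cos(a), a) for a in angles]
    max_steps = int(4 * (r_stop - r_start)) + 100  # hard bound on the growth front
    for _ in range(max_steps):
        if not walkers:
            break
        new_walkers = []
        radii = []
        for y, x, d in walkers:
            # one step; wander around the radial direction
            d += rng.normal(0.0, 0.2)
            radial = np.arctan2(y - cy, x - cx)
            # soft pull back toward radial so walkers head outward
            delta = (radial - d + np.pi) % (2 * np.pi) - np.pi
            d += 0.3 * delta
            y += np.sin(d)
            x += np.cos(d)
            rr = np.hypot(y - cy, x - cx)
            if rr >= r_stop or not (0 <= y < shape[0] and 0 <= x < shape[1]):
                continue
            if rr >= r_start - 1:
                _stamp(mask, int(round(y)), int(round(x)), disc)
            new_walkers.append((y, x, d))
            radii.append(rr)
        # adaptive branching: clone interior walkers until the population
        # matches the count that keeps inter-vessel spacing constant at the
        # current mean radius; walkers at the rim are not cloned, so the
        # population dies out once the whole growth front reaches the edge
        if new_walkers:
            mean_r = float(np.mean(radii))
            target = int(round(2 * np.pi * mean_r * spec.n_trunks_per_px))
            interior = [w for w, rr in zip(new_walkers, radii) if rr < r_stop - 3]
            while interior and len(new_walkers) < target:
                # sprout into the widest angular gap of the walker population
                # so the plexus fills the full circumference instead of braiding
                phis = np.sort([np.arctan2(y - cy, x - cx) for y, x, _ in new_walkers])
                gaps = np.diff(np.append(phis, phis[0] + 2 * np.pi))
                gap_lo = phis[int(np.argmax(gaps))]
                gap_target = gap_lo + gaps.max() / 2.0
                # parent: interior walker angularly closest to the gap centre
                phi_int = np.array([np.arctan2(y - cy, x - cx) for y, x, _ in interior])
                dphi = (gap_target - phi_int + np.pi) % (2 * np.pi) - np.pi
                y, x, d = interior[int(np.argmin(np.abs(dphi)))]
                turn = np.sign(dphi[int(np.argmin(np.abs(dphi)))]) or 1.0
                new_walkers.append((y, x, d + turn * rng.uniform(0.35, 0.7)))
        walkers = new_walkers
    return mask


def generate_flatmount(spec: FlatmountSpec | None = None, seed: int | None = None):
    """Render a flatmount phantom. Returns ``(Image2D, FlatmountTruth)``.

    The avascular-zone radius is calibrated by quantile so the realized
    avascular fraction matches the request exactly at pixel resolution;
    tufts are accumulated until the requested neovascular fraction is
    reached, so realized fractions sit within ±2 percentage points of the
    request.
    """
    spec = spec or FlatmountSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    # retina disc with petal-cut wedges removed from the outer zone
    retina = rr <= spec.retina_radius
    half = np.deg2rad(spec.petal_angle_deg) / 2.0
    cut_phase = rng.uniform(0, 2 * np.pi)
    for k in range(spec.petal_count):
        a = cut_phase + k * 2 * np.pi / max(spec.petal_count, 1)
        d = np.abs((theta - a + np.pi) % (2 * np.pi) - np.pi)
        retina &= ~((d < half) & (rr > spec.petal_depth * spec.retina_radius))
    n_retina = int(retina.sum())

    # neovascular tufts: blobs clustered around the nominal ischemic border
    r_av_nominal = np.sqrt(spec.f_av * n_retina / np.pi)
    tufts = np.zeros((h, w), dtype=bool)
    target_nv = int(round(spec.f_nv * n_retina))
    lo, hi = spec.tuft_radius_range
    guard = 0
    while int((tufts & retina).sum()) < target_nv and guard < 20000:
        guard += 1
        ang = rng.uniform(0, 2 * np.pi)
        # tufts garland the ischemic border, mostly on its vascular side
        rad = r_av_nominal + abs(rng.normal(0, spec.tuft_radial_sd))
        trad = int(rng.integers(lo, hi + 1))
        _stamp(tufts, int(round(cy + rad * np.sin(ang))), int(round(cx + rad * np.cos(ang))), _disc_stamp(trad))
    tufts &= retina

    # avascular zone: radial quantile over non-tuft retina pixels -> exact f_av
    target_av = int(round(spec.f_av * n_retina))
    candidates = rr[retina & ~tufts]
    if target_av > 0 and candidates.size:
        r_av = float(np.partition(candidates, min(target_av, candidates.size) - 1)[
            min(target_av, candidates.size) - 1
        ])
        avascular = retina & ~tufts & (rr <= r_av)
    else:
        r_av = 0.0
        avascular = np.zeros((h, w), dtype=bool)

    # vessel network fills the vascularized territory outside the zone
    vessels = _grow_vessels(rng, (h, w), (cy, cx), max(r_av, 1.0), spec.retina_radius, spec)
    vessels &= retina & ~avascular
    vascular = (vessels | tufts) & retina & ~avascular

    # render intensities: tissue disc, vessels, tufts; illumination + noise
    img = np.full((h, w), float(spec.background_level))
    img[retina] = spec.tissue_level
    img[vascular] = spec.vessel_level
    img[tufts] = spec.vessel_level * spec.tuft_multiplier
    gx, gy = rng.uniform(-1, 1, 2)
    illum = 1.0 + spec.illumination_amplitude * (gx * (xx - cx) / w + gy * (yy - cy) / h) * 2
    img = img * illum + rng.normal(0.0, spec.noise_sd, (h, w))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = FlatmountTruth(
        retina=retina,
        vascular=vascular,
        neovascular=tufts,
        avascular=avascular,
        f_av_realized=float(avascular.sum()) / n_retina,
        f_nv_realized=float(tufts.sum()) / n_retina,
    )
    return Image2D(img, bit_depth=8), truth


# --------------------------------------------------------------------------
# CNV z-stack
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvStackSpec:
    """An ellipsoidal lesion centred inside a spherical burn."""

    seed: int = 0
    shape: tuple[int, int, int] = (64, 96, 96)  # (nz, rows, cols)
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.5
    burn_radius_um: float = 40.0
    lesion_radii_um: tuple[float, float, float] = (20.0, 20.0, 20.0)  # (z, y, x)
    background_level: int = 10
    lesion_level: int = 180
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if any(r > self.burn_radius_um for r in self.lesion_radii_um):
            raise ValueError("lesion radii must not exceed the burn radius")


@dataclass(frozen=True)
class CnvTruth:
    lesion: np.ndarray
    burn: np.ndarray
    lesion_volume_um3: float
    burn_volume_um3: float


def generate_cnv_stack(spec: CnvStackSpec | None = None, seed: int | None = None):
    """Render a CNV lesion phantom. Returns ``(Stack3D, CnvTruth)``."""
    spec = spec or CnvStackSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    cz, cyy, cxx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    dzu = (zz - cz) * spec.dz
    dyu = (yy - cyy) * spec.dy
    dxu = (xx - cxx) * spec.dx

    burn = dzu**2 + dyu**2 + dxu**2 <= spec.burn_radius_um**2
    rz, ry, rx = spec.lesion_radii_um
    if min(rz, ry, rx) > 0:
        lesion = (dzu / rz) ** 2 + (dyu / ry) ** 2 + (dxu / rx) ** 2 <= 1.0
    else:
        lesion = np.zeros(spec.shape, dtype=bool)

    vol = np.full(spec.shape, float(spec.background_level))
    vol[lesion] = spec.lesion_level
    vol += rng.normal(0.0, spec.noise_sd, spec.shape)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    vox = spec.dx * spec.dy * spec.dz
    truth = CnvTruth(
        lesion=lesion,
        burn=burn,
        lesion_volume_um3=float(lesion.sum()) * vox,
        burn_volume_um3=float(burn.sum()) * vox,
    )
    return Stack3D(vol, dx=spec.dx, dy=spec.dy, dz=spec.dz), truth


# --------------------------------------------------------------------------
# array membrane
# --------------------------------------------------------------------------

def default_grid_layout(
    n_targets: int = 43,
    n_reference: int = 6,
    spacing: int = 24,
    margin: int = 24,
    n_cols: int = 14,
):
    """Spot-centre layout: targets in adjacent duplicate pairs, row-major,
    reference (positive-control) spots appended as duplicate pairs.

    Returns a list of ``(label, spot_index, row_px, col_px, is_reference)``.
    """
    entries = []
    labels = [f"T{i + 1:02d}" for i in range(n_targets)]
    ref_labels = [f"REF{i + 1}" for i in range(n_reference // 2)]
    pair = 0
    pairs_per_row = n_cols // 2
    for label_set, is_ref in ((labels, False), (ref_labels, True)):
        for label in label_set:
            row = margin + (pair // pairs_per_row) * spacing
            col0 = margin + (pair % pairs_per_row) * 2 * spacing
            entries.append((label, 1, row, col0, is_ref))
            entries.append((label, 2, row, col0 + spacing, is_ref))
            pair += 1
    return entries


@dataclass(frozen=True)
class MembraneSpec:
    """A chemiluminescent spot membrane: 43 duplicate targets + references.

    Spots have Gaussian intensity profiles; ``amplitudes`` maps target label
    to peak amplitude (defaults drawn log-uniformly in [1000, 8000]);
    reference spots share ``reference_amplitude``. ``exposure`` multiplies
    the whole membrane, emulating film/exposure differences that the
    reference-spot normalization must cancel.
    """

    seed: int = 0
    size: tuple[int, int] = (192, 384)
    n_targets: int = 43
    spot_sigma: float = 2.5
    amplitudes: dict | None = None
    reference_amplitude: float = 5000.0
    background_offset: float = 200.0
    noise_sd: float = 20.0
    jitter_px: float = 1.0
    spot_cv: float = 0.05
    exposure: float = 1.0


@dataclass(frozen=True)
class MembraneTruth:
    grid_entries: list
    true_densities: dict  # target -> noiseless integrated density (bg-free)
    reference_density: float


def generate_array_membrane(spec: MembraneSpec | None = None, seed: int | None = None):
    """Render a membrane phantom. Returns ``(Image2D, MembraneTruth)``.

    True per-target integrated density is the analytic Gaussian mass
    ``amplitude * 2 * pi * sigma**2`` (before exposure scaling), the value a
    perfect background-subtracted disc integration recovers.
    """
    spec = spec or MembraneSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    entries = default_grid_layout(n_targets=spec.n_targets)

    amplitudes = dict(spec.amplitudes) if spec.amplitudes else {}
    for label, *_ , is_ref in entries:
        if is_ref:
            amplitudes.setdefault(label, spec.reference_amplitude)
        elif label not in amplitudes:
            amplitudes[label] = float(np.exp(rng.uniform(np.log(1000.0), np.log(8000.0))))

    img = np.full((h, w), spec.background_offset)
    win = int(np.ceil(6 * spec.spot_sigma))  # ±6σ window holds >99.999% of the mass
    for label, _idx, r, c, _is_ref in entries:
        amp = amplitudes[label] * (1.0 + (rng.normal(0.0, spec.spot_cv) if spec.spot_cv else 0.0))
        ang, mag = rng.uniform(0, 2 * np.pi), rng.uniform(0, spec.jitter_px)
        dr, dc = mag * np.sin(ang), mag * np.cos(ang)
        r0, r1 = max(r - win, 0), min(r + win + 1, h)
        c0, c1 = max(c - win, 0), min(c + win + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        d2 = (yy - (r + dr)) ** 2 + (xx - (c + dc)) ** 2
        img[r0:r1, c0:c1] += amp * np.exp(-d2 / (2.0 * spec.spot_sigma**2))
    img *= spec.exposure
    if spec.noise_sd:
        img += rng.normal(0.0, spec.noise_sd, (h, w))
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    mass = 2.0 * np.pi * spec.spot_sigma**2
    truth = MembraneTruth(
        grid_entries=entries,
        true_densities={
            label: amplitudes[label] * mass
            for label, *_ , is_ref in entries
            if not is_ref
        },
        reference_density=spec.reference_amplitude * mass,
    )
    return Image2D(img, bit_depth=16), truth


@dataclass(frozen=True)
class MembraneStudyTruth:
    spiked_targets: list
    grid_entries: list


def generate_membrane_study(
    seed: int = 0,
    n_spiked: int = 5,
    fold: float = 3.0,
    n_replicates: int = 4,
    spot_cv: float = 0.05,
    exposure_sd: float = 0.2,
    n_targets: int = 43,
):
    """Two-group replicate membrane study with known differential targets.

    One set of baseline target amplitudes is drawn and shared by all
    membranes; ``n_spiked`` randomly chosen targets are multiplied by
    ``fold`` in the treated group. Each replicate membrane gets its own
    per-spot noise and a lognormal exposure factor (sd ``exposure_sd`` on
    the log scale) that the reference-spot normalization must cancel.

    Returns ``(groups, truth)`` where ``groups`` maps ``"control"`` and
    ``"treated"`` to lists of :class:`~oirquant.image.Image2D`.
    """
    master = np.random.default_rng(seed)
    base_spec = MembraneSpec(seed=int(master.integers(2**31)), n_targets=n_targets)
    _, tr0 = generate_array_membrane(base_spec)
    mass = 2.0 * np.pi * base_spec.spot_sigma**2
    base = {t: d / mass for t, d in tr0.true_densities.items()}
    spiked = sorted(master.choice(sorted(base), size=n_spiked, replace=False).tolist())

    groups: dict[str, list] = {}
    for name, amps in (
        ("control", base),
        ("treated", {t: (a * fold if t in spiked else a) for t, a in base.items()}),
    ):
        ims = []
        for _ in range(n_replicates):
            spec = MembraneSpec(
                seed=int(master.integers(2**31)),
                n_targets=n_targets,
                amplitudes=amps,
                spot_cv=spot_cv,
                exposure=float(np.exp(master.normal(0.0, exposure_sd))),
            )
            im, _ = generate_array_membrane(spec)
            ims.append(im)
        groups[name] = ims
    return groups, MembraneStudyTruth(spiked_targets=spiked, grid_entries=tr0.grid_entries)
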