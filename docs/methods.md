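# Methods

This note records the models, conventions, parameter choices and known
limitations behind each pipeline, in the order data flows through them.

## Thresholding

Both automatic thresholds operate on 256-bin histograms; 16-bit input is
min–max rescaled into 256 bins (over the selected pixels) and the affine
mapping recorded, so thresholds can be reported on the original gray scale.
The foreground convention is strictly greater than t; background is ≤ t.

**Otsu.** The between-class variance is maximised over every admissible
split (both classes non-empty). For integer bin counts,
σ_B²(t) ∝ (S₀W₁ − S₁W₀)²/(W₀W₁) with W the class counts and S the class
intensity sums, so the comparison is done in exact Python integers:
mathematically tied splits (e.g. any t between two isolated occupied bins)
deterministically resolve to the smallest t, independent of floating-point
summation order.

**Huang.** The fuzzy Shannon entropy E(t) = Σ_g p(g)·S(μ_t(g)) is minimised,
with membership μ_t(g) = 1/(1 + |g − m(t,g)|/C); m(t,g) is the mean of the
class g falls into at threshold t and C is the occupied gray range
(g_max − g_min), which keeps μ in [½, 1]. S(u) = −u ln u − (1−u) ln(1−u)
takes its limit value 0 at u ∈ {0, 1}. This is the original 1995
formulation; later re-implementations differ in membership normalization
and can select different thresholds on the same histogram, which is one
reason the pipeline records the thresholds it used. Ties resolve to the
smallest t (first minimum of the scan).

Histograms with fewer than two occupied bins raise an error instead of
returning an arbitrary threshold — a silent default here would corrupt
every downstream area metric.

## OIR flatmount pipeline

The four user-adjustable values are (1) the retina threshold (Huang auto),
(2) the vascular threshold (Otsu auto, computed on the histogram restricted
to retina pixels), (3) the neovascular threshold (Otsu auto on vascular
pixels), and (4) a closing radius, default 8 px, absorbing inter-capillary
gaps before the avascular complement is taken. Deriving the avascular zone
as `retina AND NOT close(vascular)` — rather than thresholding it directly —
guarantees avascular + vascular = retina, which the subtraction formula
normal = total vascular − neovascular presupposes. After the complement, the
effective vascular mask is redefined as retina − avascular so the partition
is exact.

Steps and conventions:

* retina: threshold, radius-1 opening (despeckle), hole fill, largest
  8-connected component. The opening is needed because background noise at
  ~40% occupancy sits near the site-percolation threshold of the
  8-connected lattice; without it a threshold at the edge of the background
  mode can fuse noise speckle with the retina into one giant component.
  Petal cuts and debris are background; flatmounts are contiguous after
  mounting, so keeping one component is correct.
* vasculature: within-retina Otsu, intersected with the retina, components
  smaller than `min_object_px` (default 30 px) removed.
* neovascular: second-stage Otsu on vascular pixels; tufts are the bright
  class. If the within-vessel class separation μ₁ − μ₀ falls below
  `min_tuft_contrast` (default 25 bins, ≈6× the default phantom noise sd),
  the split is judged to be noise and the tuft mask is empty — this is what
  makes neovascular% exactly 0 on tuft-free retinas instead of a small
  noise-driven value.
* closing radius: should exceed half the typical inter-capillary spacing
  (default 8 px matches the phantom's ~5 px vessel spacing with margin);
  too small leaves capillary gaps classified avascular, too large erodes
  genuine avascular territory near the ischemic border.
* percentages are exact `Fraction`s of pixel counts; the float views are
  derived from them. Calibration (μm/px) scales areas quadratically and
  never touches percentages.

## CNV volumetry

One global threshold over the pooled stack histogram (per-slice thresholds
fragment dim lesion tops and make volume non-monotone in depth); 26-connected
components below `min_size` (default 27 voxels ≈ a 3×3×3 speck) are dropped
and the largest remaining component is the lesion. Volume is
`count × dx × dy × dz` — anisotropy (default dz = 1.5 μm) is handled in the
measurement, never by resampling, avoiding interpolation artifacts. The burn
volume has no automatic definition (autofluorescence modelling is out of
scope); it is supplied as a second stack or a full-depth cylindrical ROI.
Lesion voxels outside the burn are excluded from the numerator and reported
as a warning count. The digital-ball fixture (radii r and 2r) reproduces the
analytic volume ratio (1/2)³ = 12.5% to within the voxelization error, which
shrinks as resolution grows.

## Vessel metrics

Skeletons come from topology-preserving thinning (scikit-image). Length is
chain length over skeleton adjacency — 1 per axial neighbour pair, √2 per
diagonal pair, each edge counted once. This rule is exact for axial and 45°
runs; like every chain-code estimator it overestimates intermediate angles
(≈7% at 30°, the known worst case ~8%). No corner-correction coefficients
are applied because they would break the exact axial case; comparisons
should therefore be within-method, which is how the metric is used in
practice. Junctions are skeleton pixels with ≥3 skeleton neighbours,
8-connected clusters merged into one junction (thinning produces junction
clumps at crossings; raw pixel counts over-report — an X counts once, not
four times). Branching index divides by the analyzed area; pass the retina
area when available so densities are comparable across crops. Lacunarity is
the gliding-box statistic Λ(r) = var(M_r)/mean(M_r)² over fully interior
r×r windows (stride 1, integral-image implementation), summarised as the
mean over a dyadic ladder r = 2, 4, … ⌊min_dim/4⌋ — the common
single-number convention; the slope of log Λ vs log r is a reasonable
alternative summary not implemented here.

## Array densitometry and statistics

Per-spot integrated density is the disc sum minus disc-area × median of a
background annulus, floored at 0; the median resists bleed from bright
neighbours. Duplicates combine by arithmetic mean (densitometry convention).
Normalization multiplies by `reference_constant / membrane reference mean`;
with the control membrane's reference mean as the constant, a uniform
exposure factor k cancels exactly, which is the point of the positive
control spots. The default layout is 43 targets in duplicate plus 3
duplicate pairs of reference spots (integration disc 10 px, annulus
12–16 px at 24 px spot pitch); any layout can be supplied as a CSV grid.
Per-target inference is a one-way F-test across treatment groups (≥2 groups,
≥2 replicates each; constant targets get p = 1), followed by
Benjamini–Hochberg step-up adjustment q(i) = min_{j≥i} min(1, p(j)·m/j).

A note on the spiked-membrane simulation: with 5 of 43 targets spiked the
procedure recovers all 5 in every seeded run, but the chance that *no*
additional null target clears the step-up threshold is bounded by
(1 − 6α/m)^38 ≈ 0.77 at α = 0.05 — BH controls the false discovery rate,
not the family-wise error rate, so occasional single false positives are
expected behaviour, not an implementation defect.

## Synthetic phantoms

The generators emulate geometry and intensity ordering, with one explicitly
seeded PRNG each (numpy default_rng); identical spec + seed gives
byte-identical output.

**Flatmount** (512×512, 8-bit): retina disc radius 230 px with 4 petal-cut
wedges (18°, outer 45% of the radius); central avascular zone whose radius
is calibrated by quantile so the realized avascular fraction equals the
request exactly at pixel resolution; vessel network grown by a branching
random walk from the zone border outward — walkers step 1 px with angular
wander (sd 0.2 rad) and a 0.3 pull toward radial, and new branches sprout
into the widest angular gap whenever the population falls below the count
that keeps spacing at ~5 px per walker around the current circumference
(trunk count floored at a 30 px circumference so near-zero avascular zones
still fan out); tufts are 4–8 px discs garlanding the ischemic border
(outward half-normal, sd 15 px), accumulated until the requested
neovascular fraction is reached. Intensities: background 12, tissue 60,
vessels 140, tufts 1.6×140 = 224, times a ±10% linear illumination
gradient, plus Gaussian noise sd 4. Default fractions are the typical P17
OIR control retina: 40% avascular, 20% neovascular (hence 40% normal
vascular). Intensity levels and vessel density are set so that the three
intensity classes are separable by the pipeline's own auto-thresholds —
i.e. the phantom sits in the operating regime the semi-automatic method
assumes; tuft brightness stays below 8-bit saturation so the illumination
gradient cannot clip the tuft class. What the phantoms do *not* model:
point-spread blur, staining heterogeneity, vignetting, montage seams,
dissection debris. Closed-loop recovery on phantoms therefore demonstrates
algorithmic correctness, not robustness to those real-image effects — on
real data the four values remain user-adjustable.

**CNV stack** (64×96×96, dz 1.5 μm): ellipsoidal bright lesion (default
20 μm radii, level 180) centred in a spherical burn (default 40 μm),
background 10, noise sd 5.

**Membrane** (192×384, 16-bit): Gaussian-profile spots (σ 2.5 px), target
amplitudes log-uniform in [1000, 8000], reference spots at 5000, background
offset 200, noise sd 20, duplicate jitter ≤1 px, optional per-spot CV and
whole-membrane exposure factor. The analytic truth density is
amplitude × 2πσ²; a 10 px integration disc captures ≥99.8% of it, and
16-bit quantization keeps the closed-loop error well under 1%. The
replicate-study generator shares one baseline amplitude set across all
membranes, spikes a random subset by a fold factor (default 5 targets ×3)
in the treated group, and draws per-membrane lognormal exposure (sd 0.2)
plus 5% per-spot CV — typical chemiluminescent variability.

## Problem sizes used in validation

Closed-loop flatmount statistics use 20 seeds (and 10 seeds per tuft
fraction for the monotonicity trend); threshold oracle checks use 100–120
random histograms; BH is checked on 200 random p-vectors; the spiked-membrane
study uses 50 seeded runs of 8 membranes each. These sizes give standard
errors far below the tolerances being asserted (e.g. the sd of recovered
neovascular% across seeds is ≈0.02 pp) while the whole validation completes
in well under a minute per pipeline.

## Known limitations

* The Huang variant implemented is the original formulation; thresholds from
  tools using later variants can differ on the same image.
* Chain-code length bias at intermediate angles (above).
* No adaptive/local thresholding: strong uneven illumination beyond the
  phantom's ±10% should be flat-fielded upstream.
* Burn volume requires an explicit mask or ROI; there is no automatic burn
  detection.
* Lacunarity is reported as a single mean over box sizes; multi-scale curves
  are not exposed.
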