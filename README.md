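# oirquant

Quantification toolkit for the image-analysis endpoints of retinal
angiogenesis studies: oxygen-induced retinopathy (OIR) flatmount area
accounting, choroidal neovascularization (CNV) lesion volumetry,
vessel-network metrics, and phospho-kinase membrane-array densitometry —
plus seeded synthetic phantoms with exact ground truth so every pipeline can
be validated end to end without animal images.

## Who this is for

Labs running the mouse OIR model (hyperoxia P7–P12, preretinal
neovascularization maximal ~P17) and laser-induced CNV, who need
reproducible, scriptable versions of the semi-automatic measurements usually
done interactively in ImageJ/IMARIS/AngioTool-style tools.

## The measurements

**OIR flatmount areas.** An isolectin-stained flatmount is segmented with
four user-adjustable values, each auto-initialised: a Huang fuzzy-entropy
threshold for the whole retina, an Otsu between-class-variance threshold for
the vasculature (restricted to retina pixels), a second-stage Otsu for the
hyper-intense neovascular tufts (restricted to vascular pixels), and a
morphological closing radius that absorbs inter-capillary gaps before the
central avascular zone is taken as the complement of the closed vasculature.
With |R|, |AV|, |NV| the pixel counts of retina, avascular and neovascular
masks, the report is

    avascular% = 100·|AV|/|R|,  neovascular% = 100·|NV|/|R|,
    normal vascular% = 100·(|R| − |AV| − |NV|)/|R|,

computed in exact rational arithmetic so the three classes always sum to
exactly 100. The thresholds used are recorded so any run can be repeated
bit-identically with manual values.

The two auto-thresholds are implemented from scratch on 256-bin histograms:
Otsu maximises σ_B²(t) = ω₀ω₁(μ₀ − μ₁)² (decided in exact integer
arithmetic; ties → smallest t), and Huang minimises the fuzzy Shannon
entropy E(t) = Σ_g h(g)·S(μ_t(g)) with membership
μ_t(g) = 1/(1 + |g − m(t,g)|/C). Both are tested against exhaustive-search
oracles.

**CNV volumetry.** A z-stack (default 1.5 μm step) is segmented with one
global Otsu threshold; the largest 26-connected component is the lesion, and
the result is `lesion volume / burn volume × 100` with the burn supplied as
a second stack or a cylindrical ROI.

**Vessel-network metrics.** From a binary vessel mask: total skeleton chain
length (1 per axial step, √2 per diagonal step), branching index (junction
clusters per mm²), and gliding-box lacunarity Λ(r) = var(M_r)/mean(M_r)²
averaged over a dyadic ladder of box sizes.

**Array densitometry.** Duplicate-spot integrated densities (disc sum minus
disc-area × annulus median, floored at 0), per-membrane normalization to
positive-control reference spots, fold changes vs an untreated control
membrane, per-target one-way F-tests and Benjamini–Hochberg FDR adjustment.
The arcsine transform `asin(sqrt(p/100))` for percentage endpoints is
included.

## Worked example

```sh
oirquant simulate flatmount --seed 1 --out sim/
oirquant oir sim/flatmount.tif --out report.csv --masks masks.tif
cat report.csv
```

prints (reformatted):

```
image,retina_px,neovascular_pct,avascular_pct,normal_vascular_pct,t_retina,t_vascular,t_neovascular,closing_radius
flatmount.tif,142963,19.9912,38.1917,41.8171,45,121,166,8
```

The phantom was generated with a 40% avascular zone and 20% neovascular
tufts — the typical control values of a P17 OIR retina — and the pipeline,
running fully automatically (Huang threshold 45 for the retina, Otsu 121
for vessels, Otsu 166 for tufts), recovers 38.2% / 20.0% / 41.8%. The three
percentages sum to 100 exactly; `masks.tif` holds the four binary masks
(retina, vascular, neovascular, avascular) as 0/255 TIFF pages.

The same CLI exposes `cnv`, `vessels`, `array` and the other `simulate`
phantoms; the Python API (`oirquant.run_oir_select`,
`oirquant.cnv_percentage`, `oirquant.compute_vessel_metrics`,
`oirquant.analyze_membranes`, `oirquant.generate_flatmount`, …) gives the
same results programmatically.

## Limitations

The synthetic phantoms emulate geometry and intensity ordering, not optics:
no point-spread function, no saturation artifacts, no staining variability.
Validation on phantoms bounds algorithmic correctness, not biological
accuracy on real images — thresholds remain user-adjustable for that reason.
See `docs/methods.md` for models, parameter choices and numerical details.
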