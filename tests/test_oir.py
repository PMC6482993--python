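"""OIR flatmount pipeline: segmentation fidelity and exact area accounting."""

from fractions import Fraction

import numpy as np
import pytest

from oirquant.errors import (
    DegenerateHistogramError,
    EmptyRetinaError,
    MaskHierarchyError,
)
from oirquant.image import Image2D
from oirquant.oir import (
    OirConfig,
    OirMaskSet,
    compute_area_report,
    derive_avascular,
    run_oir_select,
    segment_neovascular,
    segment_retina,
    segment_vasculature,
)
from oirquant.synthetic import FlatmountSpec, generate_flatmount


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


def dice(a, b):
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2 * (a & b).sum() / s


def masks_from_counts(n_av=4000, n_nv=2000):
    """Masks over a 10000-px retina realizing given avascular/neovascular
    pixel counts: avascular fills from the start, neovascular from the end."""
    retina = np.zeros((100, 120), dtype=bool)
    retina[:, :100] = True  # 10000 px
    inside = np.flatnonzero(retina.ravel())
    avascular = np.zeros(retina.size, dtype=bool)
    avascular[inside[:n_av]] = True
    neovascular = np.zeros(retina.size, dtype=bool)
    if n_nv:
        neovascular[inside[-n_nv:]] = True
    avascular = avascular.reshape(retina.shape)
    neovascular = neovascular.reshape(retina.shape)
    vascular = retina & ~avascular
    return OirMaskSet(retina=retina, vascular=vascular, neovascular=neovascular, avascular=avascular)


class TestSegmentRetina:
    def test_recovers_synthetic_retina(self):
        img, truth = generate_flatmount(seed=11)
        mask, _ = segment_retina(img, OirConfig())
        assert iou(mask, truth.retina) >= 0.95

    def test_interior_hole_is_filled(self):
        px = np.full((40, 40), 10, dtype=np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        px[disc] = 200
        px[18:23, 18:23] = 10  # dark interior hole
        mask, _ = segment_retina(Image2D(px), OirConfig())
        assert mask[20, 20]

    def test_all_zero_image_raises(self):
        with pytest.raises((EmptyRetinaError, DegenerateHistogramError)):
            segment_retina(Image2D(np.zeros((10, 10), dtype=np.uint8)), OirConfig())


class TestSegmentVasculature:
    def test_recovers_synthetic_vessels(self):
        img, truth = generate_flatmount(seed=11)
        cfg = OirConfig()
        retina, _ = segment_retina(img, cfg)
        mask, _ = segment_vasculature(img, retina, cfg)
        assert dice(mask, truth.vascular) >= 0.80

    def test_restricted_to_retina(self):
        px = np.full((30, 60), 10, dtype=np.uint8)
        px[5:25, 5:25] = 80  # retina
        px[10:15, 10:20] = 200  # vessels inside
        px[10:15, 40:50] = 200  # "vessels" outside the retina mask
        retina = np.zeros((30, 60), dtype=bool)
        retina[5:25, 5:25] = True
        mask, _ = segment_vasculature(Image2D(px), retina, OirConfig(min_object_px=0))
        assert mask[12, 15] and not mask[12, 45]

    def test_uniform_retina_raises(self):
        px = np.full((20, 20), 99, dtype=np.uint8)
        retina = np.ones((20, 20), dtype=bool)
        with pytest.raises(DegenerateHistogramError):
            segment_vasculature(Image2D(px), retina, OirConfig())


class TestSegmentNeovascular:
    def test_recovers_bright_tufts_from_truth_vessels(self):
        spec = FlatmountSpec(seed=11, tuft_multiplier=1.8)
        img, truth = generate_flatmount(spec)
        mask, _ = segment_neovascular(img, truth.vascular, OirConfig())
        assert dice(mask, truth.neovascular) >= 0.70

    def test_tuft_free_image_yields_empty_mask(self):
        img, truth = generate_flatmount(FlatmountSpec(seed=5, f_nv=0.0))
        _, report = run_oir_select(img)
        assert report.neovascular_pct == 0.0

    def test_subset_of_vascular_by_construction(self):
        img, truth = generate_flatmount(seed=3)
        mask, _ = segment_neovascular(img, truth.vascular, OirConfig())
        assert not (mask & ~truth.vascular).any()


class TestDeriveAvascular:
    def test_full_vascularization_gives_empty(self):
        retina = np.zeros((30, 30), dtype=bool)
        retina[5:25, 5:25] = True
        assert not derive_avascular(retina, retina.copy(), OirConfig()).any()

    def test_empty_vascular_gives_retina(self):
        retina = np.zeros((30, 30), dtype=bool)
        retina[5:25, 5:25] = True
        empty = np.zeros_like(retina)
        assert (derive_avascular(retina, empty, OirConfig()) == retina).all()

    def test_subset_precondition_enforced(self):
        retina = np.zeros((10, 10), dtype=bool)
        retina[2:5, 2:5] = True
        vascular = np.ones_like(retina)
        with pytest.raises(MaskHierarchyError):
            derive_avascular(retina, vascular, OirConfig())

    def test_requested_fraction_recovered(self):
        img, _ = generate_flatmount(seed=17)
        _, report = run_oir_select(img)
        assert report.avascular_pct == pytest.approx(40.0, abs=5.0)


class TestAreaReport:
    def test_typical_control_triple(self):
        """10000 retina px with 4000 avascular / 2000 neovascular gives the
        40 / 20 / 40 split typical of a P17 OIR control retina."""
        report = compute_area_report(masks_from_counts(), OirConfig())
        assert report.avascular_pct == 40.0
        assert report.neovascular_pct == 20.0
        assert report.normal_vascular_pct == 40.0

    def test_fully_normal_retina(self):
        masks = masks_from_counts(n_av=0, n_nv=0)
        report = compute_area_report(masks, OirConfig())
        assert (report.avascular_pct, report.neovascular_pct) == (0.0, 0.0)
        assert report.normal_vascular_pct == 100.0

    def test_counts_exceeding_retina_raise(self):
        # 5000 avascular + 6000 neovascular cannot fit a 10000-px retina
        with pytest.raises(MaskHierarchyError):
            compute_area_report(masks_from_counts(n_av=5000, n_nv=6000), OirConfig())

    def test_exact_partition_identity(self):
        for seed in (0, 1, 2):
            img, _ = generate_flatmount(seed=seed)
            _, report = run_oir_select(img)
            total = report.avascular_frac + report.neovascular_frac + report.normal_vascular_frac
            assert total == Fraction(100)

    def test_calibration_changes_areas_not_percentages(self):
        img, _ = generate_flatmount(seed=2)
        _, r1 = run_oir_select(img, OirConfig(um_per_px=1.0))
        _, r2 = run_oir_select(img, OirConfig(um_per_px=2.0))
        assert r2.retina_um2 == pytest.approx(4 * r1.retina_um2)
        assert r2.avascular_frac == r1.avascular_frac
        assert r2.neovascular_frac == r1.neovascular_frac


class TestFullPipeline:
    def test_nestedness_on_pipeline_output(self):
        img, _ = generate_flatmount(seed=9)
        masks, _ = run_oir_select(img)
        masks.validate()
        assert not (masks.neovascular & ~masks.vascular).any()
        assert not (masks.vascular & ~masks.retina).any()

    def test_rerun_with_recorded_thresholds_is_bit_identical(self):
        img, _ = generate_flatmount(seed=4)
        masks, report = run_oir_select(img)
        cfg = OirConfig(
            t_retina=report.thresholds["t_retina"],
            t_vascular=report.thresholds["t_vascular"],
            t_neovascular=report.thresholds["t_neovascular"],
        )
        masks2, _ = run_oir_select(img, cfg)
        for name in ("retina", "vascular", "neovascular", "avascular"):
            assert (getattr(masks, name) == getattr(masks2, name)).all()

    def test_tuft_fraction_monotonicity(self):
        """Mean recovered neovascular% strictly increases with the generated
        tuft fraction (3 seeds per level here; the acceptance suite uses 10)."""
        means = []
        for f in (0.05, 0.10, 0.20):
            vals = [
                run_oir_select(generate_flatmount(FlatmountSpec(seed=s, f_nv=f))[0])[1].neovascular_pct
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
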