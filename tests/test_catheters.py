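"""Electrode rasterization, vectoring schemes, and metal-area conventions."""

import numpy as np
import pytest
from scipy import ndimage

from pfa_fieldsim.anatomy import build_phantom, define_target
from pfa_fieldsim.catheters import (
    DESIGNS,
    DOSE_SCHEDULES,
    MONOPOLAR_DESIGNS,
    N_VECTORS_ON_TARGET,
    DoseSchedule,
    build_catheter,
    electrode_metal_area,
    make_vector_scheme,
    oneshot_panel_probe_points,
)


@pytest.fixture(scope="module")
def built(antrum_grid, antrum_target):
    out = {}
    for d in DESIGNS:
        es = build_catheter(d, antrum_grid, antrum_target)
        out[d] = (es, make_vector_scheme(es))
    return out


class TestBuildCatheter:
    @pytest.mark.parametrize("design", DESIGNS)
    def test_masks_disjoint_from_myocardium(self, built, antrum_grid, design):
        es, _ = built[design]
        myo = antrum_grid.mask("myocardium")
        for el in es.electrodes:
            assert not (el.mask & myo).any()

    @pytest.mark.parametrize("design", DESIGNS)
    def test_codeployed_masks_pairwise_disjoint(self, built, design):
        es, _ = built[design]
        for pl in es.placements():
            group = [el for el in es.electrodes if el.placement == pl]
            acc = np.zeros_like(group[0].mask)
            for el in group:
                assert not (acc & el.mask).any()
                acc |= el.mask

    @pytest.mark.parametrize("design", DESIGNS)
    def test_build_is_deterministic(self, antrum_grid, antrum_target, built, design):
        es2 = build_catheter(design, antrum_grid, antrum_target)
        es1, _ = built[design]
        for a, b in zip(es1.electrodes, es2.electrodes, strict=True):
            assert a.name == b.name
            assert np.array_equal(a.mask, b.mask)

    def test_monopolar_designs_have_return_patch(self, built):
        for d in DESIGNS:
            es, _ = built[d]
            assert (es.return_patch is not None) == (d in MONOPOLAR_DESIGNS)

    def test_circular_ten_rings_nominal_pitch_on_slab(self):
        g = build_phantom("slab", {"extent_mm": (80.0, 24.0, 16.0)}, 0.5)
        t = define_target(g, band_length_mm=70.0, band_width_mm=6.0)
        es = build_catheter("circular", g, t)
        assert len(es.electrodes) == 10
        centers = sorted(el.center_s_mm for el in es.electrodes)
        pitches = np.diff(centers)
        # 3 mm electrode + 3.7 mm edge-to-edge gap
        assert np.allclose(pitches, 6.7)

    def test_penta_spline_is_four_rings_one_node(self, antrum_grid, antrum_target):
        g = build_phantom("antrum", spacing_mm=0.5)
        t = define_target(g)
        es = build_catheter("penta_spline", g, t)
        spline = es.get("app0_spline0")
        # one electrical node rasterized as four separate rings along the axis
        n_components = ndimage.label(spline.mask)[1]
        assert n_components == 4

    def test_oneshot_diamond_openings_not_metal(self, built):
        es, _ = built["oneshot_sphere"]
        frame = es.frame
        pts = oneshot_panel_probe_points(es.params)
        s_o, t_o = pts["opening_center"]
        panel = es.get("panel0")
        near_opening = (
            (np.abs(frame.ds(s_o)) <= 1.0)
            & (np.abs(frame.T - t_o) <= 1.0)
        )
        assert not (panel.mask & near_opening).any()
        s_x, t_x = pts["strut_crossing"]
        near_crossing = (
            (np.abs(frame.ds(s_x)) <= 1.0)
            & (np.abs(frame.T - t_x) <= 1.0)
        )
        assert (panel.mask & near_crossing).any()

    def test_balloon_fills_lumen_with_insulator(self, built, antrum_grid):
        es, _ = built["balloon"]
        assert len(es.insulator_masks) == 1
        body = es.insulator_masks[0]
        assert body.sum() > 1000
        assert not any((body & el.mask).any() for el in es.electrodes)
        es_flex, _ = built["flex_splines"]
        assert es_flex.insulator_masks == []

    def test_unknown_design_rejected(self, antrum_grid, antrum_target):
        with pytest.raises(ValueError, match="unknown design"):
            build_catheter("laser", antrum_grid, antrum_target)

    def test_footprint_must_fit_phantom(self):
        g = build_phantom("slab", {"extent_mm": (30.0, 20.0, 16.0)}, 0.5)
        t = define_target(g, band_length_mm=25.0, band_width_mm=6.0)
        with pytest.raises(ValueError, match="footprint"):
            build_catheter("circular", g, t)


class TestRasterizedAreaOracle:
    def test_ring_and_plate_areas_match_analytic(self):
        """Voxelized metal agrees with the cylinder/plate formulas at 0.25 mm."""
        g = build_phantom("slab", {"extent_mm": (80.0, 24.0, 12.0)}, 0.25)
        t = define_target(g, band_length_mm=70.0, band_width_mm=6.0)
        h = g.spacing_mm
        es = build_catheter("circular", g, t)
        ring = es.get("ring4")
        r = es.params["electrode_diameter_mm"] / 2.0
        # lateral area of a solid cylinder from its voxelized volume: A = 2V/r
        a_est = 2.0 * ring.mask.sum() * h**3 / r / 100.0
        assert a_est == pytest.approx(ring.metal_area_cm2, rel=0.15)

        es = build_catheter("flex_splines", g, t)
        plate = es.get("app0_spline1_e2")
        # footprint area: project the (possibly multi-layer) mask onto the wall
        footprint = plate.mask.any(axis=2).sum()
        a_est = footprint * h**2 / 100.0
        assert a_est == pytest.approx(plate.metal_area_cm2, rel=0.15)


class TestVectorScheme:
    @pytest.mark.parametrize("design", DESIGNS)
    def test_every_delivery_has_both_polarities(self, built, design):
        _, sc = built[design]
        for d in sc.deliveries:
            assert 1 in d.polarity.values()
            assert -1 in d.polarity.values()

    @pytest.mark.parametrize("design", DESIGNS)
    def test_on_target_vector_counts_match_deployment(self, built, design):
        _, sc = built[design]
        assert sc.n_vectors_on_target == N_VECTORS_ON_TARGET[design]

    def test_circular_alternates_polarity(self, built):
        _, sc = built["circular"]
        (d,) = sc.deliveries
        pol = [d.polarity[f"ring{k}"] for k in range(10)]
        assert pol == [1, -1] * 5

    def test_penta_rotating_bipole_counts(self, built):
        _, sc = built["penta_spline"]
        assert len(sc.deliveries) == 10  # five per application, two applications
        assert all(d.n_positive == 1 for d in sc.deliveries)

    def test_monopolar_patch_is_cathode(self, built):
        for design in MONOPOLAR_DESIGNS:
            _, sc = built[design]
            for d in sc.deliveries:
                assert d.polarity["return_patch"] == -1


class TestMetalAreaConvention:
    def test_published_single_electrode_areas(self, built):
        es, _ = built["flex_splines"]
        assert electrode_metal_area("flex_splines", es) == pytest.approx(0.13, abs=0.005)
        es, _ = built["circular"]
        assert electrode_metal_area("circular", es) == pytest.approx(0.15, abs=0.005)
        es, _ = built["penta_spline"]
        assert electrode_metal_area("penta_spline", es) == pytest.approx(0.49, abs=0.005)

    def test_design_mismatch_rejected(self, built):
        es, _ = built["circular"]
        with pytest.raises(ValueError):
            electrode_metal_area("balloon", es)


class TestDoseSchedule:
    def test_negative_fields_rejected(self):
        with pytest.raises(ValueError):
            DoseSchedule(-1, 5, 100.0)

    def test_published_schedules_present(self):
        assert DOSE_SCHEDULES["oneshot_sphere"] == DoseSchedule(4, 30, 150.0)
        assert DOSE_SCHEDULES["circular"] == DoseSchedule(12, 4, 130.0)
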