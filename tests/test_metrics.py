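"""Dosimetry metrics: transmurality, dose-current search, power fraction, ECD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfa_fieldsim.anatomy import (
    TargetRegion,
    assign_conductivity,
    build_phantom,
    default_conductivity_table,
    define_target,
)
from pfa_fieldsim.catheters import DoseSchedule, build_catheter, make_vector_scheme
from pfa_fieldsim.metrics import (
    current_for_transmurality,
    electrode_current_density,
    lesion_volume_mm3,
    linear_current_for_transmurality,
    power_fraction_in_target,
    total_delivery_duration,
    transmural_fraction,
)
from pfa_fieldsim.solver import solve_delivery


def _target_from(mask):
    return TargetRegion(mask=mask, nominal_dims_mm=(0, 0, 0))


class TestTransmuralFraction:
    def test_uniform_field_above_threshold(self, rng):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        field = np.full((10, 10, 10), 700.0)
        assert transmural_fraction([field], _target_from(mask)) == 1.0

    def test_union_of_disjoint_halves(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        f1 = np.zeros((4, 4, 4))
        f2 = np.zeros((4, 4, 4))
        f1[:2] = 900.0
        f2[2:] = 900.0
        assert transmural_fraction([f1], _target_from(mask)) == 0.5
        assert transmural_fraction([f1, f2], _target_from(mask)) == 1.0

    def test_matches_brute_force_count(self, rng):
        field = rng.uniform(0, 1200, size=(12, 12, 12))
        mask = rng.random((12, 12, 12)) < 0.4
        expected = np.sum(field[mask] > 600.0) / mask.sum()
        assert transmural_fraction([field], _target_from(mask)) == pytest.approx(expected)

    def test_union_monotonicity(self, rng):
        mask = rng.random((10, 10, 10)) < 0.5
        fields = [rng.uniform(0, 900, size=(10, 10, 10)) for _ in range(4)]
        fracs = [
            transmural_fraction(fields[: k + 1], _target_from(mask))
            for k in range(4)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            transmural_fraction([np.ones((3, 3, 3))], _target_from(np.zeros((3, 3, 3), bool)))


class TestCurrentForTransmurality:
    def _linear_evaluator(self, field_per_amp, mask, threshold=600.0):
        target = _target_from(mask)

        def fraction(i):
            return transmural_fraction([field_per_amp * i], target, threshold)

        return fraction

    def test_bisection_matches_quantile_closed_form(self, rng):
        field_per_amp = rng.uniform(5.0, 60.0, size=(16, 16, 16))
        mask = rng.random((16, 16, 16)) < 0.5
        res = current_for_transmurality(
            self._linear_evaluator(field_per_amp, mask), level=0.9
        )
        assert res.achieved
        closed = linear_current_for_transmurality(
            [field_per_amp * 1.0], _target_from(mask), reference_current_a=1.0
        )
        assert res.current_a == pytest.approx(closed, rel=0.015)

    def test_doubling_threshold_doubles_current(self, rng):
        field_per_amp = rng.uniform(5.0, 60.0, size=(16, 16, 16))
        mask = rng.random((16, 16, 16)) < 0.5
        r1 = current_for_transmurality(
            self._linear_evaluator(field_per_amp, mask, 300.0), level=0.9
        )
        r2 = current_for_transmurality(
            self._linear_evaluator(field_per_amp, mask, 600.0), level=0.9
        )
        assert r2.current_a == pytest.approx(2 * r1.current_a, rel=0.03)

    def test_unreachable_level_reported_not_raised(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        field_per_amp = np.full((4, 4, 4), 1e9)
        field_per_amp[0, 0, 0] = 0.0  # one shadowed voxel never electroporates
        res = current_for_transmurality(self._linear_evaluator(field_per_amp, mask), level=1.0)
        assert not res.achieved
        assert res.current_a == 70.0
        assert "not achieved" in str(res)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            current_for_transmurality(lambda i: 1.0, level=1.5)


@pytest.fixture(scope="module")
def slab_solution():
    g = build_phantom("slab", {"extent_mm": (40.0, 24.0, 16.0)}, 0.5)
    t = define_target(g, band_length_mm=30.0, band_width_mm=6.0)
    es = build_catheter("circular", g, t, {"n_electrodes": 4})
    sc = make_vector_scheme(es, 30.0, 6.0)
    cond = assign_conductivity(g, default_conductivity_table())
    sol = solve_delivery(g, cond, es, sc.deliveries[0], 10.0)
    return g, t, sol


class TestPowerFraction:
    def test_whole_domain_receives_all_power(self, slab_solution):
        g, _, sol = slab_solution
        everything = _target_from(np.ones(g.shape, dtype=bool))
        assert power_fraction_in_target([sol], everything) == pytest.approx(100.0, abs=2.0)

    def test_partition_sums_to_total(self, slab_solution):
        g, t, sol = slab_solution
        inside = power_fraction_in_target([sol], t)
        complement = _target_from(~t.mask)
        outside = power_fraction_in_target([sol], complement)
        assert inside + outside == pytest.approx(100.0, abs=2.0)
        assert 0.0 <= inside <= 100.0

    def test_parallel_plate_fully_in_target(self):
        from pfa_fieldsim.validation import parallel_plate_case

        sol, ctx = parallel_plate_case(0.5)
        everything = _target_from(np.ones(ctx["grid"].shape, dtype=bool))
        assert power_fraction_in_target([sol], everything) == pytest.approx(100.0, abs=2.0)

    def test_zero_power_rejected(self, slab_solution):
        _, t, sol = slab_solution
        with pytest.raises(ValueError):
            power_fraction_in_target([sol], t, weights=[0.0])


class TestECD:
    @pytest.mark.parametrize(
        "current,area,expected",
        [(36.1, 0.49, 74), (12.5, 0.15, 83), (5.3, 0.13, 41), (4.0, 0.13, 31), (39.0, 1.55, 25)],
    )
    def test_published_table_arithmetic(self, current, area, expected):
        assert round(electrode_current_density(current, area)) == expected

    def test_zero_current(self):
        assert electrode_current_density(0.0, 0.5) == 0.0

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            electrode_current_density(1.0, 0.0)

    @given(i=st.floats(0.1, 100), a=st.floats(0.05, 3.0), k=st.floats(1.1, 4.0))
    def test_scales_linearly_with_current(self, i, a, k):
        assert electrode_current_density(k * i, a) == pytest.approx(
            k * electrode_current_density(i, a), rel=1e-12
        )


class TestDoseDuration:
    @pytest.mark.parametrize(
        "sched,expected",
        [
            (DoseSchedule(4, 30, 150.0), 18000.0),
            (DoseSchedule(7, 12, 150.0), 12600.0),
            (DoseSchedule(8, 5, 200.0), 8000.0),
            (DoseSchedule(12, 4, 130.0), 6240.0),
        ],
    )
    def test_published_totals(self, sched, expected):
        assert total_delivery_duration(sched) == expected

    @given(k=st.integers(0, 50))
    def test_zero_duration_gives_zero(self, k):
        assert total_delivery_duration(DoseSchedule(k, 1, 0.0)) == 0.0


class TestLesionVolume:
    def test_counts_only_myocardium(self, antrum_grid):
        field = np.full(antrum_grid.shape, 900.0)
        vol = lesion_volume_mm3([field], antrum_grid)
        myo_vol = np.count_nonzero(antrum_grid.mask("myocardium")) * antrum_grid.voxel_volume_mm3
        assert vol == pytest.approx(myo_vol)
        assert lesion_volume_mm3([np.zeros(antrum_grid.shape)], antrum_grid) == 0.0
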