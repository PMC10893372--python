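"""Delta arithmetic, plant mass balance, treatment averaging, solution bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdisoflux import tables
from cdisoflux.isotope_metrics import (
    DeltaValue,
    OrganMeasurement,
    PlantRecord,
    capital_delta,
    delta_from_ratio,
    final_solution_state,
    ivw_mean,
    organ_cd_mass,
    plant_fractionation,
    plant_totals,
    ratio_from_delta,
    solution_after_uptake,
    translocation_factor,
)

STD_RATIO = 2.30024


def make_plant(organs, tid="T1", rid="P1", **flags) -> PlantRecord:
    measurements = {
        organ: OrganMeasurement(organ, mass, conc, DeltaValue(delta, two_sd))
        for organ, (mass, conc, delta, two_sd) in organs.items()
    }
    return PlantRecord(tid, rid, measurements, **flags)


class TestDeltaRatio:
    def test_identity_and_definition(self):
        assert delta_from_ratio(STD_RATIO, STD_RATIO) == 0.0
        assert delta_from_ratio(1.001 * STD_RATIO, STD_RATIO) == pytest.approx(1.0)

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, delta, std):
        r = ratio_from_delta(delta, std)
        assert delta_from_ratio(r, std) == pytest.approx(delta, abs=1e-10)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta_from_ratio(-1.0, STD_RATIO)


class TestCapitalDelta:
    def test_treatment2_total_minus_solution(self):
        # printed treatment-2 total delta vs the solution composition
        d = capital_delta(DeltaValue(-0.67, 0.04), tables.DELTA_SOLUTION)
        assert d.value == pytest.approx(-0.31)
        assert d.two_sd == pytest.approx(math.hypot(0.04, 0.04))

    def test_self_difference_and_antisymmetry(self):
        a, b = DeltaValue(-0.5, 0.05), DeltaValue(-0.7, 0.03)
        assert capital_delta(a, a).value == 0.0
        assert capital_delta(a, b).value == -capital_delta(b, a).value


class TestIvwMean:
    def test_equal_uncertainties_is_arithmetic_mean(self):
        vals = [DeltaValue(-0.5, 0.06), DeltaValue(-0.7, 0.06)]
        assert ivw_mean(vals).value == pytest.approx(-0.6)

    def test_single_value_is_itself(self):
        v = DeltaValue(-0.42, 0.08)
        assert ivw_mean([v]) == v

    def test_hand_weighted_example(self):
        # sigma 0.05 vs 0.1 -> weights 4:1 -> mean 0.1
        out = ivw_mean([DeltaValue(0.0, 0.1), DeltaValue(0.5, 0.2)])
        assert out.value == pytest.approx(0.1)
        assert out.two_sd == pytest.approx(2.0 / math.sqrt(400 + 100))

    def test_invariant_under_uniform_sigma_rescaling(self):
        vals = [DeltaValue(-0.4, 0.02), DeltaValue(-0.8, 0.08)]
        scaled = [DeltaValue(v.value, 3 * v.two_sd) for v in vals]
        assert ivw_mean(vals).value == pytest.approx(ivw_mean(scaled).value)

    def test_empty_rejected_and_zero_sigma_falls_back(self):
        with pytest.raises(ValueError):
            ivw_mean([])
        with pytest.warns(UserWarning, match="unweighted"):
            out = ivw_mean([DeltaValue(0.0, 0.0), DeltaValue(1.0, 0.1)])
        assert out.value == pytest.approx(0.5)


class TestPlantTotals:
    def test_organ_mass_unit_arithmetic(self):
        m = OrganMeasurement("root", 0.10, 322.0, DeltaValue(-0.7))
        assert organ_cd_mass(m) == pytest.approx(32.2)
        zero = OrganMeasurement("root", 0.10, 0.0, DeltaValue(-0.7))
        assert organ_cd_mass(zero) == 0.0

    def test_single_organ_plant(self):
        p = make_plant({"root": (0.1, 300.0, -0.7, 0.05)})
        d = plant_totals(p)
        assert d.delta_total.value == -0.7
        assert d.fractions == {"root": 1.0}
        assert d.missing_organs == ("stem", "leaf")

    def test_equal_mass_midpoint(self):
        p = make_plant(
            {"root": (0.1, 300.0, -0.5, 0.05), "stem": (0.2, 150.0, -0.7, 0.05)}
        )
        assert plant_totals(p).delta_total.value == pytest.approx(-0.6)

    def test_three_organ_hand_example(self):
        # leaf 50 ug @ -0.40, stem 30 @ -0.70, root 40 @ -0.70
        p = make_plant(
            {
                "leaf": (0.5, 100.0, -0.40, 0.05),
                "stem": (0.2, 150.0, -0.70, 0.05),
                "root": (0.1, 400.0, -0.70, 0.05),
            }
        )
        d = plant_totals(p)
        assert d.total_cd_ug == pytest.approx(120.0)
        assert d.delta_total.value == pytest.approx(-0.575)
        assert d.f_shoot == pytest.approx(2.0 / 3.0)
        assert translocation_factor(d) == pytest.approx(200.0)

    def test_conservation(self, default_run):
        from cdisoflux.isotope_metrics import plants_from_frame

        _, res = default_run
        for p in plants_from_frame(res.plants):
            d = plant_totals(p)
            assert sum(d.cd_mass_per_organ.values()) == pytest.approx(
                d.total_cd_ug, rel=1e-12
            )
            assert sum(d.fractions.values()) == pytest.approx(1.0, rel=1e-12)

    def test_tf_boundary_and_undefined(self):
        balanced = make_plant(
            {
                "leaf": (0.1, 200.0, -0.4, 0.05),
                "stem": (0.1, 200.0, -0.7, 0.05),
                "root": (0.1, 400.0, -0.7, 0.05),
            }
        )
        assert translocation_factor(plant_totals(balanced)) == pytest.approx(100.0)
        rootless = make_plant({"leaf": (0.1, 200.0, -0.4, 0.05)})
        with pytest.raises(ValueError, match="no root"):
            translocation_factor(plant_totals(rootless))


class TestPlantFractionation:
    def test_delta_chain_identity(self):
        # within one plant, L-R = L-S + S-R exactly
        p = make_plant(
            {
                "leaf": (0.5, 90.0, -0.47, 0.08),
                "stem": (0.2, 160.0, -0.73, 0.05),
                "root": (0.12, 350.0, -0.71, 0.06),
            }
        )
        _, ds, eps = plant_fractionation(p, tables.DELTA_SOLUTION)
        assert ds["leaf_root"].value == pytest.approx(
            ds["leaf_stem"].value + ds["stem_root"].value, abs=1e-12
        )
        assert eps is not None and eps < 0  # heavy sink at f < 1


class TestSolutionMassBalance:
    def test_no_uptake_is_identity(self):
        assert solution_after_uptake(-0.36, -0.7, 1.0) == -0.36

    def test_five_percent_uptake_hand_example(self):
        # reservoir at -0.36, plants remove 5% at -0.635
        out = solution_after_uptake(-0.36, -0.635, 0.95)
        assert out == pytest.approx((-0.36 + 0.05 * 0.635) / 0.95)
        assert out == pytest.approx(-0.3455, abs=1e-4)

    @given(
        st.floats(-1.0, 1.0),
        st.floats(-1.0, 1.0),
        st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_balance_identity(self, d_init, d_removed, f):
        d_final = solution_after_uptake(d_init, d_removed, f)
        assert f * d_final + (1 - f) * d_removed == pytest.approx(d_init, abs=1e-12)

    def test_final_solution_state_from_plants(self):
        p = make_plant(
            {
                "leaf": (0.5, 100.0, -0.40, 0.05),
                "stem": (0.2, 150.0, -0.70, 0.05),
                "root": (0.1, 400.0, -0.70, 0.05),
            }
        )
        d = plant_totals(p)
        state = final_solution_state(tables.DELTA_SOLUTION, 6750.0, [d, d, d])
        assert state.f_remaining == pytest.approx(1 - 360.0 / 6750.0)
        assert state.f_remaining * state.delta_final + (
            1 - state.f_remaining
        ) * d.delta_total.value == pytest.approx(-0.36, abs=1e-12)

    def test_overdrawn_reservoir_rejected(self):
        p = make_plant({"root": (10.0, 1000.0, -0.7, 0.05)})
        with pytest.raises(ValueError, match="reservoir"):
            final_solution_state(tables.DELTA_SOLUTION, 6750.0, [plant_totals(p)])
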