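"""Flux model: component fluxes, fractionation factors, mass balance."""

from dataclasses import replace

import pytest

from oxflux.iso import TripleOxygenComposition
from oxflux.model import (
    MassBalanceError,
    MeasuredFluxTotals,
    ModelParameters,
    base_model_parameters,
    base_model_totals,
    fractionation_factors,
    input_fluxes,
    output_fluxes,
    predict_body_water,
    run_model,
    vapour_pressure_deficit,
)


def _by_name(components):
    return {c.name: c for c in components}


class TestInputFluxes:
    def test_component_moles(self, base_params, base_totals):
        inputs = _by_name(input_fluxes(base_params, base_totals))
        # independent hand evaluation of each flux from the base totals
        assert inputs["drinking_water"].moles_O == pytest.approx(
            10.44 / 18.0, abs=1e-12)
        assert inputs["food_water"].moles_O == pytest.approx(
            0.07126943736263737, abs=1e-10)
        assert inputs["oxidase_water"].moles_O == pytest.approx(
            0.4980291873963516, abs=1e-10)
        assert inputs["inhaled_vapour"].moles_O == pytest.approx(
            0.06453293713293776, abs=1e-10)
        assert inputs["condensation_water"].moles_O == pytest.approx(
            0.08238211967999999, abs=1e-10)
        assert inputs["decarboxylation_oxygen"].moles_O == pytest.approx(
            0.18482882936, abs=1e-10)

    def test_every_input_has_source(self, base_params, base_totals):
        for c in input_fluxes(base_params, base_totals):
            assert c.source is not None
            assert c.role == "input"

    def test_non_fractionating_inputs(self, base_params, base_totals):
        inputs = _by_name(input_fluxes(base_params, base_totals))
        for name in ("drinking_water", "food_water"):
            assert inputs[name].frac_factor.alpha18 == 1.0
            assert inputs[name].frac_factor.alpha17 == 1.0

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            MeasuredFluxTotals(o2_ml=-1.0, co2_ml=0.0, food_kg=0.0,
                               water_ml=0.0, window_hours=96.0)


class TestFractionationFactors:
    def test_oxidase_alpha(self, base_params):
        ff = fractionation_factors(base_params)
        assert ff["oxidase_water"].alpha18 == pytest.approx(
            0.994155861487993, abs=1e-12)
        assert ff["oxidase_water"].theta == 0.5179

    def test_vapour_equilibrium_alpha(self, base_params):
        ff = fractionation_factors(base_params)
        assert ff["inhaled_vapour"].alpha18 == pytest.approx(
            1.0093440468616066, abs=1e-12)

    def test_co2_alpha_at_38C(self, base_params):
        ff = fractionation_factors(base_params)
        assert ff["exhaled_co2"].alpha18 == pytest.approx(
            1.0383786165322528, abs=1e-12)

    def test_bound_oxygen_weighted_alpha(self, base_params):
        ff = fractionation_factors(base_params)
        # mass-weighted mean of per-ingredient (1000+δcell)/(1000+δpre)
        assert ff["bound_oxygen"].alpha18 == pytest.approx(
            1.0304347389558233, abs=1e-12)

    def test_equilibrium_sanity(self, base_params):
        ff = fractionation_factors(base_params)
        assert ff["oral_vapour"].alpha18 < 1.0 < ff["inhaled_vapour"].alpha18
        assert ff["exhaled_co2"].alpha18 == pytest.approx(1.038, abs=1e-3)
        # nasal air is cooler than body air: stronger retention of 18O
        assert ff["nasal_vapour"].alpha18 < ff["oral_vapour"].alpha18

    def test_override_replaces_alpha_keeps_theta(self, base_params):
        p = replace(base_params,
                    alpha18_overrides={"oxidase_water": 0.99})
        ff = fractionation_factors(p)
        assert ff["oxidase_water"].alpha18 == 0.99
        assert ff["oxidase_water"].theta == 0.5179

    def test_unknown_override_rejected(self, base_params):
        p = replace(base_params, alpha18_overrides={"drinking_water": 1.0})
        with pytest.raises(KeyError):
            fractionation_factors(p)

    def test_ouf_of_one_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(ouf=1.0)


class TestVapourPressureDeficit:
    def test_saturated_air(self):
        kpa, mmhg = vapour_pressure_deficit(25.0, 1.0)
        assert kpa == 0.0 and mmhg == 0.0

    def test_base_conditions(self):
        kpa, mmhg = vapour_pressure_deficit(25.0, 0.45)
        assert kpa == pytest.approx(1.742121067057489, abs=1e-9)
        assert mmhg == pytest.approx(13.066988117992741, abs=1e-6)

    def test_freezing_dry_air(self):
        kpa, _ = vapour_pressure_deficit(0.0, 0.0)
        assert kpa == pytest.approx(0.61078, abs=1e-9)

    def test_invalid_humidity(self):
        with pytest.raises(ValueError):
            vapour_pressure_deficit(25.0, 1.5)


class TestOutputFluxes:
    @pytest.fixture()
    def outputs(self, base_params, base_totals):
        total_in = sum(c.moles_O
                       for c in input_fluxes(base_params, base_totals))
        return _by_name(output_fluxes(base_params, base_totals, total_in))

    def test_component_moles(self, outputs):
        assert outputs["faecal_bound"].moles_O == 0.0
        assert outputs["faecal_water"].moles_O == pytest.approx(
            0.13211242, abs=1e-8)
        assert outputs["transcutaneous"].moles_O == pytest.approx(
            0.14120830773586512, abs=1e-8)
        assert outputs["oral_vapour"].moles_O == pytest.approx(
            0.16089365680134296, abs=1e-8)
        assert outputs["nasal_vapour"].moles_O == pytest.approx(
            0.08044682840067148, abs=1e-8)
        assert outputs["exhaled_co2"].moles_O == pytest.approx(
            0.42834, abs=1e-10)
        assert outputs["urea_oxygen"].moles_O == pytest.approx(
            0.033602676, abs=1e-10)

    def test_urinary_closes_balance(self, base_params, base_totals):
        inputs = input_fluxes(base_params, base_totals)
        total_in = sum(c.moles_O for c in inputs)
        outputs = output_fluxes(base_params, base_totals, total_in)
        assert sum(c.moles_O for c in outputs) == pytest.approx(
            total_in, rel=1e-14)

    def test_trivial_conservation(self, base_params, base_totals):
        outputs = output_fluxes(base_params, base_totals, 10.0)
        urinary = _by_name(outputs)["urinary_water"].moles_O
        others = sum(c.moles_O for c in outputs) - urinary
        assert urinary == pytest.approx(10.0 - others, rel=1e-14)

    def test_negative_residual_raises_with_magnitudes(self, base_params,
                                                      base_totals):
        with pytest.raises(MassBalanceError, match="co2"):
            output_fluxes(base_params, base_totals, 0.1)


class TestPrediction:
    def test_degenerate_well_mixed_case(self, base_totals):
        source = TripleOxygenComposition.from_cap17(-7.5, 12.0)
        p = base_model_parameters(
            preformed_water=source, atmospheric_O2=source,
            food_free_water=source,
            alpha18_overrides={name: 1.0 for name in (
                "oxidase_water", "inhaled_vapour", "transcutaneous",
                "oral_vapour", "nasal_vapour", "exhaled_co2")},
            cellulose_d18O_by_ingredient={"chow": (source.d18O, 1.0)},
        )
        # bound-oxygen alpha is cellulose/pre-formed: equal deltas give 1
        pred = run_model(p, base_totals)
        assert pred.d18O_bw == pytest.approx(source.d18O, abs=1e-9)
        assert pred.d17O_bw == pytest.approx(source.d17O, abs=1e-9)
        assert pred.cap17O_bw == pytest.approx(source.cap17O, abs=1e-6)

    def test_fraction_maps_sum_to_one(self, base_params, base_totals):
        pred = run_model(base_params, base_totals)
        assert sum(pred.input_fractions.values()) == pytest.approx(
            1.0, abs=1e-12)
        assert sum(pred.output_fractions.values()) == pytest.approx(
            1.0, abs=1e-12)

    def test_redistribution_among_non_fractionating_outputs(
            self, base_params, base_totals):
        # moving moles between faecal water and urinary water (both α=1)
        # must leave the prediction unchanged
        base = run_model(base_params, base_totals)
        moved = run_model(replace(base_params, faecal_water_fraction=0.30),
                          base_totals)
        assert moved.d18O_bw == pytest.approx(base.d18O_bw, abs=1e-9)
        assert moved.cap17O_bw == pytest.approx(base.cap17O_bw, abs=1e-6)

    def test_unclosed_balance_rejected(self, base_params, base_totals):
        inputs = input_fluxes(base_params, base_totals)
        outputs = output_fluxes(base_params, base_totals,
                                sum(c.moles_O for c in inputs) + 1.0)
        with pytest.raises(MassBalanceError):
            predict_body_water(inputs, outputs, base_params)

    def test_more_drinking_raises_cap17(self, base_params, base_totals):
        caps = []
        for scale in [0.8 + 0.05 * i for i in range(10)]:
            t = replace(base_totals, water_ml=base_totals.water_ml * scale)
            caps.append(run_model(base_params, t).cap17O_bw)
        assert all(b > a for a, b in zip(caps, caps[1:]))

    def test_more_oxygen_lowers_cap17(self, base_params, base_totals):
        rq = base_totals.co2_ml / base_totals.o2_ml
        caps = []
        for scale in [0.8 + 0.05 * i for i in range(10)]:
            o2 = base_totals.o2_ml * scale
            t = replace(base_totals, o2_ml=o2, co2_ml=o2 * rq)
            caps.append(run_model(base_params, t).cap17O_bw)
        assert all(b < a for a, b in zip(caps, caps[1:]))

    def test_base_model_prediction_regression(self, base_params, base_totals):
        pred = run_model(base_params, base_totals)
        # frozen output of this implementation (guards against drift)
        assert pred.d18O_bw == pytest.approx(0.14044971, abs=1e-6)
        assert pred.cap17O_bw == pytest.approx(-75.7832, abs=1e-3)
        assert pred.urinary_moles == pytest.approx(0.504439, abs=1e-5)


class TestTotals:
    def test_co2_mol_round_trip(self):
        t = MeasuredFluxTotals.from_co2_mol(5582.0, 0.21417, 0.01297,
                                            10.44, 96.0)
        assert t.co2_mol == pytest.approx(0.21417, rel=1e-14)
        assert t.co2_ml == pytest.approx(0.21417 * 22.4 * 1000, rel=1e-14)

    def test_window_days(self):
        assert base_model_totals().window_days == 4.0
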