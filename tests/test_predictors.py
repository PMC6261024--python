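"""Prediction formulae: hand-algebra oracles, identities and property tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracle_hand_algebra as oracle
from natribalance import (
    KURTZ_NGUYEN_OFFSET,
    KURTZ_NGUYEN_SLOPE,
    FluidFlux,
    PatientEpoch,
    PredictorConfig,
    efwc_rose,
    predict_adrogue_madias,
    predict_all,
    predict_barsoum_levine,
    predict_efwc,
    predict_kurtz_nguyen,
    predict_mass_balance,
    summarize_balance,
    total_body_water,
)
from natribalance.errors import DegenerateBalanceError, ValidationError


def make_epoch(na1=140.0, weight=70.0, fluxes=(), **kw):
    return PatientEpoch("P1", "epoch1", weight, na1, fluxes=tuple(fluxes), **kw)


class TestTotalBodyWater:
    def test_half_body_weight_rule(self):
        assert total_body_water(70.0) == 35.0
        assert total_body_water(70.0, 0.6) == pytest.approx(42.0)

    @pytest.mark.parametrize("weight,fraction", [(0.0, 0.5), (-10.0, 0.5), (70.0, 0.0), (70.0, 1.0)])
    def test_invalid_arguments(self, weight, fraction):
        with pytest.raises(ValidationError):
            total_body_water(weight, fraction)


class TestBalanceSummary:
    def test_no_fluxes_all_zero(self):
        bal = summarize_balance(make_epoch())
        assert bal.tbw == 35.0
        assert (bal.total_input_volume, bal.total_output_volume, bal.equilibrium) == (0, 0, 0)
        assert (bal.na_in, bal.na_out, bal.k_in, bal.k_out) == (0, 0, 0, 0)

    def test_equilibrium_is_signed_net_volume(self):
        ep = make_epoch(fluxes=[
            FluidFlux("infused", 1.0, 154.0),
            FluidFlux("enteral", 0.5, 40.0, 20.0),
            FluidFlux("urine", 1.0, 80.0),
        ])
        bal = summarize_balance(ep)
        assert bal.equilibrium == pytest.approx(0.5)
        assert bal.equilibrium == bal.total_input_volume - bal.total_output_volume
        assert bal.na_in == pytest.approx(154.0 + 20.0)
        assert bal.na_out == pytest.approx(80.0)
        assert bal.k_in == pytest.approx(10.0)

    def test_single_isotonic_liter(self):
        bal = summarize_balance(make_epoch(fluxes=[FluidFlux("infused", 1.0, 154.0)]))
        assert bal.na_in == pytest.approx(154.0)


class TestMassBalance:
    def test_zero_flux_identity_exact(self):
        assert predict_mass_balance(make_epoch()) == 140.0

    def test_single_infusion_hand_algebra(self):
        ep = make_epoch(fluxes=[FluidFlux("infused", 1.0, 154.0)])
        assert predict_mass_balance(ep) == pytest.approx(140.3889, abs=1e-4)
        assert predict_mass_balance(ep) == pytest.approx(
            oracle.mass_balance_symbolic(140, 35, [(154, 1)]), abs=1e-9
        )

    def test_urine_only_hand_algebra(self):
        ep = make_epoch(fluxes=[FluidFlux("urine", 1.0, 70.0)])
        assert predict_mass_balance(ep) == pytest.approx(142.0588, abs=1e-4)
        assert predict_mass_balance(ep) == pytest.approx(
            oracle.mass_balance_symbolic(140, 35, [], urine_vol=1, urine_na=70), abs=1e-9
        )

    def test_degenerate_balance_names_patient(self):
        ep = make_epoch(weight=2.0, fluxes=[FluidFlux("urine", 1.5, 50.0)])
        with pytest.raises(DegenerateBalanceError, match="P1"):
            predict_mass_balance(ep)

    def test_potassium_never_enters_mass_balance(self):
        with_k = make_epoch(fluxes=[FluidFlux("infused", 1.0, 154.0, k_conc=40.0)])
        without_k = make_epoch(fluxes=[FluidFlux("infused", 1.0, 154.0)])
        assert predict_mass_balance(with_k) == predict_mass_balance(without_k)


class TestComparators:
    def test_adrogue_madias_hand_algebra(self):
        assert predict_adrogue_madias(140, 35, 0, 154) == 140.0
        assert predict_adrogue_madias(140, 35, 1, 154) == pytest.approx(140.3889, abs=1e-4)
        assert predict_adrogue_madias(140, 35, 1, 0) == pytest.approx(136.1111, abs=1e-4)
        assert predict_adrogue_madias(140, 35, 1, 154) == pytest.approx(
            oracle.adrogue_madias_fraction(140, 35, 1, 154), abs=1e-9
        )

    def test_barsoum_levine_hand_algebra(self):
        assert predict_barsoum_levine(140, 35, 0, 0, 0, 0) == 140.0
        assert predict_barsoum_levine(140, 35, 1, 154, 1, 120) == pytest.approx(140.9714, abs=1e-4)
        assert predict_barsoum_levine(140, 35, 1, 154, 1, 120) == pytest.approx(
            oracle.barsoum_levine_fraction(140, 35, 1, 154, 1, 120), abs=1e-9
        )

    def test_barsoum_levine_reduces_to_adrogue_madias_without_output(self):
        assert predict_barsoum_levine(140, 35, 1, 154, 0, 0) == pytest.approx(
            predict_adrogue_madias(140, 35, 1, 154), abs=1e-12
        )

    def test_kurtz_nguyen_hand_algebra(self):
        assert predict_kurtz_nguyen(140, 35, 0, 0, 0) == 140.0
        assert predict_kurtz_nguyen(140, 35, 100, 0, 0) == pytest.approx(142.9429, abs=1e-4)
        assert predict_kurtz_nguyen(140, 35, 0, 0, 1) == pytest.approx(135.45, abs=1e-4)
        assert predict_kurtz_nguyen(141, 33, 80, 30, 0.4) == pytest.approx(
            oracle.kurtz_nguyen_fraction(141, 33, 80, 30, 0.4), abs=1e-9
        )

    def test_kurtz_nguyen_constants_exported(self):
        assert KURTZ_NGUYEN_OFFSET == 23.8
        assert KURTZ_NGUYEN_SLOPE == 1.03

    def test_efwc_rose_hand_algebra(self):
        assert efwc_rose(0, 100, 0, 140) == 0.0
        assert efwc_rose(2, 70, 0, 140) == pytest.approx(1.0, abs=1e-12)
        # urine more concentrated than serum: negative clearance allowed
        assert efwc_rose(1, 214, 0, 107) == pytest.approx(-1.0, abs=1e-12)
        assert efwc_rose(1.3, 110, 25, 143) == pytest.approx(
            oracle.efwc_fraction(1.3, 110, 25, 143), abs=1e-12
        )
        with pytest.raises(ValidationError):
            efwc_rose(1, 100, 0, 0)

    def test_efwc_prediction_hand_algebra(self):
        assert predict_efwc(140, 35, 0) == 140.0
        assert predict_efwc(140, 35, 1) == pytest.approx(144.1176, abs=1e-4)
        assert predict_efwc(140, 35, -1) == pytest.approx(136.1111, abs=1e-4)
        assert predict_efwc(140, 35, 1) == pytest.approx(
            oracle.efwc_prediction_fraction(140, 35, 1), abs=1e-9
        )

    @pytest.mark.parametrize("call", [
        lambda: predict_adrogue_madias(140, 1, -1.5, 154),
        lambda: predict_barsoum_levine(140, 1, 0, 0, 2, 100),
        lambda: predict_kurtz_nguyen(140, 1, 0, 0, -2),
        lambda: predict_efwc(140, 1, 2),
    ])
    def test_nonpositive_denominators_raise(self, call):
        with pytest.raises(DegenerateBalanceError):
            call()


class TestPredictAll:
    def test_zero_flux_epoch_all_predictors_identity(self):
        results, failures = predict_all(make_epoch())
        assert not failures
        assert len(results) == 5
        assert all(r.na_predicted == 140.0 for r in results)

    def test_mass_balance_equals_adrogue_madias_on_single_infusion(self, simple_epoch):
        results, _ = predict_all(simple_epoch)
        by_name = {r.predictor: r.na_predicted for r in results}
        assert by_name["mass_balance"] == pytest.approx(by_name["adrogue_madias"], abs=1e-9)
        assert by_name["mass_balance"] == pytest.approx(by_name["barsoum_levine"], abs=1e-9)

    def test_degenerate_predictor_tagged_others_survive(self):
        # massive urinary loss: mass balance, Barsoum-Levine and Kurtz-Nguyen
        # denominators collapse, Adrogue-Madias (closed system) survives
        ep = make_epoch(weight=4.0, fluxes=[FluidFlux("urine", 2.5, 50.0)])
        results, failures = predict_all(ep)
        failed = {name for name, _ in failures}
        assert failed == {"mass_balance", "barsoum_levine", "kurtz_nguyen"}
        assert {r.predictor for r in results} == {"adrogue_madias", "efwc"}

    def test_potassium_flag_affects_comparators_only(self):
        ep = make_epoch(fluxes=[
            FluidFlux("parenteral", 1.0, 77.0, k_conc=20.0),
            FluidFlux("urine", 0.5, 60.0),
        ])
        with_k, _ = predict_all(ep, PredictorConfig(include_potassium=True))
        no_k, _ = predict_all(ep, PredictorConfig(include_potassium=False))
        w = {r.predictor: r.na_predicted for r in with_k}
        n = {r.predictor: r.na_predicted for r in no_k}
        assert w["mass_balance"] == n["mass_balance"]
        assert w["barsoum_levine"] != n["barsoum_levine"]
        assert w["kurtz_nguyen"] != n["kurtz_nguyen"]

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValidationError):
            PredictorConfig(predictors=("mass_balance", "magic"))


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

na1_st = st.floats(120, 160)
tbw_st = st.floats(20, 50)
vol_st = st.floats(0.001, 3)
conc_st = st.floats(0, 513)


@given(na1=na1_st, weight=st.floats(30, 140))
def test_every_predictor_is_exact_on_flux_free_epochs(na1, weight):
    results, failures = predict_all(make_epoch(na1=na1, weight=weight))
    assert not failures
    assert all(r.na_predicted == na1 for r in results)


@given(na1=na1_st, tbw=tbw_st, vol=vol_st, conc=conc_st)
def test_single_infusion_cross_formula_equivalence(na1, tbw, vol, conc):
    """Mass balance, Adrogue-Madias and Barsoum-Levine coincide on a single
    potassium-free infusion with no urinary output."""
    ep = make_epoch(na1=na1, weight=2 * tbw, fluxes=[FluidFlux("infused", vol, conc)])
    mb = predict_mass_balance(ep)
    am = predict_adrogue_madias(na1, tbw, vol, conc)
    bl = predict_barsoum_levine(na1, tbw, vol, conc * vol, 0, 0)
    assert mb == pytest.approx(am, abs=1e-9)
    assert mb == pytest.approx(bl, abs=1e-9)


@given(na1=na1_st, tbw=tbw_st, vol=st.floats(0.1, 3), conc=conc_st,
       extra=st.floats(0.1, 2))
def test_mass_balance_monotone_in_infused_volume(na1, tbw, vol, conc, extra):
    """More of a hypotonic (relative to the current prediction) infusate
    lowers the predicted sodium; more of a hypertonic one raises it."""
    def pred(v):
        return predict_mass_balance(
            make_epoch(na1=na1, weight=2 * tbw, fluxes=[FluidFlux("infused", v, conc)])
        )

    base = pred(vol)
    more = pred(vol + extra)
    if conc < base - 1e-6:
        assert more < base
    elif conc > base + 1e-6:
        assert more > base


@given(na1=na1_st, tbw=tbw_st, vol=vol_st, conc=conc_st,
       uvol=st.floats(0.05, 1), una=st.floats(10, 215), scale=st.floats(0.2, 5))
def test_dimensional_invariance_under_volume_scaling(na1, tbw, vol, conc, uvol, una, scale):
    """Scaling every volume and TBW by a common factor, concentrations fixed,
    leaves every predicted concentration unchanged."""
    def build(c):
        return make_epoch(na1=na1, weight=2 * tbw * c, fluxes=[
            FluidFlux("infused", vol * c, conc),
            FluidFlux("urine", uvol * c, una),
        ])

    p1, _ = predict_all(build(1.0))
    p2, _ = predict_all(build(scale))
    a = {r.predictor: r.na_predicted for r in p1}
    b = {r.predictor: r.na_predicted for r in p2}
    assert set(a) == set(b)
    for name in a:
        assert a[name] == pytest.approx(b[name], rel=1e-9)


@given(na1=na1_st, tbw=tbw_st, vol=vol_st, conc=conc_st,
       uvol=st.floats(0.05, 1), una=st.floats(10, 215))
def test_numerator_conservation_identity(na1, tbw, vol, conc, uvol, una):
    """The mass-balance numerator equals na1*TBW + na_in - na_out exactly."""
    ep = make_epoch(na1=na1, weight=2 * tbw, fluxes=[
        FluidFlux("infused", vol, conc),
        FluidFlux("urine", uvol, una),
    ])
    bal = summarize_balance(ep)
    pred = predict_mass_balance(ep)
    assert pred * (bal.tbw + bal.equilibrium) == pytest.approx(
        na1 * bal.tbw + bal.na_in - bal.na_out, rel=1e-12
    )
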