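"""Independent hand-algebra oracles for the prediction and dosing formulae.

These recompute every formula by a route independent of the package
implementation: the mass balance and its dosing inverse are solved
symbolically with sympy from the conservation statement, the comparator
formulae are evaluated with exact rational arithmetic (fractions.Fraction),
and the agreement statistics use the stdlib ``statistics`` module. They are
used by the tests to cross-check the numpy/float implementation and are
never imported by the package itself.
"""

from __future__ import annotations

from fractions import Fraction
from statistics import mean, stdev

import sympy as sp


def mass_balance_symbolic(na1, tbw, inputs, urine_vol=0, urine_na=0):
    """Solve the conservation statement for the final sodium with sympy.

    ``inputs`` is a list of (na_conc, volume) pairs. The statement is:
    initial sodium amount + input amounts - urinary amount =
    final concentration x (TBW + net volume balance).
    """
    na_final = sp.Symbol("na_final")
    vol_in = sum(sp.Rational(str(v)) for _, v in inputs)
    na_in = sum(sp.Rational(str(c)) * sp.Rational(str(v)) for c, v in inputs)
    equilibrium = vol_in - sp.Rational(str(urine_vol))
    lhs = (
        sp.Rational(str(na1)) * sp.Rational(str(tbw))
        + na_in
        - sp.Rational(str(urine_na)) * sp.Rational(str(urine_vol))
    )
    eq = sp.Eq(lhs, na_final * (sp.Rational(str(tbw)) + equilibrium))
    (sol,) = sp.solve(eq, na_final)
    return float(sol)


def infusion_volume_symbolic(na1, tbw, na_target, infusate_na,
                             inputs=(), urine_vol=0, urine_na=0):
    """Solve the same conservation statement for the unknown infusion volume,
    which also enters the net volume balance."""
    v = sp.Symbol("v")
    vol_other = sum(sp.Rational(str(vv)) for _, vv in inputs)
    na_other = sum(sp.Rational(str(c)) * sp.Rational(str(vv)) for c, vv in inputs)
    lhs = (
        sp.Rational(str(na1)) * sp.Rational(str(tbw))
        + na_other
        + sp.Rational(str(infusate_na)) * v
        - sp.Rational(str(urine_na)) * sp.Rational(str(urine_vol))
    )
    rhs = sp.Rational(str(na_target)) * (
        sp.Rational(str(tbw)) + vol_other + v - sp.Rational(str(urine_vol))
    )
    sols = sp.solve(sp.Eq(lhs, rhs), v)
    if not sols:
        return None
    return float(sols[0])


def _F(x) -> Fraction:
    return Fraction(str(x))


def adrogue_madias_fraction(na1, tbw, vol_inf, na_k_conc) -> float:
    return float((_F(na1) * _F(tbw) + _F(vol_inf) * _F(na_k_conc)) / (_F(tbw) + _F(vol_inf)))


def barsoum_levine_fraction(na1, tbw, vol_in, na_k_in, vol_out, na_k_out) -> float:
    return float(
        (_F(na1) * _F(tbw) + _F(na_k_in) - _F(na_k_out))
        / (_F(tbw) + _F(vol_in) - _F(vol_out))
    )


def kurtz_nguyen_fraction(na1, tbw, na_k_in, na_k_out, delta_vol) -> float:
    num = (_F(na1) + _F("23.8")) * _F(tbw) + _F("1.03") * (_F(na_k_in) - _F(na_k_out))
    return float(num / (_F(tbw) + _F(delta_vol)) - _F("23.8"))


def efwc_fraction(vol_urine, na_urine, k_urine, na_serum) -> float:
    return float(_F(vol_urine) * (1 - (_F(na_urine) + _F(k_urine)) / _F(na_serum)))


def efwc_prediction_fraction(na1, tbw, efwc) -> float:
    return float(_F(na1) * _F(tbw) / (_F(tbw) - _F(efwc)))


def bland_altman_brute(predicted, measured):
    """Bias, sample SD and 95% limits via the stdlib statistics module."""
    diffs = [p - m for p, m in zip(predicted, measured, strict=True)]
    bias = mean(diffs)
    sd = stdev(diffs)
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def percentage_similarity_brute(predicted, measured):
    sims = [100.0 * ((p + m) / 2.0) / m for p, m in zip(predicted, measured, strict=True)]
    m_ = mean(sims)
    sd = stdev(sims)
    return m_, sd, m_ - 100.0, 100.0 * sd / m_
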