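"""Serum-sodium prediction formulae over one 8-hour epoch.

The core predictor is a mass-conservation balance: the sodium amount in body
water at the end of an epoch equals the initial amount plus every recorded
sodium input (infused, drug, enteral, parenteral solutions) minus the urinary
output, while body water changes by the net fluid balance ("equilibrium" =
total input volume - total output volume)::

    Na_final = (Na_initial*TBW + sum_i Na_i*V_i - Na_urine*V_urine) / (TBW + equilibrium)

Total body water (TBW) is estimated as body weight x 0.5 for all patients.
Insensible (skin/gastrointestinal) water and sodium losses are not modeled,
and the mass-balance formula deliberately omits potassium.

Four published comparator formulae are provided in their standard closed
forms: Adrogue-Madias (single-infusion, closed-system), Barsoum-Levine
(adds renal losses), the electrolyte-free water clearance (EFWC) formula,
and Kurtz-Nguyen (plasma-water correction with constants 1.03 and 23.8).
Where a comparator admits potassium, recorded potassium contributes by
default; the mass-balance predictor never includes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domain import FluidFlux, PatientEpoch, PredictionResult
from .errors import DegenerateBalanceError, ValidationError

__all__ = [
    "TBW_FRACTION_DEFAULT",
    "KURTZ_NGUYEN_OFFSET",
    "KURTZ_NGUYEN_SLOPE",
    "PREDICTOR_NAMES",
    "BalanceSummary",
    "PredictorConfig",
    "total_body_water",
    "summarize_balance",
    "predict_mass_balance",
    "predict_adrogue_madias",
    "predict_barsoum_levine",
    "predict_kurtz_nguyen",
    "efwc_rose",
    "predict_efwc",
    "predict_all",
]

#: Default total-body-water fraction of actual body weight (both sexes, all ages).
TBW_FRACTION_DEFAULT = 0.5
#: Kurtz-Nguyen additive plasma-water offset (mmol/L).
KURTZ_NGUYEN_OFFSET = 23.8
#: Kurtz-Nguyen electrolyte-gain coefficient (dimensionless).
KURTZ_NGUYEN_SLOPE = 1.03

#: Smallest denominator (liters) accepted before a balance is called degenerate.
_DENOMINATOR_GUARD = 1e-9

PREDICTOR_NAMES = (
    "mass_balance",
    "adrogue_madias",
    "barsoum_levine",
    "kurtz_nguyen",
    "efwc",
)


@dataclass(frozen=True)
class BalanceSummary:
    """Aggregated volumes (L) and electrolyte amounts (mmol) for one epoch.

    ``equilibrium`` is the signed net fluid balance, total_input_volume -
    total_output_volume.
    """

    tbw: float
    total_input_volume: float
    total_output_volume: float
    equilibrium: float
    na_in: float
    na_out: float
    k_in: float
    k_out: float


@dataclass(frozen=True)
class PredictorConfig:
    """Configuration shared by :func:`predict_all`.

    ``include_potassium`` controls whether recorded potassium contributes to
    the comparator formulae; the mass-balance formula never includes it.
    """

    tbw_fraction: float = TBW_FRACTION_DEFAULT
    predictors: tuple[str, ...] = PREDICTOR_NAMES
    include_potassium: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.predictors) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValidationError(f"unknown predictor(s): {sorted(unknown)}")


def total_body_water(weight: float, fraction: float = TBW_FRACTION_DEFAULT) -> float:
    """Total body water (L) as a fixed fraction of actual body weight (kg)."""
    if not weight > 0:
        raise ValidationError(f"weight must be > 0 kg, got {weight!r}")
    if not 0 < fraction < 1:
        raise ValidationError(f"tbw fraction must lie in (0, 1), got {fraction!r}")
    return weight * fraction


def summarize_balance(
    epoch: PatientEpoch, tbw_fraction: float = TBW_FRACTION_DEFAULT
) -> BalanceSummary:
    """Aggregate an epoch's fluxes into input/output volumes and electrolyte amounts."""
    vol_in = sum(f.volume for f in epoch.fluxes if not f.is_output)
    vol_out = sum(f.volume for f in epoch.fluxes if f.is_output)
    return BalanceSummary(
        tbw=total_body_water(epoch.weight, tbw_fraction),
        total_input_volume=vol_in,
        total_output_volume=vol_out,
        equilibrium=vol_in - vol_out,
        na_in=sum(f.na_amount for f in epoch.fluxes if not f.is_output),
        na_out=sum(f.na_amount for f in epoch.fluxes if f.is_output),
        k_in=sum(f.k_amount for f in epoch.fluxes if not f.is_output),
        k_out=sum(f.k_amount for f in epoch.fluxes if f.is_output),
    )


def _checked_denominator(value: float, context: str) -> float:
    if value <= _DENOMINATOR_GUARD:
        raise DegenerateBalanceError(
            f"non-positive denominator ({value:g} L) in {context}"
        )
    return value


def predict_mass_balance(
    epoch: PatientEpoch, tbw_fraction: float = TBW_FRACTION_DEFAULT
) -> float:
    """Mass-conservation sodium prediction (mmol/L) for one epoch.

    Returns ``(Na_initial*TBW + na_in - na_out) / (TBW + equilibrium)`` where
    the equilibrium is the signed net fluid balance. Potassium never enters
    this formula.
    """
    bal = summarize_balance(epoch, tbw_fraction)
    denom = _checked_denominator(
        bal.tbw + bal.equilibrium, f"mass balance for patient {epoch.patient_id}"
    )
    # exact zero-flux identity: the formula reduces algebraically to na_initial
    if bal.equilibrium == 0 and bal.na_in == bal.na_out:
        return epoch.na_initial
    return (epoch.na_initial * bal.tbw + bal.na_in - bal.na_out) / denom


def predict_adrogue_madias(
    na1: float, tbw: float, vol_inf: float, na_k_inf_conc: float
) -> float:
    """Adrogue-Madias prediction (mmol/L): serum sodium after infusing
    ``vol_inf`` liters of a solution with combined Na+K concentration
    ``na_k_inf_conc`` (mmol/L), treating the body as a closed system.

    Originally derived for a 1 L infusion; other volumes are accepted.
    """
    denom = _checked_denominator(tbw + vol_inf, "Adrogue-Madias")
    if vol_inf == 0:  # exact no-infusion identity
        return na1
    return (na1 * tbw + vol_inf * na_k_inf_conc) / denom


def predict_barsoum_levine(
    na1: float,
    tbw: float,
    vol_in: float,
    na_k_in: float,
    vol_out: float,
    na_k_out: float,
) -> float:
    """Barsoum-Levine prediction (mmol/L), extending Adrogue-Madias with renal
    losses. ``na_k_in``/``na_k_out`` are electrolyte *amounts* in mmol."""
    delta_vol = vol_in - vol_out
    denom = _checked_denominator(tbw + delta_vol, "Barsoum-Levine")
    if delta_vol == 0 and na_k_in == na_k_out:  # exact balanced-exchange identity
        return na1
    return (na1 * tbw + na_k_in - na_k_out) / denom


def predict_kurtz_nguyen(
    na1: float, tbw: float, na_k_in: float, na_k_out: float, delta_vol: float
) -> float:
    """Kurtz-Nguyen prediction (mmol/L): mass balance in plasma water, with the
    empirical offset 23.8 mmol/L and gain coefficient 1.03 on the net
    electrolyte amount (mmol)."""
    denom = _checked_denominator(tbw + delta_vol, "Kurtz-Nguyen")
    if delta_vol == 0 and na_k_in == na_k_out:  # exact balanced-exchange identity
        return na1
    return (
        (na1 + KURTZ_NGUYEN_OFFSET) * tbw + KURTZ_NGUYEN_SLOPE * (na_k_in - na_k_out)
    ) / denom - KURTZ_NGUYEN_OFFSET


def efwc_rose(
    vol_urine: float, na_urine: float, k_urine: float, na_serum: float
) -> float:
    """Electrolyte-free water clearance (L) after Rose:
    ``V_urine * (1 - (Na_u + K_u)/Na_serum)``.

    Negative when urine is more concentrated than serum (net free-water gain).
    """
    if not na_serum > 0:
        raise ValidationError(f"serum sodium must be > 0, got {na_serum!r}")
    if vol_urine < 0:
        raise ValidationError(f"urine volume must be >= 0, got {vol_urine!r}")
    return vol_urine * (1.0 - (na_urine + k_urine) / na_serum)


def predict_efwc(na1: float, tbw: float, efwc: float) -> float:
    """EFWC-based prediction (mmol/L): the serum sodium after the kidneys clear
    ``efwc`` liters of electrolyte-free water, ``na1 * TBW / (TBW - EFWC)``."""
    denom = _checked_denominator(tbw - efwc, "EFWC prediction")
    if efwc == 0:  # exact zero-clearance identity
        return na1
    return na1 * tbw / denom


def _comparator_inputs(
    epoch: PatientEpoch, bal: BalanceSummary, include_potassium: bool
) -> dict:
    k_in = bal.k_in if include_potassium else 0.0
    k_out = bal.k_out if include_potassium else 0.0
    urine = epoch.urine
    return {
        "vol_in": bal.total_input_volume,
        "vol_out": bal.total_output_volume,
        "na_k_in": bal.na_in + k_in,
        "na_k_out": bal.na_out + k_out,
        "urine_vol": urine.volume if urine else 0.0,
        "urine_na": urine.na_conc if urine else 0.0,
        "urine_k": (urine.k_conc if include_potassium else 0.0) if urine else 0.0,
    }


def predict_all(
    epoch: PatientEpoch, config: PredictorConfig = PredictorConfig()
) -> tuple[list[PredictionResult], list[tuple[str, str]]]:
    """Run every enabled predictor on one epoch.

    Comparator inputs (total volumes, Na+K amounts, EFWC) are assembled from
    the epoch's :class:`BalanceSummary`; the comparators are applied to the
    epoch's *total* fluxes, not per liter. Returns ``(results, failures)``
    where each failure is ``(predictor_name, message)``; a failing predictor
    never prevents the others from being evaluated.
    """
    bal = summarize_balance(epoch, config.tbw_fraction)
    inp = _comparator_inputs(epoch, bal, config.include_potassium)
    na1, tbw = epoch.na_initial, bal.tbw

    def run_mass_balance() -> float:
        return predict_mass_balance(epoch, config.tbw_fraction)

    def run_adrogue_madias() -> float:
        vol_in = inp["vol_in"]
        conc = inp["na_k_in"] / vol_in if vol_in > 0 else 0.0
        return predict_adrogue_madias(na1, tbw, vol_in, conc)

    def run_barsoum_levine() -> float:
        return predict_barsoum_levine(
            na1, tbw, inp["vol_in"], inp["na_k_in"], inp["vol_out"], inp["na_k_out"]
        )

    def run_kurtz_nguyen() -> float:
        return predict_kurtz_nguyen(
            na1, tbw, inp["na_k_in"], inp["na_k_out"], bal.equilibrium
        )

    def run_efwc() -> float:
        efwc = efwc_rose(inp["urine_vol"], inp["urine_na"], inp["urine_k"], na1)
        return predict_efwc(na1, tbw, efwc)

    runners = {
        "mass_balance": run_mass_balance,
        "adrogue_madias": run_adrogue_madias,
        "barsoum_levine": run_barsoum_levine,
        "kurtz_nguyen": run_kurtz_nguyen,
        "efwc": run_efwc,
    }

    results: list[PredictionResult] = []
    failures: list[tuple[str, str]] = []
    for name in config.predictors:
        try:
            value = runners[name]()
            results.append(
                PredictionResult(
                    predictor=name,
                    na_predicted=value,
                    epoch_label=epoch.epoch_label,
                    patient_id=epoch.patient_id,
                )
            )
        except (DegenerateBalanceError, ValidationError) as exc:
            failures.append((name, str(exc)))
    return results, failures
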