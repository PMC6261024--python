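"""Inverse dosing: the infusion volume that drives the mass-balance
prediction to a target serum sodium.

The forward mass balance is linear in the unknown infusion volume ``V`` once
every other flux is held fixed, because ``V`` appears both in the sodium
input term (``infusate_na * V``) and inside the net fluid balance in the
denominator::

    na_target * (TBW + eq_other + V) = na1*TBW + na_in_other - na_out + infusate_na * V

so ``V * (infusate_na - na_target) = na_target*(TBW + eq_other)
- (na1*TBW + na_in_other - na_out)``. A negative solution (the infusate
cannot move the sodium toward the target) is reported as infeasible, not as
fluid removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .domain import FluidFlux, FluxKind, PatientEpoch
from .errors import InfeasibleDoseError, ValidationError
from .predictors import (
    TBW_FRACTION_DEFAULT,
    predict_mass_balance,
    summarize_balance,
)

__all__ = ["DosingPlan", "solve_infusion_volume"]

_TONICITY_EPS = 1e-12


@dataclass(frozen=True)
class DosingPlan:
    """Result of the dosing inversion for one epoch.

    When ``feasible``, adding ``volume_required`` liters of the infusate to
    the epoch makes the forward mass-balance prediction hit ``na_target``
    (to numerical precision). Otherwise ``reason`` says why not.
    """

    na_target: float
    infusate_na: float
    volume_required: float
    feasible: bool
    reason: Optional[str] = None


def solve_infusion_volume(
    epoch: PatientEpoch,
    na_target: float,
    infusate_na: float,
    tbw_fraction: float = TBW_FRACTION_DEFAULT,
) -> DosingPlan:
    """Solve the mass balance for the infusion volume reaching ``na_target``.

    All of the epoch's existing fluxes are treated as fixed; the solved
    infusion is an *additional* input whose volume also enters the net fluid
    balance. Raises :class:`InfeasibleDoseError` when the infusate tonicity
    equals the target (the equation then has no solution unless the target is
    already met), and :class:`ValidationError` for a target outside the
    plausible sodium range.
    """
    if not (100.0 <= na_target <= 200.0):
        raise ValidationError(
            f"implausible target sodium {na_target!r} mmol/L (expected [100, 200])"
        )
    if infusate_na < 0:
        raise ValidationError(f"infusate sodium must be >= 0, got {infusate_na!r}")

    bal = summarize_balance(epoch, tbw_fraction)
    coeff = infusate_na - na_target
    rhs = na_target * (bal.tbw + bal.equilibrium) - (
        epoch.na_initial * bal.tbw + bal.na_in - bal.na_out
    )

    if abs(coeff) <= _TONICITY_EPS:
        if abs(rhs) <= 1e-9:
            return DosingPlan(na_target, infusate_na, 0.0, True)
        raise InfeasibleDoseError(
            "infusate tonicity equals target: no infusion volume can reach "
            f"{na_target:g} mmol/L for patient {epoch.patient_id}"
        )

    volume = rhs / coeff
    if volume < 0:
        return DosingPlan(
            na_target,
            infusate_na,
            volume,
            False,
            reason=(
                "negative volume: the infusate cannot move sodium toward the "
                "target (would require fluid removal)"
            ),
        )
    if bal.tbw + bal.equilibrium + volume <= 0:
        return DosingPlan(
            na_target,
            infusate_na,
            volume,
            False,
            reason="degenerate balance: body water would be non-positive",
        )
    return DosingPlan(na_target, infusate_na, volume, True)


def apply_plan(epoch: PatientEpoch, plan: DosingPlan) -> PatientEpoch:
    """Return the epoch with the planned infusion appended as an ``infused`` flux."""
    if not plan.feasible:
        raise InfeasibleDoseError(f"cannot apply infeasible plan: {plan.reason}")
    return epoch.with_flux(
        FluidFlux(kind=FluxKind.INFUSED, volume=plan.volume_required, na_conc=plan.infusate_na)
    )


__all__.append("apply_plan")
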