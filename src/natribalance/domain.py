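"""Core data model for ICU fluid charts.

A *chart* records, for one patient over one 8-hour epoch, the baseline state
(weight, serum sodium) and every itemized fluid stream — infused, drug,
enteral and parenteral solutions on the input side and urine on the output
side — each with its volume (L) and sodium (and optionally potassium)
concentration (mmol/L). The end-of-epoch measured sodium is attached when the
chart is used for evaluation rather than pure prediction.

Units are part of the file contract: volumes in liters, concentrations in
mmol/L, weight in kg. No unit autodetection is attempted — a wrong-unit chart
is a silent disaster.

The chart CSV is long-format (one flux per row; the patient/epoch columns are
repeated on each row). An epoch with no fluxes occupies a single row whose
flux columns are empty. Columns::

    patient_id, epoch, weight_kg, na_initial, na_final_measured,
    flux_kind, volume_l, na_mmol_per_l, k_mmol_per_l

``na_final_measured`` and ``k_mmol_per_l`` may be empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import ChartParseError, ChartValidationError, ValidationError

__all__ = [
    "FluxKind",
    "EpochLabel",
    "Natremia",
    "FluidFlux",
    "PatientEpoch",
    "PredictionResult",
    "AgreementReport",
    "classify_natremia",
    "read_chart",
    "write_chart",
    "CHART_COLUMNS",
]

#: Serum sodium outside this range (mmol/L) is rejected as an implausible chart entry.
SODIUM_PLAUSIBLE_RANGE = (100.0, 200.0)

#: Hyponatremia threshold (mmol/L); serum sodium strictly below is hyponatremic.
HYPONATREMIA_THRESHOLD = 135.0
#: Hypernatremia threshold (mmol/L); serum sodium strictly above is hypernatremic.
HYPERNATREMIA_THRESHOLD = 145.0

CHART_COLUMNS = [
    "patient_id",
    "epoch",
    "weight_kg",
    "na_initial",
    "na_final_measured",
    "flux_kind",
    "volume_l",
    "na_mmol_per_l",
    "k_mmol_per_l",
]


class FluxKind(str, Enum):
    """Kind of fluid stream. ``urine`` is the only output; all others are inputs."""

    INFUSED = "infused"
    DRUG = "drug"
    ENTERAL = "enteral"
    PARENTERAL = "parenteral"
    URINE = "urine"

    @property
    def is_output(self) -> bool:
        return self is FluxKind.URINE


class EpochLabel(str, Enum):
    EPOCH1 = "epoch1"
    EPOCH2 = "epoch2"


class Natremia(str, Enum):
    HYPONATREMIC = "hyponatremic"
    NORMONATREMIC = "normonatremic"
    HYPERNATREMIC = "hypernatremic"


def classify_natremia(na: float) -> Natremia:
    """Classify a serum sodium concentration (mmol/L).

    Hyponatremia is serum sodium < 135 mmol/L and hypernatremia > 145 mmol/L,
    both strict; the boundary values 135 and 145 are therefore normonatremic.

    Raises :class:`ValidationError` for sodium outside the plausible
    [100, 200] mmol/L chart range.
    """
    lo, hi = SODIUM_PLAUSIBLE_RANGE
    if not (lo <= na <= hi):
        raise ValidationError(
            f"implausible sodium {na!r} mmol/L (expected within [{lo:g}, {hi:g}])"
        )
    if na < HYPONATREMIA_THRESHOLD:
        return Natremia.HYPONATREMIC
    if na > HYPERNATREMIA_THRESHOLD:
        return Natremia.HYPERNATREMIC
    return Natremia.NORMONATREMIC


@dataclass(frozen=True)
class FluidFlux:
    """One itemized fluid stream within an epoch.

    Electrolyte *amounts* (mmol) are always derived as concentration x volume,
    never stored.
    """

    kind: FluxKind
    volume: float  # liters
    na_conc: float  # mmol/L
    k_conc: float = 0.0  # mmol/L; 0 when unrecorded

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", FluxKind(self.kind))
        for name in ("volume", "na_conc", "k_conc"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def is_output(self) -> bool:
        return self.kind.is_output

    @property
    def na_amount(self) -> float:
        """Sodium amount in mmol."""
        return self.na_conc * self.volume

    @property
    def k_amount(self) -> float:
        """Potassium amount in mmol."""
        return self.k_conc * self.volume


@dataclass(frozen=True)
class PatientEpoch:
    """One patient's 8-hour chart: baseline state, fluxes, and (optionally) the
    measured end-of-epoch serum sodium."""

    patient_id: str
    epoch_label: EpochLabel
    weight: float  # kg
    na_initial: float  # mmol/L
    fluxes: tuple[FluidFlux, ...] = field(default_factory=tuple)
    na_final_measured: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "epoch_label", EpochLabel(self.epoch_label))
        object.__setattr__(self, "fluxes", tuple(self.fluxes))
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ValidationError(
                f"weight must be > 0 kg, got {self.weight!r} (patient {self.patient_id})"
            )
        lo, hi = SODIUM_PLAUSIBLE_RANGE
        for name, value in (
            ("na_initial", self.na_initial),
            ("na_final_measured", self.na_final_measured),
        ):
            if value is None:
                continue
            if not (math.isfinite(value) and lo <= value <= hi):
                raise ValidationError(
                    f"implausible sodium: {name}={value!r} mmol/L "
                    f"(patient {self.patient_id})"
                )
        n_urine = sum(1 for f in self.fluxes if f.kind is FluxKind.URINE)
        if n_urine > 1:
            raise ValidationError(
                f"at most one (aggregate) urine flux per epoch, got {n_urine} "
                f"(patient {self.patient_id})"
            )

    @property
    def urine(self) -> Optional[FluidFlux]:
        for f in self.fluxes:
            if f.kind is FluxKind.URINE:
                return f
        return None

    @property
    def inputs(self) -> tuple[FluidFlux, ...]:
        return tuple(f for f in self.fluxes if not f.is_output)

    def with_flux(self, flux: FluidFlux) -> "PatientEpoch":
        """Return a copy with one additional flux appended."""
        return replace(self, fluxes=self.fluxes + (flux,))

    @property
    def baseline_natremia(self) -> Natremia:
        return classify_natremia(self.na_initial)


@dataclass(frozen=True)
class PredictionResult:
    """A named predictor's forecast serum sodium for one epoch."""

    predictor: str
    na_predicted: float  # mmol/L
    epoch_label: EpochLabel
    patient_id: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.na_predicted):
            raise ValidationError(
                f"na_predicted must be finite, got {self.na_predicted!r} "
                f"({self.predictor}, patient {self.patient_id})"
            )


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman and Percentage Similarity summary for one predictor over a
    cohort (or a natremia subgroup of it).

    ``bias`` is mean(predicted - measured), so a negative bias means the
    predictor under-predicts. ``loa_low``/``loa_high`` are the 95% limits of
    agreement, bias +/- 1.96 x sd_diff. ``cv`` is the coefficient of variation
    of the per-pair percentage similarities, 100 x sd_similarity /
    mean_similarity.
    """

    predictor: str
    subgroup: str  # "all" or a Natremia value
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_similarity: float
    sd_similarity: float
    mean_pct_diff: float
    cv: float


# ---------------------------------------------------------------------------
# Chart CSV I/O
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = [c for c in CHART_COLUMNS if c not in ("na_final_measured", "k_mmol_per_l")]


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def _parse_float(value, column: str, row: int, errors: list[str]) -> Optional[float]:
    try:
        return float(value)
    except (TypeError, ValueError):
        errors.append(f"row {row}: column {column!r} is not numeric: {value!r}")
        return None


def read_chart(path: str | Path) -> list[PatientEpoch]:
    """Read a long-format chart CSV into validated :class:`PatientEpoch` records.

    Rows sharing (patient_id, epoch) form one epoch; each row with a non-empty
    ``flux_kind`` contributes one flux. Invariant violations are collected and
    raised together as a :class:`ChartValidationError` whose ``report_lines``
    cite chart row numbers (header = row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ChartParseError(f"cannot parse chart file {path}: {exc}") from exc

    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ChartParseError(
            f"chart file {path} is missing mandatory column(s): {', '.join(missing)}"
        )
    has_final = "na_final_measured" in df.columns
    has_k = "k_mmol_per_l" in df.columns

    errors: list[str] = []
    # insertion-ordered grouping by (patient_id, epoch)
    groups: dict[tuple[str, str], list[tuple[int, pd.Series]]] = {}
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, after the header row
        groups.setdefault((row["patient_id"], row["epoch"]), []).append((rownum, row))

    epochs: list[PatientEpoch] = []
    for (patient_id, epoch), rows in groups.items():
        first_rownum, first = rows[0]
        try:
            EpochLabel(epoch)
        except ValueError:
            errors.append(
                f"row {first_rownum}: unknown epoch label {epoch!r} "
                f"(expected 'epoch1' or 'epoch2')"
            )
            continue
        weight = _parse_float(first["weight_kg"], "weight_kg", first_rownum, errors)
        na_initial = _parse_float(first["na_initial"], "na_initial", first_rownum, errors)
        na_final: Optional[float] = None
        if has_final and not _is_blank(first["na_final_measured"]):
            na_final = _parse_float(
                first["na_final_measured"], "na_final_measured", first_rownum, errors
            )
        if weight is None or na_initial is None:
            continue

        fluxes: list[FluidFlux] = []
        ok = True
        for rownum, row in rows:
            kind = row["flux_kind"].strip() if isinstance(row["flux_kind"], str) else ""
            if kind == "":
                continue  # epoch-header row (no flux)
            volume = _parse_float(row["volume_l"], "volume_l", rownum, errors)
            na_conc = _parse_float(row["na_mmol_per_l"], "na_mmol_per_l", rownum, errors)
            k_conc = 0.0
            if has_k and not _is_blank(row["k_mmol_per_l"]):
                k_conc = _parse_float(row["k_mmol_per_l"], "k_mmol_per_l", rownum, errors)
            if volume is None or na_conc is None or k_conc is None:
                ok = False
                continue
            try:
                fluxes.append(FluidFlux(kind=kind, volume=volume, na_conc=na_conc, k_conc=k_conc))
            except (ValidationError, ValueError) as exc:
                errors.append(f"row {rownum}: patient {patient_id}: {exc}")
                ok = False
        if not ok:
            continue
        try:
            epochs.append(
                PatientEpoch(
                    patient_id=patient_id,
                    epoch_label=EpochLabel(epoch),
                    weight=weight,
                    na_initial=na_initial,
                    fluxes=tuple(fluxes),
                    na_final_measured=na_final,
                )
            )
        except ValidationError as exc:
            errors.append(f"row {first_rownum}: patient {patient_id}: {exc}")

    if errors:
        raise ChartValidationError(errors)
    return epochs


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def write_chart(epochs: Iterable[PatientEpoch], path: str | Path) -> Path:
    """Write epochs to a long-format chart CSV (round-trip inverse of
    :func:`read_chart`). Floats are written at full precision so the
    round-trip is exact field-for-field."""
    path = Path(path)
    rows: list[dict[str, str]] = []
    for ep in epochs:
        base = {
            "patient_id": ep.patient_id,
            "epoch": ep.epoch_label.value,
            "weight_kg": _fmt(ep.weight),
            "na_initial": _fmt(ep.na_initial),
            "na_final_measured": _fmt(ep.na_final_measured),
        }
        if not ep.fluxes:
            rows.append({**base, "flux_kind": "", "volume_l": "", "na_mmol_per_l": "", "k_mmol_per_l": ""})
        for f in ep.fluxes:
            rows.append(
                {
                    **base,
                    "flux_kind": f.kind.value,
                    "volume_l": _fmt(f.volume),
                    "na_mmol_per_l": _fmt(f.na_conc),
                    "k_mmol_per_l": _fmt(f.k_conc),
                }
            )
    df = pd.DataFrame(rows, columns=CHART_COLUMNS)
    df.to_csv(path, index=False)
    return path
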