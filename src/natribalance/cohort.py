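"""Seeded generator of ICU-like patient epochs.

The generated cohort emulates a mixed medical/surgical ICU population with
hypo-, normo- and hypernatremic patients observed over two consecutive
8-hour epochs. Ground truth is the mass-conservation balance itself: each
epoch's latent true final sodium is computed from the drawn baseline state
and fluxes, and the "measured" final sodium adds Gaussian measurement noise.
The generator therefore answers questions about formula implementation and
evaluation-harness correctness, not physiological realism.

All continuous quantities are drawn from truncated normals; the defaults
mimic the printed characteristics of a real cohort (baseline sodium mean
143.5 mmol/L over 129-164, urine sodium mean 99.2 mmol/L over 11-214,
roughly 10% hyponatremic and 37% hypernatremic at enrollment, enteral
feeding in ~76% and parenteral solutions in ~61% of patients). Epoch 2's
baseline sodium is chained from epoch 1's measured final value, as it would
be charted at the bedside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats

from .domain import FluidFlux, FluxKind, PatientEpoch, write_chart
from .errors import ValidationError
from .predictors import TBW_FRACTION_DEFAULT, predict_mass_balance

__all__ = ["TruncNormal", "FluxModel", "UrineModel", "CohortSpec", "generate_cohort", "generate_fixture"]

_SODIUM_CLIP = (100.0, 200.0)  # chart-plausible range


@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal distribution parameters (mean, sd, [lower, upper])."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"sd must be > 0, got {self.sd!r}")
        if not self.lower < self.upper:
            raise ValidationError(
                f"degenerate truncation range [{self.lower!r}, {self.upper!r}]"
            )

    def sample(self, rng: np.random.Generator, size: int | None = None,
               lower: float | None = None, upper: float | None = None):
        """Draw, optionally narrowing the truncation window (used for
        stratified baseline-sodium draws)."""
        lo = self.lower if lower is None else max(lower, self.lower)
        hi = self.upper if upper is None else min(upper, self.upper)
        if not lo < hi:
            raise ValidationError(f"empty truncation window [{lo!r}, {hi!r}]")
        a, b = (lo - self.mean) / self.sd, (hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=size, random_state=rng)


def _range_dist(lo: float, hi: float) -> TruncNormal:
    """Truncated normal centered on a (lo, hi) range, sd = range/4."""
    return TruncNormal(mean=(lo + hi) / 2.0, sd=(hi - lo) / 4.0, lower=lo, upper=hi)


@dataclass(frozen=True)
class FluxModel:
    """Presence probability and volume/concentration ranges for one flux kind."""

    probability: float
    volume_range: tuple[float, float]  # liters
    na_range: tuple[float, float]  # mmol/L
    k_range: tuple[float, float] = (0.0, 0.0)  # mmol/L

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"probability must be in [0, 1], got {self.probability!r}")
        for name in ("volume_range", "na_range", "k_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValidationError(f"invalid {name}: ({lo!r}, {hi!r})")

    def draw(self, rng: np.random.Generator, kind: FluxKind) -> Optional[FluidFlux]:
        if rng.uniform() >= self.probability:
            return None
        volume = float(_range_dist(*self.volume_range).sample(rng))
        na = 0.0 if self.na_range[1] == 0 else float(_range_dist(*self.na_range).sample(rng))
        k = 0.0 if self.k_range[1] == 0 else float(_range_dist(*self.k_range).sample(rng))
        return FluidFlux(kind=kind, volume=volume, na_conc=na, k_conc=k)


@dataclass(frozen=True)
class UrineModel:
    """Urinary output model: volume range and a truncated-normal urine sodium."""

    volume_range: tuple[float, float] = (0.3, 2.0)  # L per 8 h
    na_dist: TruncNormal = field(
        default_factory=lambda: TruncNormal(mean=99.2, sd=45.0, lower=10.0, upper=215.0)
    )

    def draw(self, rng: np.random.Generator) -> FluidFlux:
        volume = float(_range_dist(*self.volume_range).sample(rng))
        na = float(self.na_dist.sample(rng))
        return FluidFlux(kind=FluxKind.URINE, volume=volume, na_conc=na, k_conc=0.0)


def _default_flux_models() -> dict[str, FluxModel]:
    return {
        "infused": FluxModel(probability=0.90, volume_range=(0.1, 2.0), na_range=(0.0, 154.0)),
        "drug": FluxModel(probability=0.50, volume_range=(0.05, 0.5), na_range=(0.0, 154.0)),
        "enteral": FluxModel(
            probability=0.758, volume_range=(0.2, 1.0), na_range=(20.0, 100.0),
            k_range=(0.0, 40.0),
        ),
        "parenteral": FluxModel(
            probability=0.607, volume_range=(0.2, 1.5), na_range=(0.0, 154.0),
            k_range=(0.0, 20.0),
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters driving the synthetic cohort generator.

    ``dysnatremia_mix`` gives the target (hypo, normo, hyper) proportions at
    enrollment, realized by stratified baseline-sodium draws within the
    corresponding sodium intervals. A fixed seed yields an identical cohort
    on repeated calls.
    """

    n_patients: int = 178
    seed: int = 0
    weight_dist: TruncNormal = field(
        default_factory=lambda: TruncNormal(mean=75.0, sd=15.0, lower=40.0, upper=120.0)
    )
    na_baseline_dist: TruncNormal = field(
        default_factory=lambda: TruncNormal(mean=143.5, sd=8.0, lower=125.0, upper=165.0)
    )
    dysnatremia_mix: tuple[float, float, float] = (0.10, 0.53, 0.37)
    flux_models: dict[str, FluxModel] = field(default_factory=_default_flux_models)
    urine_model: UrineModel = field(default_factory=UrineModel)
    measurement_noise_sd: float = 2.0  # mmol/L
    epochs_per_patient: int = 2
    tbw_fraction: float = TBW_FRACTION_DEFAULT

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError(f"n_patients must be >= 0, got {self.n_patients!r}")
        if abs(sum(self.dysnatremia_mix) - 1.0) > 1e-9 or any(
            p < 0 for p in self.dysnatremia_mix
        ):
            raise ValidationError(
                f"dysnatremia_mix must be non-negative and sum to 1, got {self.dysnatremia_mix!r}"
            )
        if self.measurement_noise_sd < 0:
            raise ValidationError("measurement_noise_sd must be >= 0")
        if self.epochs_per_patient not in (1, 2):
            raise ValidationError(
                f"epochs_per_patient must be 1 or 2, got {self.epochs_per_patient!r}"
            )
        unknown = set(self.flux_models) - {"infused", "drug", "enteral", "parenteral"}
        if unknown:
            raise ValidationError(f"unknown flux model kind(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        """Load a spec from a YAML mapping; unspecified keys keep their defaults.

        Distribution values are 4-element lists ``[mean, sd, lower, upper]``;
        flux models are mappings with ``probability`` and ``*_range`` lists.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("n_patients", "seed", "measurement_noise_sd",
                    "epochs_per_patient", "tbw_fraction"):
            if key in raw:
                kwargs[key] = raw[key]
        if "dysnatremia_mix" in raw:
            kwargs["dysnatremia_mix"] = tuple(raw["dysnatremia_mix"])
        for key in ("weight_dist", "na_baseline_dist"):
            if key in raw:
                kwargs[key] = TruncNormal(*raw[key])
        if "flux_models" in raw:
            models = _default_flux_models()
            for kind, cfg in raw["flux_models"].items():
                models[kind] = FluxModel(
                    probability=cfg["probability"],
                    volume_range=tuple(cfg["volume_range"]),
                    na_range=tuple(cfg["na_range"]),
                    k_range=tuple(cfg.get("k_range", (0.0, 0.0))),
                )
            kwargs["flux_models"] = models
        if "urine_model" in raw:
            cfg = raw["urine_model"]
            kwargs["urine_model"] = UrineModel(
                volume_range=tuple(cfg.get("volume_range", (0.3, 2.0))),
                na_dist=TruncNormal(*cfg["na_dist"]) if "na_dist" in cfg
                else UrineModel().na_dist,
            )
        return cls(**kwargs)


# stratum sodium windows: hypo < 135, normo [135, 145], hyper > 145
_STRATA = (
    ("hypo", None, 135.0 - 1e-6),
    ("normo", 135.0, 145.0),
    ("hyper", 145.0 + 1e-6, None),
)


def _draw_epoch_fluxes(spec: CohortSpec, rng: np.random.Generator) -> tuple[FluidFlux, ...]:
    fluxes: list[FluidFlux] = []
    for kind_name in ("infused", "drug", "enteral", "parenteral"):
        model = spec.flux_models.get(kind_name)
        if model is None:
            continue
        flux = model.draw(rng, FluxKind(kind_name))
        if flux is not None:
            fluxes.append(flux)
    fluxes.append(spec.urine_model.draw(rng))
    return tuple(fluxes)


def generate_cohort(spec: CohortSpec) -> list[PatientEpoch]:
    """Generate a cohort of patient epochs whose latent truth obeys the mass
    balance.

    For each patient: weight and a stratified baseline sodium are drawn, then
    per-epoch fluxes; the true final sodium is the mass-balance prediction
    and the recorded ``na_final_measured`` adds N(0, measurement_noise_sd)
    noise (clipped into the chart-plausible [100, 200] mmol/L). Epoch 2's
    baseline is epoch 1's measured final sodium. Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    epochs: list[PatientEpoch] = []
    width = max(3, len(str(max(spec.n_patients, 1))))
    for i in range(spec.n_patients):
        patient_id = f"P{i + 1:0{width}d}"
        weight = float(spec.weight_dist.sample(rng))
        stratum = rng.choice(3, p=spec.dysnatremia_mix)
        _, lo, hi = _STRATA[stratum]
        na_baseline = float(spec.na_baseline_dist.sample(rng, lower=lo, upper=hi))

        na_initial = na_baseline
        for e in range(spec.epochs_per_patient):
            label = f"epoch{e + 1}"
            fluxes = _draw_epoch_fluxes(spec, rng)
            epoch = PatientEpoch(
                patient_id=patient_id,
                epoch_label=label,
                weight=weight,
                na_initial=na_initial,
                fluxes=fluxes,
            )
            na_true = predict_mass_balance(epoch, spec.tbw_fraction)
            noise = float(rng.normal(0.0, spec.measurement_noise_sd)) if spec.measurement_noise_sd > 0 else 0.0
            na_measured = float(np.clip(na_true + noise, *_SODIUM_CLIP))
            epochs.append(
                PatientEpoch(
                    patient_id=patient_id,
                    epoch_label=label,
                    weight=weight,
                    na_initial=na_initial,
                    fluxes=fluxes,
                    na_final_measured=na_measured,
                )
            )
            na_initial = na_measured  # chart-chained baseline for the next epoch
    return epochs


def generate_fixture(path: str | Path, spec: CohortSpec) -> Path:
    """Generate a cohort and write it as a chart CSV (byte-deterministic for a
    fixed spec and seed)."""
    return write_chart(generate_cohort(spec), path)
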