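"""Method-comparison statistics: Bland-Altman and Percentage Similarity.

Bland-Altman agreement is summarized by the bias (mean of predicted -
measured differences; negative bias = under-prediction), the sample SD of
the differences, and 95% limits of agreement bias +/- 1.96 SD.

Percentage Similarity references the mean of each (predicted, measured) pair
to the measured value (the gold standard): s_i = 100 * ((p_i + m_i)/2) / m_i.
It is summarized by its mean, sample SD, the mean percentage difference
(mean similarity - 100), and the coefficient of variation
100 * SD / mean.

Reports are produced for the whole cohort and within natremia subgroups
assigned from each epoch's *baseline* (enrollment) sodium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .domain import AgreementReport, PatientEpoch, classify_natremia
from .errors import InsufficientDataError, ValidationError
from .predictors import PredictorConfig, predict_all

__all__ = [
    "PairedSeries",
    "bland_altman",
    "percentage_similarity",
    "evaluate_cohort",
    "reports_to_frame",
    "reports_to_csv",
    "summary_text",
    "agreement_plots",
    "SUBGROUPS",
    "LOA_MULTIPLIER",
]

logger = logging.getLogger(__name__)

#: Normal quantile used for the 95% limits of agreement.
LOA_MULTIPLIER = 1.96

SUBGROUPS = ("all", "hyponatremic", "normonatremic", "hypernatremic")


@dataclass(frozen=True)
class PairedSeries:
    """Parallel predicted/measured sodium series with per-pair labels
    ``(patient_id, epoch_label, subgroup)``."""

    predicted: tuple[float, ...]
    measured: tuple[float, ...]
    labels: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicted", tuple(float(x) for x in self.predicted))
        object.__setattr__(self, "measured", tuple(float(x) for x in self.measured))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.predicted) != len(self.measured):
            raise ValidationError("predicted and measured series differ in length")
        if self.labels and len(self.labels) != len(self.predicted):
            raise ValidationError("labels length does not match the series")
        if len(self.predicted) < 1:
            raise ValidationError("a paired series needs at least one pair")
        values = np.asarray(self.predicted + self.measured, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("paired series values must be finite")

    def __len__(self) -> int:
        return len(self.predicted)

    def subset(self, subgroup: str) -> "PairedSeries":
        """Pairs whose label's subgroup matches (requires labels)."""
        idx = [i for i, lab in enumerate(self.labels) if lab[2] == subgroup]
        if not idx:
            raise InsufficientDataError(f"no pairs in subgroup {subgroup!r}")
        return PairedSeries(
            predicted=tuple(self.predicted[i] for i in idx),
            measured=tuple(self.measured[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
        )


def bland_altman(series: PairedSeries) -> tuple[float, float, float, float]:
    """Bland-Altman ``(bias, sd_diff, loa_low, loa_high)`` in mmol/L.

    Differences are predicted - measured; sd_diff uses the sample (n-1)
    denominator; limits of agreement are bias +/- 1.96 sd.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"Bland-Altman needs n >= 2 pairs, got {len(series)}"
        )
    d = np.asarray(series.predicted, dtype=float) - np.asarray(series.measured, dtype=float)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd


def percentage_similarity(series: PairedSeries) -> tuple[float, float, float, float]:
    """Percentage Similarity ``(mean, sd, mean_pct_diff, cv)``, all in percent.

    Per pair: ``100 * ((predicted + measured)/2) / measured``, the mean of the
    pair referenced to the measured gold standard. ``mean_pct_diff`` equals
    ``mean - 100`` and ``cv`` equals ``100 * sd / mean`` by construction.
    """
    if len(series) < 2:
        raise InsufficientDataError(
            f"percentage similarity needs n >= 2 pairs, got {len(series)}"
        )
    m = np.asarray(series.measured, dtype=float)
    if np.any(m <= 0):
        raise ValidationError("measured values must be > 0 for percentage similarity")
    p = np.asarray(series.predicted, dtype=float)
    s = 100.0 * ((p + m) / 2.0) / m
    mean = float(np.mean(s))
    sd = float(np.std(s, ddof=1))
    return mean, sd, mean - 100.0, 100.0 * sd / mean


def _series_for_predictor(
    epochs: Sequence[PatientEpoch], predictor: str, config: PredictorConfig
) -> tuple[PairedSeries | None, int]:
    """Paired series over all epochs for one predictor, and the count of
    epochs excluded because the predictor errored."""
    preds, meas, labels = [], [], []
    n_errors = 0
    cfg = PredictorConfig(
        tbw_fraction=config.tbw_fraction,
        predictors=(predictor,),
        include_potassium=config.include_potassium,
    )
    for ep in epochs:
        results, failures = predict_all(ep, cfg)
        if failures:
            n_errors += 1
            continue
        preds.append(results[0].na_predicted)
        meas.append(ep.na_final_measured)
        labels.append((ep.patient_id, ep.epoch_label.value, ep.baseline_natremia.value))
    if not preds:
        return None, n_errors
    return PairedSeries(tuple(preds), tuple(meas), tuple(labels)), n_errors


def evaluate_cohort(
    epochs: Sequence[PatientEpoch],
    config: PredictorConfig = PredictorConfig(),
) -> list[AgreementReport]:
    """Agreement reports for every enabled predictor and natremia subgroup.

    Every epoch must carry a measured final sodium. Subgroups are assigned
    from the baseline sodium; a subgroup with fewer than 2 evaluable pairs is
    omitted with a logged notice, as is any epoch where a predictor errored
    (counted per predictor).
    """
    epochs = list(epochs)
    if not epochs:
        raise ValidationError("cannot evaluate an empty cohort")
    missing = [ep.patient_id for ep in epochs if ep.na_final_measured is None]
    if missing:
        raise ValidationError(
            f"epochs without measured final sodium: {sorted(set(missing))}"
        )

    reports: list[AgreementReport] = []
    for predictor in config.predictors:
        series, n_errors = _series_for_predictor(epochs, predictor, config)
        if n_errors:
            logger.info("%s: %d epoch(s) excluded due to predictor errors", predictor, n_errors)
        if series is None:
            logger.info("%s: no evaluable epochs, predictor skipped", predictor)
            continue
        for subgroup in SUBGROUPS:
            try:
                sub = series if subgroup == "all" else series.subset(subgroup)
            except InsufficientDataError:
                logger.info("%s/%s: subgroup empty, report omitted", predictor, subgroup)
                continue
            if len(sub) < 2:
                logger.info(
                    "%s/%s: n=%d < 2, report omitted", predictor, subgroup, len(sub)
                )
                continue
            bias, sd, lo, hi = bland_altman(sub)
            mean_s, sd_s, mpd, cv = percentage_similarity(sub)
            reports.append(
                AgreementReport(
                    predictor=predictor,
                    subgroup=subgroup,
                    n=len(sub),
                    bias=bias,
                    sd_diff=sd,
                    loa_low=lo,
                    loa_high=hi,
                    mean_similarity=mean_s,
                    sd_similarity=sd_s,
                    mean_pct_diff=mpd,
                    cv=cv,
                )
            )
    return reports


_REPORT_COLUMNS = [
    "predictor",
    "subgroup",
    "n",
    "bias",
    "sd_diff",
    "loa_low",
    "loa_high",
    "mean_similarity",
    "sd_similarity",
    "mean_pct_diff",
    "cv",
]


def reports_to_frame(reports: Iterable[AgreementReport]) -> pd.DataFrame:
    """Reports as a tidy DataFrame (one row per predictor x subgroup)."""
    return pd.DataFrame(
        [{c: getattr(r, c) for c in _REPORT_COLUMNS} for r in reports],
        columns=_REPORT_COLUMNS,
    )


def reports_to_csv(reports: Iterable[AgreementReport], path: str | Path) -> Path:
    path = Path(path)
    reports_to_frame(reports).to_csv(path, index=False)
    return path


def summary_text(reports: Iterable[AgreementReport]) -> str:
    """Human-readable agreement summary, one line per report."""
    lines = []
    for r in reports:
        lines.append(
            f"{r.predictor:>15s} [{r.subgroup:>13s}] n={r.n:4d}  "
            f"bias {r.bias:+7.3f} ± {r.sd_diff:.3f} mmol/L "
            f"(LoA {r.loa_low:+.3f} to {r.loa_high:+.3f})  "
            f"similarity {r.mean_similarity:.2f}% ± {r.sd_similarity:.2f}% "
            f"(CV {r.cv:.2f}%)"
        )
    return "\n".join(lines)


def agreement_plots(
    reports: Sequence[AgreementReport],
    series_by_predictor: dict[str, PairedSeries],
    path: str | Path,
    fmt: str = "png",
) -> list[Path]:
    """Write one Bland-Altman scatter and one percentage-similarity histogram
    per predictor to ``path``.

    Files are named ``bland_altman_<predictor>.<fmt>`` and
    ``similarity_<predictor>.<fmt>``. Predictors with an empty series are
    skipped with a logged notice. Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    by_pred = {r.predictor: r for r in reports if r.subgroup == "all"}
    written: list[Path] = []
    for predictor, series in series_by_predictor.items():
        if series is None or len(series) == 0:
            logger.info("%s: empty series, no plot written", predictor)
            continue
        rep = by_pred.get(predictor)
        if rep is None:
            logger.info("%s: no overall report, no plot written", predictor)
            continue
        p = np.asarray(series.predicted)
        m = np.asarray(series.measured)

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter((p + m) / 2, p - m, s=12, alpha=0.6, edgecolors="none")
        ax.axhline(rep.bias, color="k", lw=1.2, label=f"bias {rep.bias:+.2f}")
        for y in (rep.loa_low, rep.loa_high):
            ax.axhline(y, color="k", ls="--", lw=0.9)
        ax.set_xlabel("mean of predicted and measured Na (mmol/L)")
        ax.set_ylabel("predicted − measured (mmol/L)")
        ax.set_title(f"Bland–Altman: {predictor}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        ba_path = outdir / f"bland_altman_{predictor}.{fmt}"
        fig.savefig(ba_path, dpi=120)
        plt.close(fig)
        written.append(ba_path)

        s = 100.0 * ((p + m) / 2.0) / m
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.hist(s, bins=min(30, max(5, len(s) // 5)), color="#4477aa", edgecolor="white")
        ax.axvline(100.0, color="k", lw=1.0)
        ax.set_xlabel("percentage similarity (%)")
        ax.set_ylabel("count")
        ax.set_title(f"Percentage similarity: {predictor}")
        fig.tight_layout()
        ps_path = outdir / f"similarity_{predictor}.{fmt}"
        fig.savefig(ps_path, dpi=120)
        plt.close(fig)
        written.append(ps_path)
    return written
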