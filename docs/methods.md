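# Methods

## The mass-balance model

The core predictor treats the patient over one 8-hour epoch as an open
compartment of well-mixed body water. Sodium amount is conserved: the final
amount equals the initial store `[Na]₀ × TBW` plus every recorded sodium
input (infused, drug, enteral and parenteral solutions, each as
concentration × volume) minus the urinary output, while the water
compartment changes by the net fluid balance ΔVol = total input volume −
total output volume. Dividing the final amount by the final water volume
`TBW + ΔVol` gives the predicted concentration. The model's assumptions,
and hence its known blind spots, are:

- **TBW = weight × 0.5 for all patients.** A single fraction for both sexes
  and all ages trades accuracy for bedside practicality; the fraction is
  configurable (`tbw_fraction`) wherever a prediction is made.
- **No insensible losses.** Skin and gastrointestinal water/sodium losses
  are not on the chart and are not modeled.
- **No potassium in the core formula.** The mass-balance predictor
  deliberately omits potassium; recorded potassium does contribute to the
  comparator formulae that admit it (Barsoum–Levine, Kurtz–Nguyen, EFWC via
  urine K), controlled by `PredictorConfig.include_potassium` (default on).
- **Urine is one aggregate flux per epoch.** In bedside practice the urine
  sodium is typically measured at the start of the epoch and the volume
  taken from the preceding 8-hour chart window on the assumption that
  output is steady; the chart format stores a single aggregate urine flux
  and leaves that windowing convention to the data preparer.

## Comparator formulae

The four comparators are implemented in their standard closed forms:
Adrogué–Madias `(Na₀·TBW + V·C)/(TBW + V)` with C the infusate Na+K
concentration; Barsoum–Levine `(Na₀·TBW + (Na+K)ᵢₙ − (Na+K)ₒᵤₜ)/(TBW +
ΔVol)` with electrolyte terms as *amounts* in mmol; the EFWC prediction
`Na₀·TBW/(TBW − EFWC)` with `EFWC = Vᵤ(1 − (Naᵤ+Kᵤ)/Na_serum)` (negative
when urine is more concentrated than serum, i.e. net free-water gain); and
Kurtz–Nguyen `((Na₀+23.8)·TBW + 1.03·Δ(Na+K))/(TBW+ΔVol) − 23.8`, whose
constants are exported as `KURTZ_NGUYEN_OFFSET`/`KURTZ_NGUYEN_SLOPE`.
Taking the Barsoum–Levine and Kurtz–Nguyen electrolyte terms as amounts
(rather than concentration × volume products assembled differently) makes
the three open-system formulae mutually consistent and algebraically
reducible to one another in the single-infusion case — a property the tests
exploit as a cross-formula oracle.

Although Adrogué–Madias was derived for a 1 L infusion, `predict_all`
applies every comparator to the epoch's *total* fluxes (assembled from the
`BalanceSummary`), not per liter; this is a documented package choice. The
serum sodium used inside the EFWC term is the epoch's baseline sodium
(urine chemistry is drawn at the start of the epoch).

## Dosing inverse

The infusion volume reaching a target sodium solves the same conservation
statement for V, with V included in ΔVol (self-consistent denominator):
`V(Na_inf − Na_target) = Na_target(TBW + ΔVol_other) − (Na₀·TBW +
Na_in,other − Na_out)`. Correctness is defined by the roundtrip property —
the forward prediction after appending the solved infusion reproduces the
target — which the suite verifies to 1e-9 mmol/L on 500 random feasible
cases. A negative solution is reported as infeasible (`feasible=False` with
a reason) rather than as fluid removal; when the infusate tonicity equals
the target the equation is singular and an `InfeasibleDoseError` is raised
unless the target is already met (volume 0). No correction-rate safety
ceilings are imposed; dosing output is an arithmetic consequence of the
model, not clinical guidance.

## Agreement statistics

Differences are **predicted − measured**, so negative bias means
under-prediction; Bland–Altman sign conventions vary, so this is stated
prominently. The SD of differences uses the sample (n−1) denominator and
the 95% limits of agreement are bias ± 1.96 SD, with no confidence
intervals on the limits. Percentage Similarity references the mean of each
pair to the measured gold standard, `sᵢ = 100·((pᵢ+mᵢ)/2)/mᵢ`, summarized
by its mean, sample SD, mean percentage difference (= mean − 100 by
construction) and CV (= 100·SD/mean). Subgroups (hypo < 135, normo, hyper
> 145 mmol/L, strict inequalities so the boundary values are normonatremic)
are assigned from the *enrollment* (baseline) sodium. Epochs from the same
patient are treated as independent; no repeated-measures correction is
applied. A subgroup with fewer than two evaluable pairs is omitted with a
logged notice, and an epoch on which a predictor errors (degenerate
denominator) is excluded from that predictor's report only.

## Synthetic cohort generator

The generator emulates a mixed medical/surgical ICU cohort: truncated
normal weight (mean 75 kg, SD 15, bounds 40–120), baseline sodium truncated
normal (mean 143.5 mmol/L, SD 8, bounds 125–165) drawn *stratified* so that
enrollment hits a target dysnatremia mix (default 10% hypo / 53% normo /
37% hyper), per-kind flux presence probabilities (infused 0.90, drug 0.50,
enteral 0.758, parenteral 0.607) with truncated-normal volumes and
concentrations over clinically plausible ranges (0–154 mmol/L Na for
crystalloids; modest potassium in enteral/parenteral feeds), and urine with
truncated-normal sodium (mean 99.2 mmol/L, SD 45, bounds 10–215). Each
patient contributes two chained epochs: epoch 2's baseline is epoch 1's
measured final sodium, as it would be charted.

The ground truth is the mass balance itself: the latent true final sodium
is the mass-balance prediction and the recorded measurement adds Gaussian
noise (default SD 2 mmol/L), clipped into the chart-plausible
[100, 200] mmol/L (the clip is effectively never active at the default
noise level). This makes the cohort a controlled test bed: with zero noise
the evaluation harness must recover zero bias and zero spread for the
mass-balance predictor exactly, and with noise SD σ it must recover bias ≈ 0
and SD of differences ≈ σ, which is what the acceptance run measures
(500 patients, σ = 2). The comparators then display *structured* bias on
the same cohort (each neglects part of the chart), exercising the
comparison machinery realistically. What passing these tests shows is that
the formulae and the evaluation harness are implemented correctly — not
that the mass balance is physiologically accurate in real patients, since
real data contain TBW misestimation, insensible losses, chart errors and
non-steady urine output that the generator deliberately omits.

## Numerical choices

- **Exact identity fast paths.** Each predictor returns the baseline sodium
  exactly (bit-for-bit) when its net terms vanish (no fluxes, zero
  infusion, balanced exchange, zero EFWC), since the formula reduces to the
  identity algebraically; this avoids spurious last-ulp drift from
  `(a·b)/b` rounding.
- **Denominator guard.** Any predictor denominator ≤ 1e-9 L raises a
  `DegenerateBalanceError` naming the patient rather than returning an
  unbounded value.
- **Chart round-trip.** Floats are written to CSV via `repr` (shortest
  round-trip form), so `read_chart(write_chart(x)) == x` field-for-field.
- **Sodium plausibility.** Serum sodium outside [100, 200] mmol/L is
  rejected at parse time as an implausible chart entry; units are part of
  the file contract (liters, mmol/L, kg) with no autodetection.
- **Determinism.** All simulation randomness flows through a single
  `numpy.random.default_rng(seed)`; a fixed spec and seed reproduce a
  byte-identical chart file (the committed 10-patient fixture is verified
  against regeneration).

## Problem sizes

The test suite and acceptance run use desk-scale sizes chosen as the
package's own defaults: a 1000-point zero-flux grid, 500 random cases each
for cross-formula equivalence and dosing roundtrip, 100 random series for
the statistics oracles, a 500-patient (1000-epoch) cohort for parameter
recovery and a 1000-patient cohort for mix control. Clinical-scale results
(a real 178-patient cohort's biases and similarities) are not reproducible
without the clinical data and are not claimed.

## Known limitations

Single-compartment, single-epoch arithmetic: no osmotically inactive sodium
stores, glucose/osmolality corrections, SIADH-specific handling, CRRT, or
time-resolved dynamics within an epoch. The CSV reader takes the first
row's weight/baseline values per epoch without reconciling duplicates. The
dosing solver returns one volume for one infusate; multi-step correction
scheduling and rate-of-correction safety limits are out of scope.
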