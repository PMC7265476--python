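# Methods

## Detection model

The detector is an individualized control chart on the normalized body-weight
course. Weights are first expressed as percent of the animal's first
measurement, which removes the dependence on absolute body weight and lets one
threshold rule serve both adult and growing animals.

For measurement index `d` (0-based, ordered by day) with at least
`window_size` preceding measurements, the moving statistics are

- `m_d` — unweighted mean of the `window_size` values at indices
  `d − window_size … d − 1`;
- `s_d` — sample standard deviation (denominator `n − 1`) of the same values.

The window is strictly lagging: the current day's value is excluded so an
abrupt drop cannot inflate its own window SD and thereby mask itself. The
first `window_size` measurements have no boundaries and can never alarm.
The decision boundaries are `m_d ± k·s_d` with width-factor `k`; an alarm is
raised when the day's value falls **strictly below** the lower boundary. The
upper boundary is reported for plotting but never alarms — only weight *loss*
endangers the animal.

### Modes

Narrowing `n_d ≥ 0` is subtracted from the boundary half-width, clamped so
neither boundary crosses the mean
(`lower = min(m, m − k·s + n_d)`, `upper = max(m, m + k·s − n_d)`):

- **regular** — `n_d = 0`.
- **mad** — `n_d = max(0, round_half_up(m_d − x_d))`, the day's deficit below
  the window mean, rounded to whole percentage points. A value above the mean
  clamps to 0 so it never widens the band.
- **score** — `n_d = score_narrowing_unit × clinical_score_d`. The
  mechanism (a linear raise of the lower boundary per score point, default
  1.0 percentage point) is this package's design choice: it is monotone in
  clinical severity, exactly zero for a healthy animal, dimensionally
  explicit, and governed by a single knob. Score mode refuses to run on
  cohorts without scores rather than silently falling back.

Because both constrained modes only ever *raise* the lower boundary, the
regular-mode alarm set is a subset of either constrained mode's on every
animal and day. That nesting is the mechanism behind the characteristic
evaluation pattern: constrained modes achieve an equal or higher endpoint
detection rate at an equal or higher false-alarm cost.

### Numerical conventions

- Sample SD (ddof = 1), the small-window convention; the test suite checks
  the rolling statistics against an independent brute-force re-computation.
- Zero window variance (perfectly constant window) collapses the boundaries
  onto the mean, so any strict drop alarms; degenerate but consistent, and
  the basis of the exact constant-cohort tests.
- A value exactly on the lower boundary does not alarm (strict inequality).
- MAD rounding is round-half-up to integer percentage points.
- Days may have gaps (missed weighings); the window runs over *measurements*,
  with a logged warning when gaps are present.

## Evaluation metrics

An alarm on the animal's endpoint day (its last day alive) is the true
positive; all other alarms are false positives, counted per alarm day without
episode merging. For a cohort: `EDR = detected / n`, `mean false alarms` is
the per-animal average count, and the **adjusted** mean discounts false
alarms on the day before the endpoint and the day after a resection surgery —
days on which an alarm arguably flags genuinely elevated risk. The adjusted
mean can never exceed the raw mean. Animals too short to have any evaluable
day stay in the denominator as failed detections with zero false alarms
(logged), keeping set sizes comparable across window sizes.

## Parameter selection

The grid covers window sizes 2–10 days and width-factors 0.5–3.0; the width
step of 0.25 covers that range including the canonical operating point 2.5.
Selection is a two-stage rule formalizing the usual practice:

1. choose the window whose mean false alarms, averaged over all widths, is
   smallest (ties → smaller window);
2. at that window, choose the **largest** width still achieving the maximum
   EDR (wider bands give fewer false alarms at equal sensitivity).

The rule is deterministic and invariant to grid-entry order. Selection should
be run on a training cohort and the chosen parameters applied to a held-out
validation cohort (`EndpointDetectorResults.evaluate`); on the bundled
synthetic presets the selected window tends to be larger than on noisier real
data, because the simulator's stable phase is smoother than a real rat's —
larger windows then cost nothing in false alarms.

## Synthetic cohorts

The simulator generates the trajectory structure of a fast intracranial
glioma model:

| parameter | default | meaning |
|---|---|---|
| `baseline_weight_g` | (280, 25) g | starting weight of an adult rat (> 200 g) |
| `daily_noise_pct` | 1.0 % | SD of i.i.d. multiplicative day-to-day noise |
| `growth_pct_per_day` | 0 %/day | deterministic drift (set > 0 for growing animals) |
| `endpoint_day_distribution` | (15, 3) days | Gaussian endpoint day, clamped below at `min_endpoint_day` = 10 |
| `terminal_drop_pct` | (5, 15) % | total terminal loss, drawn uniformly |
| `terminal_days` | 2 | days over which the drop unfolds (cumulative fractions 0.3, 1.0) |
| `terminal_scores` | (1, 2) | clinical score on the second-last / last day |
| `resection` | off | day-8 surgery, 4 % dip the day after, 2-day linear recovery |

Noise is multiplicative log-normal: weights are positive and fluctuations
scale with body size. The terminal drop is drawn uniformly because only its
range, not its distribution, is characterized; the 0.3/1.0 two-day schedule
puts most of the loss on the final day (the rapid last-day drop) while the
day before shows a milder decline — which is also what makes day-before-
endpoint false alarms, and hence the adjusted metric, meaningful. Each animal
uses an RNG sub-stream keyed by `(seed, animal_index)`, so cohorts are
reproducible under subsetting. Presets: `training` n = 34, `validation`
n = 63 (the evaluation-table set sizes; the source study's design section
gives 36/61, a discrepancy resolved here in favour of the evaluation tables),
`resection` n = 5 with endpoint near day 20.

What the simulator does **not** emulate: real day-to-day weight
autocorrelation (illness trends, feeding cycles), heterogeneous noise across
animals, missed weighing days, slow pre-terminal decline, or any behavioural/
telemetry channel. Passing tests therefore demonstrate the algorithm's
correctness and its qualitative sensitivity/false-alarm trade-off, not the
quantitative performance to expect on real colony data; real courses with
high weight variance will push the optimal window and width away from the
synthetic optimum.

## Problem sizes and determinism

The test suite and the acceptance script run on cohorts of 20–63 animals
(1000 for the endpoint-day convergence check), full 99-point grids, and 200
random sequences for the rolling-statistics oracle; every stochastic test is
seeded, and all CLI commands are deterministic given their inputs and seed,
which is what the run manifests exploit for byte-identical replay.

## Known limitations

- The score-mode narrowing mechanism is a design choice (see above); other
  monotone mappings from score to narrowing are plausible and would change
  the score-mode false-alarm count.
- False alarms are counted per day; consecutive alarm days are not merged
  into episodes.
- No imputation for missing days and no multi-signal fusion (weight +
  telemetry); the detector sees body weight and, in score mode, the clinical
  score only.
- The adjusted metric assumes the endpoint day and resection day are known
  exactly; in prospective use the "day before endpoint" is only identifiable
  retrospectively.
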