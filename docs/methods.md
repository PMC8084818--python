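# Methods notes

## Model and assumptions

The core model treats a single response as a draw from N(S, σ²), where S
is the intended aim point and σ the responder's noise, taken constant
across aims within a block. Expected gain is the gain of each outcome
class (early/close, hit, late/far) weighted by its Gaussian probability;
the optimal aim S\*(σ) maximizes it. Assumptions worth keeping in mind:

- **Gaussian noise, σ independent of S.** The analysis pairs each penalty
  block's empirically measured SD with that block's mean, so no scalar
  (σ ∝ S) structure is imposed. A scalar-timing variant (σ grows
  proportionally with the aim) exists in the generator as the
  `scalar_sigma` flag, off by default, because the analysis model itself
  never needs it.
- **No truncation at zero inside the EG integral.** The Gaussian support
  formally includes negative magnitudes; for realistic parameters
  (σ ≲ target/2) the mass below zero is negligible, so the closed-form
  CDF expressions are used untruncated. The generator does floor its
  *responses* at 1 ms / 0.1 mm to keep data physically valid.
- **Closed hit window.** |x − L| and |x − U| boundary responses count as
  hits. Under the continuous model exact boundaries have probability
  zero; the choice only matters for classifying recorded data.

## Numerical choices

- `optimal_aim` runs bounded scalar maximization on
  S ∈ [L − 2σ, U + 4σ] with tolerance 10⁻⁴·target, backed by a 513-point
  grid scan to guard against local maxima when large penalties carve a
  trough into the surface. When the maximum is a plateau (EG within
  ~10⁻¹² points), the plateau point closest to the target is returned;
  this makes the zero-penalty optimum exactly the target for every σ and
  gives S\* → target as σ → 0.
- At small σ the EG surface is flat to machine precision over a wide
  range of aims, so tests compare *optimum values* rather than optimum
  locations in that regime.
- Efficiency uses realized (received) points in the numerator and
  n_kept · max-expected-gain in the denominator; excluded trials' points
  do not count on either side, keeping the ratio internally consistent.
  It is undefined (raises) when the maximum expected gain is not
  positive, as in the unrewarded practice block.

## Outlier filtering

Responses are filtered per participant × modality, pooled over all 250
experimental trials (practice excluded from both the pool and the
summaries, as it earns no points), keeping |x − median| ≤ 3·MAD. Two MAD
conventions exist:

- the **raw MAD** (the literal reading), whose 3-MAD bound sits at
  ≈ 2.02 Gaussian SDs and removes ≈ 4.3% of perfectly clean Gaussian
  data while biasing the kept-sample SD downward by ≈ 12%;
- the **normalized MAD** (× 1.4826), whose bound sits at ≈ 3 SDs,
  removing ≈ 0.3% of clean data plus whatever contaminants are present —
  matching the ~2–3% exclusion rates this design typically produces.

The `mad_filter` primitive defaults to raw; the analysis pipeline
defaults to normalized, because the raw cut's SD bias propagates directly
into the optimal-adjustment denominator and visibly distorts
optimality/efficiency statistics (verified by closed-loop recovery: under
the raw default a true λ of 1.5 is estimated as ≈ 1.86; under the
normalized default as ≈ 1.53–1.56). Both are exposed
(`--mad-raw` / `PipelineConfig.mad_normalized`).

## Cross-modal inference

Timing optimality is regressed on distance optimality plus a
punishment-level indicator (−5 block as reference) by OLS; 95% CIs come
from a percentile bootstrap that resamples participants (clusters) with
replacement, 2000 resamples, fixed seed. This keeps the fixed-effect
structure of a random-intercept mixed model while staying fully
transparent and dependency-free: clustering at the participant level is
what the random intercept would otherwise absorb. Units are native
(ms per mm); a z-scored variant (`standardize=True`) is available since
raw and standardized slopes answer slightly different questions and
neither is canonical. Per-modality adjustment models (adjustment on
punishment level and block SD) use the same machinery.

## Synthetic cohorts

The generator emulates the experiment's design: 36 participants × 2
modalities × (50 practice + 5 × 50 experimental trials) under the
standard payoff scheme (hit +5; early penalties 0, −5, 0, −30, 0 in
blocks 1–5; practice unrewarded). Ground truth per participant:

| parameter | default | units | role |
|---|---|---|---|
| σ median (timing / distance) | 80 / 5.9 | ms / mm | log-normal between-participant noise scale |
| σ log-SD | 0.15 | — | spread of noise across participants |
| baseline bias SD | 8 / 0.6 | ms / mm | aim offset from target, all blocks |
| λ mean | 1.0 | — | adjustment propensity (1 = optimal) |
| λ SD | 0.7 | — | between-participant strategy spread |
| ρ | 0.6 | — | timing–distance correlation of λ |
| outlier rate | 0.02 | — | uniform contaminants, [100, 3000] ms / [5, 200] mm |

In penalty blocks the aim is `aim₁ + λ·(S*(σ) − aim₁)`: λ scales the
required shift multiplicatively, so λ = 0.5 means a participant who
should shift 40 ms shifts 20 ms. The timing and distance λ of one
participant are bivariate normal with correlation ρ, encoding a
modality-shared risk propensity.

Scale choices: the timing σ median of 80 ms reflects typical
interval-reproduction precision at 750 ms; the distance median is set so
that σ/target is equal across modalities (80/750 → 5.87 ≈ 5.9 mm),
preserving the symmetry of the two tasks' identical relative reward
windows. λ is centred on the optimal strategy with a wide spread
(SD 0.7) and biases are kept small, so that individual strategies are
resolvable against the estimation noise of a 50-trial block — a
deliberate calibration: the generator's purpose is recoverable ground
truth, and with a strategy spread much below the per-block
standard-error floor (σ/√50 ≈ 11 ms / 0.8 mm) no analysis could separate
strategy from noise at this design size.

What the generator does **not** emulate: trial-by-trial feedback
learning (aims are constant within a block), drifts or fatigue, scalar
growth of σ with the aim (optional flag), and any touch-geometry detail
of the distance task (responses are scalar magnitudes). Passing
closed-loop tests therefore shows that the pipeline recovers the
parameters of this stationary model — not that real participants behave
stationarily.

## Problem sizes in tests

Closed-loop recovery checks run 36-participant cohorts at 50 trials per
block: λ sweeps use 20 seeds per λ ∈ {0.5, 1.0, 1.5}; cross-modal CI
checks use 20 seeds per ρ ∈ {0, 0.9} with 2000 bootstrap resamples.
These sizes put the λ estimate's seed-to-seed SD near 0.08–0.11, well
inside the ±0.15 recovery band, and were additionally validated on 40
held-out seeds during development.

## Known limitations

- The percentile cluster bootstrap can be slightly anticonservative at
  36 clusters; with ρ = 0 the slope CI covers zero in ≈ 95% of seeds,
  consistent with its nominal level.
- Efficiency compares realized points against the expected maximum, so
  single blocks can exceed 100%; it is a noisy per-block statistic and
  is reported as medians.
- The MAD filter is applied once, pooled; re-filtering kept data with
  re-estimated statistics can remove further points (the filter is only
  idempotent under frozen pooled statistics).
- With heavy penalties and large σ the optimal aim can exceed the upper
  window edge; the optimizer bracket (U + 4σ) accommodates this, but
  grid-based surfaces need an aim grid wide enough to contain the ridge.
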