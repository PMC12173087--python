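# Methods

This note documents the generative model, the analysis chain, and the
numerical and design choices behind `crowdtrack`. Angles are in degrees
unless noted; all circular arithmetic is modulo 360 with orientations
stored in [0, 360) and signed differences represented in [−180, 180)
(the tie at ±180 resolves to −180).

## Stimulus paradigms

**Continuous paradigm.** Each trial lasts `trial_duration_s` (default 40 s)
sampled at `sample_rate_hz` (default 144 Hz), giving
`round(144 × 40) = 5760` frames. The target gap orientation advances by
`rotation_speed / sample_rate` (default 0.5°/frame) in the current
direction. The target–flanker distance sweeps at `distance_speed_deg_s`
(default 0.13 °/s) from one range boundary to the other; since 0.13 × 40 =
5.2° exceeds the 5° range, the sweep is clamped and held at the boundary.
When the (unclamped) sweep first crosses a preselected jump distance
(defaults 0.31, 0.35, 1.35, 2.20, 3.37°), the target orientation is redrawn
uniformly, the four flanker gaps are reassigned (first gap ~ wrapped normal
around the target with 45° SD, the rest at fixed 90° offsets), and the
rotation direction is redrawn uniformly over {clockwise, counterclockwise}.
A helper reproduces the alternative log-spaced construction of jump
distances between inner/outer borders of 0.8° and 5.8°, but the listed
values are the defaults. Isolated trials carry the matched trend's jump
schedule and retain the "as-if" distance sweep internally (it supplies the
distance axis for the isolated regression line) without exposing flanker
channels. A block comprises 8 flanked trials (4 per sweep direction) and 4
isolated trials (2 per matched schedule), permuted.

**Trial-based paradigm.** Static orientations; 7 flanked distances
(0–5°) plus isolated, each repeated 25 times (200 trials), permuted.

Per-trial RNG streams are derived from (schedule seed, trial index), so
every trial is independently reproducible and datasets are byte-identical
across reruns of the same seed.

## The synthetic observer

No human data accompany this package; a generative observer supplies
ground truth for parameter-recovery testing. Its guiding principle is that
the *analysis-side estimators should be correctly specified* under the
generative model, so that recovery failures indicate analysis bugs rather
than model mismatch.

* **Hinged report noise.** The percept noise SD is
  σ(d) = `baseline_noise_sd_deg` + `crowding_slope_deg_per_deg` ·
  max(0, e_c − d), with e_c = `crowding_extent_deg` (defaults 10°, 8°/°,
  5°). The wrapped-normal circular SD equals its σ parameter, and the
  trial-based Von Mises concentration is obtained by *exact* numerical
  inversion of circular SD(κ) = σ(d) (not the small-angle κ = 1/σ², which
  errs by ~25% at σ = 50°), so both paradigms share the same hinge by
  construction.
* **Predictive tracking (default).** The rotation is constant and fully
  predictable between jumps, so the observer tracks it with no steady-state
  phase error — as in smooth pursuit of predictable motion. The motor
  latency (default 280 ms ≈ 40 frames) expresses itself at the
  unpredictable jumps: the response continues the pre-jump trajectory for
  one latency period. A `predictive=False` mode implements the literal
  pure-delay tracker (response = stimulus delayed by the latency, offset by
  the first-order-lag steady-state error −ω·τ); it exists because its
  closed-form steady-state error ω·L is a useful test oracle, but its ≈31°
  constant offset would swamp the hinge signal in absolute error and is not
  how practiced observers track predictable rotation.
* **Post-jump recovery as calibrated variance inflation.** After the
  latency window the carried error e₀ relaxes at the condition's recovery
  rate (defaults: flanked 2.0/s, isolated 3.5/s). It is generated not as a
  signed decaying offset but as inflated report noise whose per-frame SD is
  chosen, via a precomputed wrapped-normal table, so that the expected
  absolute (wrapped) error is exactly
  `floor(d) + e₀·e^(−b·t)`. This matters: with a signed offset m(t) in
  noise of SD σ, E|m + noise| approaches the floor like m² (rate 2b),
  which deterministically biases the fitted rate by +19% (isolated) to
  +42% (flanked) at the default noise levels; naive variance inflation
  overshoots into the wrapping regime, where mean |error| saturates near
  90°, biasing the rate −25%. The calibrated form keeps the decay fit
  unbiased at any noise level. The injected amplitude is limited to the
  headroom below the ~90° saturation, which also reproduces a known
  phenomenon: when the baseline error is already high (flanked), the
  visible post-jump error increment is smaller.
* **Noise autocorrelation.** The unit noise is AR(1) with the pursuit time
  constant (default 150 ms), mimicking the smooth error autocorrelation of
  real mouse tracking. Marginal SD is preserved.

What the generator does **not** emulate: fixation breaks and blinks (the
`gap_mask` channel exists in the data format but defaults to all-false),
saccades, attention fluctuations, learning across trials, and directed
(signed) post-jump corrections — after the latency window the recovery is
an error-magnitude process, not a smooth signed pursuit of the new
orientation. Passing tests therefore validate the *analysis chain* against
a model with the assumed statistical structure, not the realism of any
particular human mechanism.

## Analysis chain

1. **Report error** = wrapped(response − stimulus) ∈ [−180, 180);
   magnitudes |error| feed all condition averages.
2. **Artifact cleaning.** Thresholds come from the *signed* errors of the
   isolated trials of the same sweep direction: a peak is |error| > 2·SD;
   around each peak the maximal contiguous run with |error| > |mean| + 1·SD
   is marked; the union of the isolated trials' masks is deleted from every
   trial (flanked and isolated) of that trend, keeping frame availability
   identical across conditions. Under default conditions this removes ≈8%
   of frames per trial, dominated by post-jump transients. Deleted frames
   become missing values; nothing is imputed.
3. **Tracking performance.** Cosine similarity over the cleaned, pooled
   frames of each condition and run.
4. **Crowding extent (continuous).** Decreasing-sweep trials are reversed
   in time (flip-and-average) onto the increasing-distance axis; absolute
   errors are averaged per frame and regressed on distance separately for
   flanked and isolated trials; the lines' intersection is the extent,
   clipped to [0, 5] with the raw value retained. Two refinements are
   applied by default and can be disabled: (a) frames inside the 300-sample
   post-jump window are excluded from this regression (they reflect
   temporal recovery, not spatial crowding — without the guard the slower
   flanked transients bias the extent by > 1° when the hinge is small);
   (b) the flanked line is iteratively refit on distances below the current
   intersection until a fixed point (tolerance 10⁻⁴, ≤ 200 iterations) —
   the plain single-pass line is only consistent when the hinge lies at or
   beyond the largest tested distance.
5. **Crowding extent (trial-based).** Von Mises MLE per distance (mean
   direction free; κ̂ by inverting the mean resultant length with Brent's
   method; all-identical samples give σ = 0). The flanked σ(d) line is
   intersected with the horizontal isolated baseline, with the same
   iterated refinement (never fewer than 3 points). Degenerate geometries
   (parallel/never-intersecting/coincident lines) return flagged estimates
   at the range boundary rather than raising.
6. **Recovery.** Post-jump windows of 300 samples (~2080 ms) of absolute
   error are cut from the *raw* per-trial series (the cleaning deliberately
   deletes exactly these peaks), never reading across the next jump; the
   across-jump mean is fit with a·e^(−bt)+c (SciPy trust-region least
   squares, bounds a, b, c ≥ 0; initial values a₀ = first − last,
   b₀ = 1/s, c₀ = last; five jittered restarts; tolerances 10⁻⁸). The
   motor-corrected variant drops the first 40 samples (~280 ms) — exactly
   the latency plateau, so it is the variant that recovers the generative
   rate. Recovery time scans columns with Welch two-sample t-tests against
   the pooled last-50-column baseline (α = 0.05, no multiple-testing
   correction, matching the original sequential procedure); if no column is
   non-significant the window end is returned, flagged.
7. **Group statistics.** 2×2 within-subject ANOVA (flank condition × run)
   on tracking performance and on recovery rates, from closed-form sums of
   squares with F(1, n−1) and partial η² (sphericity is moot at 1 df);
   paired t-tests (run 1 vs run 2 extents; continuous vs trial-based
   extents) with Cohen's d on the differences; Pearson correlation between
   paradigms' extents.

## Validation designs and problem sizes

* Extent parameter recovery: true e_c ∈ {2, 3.5, 5}°, 8 observers × 2
  continuous runs + one trial-based session each, fixed seeds; group-mean
  recovery is within ±0.75° for both estimators and the two estimators
  correlate across the pooled estimates. Individual trial-based estimates
  carry sampling noise of a few tenths of a degree at 25 repetitions per
  condition (the baseline σ̂ from 25 isolated trials occasionally pulls a
  single estimate to the range edge).
* Decay-rate recovery and recovery-time monotonicity use a jump schedule
  with well-separated distances (0.5–4.5°, ≥ 2.1 s apart): the default
  schedule places two jumps 0.31 s apart, which truncates and overlaps
  their windows and is a property of the original design, not of the
  estimator. 50 jumps (10 trials) recover the rate within 15%; recovery
  time is probed at rates {2, 4, 8}/s with 150 jumps, because a 1/s decay
  does not stabilize inside the 2080 ms window (the estimator saturates at
  the window end).
* The end-to-end check simulates the full default study (8 observers ×
  2 runs × 12 continuous trials + 200 trial-based trials each), analyzes
  it through the CLI, and asserts byte-identical reruns; it completes in
  well under a minute per pass on one CPU.

## Known limitations

* The continuous-extent refinement assumes a flat isolated error level and
  a monotone flanked error below the hinge; heavily non-monotone error
  profiles would need a different breakpoint model.
* The sequential recovery-time estimator is bounded by the window length
  and loses discrimination for rates below ~2/s; it also inherits the
  original procedure's lack of multiple-testing control.
* Flip-and-average assumes near-symmetric full-range sweeps; for truncated
  trials (short durations) the flipped distance axes do not align and the
  extent output, while computed, is not meaningful.
* The cleaning-order question (clean before vs after flipping) is resolved
  as clean-first on the unflipped trial-matched series; the alternative
  order was not implemented.
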