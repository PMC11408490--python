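# Methods

## Auction mechanics

Bids are represented throughout as fractions of the water budget in [0, 1];
milliliters appear only in payout fields and at I/O. With budget *B* and a
uniform computer bid *c*, a bid *b* wins iff *b* ≥ *c* (ties win, per the
"equal to or exceeded" rule) at price *c·B*. Integrating over the opponent
gives E[payoff] = B + b·v − B·b²/2 for a juice value of *v* ml
water-equivalent, so the optimum is b\* = v/B and the optimal expected
payoff is B + v²/(2B). The package treats the juice→water exchange rate as
the caller's business: latent values live directly in bid-space units.

## Behavioral generator

Each trial's bid is

    bid = clip( base[mag] + s + L_t + Σ w_k x_k + ε , 0, 1 )

* `base` — per-magnitude latent value (defaults 0.25/0.50/0.75 of the bid
  space for the 0.3/1.0/1.7 ml subject; 0.20/0.40/0.60 for the
  0.2/0.45/0.7 ml subject). Chosen so the three bid distributions are
  rank-ordered, overlap, and jointly span most of the bid space.
* `s` — per-session offset, N(0, 0.08): day-to-day value fluctuation.
* `L_t` — AR(1) shared across magnitudes (φ = 0.95, innovation SD 0.03,
  stationary SD ≈ 0.10): within-session coherent drift. Because one scalar
  drives all three magnitudes, bids are coherent across reward levels —
  the property the coherence analysis quantifies.
* history terms `x_k`: starting bid (uniform cursor start, weight −0.05),
  normalized cumulative liquid (satiety, +0.10), previous same-magnitude
  computer bid (−0.03), previous same-magnitude result coded ±1 (+0.03),
  same-magnitude win/lose streak lengths (+0.01/−0.01).
* `ε` — trial noise, N(0, 0.05).
* 2% of trials fail (no stable bid); they produce no payout, do not update
  histories, and are excluded from analysis.

Magnitudes are interleaved uniformly at random (no block constraints).
Movement covariates (velocity, absement) are by default independent
standard normal noise — value-independent by construction, which is the
null hypothesis of the movement-control analysis; a `movement_coupling`
parameter ties them to the bid excursion for positive controls.

## Neuron generator

Rates around cue (fractal) onset, −500 to +1000 ms in 1 ms bins:

    rate(t) = baseline + attentional(t) + gain · (signal − mean_prediction) · value(t)

floored at 0 Hz, Poisson counts per bin. Defaults: baseline 5 Hz; waveform
width 2.5 ms; attentional bump 90–180 ms, +15 Hz, value-independent; value
component 180–340 ms, gain 25 Hz per unit prediction error. The signal is
the trial's bid (bid coder), the magnitude level's mean bid (magnitude
coder; this puts magnitude coding on the bid scale), or nothing.
`mean_prediction` defaults to the across-trial mean of the coded signal —
the expectation formed at the trial-start cue — so low-value trials depress
and high-value trials excite, i.e. a bidirectional prediction-error
response. The gain yields ±7–8 Hz swings over the realized bid range,
within the dynamic range reported for midbrain dopamine responses.

The baseline window is the 500 ms preceding cue onset. (Rasters are aligned
to the cue; a fixation-cross-aligned baseline is not representable and the
pre-cue window stands in for it.)

## Window detection

The value window is estimated from the population, not assumed: the start
is where the averaged lowest-magnitude trace (z-scored per neuron against
its own baseline, 20 ms boxcar-smoothed) first returns to the baseline mean
after the initial excitation, rounded to the nearest 20 ms; the end scans
20 ms bins of the highest-magnitude responses from the start and stops at
the first bin whose across-neuron z-rates are no longer significantly above
zero (one-sided sign-rank, Holm-corrected over the scanned bins, α = 0.05,
scan 0–500 ms). A trace that never returns to baseline, or a start with no
subsequent significant bin, yields an explicit failure status rather than a
window. On the default generator the injected 180–340 ms window is
recovered within one 20 ms bin in 50/50 seeded populations (12 neurons,
500 trials).

## Statistical choices

* **Responsiveness screen** (dopamine classification): the 0–200 ms
  post-event rate is paired against an equal-duration (−200 to 0 ms)
  baseline slice. Equal window lengths keep the paired count distributions
  identical under the null; pairing against the full 500 ms baseline makes
  the sign-rank grossly anticonservative (≈40% false positives at 1200
  trials, measured) because the two rate estimates have different skew.
* **Lasso**: coordinate-descent lasso on z-standardized columns over a
  60-point log-spaced path; K-fold CV (default 20 folds — fold counts far
  above the number of observations are accepted when the data allow);
  λ(1-SE) is the largest penalty whose mean CV MSE is within one standard
  error of the minimum. Day of week is one-hot encoded inside the lasso and
  collapsed back to one variable on report; previous-trial failure is
  binary. Constant columns are dropped with a warning; rows with undefined
  lags are dropped listwise, never imputed.
* **Mixed models**: statsmodels MixedLM. All three models carry a
  per-session random intercept and a per-session random trial-number slope
  (this is how trial progression and between-day variability are removed
  from the fixed effects); a session-number random slope is unidentifiable
  within single-session groups and is absorbed by the session intercept.
  Reward magnitude (models 2–3) and previous result (model 3) enter as
  variance components over their level indicators. Continuous fixed-effect
  predictors are z-scaled for conditioning; adjusted R² is computed from
  fitted (fixed + random) values. Non-convergence raises a warning and is
  flagged in the result, never silent.
* **Coherence**: per session, each magnitude's bids are linearly
  interpolated onto the full trial grid and the three series are
  Spearman-correlated pairwise. Interpolation fills trials where a
  magnitude was absent, so the statistic is a lower bound on the true
  coherence; with AR(1) drift the bound is visibly below 1 even at zero
  noise. Summary rho is the median across sessions, with a sign-rank test
  of the session rho distribution against zero.
* **Matched-bid comparison**: greedy one-to-one nearest-bid matching within
  neuron and session, caliper 5% of the bid space. A comparison whose
  matched bid values differ in distribution between the two magnitude
  groups (rank-sum p < 0.05) is eliminated before testing. The test is a
  two-sided sign-rank over *per-neuron mean* differences — the neuron is
  the unit of analysis, since matches within a neuron share trials — with
  Holm correction across the three magnitude pairings. Calibration of this
  test assumes different neurons contribute matches from different
  sessions; when many neurons share the same behavioral sessions the
  pooled differences are correlated and p-values are anticonservative (the
  demo pipeline is in this regime; the calibration fixtures use one neuron
  per session).
* **SVR decoding**: bids are discretized into ten equal-width ranges of
  the bid space; per neuron, 10 trials per range are drawn without
  replacement (neurons lacking coverage are excluded by name); the target
  is the bin midpoint. Folds are stratified — two test trials per range,
  rotated deterministically across the five folds. Hyperparameters:
  ε = 0.04 (≈ IQR of the targets / 13.5) and box constraint
  C = 0.06 / n_neurons. The inverse-n scaling is set by the chance-
  calibration requirement: the shuffled-label control must decode at
  chance (|mean R²| < 0.1) at any population size, and an n-independent
  constraint lets shuffled fits drift strongly negative as features are
  added (−0.67 at 20 neurons with C = 1, measured). With this rule the
  shuffled mean sits at −0.07…−0.03 for 1–40 neurons while real decoding
  rises monotonically. Raw R² values are kept internally; the headline
  accuracy clamps the iteration-mean at zero and reports percent, so a
  chance decoder reads 0%. Shuffling permutes the response–target pairing
  globally across the 100 pseudo-trials (within-bin shuffling is available
  as an option via the response pools).

## Problem sizes

Simulation sizes used by the test suite and the acceptance script: sessions
of 100–400 trials, 2–10 sessions per subject, populations of 10–20 neurons,
50 decoding iterations for curve properties and the full 300 for the
shuffled control; calibration checks use 20–50 seeds. These sizes give
Monte-Carlo error well inside the asserted margins while a full run stays
in the minutes range on one core.

## Limitations

* The generator's bid distributions are clipped Gaussians, not the skewed
  empirical shapes of real bidding; the skew-corrected tercile binning is
  exercised but not stressed.
* Magnitude coding is modeled on the bid scale (level mean bid); real
  magnitude-sensitive neurons may code nonlinear transforms.
* Neurons are conditionally independent given the trial sequence — no
  noise correlations, so pseudo-population decoding here is, if anything,
  easier than with simultaneously recorded populations.
* Passing calibration on this generator shows the procedures are correct
  and calibrated under the stated model; it does not certify behavior on
  real recordings with drift, instabilities, or non-Poisson firing.
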