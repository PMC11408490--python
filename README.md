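# dopabid

Analysis pipeline for Becker-DeGroot-Marschak (BDM) auction experiments in
which a subject's trial-by-trial bids reveal instantaneous subjective reward
value, and neuronal responses are tested for tracking those bids.

In the task a subject bids a fraction *b* ∈ [0, 1] of a fixed water budget
*B* (1.2 ml) for one of three juice volumes, against a computer opponent
whose bid *c* is uniform on the bid space. The subject wins iff *b* ≥ *c*,
receives the juice, and pays the *computer's* price (second-price rule):
water delivered = *B*(1 − *c*). On a loss the full budget is paid out and no
juice. For a subjective juice value *v* (in ml water-equivalent) the
expected payoff is

    E[payoff](b) = B + b·v − B·b²/2,

maximized exactly at b\* = v/B — bidding one's true value is optimal
("incentive compatibility"), so the bid is a per-trial readout of value.

The package implements, end to end and on reproducible synthetic data:

* **`dopabid.bdm`** — auction payoff rules, closed-form expected payoff,
  numeric incentive-compatibility checks.
* **`dopabid.synth`** — seeded generators: bidding sessions driven by a
  shared drifting latent value plus outcome history, and dopamine-like
  spike rasters with a two-component response whose second ("value")
  component encodes the bid-referenced prediction error (Poisson, 1 ms bins).
* **`dopabid.behavior`** — the 31 candidate trial-history regressors,
  cross-validated lasso selection (one-standard-error rule), three
  mixed-effects bid models (magnitude fixed / magnitude random / streak
  model), rank-order and bid-coherence statistics.
* **`dopabid.neural`** — dopamine classification (waveform > 1.8 ms,
  baseline < 10 Hz, event-responsive), data-driven detection of the value
  analysis window, z-normalized windowed rates, per-neuron bid regressions
  (y = β₀ + β₁·bid), matched-bid comparisons across reward magnitudes, and
  movement-parameter control regressions.
* **`dopabid.decoding`** — pseudo-population linear support-vector
  regression of bids (10 bid ranges × 10 trials, stratified five-fold CV,
  300 resampling iterations), neuron-ordering curves, shuffled controls.
* **`dopabid.pipeline` / CLI `dopabid`** — orchestrated runs with a single
  master seed and a JSON report.

## Worked example

```bash
dopabid run-all --out runs/demo --seed 7
```

generates one synthetic subject (6 sessions × 400 trials, reward magnitudes
0.3/1.0/1.7 ml, 1.2 ml budget; 12 bid-coding, 4 magnitude-coding and 4
non-coding neurons), runs every stage, and writes `runs/demo/report.json`.
With seed 7 the report contains, among other entries:

* Bids are rank-ordered by juice volume: pooled Spearman ρ = 0.854, with
  100% of sessions individually significant — larger rewards draw larger
  bids.
* Full mixed model (magnitude as fixed effect): β(reward magnitude) = 0.23,
  β(previous same-magnitude result) = 0.10, β(starting bid) = −0.011,
  adjusted R² = 0.92 — bids are driven by reward magnitude plus outcome
  history, as injected by the generator.
* Value window detected from the population: 180–340 ms after cue onset
  (the generator's ground-truth value component), and 16/20 neurons pass
  the positive bid-regression screen.
* Random-order decoding (30 iterations): mean R² rises from 0.31 with one
  neuron to 0.80 with 12 neurons, while the shuffled control sits at
  −0.067 raw (clamped accuracy 0%); real vs. shuffled rank-sum
  p ≈ 2.9 × 10⁻¹¹ — a small population of bid-coding neurons suffices to
  decode the upcoming bid, and the decoder is calibrated at chance.

`dopabid generate / behavior / neural / decode / validate` run individual
stages; `--config cfg.json` overrides any `RunConfig` field.

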