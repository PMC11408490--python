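"""Seeded synthetic BDM sessions and dopamine-like spike rasters.

The behavioral generator emulates a monkey bidding part of a 1.2 ml water
budget for one of three juice magnitudes per trial. Bids are driven by a
per-magnitude base value plus a *shared* latent value process (AR(1) within
session, an independent offset between sessions) plus outcome-history terms
(starting bid, satiety, previous computer bid / result / streaks for the
same magnitude) plus trial noise, clipped to the bid space. Sharing the
latent process across magnitudes is what makes bids coherent across reward
levels, which the behavioral coherence analysis measures.

The neural generator produces two-component responses around fractal
(reward-cue) onset: a value-independent "attentional" excitation followed by
a value component whose rate is proportional to the trial's prediction error
— the coded signal (bid, magnitude value, or nothing) minus the mean
prediction at the trial-start cue. Counts are Poisson in 1 ms bins, rates
floored at zero so that negative prediction errors depress firing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from dopabid.bdm import AuctionConfig, resolve_auction

__all__ = [
    "AgentParams",
    "SubjectConfig",
    "NeuronModel",
    "SpikeRaster",
    "MONKEY_V",
    "MONKEY_U",
    "simulate_behavior",
    "simulate_neuron",
    "simulate_population",
    "generate_dataset",
    "RASTER_T_START_MS",
    "RASTER_T_STOP_MS",
    "TRIAL_COLUMNS",
]

# Raster span around fractal onset, 1 ms bins: covers a 500 ms pre-event
# baseline and both response components.
RASTER_T_START_MS = -500
RASTER_T_STOP_MS = 1000


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the bidding agent (bid-space units).

    ``base_values`` are the latent values of the three magnitudes. The shared
    latent scalar follows an AR(1) with coefficient ``ar_coef`` and
    innovation ``trial_drift_sd``; each session additionally draws an offset
    with ``session_drift_sd``. History weights multiply normalized
    regressors: starting bid and previous computer bid in [0, 1], total
    liquid as fraction of the session's maximal possible intake, previous
    result coded +1 win / -1 lose, streak lengths in trials.
    """

    base_values: tuple[float, float, float] = (0.25, 0.5, 0.75)
    ar_coef: float = 0.95
    trial_drift_sd: float = 0.03
    session_drift_sd: float = 0.08
    bid_noise_sd: float = 0.05
    w_starting_bid: float = -0.05
    w_total_liquid: float = 0.10
    w_prev_computer_bid: float = -0.03
    w_prev_result: float = 0.03
    w_win_streak: float = 0.01
    w_lose_streak: float = -0.01
    fail_prob: float = 0.02
    # Coupling of the movement covariates to the executed bid excursion;
    # zero keeps movement independent of value (the null of the movement
    # control analysis).
    movement_coupling: float = 0.0

    @property
    def stationary_sd(self) -> float:
        if abs(self.ar_coef) < 1:
            return self.trial_drift_sd / np.sqrt(1.0 - self.ar_coef**2)
        return self.trial_drift_sd


@dataclass(frozen=True)
class SubjectConfig:
    """One simulated subject: reward magnitudes, budget, session layout."""

    name: str = "V"
    magnitudes: tuple[float, float, float] = (0.3, 1.0, 1.7)
    budget: float = 1.2
    n_sessions: int = 10
    trials_per_session: int = 100
    agent: AgentParams = field(default_factory=AgentParams)

    def __post_init__(self) -> None:
        if len(self.magnitudes) != 3 or not (
            self.magnitudes[0] < self.magnitudes[1] < self.magnitudes[2]
        ):
            raise ValueError("magnitudes must be three strictly increasing volumes")
        if self.budget <= 0:
            raise ValueError("budget must be positive")

    @property
    def auction(self) -> AuctionConfig:
        return AuctionConfig(budget=self.budget)


#: Default configurations mirroring the two subjects' reward sets.
MONKEY_V = SubjectConfig(name="V", magnitudes=(0.3, 1.0, 1.7))
MONKEY_U = SubjectConfig(
    name="U",
    magnitudes=(0.2, 0.45, 0.7),
    agent=AgentParams(base_values=(0.2, 0.4, 0.6)),
)

MAGNITUDE_LEVELS = ("low", "mid", "high")

TRIAL_COLUMNS = [
    "subject",
    "session_id",
    "trial_index",
    "magnitude_level",
    "magnitude_ml",
    "starting_bid",
    "bid",
    "computer_bid",
    "result",
    "juice_ml",
    "water_ml",
    "cumulative_liquid_ml",
    "win_streak",
    "lose_streak",
    "day_of_week",
    "velocity",
    "absement",
    "latent_value",
    "t_trial_start",
    "t_fractal",
    "t_bidspace",
    "t_bid_stable",
    "t_computer_reveal",
    "t_juice",
    "t_water",
]


def simulate_behavior(
    cfg: SubjectConfig, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate all sessions of one subject.

    Returns the trial table (one row per trial, columns ``TRIAL_COLUMNS``)
    and the latent shared-value trajectory (session offset + AR(1) state,
    one entry per trial). ``win_streak`` / ``lose_streak`` are the counts of
    consecutive same-magnitude wins/losses *entering* the trial, i.e. the
    state that can influence the current bid.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ag = cfg.agent
    rows: list[dict] = []
    latent_all: list[float] = []
    max_liquid = cfg.trials_per_session * (cfg.budget + max(cfg.magnitudes))

    for s in range(cfg.n_sessions):
        session_offset = rng.normal(0.0, ag.session_drift_sd) if ag.session_drift_sd > 0 else 0.0
        L = rng.normal(0.0, ag.stationary_sd) if ag.trial_drift_sd > 0 else 0.0
        cum_liquid = 0.0
        win_streak = {m: 0 for m in MAGNITUDE_LEVELS}
        lose_streak = {m: 0 for m in MAGNITUDE_LEVELS}
        prev_result = {m: 0.0 for m in MAGNITUDE_LEVELS}  # +1 win, -1 lose, 0 none
        prev_cbid = {m: 0.0 for m in MAGNITUDE_LEVELS}
        clock = 0.0

        for i in range(cfg.trials_per_session):
            level_idx = int(rng.integers(3))
            level = MAGNITUDE_LEVELS[level_idx]
            if ag.trial_drift_sd > 0:
                L = ag.ar_coef * L + rng.normal(0.0, ag.trial_drift_sd)
            starting_bid = rng.uniform()
            noise = rng.normal(0.0, ag.bid_noise_sd) if ag.bid_noise_sd > 0 else 0.0
            history = (
                ag.w_starting_bid * starting_bid
                + ag.w_total_liquid * (cum_liquid / max_liquid)
                + ag.w_prev_computer_bid * prev_cbid[level]
                + ag.w_prev_result * prev_result[level]
                + ag.w_win_streak * win_streak[level]
                + ag.w_lose_streak * lose_streak[level]
            )
            latent = session_offset + L
            bid = float(np.clip(ag.base_values[level_idx] + latent + history + noise, 0.0, 1.0))
            computer_bid = float(rng.uniform())
            failed = bool(rng.uniform() < ag.fail_prob)

            ws, ls = win_streak[level], lose_streak[level]
            bid_duration = float(rng.uniform(1.0, 3.5))
            move_noise = rng.normal(0.0, 1.0, size=2)
            excursion = (bid - starting_bid) / bid_duration
            velocity = ag.movement_coupling * excursion + float(move_noise[0])
            absement = ag.movement_coupling * (bid - starting_bid) * bid_duration + float(
                move_noise[1]
            )

            t_start = clock
            t_fractal = t_start + 0.5
            t_bidspace = t_fractal + 1.0
            t_bid_stable = t_bidspace + bid_duration + 0.5

            if failed:
                result, juice, water = "failed", 0.0, 0.0
                t_reveal = t_juice = t_water = np.nan
                clock = t_bid_stable + 2.0
            else:
                out = resolve_auction(bid, computer_bid, cfg.magnitudes[level_idx], cfg.auction)
                result = "win" if out.won else "lose"
                juice, water = out.juice_delivered, out.water_delivered
                t_reveal = t_bid_stable + 0.5
                if out.won:
                    t_juice = t_reveal + 1.0
                    t_water = t_juice + 1.5
                else:
                    t_juice = np.nan
                    t_water = t_reveal + 1.0
                clock = t_water + 2.0

            rows.append(
                {
                    "subject": cfg.name,
                    "session_id": s,
                    "trial_index": i,
                    "magnitude_level": level,
                    "magnitude_ml": cfg.magnitudes[level_idx],
                    "starting_bid": starting_bid,
                    "bid": bid,
                    "computer_bid": computer_bid,
                    "result": result,
                    "juice_ml": juice,
                    "water_ml": water,
                    "cumulative_liquid_ml": cum_liquid,
                    "win_streak": ws,
                    "lose_streak": ls,
                    "day_of_week": s % 5,
                    "velocity": velocity,
                    "absement": absement,
                    "latent_value": latent,
                    "t_trial_start": t_start,
                    "t_fractal": t_fractal,
                    "t_bidspace": t_bidspace,
                    "t_bid_stable": t_bid_stable,
                    "t_computer_reveal": t_reveal,
                    "t_juice": t_juice,
                    "t_water": t_water,
                }
            )
            latent_all.append(latent)

            if not failed:
                cum_liquid += juice + water
                if result == "win":
                    win_streak[level] += 1
                    lose_streak[level] = 0
                    prev_result[level] = 1.0
                else:
                    lose_streak[level] += 1
                    win_streak[level] = 0
                    prev_result[level] = -1.0
                prev_cbid[level] = computer_bid

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df, np.asarray(latent_all)


@dataclass(frozen=True)
class NeuronModel:
    """Generative parameters of one dopamine-like neuron.

    The rate around cue onset is baseline + an attentional bump
    (value-independent) + a value component proportional to the trial's
    prediction error, floored at 0 Hz. ``coding_target`` selects what the
    value component encodes: the trial bid, the magnitude's mean value, or
    nothing.
    """

    neuron_id: str = "n0"
    baseline_rate: float = 5.0
    waveform_width_ms: float = 2.5
    attentional_latency_ms: float = 90.0
    attentional_duration_ms: float = 90.0
    attentional_amplitude_hz: float = 15.0
    value_latency_ms: float = 180.0
    value_duration_ms: float = 160.0
    value_gain_hz: float = 25.0
    coding_target: str = "bid"  # "bid" | "magnitude" | "none"

    def __post_init__(self) -> None:
        if self.coding_target not in ("bid", "magnitude", "none"):
            raise ValueError(f"unknown coding_target {self.coding_target!r}")
        if self.value_latency_ms < self.attentional_latency_ms + self.attentional_duration_ms:
            raise ValueError("value component must begin after the attentional component")


@dataclass
class SpikeRaster:
    """1 ms-binned spike counts per trial around fractal onset."""

    neuron_id: str
    counts: np.ndarray  # (n_trials, n_bins) int
    session_ids: np.ndarray
    trial_indices: np.ndarray
    t_start_ms: int = RASTER_T_START_MS
    bin_ms: int = 1

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def time_ms(self) -> np.ndarray:
        """Left edge of every bin, ms relative to fractal onset."""
        n = self.counts.shape[1]
        return self.t_start_ms + self.bin_ms * np.arange(n)


def _value_signal(model: NeuronModel, trials: pd.DataFrame) -> np.ndarray:
    if model.coding_target == "bid":
        return trials["bid"].to_numpy(float)
    if model.coding_target == "magnitude":
        # Value of the magnitude level: the mean bid placed for it, which
        # puts magnitude coding on the same scale as bid coding.
        level_value = trials.groupby("magnitude_level")["bid"].mean()
        return trials["magnitude_level"].map(level_value).to_numpy(float)
    return np.full(len(trials), np.nan)  # "none": no value signal


def simulate_neuron(
    model: NeuronModel,
    trials: pd.DataFrame,
    mean_prediction: float | None = None,
    seed: int | np.random.Generator = 0,
) -> SpikeRaster:
    """Generate the spike raster of one neuron over the given trials.

    ``mean_prediction`` is the across-trial mean value predicted at the
    trial-start cue; the value component encodes signal − mean_prediction.
    Defaults to the mean of the neuron's own coded signal (mean bid for
    non-coding neurons, so that their prediction error is exactly zero).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_bins = RASTER_T_STOP_MS - RASTER_T_START_MS
    t = RASTER_T_START_MS + np.arange(n_bins)  # bin left edges

    signal = _value_signal(model, trials)
    if np.all(np.isnan(signal)):
        signal = trials["bid"].to_numpy(float)
        pe = np.zeros(len(trials))
    else:
        mp = float(np.nanmean(signal)) if mean_prediction is None else float(mean_prediction)
        pe = signal - mp

    att = (t >= model.attentional_latency_ms) & (
        t < model.attentional_latency_ms + model.attentional_duration_ms
    )
    val = (t >= model.value_latency_ms) & (t < model.value_latency_ms + model.value_duration_ms)

    rate = np.full((len(trials), n_bins), model.baseline_rate)
    rate[:, att] += model.attentional_amplitude_hz
    rate[:, val] += model.value_gain_hz * pe[:, None]
    np.clip(rate, 0.0, None, out=rate)

    counts = rng.poisson(rate / 1000.0)
    return SpikeRaster(
        neuron_id=model.neuron_id,
        counts=counts.astype(np.int16),
        session_ids=trials["session_id"].to_numpy(),
        trial_indices=trials["trial_index"].to_numpy(),
    )


def simulate_population(
    trials: pd.DataFrame,
    n_neurons: int,
    coding_target: str = "bid",
    seed: int | np.random.Generator = 0,
    one_session_per_neuron: bool = False,
    **model_kwargs,
) -> list[tuple[NeuronModel, SpikeRaster]]:
    """Simulate a homogeneous population of neurons over the given trials.

    By default every neuron is simulated over the subject's full trial
    table, which guarantees each neuron samples the whole bid range (the
    balance requirement of the pseudo-population). With
    ``one_session_per_neuron`` each neuron instead sees only the trials of
    one session, mirroring sequential single-electrode recordings.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sessions = sorted(trials["session_id"].unique())
    out = []
    for k in range(n_neurons):
        model = NeuronModel(neuron_id=f"{coding_target}_{k}", coding_target=coding_target, **model_kwargs)
        sub = (
            trials[trials["session_id"] == sessions[k % len(sessions)]]
            if one_session_per_neuron
            else trials
        )
        out.append((model, simulate_neuron(model, sub, seed=rng)))
    return out


def _raster_to_frame(raster: SpikeRaster) -> pd.DataFrame:
    """Long spike-time representation used in the on-disk TSV."""
    rows = []
    for i in range(raster.n_trials):
        times = raster.time_ms[raster.counts[i] > 0]
        reps = raster.counts[i][raster.counts[i] > 0]
        spikes = np.repeat(times, reps)
        rows.append(
            {
                "session_id": raster.session_ids[i],
                "trial_index": raster.trial_indices[i],
                "spike_times_ms": ",".join(str(int(x)) for x in spikes),
            }
        )
    return pd.DataFrame(rows)


def raster_from_frame(df: pd.DataFrame, neuron_id: str) -> SpikeRaster:
    """Rebuild a dense 1 ms raster from the long spike-time TSV form."""
    n_bins = RASTER_T_STOP_MS - RASTER_T_START_MS
    counts = np.zeros((len(df), n_bins), dtype=np.int16)
    for i, times in enumerate(df["spike_times_ms"].fillna("")):
        if times:
            idx = np.asarray(times.split(","), dtype=int) - RASTER_T_START_MS
            np.add.at(counts[i], idx, 1)
    return SpikeRaster(
        neuron_id=neuron_id,
        counts=counts,
        session_ids=df["session_id"].to_numpy(),
        trial_indices=df["trial_index"].to_numpy(),
    )


def generate_dataset(
    out_dir: str | Path,
    subjects: list[SubjectConfig] | None = None,
    n_bid_neurons: int = 10,
    n_magnitude_neurons: int = 5,
    n_noncoding_neurons: int = 5,
    seed: int = 0,
) -> dict:
    """Write a complete synthetic dataset to ``out_dir``.

    Produces per subject a trial TSV, one raster TSV per neuron, and a JSON
    manifest recording every generative parameter (the ground truth for
    recovery tests). Deterministic: the same seed yields byte-identical
    files.
    """
    if min(n_bid_neurons, n_magnitude_neurons, n_noncoding_neurons) < 0:
        raise ValueError("neuron counts must be non-negative")
    subjects = subjects or [MONKEY_V, MONKEY_U]
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create dataset directory {out_dir}: {e}") from e

    manifest: dict = {"seed": seed, "subjects": {}}
    root_rng = np.random.default_rng(seed)

    for cfg in subjects:
        sub_seed = int(root_rng.integers(2**31))
        trials, _ = simulate_behavior(cfg, sub_seed)
        trials_path = out_dir / f"trials_{cfg.name}.tsv"
        trials.to_csv(trials_path, sep="\t", index=False, float_format="%.10g")

        neuron_manifest = []
        neuron_rng = np.random.default_rng(sub_seed + 1)
        groups = (
            ["bid"] * n_bid_neurons
            + ["magnitude"] * n_magnitude_neurons
            + ["none"] * n_noncoding_neurons
        )
        for target in ("bid", "magnitude", "none"):
            n = groups.count(target)
            if n == 0:
                continue
            for model, raster in simulate_population(
                trials, n, coding_target=target, seed=neuron_rng
            ):
                path = out_dir / f"raster_{cfg.name}_{model.neuron_id}.tsv"
                _raster_to_frame(raster).to_csv(path, sep="\t", index=False)
                neuron_manifest.append(asdict(model))

        manifest["subjects"][cfg.name] = {
            "seed": sub_seed,
            "config": {
                "name": cfg.name,
                "magnitudes": list(cfg.magnitudes),
                "budget": cfg.budget,
                "n_sessions": cfg.n_sessions,
                "trials_per_session": cfg.trials_per_session,
                "agent": asdict(cfg.agent),
            },
            "neurons": neuron_manifest,
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
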