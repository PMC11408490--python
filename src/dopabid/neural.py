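"""Dopamine-response analysis around the reward-cue (fractal) onset.

The canonical dopamine-like response has two parts: an early value-
independent "attentional" excitation and a later "value" component that
encodes the bidirectional reward prediction error. All value analyses here
run on the second component only, inside an analysis window detected from
the population itself: the window starts where the averaged response to the
*lowest* magnitude (expected to carry a negative prediction error) returns
to baseline after the attentional bump, and ends where the averaged
response to the *highest* magnitude stops being significantly positive
(20 ms bins, sign-rank, Bonferroni-Holm).

Windowed rates are z-normalized per neuron across its trials before any
group-level statistics. The matched-bid comparison pools, across neurons,
response differences for bids that agree within 5% of the bid space but
were placed for different reward magnitudes: a signed difference indicates
magnitude coding, a null difference indicates pure bid (subjective-value)
coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dopabid.synth import NeuronModel, SpikeRaster

__all__ = [
    "AnalysisWindow",
    "WindowDetection",
    "classify_dopamine",
    "detect_value_window",
    "windowed_response",
    "build_response_table",
    "z_normalize",
    "RegressionResult",
    "bid_regression",
    "select_bid_encoding",
    "bin_bids",
    "MatchedBidComparison",
    "matched_bid_comparison",
    "movement_control_regressions",
]

BASELINE_MS = (-500, 0)  # pre-fractal baseline window


@dataclass(frozen=True)
class AnalysisWindow:
    """Post-cue analysis window in ms; start is a multiple of 20 ms."""

    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if not (0 < self.start_ms < self.end_ms <= 500):
            raise ValueError(f"window must satisfy 0 < start < end <= 500, got {self}")

    @property
    def duration_s(self) -> float:
        return (self.end_ms - self.start_ms) / 1000.0


@dataclass
class WindowDetection:
    """Outcome of the value-window search; ``window`` is None on failure."""

    status: str  # "ok" | "no_baseline_return" | "no_value_component"
    window: AnalysisWindow | None
    start_ms: int | None = None
    end_ms: int | None = None


def _rate_in_window(raster: SpikeRaster, t0: float, t1: float) -> np.ndarray:
    """Per-trial firing rate (Hz) in [t0, t1) ms relative to cue onset."""
    t = raster.time_ms
    sel = (t >= t0) & (t < t1)
    return raster.counts[:, sel].sum(axis=1) / ((t1 - t0) / 1000.0)


def baseline_rate(raster: SpikeRaster) -> np.ndarray:
    return _rate_in_window(raster, *BASELINE_MS)


def classify_dopamine(
    raster: SpikeRaster,
    waveform_width_ms: float | None,
    event_windows: tuple[tuple[float, float], ...] = ((0.0, 200.0),),
    alpha: float = 0.05,
) -> str:
    """Classify a neuron as ``"dopamine"`` or ``"non_dopamine"``.

    Criteria: impulse waveform wider than 1.8 ms, baseline rate below 10 Hz,
    and a significant response (paired Wilcoxon of the 0-200 ms post-event
    rate against an equal-duration slice of the pre-cue baseline, p < alpha)
    to at least one task event. The equal window lengths keep the paired
    count distributions identical under the null, so the sign-rank screen is
    calibrated. Missing waveform metadata classifies as non-dopamine with a
    warning.
    """
    if waveform_width_ms is None:
        warnings.warn(f"neuron {raster.neuron_id}: no waveform width; classified non_dopamine")
        return "non_dopamine"
    if raster.n_trials < 20:
        raise ValueError("classification needs at least 20 trials")
    if waveform_width_ms <= 1.8:
        return "non_dopamine"
    base = baseline_rate(raster)
    if base.mean() >= 10.0:
        return "non_dopamine"
    for t0, t1 in event_windows:
        resp = _rate_in_window(raster, t0, t1)
        # equal-duration baseline slice ending at the event
        ref = _rate_in_window(raster, -(t1 - t0), 0.0)
        diff = resp - ref
        if np.allclose(diff, 0):
            continue
        if stats.wilcoxon(diff).pvalue < alpha:
            return "dopamine"
    return "non_dopamine"


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _neuron_z_trace(raster: SpikeRaster, trial_mask: np.ndarray, smooth_ms: int) -> np.ndarray:
    """Trial-averaged rate trace, z-scored by its own baseline statistics."""
    trace = raster.counts[trial_mask].mean(axis=0) * 1000.0  # Hz per 1 ms bin
    if smooth_ms > 1:
        trace = _smooth(trace, smooth_ms)
    t = raster.time_ms
    base = trace[(t >= BASELINE_MS[0]) & (t < BASELINE_MS[1])]
    sd = base.std(ddof=0)
    if sd == 0:
        return np.full_like(trace, np.nan)
    return (trace - base.mean()) / sd


def detect_value_window(
    rasters: list[SpikeRaster],
    trials: pd.DataFrame,
    smooth_ms: int = 20,
    alpha: float = 0.05,
    scan_stop_ms: int = 500,
) -> WindowDetection:
    """Detect the value-component analysis window from a population.

    Start: the first time after the initial excitation at which the
    population-averaged z-trace for the *lowest* magnitude returns to the
    baseline mean, rounded to the nearest 20 ms. End: scanning 20 ms bins of
    the *highest*-magnitude responses from the start, the left edge of the
    first bin whose across-neuron z-rates are no longer significantly above
    zero (one-sided sign-rank, Bonferroni-Holm over scanned bins).
    """
    if len(rasters) < 10:
        warnings.warn(f"window detection on only {len(rasters)} neurons (< 10 recommended)")

    key = trials.set_index(["session_id", "trial_index"])["magnitude_level"]
    low_traces = []
    for r in rasters:
        levels = key.loc[list(zip(r.session_ids, r.trial_indices))].to_numpy()
        tr = _neuron_z_trace(r, levels == "low", smooth_ms)
        if not np.all(np.isnan(tr)):
            low_traces.append(tr)
    pop_low = np.nanmean(np.vstack(low_traces), axis=0)
    t = rasters[0].time_ms

    post = (t >= 0) & (t < 300)
    peak_idx = np.flatnonzero(post)[np.argmax(pop_low[post])]
    after_peak = np.flatnonzero((np.arange(len(t)) > peak_idx) & (t < scan_stop_ms))
    crossing = after_peak[pop_low[after_peak] <= 0.0]
    if len(crossing) == 0:
        return WindowDetection(status="no_baseline_return", window=None)
    start = int(round(t[crossing[0]] / 20.0) * 20)
    start = max(start, 20)

    # z-rate of the high-magnitude trials per 20 ms bin, per neuron
    bins = [(b, b + 20) for b in range(0, scan_stop_ms, 20)]
    per_bin: list[np.ndarray] = []
    for b0, b1 in bins:
        vals = []
        for r in rasters:
            levels = key.loc[list(zip(r.session_ids, r.trial_indices))].to_numpy()
            high = levels == "high"
            if high.sum() == 0:
                continue
            base = baseline_rate(r)
            mu, sd = base.mean(), base.std(ddof=0)
            if sd == 0:
                continue
            rate = _rate_in_window(r, b0, b1)[high].mean()
            vals.append((rate - mu) / sd)
        per_bin.append(np.asarray(vals))

    scan = [i for i, (b0, _) in enumerate(bins) if b0 >= start]
    pvals = []
    for i in scan:
        v = per_bin[i]
        if len(v) < 5 or np.allclose(v, 0):
            pvals.append(1.0)
        else:
            pvals.append(stats.wilcoxon(v, alternative="greater").pvalue)
    if not pvals:
        return WindowDetection(status="no_value_component", window=None, start_ms=start)
    reject = multipletests(pvals, alpha=alpha, method="holm")[0]
    end = scan_stop_ms
    for j, i in enumerate(scan):
        if not reject[j]:
            end = bins[i][0]
            break
    if end <= start:
        return WindowDetection(status="no_value_component", window=None, start_ms=start, end_ms=end)
    return WindowDetection(
        status="ok", window=AnalysisWindow(start, end), start_ms=start, end_ms=end
    )


def windowed_response(raster: SpikeRaster, window: AnalysisWindow) -> np.ndarray:
    """Per-trial firing rate (Hz) inside the analysis window."""
    t = raster.time_ms
    if window.start_ms < t[0] or window.end_ms > t[-1] + raster.bin_ms:
        raise ValueError(f"{window} outside raster span")
    return _rate_in_window(raster, window.start_ms, window.end_ms)


def build_response_table(
    population: list[tuple[NeuronModel, SpikeRaster]],
    trials: pd.DataFrame,
    window: AnalysisWindow,
    include_failed: bool = False,
) -> pd.DataFrame:
    """Long per-neuron x per-trial response table with z-normalized rates.

    Joins each raster's trials back to the trial table for bids, magnitude
    levels, and movement covariates, then z-scores rates per neuron.
    """
    cols = ["bid", "magnitude_level", "magnitude_ml", "result", "velocity", "absement"]
    key = trials.set_index(["session_id", "trial_index"])[cols]
    frames = []
    for model, raster in population:
        meta = key.loc[list(zip(raster.session_ids, raster.trial_indices))].reset_index()
        meta["neuron_id"] = raster.neuron_id
        meta["waveform_width_ms"] = model.waveform_width_ms
        meta["rate_hz"] = windowed_response(raster, window)
        frames.append(meta)
    df = pd.concat(frames, ignore_index=True)
    if not include_failed:
        df = df[df["result"] != "failed"].reset_index(drop=True)
    df["abs_velocity"] = df["velocity"].abs()
    df["abs_absement"] = df["absement"].abs()
    return z_normalize(df)


def z_normalize(responses: pd.DataFrame) -> pd.DataFrame:
    """Add a per-neuron z-scored ``z`` column; drop zero-variance neurons."""
    out = responses.copy()
    sd = out.groupby("neuron_id")["rate_hz"].transform(lambda x: x.std(ddof=0))
    dead = out.loc[sd == 0, "neuron_id"].unique()
    if len(dead):
        warnings.warn(f"excluding zero-variance neurons: {sorted(dead)}")
        out = out[sd > 0].copy()
        sd = sd[sd > 0]
    mu = out.groupby("neuron_id")["rate_hz"].transform("mean")
    out["z"] = (out["rate_hz"] - mu) / sd
    return out.reset_index(drop=True)


@dataclass
class RegressionResult:
    """Simple linear regression of response on bid."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def bid_regression(
    responses: np.ndarray | pd.Series,
    bids: np.ndarray | pd.Series,
    n_bins: int | None = None,
) -> RegressionResult:
    """OLS of (optionally bin-averaged) responses on bids.

    With ``n_bins``, bids are first discretized into equal-width bins over
    the bid space and responses averaged per bin; the regression then runs
    on bin centers (empty bins dropped).
    """
    y = np.asarray(responses, dtype=float)
    x = np.asarray(bids, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("bids have no variance; regression undefined")
    if n_bins is not None:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        labels = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        centers, means = [], []
        for b in range(n_bins):
            m = labels == b
            if m.any():
                centers.append((edges[b] + edges[b + 1]) / 2.0)
                means.append(y[m].mean())
        x, y = np.asarray(centers), np.asarray(means)
        if len(x) < 3:
            raise ValueError(f"only {len(x)} non-empty bid bins; need >= 3")
    elif len(x) < 10:
        raise ValueError(f"need >= 10 observations for unbinned regression, got {len(x)}")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
    )


def per_neuron_bid_regression(responses: pd.DataFrame, use_z: bool = True) -> pd.DataFrame:
    """Bid regression per neuron; returns slope, R2, p per neuron."""
    col = "z" if use_z else "rate_hz"
    rows = []
    for nid, sub in responses.groupby("neuron_id"):
        try:
            r = bid_regression(sub[col], sub["bid"])
        except ValueError:
            continue
        rows.append({"neuron_id": nid, "slope": r.slope, "r2": r.r2, "p": r.p, "n": r.n})
    return pd.DataFrame(rows, columns=["neuron_id", "slope", "r2", "p", "n"])


def select_bid_encoding(responses: pd.DataFrame, alpha: float = 0.05) -> tuple[list, pd.DataFrame]:
    """Neurons whose value response correlates positively with the bids.

    Returns the selected neuron ids (regression p < alpha AND positive
    slope) and the full per-neuron regression table.
    """
    table = per_neuron_bid_regression(responses)
    sel = table[(table["p"] < alpha) & (table["slope"] > 0)]["neuron_id"].tolist()
    return sel, table


def bin_bids(
    bids: np.ndarray | pd.Series,
    scheme: str = "tenths",
    magnitudes: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Discretize bids; returns integer bin labels.

    ``tenths``/``quintiles``/``25_bins`` are equal-width on [0, 1];
    ``terciles_skew_corrected`` assigns equal-count (quantile) terciles
    separately within each magnitude group, correcting for the skew of each
    distribution (requires ``magnitudes``).
    """
    x = np.asarray(bids, dtype=float)
    widths = {"tenths": 10, "quintiles": 5, "25_bins": 25}
    if scheme in widths:
        n = widths[scheme]
        labels = np.clip(np.floor(x * n).astype(int), 0, n - 1)
        counts = np.bincount(labels, minlength=n)
        if (counts == 0).any():
            warnings.warn(f"{scheme}: empty bid bins at {np.flatnonzero(counts == 0).tolist()}")
        return labels
    if scheme == "terciles_skew_corrected":
        if magnitudes is None:
            raise ValueError("terciles_skew_corrected requires magnitudes")
        mags = np.asarray(magnitudes)
        labels = np.empty(len(x), dtype=int)
        for m in np.unique(mags):
            sel = mags == m
            # rank-based equal-count terciles within the magnitude group
            ranks = stats.rankdata(x[sel], method="ordinal") - 1
            labels[sel] = (ranks * 3 // sel.sum()).astype(int)
        return labels
    raise ValueError(f"unknown binning scheme {scheme!r}")


@dataclass
class MatchedBidComparison:
    pair: str  # "low-vs-mid" | "mid-vs-high" | "low-vs-high"
    n_matches: int
    n_neurons: int
    mean_difference: float  # higher-magnitude minus lower, z units
    p: float  # sign-rank over per-neuron mean differences; NaN if untested
    p_corrected: float  # Holm-adjusted across the tested comparisons
    eliminated: bool  # matched bid distributions differed significantly
    bid_distribution_p: float


_MAG_PAIRS = (("low", "mid"), ("mid", "high"), ("low", "high"))


def _greedy_match(bids_lo: np.ndarray, bids_hi: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """One-to-one nearest-bid matching within tolerance (greedy by distance)."""
    cand = [
        (abs(bl - bh), i, j)
        for i, bl in enumerate(bids_lo)
        for j, bh in enumerate(bids_hi)
        if abs(bl - bh) < tol
    ]
    cand.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i not in used_i and j not in used_j:
            pairs.append((i, j))
            used_i.add(i)
            used_j.add(j)
    return pairs


def matched_bid_comparison(
    responses: pd.DataFrame,
    tolerance: float = 0.05,
    alpha: float = 0.05,
    min_pairs: int = 5,
    min_neurons: int = 5,
) -> list[MatchedBidComparison]:
    """Compare responses for matched bids across reward magnitudes.

    For each magnitude pairing, bids within ``tolerance`` of the bid space
    are one-to-one matched per neuron and session and the response
    differences (higher minus lower magnitude, z units) pooled across all
    neurons. The test statistic is a two-sided sign-rank over the
    *per-neuron mean* differences, so the neuron is the unit of analysis
    (individual matches within a neuron share the same cells and sessions
    and are not independent). A comparison whose matched bid values differ
    significantly between the two magnitude groups (rank-sum, p < alpha) is
    eliminated before testing; the surviving comparisons are Holm-corrected
    as a family of three.
    """
    out = []
    for lo, hi in _MAG_PAIRS:
        per_neuron: dict = {}
        n_matches = 0
        blo_all: list[float] = []
        bhi_all: list[float] = []
        for (nid, _), grp in responses.groupby(["neuron_id", "session_id"]):
            g_lo = grp[grp["magnitude_level"] == lo]
            g_hi = grp[grp["magnitude_level"] == hi]
            if g_lo.empty or g_hi.empty:
                continue
            pairs = _greedy_match(
                g_lo["bid"].to_numpy(), g_hi["bid"].to_numpy(), tolerance
            )
            z_lo = g_lo["z"].to_numpy()
            z_hi = g_hi["z"].to_numpy()
            b_lo = g_lo["bid"].to_numpy()
            b_hi = g_hi["bid"].to_numpy()
            for i, j in pairs:
                per_neuron.setdefault(nid, []).append(z_hi[j] - z_lo[i])
                blo_all.append(b_lo[i])
                bhi_all.append(b_hi[j])
                n_matches += 1

        pair_name = f"{lo}-vs-{hi}"
        if n_matches < min_pairs or len(per_neuron) < min_neurons:
            warnings.warn(
                f"{pair_name}: {n_matches} matches over {len(per_neuron)} neurons; skipped"
            )
            out.append(
                MatchedBidComparison(
                    pair_name, n_matches, len(per_neuron), np.nan, np.nan, np.nan,
                    False, np.nan,
                )
            )
            continue
        mean_diff = float(np.mean([d for v in per_neuron.values() for d in v]))
        dist_p = float(stats.mannwhitneyu(blo_all, bhi_all, alternative="two-sided").pvalue)
        if dist_p < alpha:
            out.append(
                MatchedBidComparison(
                    pair_name, n_matches, len(per_neuron), mean_diff, np.nan, np.nan,
                    True, dist_p,
                )
            )
            continue
        d = np.asarray([np.mean(v) for v in per_neuron.values()])
        p = 1.0 if np.allclose(d, 0) else float(stats.wilcoxon(d).pvalue)
        out.append(
            MatchedBidComparison(
                pair_name, n_matches, len(d), mean_diff, p, np.nan, False, dist_p
            )
        )

    tested = [c for c in out if not c.eliminated and not np.isnan(c.p)]
    if tested:
        adj = multipletests([c.p for c in tested], alpha=alpha, method="holm")[1]
        for c, pc in zip(tested, adj):
            c.p_corrected = float(pc)
    return out


def movement_control_regressions(
    responses: pd.DataFrame,
    covariates: tuple[str, ...] = ("velocity", "abs_velocity", "absement", "abs_absement"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count neurons whose responses track movement covariates.

    For each covariate, runs the same simple linear regression used for
    bids and counts neurons with p < alpha, then tests that count against
    the 5% chance level with a one-sided binomial test.
    """
    rows = []
    n_neurons = responses["neuron_id"].nunique()
    for cov in covariates:
        n_sig = 0
        for _, sub in responses.groupby("neuron_id"):
            x = sub[cov].to_numpy(float)
            if np.ptp(x) == 0 or len(x) < 10:
                continue
            if stats.linregress(x, sub["z"].to_numpy(float)).pvalue < alpha:
                n_sig += 1
        binom_p = (
            stats.binomtest(n_sig, n_neurons, alpha, alternative="greater").pvalue
            if n_neurons
            else np.nan
        )
        rows.append(
            {
                "covariate": cov,
                "n_significant": n_sig,
                "n_neurons": n_neurons,
                "chance_level": alpha,
                "exceeds_chance_p": binom_p,
            }
        )
    return pd.DataFrame(rows)
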