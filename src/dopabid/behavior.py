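"""Behavioral value pipeline for BDM bidding data.

Covers four stages:

1. :func:`build_regressors` — the 31 candidate trial-history variables
   (reward value, starting bid, satiety, calendar terms, competing-bid lags
   and running means, win/lose streaks).
2. :func:`lasso_select` — cross-validated lasso with the one-standard-error
   rule for choosing the regularization strength.
3. :func:`fit_mixed_model` — the three mixed-effects bid models: the full
   model with reward magnitude as a fixed effect, the reduced model with
   magnitude moved to the random effects, and the streak model with the
   previous result moved to the random effects.
4. :func:`rank_order_check` / :func:`bid_coherence` — rank correlation of
   bids with juice volume, and rank coherence of interpolated per-magnitude
   bid series within and between sessions.

Lagged variables that are undefined early in a session are set to NaN and
those trials are dropped listwise from fits, never imputed. Streaks and lags
never cross session boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
import statsmodels.formula.api as smf

__all__ = [
    "REGRESSOR_COLUMNS",
    "build_regressors",
    "LassoSelection",
    "lasso_select",
    "MixedModelResult",
    "fit_mixed_model",
    "RankOrderResult",
    "rank_order_check",
    "CoherenceResult",
    "bid_coherence",
]

_PLAIN_LAGS = (1, 2, 3, 5, 7)
_SAME_MAG_LAGS = tuple(range(1, 11))
_RUNNING_MEANS = tuple(range(2, 7))

REGRESSOR_COLUMNS = (
    [
        "reward_value",
        "starting_bid",
        "prev_total_liquid",
        "day_of_week",
        "session_number",
        "prev_trial_failure",
        "prev_trial_result",
        "prev_result_same_mag",
        "trial_number",
    ]
    + [f"comp_bid_lag_{k}" for k in _PLAIN_LAGS]
    + [f"comp_bid_same_mag_lag_{k}" for k in _SAME_MAG_LAGS]
    + [f"comp_bid_same_mag_mean_{m}" for m in _RUNNING_MEANS]
    + ["win_streak", "lose_streak"]
)


def build_regressors(trials: pd.DataFrame) -> pd.DataFrame:
    """Build the candidate regressor matrix, one row per completed trial.

    History (lags, streaks, previous results) is accumulated within each
    session in trial order; competing-bid lags count back over *completed*
    trials only, since no computer bid is revealed on failed trials. Rows
    for failed trials are excluded from the output, but failed trials still
    feed the ``prev_trial_failure`` indicator. Undefined lags are NaN.
    """
    out_rows = []
    for session_id, sess in trials.groupby("session_id", sort=True):
        sess = sess.sort_values("trial_index")
        comp_hist: list[float] = []  # completed-trial computer bids, any magnitude
        mag_hist: dict[str, list[float]] = {}
        prev_result: float = np.nan  # 1 win / 0 lose, any magnitude
        prev_result_mag: dict[str, float] = {}
        prev_failed: float = np.nan
        for _, tr in sess.iterrows():
            level = tr["magnitude_level"]
            if tr["result"] != "failed":
                row = {
                    "subject": tr["subject"],
                    "session_id": session_id,
                    "trial_index": tr["trial_index"],
                    "magnitude_level": level,
                    "bid": tr["bid"],
                    "reward_value": tr["magnitude_ml"],
                    "starting_bid": tr["starting_bid"],
                    "prev_total_liquid": tr["cumulative_liquid_ml"],
                    "day_of_week": tr["day_of_week"],
                    "session_number": session_id,
                    "prev_trial_failure": prev_failed,
                    "prev_trial_result": prev_result,
                    "prev_result_same_mag": prev_result_mag.get(level, np.nan),
                    "trial_number": tr["trial_index"],
                    "win_streak": tr["win_streak"],
                    "lose_streak": tr["lose_streak"],
                }
                for k in _PLAIN_LAGS:
                    row[f"comp_bid_lag_{k}"] = comp_hist[-k] if len(comp_hist) >= k else np.nan
                hist = mag_hist.get(level, [])
                for k in _SAME_MAG_LAGS:
                    row[f"comp_bid_same_mag_lag_{k}"] = hist[-k] if len(hist) >= k else np.nan
                for m in _RUNNING_MEANS:
                    row[f"comp_bid_same_mag_mean_{m}"] = (
                        float(np.mean(hist[-m:])) if len(hist) >= m else np.nan
                    )
                out_rows.append(row)

            # update history with the current trial
            if tr["result"] == "failed":
                prev_failed = 1.0
            else:
                prev_failed = 0.0
                prev_result = 1.0 if tr["result"] == "win" else 0.0
                prev_result_mag[level] = prev_result
                comp_hist.append(tr["computer_bid"])
                mag_hist.setdefault(level, []).append(tr["computer_bid"])

    meta = ["subject", "session_id", "trial_index", "magnitude_level", "bid"]
    return pd.DataFrame(out_rows, columns=meta + REGRESSOR_COLUMNS)


@dataclass
class LassoSelection:
    """Result of cross-validated lasso selection with the 1-SE rule."""

    selected: list[str]
    alpha_min: float
    alpha_1se: float
    alphas: np.ndarray
    cv_mse: np.ndarray
    cv_se: np.ndarray
    coefs: pd.Series
    dropped_constant: list[str] = field(default_factory=list)
    n_used: int = 0


def _expand_design(X: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode day of week; everything else stays numeric."""
    X = X.copy()
    if "day_of_week" in X.columns:
        dummies = pd.get_dummies(X["day_of_week"].astype(int), prefix="day_of_week", dtype=float)
        X = pd.concat([X.drop(columns="day_of_week"), dummies.iloc[:, 1:]], axis=1)
    return X


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_folds: int = 20,
    seed: int = 0,
    n_alphas: int = 60,
) -> LassoSelection:
    """Lasso variable selection at the one-standard-error lambda.

    Columns are z-standardized; rows with any missing regressor are dropped;
    constant columns are removed with a warning. The CV curve is computed on
    a log-spaced alpha grid below the smallest alpha that zeroes every
    coefficient; ``alpha_1se`` is the largest alpha whose mean CV MSE is
    within one standard error of the minimum. Deterministic under fixed
    ``seed`` and fold count.
    """
    cols = [c for c in REGRESSOR_COLUMNS if c in X.columns] or list(X.columns)
    Xd = _expand_design(X[cols])
    mask = Xd.notna().all(axis=1) & pd.Series(np.asarray(y), index=Xd.index).notna()
    Xd = Xd.loc[mask]
    yv = np.asarray(y, dtype=float)[np.asarray(mask)]

    dropped = [c for c in Xd.columns if Xd[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant regressors: {dropped}")
        Xd = Xd.drop(columns=dropped)

    Z = (Xd - Xd.mean()) / Xd.std(ddof=0)
    Zv = Z.to_numpy(float)
    yc = yv - yv.mean()

    alpha_max = np.max(np.abs(Zv.T @ yc)) / len(yc)
    alphas = np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-4), n_alphas)

    n_folds_eff = min(n_folds, len(yc))
    kf = KFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    fold_mse = np.empty((n_folds_eff, len(alphas)))
    with warnings.catch_warnings():
        # near-zero alphas at the bottom of the path may stop at max_iter;
        # they only shape the CV curve far from the 1-SE point
        warnings.simplefilter("ignore")
        for f, (tr, te) in enumerate(kf.split(Zv)):
            for a, alpha in enumerate(alphas):
                model = Lasso(alpha=alpha, max_iter=20000)
                model.fit(Zv[tr], yc[tr])
                fold_mse[f, a] = np.mean((yc[te] - model.predict(Zv[te])) ** 2)
    cv_mse = fold_mse.mean(axis=0)
    cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(n_folds_eff)

    i_min = int(np.argmin(cv_mse))
    threshold = cv_mse[i_min] + cv_se[i_min]
    # alphas are descending: the 1-SE alpha is the first (largest) one under
    # the threshold.
    i_1se = int(np.argmax(cv_mse <= threshold))
    alpha_1se = float(alphas[i_1se])

    final = Lasso(alpha=alpha_1se, max_iter=10000)
    final.fit(Zv, yc)
    coefs = pd.Series(final.coef_, index=Z.columns)
    selected_cols = list(coefs.index[coefs != 0.0])
    # collapse one-hot day-of-week dummies back onto the original variable
    selected = sorted(
        {("day_of_week" if c.startswith("day_of_week_") else c) for c in selected_cols}
    )
    return LassoSelection(
        selected=selected,
        alpha_min=float(alphas[i_min]),
        alpha_1se=alpha_1se,
        alphas=alphas,
        cv_mse=cv_mse,
        cv_se=cv_se,
        coefs=coefs,
        dropped_constant=dropped,
        n_used=len(yc),
    )


@dataclass
class MixedModelResult:
    """Fixed effects with CIs/p-values plus fit diagnostics."""

    model_id: int
    fixed_effects: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high, p
    adjusted_r2: float
    converged: bool
    n_obs: int
    random_structure: str


_FIXED_TERMS = {
    1: [
        "reward_value",
        "starting_bid",
        "prev_total_liquid",
        "comp_bid_same_mag_lag_1",
        "prev_result_same_mag",
    ],
    2: [
        "starting_bid",
        "prev_total_liquid",
        "comp_bid_same_mag_lag_1",
        "prev_result_same_mag",
    ],
    3: [
        "starting_bid",
        "prev_total_liquid",
        "comp_bid_same_mag_lag_1",
        "win_streak",
        "lose_streak",
    ],
}


def fit_mixed_model(trials: pd.DataFrame, model_id: int) -> MixedModelResult:
    """Fit one of the three mixed-effects bid models.

    Model 1 keeps reward magnitude as a fixed effect; model 2 moves it to
    the random effects; model 3 additionally moves the previous result to
    the random effects and adds win/lose streak fixed effects. All models
    carry a per-session random intercept and a per-session random trial-
    number slope, which is how trial progression and between-day variability
    are absorbed without entering the fixed effects. ``trials`` may be a raw
    trial table (regressors are then built first) or an existing regressor
    matrix.
    """
    if model_id not in _FIXED_TERMS:
        raise ValueError(f"model_id must be 1, 2 or 3, got {model_id}")
    reg = trials if "comp_bid_same_mag_lag_1" in trials.columns else build_regressors(trials)

    terms = _FIXED_TERMS[model_id]
    needed = terms + ["bid", "session_id", "trial_number", "magnitude_level"]
    if model_id == 3:
        needed.append("prev_result_same_mag")
    df = reg[list(dict.fromkeys(needed))].dropna().copy()
    # z-scale continuous predictors so coefficients are comparable and the
    # optimizer is well conditioned
    for c in terms:
        sd = df[c].std(ddof=0)
        if sd > 0:
            df[c] = (df[c] - df[c].mean()) / sd
    df["trial_number_z"] = (df["trial_number"] - df["trial_number"].mean()) / max(
        df["trial_number"].std(ddof=0), 1e-12
    )

    formula = "bid ~ " + " + ".join(terms)
    vc: dict[str, str] = {}
    if model_id in (2, 3):
        vc["magnitude"] = "0 + C(magnitude_level)"
    if model_id == 3:
        vc["prev_result"] = "0 + C(prev_result_same_mag)"
    re_formula = "1 + trial_number_z"
    random_desc = "session intercept + session trial slope" + (
        "; vc: " + ", ".join(vc) if vc else ""
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            df,
            groups=df["session_id"],
            re_formula=re_formula,
            vc_formula=vc or None,
        )
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception as e:  # noqa: BLE001 - surfaced, not swallowed
            raise RuntimeError(f"mixed model {model_id} failed to fit: {e}") from e

    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn(f"mixed model {model_id} did not converge; estimates are provisional")

    fe_names = [t for t in res.fe_params.index]
    ci = res.conf_int().loc[fe_names]
    fixed = pd.DataFrame(
        {
            "coef": res.fe_params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": res.pvalues.loc[fe_names],
        }
    )

    fitted = np.asarray(res.fittedvalues)
    yv = df["bid"].to_numpy(float)
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    k = len(fe_names) - 1
    adj = 1.0 - (1.0 - r2) * (len(yv) - 1) / max(len(yv) - k - 1, 1)

    return MixedModelResult(
        model_id=model_id,
        fixed_effects=fixed,
        adjusted_r2=float(adj),
        converged=converged,
        n_obs=len(df),
        random_structure=random_desc,
    )


@dataclass
class RankOrderResult:
    rho: float
    p: float
    per_session: pd.DataFrame  # session_id, rho, p, n
    fraction_significant: float


def rank_order_check(trials: pd.DataFrame, alpha: float = 0.05) -> RankOrderResult:
    """Spearman rank correlation of bids with juice volume.

    Computed pooled over all completed trials and per session; sessions with
    a single magnitude level are excluded with a warning.
    """
    ok = trials[trials["result"] != "failed"]
    if ok["magnitude_ml"].nunique() < 2:
        raise ValueError("rank-order check needs at least two magnitude levels")
    rho, p = stats.spearmanr(ok["bid"], ok["magnitude_ml"])

    rows = []
    for sid, sess in ok.groupby("session_id"):
        if sess["magnitude_ml"].nunique() < 2:
            warnings.warn(f"session {sid} has a single magnitude level; excluded")
            continue
        r, pv = stats.spearmanr(sess["bid"], sess["magnitude_ml"])
        rows.append({"session_id": sid, "rho": r, "p": pv, "n": len(sess)})
    per = pd.DataFrame(rows, columns=["session_id", "rho", "p", "n"])
    frac = float((per["p"] < alpha).mean()) if len(per) else np.nan
    return RankOrderResult(rho=float(rho), p=float(p), per_session=per, fraction_significant=frac)


_PAIRINGS = (("low", "mid"), ("mid", "high"), ("low", "high"))


@dataclass
class CoherenceResult:
    """Within- and between-session rank coherence of per-magnitude bids."""

    within: pd.DataFrame  # session_id, pairing, rho, p
    summary: dict  # pairing -> {"rho_median", "p"}
    between: dict  # pairing -> {"rho", "p"}
    skipped_sessions: list


def bid_coherence(trials: pd.DataFrame, min_per_magnitude: int = 5) -> CoherenceResult:
    """Rank coherence of bid fluctuations across reward magnitudes.

    Within each session, bids for each magnitude are linearly interpolated
    onto the full trial-index grid to form three equally populated series,
    which are then Spearman-correlated pairwise. Because interpolation fills
    trials where a magnitude was absent, the values are a lower bound on the
    true coherence. Between-session coherence correlates session-mean bids
    per magnitude across sessions.
    """
    ok = trials[trials["result"] != "failed"]
    rows, skipped = [], []
    for sid, sess in ok.groupby("session_id"):
        counts = sess.groupby("magnitude_level")["bid"].size()
        if any(counts.get(lvl, 0) < min_per_magnitude for lvl in ("low", "mid", "high")):
            skipped.append(sid)
            continue
        grid = sess["trial_index"].to_numpy(float)
        series = {}
        for lvl in ("low", "mid", "high"):
            sub = sess[sess["magnitude_level"] == lvl]
            series[lvl] = np.interp(grid, sub["trial_index"].to_numpy(float), sub["bid"].to_numpy(float))
        for a, b in _PAIRINGS:
            rho, p = stats.spearmanr(series[a], series[b])
            rows.append({"session_id": sid, "pairing": f"{a}:{b}", "rho": rho, "p": p})
    within = pd.DataFrame(rows, columns=["session_id", "pairing", "rho", "p"])

    summary = {}
    for a, b in _PAIRINGS:
        key = f"{a}:{b}"
        sub = within[within["pairing"] == key]["rho"].dropna()
        if len(sub) == 0:
            summary[key] = {"rho_median": np.nan, "p": np.nan}
        else:
            p = stats.wilcoxon(sub).pvalue if len(sub) >= 5 and sub.abs().sum() > 0 else np.nan
            summary[key] = {"rho_median": float(sub.median()), "p": float(p) if p == p else np.nan}

    session_means = ok.pivot_table(index="session_id", columns="magnitude_level", values="bid")
    between = {}
    for a, b in _PAIRINGS:
        key = f"{a}:{b}"
        if (
            a in session_means.columns
            and b in session_means.columns
            and session_means[[a, b]].dropna().shape[0] >= 3
        ):
            sub = session_means[[a, b]].dropna()
            rho, p = stats.spearmanr(sub[a], sub[b])
            between[key] = {"rho": float(rho), "p": float(p)}
        else:
            between[key] = {"rho": np.nan, "p": np.nan}

    return CoherenceResult(within=within, summary=summary, between=between, skipped_sessions=skipped)
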