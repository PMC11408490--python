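"""End-to-end orchestration: generate -> behavior -> neural -> decode -> report.

Every stochastic stage receives its own seed derived from a single master
seed, so a full run is deterministic and the JSON report is reproducible
byte for byte. Stage outputs are written as TSV/JSON files under the run
directory and summarized in ``report.json``; a ``run_manifest.json`` records
seeds and software versions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from dopabid import behavior, decoding, neural, synth

log = logging.getLogger("dopabid.pipeline")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_dataset"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    The default profile is a reduced "smoke" setting (30 decoding
    iterations); pass ``n_iterations=300`` for full-scale decoding curves.
    """

    out_dir: str = "runs/demo"
    master_seed: int = 0
    subject: str = "V"
    n_sessions: int = 6
    trials_per_session: int = 400
    n_bid_neurons: int = 12
    n_magnitude_neurons: int = 4
    n_noncoding_neurons: int = 4
    run_behavior: bool = True
    run_lasso: bool = False  # slow relative to the rest; opt in
    run_neural: bool = True
    run_decode: bool = True
    lasso_folds: int = 20
    window_override: tuple[int, int] | None = None
    n_iterations: int = 30
    neuron_counts: tuple[int, ...] = (1, 2, 5, 10, 12)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        if cfg.window_override is not None:
            cfg.window_override = tuple(cfg.window_override)
        cfg.neuron_counts = tuple(cfg.neuron_counts)
        return cfg


def _subject_config(cfg: RunConfig) -> synth.SubjectConfig:
    base = synth.MONKEY_V if cfg.subject.upper() == "V" else synth.MONKEY_U
    return synth.SubjectConfig(
        name=base.name,
        magnitudes=base.magnitudes,
        budget=base.budget,
        n_sessions=cfg.n_sessions,
        trials_per_session=cfg.trials_per_session,
        agent=base.agent,
    )


def load_dataset(data_dir: str | Path, subject: str):
    """Load a generated dataset: trial table plus neuron populations."""
    data_dir = Path(data_dir)
    trials = pd.read_csv(data_dir / f"trials_{subject}.tsv", sep="\t")
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    population = []
    for params in manifest["subjects"][subject]["neurons"]:
        model = synth.NeuronModel(**params)
        path = data_dir / f"raster_{subject}_{model.neuron_id}.tsv"
        frame = pd.read_csv(path, sep="\t")
        population.append((model, synth.raster_from_frame(frame, model.neuron_id)))
    return trials, population


def _to_native(obj):
    if isinstance(obj, dict):
        return {str(k): _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _behavior_stage(trials: pd.DataFrame, cfg: RunConfig, rng: np.random.Generator) -> dict:
    out: dict = {}
    rank = behavior.rank_order_check(trials)
    out["rank_order"] = {
        "rho": rank.rho,
        "p": rank.p,
        "fraction_significant_sessions": rank.fraction_significant,
    }
    coh = behavior.bid_coherence(trials)
    out["coherence"] = {"within_summary": coh.summary, "between": coh.between}

    reg = behavior.build_regressors(trials)
    if cfg.run_lasso:
        sel = behavior.lasso_select(
            reg, reg["bid"], n_folds=cfg.lasso_folds, seed=int(rng.integers(2**31))
        )
        out["lasso"] = {
            "selected": sel.selected,
            "alpha_min": sel.alpha_min,
            "alpha_1se": sel.alpha_1se,
            "n_used": sel.n_used,
        }
    models = {}
    for mid in (1, 2, 3):
        res = behavior.fit_mixed_model(reg, mid)
        models[f"model_{mid}"] = {
            "fixed_effects": res.fixed_effects.round(6).to_dict(orient="index"),
            "adjusted_r2": res.adjusted_r2,
            "converged": res.converged,
            "n_obs": res.n_obs,
            "random_structure": res.random_structure,
        }
    out["mixed_models"] = models
    return out


def _neural_stage(trials, population, cfg: RunConfig) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    out: dict = {}
    classes = {
        model.neuron_id: neural.classify_dopamine(raster, model.waveform_width_ms)
        for model, raster in population
    }
    out["classification"] = {
        "n_dopamine": sum(v == "dopamine" for v in classes.values()),
        "n_non_dopamine": sum(v == "non_dopamine" for v in classes.values()),
    }

    if cfg.window_override is not None:
        window = neural.AnalysisWindow(*cfg.window_override)
        out["window"] = {"status": "override", "start_ms": window.start_ms, "end_ms": window.end_ms}
    else:
        det = neural.detect_value_window([r for _, r in population], trials)
        out["window"] = {"status": det.status, "start_ms": det.start_ms, "end_ms": det.end_ms}
        if det.window is None:
            raise RuntimeError(f"value-window detection failed: {det.status}")
        window = det.window

    responses = neural.build_response_table(population, trials, window)
    selected, table = neural.select_bid_encoding(responses)
    out["bid_encoding"] = {"n_selected": len(selected), "n_tested": len(table)}
    out["matched_bid"] = [asdict(c) for c in neural.matched_bid_comparison(responses)]
    out["movement_controls"] = neural.movement_control_regressions(responses).to_dict(
        orient="records"
    )
    return out, responses, table


def _decode_stage(responses, reg_table, cfg: RunConfig, rng: np.random.Generator) -> dict:
    pp = decoding.build_pseudopopulation(responses, seed=int(rng.integers(2**31)))
    ranking = (
        reg_table.set_index("neuron_id").reindex(pp.neuron_ids)["r2"].to_numpy()
    )
    counts = [c for c in cfg.neuron_counts if c <= pp.n_neurons] or [pp.n_neurons]
    out: dict = {"n_neurons_available": pp.n_neurons, "excluded": pp.excluded}
    curves = {}
    for ordering in ("best_first", "worst_first", "random"):
        curve = decoding.decoding_curve(
            pp,
            ordering=ordering,
            ranking=ranking,
            neuron_counts=counts,
            n_iterations=cfg.n_iterations,
            seed=int(rng.integers(2**31)),
        )
        curves[ordering] = curve
        out[ordering] = curve.table.round(6).to_dict(orient="records")
    shuf = decoding.shuffled_control(
        pp,
        neuron_counts=[max(counts)],
        n_iterations=cfg.n_iterations,
        seed=int(rng.integers(2**31)),
    )
    out["shuffled"] = shuf.table.round(6).to_dict(orient="records")
    out["real_vs_shuffled_p"] = decoding.compare_real_vs_shuffled(
        curves["random"], shuf, max(counts)
    )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages and write the JSON report."""
    t_all = time.time()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.master_seed)
    report: dict = {"config": _to_native(asdict(cfg)), "timing_s": {}}

    t0 = time.time()
    data_dir = out_dir / "data"
    sub_cfg = _subject_config(cfg)
    n_neurons = cfg.n_bid_neurons + cfg.n_magnitude_neurons + cfg.n_noncoding_neurons
    synth.generate_dataset(
        data_dir,
        subjects=[sub_cfg],
        n_bid_neurons=cfg.n_bid_neurons,
        n_magnitude_neurons=cfg.n_magnitude_neurons,
        n_noncoding_neurons=cfg.n_noncoding_neurons,
        seed=int(rng.integers(2**31)),
    )
    trials, population = load_dataset(data_dir, sub_cfg.name)
    report["timing_s"]["generate"] = round(time.time() - t0, 3)
    log.info("generated %d trials, %d neurons", len(trials), n_neurons)

    if cfg.run_behavior:
        t0 = time.time()
        try:
            report["behavior"] = _behavior_stage(trials, cfg, rng)
        except Exception as e:
            raise RuntimeError(f"behavior stage failed: {e}") from e
        report["timing_s"]["behavior"] = round(time.time() - t0, 3)

    responses = reg_table = None
    if cfg.run_neural:
        if n_neurons == 0:
            report["neural"] = {"skipped": "no neurons configured"}
            log.info("neural stage skipped: zero neurons")
        else:
            t0 = time.time()
            try:
                neural_report, responses, reg_table = _neural_stage(trials, population, cfg)
            except Exception as e:
                raise RuntimeError(f"neural stage failed: {e}") from e
            report["neural"] = neural_report
            responses.to_csv(out_dir / "response_table.tsv", sep="\t", index=False)
            reg_table.to_csv(out_dir / "bid_regressions.tsv", sep="\t", index=False)
            report["timing_s"]["neural"] = round(time.time() - t0, 3)

    if cfg.run_decode:
        if responses is None:
            report["decoding"] = {"skipped": "neural stage did not run"}
            log.info("decoding stage skipped")
        else:
            t0 = time.time()
            try:
                report["decoding"] = _decode_stage(responses, reg_table, cfg, rng)
            except Exception as e:
                raise RuntimeError(f"decoding stage failed: {e}") from e
            report["timing_s"]["decode"] = round(time.time() - t0, 3)

    report["timing_s"]["total"] = round(time.time() - t_all, 3)
    timings = report.pop("timing_s")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_to_native(report), fh, indent=1, sort_keys=True)
    with open(out_dir / "run_log.txt", "w") as fh:
        for stage, secs in timings.items():
            fh.write(f"{stage}\t{secs:.3f}s\n")
    report["timing_s"] = timings

    import dopabid

    manifest = {
        "master_seed": cfg.master_seed,
        "dopabid_version": dopabid.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report


def validate_inputs(trial_path: str | Path, raster_paths: list | None = None) -> dict:
    """Schema and range checks for user-supplied trial/raster tables."""
    report: dict = {"trial_table": str(trial_path), "errors": [], "warnings": []}
    trials = pd.read_csv(trial_path, sep="\t")
    missing = [c for c in synth.TRIAL_COLUMNS if c not in trials.columns]
    optional_missing = [c for c in missing if c in ("latent_value", "velocity", "absement")]
    hard_missing = [c for c in missing if c not in optional_missing]
    if hard_missing:
        report["errors"].append(f"missing trial columns: {hard_missing}")
    if optional_missing:
        report["warnings"].append(f"missing optional columns: {optional_missing}")

    if "bid" in trials.columns:
        bad = trials[(trials["bid"] < 0) | (trials["bid"] > 1)]
        if len(bad):
            report["errors"].append(f"{len(bad)} bids outside [0, 1]")
    if "magnitude_ml" in trials.columns and (trials["magnitude_ml"] <= 0).any():
        report["errors"].append("non-positive reward magnitudes")
    event_cols = ["t_trial_start", "t_fractal", "t_bidspace", "t_bid_stable"]
    if all(c in trials.columns for c in event_cols):
        ev = trials[event_cols].to_numpy(float)
        if (np.diff(ev, axis=1) < 0).any():
            report["errors"].append("event times out of order")

    for path in raster_paths or []:
        frame = pd.read_csv(path, sep="\t")
        for col in ("session_id", "trial_index", "spike_times_ms"):
            if col not in frame.columns:
                report["errors"].append(f"{path}: missing raster column {col}")
    report["ok"] = not report["errors"]
    return report
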