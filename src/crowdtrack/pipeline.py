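"""End-to-end orchestration: simulate -> preprocess -> metrics -> group stats.

Per participant and continuous run, the analysis chain is:

1. signed/absolute report errors per trial;
2. artifact cleaning keyed to the isolated trials of each trend;
3. tracking performance (cosine similarity) per condition;
4. flip-and-average onto the increasing-distance axis and the
   regression-intersection crowding extent;
5. post-jump windows, the exponential recovery fit (with and without
   motor-latency correction) and the sequential-t-test recovery time.

The trial-based session yields Von Mises perceptual errors per distance and
the hinged-line crowding extent. Group statistics mirror the reference
analysis: 2x2 within-subject ANOVAs (flank condition x run) on tracking
performance and recovery rate, paired t-tests and Pearson correlations on
the crowding extents.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Optional

import numpy as np

from . import group_stats, metrics, preprocessing as prep
from .observer import Dataset, ObserverConfig, ParticipantData, generate_dataset
from .paradigm import FLANKED, INCREASING, ISOLATED, ParadigmConfig, \
    distance_trajectory

RESULTS_SCHEMA_VERSION = "1"

WINDOW_SAMPLES = 300
SKIP_SAMPLES = 40


def _condition_cosine(trials) -> float:
    """Pooled cosine similarity over the cleaned frames of one condition."""
    stim, resp = [], []
    for trial, err in trials:
        keep = ~err.deletion_mask
        stim.append(trial.tracking.theta_stimulus_deg[keep])
        resp.append(trial.tracking.theta_response_deg[keep])
    return metrics.cosine_similarity(np.concatenate(stim), np.concatenate(resp))


def analyze_continuous_run(trials, config: ParadigmConfig,
                           refine_extent: bool = True,
                           extent_jump_guard_samples: int = WINDOW_SAMPLES) -> dict:
    """Analyze one continuous block (a list of ContinuousTrial)."""
    errors = [prep.error_series_from_trace(t.tracking) for t in trials]
    cleaned, clean_report = prep.clean_run_trials(errors)
    pairs = list(zip(trials, cleaned))

    out = {"cleaning": clean_report, "tracking_performance": {}, "windows": {}}
    for cond in (ISOLATED, FLANKED):
        cond_pairs = [p for p in pairs if p[0].spec.condition == cond]
        out["tracking_performance"][cond] = _condition_cosine(cond_pairs)

    # crowding extent: flip-and-average, then regress on the increasing axis.
    # Frames inside the post-jump recovery window reflect temporal recovery
    # rather than spatial crowding, so they are excluded from the spatial
    # regression (they remain in the tracking-performance and decay branches).
    dist_axis = distance_trajectory(config, INCREASING)
    guarded = []
    for t, e in pairs:
        guard = np.zeros(e.n_frames, dtype=bool)
        for j in e.jump_indices:
            guard[j: j + extent_jump_guard_samples] = True
        guarded.append((t, prep.apply_deletion_mask(e, guard)))
    avg = {cond: prep.flip_and_average([e for (t, e) in guarded
                                        if t.spec.condition == cond])
           for cond in (FLANKED, ISOLATED)}
    extent = metrics.estimate_extent_continuous(
        avg[FLANKED].abs_error_deg, dist_axis,
        avg[ISOLATED].abs_error_deg, dist_axis,
        config.distance_max_deg, refine=refine_extent)
    out["crowding_extent"] = extent

    # post-jump windows pooled over the run's trials, per condition; the
    # windows come from the *raw* per-trial errors -- artifact cleaning is
    # keyed to exactly the post-jump peaks the recovery analysis needs
    for cond in (ISOLATED, FLANKED):
        mats = [prep.extract_post_jump_windows(e, window_samples=WINDOW_SAMPLES).window_matrix
                for (t, e) in zip(trials, errors)
                if t.spec.condition == cond and e.jump_indices.size > 0]
        out["windows"][cond] = prep.PostJumpWindows(
            np.vstack(mats), WINDOW_SAMPLES, 0, config.dt_s) if mats else None
    return out


def decay_fits_from_windows(windows: prep.PostJumpWindows) -> dict:
    mean = windows.mean_error
    fits = {}
    fits["uncorrected"] = metrics.fit_exponential_decay(mean, windows.dt_s,
                                                        motor_corrected=False)
    fits["corrected"] = metrics.fit_exponential_decay(mean, windows.dt_s,
                                                      motor_corrected=True,
                                                      skip_samples=SKIP_SAMPLES)
    return fits


def analyze_trial_based(reports, config: ParadigmConfig,
                        refine_extent: bool = True) -> dict:
    """Perceptual errors per distance and the hinged-line crowding extent."""
    from .preprocessing import report_error

    flanked_pts = []
    for d in config.trial_based_distances_deg:
        errs = [report_error(r.target_ori_deg, r.report_ori_deg)
                for r in reports if r.condition == FLANKED
                and r.distance_deg is not None and np.isclose(r.distance_deg, d)]
        flanked_pts.append(metrics.perceptual_error_vonmises(errs, distance_deg=float(d)))
    iso_errs = [report_error(r.target_ori_deg, r.report_ori_deg)
                for r in reports if r.condition == ISOLATED]
    baseline = metrics.perceptual_error_vonmises(iso_errs, distance_deg=None)
    extent = metrics.crowding_extent_trial_based(flanked_pts, baseline,
                                                 config.distance_max_deg,
                                                 refine=refine_extent)
    return {"perceptual_errors": flanked_pts, "baseline": baseline,
            "crowding_extent": extent}


def analyze_participant(participant: ParticipantData, config: ParadigmConfig,
                        refine_extent: bool = True) -> dict:
    """Full per-participant results dictionary (schema-versioned)."""
    runs = [analyze_continuous_run(trials, config, refine_extent)
            for trials in participant.continuous_runs]
    tb = analyze_trial_based(participant.trial_based, config, refine_extent)

    res = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "observer_id": participant.observer.observer_id,
        "tracking_performance": {}, "crowding_extent": {},
        "decay": {}, "recovery_time_ms": {}, "cleaning": {},
    }
    for cond in (ISOLATED, FLANKED):
        per_run = [r["tracking_performance"][cond] for r in runs]
        res["tracking_performance"][cond] = {
            **{f"run{i + 1}": v for i, v in enumerate(per_run)},
            "mean": float(np.mean(per_run)),
        }
    ext_runs = [r["crowding_extent"].extent_deg for r in runs]
    res["crowding_extent"] = {
        **{f"continuous_run{i + 1}": v for i, v in enumerate(ext_runs)},
        "continuous_mean": float(np.mean(ext_runs)),
        "trial_based": tb["crowding_extent"].extent_deg,
    }
    res["perceptual_errors"] = {
        "flanked": [(p.distance_deg, p.circular_sd_deg) for p in tb["perceptual_errors"]],
        "isolated": tb["baseline"].circular_sd_deg,
    }
    for cond in (ISOLATED, FLANKED):
        res["decay"][cond] = {}
        pooled_rows = []
        for i, r in enumerate(runs):
            w = r["windows"][cond]
            if w is None:
                res["decay"][cond][f"run{i + 1}"] = None
                continue
            fits = decay_fits_from_windows(w)
            res["decay"][cond][f"run{i + 1}"] = {k: asdict(v) for k, v in fits.items()}
            pooled_rows.append(w.window_matrix)
        if not pooled_rows:
            res["decay"][cond]["pooled"] = None
            res["recovery_time_ms"][cond] = None
            continue
        pooled = prep.PostJumpWindows(np.vstack(pooled_rows), WINDOW_SAMPLES, 0,
                                      config.dt_s)
        res["decay"][cond]["pooled"] = {k: asdict(v)
                                        for k, v in decay_fits_from_windows(pooled).items()}
        rt = metrics.recovery_time(pooled)
        res["recovery_time_ms"][cond] = rt.recovery_ms
    res["cleaning"] = {f"run{i + 1}": r["cleaning"] for i, r in enumerate(runs)}
    return res


def group_report(participant_results: list) -> dict:
    """Group-level statistics across participants, mirroring the study's tests."""
    def collect(path):
        vals = []
        for r in participant_results:
            v = r
            for k in path:
                v = v[k]
            vals.append(v)
        return np.array(vals, dtype=float)

    n_runs = sum(1 for k in participant_results[0]["tracking_performance"][ISOLATED]
                 if k.startswith("run"))
    report = {"schema_version": RESULTS_SCHEMA_VERSION,
              "n_participants": len(participant_results)}

    def anova_2x2(extract):
        # (subject, flank condition, run) table
        table = np.stack([
            np.stack([[extract(r, cond, run) for run in range(1, n_runs + 1)]
                      for cond in (FLANKED, ISOLATED)])
            for r in participant_results])
        res = group_stats.rm_anova_2x2(table)
        return {"flank_condition": asdict(res.factor_a),
                "trial_run": asdict(res.factor_b),
                "interaction": asdict(res.interaction)}

    if len(participant_results) >= 2 and n_runs == 2:
        report["tracking_performance_anova"] = anova_2x2(
            lambda r, cond, run: r["tracking_performance"][cond][f"run{run}"])
        for variant in ("uncorrected", "corrected"):
            report[f"recovery_rate_anova_{variant}"] = anova_2x2(
                lambda r, cond, run, v=variant: r["decay"][cond][f"run{run}"][v]["b_per_s"])
        run1 = collect(["crowding_extent", "continuous_run1"])
        run2 = collect(["crowding_extent", "continuous_run2"])
        report["extent_run1_vs_run2"] = asdict(group_stats.paired_t(run1, run2))

    cont = collect(["crowding_extent", "continuous_mean"])
    tb = collect(["crowding_extent", "trial_based"])
    report["extent_means"] = {"continuous": float(cont.mean()),
                              "trial_based": float(tb.mean())}
    if len(participant_results) >= 2:
        try:
            report["extent_continuous_vs_trial_based"] = asdict(
                group_stats.paired_t(cont, tb))
        except ValueError:
            report["extent_continuous_vs_trial_based"] = None
    if len(participant_results) >= 3:
        try:
            r, p = group_stats.pearson_r(cont, tb)
            report["extent_correlation"] = {"r": r, "p": p}
        except ValueError:
            report["extent_correlation"] = None
    report["recovery_time_ms"] = {}
    for cond in (ISOLATED, FLANKED):
        vals = [r["recovery_time_ms"][cond] for r in participant_results
                if r["recovery_time_ms"][cond] is not None]
        report["recovery_time_ms"][cond] = float(np.mean(vals)) if vals else None
    report["tracking_performance_means"] = {
        cond: float(np.mean(collect(["tracking_performance", cond, "mean"])))
        for cond in (ISOLATED, FLANKED)}
    return report


def analyze_dataset(dataset: Dataset, refine_extent: bool = True) -> dict:
    config = dataset.paradigm_config
    per_participant = [analyze_participant(p, config, refine_extent)
                       for p in dataset.participants]
    return {"participants": per_participant,
            "group": group_report(per_participant)}


def default_observers(n: int = 8, base: Optional[ObserverConfig] = None,
                      seed: int = 0) -> list:
    """n observers sharing the default generative parameters, distinct seeds."""
    base = base or ObserverConfig()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(ObserverConfig(**{**base.__dict__,
                                     "seed": int(rng.integers(0, 2**31 - 1)),
                                     "observer_id": f"obs{i + 1:02d}"}))
    return out


def parameter_recovery(extent_grid, n_observers: int = 8, n_runs: int = 2,
                       seed: int = 0, config: Optional[ParadigmConfig] = None,
                       base_observer: Optional[ObserverConfig] = None) -> list:
    """Simulate + analyze across a grid of true crowding extents.

    Returns one row per grid point with per-method mean estimate, bias and
    RMSE, plus the raw per-observer estimates for downstream correlation
    checks.
    """
    config = config or ParadigmConfig()
    base = base_observer or ObserverConfig()
    rows = []
    for gi, e_c in enumerate(extent_grid):
        observers = default_observers(n_observers,
                                      ObserverConfig(**{**base.__dict__,
                                                        "crowding_extent_deg": float(e_c)}),
                                      seed=seed + 1000 * gi)
        ds = generate_dataset(config, observers, n_runs=n_runs, seed=seed + 1000 * gi)
        results = [analyze_participant(p, config) for p in ds.participants]
        cont = np.array([r["crowding_extent"]["continuous_mean"] for r in results])
        tb = np.array([r["crowding_extent"]["trial_based"] for r in results])
        rows.append({
            "true_extent_deg": float(e_c),
            "continuous": {"mean": float(cont.mean()),
                           "bias": float(cont.mean() - e_c),
                           "rmse": float(np.sqrt(np.mean((cont - e_c) ** 2))),
                           "estimates": cont.tolist()},
            "trial_based": {"mean": float(tb.mean()),
                            "bias": float(tb.mean() - e_c),
                            "rmse": float(np.sqrt(np.mean((tb - e_c) ** 2))),
                            "estimates": tb.tolist()},
        })
    return rows
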