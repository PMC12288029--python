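"""Replicate-level simulation studies over the full pipeline.

These routines run whole synthetic experiments repeatedly to characterise
the analysis: parameter recovery of the GLMM machinery, the power of the
AICc ranking to pick up a turbidity effect on event counts, the calibration
of the null model when no effects exist, and the direction of treatment
effects on the four responses.  They are the computational backbone of the
acceptance checks and the analysis drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from preyflow import detection, models, synthetic

#: default known effect for recovery studies: turbidity halves the expected
#: number of detection events (log scale)
DEFAULT_TRUTH = -0.7


def _default_design(master_seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    meta = synthetic.metadata_frame(synthetic.design_crossover(master_seed=master_seed))
    design, _ = models.build_design(meta)
    return meta, design


def recovery_study(
    n_reps: int = 200,
    truth: float = DEFAULT_TRUTH,
    intercept: float = 3.0,
    nb_size: float = 5.0,
    tank_sd: float = 0.3,
    seed: int = 0,
) -> dict:
    """Fixed-effect recovery for the NB2 event-count GLMM.

    Event counts are simulated directly from the model (91-trial crossover
    design, 4 tanks, known turbidity coefficient ``truth`` on the log
    scale), then refitted; reports the mean estimate across replicates and
    its Monte-Carlo standard error.
    """
    meta, design = _default_design(master_seed=seed)
    turb = design["turb"].to_numpy()
    tank = meta["tank"].to_numpy() - 1
    spec = models.ModelSpec("Turbidity", ("turb",), "negbinom")
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_reps):
        eta = intercept + truth * turb + rng.normal(0.0, tank_sd, 4)[tank]
        y = models.simulate_family_response("negbinom", eta, nb_size, rng)
        fit = models.fit_glmm(y, meta, spec, compute_se=False)
        estimates.append(fit.coefficients["turb"])
    estimates = np.asarray(estimates)
    return {
        "truth": truth,
        "mean_estimate": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def _replicate_event_counts(
    cfg: synthetic.SeriesConfig, master_seed: int, n_frames: int, level: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """One replicate experiment reduced to event counts at one level."""
    trials = synthetic.design_crossover(master_seed=master_seed, n_frames=n_frames)
    series = [
        synthetic.simulate_magnitude_series(cfg, t.treatment, t.n_frames, seed=t.seed)
        for t in trials
    ]
    thresholds = detection.pooled_thresholds(series, percentile_levels=(level,))
    thr = thresholds.threshold_values[0]
    counts = np.array([len(detection.group_events(s > thr)) for s in series], dtype=float)
    return synthetic.metadata_frame(trials), counts


def effect_ranking_study(
    n_reps: int = 200,
    seed: int = 0,
    n_frames: int = 1980,
    level: float = 95,
    series_config: synthetic.SeriesConfig | None = None,
) -> dict:
    """How often the turbidity model out-ranks the null on event counts.

    Each replicate runs the series-tier pipeline end to end (simulate,
    pool, threshold, count events) with the default turbidity effect on the
    visit rate, then compares the AICc of the Turbidity and Null models.
    """
    cfg = series_config or synthetic.SeriesConfig()
    spec_t = models.ModelSpec("Turbidity", ("turb",), "negbinom")
    spec_0 = models.ModelSpec("Null", (), "negbinom")
    wins = 0
    for r in range(n_reps):
        meta, counts = _replicate_event_counts(cfg, seed * 100_003 + r, n_frames, level)
        fit_t = models.fit_glmm(counts, meta, spec_t, compute_se=False)
        fit_0 = models.fit_glmm(counts, meta, spec_0, compute_se=False)
        wins += fit_t.aicc < fit_0.aicc
    return {"n_reps": n_reps, "turbidity_beats_null_fraction": wins / n_reps}


def null_calibration_study(
    n_reps: int = 60,
    seed: int = 0,
    n_frames: int = 1980,
    level: float = 95,
) -> dict:
    """Null-model calibration: with all treatment factors at 1 the null
    model should sit within 2 AICc units of the best model in most
    replicate experiments."""
    cfg = synthetic.SeriesConfig(
        temp_amplitude_factor=1.0, turb_rate_factor=1.0, turb_duration_factor=1.0
    )
    specs = models.build_candidate_set("n_events")
    hits = 0
    for r in range(n_reps):
        meta, counts = _replicate_event_counts(cfg, seed * 200_003 + r, n_frames, level)
        fits = [models.fit_glmm(counts, meta, s, compute_se=False) for s in specs]
        table = models.rank_models(fits).set_index("model")
        hits += table.loc["Null", "delta_aicc"] <= 2.0
    return {"n_reps": n_reps, "null_within_2_fraction": hits / n_reps}


def run_demo_experiment(
    master_seed: int = 0,
    n_frames: int = 19_800,
    series_config: synthetic.SeriesConfig | None = None,
):
    """Full default series-tier experiment: 91 trials, pooled thresholds,
    per-trial metrics and aggregate exceedance totals."""
    trials = synthetic.design_crossover(master_seed=master_seed, n_frames=n_frames)
    cfg = series_config or synthetic.SeriesConfig()
    series = [
        synthetic.simulate_magnitude_series(cfg, t.treatment, t.n_frames, seed=t.seed)
        for t in trials
    ]
    meta = synthetic.metadata_frame(trials)
    thresholds = detection.pooled_thresholds(series)
    metrics = detection.metrics_table(series, thresholds, trial_ids=list(meta["trial_id"]))
    totals = detection.aggregate_exceedance(series, thresholds)
    return meta, series, thresholds, metrics, totals


def treatment_sign_table(meta: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Marginal treatment contrasts per level: turbid vs clear means for
    prop_above / n_events / mean_event_duration, warm vs cool for
    mean_mag_above.  A negative difference means the stressor lowered the
    response."""
    merged = metrics.merge(meta, on="trial_id")
    turbid = merged["turbidity_NTU"] == 5
    warm = merged["temperature_C"] == 29
    rows = []
    for level, grp in merged.groupby("percentile_level"):
        t, w = turbid[grp.index], warm[grp.index]
        rows.append(
            {
                "percentile_level": level,
                "prop_above_turbid_minus_clear": grp["prop_above"][t].mean() - grp["prop_above"][~t].mean(),
                "n_events_turbid_minus_clear": grp["n_events"][t].mean() - grp["n_events"][~t].mean(),
                "duration_turbid_minus_clear": grp["mean_event_duration"][t].mean()
                - grp["mean_event_duration"][~t].mean(),
                "mag_above_warm_minus_cool": grp["mean_mag_above"][w].mean()
                - grp["mean_mag_above"][~w].mean(),
            }
        )
    return pd.DataFrame(rows).sort_values("percentile_level", ascending=False).reset_index(drop=True)
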