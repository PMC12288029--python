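"""Orchestration: simulate -> flow -> detect -> fit as reproducible runs.

Each stage writes its outputs before the next stage reads them, so stages
can be re-run individually; a JSON manifest records the seed, parameters and
a parameter hash.  Series-tier runs are bit-identical across reruns with the
same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from preyflow import detection, flow, models, synthetic
from preyflow.flow import FrameMagnitudeSeries

log = logging.getLogger("preyflow")

STAGES = ("simulate", "flow", "detect", "fit")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    out_dir: str = "runs/demo"
    tier: str = "series"
    master_seed: int = 0
    n_groups: int = 24
    n_exclusions: dict[str, int] = field(
        default_factory=lambda: {"warm": 2, "turbid": 2, "interaction": 1}
    )
    n_frames: int = 19_800
    percentile_levels: tuple[float, ...] = detection.DEFAULT_LEVELS
    percentile_method: str = "linear"
    window_radius: int = flow.DEFAULT_WINDOW_RADIUS
    noise_threshold: float = flow.DEFAULT_NOISE_THRESHOLD
    resize_factor: float = 1.0
    n_quad: int = 15
    compute_se: bool = True  # standard errors via numerical Hessian (slower)
    series: dict = field(default_factory=dict)  # SeriesConfig overrides
    arena: dict = field(default_factory=dict)  # ArenaConfig overrides

    def __post_init__(self) -> None:
        if self.tier not in ("series", "video"):
            raise ValueError("tier must be 'series' or 'video'")
        if not all(0 < lv < 100 for lv in self.percentile_levels):
            raise ValueError("percentile levels must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.percentile_levels = tuple(cfg.percentile_levels)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["percentile_levels"] = list(self.percentile_levels)
        return d

    @property
    def exclusions(self) -> tuple[tuple[str, int], ...]:
        return tuple(self.n_exclusions.items())

    def series_config(self) -> synthetic.SeriesConfig:
        return synthetic.SeriesConfig(**self.series)

    def arena_config(self) -> synthetic.ArenaConfig:
        return synthetic.ArenaConfig(**self.arena)


def _setup_logging(out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)


def stage_simulate(config: RunConfig) -> None:
    """Generate the experiment; write metadata plus series CSVs or frames."""
    out = Path(config.out_dir)
    trials = synthetic.design_crossover(
        n_groups=config.n_groups,
        exclusions=config.exclusions,
        master_seed=config.master_seed,
        n_frames=config.n_frames,
    )
    synthetic.metadata_frame(trials).to_csv(out / "metadata.csv", index=False)
    if config.tier == "series":
        (out / "series").mkdir(exist_ok=True)
        cfg = config.series_config()
        for t in trials:
            values = synthetic.simulate_magnitude_series(cfg, t.treatment, t.n_frames, seed=t.seed)
            flow.write_series_csv(
                FrameMagnitudeSeries(t.trial_id, values, cfg.frame_rate),
                out / "series" / f"{t.trial_id}.csv",
            )
    else:
        (out / "frames").mkdir(exist_ok=True)
        base = config.arena_config()
        for t in trials:
            cfg = dataclasses.replace(base, n_frames=t.n_frames, seed=t.seed)
            frames = synthetic.simulate_trial_video(cfg, t.treatment)
            flow.write_frame_dir(frames, out / "frames" / t.trial_id)
    log.info("simulate: %d trials (%s tier)", len(trials), config.tier)


def stage_flow(config: RunConfig) -> None:
    """Video tier: reduce each trial's frames to a magnitude series CSV."""
    out = Path(config.out_dir)
    if config.tier == "series":
        log.info("flow: series tier, magnitudes already simulated; nothing to do")
        return
    meta = pd.read_csv(out / "metadata.csv")
    (out / "series").mkdir(exist_ok=True)
    for trial_id in meta["trial_id"]:
        frames = flow.read_frame_dir(out / "frames" / trial_id)
        series = flow.magnitude_series(
            frames,
            trial_id=trial_id,
            window_radius=config.window_radius,
            noise_threshold=config.noise_threshold,
            resize_factor=config.resize_factor,
        )
        flow.write_series_csv(series, out / "series" / f"{trial_id}.csv")
    log.info("flow: %d trials reduced to magnitude series", len(meta))


def _load_series(out: Path, meta: pd.DataFrame) -> list[FrameMagnitudeSeries]:
    return [flow.read_series_csv(out / "series" / f"{tid}.csv", trial_id=tid) for tid in meta["trial_id"]]


def stage_detect(config: RunConfig) -> None:
    """Pooled thresholds, per-trial metrics and event tables."""
    out = Path(config.out_dir)
    meta = pd.read_csv(out / "metadata.csv")
    series = _load_series(out, meta)
    thresholds = detection.pooled_thresholds(
        series, config.percentile_levels, method=config.percentile_method
    )
    pd.DataFrame(
        {
            "percentile_level": thresholds.percentile_levels,
            "threshold": thresholds.threshold_values,
            "pooled_n": thresholds.pooled_n,
        }
    ).to_csv(out / "thresholds.csv", index=False)
    metrics = detection.metrics_table(series, thresholds)
    metrics.to_csv(out / "metrics.csv", index=False)
    detection.events_table(series, thresholds).to_csv(out / "events.csv", index=False)
    detection.aggregate_exceedance(series, thresholds).to_csv(
        out / "exceedance_totals.csv", index=False
    )
    n_missing = int(metrics["mean_mag_above"].isna().sum())
    if n_missing:
        log.warning("detect: %d trial x level rows have no frames above threshold", n_missing)
    log.info("detect: pooled_n=%d, %d metric rows", thresholds.pooled_n, len(metrics))


def stage_fit(config: RunConfig) -> None:
    """Fit the 8 candidate GLMMs per response x level; write ranking tables."""
    out = Path(config.out_dir)
    meta = pd.read_csv(out / "metadata.csv")
    metrics = pd.read_csv(out / "metrics.csv")
    (out / "rankings").mkdir(exist_ok=True)
    meta_indexed = meta.set_index("trial_id")
    coef_rows = []
    for level in config.percentile_levels:
        sub = metrics[metrics["percentile_level"] == level]
        trial_meta = meta_indexed.loc[sub["trial_id"]].reset_index()
        for kind in models.RESPONSE_KINDS:
            y = sub[models.RESPONSE_COLUMN[kind]].to_numpy(dtype=float)
            fits = []
            for spec in models.build_candidate_set(kind):
                try:
                    fit = models.fit_glmm(
                        y, trial_meta, spec, n_quad=config.n_quad,
                        seed=config.master_seed, compute_se=config.compute_se,
                    )
                except ValueError as exc:
                    log.warning("fit: %s / p%s / %s skipped (%s)", kind, level, spec.name, exc)
                    continue
                if not fit.converged:
                    log.warning("fit: %s / p%s / %s did not converge", kind, level, spec.name)
                fits.append(fit)
                for term, est in fit.coefficients.items():
                    coef_rows.append(
                        {
                            "response": kind,
                            "percentile_level": level,
                            "model": spec.name,
                            "term": term,
                            "estimate": est,
                            "se": fit.se.get(term, float("nan")),
                            "dispersion": fit.dispersion,
                            "re_sd": fit.re_sd,
                            "n": fit.n,
                            "converged": fit.converged,
                        }
                    )
            try:
                table = models.rank_models(fits)
            except ValueError as exc:
                log.warning("fit: ranking skipped for %s / p%s (%s)", kind, level, exc)
                continue
            table.to_csv(out / "rankings" / f"{kind}_p{level:g}.csv", index=False)
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    log.info("fit: ranking tables written to %s", out / "rankings")


def write_manifest(config: RunConfig, stages: tuple[str, ...]) -> None:
    out = Path(config.out_dir)
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "stages": list(stages),
        "master_seed": config.master_seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the selected stages in order; returns the output directory."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(config.out_dir)
    _setup_logging(out)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        try:
            {"simulate": stage_simulate, "flow": stage_flow, "detect": stage_detect, "fit": stage_fit}[
                stage
            ](config)
        except Exception:
            log.error("stage %r failed; downstream stages not run", stage)
            raise
    write_manifest(config, tuple(ordered))
    return out
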