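"""One-command orchestration of the full analysis.

Stage order: (simulate or load) -> day filtering -> QC/missingness report ->
imputation -> daily cosinor fits -> weekly participant averages -> weekly
population rhythms with CI bands -> between-participant SDs -> early/late
comparison -> age correlation -> leave-one-out sensitivity.  Every artifact
is written as CSV/JSON together with a manifest holding per-file content
hashes; with a deterministic imputation method the whole run is reproducible
byte-for-byte from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imputation, inference, io_model, population, synthetic

logger = logging.getLogger("circarhythm")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``input_path`` (a sample CSV) or ``simulate=True`` (synthetic
    cohorts for ``metrics``) must be set.  ``imputation_method`` is one of
    ``lstm``, ``slot_mean``, ``linear_interp`` or ``none``.
    """

    output_dir: str = "circarhythm_out"
    input_path: str | None = None
    simulate: bool = True
    metrics: tuple[str, ...] = ("HR", "RMSSD")
    n_participants: int | None = None
    missing_rate: float | None = None
    week_range: tuple[int, int] | None = None
    imputation_method: str = "lstm"
    n_components: int | str = 1
    alpha: float = 0.05
    early_weeks: tuple[int, int] = (14, 20)
    late_weeks: tuple[int, int] = (34, 40)
    min_distinct_hours: int = 7
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate and self.input_path is None:
            raise ValueError("either simulate=True or input_path is required")
        if self.imputation_method not in ("lstm", "slot_mean", "linear_interp", "none"):
            raise ValueError(f"unknown imputation method {self.imputation_method!r}")
        if self.week_range is not None and self.week_range[0] > self.week_range[1]:
            raise ValueError("empty week range")
        if not 1 <= self.min_distinct_hours <= 12:
            raise ValueError("min_distinct_hours must be in 1..12")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("metrics", "week_range", "early_weeks", "late_weeks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _simulated_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    frames, truths = [], []
    for i, metric in enumerate(config.metrics):
        cohort_cfg = synthetic.default_config(metric, seed=config.seed + i)
        if config.n_participants is not None:
            cohort_cfg = cohort_cfg.with_(n_participants=config.n_participants)
        if config.week_range is not None:
            cohort_cfg = cohort_cfg.with_(week_start=config.week_range[0], week_end=config.week_range[1])
        if config.missing_rate is not None:
            cohort_cfg = cohort_cfg.with_(missing_rate=config.missing_rate)
        samples, truth = synthetic.generate_cohort(cohort_cfg)
        samples = synthetic.apply_missingness(samples, cohort_cfg.missing_rate, seed=config.seed + 1000 + i)
        truth["metric"] = metric
        frames.append(samples)
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), pd.concat(truths, ignore_index=True)


def _impute(samples: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    method = config.imputation_method
    if method == "none":
        return samples, {"method": method}
    if method in ("slot_mean", "linear_interp"):
        return imputation.baseline_impute(samples, method), {"method": method}
    info: dict = {"method": "lstm", "per_metric": {}}
    out = samples
    for metric in sorted(samples["metric"].unique()):
        sub = out[out["metric"] == metric]
        pairs = imputation.build_sequences(sub)
        train_pairs, test_pairs = imputation.user_level_split(pairs, seed=config.seed)
        model = imputation.train_imputer(train_pairs, seed=config.seed)
        out, report = imputation.impute(model, out)
        X_test, y_test = imputation.pair_matrix(test_pairs)
        rmse = float(np.sqrt(np.mean((model.predict(X_test) - y_test) ** 2))) if len(y_test) else float("nan")
        info["per_metric"][metric] = {
            "n_pairs": len(pairs),
            "test_rmse": rmse,
            "n_imputed": report.n_imputed,
            "n_unimputable": report.n_unimputable,
        }
    return out, info


def _weekly_frame(analysis: dict) -> pd.DataFrame:
    rows = []
    for (metric, week), pop in sorted(analysis["population"].items()):
        rows.append(
            {
                "metric": metric,
                "gestational_week": week,
                "k": pop.k,
                "mesor": pop.mesor,
                "amplitude": pop.amplitude,
                "acrophase_rad": pop.acrophase,
                "peak_hour": pop.peak_hour,
                "p_value": pop.p_pooled,
                "p_population": pop.p_population,
                "residual_se": pop.residual_se,
            }
        )
    return pd.DataFrame(rows)


def _sd_frame(analysis: dict) -> pd.DataFrame:
    rows = []
    for (metric, week), rhythms in sorted(analysis["participant_rhythms"].items()):
        if len(rhythms) < 2:
            continue
        sds = population.interindividual_sd(rhythms)
        rows.append({"metric": metric, "gestational_week": week, **sds})
    return pd.DataFrame(rows)


def _curves_frame(analysis: dict) -> pd.DataFrame:
    rows = []
    for (metric, week), pop in sorted(analysis["population"].items()):
        for h, m, lo, hi in zip(pop.grid_hours, pop.mean_curve, pop.ci_low, pop.ci_high):
            rows.append(
                {
                    "metric": metric,
                    "gestational_week": week,
                    "hour": h,
                    "mean": m,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def _loocv_frame(analysis: dict) -> pd.DataFrame:
    rows = []
    for (metric, week), summary in sorted(analysis.get("loocv", {}).items()):
        for parameter in ("mesor", "amplitude", "peak_hour"):
            rows.append(
                {
                    "metric": metric,
                    "gestational_week": week,
                    "parameter": parameter,
                    "k": summary.k,
                    "mean": summary.mean[parameter],
                    "sd": summary.sd[parameter],
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts; returns the manifest dict."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("load")
    if config.simulate:
        samples, truth = _simulated_cohort(config)
        truth.to_csv(out_dir / "truth.csv", index=False)
    else:
        samples = io_model.read_samples(config.input_path)
        truth = None
    io_model.write_samples(samples, out_dir / "samples.csv")
    done("load")

    stage("filter")
    filtered, profiles = io_model.filter_days(samples, config.min_distinct_hours)
    qc_rows = []
    for metric in sorted(filtered["metric"].unique()):
        sub_all = samples[samples["metric"] == metric]
        sub_filt, sub_prof = io_model.filter_days(sub_all, config.min_distinct_hours)
        stats_m = io_model.missingness_report(sub_filt, sub_prof)
        qc_rows.append({"metric": metric, **asdict(stats_m)})
        logger.info(
            "metric %s: %d included days, missing rate %.2f%%",
            metric, stats_m.n_days, stats_m.missing_rate_pct,
        )
    pd.DataFrame(qc_rows).to_csv(out_dir / "qc_report.csv", index=False)
    profiles.to_csv(out_dir / "day_profiles.csv", index=False)
    done("filter")

    stage("impute")
    imputed, impute_info = _impute(filtered, config)
    done("impute")

    stage("rhythms")
    analysis = population.analyze_cohort(imputed, n_components=config.n_components, alpha=config.alpha)
    _weekly_frame(analysis).to_csv(out_dir / "weekly_rhythms.csv", index=False)
    _sd_frame(analysis).to_csv(out_dir / "interindividual_sd.csv", index=False)
    _curves_frame(analysis).to_csv(out_dir / "curves.csv", index=False)
    _loocv_frame(analysis).to_csv(out_dir / "loocv.csv", index=False)
    done("rhythms")

    stage("inference")
    rhythm_table = population.participant_rhythms_frame(analysis["participant_rhythms"])
    try:
        comparisons = inference.early_late_comparison(
            rhythm_table, config.early_weeks, config.late_weeks
        )
        pd.DataFrame([asdict(c) for c in comparisons]).to_csv(out_dir / "comparison.csv", index=False)
    except ValueError as exc:
        logger.warning("early/late comparison skipped: %s", exc)
    if truth is not None:
        ages = truth.groupby("participant_id")["age"].first()
        correlations = inference.age_rhythm_correlation(ages, rhythm_table)
        pd.DataFrame([asdict(c) for c in correlations]).to_csv(out_dir / "age_correlation.csv", index=False)
    done("inference")

    config_dict = asdict(config)
    # the content hash must identify the analysis, not where it was written
    hashed_config = {k: v for k, v in config_dict.items() if k != "output_dir"}
    config_hash = hashlib.sha256(
        json.dumps(hashed_config, sort_keys=True, default=str).encode()
    ).hexdigest()
    files = sorted(p.name for p in out_dir.glob("*.csv"))
    file_hashes = {name: _sha256(out_dir / name) for name in files}
    content_hash = hashlib.sha256(
        json.dumps({"config": config_hash, "seed": config.seed, "files": file_hashes},
                   sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": config_dict,
        "config_hash": config_hash,
        "seed": config.seed,
        "files": file_hashes,
        "content_hash": content_hash,
        "imputation": impute_info,
        "stage_seconds": timings,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
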