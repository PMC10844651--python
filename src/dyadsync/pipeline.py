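"""End-to-end orchestration: simulate → score → schedule → model → report.

A run writes its artifacts into a run directory with a provenance record
(config hash, seeds, package version) next to every stage output, and can
resume from existing intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .ratings_models import (
    ModelConfig,
    compute_accuracy,
    fit_accuracy_model,
    fit_enjoyment_model,
)
from .stimuli import (
    StimuliError,
    build_trial_schedule,
    counterbalance_assign,
    manifest_frame,
    schedule_frame,
    split_subsets,
)
from .synthetic import (
    TRAITS,
    RaterSimConfig,
    simulate_raters,
    simulate_stimulus_pool,
    write_ground_truth,
)

logger = logging.getLogger(__name__)

ACCURACY_COVARIATES = ["predictability", "enjoy", "reproduce", *TRAITS]
ENJOYMENT_COVARIATES = ["measured_similarity", "predictability", *TRAITS]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    n_clips: int = 198
    prop_high: float = 0.85
    n_leaders: int = 16
    n_raters: int = 60
    clips_per_rater: int = 30
    subset_size: int = 100
    subset_overlap: int = 2
    schedule_participants: int = 3
    fit_models: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    rater: RaterSimConfig = field(default_factory=RaterSimConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        model = ModelConfig(**doc.pop("model", {}))
        rater = RaterSimConfig(**doc.pop("rater", {}))
        return cls(model=model, rater=rater, **doc)

    def digest(self) -> str:
        blob = json.dumps(
            {**asdict(self), "model": asdict(self.model), "rater": asdict(self.rater)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "dyadsync_version": __version__,
    }


def build_accuracy_table(ratings: pd.DataFrame, manifest: pd.DataFrame,
                         traits: pd.DataFrame) -> pd.DataFrame:
    """Join ratings with stimulus measures into the accuracy model table.

    Pivots each participant x clip's three question responses wide, derives
    the accuracy difference from the sync estimate, and attaches trait
    scores and clip-level kinematics.
    """
    wide = ratings.pivot_table(index=["participant_id", "clip_id"], columns="question",
                               values="value").reset_index()
    merged = wide.merge(manifest, on="clip_id", how="left").merge(
        traits, on="participant_id", how="left")
    missing = merged["measured_similarity"].isna()
    if missing.any():
        raise PipelineError(
            f"{int(missing.sum())} rated clips missing from the stimulus manifest"
        )
    merged["difference"] = [
        compute_accuracy(s, e) for s, e in zip(merged["measured_similarity"], merged["sync"])
    ]
    return merged


def build_enjoyment_table(ratings: pd.DataFrame, manifest: pd.DataFrame,
                          traits: pd.DataFrame) -> pd.DataFrame:
    enjoy = ratings[ratings["question"] == "enjoy"].rename(columns={"value": "value"})
    merged = enjoy.merge(manifest, on="clip_id", how="left").merge(
        traits, on="participant_id", how="left")
    if merged["measured_similarity"].isna().any():
        raise PipelineError("rated clips missing from the stimulus manifest")
    return merged


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage: simulate + score
    manifest_path = out / "manifest.csv"
    pool = simulate_stimulus_pool(cfg.n_clips, cfg.prop_high, cfg.n_leaders, seed=cfg.seed)
    pool = counterbalance_assign(pool, rng_seed=cfg.seed)
    try:
        a, b = split_subsets(pool, cfg.subset_overlap, cfg.subset_size, rng_seed=cfg.seed)
        subset_map = {c.clip_id: c.subset for c in a + b}
        pool = [replace(c, subset=subset_map.get(c.clip_id)) for c in pool]
    except StimuliError:
        logger.warning("pool size %d incompatible with subset split; skipping", len(pool))
        a = b = None
    manifest = manifest_frame(pool)
    manifest.to_csv(manifest_path, index=False)
    (out / "manifest.provenance.json").write_text(
        json.dumps(_provenance(cfg, "simulate+score"), indent=2))

    # stage: schedule
    if a is not None:
        frames = []
        for i in range(cfg.schedule_participants):
            pid = f"P{i:03d}"
            subset = a if i % 2 == 0 else b
            n_videos = min(50, len(subset))
            frames.append(schedule_frame(
                build_trial_schedule(subset, pid, n_videos=n_videos, rng_seed=cfg.seed + i)))
        pd.concat(frames).to_csv(out / "schedules.csv", index=False)

    # stage: raters
    rater_cfg = RaterSimConfig(**{**asdict(cfg.rater),
                                  "n_raters": cfg.n_raters,
                                  "clips_per_rater": min(cfg.clips_per_rater, len(pool)),
                                  "seed": cfg.seed})
    traits, ratings, truth = simulate_raters(pool, rater_cfg)
    traits.to_csv(out / "traits.csv", index=False)
    ratings.to_csv(out / "ratings.csv", index=False)
    write_ground_truth(truth, out / "ground_truth.json")

    # stage: model
    if cfg.fit_models:
        acc = build_accuracy_table(ratings, manifest, traits)
        fit_a = fit_accuracy_model(acc, ACCURACY_COVARIATES, cfg.model)
        fit_a.summary.to_csv(out / "accuracy_posterior.csv", index=False)
        enj = build_enjoyment_table(ratings, manifest, traits)
        fit_e = fit_enjoyment_model(enj, ENJOYMENT_COVARIATES, cfg.model)
        fit_e.summary.to_csv(out / "enjoyment_posterior.csv", index=False)
        (out / "model.provenance.json").write_text(
            json.dumps({**_provenance(cfg, "model"),
                        "accuracy_converged": fit_a.converged,
                        "enjoyment_converged": fit_e.converged}, indent=2))
    return out


def generate_report(run_dir: str | Path) -> str:
    """Render a plain-text report of a completed run.

    Includes one coefficient table per fitted model and, when a ground
    truth file is present, truth-vs-estimate recovery flags.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise PipelineError(f"{run_dir} is not a run directory")
    expected = ["manifest.csv"]
    missing = [f for f in expected if not (run_dir / f).exists()]
    if missing:
        raise PipelineError(f"incomplete run; missing artifacts: {missing}")

    lines = [f"dyadsync run report: {run_dir}", "=" * 48]
    manifest = pd.read_csv(run_dir / "manifest.csv")
    counts = manifest["condition"].value_counts()
    lines.append(f"clips: {len(manifest)} "
                 f"(high {counts.get('high', 0)}, low {counts.get('low', 0)})")

    truth = None
    truth_path = run_dir / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())

    for label, fname in (("accuracy model", "accuracy_posterior.csv"),
                         ("enjoyment model", "enjoyment_posterior.csv")):
        path = run_dir / fname
        if not path.exists():
            continue
        summary = pd.read_csv(path)
        lines += ["", label, "-" * len(label)]
        for _, row in summary.iterrows():
            line = (f"  {row['parameter']:<34s} {row['mean']:8.2f} "
                    f"[{row['hpd_lo']:8.2f}, {row['hpd_hi']:8.2f}] "
                    f"p>0|p<0 max {row['mass_beyond_zero']:.3f}")
            if truth is not None:
                tv = _truth_value(truth, row["parameter"])
                if tv is not None:
                    covered = row["hpd_lo"] <= tv <= row["hpd_hi"]
                    line += f"  truth={tv:.2f} {'COVERED' if covered else 'MISSED'}"
            lines.append(line)
    if truth is None:
        lines += ["", "(no ground truth file; recovery section omitted)"]
    return "\n".join(lines) + "\n"


def _truth_value(truth: dict, parameter: str):
    if parameter == "alpha[high]":
        return truth.get("alpha_high")
    if parameter == "alpha[low]":
        return truth.get("alpha_low")
    for cond in ("high", "low"):
        prefix = f"beta[{cond},"
        if parameter.startswith(prefix):
            cov = parameter[len(prefix):-1]
            return truth.get(f"trait_slopes_{cond}", {}).get(cov)
    if parameter.startswith("gamma["):
        return truth.get("gamma", {}).get(parameter[6:-1])
    if parameter.startswith("delta["):
        return truth.get("delta", {}).get(parameter[6:-1])
    return None
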