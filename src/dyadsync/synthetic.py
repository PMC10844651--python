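"""Synthetic dyads and synthetic rater panels with known ground truth.

The movement generator works in joint-angle space: shoulder and elbow
angles are sums of 3-5 random-phase sinusoids, and elbow/wrist positions
follow by forward kinematics, so bone lengths are conserved exactly.  In
the high-synchrony condition the follower replays the leader's joint
angles with a configurable lag and angle noise (the mirror game); in the
low-synchrony condition the follower holds a resting posture with small
postural jitter (observing).

The rater generator draws correlated trait profiles and produces sync
estimates, enjoyment (two-part: very-low vs continuous) and
reproducibility ratings from configurable true coefficients, serializing
every truth value next to the outputs so model-recovery tests can score
themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import summarize_clip
from .pose_io import DyadRecording, N_JOINTS, PoseTimeSeries
from .stimuli import ClipStimulus, condition_from_task

TRAITS = (
    "extraversion",
    "self_esteem",
    "body_perception",
    "body_competence",
    "empathy",
    "autistic_traits",
)

#: Instrument-style score ranges used to map standard-normal traits onto
#: plausible raw scales (location, scale, low, high).
TRAIT_SCALES = {
    "extraversion": (24.0, 6.0, 8.0, 40.0),
    "self_esteem": (20.0, 5.0, 0.0, 30.0),
    "body_perception": (3.0, 0.8, 1.0, 5.0),
    "body_competence": (4.5, 1.0, 1.0, 7.0),
    "empathy": (44.0, 10.0, 16.0, 80.0),
    "autistic_traits": (17.0, 7.0, 0.0, 50.0),
}


class SyntheticError(ValueError):
    pass


@dataclass
class DyadSimConfig:
    condition: str = "high"  # "high" | "low"
    duration_s: float = 10.0
    fps: float = 60.0
    follower_lag_ms: float = 200.0
    follower_noise_sd: float = 0.05  # radians of angle noise
    leader_freq_lo: float = 0.1
    leader_freq_hi: float = 1.5
    upper_arm_px: float = 60.0
    forearm_px: float = 50.0
    jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("high", "low"):
            raise SyntheticError("condition must be 'high' or 'low'")
        if self.follower_lag_ms < 0:
            raise SyntheticError("lag must be >= 0")
        n = self.duration_s * self.fps
        if abs(n - round(n)) > 1e-9:
            raise SyntheticError("fps x duration must be integral")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def lag_frames(self) -> int:
        return int(round(self.follower_lag_ms / 1000.0 * self.fps))


@dataclass
class RaterSimConfig:
    n_raters: int = 100
    alpha_high: float = 28.0
    alpha_low: float = 28.0
    trait_slopes_high: dict[str, float] = field(default_factory=dict)
    trait_slopes_low: dict[str, float] = field(default_factory=dict)
    # inflation part: logit-scale intercept and slopes (similarity,
    # predictability, traits); continuous part: slider-scale coefficients.
    gamma: dict[str, float] = field(default_factory=lambda: {"intercept": -2.0})
    delta: dict[str, float] = field(default_factory=lambda: {"intercept": 55.0})
    estimate_noise_sd: float = 8.0
    enjoy_noise_sd: float = 10.0
    trait_correlation: float = 0.2
    empathy_autism_correlation: float = -0.3
    clips_per_rater: int = 50
    seed: int = 0

    def trait_covariance(self) -> np.ndarray:
        cov = np.full((len(TRAITS), len(TRAITS)), self.trait_correlation)
        np.fill_diagonal(cov, 1.0)
        i, j = TRAITS.index("empathy"), TRAITS.index("autistic_traits")
        cov[i, j] = cov[j, i] = self.empathy_autism_correlation
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise SyntheticError("trait covariance is not positive semidefinite")
        return cov


def _angle_process(rng: np.random.Generator, t: np.ndarray, freq_lo: float,
                   freq_hi: float, amplitude: float) -> np.ndarray:
    """Smooth random angle trajectory: sum of 3-5 random-phase sinusoids."""
    k = int(rng.integers(3, 6))
    freqs = rng.uniform(freq_lo, freq_hi, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    amps = rng.uniform(0.3, 1.0, size=k)
    amps *= amplitude / amps.sum()
    return (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)


def _arm_chain(shoulder: np.ndarray, theta: np.ndarray, phi: np.ndarray,
               l1: float, l2: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics: elbow and wrist from shoulder and joint angles."""
    elbow = shoulder + l1 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    wrist = elbow + l2 * np.stack([np.cos(theta + phi), np.sin(theta + phi)], axis=1)
    return elbow, wrist


def _pose_from_angles(cfg: DyadSimConfig, root: np.ndarray, angles: dict[str, np.ndarray],
                      person_id: str) -> PoseTimeSeries:
    """Assemble the 7-joint series from a (possibly jittered) torso root and
    the four arm-angle trajectories.  Bone lengths are exact by construction."""
    T = root.shape[0]
    half_span = 25.0
    neck = root
    r_shoulder = root + np.array([-half_span, 5.0])
    l_shoulder = root + np.array([half_span, 5.0])
    r_elbow, r_wrist = _arm_chain(r_shoulder, angles["r_theta"], angles["r_phi"],
                                  cfg.upper_arm_px, cfg.forearm_px)
    l_elbow, l_wrist = _arm_chain(l_shoulder, angles["l_theta"], angles["l_phi"],
                                  cfg.upper_arm_px, cfg.forearm_px)
    coords = np.stack([neck, r_shoulder, l_shoulder, r_elbow, l_elbow, r_wrist, l_wrist], axis=1)
    assert coords.shape == (T, N_JOINTS, 2)
    return PoseTimeSeries(person_id=person_id, coords=coords, conf=np.ones((T, N_JOINTS)),
                          fps=cfg.fps)


def _leader_angles(cfg: DyadSimConfig, rng: np.random.Generator, t: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "r_theta": np.pi / 2 + _angle_process(rng, t, cfg.leader_freq_lo, cfg.leader_freq_hi, 1.2),
        "r_phi": 0.4 + _angle_process(rng, t, cfg.leader_freq_lo, cfg.leader_freq_hi, 0.8),
        "l_theta": np.pi / 2 + _angle_process(rng, t, cfg.leader_freq_lo, cfg.leader_freq_hi, 1.2),
        "l_phi": -0.4 + _angle_process(rng, t, cfg.leader_freq_lo, cfg.leader_freq_hi, 0.8),
    }


def _torso_root(cfg: DyadSimConfig, rng: np.random.Generator, center: np.ndarray,
                T: int) -> np.ndarray:
    t = np.arange(T) / cfg.fps
    jitter = np.stack(
        [_angle_process(rng, t, 0.1, 0.5, 1.0) * cfg.jitter_px for _ in range(2)], axis=1
    )
    return center[None, :] + jitter


def simulate_leader(cfg: DyadSimConfig, rng: np.random.Generator | None = None,
                    center: tuple[float, float] = (200.0, 200.0)) -> PoseTimeSeries:
    """Simulate the freely moving leader figure."""
    rng = rng or np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_frames) / cfg.fps
    angles = _leader_angles(cfg, rng, t)
    root = _torso_root(cfg, rng, np.asarray(center, float), cfg.n_frames)
    return _pose_from_angles(cfg, root, angles, "leader")


def _angles_from_series(series: PoseTimeSeries) -> dict[str, np.ndarray]:
    """Recover the arm joint-angle trajectories from joint positions."""
    c = series.coords
    out = {}
    for side, sh, el, wr in (("r", 1, 3, 5), ("l", 2, 4, 6)):
        upper = c[:, el] - c[:, sh]
        fore = c[:, wr] - c[:, el]
        theta = np.arctan2(upper[:, 1], upper[:, 0])
        phi = np.arctan2(fore[:, 1], fore[:, 0]) - theta
        out[f"{side}_theta"] = theta
        out[f"{side}_phi"] = phi
    return out


def simulate_follower(
    leader: PoseTimeSeries,
    cfg: DyadSimConfig,
    rng: np.random.Generator | None = None,
    center: tuple[float, float] = (500.0, 200.0),
) -> PoseTimeSeries:
    """Simulate the partner figure for the configured condition.

    High synchrony: the leader's joint angles shifted by ``follower_lag_ms``
    plus Gaussian angle noise.  Low synchrony: a resting posture (arms
    down) with small postural jitter, independent of the leader.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    T = cfg.n_frames
    lag = cfg.lag_frames
    if lag >= T:
        raise SyntheticError(f"lag of {lag} frames >= clip length {T}")
    root = _torso_root(cfg, rng, np.asarray(center, float), T)
    if cfg.condition == "high":
        leader_angles = _angles_from_series(leader)
        angles = {}
        for key, series in leader_angles.items():
            delayed = np.concatenate([np.full(lag, series[0]), series[: T - lag]])
            angles[key] = delayed + cfg.follower_noise_sd * rng.standard_normal(T)
    else:
        t = np.arange(T) / cfg.fps
        # arms folded (wrists near shoulders): geometrically distinct from
        # the leader's extended-arm repertoire, so low clips score low
        rest = {"r_theta": np.pi / 2 + 0.3, "r_phi": 2.6,
                "l_theta": np.pi / 2 - 0.3, "l_phi": -2.6}
        angles = {k: v + _angle_process(rng, t, 0.05, 0.3, 0.02) for k, v in rest.items()}
    return _pose_from_angles(cfg, root, angles, "follower")


def simulate_dyad(cfg: DyadSimConfig, dyad_id: str = "dyad", leader_id: str = "L0") -> DyadRecording:
    """Simulate one complete dyad recording for the configured condition."""
    rng = np.random.default_rng(cfg.seed)
    leader = simulate_leader(cfg, rng)
    follower = simulate_follower(leader, cfg, rng)
    task = "mirroring" if cfg.condition == "high" else "observing"
    return DyadRecording(dyad_id=dyad_id, leader_id=leader_id, condition=task,
                         series_a=leader, series_b=follower)


def simulate_stimulus_pool(
    n_clips: int = 198,
    prop_high: float = 0.85,
    n_leaders: int = 16,
    seed: int = 0,
    base_cfg: DyadSimConfig | None = None,
) -> list[ClipStimulus]:
    """Simulate a full stimulus pool with kinematic summaries computed.

    Condition counts are the nearest integers to the configured proportions
    (198 clips at 85% high gives 168 high + 30 low); leaders are assigned
    round-robin.
    """
    if not 0 < prop_high < 1:
        raise SyntheticError("prop_high must be in (0, 1)")
    n_high = int(round(n_clips * prop_high))
    conditions = ["high"] * n_high + ["low"] * (n_clips - n_high)
    ss = np.random.SeedSequence(seed)
    clip_seeds = ss.generate_state(n_clips)
    clips = []
    for i, cond in enumerate(conditions):
        kwargs = asdict(base_cfg) if base_cfg else {}
        kwargs.update(condition=cond, seed=int(clip_seeds[i]))
        cfg = DyadSimConfig(**kwargs)
        leader = f"L{i % n_leaders:02d}"
        rec = simulate_dyad(cfg, dyad_id=f"clip{i:03d}", leader_id=leader)
        summary = summarize_clip(rec, clip_id=rec.dyad_id)
        clips.append(
            ClipStimulus(
                clip_id=rec.dyad_id,
                dyad_id=rec.dyad_id,
                leader_id=leader,
                condition=condition_from_task(rec.condition),
                kinematics=summary,
                recording=rec,
            )
        )
    return clips


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_raters(
    pool: list[ClipStimulus],
    cfg: RaterSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a rater panel over a measured stimulus pool.

    Returns ``(traits, ratings, ground_truth)``.  Sync estimates follow
    ``100 * similarity - alpha_c - sum(slopes * z_traits) + noise`` clipped
    to [0, 100], so the accuracy difference recovers ``alpha_c`` plus the
    trait effects.  Enjoyment follows the two-part process: a Bernoulli
    very-low indicator driven by ``gamma`` on the logit scale, otherwise a
    Gaussian rating driven by ``delta``, clipped to [11, 100].
    """
    if any(c.kinematics is None for c in pool):
        raise SyntheticError("pool clips need kinematic summaries; run summarize_clip first")
    if cfg.clips_per_rater > len(pool):
        raise SyntheticError(
            f"clips_per_rater={cfg.clips_per_rater} exceeds pool of {len(pool)}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_raters
    z_traits = rng.multivariate_normal(np.zeros(len(TRAITS)), cfg.trait_covariance(), size=n,
                                       method="cholesky")
    traits = pd.DataFrame({"participant_id": [f"P{i:03d}" for i in range(n)]})
    for k, name in enumerate(TRAITS):
        loc, scale, lo, hi = TRAIT_SCALES[name]
        traits[name] = np.clip(loc + scale * z_traits[:, k], lo, hi)
    # effects act on the standardized *realized* panel, so configured slope
    # truths live on exactly the covariate scale a z-scored fit estimates
    z_traits = np.column_stack(
        [_zscore(traits[name].to_numpy()) for name in TRAITS]) if n > 1 else z_traits

    sim = np.array([c.kinematics.measured_similarity for c in pool])
    pred = np.array([c.kinematics.predictability for c in pool])
    z_sim, z_pred = _zscore(sim), _zscore(pred)
    cond = np.array([c.condition for c in pool])

    def coef_vec(coefs: dict[str, float]) -> tuple[float, float, float, np.ndarray]:
        tr = np.array([coefs.get(t, 0.0) for t in TRAITS])
        return (coefs.get("intercept", 0.0), coefs.get("measured_similarity", 0.0),
                coefs.get("predictability", 0.0), tr)

    g0, g_sim, g_pred, g_tr = coef_vec(cfg.gamma)
    d0, d_sim, d_pred, d_tr = coef_vec(cfg.delta)
    slopes_high = np.array([cfg.trait_slopes_high.get(t, 0.0) for t in TRAITS])
    slopes_low = np.array([cfg.trait_slopes_low.get(t, 0.0) for t in TRAITS])

    rows = []
    for i in range(n):
        chosen = rng.choice(len(pool), size=cfg.clips_per_rater, replace=False)
        zt = z_traits[i]
        for j in chosen:
            clip = pool[j]
            is_high = cond[j] == "high"
            alpha = cfg.alpha_high if is_high else cfg.alpha_low
            slopes = slopes_high if is_high else slopes_low
            estimate = (
                100.0 * sim[j] - alpha - float(slopes @ zt)
                + cfg.estimate_noise_sd * rng.standard_normal()
            )
            estimate = float(np.clip(estimate, 0.0, 100.0))

            logit = g0 + g_sim * z_sim[j] + g_pred * z_pred[j] + float(g_tr @ zt)
            p_low = 1.0 / (1.0 + np.exp(-logit))
            if rng.random() < p_low:
                enjoy = float(rng.uniform(0.0, 10.0))
            else:
                mu = d0 + d_sim * z_sim[j] + d_pred * z_pred[j] + float(d_tr @ zt)
                enjoy = float(np.clip(mu + cfg.enjoy_noise_sd * rng.standard_normal(), 11.0, 100.0))

            reproduce = float(np.clip(
                40.0 + 30.0 * sim[j] + 10.0 * rng.standard_normal(), 0.0, 100.0))
            for question, value in (("sync", estimate), ("enjoy", enjoy), ("reproduce", reproduce)):
                rows.append(
                    {
                        "participant_id": traits["participant_id"][i],
                        "clip_id": clip.clip_id,
                        "question": question,
                        "value": value,
                    }
                )
    ratings = pd.DataFrame(rows)
    ground_truth = {
        "alpha_high": cfg.alpha_high,
        "alpha_low": cfg.alpha_low,
        "trait_slopes_high": {t: cfg.trait_slopes_high.get(t, 0.0) for t in TRAITS},
        "trait_slopes_low": {t: cfg.trait_slopes_low.get(t, 0.0) for t in TRAITS},
        "gamma": dict(cfg.gamma),
        "delta": dict(cfg.delta),
        "estimate_noise_sd": cfg.estimate_noise_sd,
        "enjoy_noise_sd": cfg.enjoy_noise_sd,
        "seed": cfg.seed,
        "n_raters": cfg.n_raters,
        "clips_per_rater": cfg.clips_per_rater,
    }
    return traits, ratings, ground_truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
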