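"""Objective kinematic measures for dyadic clips.

Two per-clip quantities are produced:

* **measured similarity** — each figure's frame is reduced to the 42 ordered
  pairwise Euclidean distances among its 7 tracked joints, L2-normalized
  into a body-centric "pose distance vector"; the two figures' vectors are
  compared by cosine similarity (range [0, 1], 1 = identical up to
  isometry/scale) and averaged over the clip's valid frames.
* **predictability** — sample entropy of the x and y wrist-coordinate
  series of both people (8 channels), averaged; lower values indicate a
  more regular, more predictable signal.

Trajectories are expected to be Savitzky-Golay smoothed first (window 13,
order 2); :func:`video_similarity` and :func:`video_predictability` warn
when the smoothing flag is absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .pose_io import N_JOINTS, DyadRecording, PoseTimeSeries

logger = logging.getLogger(__name__)

#: Ordered joint pairs (i, j), i != j, row-major: (0,1), (0,2), ... (6,5).
PAIR_INDEX: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(N_JOINTS) for j in range(N_JOINTS) if i != j
)

N_PAIRS = len(PAIR_INDEX)  # 42

#: Canonical indices of the wrist joints.
WRIST_JOINTS = (5, 6)  # r_hand, l_hand

DEFAULT_CONF_THRESHOLD = 0.1


class KinematicsError(ValueError):
    pass


@dataclass(frozen=True)
class PoseDistanceVector:
    """Normalized pairwise-distance representation of one figure's frame."""

    values: np.ndarray  # (42,), unit L2 norm when valid
    valid: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_PAIRS,):
            raise KinematicsError(f"expected {N_PAIRS} distances, got {self.values.shape}")


@dataclass
class SimilarityTrace:
    """Per-frame similarity values with validity mask and clip mean."""

    per_frame: np.ndarray  # (T,)
    valid: np.ndarray  # (T,) bool
    mean_similarity: float
    coverage: float


@dataclass
class EntropyPanel:
    """Per-channel sample entropies and their mean (the predictability)."""

    channel_values: dict[str, float]
    excluded_channels: list[str]
    predictability: float


@dataclass
class KinematicSummary:
    clip_id: str
    measured_similarity: float
    predictability: float
    coverage: float = 1.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.measured_similarity) and np.isfinite(self.predictability)):
            raise KinematicsError("KinematicSummary fields must be finite")


def smooth_series(
    series: PoseTimeSeries, window_frames: int = 13, poly_order: int = 2
) -> PoseTimeSeries:
    """Savitzky-Golay smooth each coordinate channel independently.

    Endpoints are handled by fitting the order-``poly_order`` polynomial on
    the truncated edge window (scipy's ``mode="interp"``).  Confidences are
    passed through unchanged.  Exactly reproduces polynomials of degree
    <= ``poly_order``.
    """
    if window_frames % 2 != 1 or window_frames <= poly_order:
        raise KinematicsError("window must be odd and greater than poly_order")
    if series.n_frames < window_frames:
        raise KinematicsError(
            f"series has {series.n_frames} frames; smoothing needs at least {window_frames}"
        )
    smoothed = savgol_filter(
        series.coords, window_frames, poly_order, axis=0, mode="interp"
    )
    return replace(series, coords=smoothed, conf=series.conf.copy(), smoothed=True)


def smooth_recording(rec: DyadRecording, window_frames: int = 13, poly_order: int = 2) -> DyadRecording:
    """Smooth both members of a dyad recording."""
    return replace(
        rec,
        series_a=smooth_series(rec.series_a, window_frames, poly_order),
        series_b=smooth_series(rec.series_b, window_frames, poly_order),
    )


def pose_distance_vector(
    frame_joints: np.ndarray,
    conf: np.ndarray | None = None,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> PoseDistanceVector:
    """Build the 42-entry normalized pose distance vector for one frame.

    The vector holds the Euclidean distances of all ordered joint pairs in
    :data:`PAIR_INDEX` order, L2-normalized (body-centric: invariant to the
    figure's position, rotation, reflection and uniform scale).  The vector
    is flagged invalid — never an exception — when any joint's confidence
    falls below ``conf_threshold`` or when all joints coincide (zero norm).
    """
    xy = np.asarray(frame_joints, dtype=float)
    if xy.shape != (N_JOINTS, 2):
        raise KinematicsError(f"expected ({N_JOINTS}, 2) joints, got {xy.shape}")
    valid = True
    if conf is not None and np.any(np.asarray(conf) < conf_threshold):
        valid = False
    diffs = xy[:, None, :] - xy[None, :, :]
    dmat = np.hypot(diffs[..., 0], diffs[..., 1])
    rows, cols = zip(*PAIR_INDEX)
    values = dmat[list(rows), list(cols)]
    norm = np.linalg.norm(values)
    if norm == 0 or not np.isfinite(norm):
        return PoseDistanceVector(values=np.zeros(N_PAIRS), valid=False)
    return PoseDistanceVector(values=values / norm, valid=valid)


def frame_similarity(vec_a: PoseDistanceVector, vec_b: PoseDistanceVector) -> float:
    """Cosine similarity of two valid pose distance vectors, in [0, 1].

    Returns ``nan`` when either vector is invalid.  Both inputs are
    nonnegative unit vectors, so the cosine lies in [0, 1] and equals 1
    exactly when the raw distance vectors are proportional.
    """
    if not (vec_a.valid and vec_b.valid):
        return float("nan")
    return float(np.clip(np.dot(vec_a.values, vec_b.values), 0.0, 1.0))


def _frame_vectors(series: PoseTimeSeries, conf_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized distance vectors (T, 42) and validity mask (T,)."""
    xy = series.coords
    diffs = xy[:, :, None, :] - xy[:, None, :, :]
    dmat = np.hypot(diffs[..., 0], diffs[..., 1])
    rows, cols = zip(*PAIR_INDEX)
    values = dmat[:, list(rows), list(cols)]
    norms = np.linalg.norm(values, axis=1)
    valid = (series.conf >= conf_threshold).all(axis=1) & (norms > 0)
    safe = np.where(norms > 0, norms, 1.0)
    return values / safe[:, None], valid


def video_similarity(
    rec: DyadRecording, conf_threshold: float = DEFAULT_CONF_THRESHOLD
) -> SimilarityTrace:
    """Per-frame similarity of the two figures and its mean over valid frames.

    A frame is valid when both figures pass the confidence threshold.  The
    clip mean is taken over valid frames only, with the covered fraction
    reported; zero valid frames is an error.
    """
    if not (rec.series_a.smoothed and rec.series_b.smoothed):
        logger.warning("video_similarity called on unsmoothed recording %s", rec.dyad_id)
    va, ma = _frame_vectors(rec.series_a, conf_threshold)
    vb, mb = _frame_vectors(rec.series_b, conf_threshold)
    sims = np.clip(np.einsum("tk,tk->t", va, vb), 0.0, 1.0)
    valid = ma & mb
    if not valid.any():
        raise KinematicsError(f"no comparable frames in recording {rec.dyad_id}")
    per_frame = np.where(valid, sims, np.nan)
    return SimilarityTrace(
        per_frame=per_frame,
        valid=valid,
        mean_similarity=float(sims[valid].mean()),
        coverage=float(valid.mean()),
    )


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy of a 1-D series.

    With tolerance ``r = r_factor * SD(x)``, counts pairs of distinct
    template indices whose length-``m`` (B) and length-``m + 1`` (A)
    templates lie within Chebyshev distance ``r`` (matches use ``<= r``;
    self-matches excluded), and returns ``-ln(A / B)``.  Returns ``nan``
    (undefined) when A or B is zero; a constant series returns 0.0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise KinematicsError("sample_entropy expects a 1-D series")
    n = len(x)
    if n < m + 2:
        raise KinematicsError(f"series too short for sample entropy: need >= {m + 2}, got {n}")
    r = r_factor * float(np.std(x, ddof=0))
    # Templates of length m+1; counting over the common index range keeps
    # the A and B pair sets nested, as in the standard definition.
    n_templates = n - m
    idx = np.arange(n_templates)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]  # (n - m, m + 1)
    diff = np.abs(templates[:, None, :] - templates[None, :, :])
    cheb_m = diff[:, :, :m].max(axis=2)
    cheb_m1 = diff.max(axis=2)
    off_diag = ~np.eye(n_templates, dtype=bool)
    b = int(np.count_nonzero((cheb_m <= r) & off_diag))
    a = int(np.count_nonzero((cheb_m1 <= r) & off_diag))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def video_predictability(
    rec: DyadRecording,
    m: int = 2,
    r_factor: float = 0.2,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
) -> EntropyPanel:
    """Sample entropy of both people's wrist x/y series, averaged.

    Eight channels (x, y x left/right wrist x 2 people) are computed; a
    channel is excluded — with a logged warning — when its wrist keypoint is
    unreliable (any confidence below threshold) or its entropy is undefined.
    The panel's ``predictability`` is the mean of the defined channels.
    """
    if not (rec.series_a.smoothed and rec.series_b.smoothed):
        logger.warning("video_predictability called on unsmoothed recording %s", rec.dyad_id)
    channels: dict[str, float] = {}
    excluded: list[str] = []
    for person, series in (("a", rec.series_a), ("b", rec.series_b)):
        for wrist, wname in zip(WRIST_JOINTS, ("r_hand", "l_hand")):
            reliable = bool((series.conf[:, wrist] >= conf_threshold).all())
            for axis, aname in enumerate(("x", "y")):
                name = f"{person}_{wname}_{aname}"
                if not reliable:
                    excluded.append(name)
                    continue
                value = sample_entropy(series.coords[:, wrist, axis], m=m, r_factor=r_factor)
                if np.isnan(value):
                    excluded.append(name)
                else:
                    channels[name] = value
    if excluded:
        logger.warning(
            "recording %s: %d entropy channels excluded: %s",
            rec.dyad_id, len(excluded), excluded,
        )
    if not channels:
        raise KinematicsError(f"all entropy channels undefined for recording {rec.dyad_id}")
    return EntropyPanel(
        channel_values=channels,
        excluded_channels=excluded,
        predictability=float(np.mean(list(channels.values()))),
    )


def summarize_clip(
    rec: DyadRecording,
    clip_id: str | None = None,
    smooth: bool = True,
    window_frames: int = 13,
    poly_order: int = 2,
) -> KinematicSummary:
    """Smooth (optionally) and reduce a clip to its two objective measures."""
    if smooth and not (rec.series_a.smoothed and rec.series_b.smoothed):
        rec = smooth_recording(rec, window_frames, poly_order)
    trace = video_similarity(rec)
    panel = video_predictability(rec)
    return KinematicSummary(
        clip_id=clip_id or rec.dyad_id,
        measured_similarity=trace.mean_similarity,
        predictability=panel.predictability,
        coverage=trace.coverage,
    )
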