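"""Reading, validation, alignment and persistence of two-person upper-body
keypoint time series.

Keypoints come either from OpenPose-style per-frame JSON files (BODY_25
layout, one file per frame) or from a long-format CSV.  Only seven
upper-body joints are tracked, in this canonical order:

    0 neck, 1 r_shoulder, 2 l_shoulder, 3 r_elbow, 4 l_elbow,
    5 r_hand, 6 l_hand

"Hands" are the BODY_25 wrist keypoints (indices 4 and 7); the dedicated
OpenPose hand sub-model is not used.  A person absent from a frame is kept
as an all-zero-confidence row so that series length is stable across frames.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical joint names, fixed order.
JOINTS: tuple[str, ...] = (
    "neck",
    "r_shoulder",
    "l_shoulder",
    "r_elbow",
    "l_elbow",
    "r_hand",
    "l_hand",
)

#: BODY_25 indices of the canonical joints, in canonical order.
BODY25_INDICES: tuple[int, ...] = (1, 2, 5, 3, 6, 4, 7)

N_JOINTS = len(JOINTS)

CONDITIONS = ("mirroring", "observing")


class PoseIOError(ValueError):
    """Raised on malformed keypoint input."""


@dataclass(frozen=True)
class Keypoint:
    """A single 2-D keypoint in image coordinates (y grows downward)."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise PoseIOError(f"confidence {self.confidence} outside [0, 1]")
        if self.confidence > 0 and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise PoseIOError("non-finite coordinates with positive confidence")


@dataclass
class PoseTimeSeries:
    """One person's tracked upper-body joints over time.

    Attributes
    ----------
    person_id : str
        Label for the tracked person.
    fps : float
        Frames per second; always explicit, never inferred.
    coords : ndarray, shape (T, 7, 2)
        Pixel coordinates per frame and joint, canonical joint order.
    conf : ndarray, shape (T, 7)
        Per-joint detection confidence in [0, 1].
    smoothed : bool
        Set by the smoothing step; downstream measures warn when absent.
    """

    person_id: str
    coords: np.ndarray
    conf: np.ndarray
    fps: float = 60.0
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_JOINTS, 2):
            raise PoseIOError(f"coords must have shape (T, {N_JOINTS}, 2), got {self.coords.shape}")
        if self.conf.shape != self.coords.shape[:2]:
            raise PoseIOError(f"conf shape {self.conf.shape} does not match coords")
        if self.coords.shape[0] < 1:
            raise PoseIOError("need at least one frame")
        if self.fps <= 0:
            raise PoseIOError(f"fps must be positive, got {self.fps}")
        if np.any(self.conf < 0) or np.any(self.conf > 1):
            raise PoseIOError("confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "PoseTimeSeries":
        return replace(self, coords=self.coords.copy(), conf=self.conf.copy())


@dataclass
class DyadRecording:
    """Two aligned single-person keypoint series plus dyad metadata."""

    dyad_id: str
    leader_id: str
    condition: str
    series_a: PoseTimeSeries
    series_b: PoseTimeSeries
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PoseIOError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.series_a.n_frames != self.series_b.n_frames:
            raise PoseIOError("series_a and series_b must have equal length")
        if self.series_a.fps != self.series_b.fps:
            raise PoseIOError("series_a and series_b must share fps")

    @property
    def n_frames(self) -> int:
        return self.series_a.n_frames

    @property
    def fps(self) -> float:
        return self.series_a.fps


def _extract_person(raw: list[float], path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Pull the 7 canonical joints out of a flat BODY_25 triplet list."""
    arr = np.asarray(raw, dtype=float)
    if arr.size % 3 != 0 or arr.size < 3 * (max(BODY25_INDICES) + 1):
        raise PoseIOError(
            f"{path.name}: pose_keypoints_2d has {arr.size} values; "
            f"expected BODY_25 triplets covering index {max(BODY25_INDICES)}"
        )
    triplets = arr.reshape(-1, 3)[list(BODY25_INDICES)]
    return triplets[:, :2].copy(), triplets[:, 2].copy()


def read_openpose_frames(directory: str | Path) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Read a directory of OpenPose JSON frame files.

    Returns frames in filename-sorted order.  Each frame is a list of up to
    two ``(coords (7, 2), conf (7,))`` person tuples.  A frame with a single
    detected person yields a second person with all-zero confidence; a frame
    with more than two people is an error (dyads only).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.glob("*.json") if p.is_file())
    if not files:
        raise PoseIOError(f"no frames: no JSON files found in {directory}")
    frames = []
    for path in files:
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise PoseIOError(f"malformed JSON in {path.name}: {exc}") from exc
        people = doc.get("people", [])
        if len(people) > 2:
            raise PoseIOError(f"{path.name}: {len(people)} people detected; dyads only")
        persons = [_extract_person(p["pose_keypoints_2d"], path) for p in people]
        while len(persons) < 2:
            persons.append((np.zeros((N_JOINTS, 2)), np.zeros(N_JOINTS)))
        frames.append(persons)
    return frames


def assemble_dyad(
    frames: list[list[tuple[np.ndarray, np.ndarray]]],
    fps: float = 60.0,
    dyad_id: str = "dyad",
    leader_id: str = "a",
    condition: str = "mirroring",
) -> DyadRecording:
    """Assemble per-frame person tuples into a :class:`DyadRecording`.

    Persons are tracked across frames by horizontal ordering: the person
    with the smaller confidence-weighted mean x over the whole recording
    becomes ``series_a``.  The stimuli fix one figure per side, so no
    re-identification logic is needed.
    """
    if not frames:
        raise PoseIOError("no frames to assemble")
    coords = np.zeros((len(frames), 2, N_JOINTS, 2))
    conf = np.zeros((len(frames), 2, N_JOINTS))
    for t, persons in enumerate(frames):
        if len(persons) != 2:
            raise PoseIOError(f"frame {t}: expected 2 person entries, got {len(persons)}")
        for p, (xy, c) in enumerate(persons):
            coords[t, p] = xy
            conf[t, p] = c

    # Per-frame left/right ordering: swap any frame whose detections come
    # right-person-first, then decide which slot is series_a globally.
    for t in range(len(frames)):
        if conf[t].sum(axis=1).min() <= 0:
            continue  # missing person; keep slot order
        mx = (coords[t, :, :, 0] * conf[t]).sum(axis=1) / conf[t].sum(axis=1)
        if mx[0] > mx[1]:
            coords[t] = coords[t, ::-1]
            conf[t] = conf[t, ::-1]

    w = conf.sum(axis=(0, 2))
    if np.any(w <= 0):
        order = (0, 1)
    else:
        mean_x = (coords[:, :, :, 0] * conf).sum(axis=(0, 2)) / w
        order = (0, 1) if mean_x[0] <= mean_x[1] else (1, 0)

    series = [
        PoseTimeSeries(person_id=pid, coords=coords[:, slot], conf=conf[:, slot], fps=fps)
        for pid, slot in zip(("a", "b"), order)
    ]
    return DyadRecording(
        dyad_id=dyad_id,
        leader_id=leader_id,
        condition=condition,
        series_a=series[0],
        series_b=series[1],
    )


def interpolate_gaps(series: PoseTimeSeries, max_gap_frames: int) -> PoseTimeSeries:
    """Linearly interpolate short dropout gaps in a keypoint series.

    Runs of confidence-0 samples of length <= ``max_gap_frames`` that are
    bracketed by detected samples are linearly interpolated per coordinate
    and flagged with confidence 0.5.  Longer runs, and runs touching either
    end of the series, are left untouched.
    """
    if max_gap_frames < 0:
        raise PoseIOError("max_gap_frames must be >= 0")
    out = series.copy()
    if max_gap_frames == 0:
        return out
    for j in range(N_JOINTS):
        c = out.conf[:, j]
        missing = c == 0
        if not missing.any():
            continue
        t = 0
        T = len(c)
        while t < T:
            if not missing[t]:
                t += 1
                continue
            start = t
            while t < T and missing[t]:
                t += 1
            end = t  # gap is [start, end)
            gap_len = end - start
            if start == 0 or end == T or gap_len > max_gap_frames:
                continue
            lo, hi = out.coords[start - 1, j], out.coords[end, j]
            for k in range(gap_len):
                frac = (k + 1) / (gap_len + 1)
                out.coords[start + k, j] = lo + frac * (hi - lo)
            out.conf[start:end, j] = 0.5
    return out


_CSV_COLUMNS = ["frame", "person", "joint", "x", "y", "confidence"]


def write_timeseries_csv(rec: DyadRecording, path: str | Path) -> None:
    """Persist a recording as long-format CSV.

    Columns: ``frame, person, joint, x, y, confidence`` (UTF-8, "." decimal).
    Header rows carry dyad metadata as ``# key=value`` comments.
    """
    path = Path(path)
    rows = []
    for label, series in (("a", rec.series_a), ("b", rec.series_b)):
        for t in range(rec.n_frames):
            for j, joint in enumerate(JOINTS):
                rows.append(
                    (t, label, joint, series.coords[t, j, 0], series.coords[t, j, 1], series.conf[t, j])
                )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# dyad_id={rec.dyad_id}\n")
        fh.write(f"# leader_id={rec.leader_id}\n")
        fh.write(f"# condition={rec.condition}\n")
        fh.write(f"# fps={rec.fps}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_timeseries_csv(path: str | Path) -> DyadRecording:
    """Read a long-format keypoint CSV written by :func:`write_timeseries_csv`.

    Joints listed out of canonical order are reordered canonically.
    A missing column raises a schema error naming it.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            raise PoseIOError(f"schema error: missing column {col!r} in {path.name}")
    joint_index = {name: i for i, name in enumerate(JOINTS)}
    unknown = set(df["joint"]) - set(JOINTS)
    if unknown:
        raise PoseIOError(f"unknown joints in {path.name}: {sorted(unknown)}")
    frames = np.sort(df["frame"].unique())
    T = len(frames)
    frame_index = {f: i for i, f in enumerate(frames)}
    series = {}
    for label, grp in df.groupby("person"):
        coords = np.full((T, N_JOINTS, 2), np.nan)
        conf = np.zeros((T, N_JOINTS))
        ti = grp["frame"].map(frame_index).to_numpy()
        ji = grp["joint"].map(joint_index).to_numpy()
        coords[ti, ji, 0] = grp["x"].to_numpy()
        coords[ti, ji, 1] = grp["y"].to_numpy()
        conf[ti, ji] = grp["confidence"].to_numpy()
        coords = np.nan_to_num(coords)
        series[label] = PoseTimeSeries(
            person_id=str(label), coords=coords, conf=conf, fps=float(meta.get("fps", 60.0))
        )
    if set(series) != {"a", "b"}:
        raise PoseIOError(f"expected persons 'a' and 'b' in {path.name}, got {sorted(series)}")
    return DyadRecording(
        dyad_id=meta.get("dyad_id", path.stem),
        leader_id=meta.get("leader_id", "a"),
        condition=meta.get("condition", "mirroring"),
        series_a=series["a"],
        series_b=series["b"],
    )
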