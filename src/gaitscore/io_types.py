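"""Domain types, keypoint readers/writers, bout validation and quality filtering.

Walking bouts are stored as per-joint coordinate arrays over frames.
Frames in which the person was not detected are kept as explicit NaN rows
so that time indexing stays uniform; downstream feature code interpolates
short gaps and splits at long ones.

Two on-disk dialects are supported for 2D keypoints — a per-frame JSON
record set in the OpenPose ``people -> pose_keypoints_2d`` style, and a
long-format CSV (frame, joint, u, v, confidence).  3D joints use a long
CSV (frame, joint, x, y, z).  Bout metadata travels in a flat CSV.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MPII_JOINTS",
    "KINECT_JOINTS",
    "WalkingBout",
    "BoutMetadata",
    "BoutQCResult",
    "FootStrikeSeries",
    "read_keypoints_2d",
    "write_keypoints_2d",
    "read_keypoints_3d",
    "write_keypoints_3d",
    "read_metadata",
    "write_metadata",
    "interpolate_gaps",
    "qc_bout",
    "subsample_one_per_day",
]

#: MPII-style 2D joint vocabulary (16 joints), image coordinates (u right, v down).
MPII_JOINTS: tuple[str, ...] = (
    "head_top",
    "upper_neck",
    "thorax",
    "pelvis",
    "r_shoulder",
    "r_elbow",
    "r_wrist",
    "l_shoulder",
    "l_elbow",
    "l_wrist",
    "r_hip",
    "l_hip",
    "r_knee",
    "l_knee",
    "r_ankle",
    "l_ankle",
)

#: Kinect-style 25-joint 3D vocabulary; x medio-lateral, y vertical (up), z
#: anterior-posterior, all in metres.  ``spine_base`` is the sacrum proxy.
KINECT_JOINTS: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "neck",
    "head",
    "shoulder_left",
    "elbow_left",
    "wrist_left",
    "hand_left",
    "shoulder_right",
    "elbow_right",
    "wrist_right",
    "hand_right",
    "hip_left",
    "knee_left",
    "ankle_left",
    "foot_left",
    "hip_right",
    "knee_right",
    "ankle_right",
    "foot_right",
    "spine_shoulder",
    "hand_tip_left",
    "thumb_left",
    "hand_tip_right",
    "thumb_right",
)

_JOINT_VOCAB = {2: frozenset(MPII_JOINTS), 3: frozenset(KINECT_JOINTS)}

# canonical left/right landmark names per dimensionality
ANKLES = {2: ("l_ankle", "r_ankle"), 3: ("ankle_left", "ankle_right")}
HIPS = {2: ("l_hip", "r_hip"), 3: ("hip_left", "hip_right")}
SACRUM = {3: "spine_base"}


@dataclass
class WalkingBout:
    """One recorded walking bout: joint trajectories plus identifiers.

    ``data`` maps joint name to an ``(n_frames, ndim)`` float array; missing
    observations are NaN.  ``confidence`` (2D only) maps joint name to an
    ``(n_frames,)`` array in [0, 1].
    """

    bout_id: str
    participant_id: str
    date: _dt.date
    frame_rate: float
    ndim: int
    data: dict[str, np.ndarray]
    confidence: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.ndim not in (2, 3):
            raise ValueError(f"ndim must be 2 or 3, got {self.ndim}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        vocab = _JOINT_VOCAB[self.ndim]
        unknown = set(self.data) - vocab
        if unknown:
            raise ValueError(f"unknown joint names for {self.ndim}D bout: {sorted(unknown)}")
        lengths = {arr.shape for arr in self.data.values()}
        if len({shape[0] for shape in lengths}) > 1:
            raise ValueError("all joints must cover the same number of frames")
        for name, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[1] != self.ndim:
                raise ValueError(f"joint {name!r}: expected (n, {self.ndim}) array, got {arr.shape}")
        if self.n_frames < 2:
            raise ValueError("a bout needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def duration(self) -> float:
        """Bout duration in seconds, ``(n_frames - 1) / frame_rate``."""
        return (self.n_frames - 1) / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def joint(self, name: str) -> np.ndarray:
        try:
            return self.data[name]
        except KeyError:
            raise KeyError(f"joint {name!r} not present in bout {self.bout_id!r}") from None

    def copy_with(self, data: dict[str, np.ndarray]) -> "WalkingBout":
        return WalkingBout(
            bout_id=self.bout_id,
            participant_id=self.participant_id,
            date=self.date,
            frame_rate=self.frame_rate,
            ndim=self.ndim,
            data=data,
            confidence=self.confidence,
        )


@dataclass(frozen=True)
class BoutMetadata:
    """Demographics and clinical ratings attached to one bout."""

    age: float
    sex: str
    updrs_gait: int
    sas_gait: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("updrs_gait", "sas_gait"):
            score = getattr(self, name)
            if score not in (0, 1, 2, 3, 4):
                raise ValueError(f"{name} must be an integer in 0..4, got {score!r}")


@dataclass(frozen=True)
class BoutQCResult:
    """Inclusion verdict for one bout: tracked at all, and enough steps."""

    tracked: bool
    n_steps: int
    included: bool
    reason: str  # {"ok", "too_short", "untracked"}


@dataclass(frozen=True)
class FootStrikeSeries:
    """Detected foot strikes and the step intervals they delimit.

    ``times`` are strictly increasing strike times (s); ``sides`` the foot
    striking ("left"/"right"); ``prominences`` the detector's velocity-peak
    prominence per strike (used for tie-breaking repairs).  A *step* is the
    interval between consecutive strikes and is attributed to the side of
    the strike that ends it.
    """

    times: np.ndarray
    sides: tuple[str, ...]
    prominences: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.prominences is None:
            object.__setattr__(self, "prominences", np.ones_like(times))
        if len(self.sides) != times.size:
            raise ValueError("times and sides must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("strike times must be strictly increasing")

    @property
    def n_strikes(self) -> int:
        return int(self.times.size)

    @property
    def n_steps(self) -> int:
        """Number of steps in the bout, counted as detected strikes."""
        return self.n_strikes

    @property
    def step_times(self) -> np.ndarray:
        """Successive inter-strike intervals (s)."""
        return np.diff(self.times)

    @property
    def step_sides(self) -> tuple[str, ...]:
        """Side of the strike ending each step."""
        return self.sides[1:]

    def side_step_times(self, side: str) -> np.ndarray:
        st = self.step_times
        return st[[s == side for s in self.step_sides]]

    @classmethod
    def empty(cls) -> "FootStrikeSeries":
        return cls(times=np.empty(0), sides=())


# ---------------------------------------------------------------------------
# readers / writers


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def write_keypoints_2d(bout: WalkingBout, path: str | Path) -> None:
    """Write a 2D bout.

    ``.json`` paths get a per-frame record set in the OpenPose dialect
    (``people -> pose_keypoints_2d`` flat [u, v, confidence] triplets, joint
    order declared in the header); ``.csv`` paths get a long table
    (frame, joint, u, v, confidence).  Missing-person frames are written
    with an empty ``people`` list (JSON) or omitted rows (CSV).
    """
    path = Path(path)
    if bout.ndim != 2:
        raise ValueError("write_keypoints_2d requires a 2D bout")
    joints = list(bout.data)
    if path.suffix == ".json":
        frames = []
        for i in range(bout.n_frames):
            coords = np.array([bout.data[j][i] for j in joints])
            if np.all(np.isnan(coords)):
                frames.append({"frame_index": i, "people": []})
                continue
            flat: list[float] = []
            for j in joints:
                u, v = bout.data[j][i]
                c = 1.0 if bout.confidence is None else float(bout.confidence[j][i])
                if np.isnan(u) or np.isnan(v):
                    flat.extend([0.0, 0.0, 0.0])  # OpenPose convention for undetected joints
                else:
                    flat.extend([float(u), float(v), c])
            frames.append({"frame_index": i, "people": [{"pose_keypoints_2d": flat}]})
        doc = {
            "bout_id": bout.bout_id,
            "participant_id": bout.participant_id,
            "date": bout.date.isoformat(),
            "frame_rate": bout.frame_rate,
            "joint_order": joints,
            "frames": frames,
        }
        path.write_text(json.dumps(doc))
    else:
        rows = []
        for j in joints:
            arr = bout.data[j]
            conf = bout.confidence[j] if bout.confidence else np.ones(bout.n_frames)
            for i in range(bout.n_frames):
                if np.isnan(arr[i]).any():
                    continue
                rows.append((i, j, arr[i, 0], arr[i, 1], conf[i]))
        df = pd.DataFrame(rows, columns=["frame", "joint", "u", "v", "confidence"])
        df.attrs = {}
        header = (
            f"# bout_id={bout.bout_id} participant_id={bout.participant_id} "
            f"date={bout.date.isoformat()} frame_rate={bout.frame_rate} n_frames={bout.n_frames}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.sort_values(["frame", "joint"]).to_csv(fh, index=False)


def _read_csv_header_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


def read_keypoints_2d(
    path: str | Path,
    joint_map: Mapping[str, str] | None = None,
    *,
    bout_id: str | None = None,
    participant_id: str | None = None,
    date: _dt.date | str | None = None,
    frame_rate: float | None = None,
) -> WalkingBout:
    """Read a 2D bout written by :func:`write_keypoints_2d` (or compatible files).

    ``joint_map`` remaps file joint names onto the MPII vocabulary; names
    that remain outside the vocabulary raise a configuration error.
    Missing-person frames are retained as NaN rows, not dropped.
    """
    path = Path(path)
    joint_map = dict(joint_map or {})
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        joints = [joint_map.get(j, j) for j in doc["joint_order"]]
        _check_vocab(joints, 2)
        records = doc["frames"]
        idx = [int(r["frame_index"]) for r in records]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"{path}: non-monotone or duplicated frame indices")
        n = max(idx) + 1
        data = {j: np.full((n, 2), np.nan) for j in joints}
        conf = {j: np.zeros(n) for j in joints}
        for rec in records:
            i = int(rec["frame_index"])
            if not rec["people"]:
                continue
            flat = rec["people"][0]["pose_keypoints_2d"]
            if len(flat) != 3 * len(joints):
                raise ValueError(f"{path}: frame {i} keypoint count does not match joint_order")
            for k, j in enumerate(joints):
                u, v, c = flat[3 * k : 3 * k + 3]
                if c > 0:
                    data[j][i] = (u, v)
                    conf[j][i] = c
        return WalkingBout(
            bout_id=bout_id or doc.get("bout_id", path.stem),
            participant_id=participant_id or doc.get("participant_id", "unknown"),
            date=_parse_date(date or doc.get("date", "1970-01-01")),
            frame_rate=float(frame_rate or doc.get("frame_rate", 30.0)),
            ndim=2,
            data=data,
            confidence=conf,
        )
    # long CSV dialect
    meta = _read_csv_header_meta(path)
    df = pd.read_csv(path, comment="#")
    need = {"frame", "joint", "u", "v"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    df["joint"] = df["joint"].map(lambda j: joint_map.get(j, j))
    _check_vocab(df["joint"].unique(), 2)
    n = int(meta.get("n_frames", df["frame"].max() + 1))
    data = {j: np.full((n, 2), np.nan) for j in df["joint"].unique()}
    conf = {j: np.zeros(n) for j in df["joint"].unique()}
    for row in df.itertuples(index=False):
        i = int(row.frame)
        if i < 0 or i >= n:
            raise ValueError(f"{path}: frame index {i} out of range")
        data[row.joint][i] = (row.u, row.v)
        conf[row.joint][i] = getattr(row, "confidence", 1.0)
    return WalkingBout(
        bout_id=bout_id or meta.get("bout_id", path.stem),
        participant_id=participant_id or meta.get("participant_id", "unknown"),
        date=_parse_date(date or meta.get("date", "1970-01-01")),
        frame_rate=float(frame_rate or meta.get("frame_rate", 30.0)),
        ndim=2,
        data=data,
        confidence=conf,
    )


def _check_vocab(names: Iterable[str], ndim: int) -> None:
    unknown = set(names) - _JOINT_VOCAB[ndim]
    if unknown:
        raise ValueError(
            f"unknown joint name(s) {sorted(unknown)}; remap them via joint_map "
            f"onto the {ndim}D vocabulary"
        )


def write_keypoints_3d(bout: WalkingBout, path: str | Path) -> None:
    """Write a 3D bout as a long CSV (frame, joint, x, y, z) with a metadata header line."""
    path = Path(path)
    if bout.ndim != 3:
        raise ValueError("write_keypoints_3d requires a 3D bout")
    rows = []
    for j, arr in bout.data.items():
        for i in range(bout.n_frames):
            if np.isnan(arr[i]).any():
                continue
            rows.append((i, j, arr[i, 0], arr[i, 1], arr[i, 2]))
    df = pd.DataFrame(rows, columns=["frame", "joint", "x", "y", "z"])
    header = (
        f"# bout_id={bout.bout_id} participant_id={bout.participant_id} "
        f"date={bout.date.isoformat()} frame_rate={bout.frame_rate} n_frames={bout.n_frames}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.sort_values(["frame", "joint"]).to_csv(fh, index=False)


def read_keypoints_3d(
    path: str | Path,
    *,
    bout_id: str | None = None,
    participant_id: str | None = None,
    date: _dt.date | str | None = None,
    frame_rate: float | None = None,
) -> WalkingBout:
    """Read a 3D bout from a long CSV (frame, joint, x, y, z), metres.

    Raises if ``spine_base`` is absent from every frame, since the sacrum
    proxy is required by all stability and sway features.
    """
    path = Path(path)
    meta = _read_csv_header_meta(path)
    df = pd.read_csv(path, comment="#")
    need = {"frame", "joint", "x", "y", "z"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    _check_vocab(df["joint"].unique(), 3)
    n = int(meta.get("n_frames", df["frame"].max() + 1))
    data = {j: np.full((n, 3), np.nan) for j in df["joint"].unique()}
    for row in df.itertuples(index=False):
        i = int(row.frame)
        if i < 0 or i >= n:
            raise ValueError(f"{path}: frame index {i} out of range")
        data[row.joint][i] = (row.x, row.y, row.z)
    if "spine_base" not in data or not np.isfinite(data["spine_base"]).any():
        raise ValueError(f"{path}: spine_base (sacrum) missing in all frames")
    return WalkingBout(
        bout_id=bout_id or meta.get("bout_id", path.stem),
        participant_id=participant_id or meta.get("participant_id", "unknown"),
        date=_parse_date(date or meta.get("date", "1970-01-01")),
        frame_rate=float(frame_rate or meta.get("frame_rate", 30.0)),
        ndim=3,
        data=data,
    )


_META_COLUMNS = [
    "bout_id",
    "participant_id",
    "date",
    "age",
    "sex",
    "updrs_gait",
    "sas_gait",
    "frame_rate",
]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in _META_COLUMNS if c in df.columns])


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the bout metadata CSV, validating scores and sex coding."""
    df = pd.read_csv(path, dtype={"bout_id": str, "participant_id": str})
    missing = {"bout_id", "participant_id", "updrs_gait", "sas_gait"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {sorted(missing)}")
    for _, row in df.iterrows():
        BoutMetadata(
            age=float(row.get("age", 0.0)),
            sex=str(row.get("sex", "female")),
            updrs_gait=int(row["updrs_gait"]),
            sas_gait=int(row["sas_gait"]),
        )
    return df


# ---------------------------------------------------------------------------
# gap handling, QC, subsampling


def interpolate_gaps(bout: WalkingBout, max_gap: int = 5) -> WalkingBout:
    """Linearly fill NaN runs of length <= ``max_gap`` frames, per joint and axis.

    Longer gaps are left missing; downstream code treats them as segment
    boundaries rather than fabricating long stretches of motion.
    """
    out = {}
    for name, arr in bout.data.items():
        arr = arr.copy()
        for axis in range(arr.shape[1]):
            col = arr[:, axis]
            isnan = np.isnan(col)
            if not isnan.any() or isnan.all():
                continue
            # identify NaN runs
            idx = np.flatnonzero(isnan)
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            good = np.flatnonzero(~isnan)
            for run in splits:
                if run.size == 0 or run.size > max_gap:
                    continue
                lo, hi = run[0] - 1, run[-1] + 1
                if lo < 0 or hi >= col.size or np.isnan(col[lo]) or np.isnan(col[hi]):
                    continue  # gap touches the bout edge: leave missing
                col[run] = np.interp(run, [lo, hi], [col[lo], col[hi]])
            arr[:, axis] = col
        out[name] = arr
    return bout.copy_with(out)


def tracked_fraction(bout: WalkingBout) -> float:
    """Fraction of frames in which both ankles and both hips are observed."""
    la, ra = ANKLES[bout.ndim]
    lh, rh = HIPS[bout.ndim]
    ok = np.ones(bout.n_frames, dtype=bool)
    for j in (la, ra, lh, rh):
        if j not in bout.data:
            return 0.0
        ok &= np.isfinite(bout.data[j]).all(axis=1)
    return float(ok.mean())


def qc_bout(
    bout: WalkingBout,
    strikes: FootStrikeSeries,
    min_steps: int = 3,
    tracked_floor: float = 0.5,
) -> BoutQCResult:
    """Quality-control verdict: exclude untracked bouts and bouts with too few steps.

    A bout counts as tracked when both ankles and both hips are observed in
    at least ``tracked_floor`` of its frames.  Tracked bouts with fewer than
    ``min_steps`` detected steps are excluded as too short.
    """
    tracked = tracked_fraction(bout) >= tracked_floor
    n_steps = strikes.n_steps
    if not tracked:
        return BoutQCResult(tracked=False, n_steps=n_steps, included=False, reason="untracked")
    if n_steps < min_steps:
        return BoutQCResult(tracked=True, n_steps=n_steps, included=False, reason="too_short")
    return BoutQCResult(tracked=True, n_steps=n_steps, included=True, reason="ok")


def subsample_one_per_day(bouts: Sequence[WalkingBout], seed: int) -> list[WalkingBout]:
    """Keep exactly one bout per (participant, date), chosen uniformly at random.

    Deterministic for a fixed seed; selection order does not depend on the
    input ordering (groups are processed in sorted key order and candidates
    sorted by bout_id).
    """
    groups: dict[tuple[str, _dt.date], list[WalkingBout]] = {}
    for b in bouts:
        groups.setdefault((b.participant_id, b.date), []).append(b)
    rng = np.random.default_rng(seed)
    kept = []
    for key in sorted(groups):
        candidates = sorted(groups[key], key=lambda b: b.bout_id)
        kept.append(candidates[rng.integers(len(candidates))])
    return kept
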