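"""Synthetic walking bouts and cohorts with known ground truth.

The generator produces the statistical structure the analysis assumes,
at keypoint level, so every pipeline stage can be tested without
clinical recordings:

* a kinematic walking template — the pelvis advances at constant speed
  with sinusoidal medio-lateral sway while the feet alternate stance
  (planted) and swing (raised-cosine vertical lift, eased forward
  travel), with per-step timing jitter and a controllable left/right
  timing asymmetry;
* a 3D skeleton (25-joint vocabulary, metres) sampled at the camera
  frame rate, or a 2D projection of the same skeleton through a
  perspective camera mounted ahead of and above the walker (MPII
  vocabulary, pixels), walker approaching the camera;
* a latent-severity cohort model: each participant carries a baseline
  severity with slow piecewise-linear drift across recording days
  (emulating medication-change dynamics); severity maps monotonically
  onto gait parameters (lower cadence and step length, more variability,
  asymmetry and sway, wider steps) and ordinal 0-4 ratings are drawn
  from a proportional-odds model on the latent severity.

Everything is deterministic given a seed, and every bout carries its
ground truth (exact strike schedule, generating parameters, severity,
rating probabilities).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from gaitscore.io_types import WalkingBout

__all__ = [
    "GaitParams",
    "GroundTruth",
    "SeverityModel",
    "simulate_bout",
    "simulate_cohort",
]

#: vertical excursion of the ankle joint during swing, metres (ankle markers
#: rise 0.10-0.18 m in adult gait, dominated by heel rise after toe-off)
SWING_AMPLITUDE = 0.12
#: swing duration as a fraction of the foot's stride (two steps)
SWING_FRACTION = 0.4
#: fraction of the swing spent lifting; the remainder is the terminal descent
LIFT_FRACTION = 0.6
#: metric inter-hip distance of the template skeleton, metres
HIP_WIDTH = 0.30
#: ankle-joint height during stance, metres
STANCE_ANKLE_HEIGHT = 0.08
#: pelvis (spine_base) height, metres
PELVIS_HEIGHT = 0.95

# perspective camera: focal length (px), principal point, mount height (m)
# and clearance between the walker's final position and the camera (m)
FOCAL_PX = 1000.0
PRINCIPAL = (960.0, 540.0)
CAMERA_HEIGHT = 2.30
CAMERA_MARGIN = 5.0


@dataclass(frozen=True)
class GaitParams:
    """Generating gait parameters for one bout.

    ``step_time_asymmetry`` is the fractional difference between the two
    sides' mean step times (right slower for positive values);
    ``keypoint_noise_sd`` is i.i.d. Gaussian keypoint noise, in hip-width
    units for 2D output and metres for 3D output.
    """

    cadence: float = 105.0  # steps/min
    step_length: float = 0.55  # m
    step_width: float = 0.10  # m
    step_time_cv: float = 0.04
    step_time_asymmetry: float = 0.0
    ml_sway_amplitude: float = 0.035  # m
    keypoint_noise_sd: float = 0.0
    n_steps: int = 10
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if min(self.cadence, self.step_length, self.step_width, self.frame_rate) <= 0:
            raise ValueError("cadence, step_length, step_width, frame_rate must be positive")
        if not 0.0 <= self.step_time_asymmetry <= 0.5:
            raise ValueError("step_time_asymmetry must be in [0, 0.5]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about a bout, for use as a test oracle."""

    strike_times: np.ndarray
    strike_sides: tuple[str, ...]
    params: GaitParams
    severity: float | None = None
    score_probs_updrs: np.ndarray | None = None
    score_probs_sas: np.ndarray | None = None


def _step_times(params: GaitParams, rng: np.random.Generator) -> tuple[np.ndarray, tuple[str, ...]]:
    base = 60.0 / params.cadence
    sides = tuple("left" if k % 2 == 0 else "right" for k in range(params.n_steps))
    means = np.array(
        [base * (1 - params.step_time_asymmetry / 2) if s == "left" else base * (1 + params.step_time_asymmetry / 2) for s in sides]
    )
    jitter = np.clip(rng.standard_normal(params.n_steps), -3, 3) * params.step_time_cv
    times = means * (1.0 + jitter)
    if np.any(times < 0.15):
        raise ValueError("step-time parameters imply overlapping strikes")
    return times, sides


def _skeleton_3d(
    params: GaitParams,
    strike_times: np.ndarray,
    sides: tuple[str, ...],
    n_frames: int,
) -> dict[str, np.ndarray]:
    """Sample the 25-joint kinematic template: x ML (left +), y up, z AP, metres."""
    fs = params.frame_rate
    t = np.arange(n_frames) / fs
    base_T = 60.0 / params.cadence
    speed = params.step_length / base_T

    # the pelvis is stationary until walking starts one nominal step before
    # the first strike, then advances at constant speed
    walk_start = max(strike_times[0] - base_T, 0.0)
    pelvis_z = speed * np.maximum(t - walk_start, 0.0)
    phase = np.pi * (t - strike_times[0]) / base_T
    pelvis_x = params.ml_sway_amplitude * np.sin(phase)
    pelvis_y = PELVIS_HEIGHT + 0.015 * np.cos(2 * phase)

    # per-foot landing schedule: foot lands half a step length ahead of the pelvis
    landings: dict[str, list[tuple[float, float]]] = {"left": [], "right": []}
    for t_k, side in zip(strike_times, sides):
        pelvis_at_strike = speed * max(t_k - walk_start, 0.0)
        landings[side].append((t_k, pelvis_at_strike + params.step_length / 2.0))

    ankle = {}
    for side, ml_sign in (("left", +1.0), ("right", -1.0)):
        z = np.empty(n_frames)
        y = np.full(n_frames, STANCE_ANKLE_HEIGHT)
        events = landings[side]
        stride = 2 * base_T
        pos_prev = (events[0][1] - 2 * params.step_length) if events else -params.step_length / 2
        z[:] = pos_prev
        for idx, (t_k, pos_k) in enumerate(events):
            prev_strike = events[idx - 1][0] if idx > 0 else None
            t_sw = SWING_FRACTION * ((t_k - prev_strike) if prev_strike is not None else stride)
            start = max(0.0, t_k - t_sw)
            in_swing = (t >= start) & (t <= t_k)
            s = np.clip((t[in_swing] - start) / max(t_k - start, 1e-9), 0.0, 1.0)
            z[in_swing] = pos_prev + (pos_k - pos_prev) * (1 - np.cos(np.pi * s)) / 2.0
            # raised-cosine lift, then a linear descent that ends with nonzero
            # downward velocity: heel strike is an impact, the foot keeps
            # descending until contact and stops abruptly
            lift = np.where(
                s <= LIFT_FRACTION,
                (1 - np.cos(np.pi * s / LIFT_FRACTION)) / 2.0,
                (1.0 - s) / (1.0 - LIFT_FRACTION),
            )
            y[in_swing] = STANCE_ANKLE_HEIGHT + SWING_AMPLITUDE * lift
            z[t > t_k] = pos_k
            pos_prev = pos_k
        x = np.full(n_frames, ml_sign * params.step_width / 2.0)
        ankle[side] = np.column_stack([x, y, z])

    def stacked(x, y, z):
        return np.column_stack([np.broadcast_to(x, n_frames), np.broadcast_to(y, n_frames), np.broadcast_to(z, n_frames)])

    pelvis = stacked(pelvis_x, pelvis_y, pelvis_z)
    joints: dict[str, np.ndarray] = {"spine_base": pelvis}
    hip = {
        "left": pelvis + np.array([+HIP_WIDTH / 2, 0.0, 0.0]),
        "right": pelvis + np.array([-HIP_WIDTH / 2, 0.0, 0.0]),
    }
    joints["hip_left"], joints["hip_right"] = hip["left"], hip["right"]
    joints["ankle_left"], joints["ankle_right"] = ankle["left"], ankle["right"]
    for side in ("left", "right"):
        joints[f"knee_{side}"] = 0.5 * (hip[side] + ankle[side]) + np.array([0.0, 0.02, 0.0])
        joints[f"foot_{side}"] = ankle[side] + np.array([0.0, -0.05, 0.12])
    trunk = {
        "spine_mid": (0.0, 0.30, 0.0),
        "spine_shoulder": (0.0, 0.48, 0.0),
        "neck": (0.0, 0.55, 0.0),
        "head": (0.0, 0.70, 0.0),
    }
    for name, off in trunk.items():
        joints[name] = pelvis + np.array(off)
    arm = {"shoulder": (0.19, 0.50), "elbow": (0.22, 0.24), "wrist": (0.23, 0.00)}
    for side, sign in (("left", +1.0), ("right", -1.0)):
        for part, (dx, dy) in arm.items():
            joints[f"{part}_{side}"] = pelvis + np.array([sign * dx, dy, 0.0])
        joints[f"hand_{side}"] = joints[f"wrist_{side}"] + np.array([0.0, -0.05, 0.02])
        joints[f"hand_tip_{side}"] = joints[f"hand_{side}"] + np.array([0.0, -0.05, 0.01])
        joints[f"thumb_{side}"] = joints[f"hand_{side}"] + np.array([sign * 0.03, 0.0, 0.02])
    return joints


# MPII joint -> source joint of the 3D template
_MPII_FROM_3D = {
    "head_top": "head",
    "upper_neck": "neck",
    "thorax": "spine_shoulder",
    "pelvis": "spine_base",
    "l_shoulder": "shoulder_left",
    "l_elbow": "elbow_left",
    "l_wrist": "wrist_left",
    "r_shoulder": "shoulder_right",
    "r_elbow": "elbow_right",
    "r_wrist": "wrist_right",
    "l_hip": "hip_left",
    "r_hip": "hip_right",
    "l_knee": "knee_left",
    "r_knee": "knee_right",
    "l_ankle": "ankle_left",
    "r_ankle": "ankle_right",
}


def _project_2d(
    joints3d: dict[str, np.ndarray],
    camera_distance_extra: float = 0.0,
) -> dict[str, np.ndarray]:
    """Perspective projection onto the image plane of a camera ahead of the walker.

    The camera sits ``CAMERA_MARGIN`` (+ any extra) metres beyond the
    walker's final position at ``CAMERA_HEIGHT`` metres, looking straight
    back down the walking axis; image u grows rightward, v downward.
    """
    z_end = max(arr[:, 2].max() for arr in joints3d.values())
    z_cam = z_end + CAMERA_MARGIN + camera_distance_extra
    out = {}
    for mpii, src in _MPII_FROM_3D.items():
        p = joints3d[src]
        depth = z_cam - p[:, 2]
        u = FOCAL_PX * (-p[:, 0]) / depth + PRINCIPAL[0]  # walker's left appears image-right
        v = FOCAL_PX * (CAMERA_HEIGHT - p[:, 1]) / depth + PRINCIPAL[1]
        out[mpii] = np.column_stack([u, v])
    return out


def simulate_bout(
    params: GaitParams,
    dim: str = "2d",
    seed: int = 0,
    *,
    bout_id: str = "bout",
    participant_id: str = "p0",
    date: _dt.date = _dt.date(2020, 1, 1),
    camera_distance_extra: float = 0.0,
    lead_in: float = 0.5,
    tail: float = 0.5,
) -> tuple[WalkingBout, GroundTruth]:
    """Simulate one walking bout and return it with its ground truth.

    ``dim`` selects metric 3D output (25-joint skeleton) or the 2D pixel
    projection (MPII joints, confidence 1).  ``camera_distance_extra``
    pushes the camera further away without changing the walk, for
    exercising distance normalization.  Deterministic under ``seed``.
    """
    if dim not in ("2d", "3d"):
        raise ValueError("dim must be '2d' or '3d'")
    rng = np.random.default_rng(seed)
    step_times, sides = _step_times(params, rng)
    # a short stationary lead-in before the first step, as in triggered
    # hallway recordings where capture starts as the person approaches
    strike_times = lead_in + np.cumsum(step_times)
    duration = float(strike_times[-1] + tail)
    if duration > 30.0:
        raise ValueError(f"bout duration {duration:.1f}s exceeds the 30 s recording window")
    n_frames = int(round(duration * params.frame_rate)) + 1
    joints3d = _skeleton_3d(params, strike_times, sides, n_frames)
    truth = GroundTruth(strike_times=strike_times, strike_sides=sides, params=params)

    if dim == "3d":
        data = {
            name: arr + rng.normal(0.0, params.keypoint_noise_sd, arr.shape)
            if params.keypoint_noise_sd > 0
            else arr.copy()
            for name, arr in joints3d.items()
        }
        bout = WalkingBout(
            bout_id=bout_id,
            participant_id=participant_id,
            date=date,
            frame_rate=params.frame_rate,
            ndim=3,
            data=data,
        )
        return bout, truth

    data2d = _project_2d(joints3d, camera_distance_extra)
    if params.keypoint_noise_sd > 0:
        hip_px = np.linalg.norm(data2d["l_hip"] - data2d["r_hip"], axis=1)
        for name in data2d:
            noise = rng.normal(0.0, params.keypoint_noise_sd, (len(hip_px), 2))
            data2d[name] = data2d[name] + noise * hip_px[:, None]
    conf = {name: np.ones(n_frames) for name in data2d}
    bout = WalkingBout(
        bout_id=bout_id,
        participant_id=participant_id,
        date=date,
        frame_rate=params.frame_rate,
        ndim=2,
        data=data2d,
        confidence=conf,
    )
    return bout, truth


@dataclass(frozen=True)
class SeverityModel:
    """Latent-severity cohort model.

    ``effect`` maps a latent severity scalar (roughly 0 = unimpaired,
    4 = severe) monotonically onto gait parameters; ordinal scores come
    from ``logit P(score <= j) = theta_j - latent_scale * severity`` with
    separate cut-points for the two rating scales.
    """

    base: GaitParams = field(default_factory=GaitParams)
    cadence_slope: float = -7.0  # steps/min per severity unit
    step_length_slope: float = -0.075  # m
    step_time_cv_slope: float = 0.015
    asymmetry_slope: float = 0.04
    #: sway amplitude barely grows with severity; medio-lateral *velocity*
    #: falls through the cadence channel instead
    sway_slope: float = 0.002  # m
    step_width_slope: float = 0.012  # m
    cutpoints_updrs: tuple[float, ...] = (-1.2, 0.8, 2.8, 4.6)
    cutpoints_sas: tuple[float, ...] = (-0.6, 1.4, 3.4, 5.2)
    latent_scale: float = 1.5
    baseline_mean: float = 0.9
    baseline_sd: float = 1.1
    drift_sd: float = 0.9
    bout_noise_sd: float = 0.3
    #: within-severity biological variability: independent multiplicative
    #: jitter (lognormal sigma) applied per bout to each gait parameter, so
    #: severity does not determine the gait pattern exactly
    param_jitter: float = 0.18

    def params_for(self, severity: float, **overrides) -> GaitParams:
        """Monotone severity -> gait-parameter map, clipped to physiological ranges."""
        b = self.base
        return replace(
            b,
            cadence=float(np.clip(b.cadence + self.cadence_slope * severity, 55.0, 140.0)),
            step_length=float(np.clip(b.step_length + self.step_length_slope * severity, 0.15, 0.85)),
            step_time_cv=float(np.clip(b.step_time_cv + self.step_time_cv_slope * severity, 0.005, 0.25)),
            step_time_asymmetry=float(
                np.clip(b.step_time_asymmetry + self.asymmetry_slope * severity, 0.0, 0.35)
            ),
            ml_sway_amplitude=float(np.clip(b.ml_sway_amplitude + self.sway_slope * severity, 0.005, 0.09)),
            step_width=float(np.clip(b.step_width + self.step_width_slope * severity, 0.04, 0.25)),
            **overrides,
        )

    def sample_params(
        self, severity: float, rng: np.random.Generator, **overrides
    ) -> GaitParams:
        """Severity map plus independent per-parameter biological jitter."""
        mapped = self.params_for(severity)
        if self.param_jitter <= 0:
            return replace(mapped, **overrides)
        jit = lambda v: v * float(np.exp(rng.normal(0.0, self.param_jitter)))  # noqa: E731
        jittered = replace(
            mapped,
            cadence=float(np.clip(jit(mapped.cadence), 55.0, 140.0)),
            step_length=float(np.clip(jit(mapped.step_length), 0.15, 0.85)),
            step_time_cv=float(np.clip(jit(mapped.step_time_cv), 0.005, 0.25)),
            step_time_asymmetry=float(np.clip(jit(mapped.step_time_asymmetry), 0.0, 0.35)),
            ml_sway_amplitude=float(np.clip(jit(mapped.ml_sway_amplitude), 0.005, 0.09)),
            step_width=float(np.clip(jit(mapped.step_width), 0.04, 0.25)),
        )
        return replace(jittered, **overrides)

    def score_probs(self, severity: float, scale: str = "updrs") -> np.ndarray:
        theta = np.asarray(self.cutpoints_updrs if scale == "updrs" else self.cutpoints_sas)
        cum = expit(theta - self.latent_scale * severity)
        cum = np.concatenate([[0.0], cum, [1.0]])
        return np.diff(cum)

    def null(self) -> "SeverityModel":
        """Copy with all gait-parameter slopes zeroed (features independent of scores)."""
        return replace(
            self,
            cadence_slope=0.0,
            step_length_slope=0.0,
            step_time_cv_slope=0.0,
            asymmetry_slope=0.0,
            sway_slope=0.0,
            step_width_slope=0.0,
        )


def simulate_cohort(
    n_participants: int = 14,
    bouts_per_participant: int = 28,
    model: SeverityModel | None = None,
    seed: int = 0,
    dim: str = "2d",
    noise_sd: float | None = None,
) -> tuple[list[WalkingBout], pd.DataFrame, list[GroundTruth]]:
    """Simulate a longitudinal cohort of walking bouts with ordinal ratings.

    Per participant: age ~ Normal(76, 9) truncated to [60, 95], sex male
    with probability 0.57, one bout per day.  Per bout: severity =
    participant baseline + piecewise-linear drift over the recording
    period + noise; gait parameters via the severity map; UPDRS-gait and
    SAS-gait drawn from the ordinal model.  ``noise_sd`` overrides the
    keypoint noise (hip-widths for 2D, metres for 3D; default 0.02 / 5 mm).

    Returns (bouts, metadata table, per-bout ground truths).
    """
    model = model or SeverityModel()
    if noise_sd is None:
        noise_sd = 0.02 if dim == "2d" else 0.005
    rng = np.random.default_rng(seed)
    bouts: list[WalkingBout] = []
    truths: list[GroundTruth] = []
    rows = []
    start = _dt.date(2020, 1, 6)
    for i in range(n_participants):
        pid = f"p{i:02d}"
        age = float(np.clip(rng.normal(76.0, 9.0), 60.0, 95.0))
        sex = "male" if rng.random() < 0.57 else "female"
        baseline = rng.normal(model.baseline_mean, model.baseline_sd)
        # piecewise-linear drift: two linear segments with a random breakpoint,
        # emulating a medication change partway through the recording period
        drift_break = rng.uniform(0.3, 0.7)
        d0, d1, d2 = rng.normal(0.0, model.drift_sd, 3)
        for j in range(bouts_per_participant):
            frac = j / max(bouts_per_participant - 1, 1)
            if frac <= drift_break:
                drift = d0 + (d1 - d0) * frac / drift_break
            else:
                drift = d1 + (d2 - d1) * (frac - drift_break) / (1 - drift_break)
            severity = baseline + drift + rng.normal(0.0, model.bout_noise_sd)
            # a fixed hallway is walked end to end, so shorter steps mean
            # more captured steps per bout
            hallway = rng.uniform(4.0, 6.5)
            base = model.sample_params(severity, rng)
            n_steps = int(np.clip(round(hallway / base.step_length), 5, 24))
            params = replace(base, n_steps=n_steps, keypoint_noise_sd=noise_sd)
            bout_seed = int(rng.integers(2**31))
            bout_id = f"{pid}_b{j:03d}"
            date = start + _dt.timedelta(days=int(j))
            try:
                bout, truth = simulate_bout(
                    params, dim=dim, seed=bout_seed, bout_id=bout_id, participant_id=pid, date=date
                )
            except ValueError:
                continue  # pathological parameter draw; skip the bout
            p_updrs = model.score_probs(severity, "updrs")
            p_sas = model.score_probs(severity, "sas")
            updrs = int(rng.choice(5, p=p_updrs))
            sas = int(rng.choice(5, p=p_sas))
            truth = replace(
                truth, severity=severity, score_probs_updrs=p_updrs, score_probs_sas=p_sas
            )
            bouts.append(bout)
            truths.append(truth)
            rows.append(
                {
                    "bout_id": bout_id,
                    "participant_id": pid,
                    "date": date.isoformat(),
                    "age": age,
                    "sex": sex,
                    "updrs_gait": updrs,
                    "sas_gait": sas,
                    "frame_rate": params.frame_rate,
                }
            )
    meta = pd.DataFrame(rows)
    return bouts, meta, truths
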