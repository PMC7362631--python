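"""The eight 2D gait features computed from pixel keypoints.

Pixel coordinates carry no metric scale and the walker's distance to the
camera changes during the bout, so every distance is expressed in
*hip-width units*: within-frame distances are divided by that frame's
inter-hip pixel distance.  Quantities that involve positions over time
(ankle height for strike detection, the hip-centre velocity feeding the
extrapolated centre of mass) are additionally taken relative to the
per-frame hip centre, which makes every feature exactly invariant to
uniform scaling *and* translation of the pixel coordinates.

Features (one bout -> one vector): number of steps, cadence, symmetry
index (SI) of step time, coefficient of variation (CV) of step time,
average step width, CV of step width, average margin of stability (MOS)
and average per-step minimum MOS.  Depth-dependent features (step length,
walking speed) are not computable from a single 2D view and are not
attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from gaitscore.config import StepDetectionConfig, XcomParams
from gaitscore.io_types import FootStrikeSeries, WalkingBout, interpolate_gaps
from gaitscore._events import (
    detect_strikes_from_heights,
    estimate_velocity,
    moving_average,
)

__all__ = [
    "GaitFeatures2D",
    "normalize_by_hip_distance",
    "hip_relative_normalized",
    "ankle_vertical_velocity",
    "detect_foot_strikes",
    "cadence",
    "symmetry_index",
    "coefficient_of_variation",
    "step_width_series",
    "margin_of_stability",
    "extract_features_2d",
    "FEATURES_2D",
]

#: canonical 2D feature column order (tidy-CSV output)
FEATURES_2D = (
    "steps_of_walk",
    "cadence",
    "si_step_time",
    "cv_step_time",
    "avg_step_width",
    "avg_mos",
    "avg_min_mos",
    "cv_step_width",
)


@dataclass(frozen=True)
class GaitFeatures2D:
    """2D gait feature vector for one bout; NaN marks an undefined feature.

    Units: cadence steps/min; SI in percent; CVs unitless; widths and MOS
    in hip-width units.
    """

    steps_of_walk: float
    cadence: float
    si_step_time: float
    cv_step_time: float
    avg_step_width: float
    avg_mos: float
    avg_min_mos: float
    cv_step_width: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _hip_distance(bout: WalkingBout) -> np.ndarray:
    lh, rh = bout.joint("l_hip"), bout.joint("r_hip")
    return np.linalg.norm(lh - rh, axis=1)


def normalize_by_hip_distance(bout: WalkingBout, eps: float = 1e-9) -> WalkingBout:
    """Divide every coordinate by the same-frame inter-hip pixel distance.

    Output coordinates are in hip-width units, cancelling the walker's
    changing distance to the camera.  Frames whose hips coincide (distance
    below ``eps``) are marked unusable (NaN).
    """
    d = _hip_distance(bout)
    scale = np.where(d > eps, d, np.nan)
    return bout.copy_with({name: arr / scale[:, None] for name, arr in bout.data.items()})


def _hip_scale(bout: WalkingBout, window: int = 1, eps: float = 1e-9) -> np.ndarray:
    """Per-frame normalization scale (pixels per hip-width).

    With ``window > 1`` the raw inter-hip distance is smoothed with a
    moving average: the true scale tracks the slowly changing distance to
    the camera, while the raw per-frame distance carries the full keypoint
    noise of both hips.
    """
    d = _hip_distance(bout)
    if window > 1:
        d = moving_average(d, window)
    return np.where(d > eps, d, np.nan)


def hip_relative_normalized(
    bout: WalkingBout, eps: float = 1e-9, scale_window: int = 1
) -> WalkingBout:
    """Hip-centred, hip-width-normalized coordinates.

    Subtracting the per-frame hip centre before dividing by the hip
    distance removes the global image position, so derived kinematics are
    exactly translation- as well as scale-invariant.  The vertical axis is
    flipped (height = -v) so that larger values mean physically higher.
    """
    scale = _hip_scale(bout, scale_window, eps)
    centre = (bout.joint("l_hip") + bout.joint("r_hip")) / 2.0
    flip = np.array([1.0, -1.0])
    return bout.copy_with(
        {name: (arr - centre) * flip / scale[:, None] for name, arr in bout.data.items()}
    )


def _prepared(bout: WalkingBout, cfg: StepDetectionConfig) -> WalkingBout:
    """Gap-filled, hip-centred, normalized copy used by all kinematic features."""
    return hip_relative_normalized(
        interpolate_gaps(bout, cfg.max_gap_frames), scale_window=cfg.reference_window
    )


def normalized_ankle_height(bout: WalkingBout, side: str, cfg: StepDetectionConfig) -> np.ndarray:
    """Ankle height for strike detection, hip-width units, larger = higher.

    The vertical reference is the pelvis path lowpassed over roughly a
    stride (``cfg.reference_window``): subtracting it cancels image
    translation and the walker's changing distance to the camera exactly,
    while leaving the swing-frequency ankle motion untouched.
    """
    gap_filled = interpolate_gaps(bout, cfg.max_gap_frames)
    name = {"left": "l_ankle", "right": "r_ankle"}[side]
    scale = _hip_scale(gap_filled, cfg.reference_window)
    centre_v = (gap_filled.joint("l_hip")[:, 1] + gap_filled.joint("r_hip")[:, 1]) / 2.0
    reference = moving_average(centre_v, cfg.reference_window)
    return -(gap_filled.joint(name)[:, 1] - reference) / scale


def ankle_vertical_velocity(
    bout: WalkingBout, side: str, cfg: StepDetectionConfig | None = None
) -> np.ndarray:
    """Time derivative of the normalized ankle height (hip-widths/s).

    The height is the pelvis-referenced, hip-width-normalized vertical
    ankle position (see :func:`normalized_ankle_height`); it is smoothed
    with ``cfg.smoothing_window`` frames before central differencing.
    Gaps propagate as NaN.
    """
    cfg = cfg or StepDetectionConfig()
    height = normalized_ankle_height(bout, side, cfg)
    if np.isfinite(height).sum() < 2:
        raise ValueError(f"{side} ankle usable in fewer than 2 frames")
    return estimate_velocity(height, bout.frame_rate, cfg.smoothing_window)


def detect_foot_strikes(bout: WalkingBout, cfg: StepDetectionConfig | None = None) -> FootStrikeSeries:
    """Detect foot strikes from the 35%-of-peak downward ankle-velocity rule."""
    cfg = cfg or StepDetectionConfig()
    return detect_strikes_from_heights(
        normalized_ankle_height(bout, "left", cfg),
        normalized_ankle_height(bout, "right", cfg),
        bout.frame_rate,
        cfg,
    )


def cadence(strikes: FootStrikeSeries, duration_walked: float | None = None) -> float:
    """Steps per minute from the detected strike series.

    Estimated as steps-per-unit-time over the strike-to-strike span:
    ``(n_strikes - 1) / (t_last - t_first) * 60``.  Undefined (NaN) with
    fewer than 2 strikes.  ``duration_walked``, when given, overrides the
    denominator.
    """
    if strikes.n_strikes < 2:
        return float("nan")
    span = duration_walked if duration_walked is not None else strikes.times[-1] - strikes.times[0]
    if span <= 0:
        return float("nan")
    return (strikes.n_strikes - 1) / span * 60.0


def symmetry_index(left_vals: np.ndarray, right_vals: np.ndarray) -> float:
    """Robinson symmetry index in percent: |L - R| / ((L + R)/2) * 100 on side means."""
    left_vals = np.asarray(left_vals, dtype=float)
    right_vals = np.asarray(right_vals, dtype=float)
    if left_vals.size == 0 or right_vals.size == 0:
        raise ValueError("symmetry_index needs at least one value per side")
    ml, mr = np.nanmean(left_vals), np.nanmean(right_vals)
    denom = (ml + mr) / 2.0
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return abs(ml - mr) / denom * 100.0


def coefficient_of_variation(vals: np.ndarray) -> float:
    """Sample standard deviation divided by mean; NaN if < 2 values or zero mean."""
    vals = np.asarray(vals, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return float("nan")
    mean = vals.mean()
    if mean == 0:
        return float("nan")
    return float(vals.std(ddof=1) / mean)


def _strike_frames(strikes: FootStrikeSeries, fs: float, n_frames: int) -> np.ndarray:
    return np.clip(np.round(strikes.times * fs).astype(int), 0, n_frames - 1)


def step_width_series(
    bout: WalkingBout, strikes: FootStrikeSeries, cfg: StepDetectionConfig | None = None
) -> np.ndarray:
    """Per-step horizontal ankle separation (hip-width units) at strike frames."""
    cfg = cfg or StepDetectionConfig()
    if strikes.n_strikes < 2:
        return np.empty(0)
    prep = _prepared(bout, cfg)
    frames = _strike_frames(strikes, bout.frame_rate, bout.n_frames)
    la = prep.joint("l_ankle")[:, 0]
    ra = prep.joint("r_ankle")[:, 0]
    return np.abs(la[frames] - ra[frames])


def margin_of_stability(
    bout: WalkingBout,
    strikes: FootStrikeSeries,
    p: XcomParams | None = None,
    cfg: StepDetectionConfig | None = None,
) -> tuple[float, float]:
    """Average and average per-step minimum margin of stability (hip-width units).

    The extrapolated centre of mass (XCoM) is the hip-centre lateral
    position plus ``velocity_scale`` times its lateral velocity; the margin
    is its signed lateral distance to the stance ankle, taken positive when
    the XCoM lies medial to (inside) the stance foot.  The stance foot per
    frame is the ankle with the smaller absolute vertical velocity.
    Frames outside the strike-delimited portion of the walk are ignored.
    Returns ``(avg_mos, avg_min_mos)``: the mean absolute margin over
    frames, and the mean over steps of each step's least-stable (minimum
    signed) margin.
    """
    p = p or XcomParams()
    cfg = cfg or StepDetectionConfig()
    if strikes.n_strikes < 2:
        return float("nan"), float("nan")
    prep = _prepared(bout, cfg)
    fs = bout.frame_rate
    la, ra = prep.joint("l_ankle"), prep.joint("r_ankle")

    # hip-centre lateral velocity, measured from frame-to-frame displacement of
    # the raw hip centre scaled by the per-frame hip distance (translation-safe)
    centre_u_rel = np.zeros(bout.n_frames)  # hip centre is the origin of prep coords
    raw_centre = (bout.joint("l_hip") + bout.joint("r_hip")) / 2.0
    vel_u = estimate_velocity(raw_centre[:, 0], fs, cfg.smoothing_window) / _hip_scale(
        bout, cfg.reference_window
    )
    xcom = centre_u_rel + p.velocity_scale * vel_u

    vla = estimate_velocity(la[:, 1], fs, cfg.smoothing_window)
    vra = estimate_velocity(ra[:, 1], fs, cfg.smoothing_window)
    stance_is_left = np.abs(vla) <= np.abs(vra)
    ankle_u = np.where(stance_is_left, la[:, 0], ra[:, 0])

    # sign: positive margin when the XCoM is medial to the stance ankle
    outward = np.sign(ankle_u - centre_u_rel)
    outward[outward == 0] = 1.0
    mos = outward * (ankle_u - xcom)

    frames = _strike_frames(strikes, fs, bout.n_frames)
    lo, hi = frames[0], frames[-1]
    window = mos[lo : hi + 1]
    if not np.isfinite(window).any():
        return float("nan"), float("nan")
    avg_mos = float(np.nanmean(np.abs(window)))
    step_minima = []
    for a, b in zip(frames[:-1], frames[1:]):
        seg = mos[a : b + 1]
        if np.isfinite(seg).any():
            step_minima.append(np.nanmin(seg))
    avg_min_mos = float(np.mean(step_minima)) if step_minima else float("nan")
    return avg_mos, avg_min_mos


def extract_features_2d(
    bout: WalkingBout,
    cfg: StepDetectionConfig | None = None,
    p: XcomParams | None = None,
    strikes: FootStrikeSeries | None = None,
) -> GaitFeatures2D:
    """Compute the full 8-feature 2D vector for one bout.

    Features that cannot be computed (too few strikes, missing joints at
    the relevant frames) come back NaN rather than raising.
    """
    cfg = cfg or StepDetectionConfig()
    p = p or XcomParams()
    if strikes is None:
        strikes = detect_foot_strikes(bout, cfg)
    st = strikes.step_times
    left_st = strikes.side_step_times("left")
    right_st = strikes.side_step_times("right")
    si = (
        symmetry_index(left_st, right_st)
        if left_st.size and right_st.size
        else float("nan")
    )
    widths = step_width_series(bout, strikes, cfg)
    widths = widths[np.isfinite(widths)] if widths.size else widths
    avg_mos, avg_min_mos = margin_of_stability(bout, strikes, p, cfg)
    return GaitFeatures2D(
        steps_of_walk=float(strikes.n_steps),
        cadence=cadence(strikes),
        si_step_time=si,
        cv_step_time=coefficient_of_variation(st),
        avg_step_width=float(np.mean(widths)) if widths.size else float("nan"),
        avg_mos=avg_mos,
        avg_min_mos=avg_min_mos,
        cv_step_width=coefficient_of_variation(widths),
    )
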