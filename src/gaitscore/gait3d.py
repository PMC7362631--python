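"""The sixteen 3D gait features computed from metric joint trajectories.

Coordinates follow the depth-sensor convention: x medio-lateral, y
vertical (up), z anterior-posterior, metres.  No axis is trusted as the
walking direction: it is estimated per bout as the first principal axis
of the horizontal sacrum path and oriented along the net displacement,
which makes every feature invariant to rigid translation and to rotation
about the vertical axis.

Feature groups: spatiotemporal (walking speed, step length/time/width,
cadence), variability (CVs of step length/time/width), symmetry
(symmetry angles of step length/time/width), sacrum medio-lateral
dynamics (RMS velocity, SD, range of motion of the detrended ML path),
and lateral stability (average and minimum margin of stability, mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from gaitscore.config import GRAVITY, METRIC_STEP_DETECTION, StepDetectionConfig
from gaitscore.io_types import FootStrikeSeries, WalkingBout, interpolate_gaps
from gaitscore._events import central_velocity, detect_strikes_from_heights, estimate_velocity

__all__ = [
    "GaitFeatures3D",
    "detect_foot_strikes_3d",
    "walking_frame",
    "spatiotemporal_3d",
    "symmetry_angle",
    "sacrum_ml_dynamics",
    "margin_of_stability_3d",
    "estimate_leg_length",
    "extract_features_3d",
    "FEATURES_3D",
]

FEATURES_3D = (
    "walking_speed",
    "step_length",
    "step_time",
    "step_width",
    "cadence",
    "cv_step_length",
    "cv_step_time",
    "cv_step_width",
    "sa_step_length",
    "sa_step_time",
    "sa_step_width",
    "rms_sacrum_ml_velocity",
    "sd_sacrum_ml",
    "rom_sacrum_ml",
    "avg_mos",
    "min_mos",
)


@dataclass(frozen=True)
class GaitFeatures3D:
    """3D gait feature vector for one bout; NaN marks an undefined feature.

    Units: speed m/s, lengths/widths m, times s, cadence steps/min,
    symmetry angles degrees (as percent-of-90-degree deviations, signed),
    sacrum ML terms m and m/s, MOS terms mm.
    """

    walking_speed: float
    step_length: float
    step_time: float
    step_width: float
    cadence: float
    cv_step_length: float
    cv_step_time: float
    cv_step_width: float
    sa_step_length: float
    sa_step_time: float
    sa_step_width: float
    rms_sacrum_ml_velocity: float
    sd_sacrum_ml: float
    rom_sacrum_ml: float
    avg_mos: float
    min_mos: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def detect_foot_strikes_3d(
    bout: WalkingBout, cfg: StepDetectionConfig | None = None
) -> FootStrikeSeries:
    """Apply the 35%-of-peak downward ankle-velocity rule to metric ankle heights."""
    cfg = cfg or METRIC_STEP_DETECTION
    prep = interpolate_gaps(bout, cfg.max_gap_frames)
    return detect_strikes_from_heights(
        prep.joint("ankle_left")[:, 1], prep.joint("ankle_right")[:, 1], bout.frame_rate, cfg
    )


def walking_frame(bout: WalkingBout) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (ap, ml) horizontal unit vectors from the sacrum path.

    ap is the first principal axis of the horizontal (x, z) sacrum
    trajectory, oriented along the net displacement; ml = up x ap, i.e.
    the walker's left.  Falls back to +z when the path is degenerate.
    """
    sac = bout.joint("spine_base")
    horiz = sac[:, [0, 2]]
    horiz = horiz[np.isfinite(horiz).all(axis=1)]
    if horiz.shape[0] < 2:
        ap2 = np.array([0.0, 1.0])
    else:
        centred = horiz - horiz.mean(axis=0)
        cov = centred.T @ centred
        w, v = np.linalg.eigh(cov)
        if not np.isfinite(w).all() or w.max() < 1e-12:
            ap2 = np.array([0.0, 1.0])  # stationary path: fall back to +z
        else:
            ap2 = v[:, np.argmax(w)]
            net = horiz[-1] - horiz[0]
            if float(net @ ap2) < 0:
                ap2 = -ap2
    ap = np.array([ap2[0], 0.0, ap2[1]])
    # ml = up x ap with up = +y
    ml = np.array([ap[2], 0.0, -ap[0]])
    return ap, ml


def _project(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return points @ axis


def _strike_frames(strikes: FootStrikeSeries, fs: float, n_frames: int) -> np.ndarray:
    return np.clip(np.round(strikes.times * fs).astype(int), 0, n_frames - 1)


def spatiotemporal_3d(
    bout: WalkingBout, strikes: FootStrikeSeries, cfg: StepDetectionConfig | None = None
) -> dict[str, float]:
    """Spatiotemporal, variability and symmetry features from strikes and sacrum.

    Step length is the anterior-posterior sacrum displacement between
    consecutive (contralateral) strikes; step width the ML ankle
    separation at the strike frame; walking speed the net AP sacrum
    displacement over the strike-to-strike span.
    """
    cfg = cfg or METRIC_STEP_DETECTION
    nan = float("nan")
    out = {k: nan for k in FEATURES_3D[:11]}
    if strikes.n_strikes < 2:
        return out
    prep = interpolate_gaps(bout, cfg.max_gap_frames)
    ap, ml = walking_frame(prep)
    sac_ap = _project(prep.joint("spine_base"), ap)
    frames = _strike_frames(strikes, bout.frame_rate, bout.n_frames)

    step_lengths = np.diff(sac_ap[frames])
    step_times = strikes.step_times
    la_ml = _project(prep.joint("ankle_left"), ml)
    ra_ml = _project(prep.joint("ankle_right"), ml)
    step_widths = np.abs(la_ml[frames] - ra_ml[frames])[1:]
    sides = strikes.step_sides

    span = strikes.times[-1] - strikes.times[0]
    disp = sac_ap[frames[-1]] - sac_ap[frames[0]]
    out["walking_speed"] = disp / span if span > 0 and abs(disp) > 1e-9 else nan
    out["step_length"] = float(np.nanmean(step_lengths)) if step_lengths.size else nan
    out["step_time"] = float(np.mean(step_times)) if step_times.size else nan
    out["step_width"] = float(np.nanmean(step_widths)) if step_widths.size else nan
    out["cadence"] = (strikes.n_strikes - 1) / span * 60.0 if span > 0 else nan

    from gaitscore.gait2d import coefficient_of_variation

    out["cv_step_length"] = coefficient_of_variation(step_lengths)
    out["cv_step_time"] = coefficient_of_variation(step_times)
    out["cv_step_width"] = coefficient_of_variation(step_widths)

    def _side_mean(values: np.ndarray, side: str) -> float:
        mask = np.array([s == side for s in sides])
        vals = values[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else nan

    for name, values in (
        ("sa_step_length", step_lengths),
        ("sa_step_time", step_times),
        ("sa_step_width", step_widths),
    ):
        lm, rm = _side_mean(values, "left"), _side_mean(values, "right")
        out[name] = symmetry_angle(lm, rm) if np.isfinite(lm) and np.isfinite(rm) else nan
    return out


def symmetry_angle(left_mean: float, right_mean: float) -> float:
    """Symmetry angle in degrees: (45 - atan2(left, right) [deg]) / 90 * 100.

    Zero for perfect symmetry; swapping sides flips the sign (atan(L/R)
    and atan(R/L) are complementary).  Undefined when both sides are zero.
    """
    if left_mean == 0 and right_mean == 0:
        return float("nan")
    ang = math.degrees(math.atan2(left_mean, right_mean))
    return (45.0 - ang) / 90.0 * 100.0


def sacrum_ml_dynamics(bout: WalkingBout, trend_cutoff_hz: float = 0.5) -> tuple[float, float, float]:
    """(RMS ML velocity, SD ML, ROM ML) of the detrended sacrum lateral path.

    The sacrum is projected onto the estimated ML axis, then the
    walking-direction-aligned mean path — everything slower than
    ``trend_cutoff_hz`` — is removed with a zero-phase high-pass, leaving
    the stride-frequency lateral sway free of residual path curvature and
    slow drift the axis estimate leaves behind.  SD and range of motion
    are taken on the residual, the RMS on its time derivative.
    """
    from scipy.signal import butter, filtfilt

    _, ml = walking_frame(bout)
    sac_ml = _project(bout.joint("spine_base"), ml)
    ok = np.isfinite(sac_ml)
    if ok.sum() < 3:
        return float("nan"), float("nan"), float("nan")
    n = sac_ml.size
    fs = bout.frame_rate
    # straight-line component first, through the means of the first and last
    # ~second (local means average the stride-frequency sway out); removing
    # it exactly avoids high-pass edge transients on a drifting path
    w = int(min(max(fs, 3), n // 3))
    if w >= 3 and np.isfinite(sac_ml[:w]).any() and np.isfinite(sac_ml[-w:]).any():
        t = bout.times
        y0, y1 = np.nanmean(sac_ml[:w]), np.nanmean(sac_ml[-w:])
        t0, t1 = np.nanmean(t[:w]), np.nanmean(t[-w:])
        line = y0 + (y1 - y0) / (t1 - t0) * (t - t0)
        resid = sac_ml - line
    else:
        resid = sac_ml - np.nanmean(sac_ml)
    if ok.sum() > 31 and ok.all() and 0 < trend_cutoff_hz < fs / 2:
        b, a = butter(4, trend_cutoff_hz / (fs / 2.0), "highpass")
        resid = filtfilt(b, a, resid)
        # discard the filter's edge transients before taking extremes
        trim = min(int(round(0.75 * fs / trend_cutoff_hz)), resid.size // 4)
        if trim > 0:
            resid = resid[trim:-trim]
    else:
        resid = resid - np.nanmean(resid)
    vel = central_velocity(resid, bout.frame_rate)
    resid_ok = resid[np.isfinite(resid)]
    vel_ok = vel[np.isfinite(vel)]
    rms_vel = float(np.sqrt(np.mean(vel_ok**2))) if vel_ok.size else float("nan")
    sd = float(resid_ok.std(ddof=1)) if resid_ok.size > 1 else float("nan")
    rom = float(resid_ok.max() - resid_ok.min())
    return rms_vel, sd, rom


def estimate_leg_length(bout: WalkingBout, fraction: float = 0.53) -> float:
    """Leg length (m) as a fraction of stature estimated from the skeleton.

    Stature is taken as the median vertical head-to-ankle extent; 53% of
    stature is the conventional greater-trochanter height used for the
    inverted-pendulum eigenfrequency.
    """
    head = bout.joint("head")[:, 1]
    ankles = np.nanmin(
        np.column_stack([bout.joint("ankle_left")[:, 1], bout.joint("ankle_right")[:, 1]]), axis=1
    )
    extent = head - ankles
    extent = extent[np.isfinite(extent)]
    if extent.size == 0:
        raise ValueError("cannot estimate stature: head/ankle joints missing throughout")
    return fraction * float(np.median(extent))


def margin_of_stability_3d(
    bout: WalkingBout,
    strikes: FootStrikeSeries,
    leg_length: float | None = None,
    cfg: StepDetectionConfig | None = None,
    g: float = GRAVITY,
) -> tuple[float, float]:
    """Average and minimum lateral margin of stability, in millimetres.

    XCoM = sacrum ML position + sacrum ML velocity / omega0, with
    omega0 = sqrt(g / leg_length).  The per-frame margin is the signed ML
    distance from the XCoM to the stance-ankle boundary, positive when the
    XCoM lies medial to the stance foot.  The stance foot is the lower
    ankle.  Returns (mean absolute margin over the strike-delimited frames,
    minimum over steps of the per-step minimum signed margin), in mm.
    """
    cfg = cfg or METRIC_STEP_DETECTION
    if strikes.n_strikes < 2:
        return float("nan"), float("nan")
    if leg_length is None:
        leg_length = estimate_leg_length(bout)
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    omega0 = math.sqrt(g / leg_length)

    prep = interpolate_gaps(bout, cfg.max_gap_frames)
    _, ml = walking_frame(prep)
    sac_ml = _project(prep.joint("spine_base"), ml)
    vel_ml = estimate_velocity(sac_ml, bout.frame_rate, cfg.smoothing_window)
    xcom = sac_ml + vel_ml / omega0

    la, ra = prep.joint("ankle_left"), prep.joint("ankle_right")
    stance_is_left = la[:, 1] <= ra[:, 1]
    ankle_ml = np.where(stance_is_left, _project(la, ml), _project(ra, ml))
    outward = np.sign(ankle_ml - sac_ml)
    outward[outward == 0] = 1.0
    mos = outward * (ankle_ml - xcom)

    frames = _strike_frames(strikes, bout.frame_rate, bout.n_frames)
    window = mos[frames[0] : frames[-1] + 1]
    if not np.isfinite(window).any():
        return float("nan"), float("nan")
    avg = float(np.nanmean(np.abs(window))) * 1000.0
    minima = []
    for a, b in zip(frames[:-1], frames[1:]):
        seg = mos[a : b + 1]
        if np.isfinite(seg).any():
            minima.append(np.nanmin(seg))
    mn = float(np.min(minima)) * 1000.0 if minima else float("nan")
    return avg, mn


def extract_features_3d(
    bout: WalkingBout,
    cfg: StepDetectionConfig | None = None,
    leg_length: float | None = None,
    strikes: FootStrikeSeries | None = None,
) -> GaitFeatures3D:
    """Compute the full 16-feature 3D vector for one bout."""
    cfg = cfg or METRIC_STEP_DETECTION
    if strikes is None:
        strikes = detect_foot_strikes_3d(bout, cfg)
    spa = spatiotemporal_3d(bout, strikes, cfg)
    rms_vel, sd_ml, rom_ml = sacrum_ml_dynamics(bout)
    try:
        avg_mos, min_mos = margin_of_stability_3d(bout, strikes, leg_length, cfg)
    except ValueError:
        avg_mos, min_mos = float("nan"), float("nan")
    return GaitFeatures3D(
        rms_sacrum_ml_velocity=rms_vel,
        sd_sacrum_ml=sd_ml,
        rom_sacrum_ml=rom_ml,
        avg_mos=avg_mos,
        min_mos=min_mos,
        **spa,
    )
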