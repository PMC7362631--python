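"""Foot-strike detection from vertical ankle trajectories.

The detector works on the *downward* vertical velocity of each ankle.
During swing the foot lifts, travels and descends; the downward velocity
rises to a prominent peak during the final descent and falls back toward
zero as the foot decelerates into ground contact.  Per cycle — delimited
by successive prominent downward-velocity peaks — the strike is marked at
the first downward crossing of ``peak_fraction`` times that cycle's peak
value after the peak, with the crossing time interpolated between frames.

The left and right series are merged in time; violations of left/right
alternation and implausibly close strike pairs are repaired by dropping
the strike with the smaller velocity-peak prominence.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, savgol_filter

from gaitscore.config import StepDetectionConfig
from gaitscore.io_types import FootStrikeSeries


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """NaN-preserving centred moving average; window 1 is the identity."""
    if window <= 1:
        return x.astype(float)
    out = np.full(x.size, np.nan)
    half = window // 2
    valid = np.isfinite(x)
    for i in np.flatnonzero(valid):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        seg = x[lo:hi]
        seg = seg[np.isfinite(seg)]
        out[i] = seg.mean()
    return out


def central_velocity(x: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference time derivative; one-sided at the ends; NaNs propagate."""
    v = np.full(x.size, np.nan)
    if x.size < 2:
        return v
    v[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    v[0] = (x[1] - x[0]) * fs
    v[-1] = (x[-1] - x[-2]) * fs
    return v


def estimate_velocity(x: np.ndarray, fs: float, window: int) -> np.ndarray:
    """Smoothed time derivative: Savitzky-Golay (quadratic) over ``window`` frames.

    Computed per contiguous finite segment; segments shorter than the
    window fall back to a plain central difference, and ``window <= 1``
    disables smoothing entirely.  NaN gaps propagate.
    """
    x = np.asarray(x, dtype=float)
    if window <= 1:
        out = np.full(x.size, np.nan)
        for a, b in _segments(np.isfinite(x)):
            if b - a >= 2:
                out[a:b] = central_velocity(x[a:b], fs)
        return out
    win = window if window % 2 == 1 else window + 1
    out = np.full(x.size, np.nan)
    for a, b in _segments(np.isfinite(x)):
        if b - a >= max(win, 4):
            out[a:b] = savgol_filter(x[a:b], win, 2, deriv=1, delta=1.0 / fs, mode="interp")
        elif b - a >= 2:
            out[a:b] = central_velocity(x[a:b], fs)
    return out


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float | None) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass, applied per finite segment.

    Segments too short for stable filtering (or a disabled/unusable
    cut-off) pass through unchanged.
    """
    if cutoff_hz is None or cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return x
    b, a = butter(4, cutoff_hz / (fs / 2.0))
    pad = 3 * max(len(a), len(b))
    out = x.astype(float).copy()
    for s, e in _segments(np.isfinite(x)):
        if e - s > pad:
            out[s:e] = filtfilt(b, a, x[s:e])
    return out


def _segments(finite: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of finite samples as (start, stop) index pairs."""
    runs = []
    idx = np.flatnonzero(finite)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = idx[0]
    for b in breaks:
        runs.append((start, idx[b] + 1))
        start = idx[b + 1]
    runs.append((start, idx[-1] + 1))
    return runs


def strikes_one_side(height: np.ndarray, fs: float, cfg: StepDetectionConfig) -> list[tuple[float, float]]:
    """Detect strikes from one ankle's vertical height series.

    Returns (time, prominence) pairs.  ``height`` is the upward vertical
    position (any units; the velocity floor in ``cfg`` must match them).
    """
    height = lowpass(np.asarray(height, dtype=float), fs, cfg.lowpass_hz)
    velocity = estimate_velocity(height, fs, cfg.smoothing_window)
    events: list[tuple[float, float]] = []
    for start, stop in _segments(np.isfinite(velocity)):
        if stop - start < 3:
            continue
        down_v = -velocity[start:stop]
        cand, props = find_peaks(down_v, prominence=1e-12)
        if cand.size == 0:
            continue
        median_h = float(np.median(down_v[cand]))
        floor = max(cfg.peak_prominence_frac * median_h, cfg.min_peak_velocity * 0.5)
        keep = (props["prominences"] >= floor) & (down_v[cand] >= cfg.min_peak_velocity)
        peaks = cand[keep]
        proms = props["prominences"][keep]
        for k, pk in enumerate(peaks):
            cycle_end = peaks[k + 1] if k + 1 < peaks.size else down_v.size
            thr = cfg.peak_fraction * down_v[pk]
            seg = down_v[pk:cycle_end]
            below = np.flatnonzero(seg < thr)
            # the crossing must be sustained: a single sub-threshold sample can
            # be a noise dip, the post-strike stance stays below the threshold
            j = None
            for idx in below:
                if idx == 0:
                    continue
                nxt = seg[idx : idx + 3]
                if nxt.size < 2 or np.sum(nxt < thr) >= min(2, nxt.size):
                    j = pk + idx
                    break
            if j is None:
                continue
            # linear interpolation of the crossing between samples j-1 and j
            d0, d1 = down_v[j - 1], down_v[j]
            frac = (d0 - thr) / (d0 - d1) if d0 != d1 else 0.0
            t = (start + j - 1 + frac) / fs
            events.append((t, float(proms[k])))
    return events


def merge_and_repair(
    left: list[tuple[float, float]],
    right: list[tuple[float, float]],
    cfg: StepDetectionConfig,
) -> FootStrikeSeries:
    """Merge per-side strike candidates and enforce alternation and spacing.

    Same-side adjacency and pairs closer than ``min_step_interval`` keep
    only the strike with the larger velocity-peak prominence.
    """
    merged = [(t, "left", p) for t, p in left] + [(t, "right", p) for t, p in right]
    merged.sort()
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i in range(len(merged) - 1):
            t0, s0, p0 = merged[i]
            t1, s1, p1 = merged[i + 1]
            if s0 == s1 or (t1 - t0) < cfg.min_step_interval:
                del merged[i + 1 if p0 >= p1 else i]
                changed = True
                break
    if not merged:
        return FootStrikeSeries.empty()
    return FootStrikeSeries(
        times=np.array([m[0] for m in merged]),
        sides=tuple(m[1] for m in merged),
        prominences=np.array([m[2] for m in merged]),
    )


def detect_strikes_from_heights(
    height_left: np.ndarray,
    height_right: np.ndarray,
    fs: float,
    cfg: StepDetectionConfig,
) -> FootStrikeSeries:
    left = strikes_one_side(height_left, fs, cfg)
    right = strikes_one_side(height_right, fs, cfg)
    return merge_and_repair(left, right, cfg)
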