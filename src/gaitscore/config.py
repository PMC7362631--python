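"""Configuration objects shared across the feature-extraction and pipeline stages."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: gravitational acceleration, m/s^2
GRAVITY = 9.81

#: assumed metric pelvis (inter-hip) width used only to express gravity in
#: hip-width units for the 2D extrapolated-centre-of-mass offset, metres
DEFAULT_HIP_WIDTH_M = 0.30


@dataclass(frozen=True)
class StepDetectionConfig:
    """Parameters of the ankle-velocity foot-strike detector.

    A foot strike is placed, per gait cycle, where the downward vertical
    ankle velocity falls back through ``peak_fraction`` of that cycle's peak
    downward velocity — the foot decelerating into ground contact.

    Attributes
    ----------
    peak_fraction:
        Fraction of the per-cycle peak downward ankle velocity at which the
        strike is marked (default 0.35).
    smoothing_window:
        Savitzky-Golay (quadratic) window, in frames, for the smoothed
        velocity estimate; about half a step long. 1 disables smoothing
        (plain central difference).
    min_step_interval:
        Physiological floor (s) between consecutive strikes of opposite
        feet; closer pairs keep only the more prominent strike.
    peak_prominence_frac:
        A velocity peak delimits a cycle only if its prominence is at least
        this fraction of the median candidate-peak height.
    min_peak_velocity:
        Absolute floor on the per-cycle peak downward velocity; cycles whose
        peak falls below it are ignored. Units are hip-widths/s for 2D
        pixel input and m/s for metric 3D input.
    max_gap_frames:
        Longest run of missing frames filled by linear interpolation before
        differentiation; longer gaps split the signal into segments.
    reference_window:
        Window (frames) of the slow moving-average pelvis reference
        subtracted from 2D ankle heights before strike detection; about a
        stride long, it removes the camera-distance drift (and incidental
        pelvis bob) without contaminating the swing signal.
    lowpass_hz:
        Cut-off of the zero-phase Butterworth low-pass applied to ankle
        height before differentiation inside the strike detector; gait
        content relevant to foot-strike timing sits below ~5 Hz.  None
        disables the pre-filter.
    """

    peak_fraction: float = 0.35
    smoothing_window: int = 11
    min_step_interval: float = 0.2
    peak_prominence_frac: float = 0.5
    min_peak_velocity: float = 0.5
    max_gap_frames: int = 5
    reference_window: int = 31
    lowpass_hz: float | None = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.peak_fraction < 1.0:
            raise ValueError(f"peak_fraction must be in (0,1), got {self.peak_fraction}")
        if self.min_step_interval <= 0:
            raise ValueError("min_step_interval must be positive")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


#: detector defaults for metric (3D) ankle trajectories: the velocity floor
#: is in m/s rather than hip-widths/s, and the narrower smoothing window
#: suits the cleaner, sharper metric impact edge.
METRIC_STEP_DETECTION = StepDetectionConfig(min_peak_velocity=0.10, smoothing_window=5)


@dataclass(frozen=True)
class XcomParams:
    """Extrapolated-centre-of-mass parameters for the 2D margin of stability.

    The XCoM adds a velocity-proportional offset to the hip-centre
    position: ``xcom = hip_centre + velocity_scale * hip_centre_velocity``.
    In metric balance analysis the scale is ``1/omega0`` with
    ``omega0 = sqrt(g / pendulum_length)``.  In hip-width-normalized pixel
    space the same construction uses a pendulum length expressed in
    hip-widths and gravity converted through an assumed metric hip width.
    """

    velocity_scale: float = 1.0 / math.sqrt(GRAVITY / DEFAULT_HIP_WIDTH_M)

    def __post_init__(self) -> None:
        if self.velocity_scale < 0:
            raise ValueError("velocity_scale must be >= 0")

    @classmethod
    def from_pendulum(
        cls,
        pendulum_length_hw: float = 1.0,
        hip_width_m: float = DEFAULT_HIP_WIDTH_M,
        g: float = GRAVITY,
    ) -> "XcomParams":
        """Derive ``velocity_scale = 1/omega0`` from an inverted-pendulum
        length given in hip-width units and an assumed metric hip width."""
        g_hw = g / hip_width_m  # gravity in hip-widths / s^2
        omega0 = math.sqrt(g_hw / pendulum_length_hw)
        return cls(velocity_scale=1.0 / omega0)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see :func:`gaitscore.pipeline.run_pipeline`)."""

    input_dir: str | None = None
    metadata_path: str | None = None
    dimensionality: str = "2d"  # {"2d", "3d"}
    outcome: str = "updrs_gait"  # {"updrs_gait", "sas_gait"}
    alpha: float = 0.05
    r_threshold: float = 0.5
    step_detection: StepDetectionConfig = field(default_factory=StepDetectionConfig)
    xcom: XcomParams = field(default_factory=XcomParams)
    min_steps: int = 3
    subsample_daily: bool = True
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must be in (0,1)")
        if self.dimensionality not in ("2d", "3d"):
            raise ValueError("dimensionality must be '2d' or '3d'")
        if self.outcome not in ("updrs_gait", "sas_gait"):
            raise ValueError("outcome must be 'updrs_gait' or 'sas_gait'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "step_detection" in raw:
            raw["step_detection"] = StepDetectionConfig(**raw["step_detection"])
        if "xcom" in raw:
            raw["xcom"] = XcomParams(**raw["xcom"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, stamped on artifacts."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
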