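"""Position filtering, speed/acceleration/jerk derivation, and kinematic anchors.

The measurand downstream is a *time* (when the hand reaches peak velocity,
etc.), so the filtering here is zero-phase: a first-order Butterworth
low-pass (33 Hz cut-off by default) run forward and backward over each
position axis before differentiation.  A single forward pass would delay
every anchor by a constant and bias every synchrony offset.

Four anchors are extracted per annotated gesture event: the event onset,
peak acceleration (constrained to precede peak velocity), peak velocity,
and peak deceleration (constrained to follow peak velocity).  Ties are
broken toward the earlier sample, and the anchors are always ordered
``onset <= peak_acc <= peak_vel <= peak_dec``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import GestureAnnotation, MotionTrace

logger = logging.getLogger(__name__)

ANCHOR_NAMES = ("onset", "peak_acc", "peak_vel", "peak_dec")


@dataclass
class KinematicTrace:
    """Speed (cm/s), acceleration (cm/s^2) and jerk (cm/s^3) on the motion grid."""

    time_s: np.ndarray
    speed_cm_s: np.ndarray
    accel_cm_s2: np.ndarray
    jerk_cm_s3: np.ndarray
    rate_hz: float

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class KinematicAnchors:
    """The four kinematic anchor times of one gesture event."""

    t_onset: float
    t_peak_acc: float
    t_peak_vel: float
    t_peak_dec: float
    v_peak: float

    def __post_init__(self):
        if not (self.t_onset <= self.t_peak_acc <= self.t_peak_vel <= self.t_peak_dec):
            raise ValueError("anchor ordering violated")

    def as_dict(self) -> dict[str, float]:
        return {
            "onset": self.t_onset,
            "peak_acc": self.t_peak_acc,
            "peak_vel": self.t_peak_vel,
            "peak_dec": self.t_peak_dec,
        }


def lowpass_filter(series: np.ndarray, rate_hz: float, cutoff_hz: float = 33.0,
                   order: int = 1) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The two-pass gain at the cut-off is |H|^2 = 1/2 for a first-order
    filter; DC gain is exactly 1, and the output has the input's length.
    """
    nyquist = rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)")
    if cutoff_hz <= 0 or order < 1:
        raise ValueError("cutoff_hz must be positive and order >= 1")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def filter_motion(motion: MotionTrace, cutoff_hz: float = 33.0, order: int = 1) -> MotionTrace:
    """Apply :func:`lowpass_filter` to each position axis."""
    pos = np.column_stack(
        [lowpass_filter(motion.pos_cm[:, k], motion.rate_hz, cutoff_hz, order) for k in range(3)]
    )
    return MotionTrace(time_s=motion.time_s, pos_cm=pos, rate_hz=motion.rate_hz)


def derive_kinematics(motion: MotionTrace) -> KinematicTrace:
    """Differentiate a (filtered) motion trace into speed, acceleration and jerk.

    Speed is the Euclidean norm of the per-axis central-difference
    derivatives (second-order accurate in the interior, one-sided at the
    endpoints); acceleration and jerk are successive central differences of
    the speed.  A constant trace therefore has exactly zero speed.
    """
    if len(motion) < 5:
        raise ValueError("need at least 5 samples to differentiate stably")
    t = motion.time_s
    vel = np.column_stack([np.gradient(motion.pos_cm[:, k], t) for k in range(3)])
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, t)
    jerk = np.gradient(accel, t)
    return KinematicTrace(time_s=t, speed_cm_s=speed, accel_cm_s2=accel,
                          jerk_cm_s3=jerk, rate_hz=motion.rate_hz)


def extract_anchors(kin: KinematicTrace, event: GestureAnnotation) -> KinematicAnchors | None:
    """Locate the four kinematic anchors inside ``[onset, offset)``.

    Peak velocity is the argmax of speed over the event; peak acceleration
    is the argmax of acceleration on ``[onset, t_peak_vel]`` and peak
    deceleration the argmin of acceleration on ``[t_peak_vel, offset)``.
    Returns ``None`` (logged) for a flat zero-speed event; such events are
    excluded downstream.
    """
    t = kin.time_s
    if event.onset_s < t[0] - 1e-9 or event.offset_s > t[-1] + 1e-9:
        raise ValueError("event interval outside trace span")
    i0 = int(np.searchsorted(t, event.onset_s - 1e-12, side="left"))
    i1 = int(np.searchsorted(t, event.offset_s - 1e-12, side="left"))
    if i1 - i0 < 3:
        raise ValueError("event contains fewer than 3 samples")
    speed = kin.speed_cm_s[i0:i1]
    if np.max(speed) <= 1e-12:
        logger.warning("flat zero-speed event at %.3f s: no anchors", event.onset_s)
        return None
    iv = i0 + int(np.argmax(speed))  # argmax returns the first (earliest) max
    ia = i0 + int(np.argmax(kin.accel_cm_s2[i0 : iv + 1]))
    idec = iv + int(np.argmin(kin.accel_cm_s2[iv:i1]))
    return KinematicAnchors(
        t_onset=event.onset_s,
        t_peak_acc=float(t[ia]),
        t_peak_vel=float(t[iv]),
        t_peak_dec=float(t[idec]),
        v_peak=float(kin.speed_cm_s[iv]),
    )


def event_jerk_summary(kin: KinematicTrace, events: list[GestureAnnotation],
                       standardize: bool = True) -> np.ndarray:
    """Mean absolute jerk per event, z-standardized across the events.

    Standardization uses the sample SD (ddof=1), so three events with raw
    means 1, 2, 3 come out as -1, 0, 1.  With a single event (or zero
    variance) the z-score is undefined: a single event yields NaN, a
    zero-variance set yields all zeros with a warning.
    """
    t = kin.time_s
    raw = []
    for ev in events:
        i0 = int(np.searchsorted(t, ev.onset_s - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, ev.offset_s - 1e-12, side="left"))
        raw.append(np.mean(np.abs(kin.jerk_cm_s3[i0:i1])) if i1 > i0 else np.nan)
    raw = np.asarray(raw, dtype=float)
    if not standardize:
        return raw
    if len(raw) < 2:
        logger.warning("z-scored jerk undefined for a single event")
        return np.full_like(raw, np.nan)
    sd = np.nanstd(raw, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        logger.warning("zero variance in event jerk; z-scores set to 0")
        return np.zeros_like(raw)
    return (raw - np.nanmean(raw)) / sd
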