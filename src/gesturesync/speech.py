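"""Speech anchors and rhythm features: per-event peak pitch and the amplitude envelope.

The speech anchor for every gesture event is the maximum voiced F0 inside
the event interval; one peak pitch per event is shared by all four
kinematic anchors' offsets.  If the event window contains no voiced frame
it is widened symmetrically once (default +/-250 ms); an event that is
still unvoiced yields no anchor and is excluded downstream.

The amplitude envelope is the modulus of the analytic (Hilbert) signal of
the mono audio, smoothed with a zero-phase low-pass (10 Hz default),
resampled to the common 240 Hz grid and min-max scaled per recording to
[0, 1] ("scaled Hilbert units").  The scaled envelope carries no
between-recording amplitude information, only rhythm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import GestureAnnotation, PitchTrack

logger = logging.getLogger(__name__)


@dataclass
class EnvelopeTrack:
    """Amplitude envelope in scaled [0, 1] units on a uniform grid."""

    time_s: np.ndarray
    env: np.ndarray
    rate_hz: float

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class PeakPitch:
    """Peak-pitch anchor of one gesture event."""

    t_peak_s: float
    f0_peak_hz: float
    found: bool
    extended: bool = False


def find_peak_pitch(pitch: PitchTrack, event: GestureAnnotation,
                    extension_ms: float = 250.0) -> PeakPitch:
    """Locate the maximum voiced F0 in ``[onset, offset)``.

    Fully-unvoiced windows are widened symmetrically by ``extension_ms``
    once; ties go to the earlier sample.  ``found=False`` is the degenerate
    outcome, never an error.
    """
    t, f0, voiced = pitch.time_s, pitch.f0_hz, pitch.voiced

    def _search(lo: float, hi: float):
        sel = (t >= lo) & (t < hi) & voiced
        if not np.any(sel):
            return None
        idx = np.flatnonzero(sel)
        best = idx[int(np.argmax(f0[idx]))]  # first max on ties
        return best

    best = _search(event.onset_s, event.offset_s)
    extended = False
    if best is None:
        ext = extension_ms / 1000.0
        best = _search(event.onset_s - ext, event.offset_s + ext)
        extended = True
    if best is None:
        return PeakPitch(t_peak_s=np.nan, f0_peak_hz=np.nan, found=False, extended=True)
    return PeakPitch(t_peak_s=float(t[best]), f0_peak_hz=float(f0[best]),
                     found=True, extended=extended)


def amplitude_envelope(audio: np.ndarray, audio_rate_hz: float, smooth_hz: float = 10.0,
                       out_rate_hz: float = 240.0, t0_s: float = 0.0,
                       scale: bool = True) -> EnvelopeTrack:
    """Scaled Hilbert amplitude envelope of mono audio.

    The analytic-signal modulus is low-pass smoothed at ``smooth_hz`` with a
    zero-phase 2nd-order Butterworth, linearly resampled to ``out_rate_hz``
    (safe: the smoothing band is far below the output Nyquist) and min-max
    scaled to [0, 1].  Constant (silent) audio degenerates to an all-zero
    envelope with a warning.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    if audio_rate_hz < 2.0 * smooth_hz:
        raise ValueError("audio rate must be at least twice the smoothing cut-off")
    env = np.abs(signal.hilbert(audio - np.mean(audio)))
    sos = signal.butter(2, smooth_hz, btype="low", fs=audio_rate_hz, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = np.clip(env, 0.0, None)  # filtering may undershoot slightly
    t_in = np.arange(len(audio)) / audio_rate_hz
    n_out = int(np.floor(t_in[-1] * out_rate_hz)) + 1
    t_out = np.arange(n_out) / out_rate_hz
    env = np.interp(t_out, t_in, env)
    if scale:
        lo, hi = float(np.min(env)), float(np.max(env))
        if hi - lo <= 1e-12:
            logger.warning("degenerate (constant) envelope; returning all zeros")
            env = np.zeros_like(env)
        else:
            env = (env - lo) / (hi - lo)
    return EnvelopeTrack(time_s=t_out + t0_s, env=env, rate_hz=out_rate_hz)


def write_envelope(track: EnvelopeTrack, path) -> None:
    import pandas as pd

    pd.DataFrame({"time": track.time_s, "env": track.env}).to_csv(
        path, sep="\t", index=False, float_format="%.9f"
    )


def read_envelope(path) -> EnvelopeTrack:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    env = df.iloc[:, 1].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(time)))
    return EnvelopeTrack(time_s=time, env=env, rate_hz=rate)
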