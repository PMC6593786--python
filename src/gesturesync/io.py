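"""Reading and writing of external formats, track resampling, and condition labels.

Three kinds of files enter the pipeline: motion-capture position tables
(time + x/y/z in cm), pitch tracks exported from an external pitch extractor
(PRAAT PitchTier text or a two-column time/F0 listing), and gesture
annotations exported from an annotation tool as tab-delimited tier rows.
Everything downstream works on a common uniform time grid (240 Hz by
default, matching the motion tracker), so this module also owns resampling
and the block schedule that assigns each gesture event to the DAF or NO-DAF
condition.

Conventions: time is in seconds from session start; every interval
(gesture events, condition blocks) is half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODAF = "NODAF"
DAF = "DAF"
CONDITIONS = (NODAF, DAF)
GESTURE_TYPES = ("beat", "iconic", "undefined")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class MotionTrace:
    """3-D position samples of the tracked hand.

    Parameters
    ----------
    time_s : array of float
        Sample times in seconds, strictly increasing.
    pos_cm : array of shape (n, 3)
        Positions in cm (x, y, z).
    rate_hz : float
        Nominal sampling rate in Hz.
    """

    time_s: np.ndarray
    pos_cm: np.ndarray
    rate_hz: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.time_s.ndim != 1 or len(self.time_s) < 2:
            raise FormatError("motion trace needs at least 2 samples")
        if self.pos_cm.shape != (len(self.time_s), 3):
            raise FormatError("pos_cm must have shape (n, 3)")
        if not np.all(np.isfinite(self.time_s)) or not np.all(np.isfinite(self.pos_cm)):
            raise FormatError("motion trace contains non-finite values")
        if np.any(np.diff(self.time_s) <= 0):
            raise FormatError("motion time column must be strictly increasing")
        if self.rate_hz <= 0:
            raise FormatError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class PitchTrack:
    """F0 samples with voicing gaps.

    ``f0_hz`` is NaN wherever ``voiced`` is False.  Voiced F0 values are
    expected inside a plausible search range (e.g. 75-500 Hz for a male
    voice, 100-500 Hz for a female voice); the range is carried for
    bookkeeping but only positivity is enforced.
    """

    time_s: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray
    search_range_hz: tuple[float, float] = (75.0, 500.0)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        self.voiced = np.asarray(self.voiced, dtype=bool)
        if not (len(self.time_s) == len(self.f0_hz) == len(self.voiced)):
            raise FormatError("pitch track arrays must share a length")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise FormatError("pitch time column must be strictly increasing")
        if np.any(self.f0_hz[self.voiced] <= 0):
            raise FormatError("voiced F0 values must be positive")
        self.f0_hz = np.where(self.voiced, self.f0_hz, np.nan)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class GestureAnnotation:
    """One annotated gesture event (stroke interval plus labels)."""

    participant_id: str
    onset_s: float
    offset_s: float
    gesture_type: str = "undefined"
    condition: str = "unassigned"

    def __post_init__(self):
        if not self.onset_s < self.offset_s:
            raise FormatError(
                f"annotation onset must precede offset ({self.onset_s} >= {self.offset_s})"
            )
        if self.gesture_type not in GESTURE_TYPES:
            raise FormatError(f"unknown gesture type {self.gesture_type!r}")


@dataclass
class ConditionSchedule:
    """Alternating DAF / NO-DAF block schedule.

    The first ``warmup_s`` seconds are always NO DAF; after the warm-up the
    condition toggles every ``block_s`` seconds starting from
    ``first_block``.  Blocks are half-open intervals.
    """

    warmup_s: float = 30.0
    block_s: float = 60.0
    first_block: str = DAF

    def __post_init__(self):
        if self.warmup_s < 0:
            raise ValueError("warmup_s must be >= 0")
        if self.block_s <= 0:
            raise ValueError("block_s must be > 0")
        if self.first_block not in CONDITIONS:
            raise ValueError(f"first_block must be one of {CONDITIONS}")

    def condition_at(self, t_s: float) -> str:
        """Condition active at time ``t_s`` (seconds from session start)."""
        if t_s < self.warmup_s:
            return NODAF
        block = int(np.floor((t_s - self.warmup_s) / self.block_s))
        other = DAF if self.first_block == NODAF else NODAF
        return self.first_block if block % 2 == 0 else other

    def time_in_condition(self, condition: str, session_s: float) -> float:
        """Total seconds spent in ``condition`` over a session of given length."""
        edges = [0.0, min(self.warmup_s, session_s)]
        t = self.warmup_s
        while t < session_s:
            edges.append(min(t + self.block_s, session_s))
            t += self.block_s
        total = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo and self.condition_at(lo) == condition:
                total += hi - lo
        return total


# ---------------------------------------------------------------------------
# readers / writers


def _infer_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_motion_trace(path, dialect: dict | None = None) -> MotionTrace:
    """Read a delimited motion table into a :class:`MotionTrace`.

    ``dialect`` may override ``columns`` (names of the time/x/y/z columns),
    ``sep`` and ``unit_scale`` (multiplier to convert positions to cm).
    Duplicate timestamps are collapsed last-wins; non-monotone time is a
    :class:`FormatError`.
    """
    dialect = dialect or {}
    sep = dialect.get("sep") or _infer_sep(path)
    df = pd.read_csv(path, sep=sep)
    cols = dialect.get("columns", ("time", "x", "y", "z"))
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"motion table missing columns {missing}")
    df = df.drop_duplicates(subset=cols[0], keep="last")
    time = df[cols[0]].to_numpy(dtype=float)
    pos = df[list(cols[1:])].to_numpy(dtype=float) * dialect.get("unit_scale", 1.0)
    if len(time) < 2:
        raise FormatError("motion table has fewer than 2 samples")
    rate = 1.0 / float(np.median(np.diff(time)))
    return MotionTrace(time_s=time, pos_cm=pos, rate_hz=rate)


def write_motion_trace(trace: MotionTrace, path) -> None:
    df = pd.DataFrame(
        {"time": trace.time_s, "x": trace.pos_cm[:, 0], "y": trace.pos_cm[:, 1], "z": trace.pos_cm[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_pitch_track(path, dialect: dict | None = None) -> PitchTrack:
    """Read a pitch track from a PitchTier text file or a two-column listing.

    Two-column listings mark unvoiced frames with 0, NaN, empty fields or
    ``--undefined--``.  PitchTier point files contain voiced points only.
    """
    dialect = dialect or {}
    with open(path) as fh:
        head = fh.read(256)
    if "ooTextFile" in head or "PitchTier" in head:
        return _read_pitchtier(path, dialect)
    sep = dialect.get("sep") or _infer_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#", names=["time", "f0"], skiprows=_header_rows(path, sep))
    time = df["time"].to_numpy(dtype=float)
    f0 = pd.to_numeric(df["f0"].replace("--undefined--", np.nan), errors="coerce").to_numpy(dtype=float)
    voiced = np.isfinite(f0) & (f0 != 0)
    if np.any(f0[np.isfinite(f0) & ~voiced] < 0):
        raise FormatError("negative F0 value in pitch listing")
    return PitchTrack(time_s=time, f0_hz=np.where(voiced, f0, np.nan), voiced=voiced,
                      search_range_hz=dialect.get("search_range_hz", (75.0, 500.0)))


def _header_rows(path, sep) -> int:
    # tolerate a single header row of column names
    with open(path) as fh:
        first = fh.readline().strip()
    fields = first.split(sep)
    try:
        [float(f) for f in fields]
        return 0
    except ValueError:
        return 1


def _read_pitchtier(path, dialect: dict) -> PitchTrack:
    """Minimal parser for PRAAT's long-form 'ooTextFile' PitchTier export."""
    times, values = [], []
    number, time_next = None, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("number") and "=" in line:
                times.append(float(line.split("=")[1]))
            elif line.startswith("value") and "=" in line:
                values.append(float(line.split("=")[1]))
    if len(times) != len(values):
        raise FormatError("malformed PitchTier: unequal number/value counts")
    if not times:
        raise FormatError("PitchTier contains no points")
    order = np.argsort(times)
    time = np.asarray(times, dtype=float)[order]
    f0 = np.asarray(values, dtype=float)[order]
    if np.any(f0 <= 0):
        raise FormatError("non-positive F0 value in PitchTier")
    return PitchTrack(time_s=time, f0_hz=f0, voiced=np.ones(len(f0), dtype=bool),
                      search_range_hz=dialect.get("search_range_hz", (75.0, 500.0)))


def write_pitch_track(track: PitchTrack, path) -> None:
    f0 = np.where(track.voiced, track.f0_hz, 0.0)
    pd.DataFrame({"time": track.time_s, "f0": f0}).to_csv(
        path, sep="\t", index=False, header=False, float_format="%.9f"
    )


def read_annotations(path, participant_id: str = "") -> list[GestureAnnotation]:
    """Parse a tab-delimited annotation export into gesture events.

    Expected rows: ``tier<TAB>onset<TAB>offset<TAB>label`` (a 5-column
    variant with a duration column before the label is also accepted).
    Rows with ``offset <= onset`` are dropped with a warning; unknown labels
    map to ``undefined`` with a warning.  Overlapping events are preserved
    as-is.  Output is sorted by onset, condition left unassigned.
    """
    annotations: list[GestureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 tab-delimited fields")
            tier = fields[0]
            try:
                onset, offset = float(fields[1]), float(fields[2])
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise FormatError(f"{path}:{lineno}: non-numeric onset/offset") from None
            label = fields[4] if len(fields) >= 5 else fields[3]
            if offset <= onset:
                logger.warning("%s:%d: dropped row with offset <= onset", path, lineno)
                continue
            gtype = label.strip().lower()
            if gtype not in GESTURE_TYPES:
                logger.warning("%s:%d: unknown label %r mapped to 'undefined'", path, lineno, label)
                gtype = "undefined"
            annotations.append(
                GestureAnnotation(participant_id=participant_id or tier, onset_s=onset,
                                  offset_s=offset, gesture_type=gtype)
            )
    annotations.sort(key=lambda a: a.onset_s)
    return annotations


def write_annotations(annotations: list[GestureAnnotation], path, tier: str = "gesture") -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{tier}\t{a.onset_s:.9f}\t{a.offset_s:.9f}\t{a.gesture_type}\n")


def assign_condition(
    annotations: list[GestureAnnotation], schedule: ConditionSchedule
) -> list[GestureAnnotation]:
    """Label each event with the condition active at its onset.

    Warm-up events are NO DAF by construction.  Events are labeled by onset
    time (not midpoint), so an event straddling a block boundary belongs to
    the block it started in.
    """
    return [replace(a, condition=schedule.condition_at(a.onset_s)) for a in annotations]


# ---------------------------------------------------------------------------
# resampling


def _uniform_grid(time_s: np.ndarray, rate_hz: float) -> np.ndarray:
    n = int(np.floor((time_s[-1] - time_s[0]) * rate_hz)) + 1
    return time_s[0] + np.arange(n) / rate_hz


def resample_track(track, rate_hz: float = 240.0):
    """Resample a motion or pitch track onto a uniform grid at ``rate_hz``.

    Continuous channels are linearly interpolated; nothing is extrapolated
    beyond the original time span.  For pitch tracks, the voiced flag is
    carried over and no values are fabricated across unvoiced spans: a new
    sample is voiced only if both bracketing original samples are voiced
    (within a small bridging tolerance for sparse point files).  A track
    that is already uniform at ``rate_hz`` is returned unchanged.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    t = track.time_s
    dt = np.diff(t)
    if len(dt) and np.allclose(dt, 1.0 / rate_hz, rtol=0, atol=1e-9):
        return replace(track) if isinstance(track, MotionTrace) else replace(track)
    grid = _uniform_grid(t, rate_hz)

    if isinstance(track, MotionTrace):
        pos = np.column_stack([np.interp(grid, t, track.pos_cm[:, k]) for k in range(3)])
        return MotionTrace(time_s=grid, pos_cm=pos, rate_hz=rate_hz)

    if isinstance(track, PitchTrack):
        voiced_idx = np.flatnonzero(track.voiced)
        f0 = np.full(len(grid), np.nan)
        voiced = np.zeros(len(grid), dtype=bool)
        if len(voiced_idx):
            tv, fv = t[voiced_idx], track.f0_hz[voiced_idx]
            # bridge gaps between consecutive voiced samples only when short
            native_dt = np.median(np.diff(t)) if len(t) > 1 else 1.0 / rate_hz
            # bridge only directly adjacent voiced samples; any dropped frame
            # between two voiced samples keeps its span unvoiced
            max_gap = 1.5 * native_dt
            left = np.searchsorted(tv, grid, side="right") - 1
            right = left + 1
            inside = (left >= 0) & (right < len(tv))
            ok = inside.copy()
            ok[inside] &= (tv[right[inside]] - tv[left[inside]]) <= max_gap
            # grid points next to a lone/edge voiced sample count as voiced
            nearest = np.clip(np.searchsorted(tv, grid), 0, len(tv) - 1)
            dist = np.minimum(np.abs(grid - tv[nearest]), np.abs(grid - tv[np.maximum(nearest - 1, 0)]))
            ok |= dist <= 0.5 * native_dt + 1e-12
            interp = np.interp(grid, tv, fv)
            f0[ok] = interp[ok]
            voiced = ok
        return PitchTrack(time_s=grid, f0_hz=f0, voiced=voiced, search_range_hz=track.search_range_hz)

    raise TypeError(f"cannot resample object of type {type(track).__name__}")


def annotations_to_frame(annotations: list[GestureAnnotation]) -> pd.DataFrame:
    """Tidy one-row-per-event table of annotations."""
    return pd.DataFrame(
        {
            "participant": [a.participant_id for a in annotations],
            "onset_s": [a.onset_s for a in annotations],
            "offset_s": [a.offset_s for a in annotations],
            "gesture_type": [a.gesture_type for a in annotations],
            "condition": [a.condition for a in annotations],
        }
    )
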