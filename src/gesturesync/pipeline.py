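"""End-to-end orchestration: preprocess -> anchors -> D -> models -> robustness -> wavelet.

`run_pipeline` takes a dataset (a directory of per-participant session
files, or an in-memory synthetic dataset) and produces the full results
bundle: the event-level D table, the descriptive tables (rates,
kinematics, per-cell D summaries), the model reports (coupling strength,
entrainment, SD-mean correlation), the leave-two-out robustness report,
and the band-averaged wavelet coherence analyses.  A manifest records the
seed, a hash of the configuration and the package version so that every
number in a report is traceable to config + seed + inputs.

Events that yield no anchors (flat strokes) or no peak pitch (unvoiced
windows) are skipped and counted in the warnings section of the manifest;
exclusions are never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from . import __version__
from .io import (
    CONDITIONS,
    ConditionSchedule,
    GestureAnnotation,
    MotionTrace,
    PitchTrack,
    annotations_to_frame,
    assign_condition,
    read_annotations,
    read_motion_trace,
    read_pitch_track,
    resample_track,
)
from .kinematics import derive_kinematics, event_jerk_summary, extract_anchors, filter_motion
from .mixedlm import SingularModelError
from .speech import EnvelopeTrack, amplitude_envelope, find_peak_pitch, read_envelope
from .synchrony import (
    compute_D,
    csh_absolute_D_analysis,
    csh_SDD_analysis,
    descriptive_rates,
    eh_shift_analysis,
    leave_two_out_robustness,
    sd_mean_correlation,
    summarize_D,
)
from .synthetic import SyntheticDataset
from .wavelet import (
    XWaveletConfig,
    band_average,
    coherence_band_models,
    coherence_significance,
    prepare_condition_series,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis in one place."""

    rate_hz: float = 240.0
    filter_cutoff_hz: float = 33.0
    filter_order: int = 1
    pitch_extension_ms: float = 250.0
    warmup_s: float = 30.0
    block_s: float = 60.0
    first_block: str = "DAF"
    wavelet: XWaveletConfig = field(default_factory=XWaveletConfig)
    wavelet_rate_hz: float = 24.0  # velocity/envelope decimated before the CWT
    run_wavelet: bool = True
    run_robustness: bool = True
    seed: int = 0

    @property
    def schedule(self) -> ConditionSchedule:
        return ConditionSchedule(self.warmup_s, self.block_s, self.first_block)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "wavelet"}
        d["wavelet"] = self.wavelet.__dict__
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SessionData:
    """One participant's aligned inputs."""

    participant_id: str
    motion: MotionTrace
    pitch: PitchTrack
    envelope: EnvelopeTrack | None
    annotations: list[GestureAnnotation]


def load_session(pdir: Path, config: PipelineConfig) -> SessionData:
    pdir = Path(pdir)
    pid = pdir.name
    motion_path = pdir / "motion.csv"
    pitch_path = pdir / "pitch.txt"
    ann_path = pdir / "annotations.txt"
    for p, what in ((motion_path, "motion"), (pitch_path, "pitch"), (ann_path, "annotations")):
        if not p.exists():
            raise PipelineError(f"participant {pid}: missing {what} file {p}")
    motion = read_motion_trace(motion_path)
    pitch = read_pitch_track(pitch_path)
    annotations = read_annotations(ann_path, participant_id=pid)
    env = None
    if (pdir / "envelope.tsv").exists():
        env = read_envelope(pdir / "envelope.tsv")
    elif (pdir / "audio.wav").exists():
        from scipy.io import wavfile

        sr, audio = wavfile.read(pdir / "audio.wav")
        env = amplitude_envelope(audio.astype(float), sr, out_rate_hz=config.rate_hz)
    return SessionData(participant_id=pid, motion=motion, pitch=pitch, envelope=env,
                       annotations=annotations)


def load_dataset(path, config: PipelineConfig) -> list[SessionData]:
    path = Path(path)
    pdirs = sorted(d for d in path.iterdir() if d.is_dir() and (d / "motion.csv").exists())
    if not pdirs:
        raise PipelineError(f"no participant session directories under {path}")
    return [load_session(d, config) for d in pdirs]


def _sessions_from_memory(dataset: SyntheticDataset) -> list[SessionData]:
    return [
        SessionData(participant_id=s.participant_id, motion=s.motion, pitch=s.pitch,
                    envelope=s.envelope, annotations=s.annotations)
        for s in dataset.sessions
    ]


@dataclass
class SessionFeatures:
    """Derived per-session series kept for the wavelet stage."""

    participant_id: str
    time_s: np.ndarray
    speed_cm_s: np.ndarray
    env: np.ndarray | None
    session_s: float
    f0_mean_by_condition: dict


def compute_records(sessions: list[SessionData], config: PipelineConfig
                    ) -> tuple[pd.DataFrame, list[SessionFeatures], list[str]]:
    """Anchor extraction and D computation for every annotated event."""
    rows, features, warnings_log = [], [], []
    schedule = config.schedule
    for sess in sessions:
        pid = sess.participant_id
        try:
            pitch = resample_track(sess.pitch, config.rate_hz)
            filtered = filter_motion(sess.motion, config.filter_cutoff_hz, config.filter_order)
            kin = derive_kinematics(filtered)
        except Exception as exc:
            raise PipelineError(f"preprocess stage failed for participant {pid}: {exc}") from exc
        annotations = assign_condition(sess.annotations, schedule)
        jerk_z = event_jerk_summary(kin, annotations)
        for i, (event, jz) in enumerate(zip(annotations, jerk_z)):
            anchors = extract_anchors(kin, event)
            if anchors is None:
                warnings_log.append(f"{pid} event {i}: flat stroke, no anchors")
                continue
            peak = find_peak_pitch(pitch, event, config.pitch_extension_ms)
            if not peak.found:
                warnings_log.append(f"{pid} event {i}: no voiced peak pitch")
                continue
            rec = compute_D(anchors, peak, pid, event.condition, event.gesture_type,
                            event_id=f"{pid}_e{i:03d}")
            rec |= {"onset_s": event.onset_s, "offset_s": event.offset_s,
                    "v_peak_cm_s": anchors.v_peak, "jerk_z": jz,
                    "duration_ms": (event.offset_s - event.onset_s) * 1000.0,
                    "pitch_window_extended": peak.extended}
            rows.append(rec)
        cond_grid = np.array([schedule.condition_at(x) for x in kin.time_s])
        f0_means = {}
        for cond in CONDITIONS:
            sel = (cond_grid == cond) & pitch.voiced[: len(cond_grid)]
            f0_means[cond] = float(np.nanmean(pitch.f0_hz[: len(cond_grid)][sel])) if sel.any() else np.nan
        features.append(SessionFeatures(
            participant_id=pid, time_s=kin.time_s, speed_cm_s=kin.speed_cm_s,
            env=None if sess.envelope is None else sess.envelope.env,
            session_s=float(kin.time_s[-1]), f0_mean_by_condition=f0_means,
        ))
    if not rows:
        raise PipelineError("no usable events: every event lacked anchors or peak pitch")
    return pd.DataFrame(rows), features, warnings_log


def _condition_segments(schedule: ConditionSchedule, session_s: float) -> list[tuple[float, float, str]]:
    edges = [0.0, min(schedule.warmup_s, session_s)]
    t = schedule.warmup_s
    while t < session_s:
        edges.append(min(t + schedule.block_s, session_s))
        t += schedule.block_s
    return [
        (lo, hi, schedule.condition_at(lo))
        for lo, hi in zip(edges[:-1], edges[1:])
        if hi > lo
    ]


def _decimate(x: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    q = int(round(in_rate / out_rate))
    if q <= 1:
        return x
    return _sig.decimate(x, q, ftype="fir", zero_phase=True)


def wavelet_band_analysis(features: list[SessionFeatures], config: PipelineConfig,
                          seed: int) -> tuple[pd.DataFrame, dict]:
    """Per participant x condition coherence of speed and envelope, band-averaged.

    Trials (schedule blocks) are standardized individually and concatenated
    per condition; the series are decimated to ``wavelet_rate_hz`` before
    the CWT (the analysis bands start at 0.2 s periods, far below the
    decimated Nyquist).  Surrogate p-values use the configured number of
    white-noise simulations; band averages are reported raw and restricted
    to periods significant at p < .05.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(features) * 2)]
    k = 0
    schedule = config.schedule
    for feat in features:
        if feat.env is None:
            logger.warning("participant %s has no envelope; skipped in wavelet stage",
                           feat.participant_id)
            continue
        segs = _condition_segments(schedule, feat.session_s)
        for cond in CONDITIONS:
            rng = rngs[k]
            k += 1
            speed_trials, env_trials = [], []
            for lo, hi, c in segs:
                if c != cond:
                    continue
                sel = (feat.time_s >= lo) & (feat.time_s < hi)
                speed_trials.append(_decimate(feat.speed_cm_s[sel], config.rate_hz,
                                              config.wavelet_rate_hz))
                env_trials.append(_decimate(feat.env[sel], config.rate_hz,
                                            config.wavelet_rate_hz))
            if not speed_trials:
                continue
            x, bounds = prepare_condition_series(speed_trials)
            y, _ = prepare_condition_series(env_trials)
            dt = 1.0 / config.wavelet_rate_hz
            plane = coherence_significance(x, y, dt, config.wavelet, boundaries=bounds, rng=rng)
            for filt in (False, True):
                tab = band_average(plane, filter_significant=filt)
                for _, r in tab.iterrows():
                    rows.append({"participant": feat.participant_id, "condition": cond,
                                 "band": r["band"], "coherence": r["coherence"],
                                 "n_periods": r["n_periods"], "filtered": filt})
    band_df = pd.DataFrame(rows)
    models = {}
    for filt, name in ((False, "raw"), (True, "significant_only")):
        sub = band_df[band_df["filtered"] == filt]
        try:
            models[name] = coherence_band_models(sub).to_dict()
        except (ValueError, SingularModelError) as exc:
            logger.warning("band model (%s) skipped: %s", name, exc)
            models[name] = {"skipped": str(exc)}
    return band_df, models


@dataclass
class PipelineResult:
    records: pd.DataFrame
    summary_D: pd.DataFrame
    rates: pd.DataFrame
    kinematics_table: pd.DataFrame
    analyses: dict
    robustness: dict
    band_summaries: pd.DataFrame | None
    band_models: dict | None
    manifest: dict

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.summary_D.to_csv(outdir / "summary_D.csv", index=False)
        self.rates.to_csv(outdir / "rates.csv", index=False)
        self.kinematics_table.to_csv(outdir / "kinematics.csv", index=False)
        (outdir / "models.json").write_text(json.dumps(self.analyses, indent=2, default=_jsonify))
        (outdir / "robustness.json").write_text(json.dumps(self.robustness, indent=2, default=_jsonify))
        if self.band_summaries is not None:
            self.band_summaries.to_csv(outdir / "coherence_bands.csv", index=False)
            (outdir / "band_models.json").write_text(
                json.dumps(self.band_models, indent=2, default=_jsonify))
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=_jsonify))
        return outdir


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _table_hash(*frames: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for f in frames:
        h.update(f.round(9).to_csv(index=False).encode())
    return h.hexdigest()[:16]


def analyze_records(records: pd.DataFrame, config: PipelineConfig) -> dict:
    """All model-based analyses on an event-level D table."""
    analyses: dict = {}
    both = records[records["gesture_type"].isin(["beat", "iconic"])]

    def _try(name, fn):
        try:
            analyses[name] = fn().to_dict()
        except (ValueError, KeyError, SingularModelError) as exc:
            logger.warning("analysis %s skipped: %s", name, exc)
            analyses[name] = {"skipped": str(exc)}

    _try("csh_absolute_D_beat", lambda: csh_absolute_D_analysis(records, "beat"))
    _try("csh_sdd", lambda: csh_SDD_analysis(both))
    _try("eh_beat", lambda: eh_shift_analysis(records, "beat"))
    _try("eh_iconic", lambda: eh_shift_analysis(records, "iconic"))
    _try("sd_mean_correlation_daf", lambda: sd_mean_correlation(records, "peak_vel", "DAF"))
    _try("sd_mean_correlation_nodaf", lambda: sd_mean_correlation(records, "peak_vel", "NODAF"))
    return analyses


def run_pipeline(dataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Full analysis on a dataset directory or in-memory synthetic dataset."""
    config = config or PipelineConfig()
    if isinstance(dataset, SyntheticDataset):
        sessions = _sessions_from_memory(dataset)
    else:
        sessions = load_dataset(dataset, config)

    records, features, warns = compute_records(sessions, config)
    summary = summarize_D(records)

    ann = pd.concat(
        [annotations_to_frame(assign_condition(s.annotations, config.schedule)) for s in sessions],
        ignore_index=True,
    )
    session_lengths = {f.participant_id: f.session_s for f in features}
    f0_means = {
        cond: float(np.nanmean([f.f0_mean_by_condition[cond] for f in features]))
        for cond in CONDITIONS
    }
    rates = descriptive_rates(ann, config.schedule, session_lengths, pitch_mean_hz=f0_means)

    kin_rows = []
    for (cond, gtype), grp in records.groupby(["condition", "gesture_type"], sort=True):
        kin_rows.append({
            "condition": cond, "gesture_type": gtype, "n": len(grp),
            "peak_velocity_mean": grp["v_peak_cm_s"].mean(),
            "peak_velocity_sd": grp["v_peak_cm_s"].std(ddof=1),
            "jerk_z_mean": grp["jerk_z"].mean(),
            "duration_ms_mean": grp["duration_ms"].mean(),
        })
    kin_table = pd.DataFrame(kin_rows)

    analyses = analyze_records(records, config)

    robustness: dict = {}
    if config.run_robustness:
        both = records[records["gesture_type"].isin(["beat", "iconic"])]
        try:
            rep = leave_two_out_robustness(both, lambda r: eh_shift_analysis(r, None))
            robustness["entrainment"] = rep.to_dict() | {"per_dataset": rep.table.to_dict("records")}
        except ValueError as exc:
            robustness["entrainment"] = {"skipped": str(exc)}
        try:
            rep = leave_two_out_robustness(both, csh_SDD_analysis)
            robustness["coupling_sdd"] = rep.to_dict() | {"per_dataset": rep.table.to_dict("records")}
        except ValueError as exc:
            robustness["coupling_sdd"] = {"skipped": str(exc)}

    band_df, band_models = (None, None)
    if config.run_wavelet and any(f.env is not None for f in features):
        band_df, band_models = wavelet_band_analysis(features, config, config.seed)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.to_json().encode()).hexdigest()[:16],
        "records_hash": _table_hash(records),
        "n_participants": len(sessions),
        "n_events_annotated": int(len(ann)),
        "n_events_used": int(len(records)),
        "warnings": warns,
    }
    return PipelineResult(records=records, summary_D=summary, rates=rates,
                          kinematics_table=kin_table, analyses=analyses,
                          robustness=robustness, band_summaries=band_df,
                          band_models=band_models, manifest=manifest)
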