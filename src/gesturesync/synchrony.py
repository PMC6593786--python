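"""The D offset statistic and all inferential analyses built on it.

For every gesture event the signed offset between each kinematic anchor
and the event's peak pitch is

    D_a = (t_anchor_a - t_peak_pitch) * 1000   [ms],

so negative D means the anchor preceded the pitch peak.  Because the four
anchors of an event are ordered in time and share one pitch peak, every
record obeys D_onset <= D_peak_acc <= D_peak_vel <= D_peak_dec.

Analyses (all with a participant random intercept, ML fits):

* coupling strength, confirmatory: absolute D of peak velocity (beat
  gestures), condition vs. intercept-only (LRT);
* coupling strength, exploratory: per-cell SD of D ("SDD", cells =
  participant x condition x gesture type x anchor over the three peak
  anchors), sequential ladder +condition, +gesture type, +anchor;
* entrainment: D stacked long over the four anchors, ladder anchor,
  +condition, +interaction; the condition coefficient is the entrainment
  shift;
* the SD-mean correlation across participants (Pearson, Fisher-z CI);
* leave-two-out robustness: every C(n, 2) participant-pair exclusion
  refitted.

Confirmatory analyses use alpha = .025 (two confirmatory hypotheses),
exploratory analyses alpha = .05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS, DAF, NODAF, ConditionSchedule, GestureAnnotation
from .kinematics import ANCHOR_NAMES, KinematicAnchors
from .mixedlm import (
    LRTResult,
    ModelFit,
    fit_ladder,
    fit_random_intercept_model,
    likelihood_ratio_test,
)
from .speech import PeakPitch

logger = logging.getLogger(__name__)

D_COLUMNS = tuple(f"D_{a}" for a in ANCHOR_NAMES)

ALPHA_CONFIRMATORY = 0.025
ALPHA_EXPLORATORY = 0.05

# the per-cell SD analysis uses the three peak anchors (not the onset)
SDD_ANCHORS = ("peak_acc", "peak_vel", "peak_dec")


@dataclass
class AnalysisConfig:
    alpha_confirmatory: float = ALPHA_CONFIRMATORY
    alpha_exploratory: float = ALPHA_EXPLORATORY
    n_surrogates: int = 250

    def __post_init__(self):
        for a in (self.alpha_confirmatory, self.alpha_exploratory):
            if not 0 < a < 1:
                raise ValueError("alpha must be in (0, 1)")


def compute_D(anchors: KinematicAnchors, peak: PeakPitch, participant_id: str,
              condition: str, gesture_type: str, event_id=None) -> dict:
    """One synchrony record: the four anchor offsets against peak pitch (ms)."""
    if not peak.found:
        raise ValueError("peak pitch not found; record should be skipped upstream")
    rec = {
        "participant": participant_id,
        "event_id": event_id,
        "condition": condition,
        "gesture_type": gesture_type,
        "t_peak_pitch": peak.t_peak_s,
    }
    for name, t_a in anchors.as_dict().items():
        rec[f"D_{name}"] = (t_a - peak.t_peak_s) * 1000.0
    return rec


def records_long(records: pd.DataFrame) -> pd.DataFrame:
    """Stack the four D columns into long format (one row per anchor per event)."""
    id_cols = [c for c in records.columns if c not in D_COLUMNS]
    long = records.melt(id_vars=id_cols, value_vars=list(D_COLUMNS),
                        var_name="anchor", value_name="D")
    long["anchor"] = long["anchor"].str.removeprefix("D_")
    return long.dropna(subset=["D"]).reset_index(drop=True)


def summarize_D(records: pd.DataFrame,
                grouping: tuple[str, ...] = ("participant", "condition", "gesture_type"),
                anchors: tuple[str, ...] = ANCHOR_NAMES) -> pd.DataFrame:
    """Per-cell n, mean, sample SD and t-based 95% CI of D, per anchor.

    Cells with a single observation get missing SD and CI; empty cells are
    omitted.  The SD column is the SDD statistic when the grouping is
    participant x condition x gesture type.
    """
    if records.empty:
        raise ValueError("no synchrony records to summarize")
    long = records_long(records)
    long = long[long["anchor"].isin(anchors)]
    rows = []
    for keys, grp in long.groupby(list(grouping) + ["anchor"], observed=True, sort=True):
        d = grp["D"].to_numpy(dtype=float)
        n = len(d)
        mean = float(np.mean(d))
        if n > 1:
            sd = float(np.std(d, ddof=1))
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            ci = (mean - half, mean + half)
        else:
            sd, ci = np.nan, (np.nan, np.nan)
        rows.append(dict(zip(list(grouping) + ["anchor"], keys))
                    | {"n": n, "mean_D": mean, "sd_D": sd, "ci_low": ci[0], "ci_high": ci[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coupling strength


@dataclass
class CSHAbsoluteDResult:
    """Confirmatory coupling-strength analysis: |D peak velocity| of beats."""

    fit_null: ModelFit
    fit_condition: ModelFit
    lrt: LRTResult

    @property
    def condition_coef(self) -> float:
        return _condition_coef(self.fit_condition)

    def to_dict(self) -> dict:
        return {
            "model": self.fit_condition.to_dict(),
            "lrt_condition": self.lrt.to_dict(),
            "condition_coef": self.condition_coef,
        }


def _condition_coef(fit: ModelFit) -> float:
    """The DAF-vs-NODAF fixed-effect coefficient of a fitted model."""
    for name in fit.params.index:
        if "condition" in name and DAF in name:
            return float(fit.params[name])
    raise KeyError("no condition coefficient in model")


def _condition_term() -> str:
    # NODAF is the reference level: the coefficient is the DAF effect
    return f"C(condition, Treatment('{NODAF}'))"


def csh_absolute_D_analysis(records: pd.DataFrame,
                            gesture_type: str = "beat") -> CSHAbsoluteDResult:
    """Mixed model for |D_peak_vel| with condition as predictor (vs. intercept-only)."""
    sub = records[records["gesture_type"] == gesture_type].copy()
    present = set(sub["condition"].unique())
    missing = [c for c in CONDITIONS if c not in present]
    if missing:
        raise ValueError(f"no {missing[0]} {gesture_type} records; both conditions required")
    sub["abs_D_peak_vel"] = sub["D_peak_vel"].abs()
    fits, lrts = fit_ladder(
        sub, "abs_D_peak_vel", [[], [_condition_term()]], "participant",
        labels=["condition"],
    )
    return CSHAbsoluteDResult(fit_null=fits[0], fit_condition=fits[1], lrt=lrts[0])


@dataclass
class SDDResult:
    """Exploratory coupling-strength analysis on per-cell SDs of D."""

    summaries: pd.DataFrame
    fits: list[ModelFit]
    lrts: list[LRTResult]
    fit_condition: ModelFit

    @property
    def condition_coef(self) -> float:
        return _condition_coef(self.fit_condition)

    def to_dict(self) -> dict:
        return {
            "condition_model": self.fit_condition.to_dict(),
            "lrts": [l.to_dict() for l in self.lrts],
            "condition_coef": self.condition_coef,
        }


def csh_SDD_analysis(records: pd.DataFrame,
                     anchors: tuple[str, ...] = SDD_ANCHORS) -> SDDResult:
    """Sequential LRT ladder for SDD: +condition, +gesture type, +anchor.

    SDD cells are participant x condition x gesture type x anchor over the
    peak anchors; n=1 cells contribute no row (the SD of one observation is
    undefined).  Terms whose factor has a single observed level are skipped
    with a warning.  The reported condition coefficient comes from the
    condition-only model (negative = lower SDD under DAF).
    """
    summ = summarize_D(records, anchors=anchors)
    cells = summ.dropna(subset=["sd_D"]).rename(columns={"sd_D": "sdd"}).reset_index(drop=True)
    if cells["participant"].nunique() < 2:
        raise ValueError("SDD analysis needs at least 2 participants")
    terms: list[list[str]] = [[]]
    labels = []
    cumulative: list[str] = []
    for factor, term in (
        ("condition", _condition_term()),
        ("gesture_type", "C(gesture_type)"),
        ("anchor", "C(anchor)"),
    ):
        if cells[factor].nunique() < 2:
            logger.warning("SDD ladder: factor %r has one level; term skipped", factor)
            continue
        cumulative = cumulative + [term]
        terms.append(list(cumulative))
        labels.append(factor)
    fits, lrts = fit_ladder(cells, "sdd", terms, "participant", labels=labels)
    cond_idx = labels.index("condition") + 1 if "condition" in labels else 0
    return SDDResult(summaries=cells, fits=fits, lrts=lrts, fit_condition=fits[cond_idx])


# ---------------------------------------------------------------------------
# entrainment


@dataclass
class EHResult:
    """Entrainment analysis: condition shift of D across the four anchors."""

    fits: list[ModelFit]
    lrts: list[LRTResult]
    fit_condition: ModelFit
    condition_se_clustered: float
    n_events: int

    @property
    def condition_coef(self) -> float:
        return _condition_coef(self.fit_condition)

    @property
    def lrt_condition(self) -> LRTResult:
        return next(l for l in self.lrts if l.label == "condition")

    def to_dict(self) -> dict:
        return {
            "condition_model": self.fit_condition.to_dict(),
            "lrts": [l.to_dict() for l in self.lrts],
            "condition_coef": self.condition_coef,
            "condition_se_clustered": self.condition_se_clustered,
            "n_events": self.n_events,
        }


def eh_shift_analysis(records: pd.DataFrame, gesture_type: str | None = "beat") -> EHResult:
    """Mixed-model ladder for D stacked long over anchors.

    Models: anchor category; + condition; + anchor x condition interaction
    (tested and reported).  The condition coefficient of the additive model
    is the entrainment-shift estimate (positive = D shifted later under
    DAF).  Besides the stacked model's own SE, an event-clustered SE is
    reported (from refitting the additive model on per-event mean D): the
    four rows of one event share a single pitch peak, so stacked rows are
    not independent and the naive SE understates the sampling variance.
    """
    sub = records if gesture_type is None else records[records["gesture_type"] == gesture_type]
    if sub.empty:
        raise ValueError(f"no records for gesture type {gesture_type!r}")
    missing = [c for c in CONDITIONS if c not in set(sub["condition"])]
    if missing:
        raise ValueError(f"no {missing[0]} records; both conditions required")
    long = records_long(sub)
    cond = _condition_term()
    fits, lrts = fit_ladder(
        long,
        "D",
        [[], ["C(anchor)"], ["C(anchor)", cond], ["C(anchor)", cond, f"C(anchor):{cond}"]],
        "participant",
        labels=["anchor", "condition", "interaction"],
    )
    fit_condition = fits[2]
    # event-clustered SE: collapse anchors to the per-event mean
    ev = sub.copy()
    ev["D_event_mean"] = ev[list(D_COLUMNS)].mean(axis=1)
    fit_ev = fit_random_intercept_model(ev, "D_event_mean", [cond], "participant")
    se_cl = float(fit_ev.bse[[i for i in fit_ev.bse.index if "condition" in i][0]])
    return EHResult(fits=fits, lrts=lrts, fit_condition=fit_condition,
                    condition_se_clustered=se_cl, n_events=len(sub))


# ---------------------------------------------------------------------------
# SD-mean correlation


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def sd_mean_correlation(records: pd.DataFrame, anchor: str = "peak_vel",
                        condition: str = DAF) -> CorrelationResult:
    """Pearson correlation of per-participant SD and mean of D for one anchor.

    A positive r says participants with looser coupling (higher SD) show a
    larger positive mean offset.  CI via Fisher z; t on n-2 df.  Zero
    variance in either vector leaves the correlation undefined (NaN,
    flagged with a warning).
    """
    col = f"D_{anchor}"
    sub = records[records["condition"] == condition]
    per = sub.groupby("participant")[col].agg(["mean", "std", "count"])
    per = per[per["count"] >= 2].dropna()
    n = len(per)
    if n < 3:
        raise ValueError("correlation needs at least 3 participants")
    m, s = per["mean"].to_numpy(), per["std"].to_numpy()
    if np.std(m) == 0 or np.std(s) == 0:
        logger.warning("zero variance in SD or mean vector; correlation undefined")
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n - 2, np.nan, n)
    r, p = stats.pearsonr(s, m)
    t = r * np.sqrt((n - 2) / max(1e-12, 1 - r**2))
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3) if n > 3 else np.inf
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=float(r), ci_low=ci[0], ci_high=ci[1], t=float(t),
                             df=n - 2, p=float(p), n=n)


# ---------------------------------------------------------------------------
# descriptives


def descriptive_rates(annotations: pd.DataFrame, schedule: ConditionSchedule,
                      session_s: float | dict[str, float],
                      word_counts: dict[str, float] | None = None,
                      speech_minutes: dict[str, float] | None = None,
                      pitch_mean_hz: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-condition gesture rates (per minute narration) and optional speech rates.

    ``annotations`` is the tidy event table (must carry condition labels).
    ``session_s`` is one session length or a per-participant mapping; the
    schedule splits it into per-condition narration time.  Optional word
    counts (per condition) yield words/min speech.
    """
    if isinstance(session_s, dict):
        minutes = {
            c: sum(schedule.time_in_condition(c, s) for s in session_s.values()) / 60.0
            for c in CONDITIONS
        }
    else:
        minutes = {c: schedule.time_in_condition(c, session_s) / 60.0 for c in CONDITIONS}
    rows = []
    for cond in CONDITIONS:
        if minutes[cond] <= 0:
            raise ValueError(f"zero narration time for condition {cond}")
        sub = annotations[annotations["condition"] == cond]
        row = {"condition": cond, "narration_min": minutes[cond]}
        for gtype in ("beat", "iconic", "undefined"):
            row[f"{gtype}_per_min"] = len(sub[sub["gesture_type"] == gtype]) / minutes[cond]
        row["gestures_per_min"] = len(sub) / minutes[cond]
        if word_counts is not None:
            speech_min = (speech_minutes or minutes)[cond]
            row["words_per_min_speech"] = word_counts.get(cond, 0) / speech_min
        if pitch_mean_hz is not None:
            row["f0_mean_hz"] = pitch_mean_hz.get(cond, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# robustness


@dataclass
class RobustnessReport:
    """Leave-two-out refits of one analysis over all participant pairs."""

    table: pd.DataFrame  # one row per exclusion dataset
    n_datasets: int
    n_valid: int
    n_significant: int
    alpha: float

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_valid if self.n_valid else np.nan

    def to_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "n_valid": self.n_valid,
            "n_significant": self.n_significant,
            "fraction_significant": self.fraction_significant,
            "alpha": self.alpha,
            "coef_min": float(self.table["coef"].min()) if self.n_valid else np.nan,
            "coef_max": float(self.table["coef"].max()) if self.n_valid else np.nan,
        }


def leave_two_out_robustness(records: pd.DataFrame, analysis, alpha: float = ALPHA_EXPLORATORY,
                             ) -> RobustnessReport:
    """Re-run ``analysis`` on every dataset excluding one pair of participants.

    ``analysis`` maps a records table to any result exposing a condition
    coefficient and a condition LRT (e.g. :func:`eh_shift_analysis` or
    :func:`csh_SDD_analysis`).  Exclusion datasets that lose a condition
    entirely (or otherwise fail the analysis preconditions) are flagged and
    excluded from the denominator of the significant fraction.
    """
    participants = sorted(records["participant"].unique())
    if len(participants) < 3:
        raise ValueError("leave-two-out needs at least 3 participants")
    rows = []
    for pair in combinations(participants, 2):
        sub = records[~records["participant"].isin(pair)]
        row = {"excluded": "+".join(map(str, pair))}
        try:
            res = _run_robustness_analysis(analysis, sub)
            row |= {"coef": res[0], "p": res[1], "valid": True}
        except (ValueError, KeyError) as exc:
            logger.warning("exclusion %s failed: %s", pair, exc)
            row |= {"coef": np.nan, "p": np.nan, "valid": False}
        rows.append(row)
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    return RobustnessReport(
        table=table,
        n_datasets=len(table),
        n_valid=len(valid),
        n_significant=int((valid["p"] < alpha).sum()),
        alpha=alpha,
    )


def _run_robustness_analysis(analysis, sub: pd.DataFrame) -> tuple[float, float]:
    res = analysis(sub)
    if isinstance(res, EHResult):
        return res.condition_coef, res.lrt_condition.p
    if isinstance(res, SDDResult):
        lrt = next(l for l in res.lrts if l.label == "condition")
        return res.condition_coef, lrt.p
    if isinstance(res, CSHAbsoluteDResult):
        return res.condition_coef, res.lrt.p
    coef, p = res  # plain (coef, p) callable
    return float(coef), float(p)
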