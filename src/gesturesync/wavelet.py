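"""Morlet continuous wavelet transform, cross-wavelet power and coherence.

The continuous analyses relate the hand's speed to the speech amplitude
envelope over nested time scales.  The machinery is the standard analytic
Morlet transform (base frequency ``omega0 = 6``) on a geometric period
grid, with cross-wavelet power ``|Wx Wy*|`` and coherence

    R^2 = |S(Wx Wy* / s)|^2 / ( S(|Wx|^2 / s) * S(|Wy|^2 / s) )

where ``S`` smooths in time (a Gaussian window whose width tracks the
scale ``s``) and in scale (a boxcar of 0.6 octave).  Unsmoothed coherence
is identically 1, so the smoothing windows must span more than one point;
this is asserted at construction.

Significance is Monte Carlo: coherence of the observed pair is compared
against coherence of independent white-noise surrogate pairs of the same
length (250 by default).  The p-value uses the plus-one estimator
``p = (1 + #{surrogate >= observed}) / (1 + n_surrogates)``, so the
smallest attainable p with 250 surrogates is 1/251.

Edge effects are handled by the cone of influence (e-folding distance
``sqrt(2) s``), extended to the internal boundaries created when per-trial
standardized segments are concatenated into one per-condition series.

Summaries average the per-period time-averaged coherence over three
period bands: fast (syllable) 0.2-0.5 s, medium (gesture) 0.5-2 s, slow
(clause/sentence) 2-6 s, half-open ``[lo, hi)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io import CONDITIONS, NODAF
from .mixedlm import LRTResult, ModelFit, fit_ladder

logger = logging.getLogger(__name__)

DEFAULT_BANDS = {"fast": (0.2, 0.5), "medium": (0.5, 2.0), "slow": (2.0, 6.0)}


@dataclass
class XWaveletConfig:
    """Grid and smoothing parameters of the wavelet analyses."""

    omega0: float = 6.0
    min_period_s: float = 0.125
    max_period_s: float = 8.0
    voices_per_octave: int = 12
    n_surrogates: int = 250
    scale_smooth_octaves: float = 0.6

    def __post_init__(self):
        if self.min_period_s <= 0 or self.max_period_s <= self.min_period_s:
            raise ValueError("need 0 < min_period_s < max_period_s")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if round(self.scale_smooth_octaves * self.voices_per_octave) < 1:
            raise ValueError("scale smoothing window must span at least one voice")

    @property
    def periods_s(self) -> np.ndarray:
        """Geometric period grid, ``voices_per_octave`` points per octave."""
        n_oct = np.log2(self.max_period_s / self.min_period_s)
        n = int(np.floor(n_oct * self.voices_per_octave)) + 1
        return self.min_period_s * 2.0 ** (np.arange(n) / self.voices_per_octave)

    @property
    def fourier_factor(self) -> float:
        return 4.0 * np.pi / (self.omega0 + np.sqrt(2.0 + self.omega0**2))

    def scales_for(self, periods: np.ndarray) -> np.ndarray:
        return np.asarray(periods) / self.fourier_factor


@dataclass
class CWTResult:
    """Complex Morlet coefficients on the period x time grid."""

    periods_s: np.ndarray
    times_s: np.ndarray
    W: np.ndarray  # complex, shape (n_periods, n_times)
    coi: np.ndarray  # bool, True = inside the cone of influence
    dt: float
    scales: np.ndarray

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.W) ** 2

    def mean_power_per_period(self, in_cone: bool = True) -> np.ndarray:
        p = self.power
        if in_cone:
            p = np.where(self.coi, p, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(p, axis=1)


def _check_length(n: int, dt: float, config: XWaveletConfig) -> None:
    max_ok = n * dt / 4.0
    if config.max_period_s > max_ok:
        raise ValueError(
            f"series of {n} samples supports periods up to {max_ok:.3f} s; "
            f"grid asks for {config.max_period_s} s"
        )


def _coi_mask(n: int, dt: float, scales: np.ndarray,
              boundaries: np.ndarray | None) -> np.ndarray:
    if boundaries is None:
        boundaries = np.array([0, n], dtype=float)
    idx = np.arange(n, dtype=float)
    dist = np.min(np.abs(idx[None, :] - np.asarray(boundaries, dtype=float)[:, None]), axis=0)
    efold = np.sqrt(2.0) * scales / dt  # e-folding distance in samples
    return dist[None, :] >= efold[:, None]


def cwt_morlet(series: np.ndarray, dt: float, config: XWaveletConfig | None = None,
               boundaries=None) -> CWTResult:
    """Morlet CWT of a uniformly sampled series (FFT implementation, zero-padded).

    ``boundaries`` are optional sample indices of internal discontinuities
    (trial joins); the cone of influence excludes the e-folding span around
    each of them as well as the series edges.
    """
    config = config or XWaveletConfig()
    x = np.asarray(series, dtype=float)
    n = len(x)
    _check_length(n, dt, config)
    periods = config.periods_s
    scales = config.scales_for(periods)

    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x - x.mean(), npad)
    wk = 2.0 * np.pi * np.fft.fftfreq(npad, dt)
    pos = wk > 0
    # daughter wavelets in the frequency domain, all scales at once
    arg = scales[:, None] * wk[None, :]
    daughter = np.zeros_like(arg)
    daughter[:, pos] = np.exp(-0.5 * (arg[:, pos] - config.omega0) ** 2)
    daughter *= (np.pi**-0.25) * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
    W = np.fft.ifft(xhat[None, :] * daughter, axis=1)[:, :n]

    coi = _coi_mask(n, dt, scales, None if boundaries is None else np.asarray(boundaries))
    times = np.arange(n) * dt
    return CWTResult(periods_s=periods, times_s=times, W=W, coi=coi, dt=dt, scales=scales)


def cross_wavelet(Wx: CWTResult, Wy: CWTResult) -> np.ndarray:
    """Cross-wavelet coefficients ``Wx * conj(Wy)`` on identical grids."""
    if Wx.W.shape != Wy.W.shape or not np.allclose(Wx.periods_s, Wy.periods_s):
        raise ValueError("cross-wavelet requires identical period x time grids")
    return Wx.W * np.conj(Wy.W)


def _smooth(plane: np.ndarray, scales: np.ndarray, dt: float,
            config: XWaveletConfig) -> np.ndarray:
    """Scale-dependent time smoothing (Gaussian, std = s) then scale boxcar."""
    n = plane.shape[1]
    npad = int(2 ** np.ceil(np.log2(2 * n)))
    F = np.fft.fft(plane, npad, axis=1)
    w = 2.0 * np.pi * np.fft.fftfreq(npad, dt)
    F *= np.exp(-0.5 * (scales[:, None] * w[None, :]) ** 2)
    out = np.fft.ifft(F, axis=1)[:, :n]
    out = out.real if not np.iscomplexobj(plane) else out
    win = max(1, int(round(config.scale_smooth_octaves * config.voices_per_octave)))
    if np.iscomplexobj(out):
        out = (ndimage.uniform_filter1d(out.real, win, axis=0, mode="nearest")
               + 1j * ndimage.uniform_filter1d(out.imag, win, axis=0, mode="nearest"))
    else:
        out = ndimage.uniform_filter1d(out, win, axis=0, mode="nearest")
    return out


@dataclass
class CoherencePlane:
    """Wavelet coherence over (period x time), with optional surrogate p-values."""

    periods_s: np.ndarray
    times_s: np.ndarray
    coherence: np.ndarray  # in [0, 1]
    coi: np.ndarray
    avg_coherence: np.ndarray  # per-period time average inside the cone
    p_plane: np.ndarray | None = None
    p_period: np.ndarray | None = None
    n_surrogates: int = 0

    def band_table(self, bands: dict[str, tuple[float, float]] | None = None,
                   filter_significant: bool = False, alpha: float = 0.05) -> pd.DataFrame:
        return band_average(self, bands=bands, filter_significant=filter_significant,
                            alpha=alpha)


def wavelet_coherence(x: np.ndarray, y: np.ndarray, dt: float,
                      config: XWaveletConfig | None = None,
                      boundaries=None) -> CoherencePlane:
    """Smoothed Morlet wavelet coherence of two aligned series.

    Coherence is normalized: rescaling either input leaves it unchanged,
    and it is symmetric in its arguments.  Values are clipped to [0, 1].
    """
    config = config or XWaveletConfig()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    Wx = cwt_morlet(x, dt, config, boundaries)
    Wy = cwt_morlet(y, dt, config, boundaries)
    s = Wx.scales[:, None]
    Sxy = _smooth(cross_wavelet(Wx, Wy) / s, Wx.scales, dt, config)
    Sxx = _smooth((np.abs(Wx.W) ** 2) / s, Wx.scales, dt, config)
    Syy = _smooth((np.abs(Wy.W) ** 2) / s, Wx.scales, dt, config)
    denom = Sxx * Syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(Sxy) ** 2 / denom
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
    avg = _avg_in_cone(coh, Wx.coi)
    return CoherencePlane(periods_s=Wx.periods_s, times_s=Wx.times_s, coherence=coh,
                          coi=Wx.coi, avg_coherence=avg)


def _avg_in_cone(plane: np.ndarray, coi: np.ndarray) -> np.ndarray:
    masked = np.where(coi, plane, np.nan)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(masked, axis=1)
    return out


def coherence_significance(x: np.ndarray, y: np.ndarray, dt: float,
                           config: XWaveletConfig | None = None,
                           boundaries=None,
                           rng: np.random.Generator | int | None = None) -> CoherencePlane:
    """Wavelet coherence with Monte-Carlo surrogate p-values.

    The null is an independent white-noise pair of the observed length;
    p-values are computed pointwise on the plane and for the per-period
    time-averaged coherence, both with the plus-one estimator.
    """
    config = config or XWaveletConfig()
    rng = np.random.default_rng(rng)
    obs = wavelet_coherence(x, y, dt, config, boundaries)
    n = len(x)
    count_plane = np.zeros_like(obs.coherence)
    count_period = np.zeros_like(obs.avg_coherence)
    for _ in range(config.n_surrogates):
        sx = rng.standard_normal(n)
        sy = rng.standard_normal(n)
        sur = wavelet_coherence(sx, sy, dt, config, boundaries)
        count_plane += sur.coherence >= obs.coherence
        with np.errstate(invalid="ignore"):
            count_period += sur.avg_coherence >= obs.avg_coherence
    m = config.n_surrogates
    obs.p_plane = (1.0 + count_plane) / (1.0 + m)
    obs.p_period = (1.0 + count_period) / (1.0 + m)
    obs.p_period[~np.isfinite(obs.avg_coherence)] = np.nan
    obs.n_surrogates = m
    return obs


def prepare_condition_series(trials: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each trial and concatenate, returning (series, boundary indices).

    Trial boundaries (including both ends) are recorded so the cone of
    influence can exclude the artificial discontinuities that concatenation
    creates.  Zero-variance trials are dropped with a warning; the boundary
    list has one more entry than the number of retained trials.
    """
    parts, edges = [], [0]
    for i, tr in enumerate(trials):
        tr = np.asarray(tr, dtype=float)
        sd = np.std(tr)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("trial %d has zero variance; dropped", i)
            continue
        parts.append((tr - tr.mean()) / sd)
        edges.append(edges[-1] + len(tr))
    if not parts:
        raise ValueError("no non-degenerate trials to concatenate")
    return np.concatenate(parts), np.asarray(edges)


def band_average(plane: CoherencePlane, bands: dict[str, tuple[float, float]] | None = None,
                 filter_significant: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Average the per-period time-averaged coherence over period bands.

    Bands are half-open ``[lo, hi)`` (period 0.5 s belongs to 'medium', not
    'fast').  With ``filter_significant``, only periods whose surrogate
    p-value is below ``alpha`` contribute; a band with no significant
    period yields NaN.
    """
    bands = bands or DEFAULT_BANDS
    rows = []
    for name, (lo, hi) in bands.items():
        sel = (plane.periods_s >= lo) & (plane.periods_s < hi)
        if not np.any(sel):
            raise ValueError(f"band {name!r} [{lo}, {hi}) contains no grid periods")
        vals = plane.avg_coherence[sel]
        if filter_significant:
            if plane.p_period is None:
                raise ValueError("significance filtering requires surrogate p-values")
            vals = vals[plane.p_period[sel] < alpha]
        ok = vals[np.isfinite(vals)]
        rows.append({
            "band": name,
            "period_lo_s": lo,
            "period_hi_s": hi,
            "coherence": float(np.mean(ok)) if len(ok) else np.nan,
            "n_periods": int(len(ok)),
            "filtered": filter_significant,
        })
    return pd.DataFrame(rows)


@dataclass
class BandModelResult:
    """Mixed-model ladder on band-averaged coherence summaries."""

    fits: list[ModelFit]
    lrts: list[LRTResult]

    @property
    def fit_condition(self) -> ModelFit:
        return self.fits[2]

    @property
    def fit_interaction(self) -> ModelFit:
        return self.fits[3]

    def to_dict(self) -> dict:
        return {
            "condition_model": self.fit_condition.to_dict(),
            "interaction_model": self.fit_interaction.to_dict(),
            "lrts": [l.to_dict() for l in self.lrts],
        }


def coherence_band_models(band_summaries: pd.DataFrame) -> BandModelResult:
    """LRT ladder for average coherence: time scale, +condition, +interaction.

    ``band_summaries`` needs columns participant, condition, band,
    coherence (one row per participant x condition x band).  Rows with
    missing coherence (significance-filtered empty bands) are dropped.
    """
    df = band_summaries.dropna(subset=["coherence"]).copy()
    if df["participant"].nunique() < 2:
        raise ValueError("band models need at least 2 participants")
    if df["condition"].nunique() < 2:
        raise ValueError("band models need both conditions")
    df["band"] = pd.Categorical(df["band"], categories=["fast", "medium", "slow"], ordered=True)
    cond = f"C(condition, Treatment('{NODAF}'))"
    fits, lrts = fit_ladder(
        df,
        "coherence",
        [[], ["C(band)"], ["C(band)", cond], ["C(band)", cond, f"C(band):{cond}"]],
        "participant",
        labels=["band", "condition", "interaction"],
    )
    return BandModelResult(fits=fits, lrts=lrts)


def plot_coherence(plane: CoherencePlane, ax=None, show_coi: bool = True):
    """Render a coherence plane (period on a log axis, time on x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    mesh = ax.pcolormesh(plane.times_s, plane.periods_s, plane.coherence,
                         shading="nearest", vmin=0, vmax=1, cmap="viridis")
    if show_coi:
        ax.contour(plane.times_s, plane.periods_s, plane.coi.astype(float),
                   levels=[0.5], colors="white", linewidths=0.8)
    ax.set_yscale("log")
    ax.set_ylabel("period (s)")
    ax.set_xlabel("time (s)")
    ax.invert_yaxis()
    plt.colorbar(mesh, ax=ax, label="coherence")
    return ax
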