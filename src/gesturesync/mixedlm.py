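"""Random-intercept mixed models and likelihood-ratio tests.

All inferential analyses in this package use the same model family: a
linear model for a response (a synchrony offset, its per-cell SD, or an
average wavelet coherence) with categorical fixed effects and a random
intercept per participant,

    y_ij = x_ij' b + u_j + e_ij,   u_j ~ N(0, s_g^2),  e_ij ~ N(0, s^2).

Fits are maximum likelihood (not REML) throughout, because model ladders
are compared with likelihood-ratio tests on fixed effects, which are
invalid under REML.  Estimation is delegated to statsmodels' ``MixedLM``;
this module wraps it in a small results object carrying coefficients, 95%
CIs, t statistics and the ML deviance.

Degenerate designs are handled explicitly: data with (numerically) zero
residual variance break the ML iteration, so such fits fall back to the
exact ordinary-least-squares solution with the group variance pinned at 0,
flagged on the results object.  The same fallback covers single-group
data, where the random intercept is unidentifiable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class SingularModelError(ValueError):
    """Raised when the fixed-effect design is singular (collinear terms)."""


@dataclass
class ModelFit:
    """Coefficients, uncertainties and fit statistics of one model."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (95%)
    tvalues: pd.Series
    df_resid: float
    deviance: float  # -2 log-likelihood (ML)
    n_obs: int
    n_fixed: int
    group: str
    group_var: float
    resid_var: float
    formula: str
    degenerate: bool = False
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, 95% CI, t)."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_low": self.conf_int["lower"],
                "ci_high": self.conf_int["upper"],
                "t": self.tvalues,
            }
        )

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n_obs": self.n_obs,
            "deviance": self.deviance,
            "group_var": self.group_var,
            "resid_var": self.resid_var,
            "degenerate": self.degenerate,
            "coefficients": self.summary().to_dict(orient="index"),
        }


@dataclass
class LRTResult:
    """Chi-square likelihood-ratio comparison of two nested ML fits."""

    chi2: float
    df: int
    p: float
    label: str = ""

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p, "label": self.label}


def _build_formula(response: str, fixed_terms: list[str] | tuple[str, ...]) -> str:
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    return f"{response} ~ {rhs}"


def _ols_fallback(formula: str, data: pd.DataFrame, group: str, reason: str) -> ModelFit:
    import statsmodels.formula.api as smf

    res = smf.ols(formula, data=data).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    logger.warning("mixed model degenerate (%s); exact OLS solution with group variance 0", reason)
    resid_var = float(np.mean(res.resid**2))
    if resid_var > 0:
        llf = float(res.llf)
    else:
        llf = np.inf  # noiseless limit: deviance unbounded below
    return ModelFit(
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        tvalues=res.tvalues,
        df_resid=float(res.df_resid),
        deviance=-2.0 * llf,
        n_obs=int(res.nobs),
        n_fixed=len(res.params),
        group=group,
        group_var=0.0,
        resid_var=resid_var,
        formula=formula,
        degenerate=True,
        converged=True,
    )


def fit_random_intercept_model(
    data: pd.DataFrame,
    response: str,
    fixed_terms: list[str] | tuple[str, ...],
    group: str,
) -> ModelFit:
    """ML fit of ``response ~ fixed_terms + (1 | group)``.

    ``fixed_terms`` are patsy terms (e.g. ``["C(condition)"]``); an empty
    list fits the intercept-only model.  Raises
    :class:`SingularModelError` when the fixed design is collinear, naming
    the offending term.
    """
    import statsmodels.formula.api as smf
    from statsmodels.regression.mixed_linear_model import MixedLM

    data = data.dropna(subset=[response]).reset_index(drop=True)
    formula = _build_formula(response, fixed_terms)

    # screen the fixed design for collinearity first: MixedLM gives cryptic errors
    import patsy

    try:
        X = patsy.dmatrix(formula.split("~", 1)[1], data, return_type="dataframe")
    except Exception as exc:  # pragma: no cover - patsy error paths
        raise SingularModelError(str(exc)) from exc
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a dependent column by leave-one-out rank (blame a named
        # term rather than the intercept where possible)
        cols = [c for c in X.columns if c != "Intercept"] + ["Intercept"]
        for col in cols:
            if col not in X.columns:
                continue
            reduced = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                raise SingularModelError(f"collinear fixed-effect term: {col}")
        raise SingularModelError("singular fixed-effect design")

    y = data[response].to_numpy(dtype=float)
    ols_res = smf.ols(formula, data=data).fit()
    y_scale = float(np.var(y)) if len(y) else 0.0
    resid_var = float(np.mean(ols_res.resid**2))
    n_groups = data[group].nunique()
    if n_groups < 2 or resid_var <= max(y_scale, 1.0) * 1e-12:
        reason = "single group" if n_groups < 2 else "zero residual variance"
        return _ols_fallback(formula, data, group, reason)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, groups=data[group], data=data)
        res = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500, disp=False)
            except (np.linalg.LinAlgError, ValueError):
                continue
            # optimizers can 'converge' onto the variance boundary with a
            # non-finite likelihood or covariance; treat that as a failure
            ok = (np.isfinite(cand.llf)
                  and np.all(np.isfinite(cand.fe_params))
                  and np.all(np.isfinite(np.asarray(cand.bse_fe))))
            if ok:
                res = cand
                if cand.converged:
                    break
        if res is None:
            return _ols_fallback(formula, data, group, "MixedLM failed")

    fe = res.fe_params
    ci_all = res.conf_int(alpha=0.05)
    ci = ci_all.loc[fe.index]
    ci.columns = ["lower", "upper"]
    return ModelFit(
        params=fe,
        bse=res.bse_fe.loc[fe.index],
        conf_int=ci,
        tvalues=res.tvalues.loc[fe.index],
        df_resid=float(len(data) - len(fe)),
        deviance=-2.0 * float(res.llf),
        n_obs=len(data),
        n_fixed=len(fe),
        group=group,
        group_var=float(res.cov_re.iloc[0, 0]),
        resid_var=float(res.scale),
        formula=formula,
        degenerate=False,
        converged=bool(res.converged),
    )


def likelihood_ratio_test(null_fit: ModelFit, alt_fit: ModelFit, label: str = "") -> LRTResult:
    """Chi-square LRT of two nested ML fits on identical rows.

    ``chi2`` is clamped at 0 (ML deviance cannot rise when parameters are
    added, but optimizers jitter); ``df`` is the fixed-parameter
    difference.  Identical models give chi2 = 0, p = 1.
    """
    if null_fit.n_obs != alt_fit.n_obs:
        raise ValueError(
            f"fits use different row counts ({null_fit.n_obs} vs {alt_fit.n_obs}); not comparable"
        )
    df = alt_fit.n_fixed - null_fit.n_fixed
    if df < 0:
        raise ValueError("alternative model has fewer parameters than the null; not nested")
    chi2 = max(0.0, null_fit.deviance - alt_fit.deviance)
    if df == 0:
        p = 1.0 if chi2 <= 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=chi2, df=df, p=p, label=label)


def fit_ladder(
    data: pd.DataFrame,
    response: str,
    term_sequence: list[list[str]],
    group: str,
    labels: list[str] | None = None,
) -> tuple[list[ModelFit], list[LRTResult]]:
    """Fit a nested sequence of models and the sequential LRTs between them.

    ``term_sequence`` lists the cumulative fixed terms of each model (the
    first entry is typically ``[]`` for intercept-only).  Adding a term can
    never increase the ML deviance; this monotonicity is asserted on every
    ladder (within numerical jitter already absorbed by the LRT clamp).
    """
    fits = [fit_random_intercept_model(data, response, terms, group) for terms in term_sequence]
    labels = labels or ["" for _ in range(len(fits) - 1)]
    lrts = [
        likelihood_ratio_test(fits[i], fits[i + 1], label=labels[i])
        for i in range(len(fits) - 1)
    ]
    return fits, lrts
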