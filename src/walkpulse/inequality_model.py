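"""Tract-level linear model of walking with metropolitan fixed effects.

The outcome is the mean distance walked per person per day in a census
tract (meters, unstandardized); covariates are area-level median income,
fraction Black, fraction public-transit users, fraction over 64, park
access and obesity prevalence, each z-scored over the estimation sample,
so coefficients read as meters walked per day per one SD of the
covariate.  An MSA indicator (fixed factor, reference level = the
lexicographically first MSA) absorbs city-level differences such as
weather and infrastructure.  Estimation is ordinary least squares with
classical standard errors; the model is fit separately for the pre- and
post-intervention periods and compared side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import PeriodWindows
from .geo_io import MODEL_COVARIATES
from .panel_stats import weighted_mean, _window_mask

logger = logging.getLogger("walkpulse")


# ---------------------------------------------------------------------------
# Outcome construction


def build_tract_outcomes(summaries: pd.DataFrame, windows: PeriodWindows,
                         min_users: int = 5) -> pd.DataFrame:
    """Weighted mean per-user-day distance by tract and period.

    Tracts with fewer than ``min_users`` distinct users in a period are
    excluded (count logged).  Returns columns ``tract_id, period,
    mean_distance_m, n_users``.
    """
    rows = []
    for period, lo, hi in (("pre", windows.pre_start, windows.pre_end),
                           ("post", windows.post_start, windows.post_end)):
        sub = summaries[_window_mask(summaries["date"], lo, hi)]
        for tr, g in sub.groupby("home_tract", sort=True):
            rows.append((tr, period,
                         weighted_mean(g["distance_m_total"], g["weight"]),
                         g["user_id"].nunique()))
    out = pd.DataFrame(rows, columns=["tract_id", "period",
                                      "mean_distance_m", "n_users"])
    small = out["n_users"] < min_users
    if small.any():
        logger.warning("build_tract_outcomes: excluded %d tract-period(s) "
                       "with < %d users", int(small.sum()), min_users)
    return out[~small].reset_index(drop=True)


def standardize_predictors(attributes: pd.DataFrame,
                           covariates=MODEL_COVARIATES
                           ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """z-score each covariate over the estimation sample (n-1 sd).

    Returns the transformed table and a scaling record (mean, sd per
    covariate) for back-transformation.  A zero-variance covariate is an
    error.
    """
    out = attributes.copy()
    recs = []
    for c in covariates:
        x = out[c].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"covariate {c!r} has zero variance")
        out[c] = (x - mu) / sd
        recs.append((c, mu, sd))
    return out, pd.DataFrame(recs, columns=["covariate", "mean", "sd"])


# ---------------------------------------------------------------------------
# Model fit


@dataclass
class FitResult:
    """OLS fit of the tract walking model with MSA fixed effects."""

    coefficients: pd.Series        # meters/day per SD, per covariate
    standard_errors: pd.Series
    p_values: pd.Series
    intercept: float               # reference-MSA constant
    intercept_se: float
    msa_effects: pd.Series         # offsets of non-reference MSAs
    r2: float
    adjusted_r2: float
    residual_se: float
    df_resid: int
    f_statistic: float
    n_obs: int
    reference_msa: str
    raw: object = None             # underlying statsmodels results

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.raw.conf_int(alpha=alpha)
        return ci.loc[self.coefficients.index].set_axis(["lo", "hi"], axis=1)


def fit_fixed_effect_model(outcomes: pd.DataFrame,
                           covariates: pd.DataFrame,
                           covariate_names=MODEL_COVARIATES,
                           weights: Optional[pd.Series] = None) -> FitResult:
    """OLS of tract mean distance on z-scored covariates + MSA dummies.

    ``outcomes`` needs ``tract_id`` and ``mean_distance_m``;
    ``covariates`` the z-scored covariate columns plus ``msa_id``.
    Rows with missing values are dropped (logged).  ``weights`` enables
    population-weighted least squares (default: unweighted).
    """
    df = outcomes.merge(covariates, on="tract_id")
    cols = list(covariate_names) + ["mean_distance_m", "msa_id"]
    n0 = len(df)
    df = df.dropna(subset=cols)
    if len(df) < n0:
        logger.warning("fit_fixed_effect_model: dropped %d row(s) with "
                       "missing data", n0 - len(df))
    msas = sorted(df["msa_id"].unique())
    if len(msas) < 2:
        logger.warning("fit_fixed_effect_model: single MSA; fixed factor "
                       "degenerates to the intercept")
    ref = msas[0]
    X = df[list(covariate_names)].astype(float)
    dummies = pd.get_dummies(df["msa_id"], prefix="msa", dtype=float)
    dummies = dummies.drop(columns=f"msa_{ref}", errors="ignore")
    # build design; statsmodels reports exact collinearity via rank
    design = pd.concat([X, dummies], axis=1)
    design = sm.add_constant(design, prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        keep = []
        for c in design.columns:
            cand = design[keep + [c]].to_numpy()
            if np.linalg.matrix_rank(cand) == len(keep):
                bad.append(c)
            else:
                keep.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    y = df["mean_distance_m"].astype(float)
    if weights is not None:
        res = sm.WLS(y, design, weights=weights.loc[df.index]).fit()
    else:
        res = sm.OLS(y, design).fit()

    coefs = res.params[list(covariate_names)]
    ses = res.bse[list(covariate_names)]
    pvals = res.pvalues[list(covariate_names)]
    msa_cols = [c for c in design.columns if c.startswith("msa_")]
    return FitResult(
        coefficients=coefs, standard_errors=ses, p_values=pvals,
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        msa_effects=res.params[msa_cols],
        r2=float(res.rsquared), adjusted_r2=float(res.rsquared_adj),
        residual_se=float(np.sqrt(res.mse_resid)),
        df_resid=int(res.df_resid),
        f_statistic=float(res.fvalue),
        n_obs=int(res.nobs), reference_msa=ref, raw=res)


# ---------------------------------------------------------------------------
# Period comparison


def significance_stars(p: float) -> str:
    """Stars: * p<0.1, ** p<0.05, *** p<0.01."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def compare_periods(fit_pre: FitResult, fit_post: FitResult) -> pd.DataFrame:
    """Side-by-side coefficient table for the two periods.

    Rows: covariates, the constant, then observations, R2, adjusted R2,
    residual SE and F statistic; columns formatted as
    ``coefficient^stars (SE)``.
    """
    def fmt(c, s, p):
        return f"{c:.3f}{significance_stars(p)} ({s:.3f})"

    rows = []
    for name in fit_pre.coefficients.index:
        rows.append((name,
                     fmt(fit_pre.coefficients[name],
                         fit_pre.standard_errors[name],
                         fit_pre.p_values[name]),
                     fmt(fit_post.coefficients[name],
                         fit_post.standard_errors[name],
                         fit_post.p_values[name])))
    for label, pre_v, post_v in (
            ("Constant",
             f"{fit_pre.intercept:.3f} ({fit_pre.intercept_se:.3f})",
             f"{fit_post.intercept:.3f} ({fit_post.intercept_se:.3f})"),
            ("MSA fixed effect", "Yes", "Yes"),
            ("Observations", str(fit_pre.n_obs), str(fit_post.n_obs)),
            ("R2", f"{fit_pre.r2:.3f}", f"{fit_post.r2:.3f}"),
            ("Adjusted R2", f"{fit_pre.adjusted_r2:.3f}",
             f"{fit_post.adjusted_r2:.3f}"),
            (f"Residual SE (df={fit_pre.df_resid})",
             f"{fit_pre.residual_se:.3f}", f"{fit_post.residual_se:.3f}"),
            ("F statistic", f"{fit_pre.f_statistic:.3f}",
             f"{fit_post.f_statistic:.3f}")):
        rows.append((label, pre_v, post_v))
    return pd.DataFrame(rows, columns=["term", "pre", "post"])


def fit_periods(summaries: pd.DataFrame, attributes: pd.DataFrame,
                windows: PeriodWindows, min_users: int = 5,
                ) -> Dict[str, FitResult]:
    """Convenience: build outcomes, standardize, fit pre and post."""
    outcomes = build_tract_outcomes(summaries, windows, min_users)
    fits = {}
    for period in ("pre", "post"):
        sub = outcomes[outcomes["period"] == period]
        attrs = attributes[attributes["tract_id"].isin(sub["tract_id"])]
        z, _ = standardize_predictors(attrs)
        fits[period] = fit_fixed_effect_model(sub, z)
    return fits
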