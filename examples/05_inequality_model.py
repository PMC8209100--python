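"""Fit the tract-level fixed-effects model on planted synthetic data.

Tract covariates are drawn from a correlated copula and the outcome
(mean meters walked per person per day) from a known linear model with
MSA intercepts; the fit should recover the planted coefficients --
exactly when noise is zero, within sampling error otherwise.
"""

import pandas as pd

import walkpulse as wp
from walkpulse.geo_io import MODEL_COVARIATES
from walkpulse.inequality_model import (fit_fixed_effect_model,
                                        standardize_predictors)

attrs, truth = wp.simulate_tract_attributes(2000, 8, noise_sd=100.0, seed=42)
z, scaling = standardize_predictors(attrs)
fit = fit_fixed_effect_model(
    truth.rename(columns={"outcome": "mean_distance_m"}), z)

table = pd.DataFrame({
    "planted_m_per_sd": [wp.DEFAULT_BETA[c] for c in MODEL_COVARIATES],
    "estimate": fit.coefficients.round(3),
    "se": fit.standard_errors.round(3),
})
print(table.to_string())
print(f"\nR2 = {fit.r2:.3f}, adjusted R2 = {fit.adjusted_r2:.3f}, "
      f"n = {fit.n_obs}, residual SE = {fit.residual_se:.1f}")

# Each estimate should sit within ~2 SE of its planted value; the
# public-transit coefficient (~54 m/day per SD) dominates, mirroring
# the strong association between transit use and walking.
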