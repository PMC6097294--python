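"""On-treatment effect estimation with a random-intercept linear mixed model.

ASIS observations collected on treatment are modelled as

    asis_ij = beta_0 + beta_1 * t_ij + b_i + e_ij,

where t_ij is years since treatment start for patient i at visit j, b_i a
patient-level random intercept and e_ij residual noise.  beta_1 is the
average annual change of ASIS on treatment; expressed relative to the
fitted baseline it gives a percent annual change,
100 * beta_1 / beta_0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .severity import InsufficientDataError


@dataclass(frozen=True)
class TreatmentObservation:
    """One on-treatment ASIS measurement."""

    patient_id: str
    time_on_treatment: float  # years since treatment start; 0 = baseline
    asis: float

    def __post_init__(self) -> None:
        if self.time_on_treatment < 0:
            raise ValueError(
                f"time on treatment must be >= 0, got {self.time_on_treatment}"
            )


@dataclass
class TreatmentFit:
    """Mixed-model estimates of on-treatment ASIS change."""

    fixed_intercept: float
    fixed_slope: float  # ASIS units per year
    random_intercept_sd: float
    residual_sd: float
    slope_p_value: float
    percent_annual_change: float
    n_patients: int
    n_observations: int
    reml: bool
    boundary_fit: bool  # random-intercept variance at (or near) zero


def observations_frame(observations: Sequence[TreatmentObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [o.patient_id for o in observations],
            "time": [o.time_on_treatment for o in observations],
            "asis": [o.asis for o in observations],
        }
    )


def fit_treatment_model(
    observations: Sequence[TreatmentObservation], reml: bool = True
) -> TreatmentFit:
    """Fit asis ~ time with a patient random intercept (REML by default).

    Requires at least two patients and repeated measures for at least one
    of them; a design with all observation times equal is degenerate.  When
    the random-intercept variance collapses to the boundary (e.g. one
    observation per patient) the fit degrades gracefully to ordinary
    regression and is flagged ``boundary_fit``.
    """
    df = observations_frame(observations)
    if len(df) < 3:
        raise InsufficientDataError("treatment model needs >= 3 observations")
    if np.ptp(df["time"].to_numpy()) == 0:
        raise ValueError("degenerate design: all observation times are equal")

    single_level = (
        df["patient_id"].nunique() < 2 or df.groupby("patient_id").size().max() < 2
    )
    if single_level:
        # The patient level is not identifiable (one patient, or no repeated
        # measures): degrade to ordinary regression with the variance at the
        # boundary, flagged for the caller.
        ols = sm.OLS(df["asis"], sm.add_constant(df["time"])).fit()
        re_var, resid_var = 0.0, float(ols.scale)
        slope, intercept = float(ols.params["time"]), float(ols.params["const"])
        slope_p = float(ols.pvalues["time"])
    else:
        model = smf.mixedlm("asis ~ time", df, groups=df["patient_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            result = model.fit(reml=reml, method=["lbfgs", "powell"])
        re_var = float(np.asarray(result.cov_re)[0, 0])
        resid_var = float(result.scale)
        slope = float(result.params["time"])
        intercept = float(result.params["Intercept"])
        slope_p = float(result.pvalues["time"])
    boundary = re_var <= 1e-8 * max(resid_var, 1e-12)
    if boundary:
        warnings.warn(
            "random-intercept variance at boundary; fit equivalent to ordinary regression",
            RuntimeWarning,
        )
    pct = percent_from(slope, intercept)
    return TreatmentFit(
        fixed_intercept=intercept,
        fixed_slope=slope,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(resid_var)),
        slope_p_value=slope_p,
        percent_annual_change=pct,
        n_patients=int(df["patient_id"].nunique()),
        n_observations=len(df),
        reml=reml,
        boundary_fit=bool(boundary),
    )


def percent_from(slope: float, intercept: float) -> float:
    if intercept == 0:
        raise ZeroDivisionError("percent annual change undefined at zero baseline")
    return 100.0 * slope / intercept


def percent_annual_change(fit: TreatmentFit) -> float:
    """Percent annual ASIS change relative to the fitted baseline (sign carried)."""
    return percent_from(fit.fixed_slope, fit.fixed_intercept)
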