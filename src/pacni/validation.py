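"""Downstream validation statistics for pace scores.

Three estimators cover the standard epidemiological checks run on a
brain-derived aging score:

* cross-sectional associations as standardized betas (outcome and exposure
  z-scored on the analysis sample, covariates raw), with optional
  cluster-robust (sandwich) standard errors for repeated observations;
* Cox proportional-hazards models (Efron tie handling) with the exposure
  z-scored so hazard ratios are per standard deviation;
* multilevel extraction of per-subject atrophy slopes (volume on age with a
  random intercept and slope per participant), whose association with
  baseline scores tests whether faster scores predict accelerated atrophy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericError

log = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    standardized_beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    robust: bool = False


@dataclass
class SurvivalResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float
    se: float
    n: int
    n_events: int
    ties_method: str = "efron"


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("cannot z-score a constant variable")
    return (x - x.mean()) / sd


def standardized_association(
    outcome, exposure, covariates=None, cluster_ids=None
) -> AssociationResult:
    """Standardized beta of ``outcome`` on ``exposure`` controlling for
    ``covariates``; optional cluster-robust variance.

    Outcome and exposure are z-scored on the analysis sample (after listwise
    deletion); covariates enter unstandardized.  With ``cluster_ids`` the
    variance is the CR0 sandwich with a G/(G-1) small-sample factor; CIs use
    the normal approximation beta +/- 1.96 se throughout.
    """
    import statsmodels.api as sm

    frame = pd.DataFrame({"outcome": np.asarray(outcome, float),
                          "exposure": np.asarray(exposure, float)})
    cov_names = []
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov.index = frame.index
        for c in cov.columns:
            frame[f"cov_{c}"] = cov[c].astype(float).to_numpy()
            cov_names.append(f"cov_{c}")
    if cluster_ids is not None:
        frame["_cluster"] = np.asarray(cluster_ids)
    before = len(frame)
    frame = frame.dropna()
    if len(frame) < before:
        log.info("listwise deletion dropped %d rows", before - len(frame))
    n = len(frame)
    if n <= 2 + len(cov_names):
        raise DataError("not enough complete cases")

    y = _zscore(frame["outcome"])
    x = _zscore(frame["exposure"])
    X = np.column_stack([np.ones(n), x] + [frame[c].to_numpy() for c in cov_names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])

    if cluster_ids is None:
        se = float(fit.bse[1])
        p = float(fit.pvalues[1])
        robust = False
    else:
        resid = fit.resid
        XtX_inv = np.linalg.inv(X.T @ X)
        groups = frame["_cluster"].to_numpy()
        meat = np.zeros((X.shape[1], X.shape[1]))
        for g in np.unique(groups):
            m = groups == g
            s = X[m].T @ resid[m]
            meat += np.outer(s, s)
        G = len(np.unique(groups))
        if G < 2:
            raise DataError("cluster-robust variance needs >= 2 clusters")
        V = XtX_inv @ meat @ XtX_inv * (G / (G - 1))
        se = float(np.sqrt(V[1, 1]))
        p = float(2 * stats.norm.sf(abs(beta / se)))
        robust = True
    return AssociationResult(
        standardized_beta=beta, se=se,
        ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        p_value=p, n=n, robust=robust,
    )


def cox_ph(time, event, exposure, covariates=None, ties_method: str = "efron") -> SurvivalResult:
    """Cox proportional-hazards model; HR per standard deviation of exposure.

    Partial-likelihood maximization uses Efron's tie correction (the only
    tie handling provided).  Exposure is z-scored before fitting; covariates
    enter unstandardized.
    """
    if ties_method != "efron":
        raise DataError(f"only Efron tie handling is available, got {ties_method!r}")
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.any(t <= 0):
        raise DataError("event/censoring times must be positive")
    if e.sum() < 1:
        raise DataError("no events observed")
    frame = pd.DataFrame({"time": t, "event": e, "exposure": _zscore(exposure)})
    cov_cols = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            name = f"cov_{c}"
            frame[name] = cov[c].astype(float).to_numpy()
            cov_cols.append(name)
        design = frame[["exposure"] + cov_cols].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([design])) < design.shape[1]:
            raise DataError("singular design: collinear exposure/covariates")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-10})
    except ConvergenceError as exc:
        raise NumericError(f"Cox model failed to converge: {exc}") from exc
    coef = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    return SurvivalResult(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p_value=float(cph.summary.loc["exposure", "p"]),
        coefficient=coef, se=se,
        n=len(frame), n_events=int(e.sum()),
        ties_method="efron",
    )


def extract_atrophy_slopes(volumes: pd.DataFrame, estimator: str = "mixed") -> pd.Series:
    """Per-subject volume slopes (mm^3/year) from a multilevel model.

    ``volumes`` columns: subject_id, age, volume.  The model regresses
    volume on age (centered at the sample mean) with a random intercept and
    random age slope per participant; each subject's slope is the fixed age
    coefficient plus their random slope.  Subjects with a single time point
    are excluded with a logged warning.
    """
    required = {"subject_id", "age", "volume"}
    if not required.issubset(volumes.columns):
        raise DataError(f"volumes table lacks columns: {sorted(required - set(volumes.columns))}")
    counts = volumes.groupby("subject_id")["age"].nunique()
    single = counts[counts < 2].index
    if len(single) == len(counts):
        raise DataError("all subjects have a single time point")
    if len(single):
        log.warning("excluding %d single-time-point subject(s)", len(single))
        volumes = volumes[~volumes["subject_id"].isin(single)]

    d = volumes.copy()
    d["age_c"] = d["age"] - d["age"].mean()
    if estimator == "per_subject_ols":
        slopes = {
            sid: float(np.polyfit(g["age_c"], g["volume"], 1)[0])
            for sid, g in d.groupby("subject_id")
        }
        return pd.Series(slopes, name="atrophy_slope")
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(
            "volume ~ age_c", d, groups=d["subject_id"], re_formula="~age_c"
        ).fit(reml=True, method=["lbfgs", "bfgs"])
    fixed = float(fit.fe_params.iloc[1])
    slopes = {g: fixed + float(re.iloc[1]) for g, re in fit.random_effects.items()}
    return pd.Series(slopes, name="atrophy_slope")
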