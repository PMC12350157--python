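"""Longitudinal Pace-of-Aging composite.

A cohort is followed over repeated waves (by default at ages 26, 32, 38 and
45) on a panel of 19 biomarkers spanning cardiovascular, metabolic, renal,
immune, pulmonary and dental function.  The composite is built in three
steps:

1. **Standardize** every biomarker against its baseline-wave distribution,
   separately for men and women, and align signs so that a larger z-score
   always means worse physiology (``decline_direction`` in the catalog).
2. **Fit a growth model** per biomarker — a linear mixed model of z-score on
   age (centered at baseline) with a random intercept and random slope per
   subject — yielding each subject's annual z-change for that biomarker.
   A per-subject OLS estimator is available for degenerate designs.
3. **Compose**: sum the 19 direction-aligned slopes per subject
   (unit weighting) and rescale the sum so the cohort mean equals 1,
   giving a year-equivalent pace score (mean 1 by construction; a score of
   1.2 reads as 20% faster-than-average physiological decline per year).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateDataError,
    InsufficientLongitudinalDataError,
)

log = logging.getLogger(__name__)

DEFAULT_WAVE_AGES = (26.0, 32.0, 38.0, 45.0)

#: The 19-biomarker catalog: name -> decline direction
#: (+1 = higher value is worse, -1 = higher value is better).
DEFAULT_BIOMARKER_CATALOG: dict[str, int] = {
    "bmi": +1,
    "waist_hip_ratio": +1,
    "hba1c": +1,
    "leptin": +1,
    "mean_arterial_pressure": +1,
    "vo2max": -1,
    "fev1_fvc_ratio": -1,
    "fev1": -1,
    "total_cholesterol": +1,
    "triglycerides": +1,
    "hdl": -1,
    "lipoprotein_a": +1,
    "apob_apoa1_ratio": +1,
    "egfr": -1,
    "blood_urea_nitrogen": +1,
    "hscrp": +1,
    "white_blood_cell_count": +1,
    "periodontal_attachment_loss": +1,
    "tooth_decay": +1,
}

N_BIOMARKERS = 19


@dataclass
class BiomarkerPanel:
    """Long-format repeated biomarker observations plus the signed catalog.

    ``data`` columns: subject_id, sex (0/1), age, biomarker, value.
    """

    data: pd.DataFrame
    catalog: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_CATALOG)
    )
    wave_ages: tuple = DEFAULT_WAVE_AGES
    standardized: bool = False

    def __post_init__(self):
        required = {"subject_id", "sex", "age", "biomarker", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise DataError(f"panel data lacks columns: {sorted(missing)}")
        unknown = set(self.data["biomarker"].unique()) - set(self.catalog)
        if unknown:
            raise DataError(f"panel contains biomarkers absent from catalog: {sorted(unknown)}")


def standardize_biomarkers(
    panel: BiomarkerPanel, baseline_wave: float = 26.0
) -> BiomarkerPanel:
    """Z-score each biomarker against its sex-specific baseline-wave
    distribution and apply the decline direction (larger z = worse).

    Every wave is scaled by the baseline stratum's mean and s.d., so the
    baseline-wave values of each biomarker x sex stratum have mean 0 and
    s.d. 1 after the transform (up to the sign flip).
    """
    df = panel.data.copy()
    base = df[df["age"] == baseline_wave]
    if base.empty:
        raise DataError(f"no observations at baseline wave {baseline_wave}")
    stats = (
        base.groupby(["biomarker", "sex"])["value"]
        .agg(["mean", "std", "count"])
        .rename(columns={"std": "sd"})
    )
    expected = {(b, s) for b in df["biomarker"].unique() for s in df["sex"].unique()}
    missing = expected - set(stats.index)
    if missing:
        raise DataError(f"strata missing baseline-wave observations: {sorted(missing)}")
    degenerate = stats[(stats["sd"] == 0) | stats["sd"].isna()]
    if not degenerate.empty:
        b, s = degenerate.index[0]
        raise DegenerateDataError(
            f"zero baseline variance for biomarker {b!r}, sex {s!r}"
        )
    merged = df.merge(
        stats.reset_index()[["biomarker", "sex", "mean", "sd"]],
        on=["biomarker", "sex"],
        how="left",
    )
    direction = merged["biomarker"].map(panel.catalog)
    merged["value"] = direction * (merged["value"] - merged["mean"]) / merged["sd"]
    out = merged.drop(columns=["mean", "sd"])
    return BiomarkerPanel(
        out, catalog=dict(panel.catalog), wave_ages=panel.wave_ages, standardized=True
    )


@dataclass
class GrowthModelFit:
    """Mixed-growth-model fit for one biomarker (z-units per year)."""

    biomarker: str
    fixed_intercept: float
    fixed_slope: float
    subject_slopes: pd.Series  # per-subject total slope (fixed + random)
    random_slopes: pd.Series
    residual_variance: float
    estimator: str


def _fit_one_mixed(sub: pd.DataFrame, name: str, baseline_age: float) -> GrowthModelFit:
    import statsmodels.formula.api as smf

    d = sub.copy()
    d["age_c"] = d["age"] - baseline_age
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ age_c", d, groups=d["subject_id"], re_formula="~age_c"
        )
        fit = model.fit(reml=True, method="lbfgs")
    # (near-)noiseless trajectories make the variance components degenerate
    # and BLUP shrinkage meaningless; the saturated per-subject OLS solution
    # is exact there.
    if not np.isfinite(fit.scale) or fit.scale < 1e-10 * d["value"].var():
        log.info("biomarker %s: degenerate mixed fit, using per-subject OLS", name)
        return _fit_one_ols(sub, name, baseline_age)
    gamma0, gamma1 = float(fit.fe_params.iloc[0]), float(fit.fe_params.iloc[1])
    rand = pd.Series(
        {g: float(re.iloc[1]) for g, re in fit.random_effects.items()},
        name=name,
    )
    total = gamma1 + rand
    return GrowthModelFit(
        biomarker=name,
        fixed_intercept=gamma0,
        fixed_slope=gamma1,
        subject_slopes=total,
        random_slopes=rand,
        residual_variance=float(fit.scale),
        estimator="mixed",
    )


def _fit_one_ols(sub: pd.DataFrame, name: str, baseline_age: float) -> GrowthModelFit:
    slopes, intercepts = {}, []
    for sid, g in sub.groupby("subject_id"):
        x = g["age"].to_numpy(float) - baseline_age
        y = g["value"].to_numpy(float)
        b1, b0 = np.polyfit(x, y, 1)
        slopes[sid] = float(b1)
        intercepts.append(float(b0))
    total = pd.Series(slopes, name=name)
    gamma1 = float(total.mean())
    return GrowthModelFit(
        biomarker=name,
        fixed_intercept=float(np.mean(intercepts)),
        fixed_slope=gamma1,
        subject_slopes=total,
        random_slopes=total - gamma1,
        residual_variance=float("nan"),
        estimator="per_subject_ols",
    )


def fit_biomarker_slopes(
    panel: BiomarkerPanel,
    estimator: str = "mixed",
    baseline_age: float | None = None,
) -> list[GrowthModelFit]:
    """Fit one growth model per biomarker; per-subject slope = fixed + random.

    Subjects with fewer than two distinct wave ages for a biomarker are
    excluded from that biomarker's fit with a logged warning.
    """
    if estimator not in ("mixed", "per_subject_ols"):
        raise DataError(f"unknown slope estimator {estimator!r}")
    baseline_age = panel.wave_ages[0] if baseline_age is None else baseline_age
    fits = []
    for name, sub in panel.data.groupby("biomarker", sort=True):
        n_waves = sub.groupby("subject_id")["age"].nunique()
        single = n_waves[n_waves < 2].index
        if len(single) == len(n_waves):
            raise InsufficientLongitudinalDataError(
                f"all subjects have a single wave for biomarker {name!r}"
            )
        if len(single):
            log.warning(
                "biomarker %s: excluding %d single-wave subject(s): %s",
                name, len(single), list(single)[:5],
            )
            sub = sub[~sub["subject_id"].isin(single)]
        fit_fn = _fit_one_mixed if estimator == "mixed" else _fit_one_ols
        fits.append(fit_fn(sub, name, baseline_age))
    return fits


def slopes_frame(fits: list[GrowthModelFit]) -> pd.DataFrame:
    """Subjects x biomarkers matrix of direction-aligned annual z-slopes."""
    return pd.concat([f.subject_slopes for f in fits], axis=1)


def compose_pace(
    fits: list[GrowthModelFit],
    catalog: dict[str, int] | None = None,
    allow_subset: bool = False,
) -> pd.DataFrame:
    """Unit-weighted composite: sum the per-subject slopes across biomarkers
    and rescale so the cohort mean is exactly 1 (year-equivalent units).

    Returns a DataFrame indexed by subject with the per-biomarker slopes,
    ``raw_sum`` and ``pace``.  Subjects missing any biomarker slope are
    dropped with a warning.
    """
    catalog = dict(DEFAULT_BIOMARKER_CATALOG) if catalog is None else catalog
    fitted = {f.biomarker for f in fits}
    missing = set(catalog) - fitted
    if missing and not allow_subset:
        raise DataError(
            f"slopes missing for {len(missing)} catalog biomarkers: {sorted(missing)[:5]}"
        )
    slopes = slopes_frame(fits)
    incomplete = slopes.index[slopes.isna().any(axis=1)]
    if len(incomplete):
        log.warning("dropping %d subject(s) with incomplete slopes", len(incomplete))
        slopes = slopes.drop(index=incomplete)
    raw_sum = slopes.sum(axis=1)
    mean = raw_sum.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise DegenerateDataError(
            f"cohort mean slope sum is {mean:.4g}; no year-equivalent scaling exists"
        )
    out = slopes.copy()
    out["raw_sum"] = raw_sum
    out["pace"] = raw_sum / mean
    out.index.name = "subject_id"
    return out


def pace_of_aging(
    panel: BiomarkerPanel,
    baseline_wave: float = 26.0,
    estimator: str = "mixed",
    allow_subset: bool = False,
) -> pd.DataFrame:
    """End-to-end composite: standardize, fit slopes, compose."""
    z = standardize_biomarkers(panel, baseline_wave=baseline_wave)
    fits = fit_biomarker_slopes(z, estimator=estimator, baseline_age=baseline_wave)
    return compose_pace(fits, catalog=panel.catalog, allow_subset=allow_subset)
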