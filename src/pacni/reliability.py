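"""Test-retest reliability via the two-way mixed-effects ICC(3,1).

Sessions are modeled as a fixed effect and participants as a random
effect; ICC(3,1) is the consistency form for single measurements,

    ICC(3,1) = (MS_rows - MS_error) / (MS_rows + (k - 1) * MS_error)

from the two-way ANOVA decomposition of an n-subjects x k-sessions score
matrix.  Consistency (not absolute agreement): a constant shift applied to
one whole session leaves the coefficient unchanged.

An optional per-subject between-session interval can be partialled out as
an effect of no interest: scores are residualized on the interval (with an
intercept) before the ANOVA.  Confidence bounds use the Shrout-Fleiss
F-distribution intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_error: float
    n_subjects: int
    k_sessions: int
    ci_low: float
    ci_high: float


def icc_3_1(scores, intervals=None, confidence: float = 0.95) -> ICCResult:
    """ICC(3,1) of an n x k complete score matrix.

    ``intervals``: optional per-subject test-retest interval (e.g., days),
    residualized out of the scores before the ANOVA.
    """
    M = np.asarray(scores, dtype=float)
    if M.ndim != 2:
        raise DataError("scores must be an n x k matrix")
    n, k = M.shape
    if n < 2 or k < 2:
        raise DataError(f"need >= 2 subjects and >= 2 sessions, got {n} x {k}")
    if not np.isfinite(M).all():
        raise DataError("score matrix is incomplete or non-finite")

    if intervals is not None:
        iv = np.asarray(intervals, dtype=float)
        if iv.shape != (n,):
            raise DataError("intervals must be one value per subject")
        if np.ptp(iv) > 0:
            X = np.column_stack([np.ones(n * k), np.repeat(iv, k)])
            yv = M.reshape(-1)
            coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
            M = (yv - X @ coef).reshape(n, k)

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ms_rows <= 0 or np.isclose(ms_rows, 0.0):
        warnings.warn("zero between-subject variance; ICC set to 0", stacklevel=2)
        return ICCResult(0.0, ms_rows, ms_err, n, k, float("nan"), float("nan"))

    if ms_err <= 0 or ms_err < 1e-12 * ms_rows:  # SS_err can go tiny-negative numerically
        return ICCResult(1.0, ms_rows, max(ms_err, 0.0), n, k, 1.0, 1.0)

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    # Shrout-Fleiss F bounds for ICC(3,1)
    a = (1 - confidence) / 2
    df1, df2 = n - 1, (n - 1) * (k - 1)
    F = ms_rows / ms_err
    fl = F / stats.f.ppf(1 - a, df1, df2)
    fu = F * stats.f.ppf(1 - a, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(ms_rows), float(ms_err), n, k,
                     float(ci_low), float(ci_high))
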