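"""Normative w-scores, cognitive domains, and impairment classification.

A w-score expresses a subject's raw test score as a deviation from the
value predicted for them from the healthy-control sample, in units of the
control residual standard deviation:

    w = (observed - predicted(age, education)) / SD(control residuals)

The normative model is an ordinary least-squares regression of the raw
score on age and education, fitted on controls only.  Tests whose raw
scale is timed or error-based (lower = better) are sign-flipped before
modelling so that higher w always means better performance.

Impairment follows the two-rule convention used in cancer-and-cognition
research: impaired iff at least two w-scores <= -1.5, or at least one
w-score <= -2.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import DEFAULT_DOMAIN_MAP, DEFAULT_TEST_ORIENTATION

__all__ = [
    "NormativeModel",
    "fit_normative_model",
    "w_score",
    "domain_scores",
    "classify_impairment",
]


@dataclass
class NormativeModel:
    """Per-test OLS coefficients and residual SD, fitted on controls."""

    coefficients: pd.DataFrame  # rows: tests; columns: intercept, age, education
    residual_sd: pd.Series
    orientation: dict = field(default_factory=dict)  # test -> higher_raw_is_better
    n_controls: int = 0

    @property
    def tests(self) -> list[str]:
        return list(self.coefficients.index)


def _oriented(raw: pd.DataFrame, orientation: dict) -> pd.DataFrame:
    """Flip timed/error tests so that higher always means better."""
    out = raw.copy()
    for test in out.columns:
        if not orientation.get(test, True):
            out[test] = -out[test]
    return out


def fit_normative_model(
    controls: pd.DataFrame,
    tests: list[str] | None = None,
    orientation: dict | None = None,
) -> NormativeModel:
    """Fit the per-test normative regressions on the control sample.

    ``controls`` must contain ``age`` and ``education`` columns plus one
    column per raw test score.  The residual SD uses an n-3 denominator
    (three fitted parameters).  Raises on degenerate predictors or a zero
    residual SD (a noiseless test has no normative spread to standardize
    against).
    """
    if orientation is None:
        orientation = DEFAULT_TEST_ORIENTATION
    if tests is None:
        tests = [c for c in controls.columns if c not in ("subject_id", "group", "age", "sex", "education")]
    n = len(controls)
    if n < 10:
        raise ValueError(f"need at least 10 controls to fit normative models, got {n}")
    age = controls["age"].to_numpy(dtype=float)
    edu = controls["education"].to_numpy(dtype=float)
    if age.std() == 0 or edu.std() == 0:
        raise ValueError("age and education must vary across controls")
    X = sm.add_constant(np.column_stack([age, edu]))

    oriented = _oriented(controls[tests], orientation)
    coefs = {}
    sds = {}
    for test in tests:
        y = oriented[test].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear predictors while fitting test {test!r}")
        resid = y - fit.fittedvalues
        sd = float(np.sqrt((resid**2).sum() / (n - 3)))
        if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
            raise ValueError(
                f"degenerate residual SD for test {test!r}: control scores are an "
                "exact function of age and education"
            )
        coefs[test] = fit.params
        sds[test] = sd

    coef_df = pd.DataFrame(coefs).T
    coef_df.columns = ["intercept", "age", "education"]
    return NormativeModel(
        coefficients=coef_df,
        residual_sd=pd.Series(sds),
        orientation=dict(orientation),
        n_controls=n,
    )


def w_score(model: NormativeModel, raw: pd.DataFrame) -> pd.DataFrame:
    """w-scores for every subject x test in ``raw``.

    ``raw`` must contain ``age`` and ``education`` plus the model's test
    columns (raw instrument scale; orientation flips are applied here with
    the model's stored convention).  Higher w = better performance.
    """
    age = raw["age"].to_numpy(dtype=float)
    edu = raw["education"].to_numpy(dtype=float)
    oriented = _oriented(raw[model.tests], model.orientation)
    out = {}
    for test in model.tests:
        b = model.coefficients.loc[test]
        predicted = b["intercept"] + b["age"] * age + b["education"] * edu
        out[test] = (oriented[test].to_numpy(dtype=float) - predicted) / model.residual_sd[test]
    return pd.DataFrame(out, index=raw.index)


def domain_scores(
    wscores: pd.DataFrame,
    domain_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Unweighted mean of member-test w-scores per cognitive domain.

    Tests missing from ``wscores`` are dropped; a domain with no present
    member tests gets NaN.  Adds an ``impaired`` boolean column applying
    :func:`classify_impairment` to each subject's test-level w-scores.
    """
    if domain_map is None:
        domain_map = DEFAULT_DOMAIN_MAP
    out = pd.DataFrame(index=wscores.index)
    for domain, members in domain_map.items():
        present = [t for t in members if t in wscores.columns]
        out[domain] = wscores[present].mean(axis=1) if present else np.nan
    out["impaired"] = [
        classify_impairment(wscores.loc[i].dropna().to_numpy()) for i in wscores.index
    ]
    return out


def classify_impairment(test_wscores) -> bool:
    """True iff >= 2 w-scores at or below -1.5, or >= 1 at or below -2.0."""
    w = np.asarray(test_wscores, dtype=float)
    if w.size == 0:
        raise ValueError("at least one test w-score is required")
    return bool(((w <= -1.5).sum() >= 2) or ((w <= -2.0).sum() >= 1))
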