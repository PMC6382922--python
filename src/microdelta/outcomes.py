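"""Adenoma-outcome models, cohort comparisons and storage-time checks.

Outcome models regress a binary adenoma endpoint on the per-subject change
in a microbiome measure, adjusted for covariates, using a generalized
linear model with log link — either Poisson (risk-ratio approximation) or
log-binomial.  Cohort comparisons reproduce the baseline-characteristics
tests: Pearson chi-square without continuity correction for categorical
variables (the form that reproduces the printed two-arm p-values from their
2x2 counts), t or Wilcoxon rank-sum for continuous ones.  Storage-time
checks fit a random-intercept mixed model of freezer time on arm and
correlate storage time with each diversity measure per timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .core_io import CohortMetadata

__all__ = [
    "GlmResult",
    "CohortTestResult",
    "outcome_regression",
    "interaction_lrt",
    "cohort_comparison",
    "storage_time_checks",
]


@dataclass(frozen=True)
class GlmResult:
    """Fitted GLM summary: coefficient table, deviance and convergence flag."""

    family: str
    coef: pd.DataFrame          # index=term; columns estimate, se, p
    deviance: float
    llf: float
    n: int
    n_params: int
    converged: bool

    def estimate(self, term: str) -> float:
        return float(self.coef.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.coef.loc[term, "p"])


def _design(
    delta: pd.Series,
    meta: CohortMetadata,
    covariates: Sequence[str],
    outcome: str,
    extra: Mapping[str, pd.Series] | None,
    subset: Sequence[str] | None,
) -> tuple[pd.DataFrame, pd.Series]:
    info = meta.subject_info()
    subjects = [s for s in delta.index if s in info.index]
    if subset is not None:
        subjects = [s for s in subjects if s in set(subset)]
    df = pd.DataFrame(index=subjects)
    df["delta"] = delta.loc[subjects]
    for cov in covariates:
        if extra and cov in extra:
            df[cov] = extra[cov].reindex(subjects)
        elif cov == "sex":
            df["sex"] = (info.loc[subjects, "sex"] == "M").astype(float)
        elif cov in info.columns:
            df[cov] = info.loc[subjects, cov].astype(float)
        else:
            raise KeyError(f"unknown covariate {cov!r}")
    y = info.loc[subjects, outcome].astype(float)
    keep = df.notna().all(axis=1) & y.notna()
    return df.loc[keep], y.loc[keep]


def outcome_regression(
    delta: pd.Series,
    meta: CohortMetadata,
    family: str = "poisson",
    covariates: Sequence[str] = ("sex", "age", "aspirin", "batch_mismatch"),
    outcome: str = "outcome_any",
    extra: Mapping[str, pd.Series] | None = None,
    subset: Sequence[str] | None = None,
) -> GlmResult:
    """GLM of a binary outcome on per-subject microbiome change.

    ``delta`` is indexed by subject id (e.g. end-minus-baseline relative
    abundance of one species); ``covariates`` name subject-level columns
    (``sex`` is coded M=1) or keys into ``extra`` (e.g. the baseline level
    of the measure).  ``family`` is ``'poisson'`` or ``'log_binomial'``,
    both with log link, fitted by IRLS with Wald p-values.  Non-convergence
    (common at the log-binomial boundary) is flagged, never silently
    replaced.
    """
    x, y = _design(delta, meta, covariates, outcome, extra, subset)
    if len(x) == 0:
        raise ValueError("no complete cases")
    xmat = sm.add_constant(x, has_constant="add")
    if family == "poisson":
        fam = sm.families.Poisson()
    elif family == "log_binomial":
        fam = sm.families.Binomial(link=sm.families.links.Log())
    else:
        raise ValueError("family must be 'poisson' or 'log_binomial'")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, xmat, family=fam)
            if family == "log_binomial":
                # start at the intercept-only solution to stay inside the
                # mean-in-(0,1) region
                p0 = min(max(y.mean(), 1e-6), 1 - 1e-6)
                start = np.zeros(xmat.shape[1])
                start[0] = np.log(p0)
                res = model.fit(start_params=start, maxiter=200)
            else:
                res = model.fit(maxiter=200)
            converged = bool(res.converged)
            coef = pd.DataFrame(
                {"estimate": res.params, "se": res.bse, "p": res.pvalues}
            )
            out = GlmResult(family, coef, float(res.deviance), float(res.llf),
                            int(res.nobs), xmat.shape[1], converged)
    except Exception:
        coef = pd.DataFrame(
            {"estimate": np.nan, "se": np.nan, "p": np.nan},
            index=list(xmat.columns),
        )
        out = GlmResult(family, coef, np.nan, np.nan, len(x), xmat.shape[1], False)
    return out


def interaction_lrt(full: GlmResult, reduced: GlmResult) -> tuple[float, float]:
    """Likelihood-ratio test of nested GLMs: chi2 = dev_reduced - dev_full."""
    if full.n != reduced.n:
        raise ValueError("models fit on different rows are not nested")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    chi2 = reduced.deviance - full.deviance
    chi2 = max(chi2, 0.0)
    return float(chi2), float(sps.chi2.sf(chi2, df))


@dataclass(frozen=True)
class CohortTestResult:
    variable: str
    groups: str
    test: str       # chi_square | t | rank_sum
    statistic: float
    p: float


def cohort_comparison(
    variable: str,
    groups: str,
    *,
    counts: np.ndarray | None = None,
    values: tuple[np.ndarray, np.ndarray] | None = None,
    test: str | None = None,
    welch: bool = False,
) -> CohortTestResult:
    """One baseline-characteristics comparison.

    For categorical variables pass a 2x2 ``counts`` table ([[yes, no] per
    group]); the test is a Pearson chi-square with df = 1 and no continuity
    correction.  For continuous variables pass per-group ``values`` and
    ``test`` = ``'t'`` (pooled by default, Welch optional) or
    ``'rank_sum'``.
    """
    if counts is not None:
        counts = np.asarray(counts, float)
        if counts.shape != (2, 2):
            raise ValueError("chi-square comparison needs a 2x2 table")
        expected = sps.contingency.expected_freq(counts)
        if (expected < 1).any():
            warnings.warn(f"{variable}: expected cell count below 1", stacklevel=2)
        chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
        assert dof == 1
        return CohortTestResult(variable, groups, "chi_square", float(chi2), float(p))
    if values is None:
        raise ValueError("pass either counts or values")
    a, b = (np.asarray(v, float) for v in values)
    if test == "t":
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    elif test == "rank_sum":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError("test must be 't' or 'rank_sum' for values")
    return CohortTestResult(variable, groups, test, float(stat), float(p))


def storage_time_checks(
    meta: CohortMetadata,
    measures: Mapping[str, pd.Series],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Storage-time diagnostics.

    Returns ``(arm_model, correlations)``: the arm coefficient of a
    random-intercept-per-subject mixed model of storage years on arm
    (REML), and Spearman correlations of storage time with each measure,
    per timepoint.  Samples missing storage values are dropped with their
    count recorded in the model frame attributes.
    """
    df = meta.data[["subject_id", "arm", "timepoint", "storage_years"]].dropna(
        subset=["storage_years"]
    )
    df = df.assign(is_udca=(df["arm"] == "UDCA").astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(
            df["storage_years"],
            sm.add_constant(df["is_udca"]),
            groups=df["subject_id"],
        )
        fit = md.fit(reml=True)
    arm_model = pd.DataFrame(
        {
            "term": ["const", "is_udca"],
            "estimate": [fit.params["const"], fit.params["is_udca"]],
            "p": [fit.pvalues["const"], fit.pvalues["is_udca"]],
        }
    )
    rows = []
    for name, series in measures.items():
        for tp in ("baseline", "end"):
            ids = [s for s in df.index[df["timepoint"] == tp] if s in series.index]
            x = df.loc[ids, "storage_years"].to_numpy()
            y = series.loc[ids].to_numpy(float)
            if len(ids) < 3 or np.ptp(y) == 0:
                rows.append({"measure": name, "timepoint": tp, "n": len(ids),
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = sps.spearmanr(x, y)
            rows.append({"measure": name, "timepoint": tp, "n": len(ids),
                         "rho": float(rho), "p": float(p)})
    return arm_model, pd.DataFrame(rows)
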