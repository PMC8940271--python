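"""Group-comparison and morphometry statistics.

The comparison pipeline mirrors common practice in plant phenotyping:
residual normality (Shapiro-Wilk) gates the omnibus test - one-way ANOVA
when residuals look normal, Kruskal-Wallis otherwise - and a significant
omnibus is followed by all pairwise Student's t-tests (unadjusted by
default; Bonferroni/Holm available). Grana morphometry uses a Poisson GLM
with log link for layer counts per stack and an ordinary linear model for
stack widths, both with optional genotype-by-covariate interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, DegenerateDataError, DomainError


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality-gated omnibus + post hoc pipeline."""

    normality_p: float
    branch: str                      # "anova" or "kruskal"
    omnibus_stat: float
    omnibus_p: float
    posthoc: pd.DataFrame | None     # pairwise t-tests, or None
    alpha: float


@dataclass(frozen=True)
class ModelFitResult:
    """Coefficient table of a fitted GLM / linear model."""

    coefficients: pd.DataFrame   # name, estimate, std_error, statistic, p_value
    family: str                  # "poisson_log" or "gaussian_identity"
    n_obs: int

    def coef(self, name: str) -> float:
        row = self.coefficients[self.coefficients["name"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["estimate"].iloc[0])


def compare_groups(
    values,
    group_labels,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> GroupComparison:
    """Normality-gated omnibus comparison of >= 2 groups with post hocs.

    Shapiro-Wilk runs on the residuals (values minus group means); p >=
    alpha selects one-way ANOVA, otherwise Kruskal-Wallis. A significant
    omnibus triggers all pairwise Student's t-tests, unadjusted unless
    ``adjust`` names a ``statsmodels`` multiple-testing method.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise DegenerateDataError(f"group {g!r} has n={len(v)} (< 3)")
    residuals = np.concatenate([v - v.mean() for v in groups.values()])
    if np.allclose(residuals, residuals[0]):
        normality_p = 1.0   # zero-variance residuals: trivially "normal"
    else:
        normality_p = float(sps.shapiro(residuals).pvalue)
    if normality_p >= alpha:
        branch = "anova"
        stat, p = sps.f_oneway(*groups.values())
    else:
        branch = "kruskal"
        stat, p = sps.kruskal(*groups.values())
    if np.isnan(p):   # identical constant groups
        stat, p = 0.0, 1.0
    posthoc = None
    if p < alpha:
        rows = []
        for a, b in itertools.combinations(groups, 2):
            t, tp = sps.ttest_ind(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "t": float(t),
                         "p_value": float(tp)})
        posthoc = pd.DataFrame(rows)
        if adjust is not None:
            posthoc["p_adjusted"] = multipletests(
                posthoc["p_value"], method=adjust
            )[1]
    return GroupComparison(normality_p=normality_p, branch=branch,
                           omnibus_stat=float(stat), omnibus_p=float(p),
                           posthoc=posthoc, alpha=alpha)


def _tidy(fit, family: str) -> ModelFitResult:
    table = pd.DataFrame({
        "name": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "std_error": fit.bse.to_numpy(),
        "statistic": fit.tvalues.to_numpy(),
        "p_value": fit.pvalues.to_numpy(),
    }).reset_index(drop=True)
    return ModelFitResult(coefficients=table, family=family,
                          n_obs=int(fit.nobs))


def fit_stack_count_model(
    records: pd.DataFrame,
    formula: str = "n_layers ~ genotype",
) -> ModelFitResult:
    """Poisson GLM (log link) for grana layer counts.

    Fitted by iteratively reweighted least squares to a deviance tolerance
    of 1e-8; coefficients come with Wald z statistics. Use a formula like
    ``n_layers ~ genotype * grana_per_section`` for the covariance
    (interaction) analysis.
    """
    response = formula.split("~")[0].strip()
    if (records[response] < 1).any():
        raise DomainError("layer counts must be >= 1")
    model = smf.glm(formula, data=records, family=sm.families.Poisson())
    fit = model.fit(maxiter=100, tol=1e-8)
    if not fit.converged:
        raise ConvergenceError(
            f"Poisson IRLS did not converge in 100 iterations "
            f"(deviance {fit.deviance:.6g})"
        )
    if not np.isfinite(fit.bse).all():
        raise DegenerateDataError("singular fit (perfect separation?)")
    return _tidy(fit, "poisson_log")


def fit_width_model(
    records: pd.DataFrame,
    formula: str = "width_nm ~ genotype",
) -> ModelFitResult:
    """Ordinary least squares for grana widths with genotype contrasts."""
    response = formula.split("~")[0].strip()
    y = records[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise DegenerateDataError("response has zero variance")
    fit = smf.ols(formula, data=records).fit()
    return _tidy(fit, "gaussian_identity")
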