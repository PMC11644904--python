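"""Repeated-measures association between HRV features and impairment.

Each HRV feature is tested in a linear mixed model of the stage
impairment score on the feature plus the exposure covariates (exercise,
high N2, high CO2, high O2), with a per-subject random intercept to
absorb within-subject correlation.  A GEE with exchangeable working
correlation is available as an alternative repeated-measures structure.
Bonferroni adjustment is over the family of features tested within a
stratum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssociationResult",
    "DEFAULT_COVARIATES",
    "fit_feature_model",
    "screen_interactions",
    "stratified_analysis",
    "association_table",
    "pearson_table",
]

DEFAULT_COVARIATES = ("exercise", "high_n2", "high_co2", "high_o2")


@dataclass
class AssociationResult:
    feature: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    stratum: str = "all"
    adjusted_p: float = float("nan")
    covariates: dict | None = None


def _fit_mixedlm(endog, exog, groups):
    """MixedLM fit with optimizer fallback.

    Boundary variance estimates can make a single optimizer fail with a
    singular matrix; trying a short sequence is standard practice.
    """
    last = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        try:
            return sm.MixedLM(endog, exog, groups=groups).fit(
                reml=True, method=method
            )
        except np.linalg.LinAlgError as exc:
            last = exc
    raise last


def _check_design(X: pd.DataFrame) -> list[str]:
    """Columns to keep: drop constants; raise on collinear sets."""
    keep = [c for c in X.columns if X[c].nunique() > 1]
    M = X[keep].to_numpy(float)
    if M.size and np.linalg.matrix_rank(M - M.mean(0)) < len(keep):
        collinear = []
        cols = list(keep)
        base = np.linalg.matrix_rank(M - M.mean(0))
        for c in cols:
            sub = X[[k for k in keep if k != c]].to_numpy(float)
            if np.linalg.matrix_rank(sub - sub.mean(0)) == base:
                collinear.append(c)
        raise ValueError(f"singular design; collinear columns: {collinear}")
    return keep


def fit_feature_model(
    data: pd.DataFrame,
    feature: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    response: str = "score",
    stratum: str = "all",
    method: str = "mixedlm",
) -> AssociationResult:
    """Mixed-model (or GEE) association of one feature with impairment.

    Returns the feature coefficient with its Wald 95% CI and two-sided
    p-value.  Covariates constant within the data (e.g. exercise inside
    an exercise stratum) are dropped automatically.
    """
    cols = [response, feature, *covariates, "subject_id"]
    d = data[cols].dropna()
    if d["subject_id"].nunique() < 10:
        raise ValueError("need >= 10 subjects")
    if d[feature].nunique() < 2:
        raise ValueError(f"feature {feature} has no variance")
    keep = _check_design(d[[feature, *covariates]])
    exog = sm.add_constant(d[keep])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "mixedlm":
            fit = _fit_mixedlm(d[response], exog, d["subject_id"])
        elif method == "gee":
            model = sm.GEE(
                d[response],
                exog,
                groups=d["subject_id"],
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            fit = model.fit()
        else:
            raise ValueError(f"unknown method {method!r}")
    ci = fit.conf_int().loc[feature]
    covs = {
        c: float(fit.params[c]) for c in keep if c != feature
    }
    return AssociationResult(
        feature=feature,
        estimate=float(fit.params[feature]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[feature]),
        stratum=stratum,
        covariates=covs,
    )


def screen_interactions(
    data: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    response: str = "score",
) -> pd.DataFrame:
    """Single mixed model with all main effects and interaction products.

    All 2-, 3- and 4-way products of the exposure covariates enter one
    model (15 terms for 4 covariates); each term is reported with its
    Wald F statistic (1 numerator df) and p-value.  Terms with empty
    cells (constant product columns) are reported as missing.
    """
    d = data.dropna(subset=[response, *covariates]).copy()
    terms = []
    for k in range(1, len(covariates) + 1):
        for combo in itertools.combinations(covariates, k):
            name = "*".join(combo)
            col = d[list(combo)].prod(axis=1)
            terms.append((name, col))
    X = pd.DataFrame({name: col for name, col in terms})
    usable = [c for c in X.columns if X[c].nunique() > 1]
    exog = sm.add_constant(X[usable])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = _fit_mixedlm(d[response].to_numpy(), exog, d["subject_id"])
    rows = []
    for name, _ in terms:
        if name in usable:
            z = fit.params[name] / fit.bse[name]
            rows.append(
                {"term": name, "F": float(z**2), "p": float(fit.pvalues[name])}
            )
        else:
            rows.append({"term": name, "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


def association_table(
    data: pd.DataFrame,
    features: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    stratum: str = "all",
    method: str = "mixedlm",
) -> pd.DataFrame:
    """Per-feature associations with Bonferroni adjustment over the family."""
    results = []
    for f in features:
        try:
            results.append(
                fit_feature_model(
                    data, f, covariates=covariates, stratum=stratum, method=method
                )
            )
        except (ValueError, np.linalg.LinAlgError):
            results.append(
                AssociationResult(f, *(float("nan"),) * 4, stratum=stratum)
            )
    m = len(features)
    rows = []
    for r in results:
        r.adjusted_p = min(1.0, m * r.p) if np.isfinite(r.p) else float("nan")
        rows.append(
            {
                "feature": r.feature,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "adjusted_p": r.adjusted_p,
                "stratum": r.stratum,
            }
        )
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def stratified_analysis(
    data: pd.DataFrame,
    features: list[str],
    stratum: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    method: str = "mixedlm",
) -> pd.DataFrame:
    """Association table restricted to resting or exercising stages."""
    if stratum == "rest":
        sub = data[data["exercise"] == 0]
    elif stratum == "exercise":
        sub = data[data["exercise"] == 1]
    else:
        raise ValueError("stratum must be 'rest' or 'exercise'")
    if sub.empty:
        raise ValueError(f"stratum {stratum!r} is empty")
    return association_table(
        sub, features, covariates=covariates, stratum=stratum, method=method
    )


def pearson_table(
    data: pd.DataFrame, features: list[str], response: str = "score"
) -> pd.DataFrame:
    """Pearson correlation of each feature with the stage impairment score."""
    rows = []
    for f in features:
        d = data[[f, response]].dropna()
        n = len(d)
        if n < 3 or d[f].nunique() < 2:
            rows.append({"feature": f, "r": float("nan"), "p": float("nan"), "n": n})
            continue
        r, p = stats.pearsonr(d[f], d[response])
        rows.append({"feature": f, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)
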