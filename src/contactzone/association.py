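"""Admixture-phenotype association models.

Per taxon and contact zone, admixture proportion (expressed as percent of
the genome, i.e. multiplied by 100) is regressed on standardized floral
phenotypes — petal size, herkogamy, protandry, flowering time — plus
binary flower colour where the zone is polymorphic.  Predictor
significance uses Type II sums of squares (each predictor tested by
dropping it from the otherwise full model); partial R^2 is the
drop-one SSE contrast, clipped at zero; collinearity is monitored with
variance inflation factors.  Across zones, a linear mixed model with a
random intercept per contact zone plays the same role; an outlier rule
(|studentized residual| > 4 or protandry beyond Q3 + 3 IQR) provides a
reproducible surrogate for ad hoc outlier removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "partial_r2",
    "standardize",
    "zone_regression",
    "outlier_refit",
    "combined_mixed_model",
]

CONTINUOUS_TRAITS = ["petal_size", "herkogamy", "protandry", "flowering_time"]


def partial_r2(sse_reduced: float, sse_full: float) -> float:
    """Drop-one partial R^2; negative values are reported as zero."""
    if sse_reduced <= 0:
        return 0.0
    return max(0.0, (sse_reduced - sse_full) / sse_reduced)


@dataclass
class RegressionReport:
    """Per-predictor estimates on the percent-admixture scale plus metadata."""

    table: pd.DataFrame  # predictor, estimate, se, statistic, stat_kind, p, partial_R2, vif
    n: int
    zone: str
    taxon: str
    model_kind: str  # "ols" or "mixed"
    outliers_removed: list[str] = field(default_factory=list)
    random_intercept_sd: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.table["partial_R2"].dropna() < 0).any():
            raise ValueError("partial R^2 must be clipped at 0")


def standardize(predictors: pd.DataFrame,
                continuous: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Center and scale continuous predictors to mean 0, sample SD 1.

    Binary columns (e.g. flower colour) pass through untouched.  A
    zero-variance continuous column is dropped with a warning.
    """
    out = predictors.copy()
    if continuous is None:
        continuous = [c for c in out.columns if out[c].nunique() > 2]
    for col in continuous:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"predictor {col!r} has zero variance; dropped")
            out = out.drop(columns=[col])
            continue
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def _vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2 of predictor j regressed on the others)."""
    vifs = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            vifs[col] = 1.0
            continue
        r2 = sm.OLS(X[col], sm.add_constant(others)).fit().rsquared
        vifs[col] = 1.0 / (1.0 - r2) if r2 < 1 else np.inf
    return pd.Series(vifs)


def zone_regression(alpha: pd.Series, phenotypes: pd.DataFrame,
                    include_color: bool = False, zone: str = "?", taxon: str = "?",
                    pre_standardized: bool = False) -> RegressionReport:
    """Multiple regression of percent admixture on floral phenotypes.

    Type II F for each predictor comes from dropping only that predictor
    from the full model: F = ((SSE_r - SSE_f)/q) / (SSE_f / df_resid);
    partial R^2 = (SSE_r - SSE_f)/SSE_r with negative values reported as 0.
    Flower colour is coded pink = 1, white = 0, so a positive coefficient
    means higher admixture in pink individuals.
    """
    traits = list(CONTINUOUS_TRAITS)
    cols = traits + (["flower_color"] if include_color else [])
    df = pd.concat([alpha.rename("alpha"), phenotypes[cols]], axis=1).dropna()
    n = len(df)
    if n <= len(cols) + 2:
        raise ValueError(f"too few complete observations (n={n}) for {len(cols)} predictors")

    X = df[cols]
    if include_color and not np.isin(X["flower_color"].unique(), [0, 1]).all():
        X = X.assign(flower_color=(X["flower_color"] == "pink").astype(float))
    if not pre_standardized:
        X = standardize(X, continuous=[c for c in traits if c in X.columns])
    y = df["alpha"] * 100.0  # percent-of-genome scale

    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise ValueError(f"design matrix is rank deficient; near-collinear set: {pair}")
    full = sm.OLS(y, Xc).fit()
    sse_full = float((full.resid**2).sum())
    df_resid = int(full.df_resid)

    rows = []
    vifs = _vif(X)
    for col in X.columns:
        reduced = sm.OLS(y, sm.add_constant(X.drop(columns=[col]))).fit()
        sse_red = float((reduced.resid**2).sum())
        q = 1
        F = ((sse_red - sse_full) / q) / (sse_full / df_resid)
        p = stats.f.sf(F, q, df_resid)
        pr2 = partial_r2(sse_red, sse_full)
        rows.append(
            {
                "predictor": col,
                "estimate": full.params[col],
                "se": full.bse[col],
                "statistic": F,
                "stat_kind": "F",
                "p": p,
                "partial_R2": pr2,
                "vif": vifs[col],
            }
        )
    return RegressionReport(
        table=pd.DataFrame(rows), n=n, zone=zone, taxon=taxon, model_kind="ols",
        notes={"coefficient_scale": "percent admixture", "ss_type": "II"},
    )


def _flag_outliers(alpha: pd.Series, phenotypes: pd.DataFrame, cols: list[str],
                   resid_threshold: float, iqr_k: float) -> pd.Index:
    df = pd.concat([alpha.rename("alpha"), phenotypes[cols]], axis=1).dropna()
    X = df[cols]
    if "flower_color" in X.columns and not np.isin(X["flower_color"].unique(), [0, 1]).all():
        X = X.assign(flower_color=(X["flower_color"] == "pink").astype(float))
    X = standardize(X, continuous=[c for c in CONTINUOUS_TRAITS if c in cols])
    fit = sm.OLS(df["alpha"] * 100.0, sm.add_constant(X)).fit()
    student = fit.get_influence().resid_studentized_external
    flagged = df.index[np.abs(student) > resid_threshold]
    if "protandry" in df.columns:
        q1, q3 = df["protandry"].quantile([0.25, 0.75])
        iqr = q3 - q1
        flagged = flagged.union(df.index[df["protandry"] > q3 + iqr_k * iqr])
    return flagged


def outlier_refit(alpha: pd.Series, phenotypes: pd.DataFrame,
                  include_color: bool = False, zone: str = "?", taxon: str = "?",
                  resid_threshold: float = 4.0, iqr_k: float = 3.0) -> RegressionReport:
    """Re-run zone_regression after removing rule-flagged outliers.

    Refuses (returns the original fit with a note) when more than 10% of
    observations are flagged.
    """
    cols = list(CONTINUOUS_TRAITS) + (["flower_color"] if include_color else [])
    flagged = _flag_outliers(alpha, phenotypes, cols, resid_threshold, iqr_k)
    n_total = len(pd.concat([alpha.rename("alpha"), phenotypes[cols]], axis=1).dropna())
    if len(flagged) > 0.10 * n_total:
        warnings.warn(
            f"{len(flagged)} of {n_total} observations flagged (> 10%); refusing removal"
        )
        report = zone_regression(alpha, phenotypes, include_color, zone, taxon)
        report.notes["outlier_refusal"] = len(flagged)
        return report
    report = zone_regression(alpha.drop(flagged), phenotypes.drop(flagged),
                             include_color, zone, taxon)
    report.outliers_removed = [str(i) for i in flagged]
    return report


def combined_mixed_model(alpha: pd.Series, phenotypes: pd.DataFrame,
                         zones: pd.Series, include_color: bool = False,
                         taxon: str = "?") -> RegressionReport:
    """Across-zone mixed model: random intercept per contact zone, REML fit.

    Fixed effects are the standardized phenotypes (plus flower colour);
    per-predictor significance is a Wald chi-square on the REML estimate.
    Partial R^2 is a marginal variance-explained contrast: the drop in
    Var(X beta) / (Var(X beta) + zone variance + residual variance)
    when the predictor is removed, clipped at zero.  A singular
    random-intercept fit falls back to fixed zone intercepts.
    """
    if zones.nunique() < 2:
        raise ValueError("combined model needs at least two contact zones")
    traits = list(CONTINUOUS_TRAITS)
    cols = traits + (["flower_color"] if include_color else [])
    df = pd.concat([alpha.rename("alpha"), phenotypes[cols], zones.rename("zone")],
                   axis=1).dropna()
    X = df[cols]
    if include_color and not np.isin(X["flower_color"].unique(), [0, 1]).all():
        X = X.assign(flower_color=(X["flower_color"] == "pink").astype(float))
    X = standardize(X, continuous=[c for c in traits if c in X.columns])
    y = (df["alpha"] * 100.0).to_numpy()
    groups = df["zone"].to_numpy()

    def fit_mixed(Xsub: pd.DataFrame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, sm.add_constant(Xsub), groups=groups)
            return md.fit(reml=True)

    res = fit_mixed(X)
    re_var = float(res.cov_re.iloc[0, 0])
    singular = not np.isfinite(re_var) or re_var < 1e-10
    if singular:
        warnings.warn("random-intercept variance is singular; using fixed zone intercepts")
        Xfix = pd.concat([X, pd.get_dummies(df["zone"], drop_first=True, dtype=float)], axis=1)
        return _fixed_zone_fallback(y, Xfix, X.columns, len(df), taxon)

    def marginal_r2(result, Xsub):
        fe = result.fe_params.drop("const")
        xb = Xsub.to_numpy() @ fe.to_numpy()
        v_fix = float(np.var(xb))
        return v_fix / (v_fix + float(result.cov_re.iloc[0, 0]) + float(result.scale))

    r2_full = marginal_r2(res, X)
    rows = []
    for col in X.columns:
        b, se = res.fe_params[col], res.bse[col]
        chi2 = (b / se) ** 2
        p = stats.chi2.sf(chi2, 1)
        red = fit_mixed(X.drop(columns=[col]))
        pr2 = max(0.0, r2_full - marginal_r2(red, X.drop(columns=[col])))
        rows.append(
            {
                "predictor": col, "estimate": b, "se": se, "statistic": chi2,
                "stat_kind": "chi2", "p": p, "partial_R2": pr2, "vif": _vif(X)[col],
            }
        )
    return RegressionReport(
        table=pd.DataFrame(rows), n=len(df), zone="all", taxon=taxon,
        model_kind="mixed", random_intercept_sd=float(np.sqrt(re_var)),
        notes={"partial_R2": "marginal variance-explained contrast (part-R2 convention)"},
    )


def _fixed_zone_fallback(y, Xfix: pd.DataFrame, predictors, n: int, taxon: str
                         ) -> RegressionReport:
    full = sm.OLS(y, sm.add_constant(Xfix)).fit()
    sse_full = float((full.resid**2).sum())
    rows = []
    for col in predictors:
        red = sm.OLS(y, sm.add_constant(Xfix.drop(columns=[col]))).fit()
        sse_red = float((red.resid**2).sum())
        F = (sse_red - sse_full) / (sse_full / full.df_resid)
        rows.append(
            {
                "predictor": col, "estimate": full.params[col], "se": full.bse[col],
                "statistic": F, "stat_kind": "F", "p": stats.f.sf(F, 1, full.df_resid),
                "partial_R2": max(0.0, (sse_red - sse_full) / sse_red),
                "vif": np.nan,
            }
        )
    return RegressionReport(
        table=pd.DataFrame(rows), n=n, zone="all", taxon=taxon, model_kind="mixed",
        random_intercept_sd=0.0,
        notes={"fallback": "fixed zone intercepts (singular random effect)"},
    )
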