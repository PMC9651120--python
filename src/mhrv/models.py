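"""Fixed-effects regression and random-intercept mixed models for HRV
features, with diagnostics, variance decomposition and effect curves.

The scientific question is how much of the variation in a (transformed) HRV
feature is explained by demographics (age, BMI, gestational age, parity) and
cardiorespiratory state (median HR, median BR), and how much by stable
differences between subjects.  The fixed-effects model is an ordinary
multiple linear regression; with repeated measurements per subject a
random-intercept linear mixed model additionally estimates the
between-subject variance :math:`\\sigma^2_b`.  The intra-class correlation

.. math:: \\mathrm{ICC} = \\sigma^2_b / (\\sigma^2_b + \\sigma^2_e)

is the fraction of residual DV variance attributable to inter-subject
differences.  Both models are estimated by maximum likelihood (not REML) so
that the likelihood-ratio test between them is valid; because the null value
of a variance component lies on the boundary of its parameter space, the LRT
p-value uses the 50:50 mixture of chi2(0) and chi2(1) (the naive chi2(1)
p-value is reported alongside for comparability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .features import DV_TRANSFORMS, transform_dv

__all__ = [
    "IV_COLUMNS",
    "ModelFrame",
    "MLRFit",
    "LMMFit",
    "LRTResult",
    "EffectCurve",
    "DiagnosticBundle",
    "RemovalReport",
    "HRVLinearModel",
    "HRVMixedModel",
    "build_frame",
    "frame_from_simulation",
    "vif",
    "fit_mlr",
    "fit_lmm",
    "lrt",
    "icc_from_variances",
    "effect_curve",
    "diagnostics",
    "remove_influential",
    "chd_screen",
]

#: canonical covariate order (CHD appended only when screened)
IV_COLUMNS = ["age", "bmi", "ga", "parity", "median_hr", "median_br"]


@dataclass
class ModelFrame:
    """One row per measurement: transformed DV, covariates, subject labels."""

    dv_name: str
    y: pd.Series  # transformed DV
    X: pd.DataFrame  # covariates, no intercept column
    subject_ids: pd.Series
    n_dropped_unusable: int = 0
    n_dropped_missing: int = 0
    row_ids: Optional[pd.Index] = None

    def __post_init__(self) -> None:
        if self.row_ids is None:
            self.row_ids = self.X.index

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class MLRFit:
    dv_name: str
    beta: pd.Series
    se: pd.Series
    ci95: pd.DataFrame  # columns low, high
    pvalues: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    f_statistic: float
    f_pvalue: float
    r2: float
    r2_adjusted: float
    loglik: float
    vif: pd.Series
    leverage: np.ndarray
    cooks_d: np.ndarray
    n: int
    result: object = field(repr=False, default=None)  # statsmodels results


@dataclass
class LMMFit:
    dv_name: str
    beta: pd.Series
    se: pd.Series
    ci95: pd.DataFrame
    pvalues: pd.Series
    sigma2_b: float
    sigma2_e: float
    icc: float
    loglik: float
    r2_adjusted: float  # conditional, from random-effects-included fits
    r2_marginal: float  # Nakagawa-style pseudo-R2 pair
    r2_conditional: float
    blups: pd.Series  # per-subject intercept deviations
    fitted: np.ndarray  # conditional fitted values
    residuals: np.ndarray
    converged: bool
    n: int
    result: object = field(repr=False, default=None)


@dataclass(frozen=True)
class LRTResult:
    stat: float
    p_mixture: float  # 50:50 chi2_0 / chi2_1 boundary-corrected
    p_naive: float  # plain chi2_1, for comparability


@dataclass(frozen=True)
class EffectCurve:
    iv_name: str
    grid: np.ndarray
    yhat: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: float
    annotate: bool  # True when p < alpha (plot annotation rule)


@dataclass(frozen=True)
class DiagnosticBundle:
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    leverage: Optional[np.ndarray]
    cooks_d: Optional[np.ndarray]
    flagged_rows: list
    blups: Optional[pd.Series] = None


@dataclass(frozen=True)
class RemovalReport:
    removed_ids: list
    removed_cooks_d: list
    threshold: float
    advisory_ids: list  # rows above the 4/n advisory threshold
    beta_before: pd.Series
    beta_after: pd.Series


def build_frame(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    dv_name: str,
    include_chd: bool = False,
    parity_numeric: bool = False,
) -> ModelFrame:
    """Join features with covariates and assemble the regression frame.

    The DV is transformed per its normalising rule; measurements failing the
    reliability gate (``usable`` False) and rows with missing covariates or
    DV are dropped and counted.  Parity is coded binary (0 nulliparous /
    1 parous) unless ``parity_numeric``.
    """
    keys = ["subject_id", "measurement_id"]
    dv = dv_name.lower()
    if dv not in DV_TRANSFORMS:
        raise ValueError(f"unknown dependent variable: {dv_name!r}")
    feat_cols = keys + [dv, "median_hr", "median_br"] + (
        ["usable"] if "usable" in features.columns else []
    )
    missing = [c for c in feat_cols if c not in features.columns]
    if missing:
        raise KeyError(f"features table missing columns: {missing}")
    try:
        merged = features[feat_cols].merge(
            cohort, on=keys, how="inner", validate="one_to_one"
        )
    except pd.errors.MergeError as exc:
        raise KeyError(f"features/cohort keying error: {exc}") from exc
    if len(merged) == 0:
        raise KeyError("no rows after joining features with cohort on "
                       "(subject_id, measurement_id)")

    n0 = len(merged)
    if "usable" in merged.columns:
        merged = merged[merged["usable"].astype(bool)]
    n_unusable = n0 - len(merged)

    cols = list(IV_COLUMNS) + ([ "chd"] if include_chd else [])
    for c in ("age", "bmi", "ga"):
        if c not in merged.columns:
            raise KeyError(f"cohort table missing column: {c}")
    parity = merged["parity"].astype(float)
    merged = merged.assign(parity=parity if parity_numeric
                           else (parity > 0).astype(float))

    frame = merged[["subject_id", "measurement_id", dv] + cols].copy()
    n1 = len(frame)
    frame = frame.dropna()
    frame = frame[frame[dv] > 0] if DV_TRANSFORMS[dv] == "log" else frame
    n_missing = n1 - len(frame)

    y = frame[dv].map(lambda v: transform_dv(v, dv).transformed)
    y.name = f"{'log_' if DV_TRANSFORMS[dv] == 'log' else ''}{dv}" + (
        "_sq" if DV_TRANSFORMS[dv] == "square" else ""
    )
    return ModelFrame(
        dv_name=dv,
        y=y,
        X=frame[cols].astype(float),
        subject_ids=frame["subject_id"],
        n_dropped_unusable=n_unusable,
        n_dropped_missing=n_missing,
        row_ids=frame.index,
    )


def frame_from_simulation(sim: pd.DataFrame, dv_name: str) -> ModelFrame:
    """Assemble a ModelFrame directly from ``simulate_features`` output
    (column ``y`` already on the transformed scale)."""
    X = sim[IV_COLUMNS].astype(float).copy()
    X["parity"] = (X["parity"] > 0).astype(float)
    return ModelFrame(
        dv_name=dv_name,
        y=sim["y"].rename("y"),
        X=X,
        subject_ids=sim["subject_id"],
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R2_j) from regressing
    column j on the remaining columns plus an intercept.  Exact collinearity
    yields ``inf``."""
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 covariates")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_mlr(frame: ModelFrame) -> MLRFit:
    """Ordinary least squares with intercept; F-test against the
    intercept-only model; adjusted R2 = 1 - (1-R2)(n-1)/(n-p-1)."""
    X = sm.add_constant(frame.X, has_constant="add")
    n, p1 = X.shape
    if n <= p1:
        raise ValueError("more parameters than rows")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p1:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(p1) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    res = sm.OLS(frame.y.to_numpy(), X).fit()
    infl = res.get_influence()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    return MLRFit(
        dv_name=frame.dv_name,
        beta=res.params,
        se=res.bse,
        ci95=ci,
        pvalues=res.pvalues,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
        loglik=float(res.llf),
        vif=(vif(frame.X) if frame.X.shape[1] >= 2
             else pd.Series(1.0, index=frame.X.columns)),
        leverage=infl.hat_matrix_diag,
        cooks_d=infl.cooks_distance[0],
        n=n,
        result=res,
    )


def icc_from_variances(sigma2_b: float, sigma2_e: float) -> float:
    """Intra-class correlation sigma2_b / (sigma2_b + sigma2_e)."""
    if sigma2_b < 0 or sigma2_e <= 0:
        raise ValueError("need sigma2_b >= 0 and sigma2_e > 0")
    return sigma2_b / (sigma2_b + sigma2_e)


def fit_lmm(frame: ModelFrame) -> LMMFit:
    """Random-intercept linear mixed model estimated by maximum likelihood.

    ML (not REML) is used so the likelihood-ratio test against the
    fixed-effects-only model is valid.  The reported ``r2_adjusted`` follows
    the fixed-effects convention applied to conditional (random-effects
    included) fitted values; the marginal/conditional pseudo-R2 pair is
    reported alongside.
    """
    groups = frame.subject_ids.to_numpy()
    if pd.Series(groups).value_counts().ge(2).sum() < 2:
        raise ValueError("need >= 2 subjects with >= 2 measurements each")
    X = sm.add_constant(frame.X, has_constant="add")
    y = frame.y.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=False)
        if not res.converged:  # pragma: no cover - retried path
            res = model.fit(reml=False, method="powell")
    if not res.converged:
        raise RuntimeError(
            "mixed model did not converge; optimizer history: "
            f"{getattr(res, 'hist', None)}"
        )
    sigma2_b = float(np.asarray(res.cov_re)[0, 0])
    sigma2_e = float(res.scale)
    fitted = np.asarray(res.fittedvalues)  # includes random effects
    resid = y - fitted
    n, p1 = X.shape
    p = p1 - 1
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2_adj = 1.0 - (sse / sst) * (n - 1) / (n - p - 1)

    # Nakagawa-style decomposition: fixed-effects variance over totals
    var_f = float(np.var(X.to_numpy() @ res.fe_params, ddof=0))
    denom = var_f + sigma2_b + sigma2_e
    blups = pd.Series(
        {k: float(np.asarray(v)[0]) for k, v in res.random_effects.items()}
    )
    names = list(X.columns)
    beta = pd.Series(np.asarray(res.fe_params), index=names)
    se = pd.Series(np.asarray(res.bse_fe), index=names)
    z = stats.norm.ppf(0.975)
    ci = pd.DataFrame({"low": beta - z * se, "high": beta + z * se})
    pvals = pd.Series(
        2 * stats.norm.sf(np.abs(beta.to_numpy() / se.to_numpy())), index=names
    )
    return LMMFit(
        dv_name=frame.dv_name,
        beta=beta,
        se=se,
        ci95=ci,
        pvalues=pvals,
        sigma2_b=sigma2_b,
        sigma2_e=sigma2_e,
        icc=sigma2_b / (sigma2_b + sigma2_e) if sigma2_b + sigma2_e > 0 else 0.0,
        loglik=float(res.llf),
        r2_adjusted=r2_adj,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + sigma2_b) / denom,
        blups=blups,
        fitted=fitted,
        residuals=resid,
        converged=bool(res.converged),
        n=n,
        result=res,
    )


def lrt(lmm: LMMFit, mlr: MLRFit) -> LRTResult:
    """Likelihood-ratio test for the random intercept.

    stat = 2 (llf_LMM - llf_MLR), clipped at zero.  Because sigma2_b = 0 is
    on the parameter boundary the reference distribution is the 50:50
    mixture of a point mass at 0 and chi2(1): p = 0.5 * P(chi2_1 > stat)
    for stat > 0 and p = 1 at stat = 0.
    """
    if lmm.n != mlr.n or lmm.dv_name != mlr.dv_name:
        raise ValueError("LMM and MLR must be fit on the same frame")
    stat = max(0.0, 2.0 * (lmm.loglik - mlr.loglik))
    p_naive = float(stats.chi2.sf(stat, df=1))
    p_mix = 1.0 if stat == 0.0 else 0.5 * p_naive
    return LRTResult(stat=stat, p_mixture=p_mix, p_naive=p_naive)


def effect_curve(
    fit: MLRFit | LMMFit,
    frame: ModelFrame,
    iv_name: str,
    n_grid: int = 50,
    alpha: float = 0.05,
) -> EffectCurve:
    """Predicted transformed DV as one covariate sweeps its 5th–95th
    percentile range while the others sit at their sample medians.

    Binary covariates use the grid {0, 1}.  Pointwise 95% bands come from
    the fixed-effect coefficient covariance.  ``annotate`` records the plot
    rule: report p on the panel only when the covariate is significant.
    """
    if iv_name not in frame.X.columns:
        raise ValueError(f"unknown covariate: {iv_name!r}")
    x = frame.X[iv_name].to_numpy()
    if set(np.unique(x)).issubset({0.0, 1.0}):
        grid = np.array([0.0, 1.0])
    else:
        lo, hi = np.percentile(x, [5, 95])
        grid = np.linspace(lo, hi, n_grid)
    med = frame.X.median()
    Xg = pd.DataFrame(
        {c: np.full(len(grid), med[c]) for c in frame.X.columns}
    )
    Xg[iv_name] = grid
    Xg = sm.add_constant(Xg, has_constant="add")[fit.beta.index]

    if isinstance(fit, MLRFit):
        cov = np.asarray(fit.result.cov_params())
        crit = stats.t.ppf(0.975, df=fit.result.df_resid)
    else:
        cov = np.asarray(fit.result.cov_params())[: len(fit.beta), : len(fit.beta)]
        crit = stats.norm.ppf(0.975)
    A = Xg.to_numpy()
    yhat = A @ fit.beta.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", A, cov, A))
    p = float(fit.pvalues[iv_name])
    return EffectCurve(
        iv_name=iv_name,
        grid=grid,
        yhat=yhat,
        ci_low=yhat - crit * se,
        ci_high=yhat + crit * se,
        p_value=p,
        annotate=p < alpha,
    )


def diagnostics(
    fit: MLRFit | LMMFit, frame: ModelFrame, cooks_threshold: float = 1.0
) -> DiagnosticBundle:
    """Numeric series for the standard model-checking plots: normal QQ of
    residuals, fitted-vs-residual pairs, leverage, Cook's distance (MLR),
    and the per-subject intercept histogram (LMM)."""
    resid = np.asarray(fit.residuals)
    osm, osr = stats.probplot(resid, dist="norm", fit=False)
    if isinstance(fit, MLRFit):
        lev, cd = fit.leverage, fit.cooks_d
        flagged = [frame.row_ids[i] for i in np.flatnonzero(cd > cooks_threshold)]
        blups = None
    else:
        lev = cd = None
        flagged = []
        blups = fit.blups
    return DiagnosticBundle(
        qq_theoretical=osm,
        qq_sample=osr,
        fitted=np.asarray(fit.fitted),
        residuals=resid,
        leverage=lev,
        cooks_d=cd,
        flagged_rows=flagged,
        blups=blups,
    )


def remove_influential(
    frame: ModelFrame,
    fit: MLRFit,
    max_removals: int = 2,
    threshold: float = 1.0,
) -> tuple[ModelFrame, MLRFit, RemovalReport]:
    """Drop up to ``max_removals`` rows with Cook's distance above
    ``threshold`` (most influential first), refit, and itemise the change.

    Rows above the advisory 4/n level are listed but not removed.  Zero
    removals is a valid outcome and returns the original fit.
    """
    cd = np.asarray(fit.cooks_d)
    order = np.argsort(cd)[::-1]
    to_drop = [i for i in order if cd[i] > threshold][:max_removals]
    advisory = [frame.row_ids[i] for i in np.flatnonzero(cd > 4.0 / fit.n)]
    if not to_drop:
        report = RemovalReport([], [], threshold, advisory, fit.beta, fit.beta)
        return frame, fit, report
    keep = np.setdiff1d(np.arange(fit.n), to_drop)
    new_frame = ModelFrame(
        dv_name=frame.dv_name,
        y=frame.y.iloc[keep],
        X=frame.X.iloc[keep],
        subject_ids=frame.subject_ids.iloc[keep],
        n_dropped_unusable=frame.n_dropped_unusable,
        n_dropped_missing=frame.n_dropped_missing,
        row_ids=frame.row_ids[keep],
    )
    new_fit = fit_mlr(new_frame)
    report = RemovalReport(
        removed_ids=[frame.row_ids[i] for i in to_drop],
        removed_cooks_d=[float(cd[i]) for i in to_drop],
        threshold=threshold,
        advisory_ids=advisory,
        beta_before=fit.beta,
        beta_after=new_fit.beta,
    )
    return new_frame, new_fit, report


def chd_screen(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    dv_names=("sdnn", "rmssd", "sampen"),
    alpha: float = 0.05,
) -> dict:
    """Screen the fetal-CHD covariate: fit each DV's MLR with and without
    CHD; keep it only where its coefficient is significant at ``alpha``.

    A cohort whose CHD column is constant cannot support the screen; the
    report then says so and the covariate is dropped without testing.
    """
    out: dict[str, dict] = {}
    if "chd" not in cohort.columns:
        return {"skipped": True, "reason": "no chd column"}
    chd = cohort["chd"].astype(float)
    if chd.nunique() < 2:
        return {"skipped": True,
                "reason": "chd column constant; screen not identifiable"}
    for dv in dv_names:
        with_chd = fit_mlr(build_frame(features, cohort, dv, include_chd=True))
        without = fit_mlr(build_frame(features, cohort, dv, include_chd=False))
        p = float(with_chd.pvalues["chd"])
        out[dv] = {
            "coef": float(with_chd.beta["chd"]),
            "p_value": p,
            "decision": "keep" if p < alpha else "drop",
            "r2_adj_with": with_chd.r2_adjusted,
            "r2_adj_without": without.r2_adjusted,
        }
    out["skipped"] = False
    return out


class HRVLinearModel(BaseEstimator, RegressorMixin):
    """Fixed-effects multiple linear regression, scikit-learn style.

    ``fit(X, y)`` accepts a covariate DataFrame (no intercept column) and a
    transformed-DV vector.  Fitted attributes expose the regression table
    and diagnostics through :attr:`result_` (an :class:`MLRFit`).
    """

    def __init__(self, dv_name: str = "rmssd"):
        self.dv_name = dv_name

    def fit(self, X, y, subject_ids=None):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        if X.isna().any().any() or y.isna().any():
            raise ValueError("missing values in design or response")
        sid = pd.Series(
            subject_ids if subject_ids is not None else X.index.astype(str),
            index=X.index,
        )
        frame = ModelFrame(dv_name=self.dv_name, y=y, X=X, subject_ids=sid)
        self.result_ = fit_mlr(frame)
        self.frame_ = frame
        self.coef_ = self.result_.beta.drop("const").to_numpy()
        self.intercept_ = float(self.result_.beta["const"])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_


class HRVMixedModel(BaseEstimator, RegressorMixin):
    """Random-intercept linear mixed model, scikit-learn style.

    ``fit(X, y, groups)`` estimates fixed effects plus a per-subject random
    intercept by maximum likelihood; fitted attributes include ``icc_``,
    ``sigma2_b_``, ``sigma2_e_`` and the full :class:`LMMFit` in
    :attr:`result_`.  ``predict`` returns marginal (fixed-effects-only)
    predictions for new subjects.
    """

    def __init__(self, dv_name: str = "rmssd"):
        self.dv_name = dv_name

    def fit(self, X, y, groups):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        frame = ModelFrame(
            dv_name=self.dv_name,
            y=y,
            X=X,
            subject_ids=pd.Series(np.asarray(groups), index=X.index),
        )
        self.result_ = fit_lmm(frame)
        self.frame_ = frame
        self.coef_ = self.result_.beta.drop("const").to_numpy()
        self.intercept_ = float(self.result_.beta["const"])
        self.icc_ = self.result_.icc
        self.sigma2_b_ = self.result_.sigma2_b
        self.sigma2_e_ = self.result_.sigma2_e
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X):
        X = pd.DataFrame(X)
        return self.intercept_ + X.to_numpy(dtype=float) @ self.coef_
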