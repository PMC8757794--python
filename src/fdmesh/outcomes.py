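"""Occlusion and time-to-occlusion models for flow-diverter cohorts.

Two models, mirroring how interventional cohorts of this kind are
analyzed:

* a multiple-regression **Logit** for the binary 12-month occlusion
  outcome, with the mesh summaries (porosity, mesh angle, expansion), the
  morphology index and the device brand as regressors;
* an **ANCOVA** for time-to-occlusion (TTO, months) on the occluded
  subset, with brand and patient age entering as factors and the
  continuous mesh/morphology variables as covariates, decomposed by
  sequential (entry-order) sums of squares so the "correction power" of
  each covariate can be read off in the order it was applied.  Fitted
  values, residuals and R^2 are invariant to the covariate entry order;
  only the decomposition table changes.

Model fitting is delegated to statsmodels (Logit MLE, OLS); the design
construction, sequential decomposition and diagnostics are assembled here.
No multiple-testing correction is applied (stated in the fit metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CohortSchemaError

__all__ = [
    "BRAND_LEVELS", "DEFAULT_LOGIT_TERMS", "DEFAULT_COVARIATE_ORDER",
    "LogitFit", "AncovaFit", "validate_cohort", "age_tertiles",
    "fit_occlusion_logit", "fit_tto_ancova", "residual_diagnostics",
    "tto_summary",
]

BRAND_LEVELS = ("Derivo", "P64", "Pipeline", "Surpass")

DEFAULT_LOGIT_TERMS = (
    "porosity_mean", "angle_mean", "expansion_mean", "maai", "brand_label",
)
DEFAULT_COVARIATE_ORDER = (
    "porosity_mean", "angle_mean", "expansion_mean", "maai",
)

_REQUIRED_COHORT_COLUMNS = (
    "patient_id", "age", "sex", "brand_label",
    "depth", "width", "volume", "neck_max", "neck_min",
    "porosity_mean", "porosity_sd", "angle_mean", "angle_sd",
    "expansion_mean", "expansion_sd",
    "occluded", "tto_months", "fu_months",
)


def validate_cohort(df: pd.DataFrame, brand_levels=BRAND_LEVELS) -> None:
    """Validate a cohort table against the schema invariants.

    Raises :class:`CohortSchemaError` naming the first offending column or
    row (1-based data rows).
    """
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing columns {missing}")
    occ = df["occluded"].to_numpy()
    if not np.isin(occ, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(occ, (0, 1)))[0]) + 1
        raise CohortSchemaError(f"occluded not in {{0,1}} at data row {row}")
    bad_brand = ~df["brand_label"].isin(brand_levels)
    if bad_brand.any():
        row = int(np.flatnonzero(bad_brand.to_numpy())[0]) + 1
        raise CohortSchemaError(
            f"brand_label outside {brand_levels} at data row {row}"
        )
    fu = df["fu_months"].to_numpy(dtype=float)
    if np.any((fu < 0) | (fu > 24)):
        row = int(np.flatnonzero((fu < 0) | (fu > 24))[0]) + 1
        raise CohortSchemaError(f"fu_months outside [0, 24] at data row {row}")
    occluded = occ == 1
    tto = df["tto_months"].to_numpy(dtype=float)
    bad_tto = occluded & (~np.isfinite(tto) | (tto <= 0) | (tto > fu + 1e-9))
    if np.any(bad_tto):
        row = int(np.flatnonzero(bad_tto)[0]) + 1
        raise CohortSchemaError(
            f"occluded row must have 0 < tto_months <= fu_months (data row {row})"
        )


# ---------------------------------------------------------------------------
# design helpers

def _dummies(values: pd.Series, prefix: str) -> tuple[pd.DataFrame, str]:
    """k-1 dummy columns against the alphabetically first observed level."""
    levels = sorted(values.unique())
    ref = levels[0]
    cols = {
        f"{prefix}[{lev}]": (values == lev).to_numpy(dtype=float)
        for lev in levels[1:]
    }
    return pd.DataFrame(cols, index=values.index), ref


def age_tertiles(age: pd.Series) -> pd.Series:
    """Tertile groups of age with labels age_young/age_mid/age_old.

    Boundaries are the 1/3 and 2/3 sample quantiles of the ages passed in,
    so generator and fitter agree exactly when given the same subset.
    """
    a = age.to_numpy(dtype=float)
    q1, q2 = np.quantile(a, [1 / 3, 2 / 3])
    lab = np.where(a <= q1, "age_young", np.where(a <= q2, "age_mid", "age_old"))
    return pd.Series(lab, index=age.index, name="age_group")


def _age_block(sub: pd.DataFrame, age_handling: str):
    """Design columns for the age term plus bookkeeping."""
    if age_handling == "tertiles":
        groups = age_tertiles(sub["age"])
        cols, ref = _dummies(groups, "age_group")
        return cols, {"age_reference": ref}, groups
    a = sub["age"].to_numpy(dtype=float)
    if age_handling == "linear":
        return pd.DataFrame({"age": a}, index=sub.index), {}, None
    if age_handling == "quadratic":
        ac = a - a.mean()
        return (pd.DataFrame({"age": a, "age_sq": ac**2}, index=sub.index),
                {}, None)
    raise ValueError(f"unknown age_handling {age_handling!r} "
                     "(expected tertiles/linear/quadratic)")


def _check_covariates(sub: pd.DataFrame, names) -> None:
    for name in names:
        if name not in sub.columns:
            raise ValueError(f"covariate {name!r} not in table")
        x = sub[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {name!r} is constant (dropped terms are "
                             "not fitted silently)")


# ---------------------------------------------------------------------------
# Logit occlusion model

@dataclass
class LogitFit:
    """Maximum-likelihood logistic fit with Wald tests per coefficient."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame        # 95% Wald intervals, columns lo/hi
    llf: float
    nobs: int
    converged: bool
    separation: bool
    terms: tuple[str, ...]
    reference_levels: dict = field(default_factory=dict)
    notes: tuple[str, ...] = ("no multiple-testing correction applied",)


def fit_occlusion_logit(table: pd.DataFrame,
                        terms=DEFAULT_LOGIT_TERMS) -> LogitFit:
    """Fit the occlusion ~ mesh + morphology (+ brand) Logit model.

    ``terms`` lists continuous covariates and optionally ``brand_label``,
    which is dummy-coded against the alphabetically first observed brand.
    Requires >= 10 rows and both outcome classes present.  Perfect or
    quasi-perfect separation is detected and flagged on the returned fit
    rather than raised.
    """
    terms = tuple(terms)
    if len(table) < 10:
        raise ValueError(f"need at least 10 rows, got {len(table)}")
    y = table["occluded"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; Logit is undefined")

    cont = [t for t in terms if t != "brand_label"]
    _check_covariates(table, cont)
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for t in cont:
        X[t] = table[t].to_numpy(dtype=float)
    refs: dict = {}
    if "brand_label" in terms:
        dum, ref = _dummies(table["brand_label"], "brand")
        refs["brand_reference"] = ref
        X = pd.concat([X, dum], axis=1)

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:  # PerfectSeparationError on older statsmodels
            separation = True
            res = sm.Logit(y, X).fit(disp=0, maxiter=400, method="bfgs")
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
    fitted = res.predict(X)
    if np.max(np.abs(res.params)) > 1e3 or np.all((fitted > 0.999) == (y == 1)):
        separation = True

    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lo", "hi"]
    return LogitFit(
        params=res.params, bse=res.bse, zvalues=res.tvalues,
        pvalues=res.pvalues, conf_int=ci, llf=float(res.llf),
        nobs=int(res.nobs), converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation, terms=terms, reference_levels=refs,
    )


# ---------------------------------------------------------------------------
# TTO ANCOVA

@dataclass
class AncovaFit:
    """Linear TTO model with sequential (entry-order) SS decomposition."""

    sequential: pd.DataFrame      # term, df, ss, F, p (entry order) + Residual
    marginal: pd.DataFrame        # drop-one F tests per term
    coef: pd.DataFrame            # estimate, se, t, p, lo, hi
    r_squared: float
    fitted: np.ndarray
    residuals: np.ndarray
    entry_order: tuple[str, ...]
    data: pd.DataFrame            # the fitted (occluded) subset incl. age_group
    age_handling: str
    reference_levels: dict
    nobs: int
    notes: tuple[str, ...] = ("no multiple-testing correction applied",)

    @property
    def model_ss(self) -> float:
        seq = self.sequential
        return float(seq.loc[seq["term"] != "Residual", "ss"].sum())


def fit_tto_ancova(table: pd.DataFrame,
                   covariate_order=DEFAULT_COVARIATE_ORDER,
                   age_handling: str = "tertiles") -> AncovaFit:
    """Fit TTO ~ brand + age + covariates on the occluded (<= 12 months) subset.

    The factors (brand, then age) enter first, then the continuous
    covariates in ``covariate_order``; the sequential decomposition follows
    that entry order.  Each included brand level needs at least 2 rows.
    """
    covariate_order = tuple(covariate_order)
    sub = table[(table["occluded"] == 1) & (table["tto_months"] <= 12)].copy()
    if len(sub) == 0:
        raise ValueError("no occluded rows with tto_months <= 12; ANCOVA undefined")
    counts = sub["brand_label"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"brand level {thin.index[0]!r} has {int(thin.iloc[0])} occluded row(s); "
            "need >= 2 per included level"
        )
    _check_covariates(sub, covariate_order)

    y = sub["tto_months"].to_numpy(dtype=float)
    refs: dict = {}
    blocks: list[tuple[str, pd.DataFrame]] = []
    dum, ref = _dummies(sub["brand_label"], "brand")
    refs["brand_reference"] = ref
    blocks.append(("brand_label", dum))
    age_cols, age_refs, age_groups = _age_block(sub, age_handling)
    refs.update(age_refs)
    blocks.append(("age", age_cols))
    if age_groups is not None:
        sub["age_group"] = age_groups
    for name in covariate_order:
        blocks.append((name, pd.DataFrame({name: sub[name].to_numpy(dtype=float)},
                                          index=sub.index)))

    X = pd.DataFrame({"Intercept": np.ones(len(sub))}, index=sub.index)
    rss = [float(sm.OLS(y, X).fit().ssr)]   # intercept-only RSS = total SS
    dfs = []
    for _, cols in blocks:
        X = pd.concat([X, cols], axis=1)
        dfs.append(cols.shape[1])
        rss.append(float(sm.OLS(y, X).fit().ssr))
    full = sm.OLS(y, X).fit()
    if full.df_resid <= 0:
        raise ValueError(f"model is saturated: {X.shape[1]} parameters, {len(sub)} rows")
    mse = full.ssr / full.df_resid

    rows = []
    for k, (name, _) in enumerate(blocks):
        ss = rss[k] - rss[k + 1]
        F = (ss / dfs[k]) / mse
        rows.append({"term": name, "df": dfs[k], "ss": ss, "F": F,
                     "p": float(stats.f.sf(F, dfs[k], full.df_resid))})
    rows.append({"term": "Residual", "df": int(full.df_resid), "ss": float(full.ssr),
                 "F": np.nan, "p": np.nan})
    sequential = pd.DataFrame(rows)

    # marginal (drop-one) tests for completeness
    mrows = []
    for name, _ in blocks:
        keep = pd.concat(
            [pd.DataFrame({"Intercept": np.ones(len(sub))}, index=sub.index)]
            + [c for nm, c in blocks if nm != name], axis=1)
        red = sm.OLS(y, keep).fit()
        df_t = X.shape[1] - keep.shape[1]
        ss = float(red.ssr - full.ssr)
        F = (ss / df_t) / mse
        mrows.append({"term": name, "df": df_t, "ss": ss, "F": F,
                      "p": float(stats.f.sf(F, df_t, full.df_resid))})
    marginal = pd.DataFrame(mrows)

    ci = full.conf_int(alpha=0.05)
    coef = pd.DataFrame({
        "estimate": full.params, "se": full.bse, "t": full.tvalues,
        "p": full.pvalues, "lo": ci[0], "hi": ci[1],
    })

    return AncovaFit(
        sequential=sequential, marginal=marginal, coef=coef,
        r_squared=float(full.rsquared), fitted=np.asarray(full.fittedvalues),
        residuals=np.asarray(full.resid), entry_order=tuple(b[0] for b in blocks),
        data=sub, age_handling=age_handling, reference_levels=refs,
        nobs=int(full.nobs),
    )


def residual_diagnostics(fit: AncovaFit, group: str = "brand_label") -> dict:
    """Normality (Shapiro–Wilk) and variance-homogeneity (median-centered
    Levene, i.e. Brown–Forsythe) checks on the ANCOVA residuals.

    Homogeneity is tested across the levels of ``group`` in the fitted
    subset; levels with fewer than 2 residuals are excluded and listed
    under ``excluded_groups``.
    """
    resid = fit.residuals
    if resid.shape[0] < 8:
        raise ValueError(f"need at least 8 residuals, got {resid.shape[0]}")
    if group not in fit.data.columns:
        raise ValueError(f"factor {group!r} not in the fitted subset")
    sw_stat, sw_p = stats.shapiro(resid)

    excluded = []
    samples = []
    for lev, idx in fit.data.groupby(group, sort=True).groups.items():
        vals = resid[fit.data.index.get_indexer(idx)]
        if vals.shape[0] < 2:
            excluded.append(str(lev))
        else:
            samples.append(vals)
    if excluded:
        warnings.warn(f"groups excluded from homogeneity test: {excluded}")
    if len(samples) < 2:
        lev_stat, lev_p = np.nan, np.nan
    else:
        lev_stat, lev_p = stats.levene(*samples, center="median")
        if np.isnan(lev_stat) and all(np.ptp(s) == 0 for s in samples):
            lev_stat, lev_p = 0.0, 1.0   # all spreads identically zero
    return {
        "shapiro": (float(sw_stat), float(sw_p)),
        "levene": (float(lev_stat), float(lev_p)),
        "group": group,
        "excluded_groups": excluded,
        "n": int(resid.shape[0]),
    }


def tto_summary(table: pd.DataFrame) -> tuple[float, float, int]:
    """Mean TTO, its standard error (sample SD / sqrt(n)) and n over the
    occluded rows."""
    tto = table.loc[table["occluded"] == 1, "tto_months"].to_numpy(dtype=float)
    n = tto.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 occluded rows, got {n}")
    return float(tto.mean()), float(tto.std(ddof=1) / np.sqrt(n)), int(n)
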