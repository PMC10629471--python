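"""Region-wise regression models, FDR control, power and normality gates.

Implements the statistical layer of the analysis: standardized region-wise
linear models of tau accumulation rate on amyloid burden, CSF sTREM2 and
baseline tau (four nested predictor sets), Benjamini-Hochberg FDR across the
200-parcel family, the partial association between the individual spreading
statistic and sTREM2, a Kolmogorov-Smirnov normality gate with log transform,
variance-inflation collinearity checks, and the Fisher-z power approximation
used to gate correlation analyses at 80% power.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: predictor sets of the four nested region-wise models
MODEL_SPECS = {
    1: ("regional_ab",),
    2: ("strem2",),
    3: ("regional_ab", "strem2"),
    4: ("regional_ab", "strem2", "baseline_tau"),
}


@dataclass
class PartialAssociation:
    """Standardized coefficient of one predictor after covariate adjustment."""

    outcome: str
    predictor: str
    covariates: tuple
    coefficient: float
    p_value: float
    n: int


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and two-sided p-values (classical t tests)."""
    n, p = X.shape
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError("not enough observations for the design")
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(XtX_inv) * s2)
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    return beta, pvals


def normality_gate(values: pd.Series | np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, bool]:
    """KS normality check with log transform for non-normal positive data.

    A one-sample Kolmogorov-Smirnov test is run against a normal with the
    sample's moments; if p < alpha the natural-log-transformed values are
    returned with the flag set.
    """
    ser = pd.Series(values)
    x = ser.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("degenerate (constant) sample: normality gate undefined")
    _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    if p >= alpha:
        return x, False
    bad = ser.index[ser <= 0].tolist()
    if bad:
        raise ValueError(
            f"log transform indicated but non-positive values present: {bad}")
    return np.log(x), True


def fdr_bh(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q-values, significance mask)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def collinearity_check(predictors: pd.DataFrame, bound: float = 5.0) -> pd.DataFrame:
    """Variance inflation factor per predictor: 1 / (1 - R^2 on the others)."""
    X = predictors.to_numpy(dtype=float)
    n, p = X.shape
    rows = []
    for j, name in enumerate(predictors.columns):
        y = X[:, j]
        if p == 1:
            vif = 1.0
        else:
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
            resid = y - others @ beta
            tss = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": name, "vif": vif, "exceeds_bound": bool(vif > bound)})
    return pd.DataFrame(rows)


def regionwise_models(
    slopes: pd.DataFrame,
    regional_ab: pd.DataFrame,
    strem2: pd.Series,
    baseline_tau: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Standardized region-wise linear models of tau accumulation rate.

    For each parcel, the tau-PET rate of change is regressed on the spec's
    predictor set (1: regional amyloid; 2: sTREM2; 3: both; 4: both plus
    baseline regional tau) with age and sex as covariates.  Outcome and
    continuous predictors are z-scored per parcel; sex stays binary
    unstandardized.  Returns a tidy table with BH q-values computed within
    one (spec, predictor) family across parcels.
    """
    if spec not in MODEL_SPECS:
        raise ValueError(f"unknown model spec {spec}")
    names = MODEL_SPECS[spec]
    ids = slopes.index
    cov = covariates.loc[ids]
    cov_cols = []
    for c in cov.columns:
        col = cov[c].to_numpy(dtype=float)
        uniq = np.unique(col)
        cov_cols.append(col if uniq.size <= 2 else zscore(col))
    s2 = zscore(strem2.loc[ids].to_numpy(dtype=float))

    rows = []
    for parcel in slopes.columns:
        y = slopes[parcel].to_numpy(dtype=float)
        pred_cols = []
        try:
            y = zscore(y)
            for nm in names:
                if nm == "regional_ab":
                    pred_cols.append(zscore(regional_ab[parcel].loc[ids].to_numpy(dtype=float)))
                elif nm == "strem2":
                    pred_cols.append(s2)
                elif nm == "baseline_tau":
                    pred_cols.append(zscore(baseline_tau[parcel].loc[ids].to_numpy(dtype=float)))
            X = np.column_stack([np.ones(len(ids))] + pred_cols + cov_cols)
            beta, pvals = _ols(X, y)
        except (ValueError, np.linalg.LinAlgError):
            for j, nm in enumerate(names):
                rows.append({"parcel": int(parcel), "spec": spec, "predictor": nm,
                             "beta": np.nan, "p_value": np.nan, "n": len(ids),
                             "excluded": True})
            continue
        for j, nm in enumerate(names):
            rows.append({"parcel": int(parcel), "spec": spec, "predictor": nm,
                         "beta": float(beta[1 + j]), "p_value": float(pvals[1 + j]),
                         "n": len(ids), "excluded": False})
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    out["significant"] = False
    for nm in names:  # FDR family: the parcels of one spec x predictor
        m = (out["predictor"] == nm) & ~out["excluded"] & out["p_value"].notna()
        if m.any():
            q, rej = fdr_bh(out.loc[m, "p_value"].to_numpy(), alpha=alpha)
            out.loc[m, "q_value"] = q
            out.loc[m, "significant"] = rej
    return out


def beta_strem2_association(
    betas: pd.Series,
    strem2: pd.Series,
    covariates: pd.DataFrame,
    extra_adjust: Optional[pd.DataFrame] = None,
    log_strem2: bool = True,
) -> PartialAssociation:
    """Partial association between the spreading statistic and sTREM2.

    Ordinary least squares of the individual standardized beta on
    standardized log-sTREM2 adjusting for the covariates (age, sex, global
    amyloid by default), optionally with extra adjustments such as baseline
    tau or CSF p-tau.
    """
    ids = betas.dropna().index
    if len(ids) < 10:
        raise ValueError(f"need at least 10 participants with a beta, got {len(ids)}")
    y = betas.loc[ids].to_numpy(dtype=float)
    if y.std(ddof=1) == 0:
        raise ValueError("zero variance in the spreading statistic")
    y = zscore(y)
    s = strem2.loc[ids].to_numpy(dtype=float)
    if log_strem2:
        if np.any(s <= 0):
            raise ValueError("sTREM2 must be positive for the log transform")
        s = np.log(s)
    x = zscore(s)
    cols = [np.ones(len(ids)), x]
    names = []
    cov = covariates.loc[ids]
    if extra_adjust is not None:
        cov = pd.concat([cov, extra_adjust.loc[ids]], axis=1)
    for c in cov.columns:
        col = cov[c].to_numpy(dtype=float)
        uniq = np.unique(col)
        cols.append(col if uniq.size <= 2 else zscore(col))
        names.append(c)
    X = np.column_stack(cols)
    beta, pvals = _ols(X, y)
    return PartialAssociation(
        outcome="spreading_beta", predictor="log_strem2",
        covariates=tuple(names), coefficient=float(beta[1]),
        p_value=float(pvals[1]), n=len(ids))


def power_check(n: int, effect_size: float = 0.3, alpha: float = 0.05) -> float:
    """Power of a two-sided correlation test via the Fisher-z approximation.

    power = Phi(sqrt(n - 3) * atanh(rho) - z_{1 - alpha/2}).
    """
    if n < 4:
        return 0.0
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(np.sqrt(n - 3) * np.arctanh(effect_size) - z_alpha))


def minimum_n_for_power(
    target_power: float = 0.8,
    effect_size: float = 0.3,
    alpha: float = 0.05,
) -> int:
    """Smallest n certified by the Fisher-z formula to reach the target power."""
    z_alpha = sps.norm.ppf(1.0 - alpha / 2.0)
    z_power = sps.norm.ppf(target_power)
    n = int(np.ceil(((z_power + z_alpha) / np.arctanh(effect_size)) ** 2 + 3))
    while power_check(n, effect_size, alpha) < target_power:
        n += 1
    return n
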