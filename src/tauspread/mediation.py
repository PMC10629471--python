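"""Covariate-adjusted linear mediation with case-resampling bootstrap.

Three nested OLS fits define the paths: M ~ X + C gives a; Y ~ X + M + C
gives b and the direct effect c'; Y ~ X + C gives the total effect c.  The
average causal mediation effect is the product a*b, the direct effect is c',
and for linear OLS the identity c = c' + a*b holds exactly on every dataset.
Inference is a nonparametric case-resampling percentile bootstrap of all
paths with a fixed seed; two-sided p-values are twice the smaller tail
fraction of bootstrap draws crossing zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stats import fdr_bh, zscore

_STATS = ("a", "b", "c", "c_prime", "acme", "ade", "delta")


@dataclass
class MediationResult:
    """Point estimates, percentile bootstrap CIs and p-values of all paths.

    delta = c' - c (direct minus total); proportion mediated = acme / c,
    reported missing when |c| is numerically zero.
    """

    a: float
    b: float
    c: float
    c_prime: float
    acme: float
    ade: float
    proportion_mediated: float
    delta: float
    ci: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    n: int = 0
    n_boot: int = 0
    seed: int = 0


def _fit_paths(X: np.ndarray, M: np.ndarray, Y: np.ndarray, C: np.ndarray) -> dict:
    n = X.size
    ones = np.ones(n)
    Zm = np.column_stack([ones, X, C]) if C.size else np.column_stack([ones, X])
    a = float(np.linalg.lstsq(Zm, M, rcond=None)[0][1])
    Zy = np.column_stack([ones, X, M, C]) if C.size else np.column_stack([ones, X, M])
    coef = np.linalg.lstsq(Zy, Y, rcond=None)[0]
    c_prime, b = float(coef[1]), float(coef[2])
    Zc = np.column_stack([ones, X, C]) if C.size else np.column_stack([ones, X])
    c = float(np.linalg.lstsq(Zc, Y, rcond=None)[0][1])
    return {"a": a, "b": b, "c": c, "c_prime": c_prime,
            "acme": a * b, "ade": c_prime, "delta": c_prime - c}


def mediate(
    X,
    M,
    Y,
    covariates: Optional[pd.DataFrame] = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    standardize: bool = True,
) -> MediationResult:
    """Linear mediation of X on Y through M, adjusted for covariates on all paths.

    Complete cases only (rows with any missing value are dropped).  With
    ``standardize`` (default) X, M and Y are z-scored before fitting so the
    paths are standardized coefficients.
    """
    x = pd.Series(X).astype(float)
    m = pd.Series(M).astype(float)
    y = pd.Series(Y).astype(float)
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    if covariates is not None and len(covariates.columns):
        cov = covariates.astype(float)
        cov.columns = [f"c_{c}" for c in cov.columns]
        df = df.join(cov)
    df = df.dropna()
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 complete cases, got {n}")
    for col in ("x", "m", "y"):
        if df[col].std(ddof=1) == 0:
            raise ValueError(f"zero variance in {col}")
    if n_boot < 100:
        import warnings
        warnings.warn(f"n_boot={n_boot} is small; bootstrap p-values will be coarse")

    Xv = zscore(df["x"].to_numpy()) if standardize else df["x"].to_numpy()
    Mv = zscore(df["m"].to_numpy()) if standardize else df["m"].to_numpy()
    Yv = zscore(df["y"].to_numpy()) if standardize else df["y"].to_numpy()
    Cv = df[[c for c in df.columns if c.startswith("c_")]].to_numpy()

    point = _fit_paths(Xv, Mv, Yv, Cv)
    prop = point["acme"] / point["c"] if abs(point["c"]) > 1e-12 else float("nan")

    rng = np.random.default_rng(seed)
    boots = {k: np.empty(n_boot) for k in _STATS}
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        bp = _fit_paths(Xv[idx], Mv[idx], Yv[idx], Cv[idx] if Cv.size else Cv)
        for k in _STATS:
            boots[k][i] = bp[k]
    lo_q, hi_q = (1.0 - ci_level) / 2.0, 1.0 - (1.0 - ci_level) / 2.0
    ci = {k: (float(np.quantile(v, lo_q)), float(np.quantile(v, hi_q)))
          for k, v in boots.items()}
    pvals = {}
    for k, v in boots.items():
        frac_le = np.mean(v <= 0.0)
        frac_ge = np.mean(v >= 0.0)
        pvals[k] = float(min(1.0, 2.0 * min(frac_le, frac_ge)))
    return MediationResult(
        a=point["a"], b=point["b"], c=point["c"], c_prime=point["c_prime"],
        acme=point["acme"], ade=point["ade"], proportion_mediated=prop,
        delta=point["delta"], ci=ci, p_values=pvals, n=n, n_boot=n_boot,
        seed=seed)


def result_row(res: MediationResult, **extra) -> dict:
    row = {
        "a": res.a, "b": res.b, "c": res.c, "c_prime": res.c_prime,
        "acme": res.acme, "ade": res.ade,
        "proportion_mediated": res.proportion_mediated, "delta": res.delta,
        "acme_ci_lo": res.ci["acme"][0], "acme_ci_hi": res.ci["acme"][1],
        "acme_p": res.p_values["acme"], "delta_p": res.p_values["delta"],
        "n": res.n, "n_boot": res.n_boot, "seed": res.seed,
    }
    row.update(extra)
    return row


def regionwise_mediation(
    regional_ab: pd.DataFrame,
    strem2: pd.Series,
    slopes: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region mediation of regional amyloid on tau accumulation through
    sTREM2, with BH-FDR over the regional ACME p-values."""
    ids = slopes.index
    rows = []
    for j, parcel in enumerate(slopes.columns):
        res = mediate(
            regional_ab[parcel].loc[ids], strem2.loc[ids], slopes[parcel],
            covariates=covariates.loc[ids] if covariates is not None else None,
            n_boot=n_boot, seed=seed + j)
        rows.append(result_row(res, parcel=int(parcel)))
    out = pd.DataFrame(rows)
    q, rej = fdr_bh(out["acme_p"].to_numpy(), alpha=alpha)
    out["acme_q"] = q
    out["acme_significant"] = rej
    return out


def cognition_mediation(
    strem2: pd.Series,
    mediator: pd.Series,
    mmse_slope: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    extra_covariate: Optional[pd.Series] = None,
    n_boot: int = 1000,
    seed: int = 0,
    log_strem2: bool = True,
) -> MediationResult:
    """Mediation of the sTREM2 - cognitive decline association through a tau
    measure (the individual spreading beta or the global tau slope)."""
    s = strem2.astype(float)
    if log_strem2:
        if (s <= 0).any():
            raise ValueError("sTREM2 must be positive for the log transform")
        s = np.log(s)
    cov = covariates
    if extra_covariate is not None:
        extra = extra_covariate.to_frame()
        cov = extra if cov is None else covariates.join(extra)
    return mediate(s, mediator, mmse_slope, covariates=cov,
                   n_boot=n_boot, seed=seed)
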