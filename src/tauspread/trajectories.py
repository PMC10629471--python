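"""Per-participant rates of change from longitudinal visits.

Regional tau-PET SUVR and MMSE trajectories are summarised as annual rates of
change.  The primary estimator is a linear mixed-effects model per region
(fixed intercept and slope on time; random intercept and random slope per
participant), from which each participant's rate is the fixed slope plus the
empirical-Bayes prediction of their random-slope deviation.  When the mixed
model fails to converge — common with two-visit subjects at small n — the
estimator falls back to per-subject ordinary least squares and flags the
method per cell.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class SlopeMatrix:
    """Participants x parcels rates of change with per-parcel diagnostics."""

    values: pd.DataFrame       # SUVR/year
    method: pd.Series          # per parcel: "mixed" or "ols"
    diagnostics: pd.DataFrame  # per parcel: converged, resid_sd


@dataclass
class CognitiveSlopes:
    """Per-participant MMSE rate of change (points/year)."""

    values: pd.Series
    n_visits: pd.Series
    method: str


def _per_subject_ols(df: pd.DataFrame, value_col: str) -> pd.Series:
    """Closed-form per-subject least-squares slopes; <2 visits -> NaN."""
    out = {}
    for pid, grp in df.groupby("id", sort=True):
        t = grp["time"].to_numpy(dtype=float)
        y = grp[value_col].to_numpy(dtype=float)
        if t.size < 2 or np.ptp(t) == 0:
            out[pid] = np.nan
            continue
        tc = t - t.mean()
        out[pid] = float(tc @ (y - y.mean()) / (tc @ tc))
    return pd.Series(out, name="slope")


def _mixed_model_slopes(df: pd.DataFrame, value_col: str) -> tuple[pd.Series, bool, float]:
    """Random-intercept/random-slope LME; returns EB slopes, converged, resid SD."""
    ids = df["id"].to_numpy()
    t = df["time"].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=ids, exog_re=X)
        # Powell is the most reliable optimizer for these small variance
        # components; gradient methods often stop with a spurious non-converged
        # flag when the random-slope variance is near zero.  When Powell lands
        # on the zero-residual boundary (noise-free trajectories) BFGS finds
        # the interior optimum; take whichever converged fit is more likely.
        res = model.fit(reml=True, method="powell", maxiter=500)
        if res.scale < 1e-8:
            try:
                alt = model.fit(reml=True, method="bfgs", maxiter=500)
                if alt.converged:
                    res = alt
            except Exception:
                pass
    if not res.converged:
        raise RuntimeError("mixed model did not converge")
    fe_slope = float(res.fe_params[1])
    re = res.random_effects
    slopes = {pid: fe_slope + float(eff.iloc[1]) for pid, eff in re.items()}
    resid_sd = float(np.sqrt(res.scale))
    return pd.Series(slopes, name="slope"), True, resid_sd


def fit_region_slopes(
    tau_scans: pd.DataFrame,
    parcel: int,
    method: str = "mixed",
) -> tuple[pd.Series, str, dict]:
    """Per-participant tau accumulation rate for one parcel.

    Returns (slopes indexed by participant id, method used, diagnostics).
    ``method='ols'`` skips the mixed model entirely.
    """
    df = tau_scans.loc[tau_scans["parcel"] == parcel, ["id", "time", "suvr"]]
    if df.empty:
        raise ValueError(f"no scans for parcel {parcel}")
    counts = df.groupby("id")["time"].nunique()
    if (counts >= 2).sum() == 0:
        raise ValueError(f"parcel {parcel}: all participants have a single visit")
    if float(df["time"].var()) == 0.0:
        raise ValueError(f"parcel {parcel}: degenerate time variance")
    multi = counts[counts >= 2]
    if method == "mixed" and multi.size >= 2:
        try:
            slopes, conv, resid_sd = _mixed_model_slopes(df, "suvr")
            slopes = slopes.reindex(sorted(df["id"].unique()))
            return slopes, "mixed", {"converged": conv, "resid_sd": resid_sd}
        except Exception:
            pass  # fall through to per-subject least squares
    slopes = _per_subject_ols(df, "suvr")
    resid_sd = float("nan")
    return slopes, "ols", {"converged": False, "resid_sd": resid_sd}


def fit_slope_matrix(tau_scans: pd.DataFrame, method: str = "mixed") -> SlopeMatrix:
    """Fit every parcel independently and assemble the slope matrix."""
    parcels = np.sort(tau_scans["parcel"].unique())
    cols, methods, diags = {}, {}, {}
    for p in parcels:
        s, m, d = fit_region_slopes(tau_scans, int(p), method=method)
        cols[int(p)] = s
        methods[int(p)] = m
        diags[int(p)] = d
    values = pd.DataFrame(cols)
    values.index.name = "id"
    return SlopeMatrix(
        values=values,
        method=pd.Series(methods, name="method"),
        diagnostics=pd.DataFrame.from_dict(diags, orient="index"),
    )


def ols_slope_matrix(tau_scans: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-subject least-squares slopes for all parcels at once.

    Equivalent to the OLS fallback path of :func:`fit_slope_matrix` but
    computed with one pass per subject (times are shared across parcels
    within a scan), which matters for simulation studies.
    """
    out = {}
    for pid, grp in tau_scans.groupby("id", sort=True):
        wide = grp.pivot_table(index="time", columns="parcel", values="suvr")
        t = wide.index.to_numpy(dtype=float)
        if t.size < 2 or np.ptp(t) == 0:
            out[pid] = pd.Series(np.nan, index=wide.columns)
            continue
        tc = t - t.mean()
        Y = wide.to_numpy(dtype=float)
        out[pid] = pd.Series((tc @ (Y - Y.mean(axis=0))) / (tc @ tc),
                             index=wide.columns)
    values = pd.DataFrame.from_dict(out, orient="index").sort_index()
    values.index.name = "id"
    return values


def fit_cognitive_slope(mmse_visits: pd.DataFrame, method: str = "mixed") -> CognitiveSlopes:
    """Per-participant MMSE rate of change (points/year).

    Participants with fewer than two visits are reported missing, never zero.
    """
    df = mmse_visits[["id", "time", "mmse"]].copy()
    counts = df.groupby("id")["time"].nunique()
    if (counts >= 2).sum() == 0:
        raise ValueError("all participants have a single MMSE visit")
    used = "ols"
    slopes = None
    if method == "mixed" and (counts >= 2).sum() >= 2:
        try:
            slopes, _, _ = _mixed_model_slopes(df, "mmse")
            used = "mixed"
        except Exception:
            slopes = None
    if slopes is None:
        slopes = _per_subject_ols(df, "mmse")
    slopes = slopes.reindex(sorted(df["id"].unique()))
    slopes[counts.reindex(slopes.index) < 2] = np.nan
    return CognitiveSlopes(values=slopes, n_visits=counts.reindex(slopes.index),
                           method=used)


def global_slope(slopes: SlopeMatrix | pd.DataFrame, parcel_subset=None) -> pd.Series:
    """Unweighted mean rate of change over a parcel subset (default: all)."""
    values = slopes.values if isinstance(slopes, SlopeMatrix) else slopes
    if parcel_subset is not None:
        parcel_subset = list(parcel_subset)
        if len(parcel_subset) == 0:
            raise ValueError("parcel subset is empty")
        values = values[parcel_subset]
    return values.mean(axis=1).rename("global_slope")
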