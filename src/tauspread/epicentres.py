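"""Tau-positivity mixture modelling and individual epicentre selection.

Baseline tau-PET SUVR in a region pools two signals: non-specific (off-target)
binding and abnormal tau aggregate binding.  A two-component univariate
Gaussian mixture is fitted per region across participants; the posterior
probability of the higher-mean component, p_abn(x), is a threshold-free
probabilistic measure of tau positivity.  Multiplying p_abn(SUVR) by the SUVR
itself gives a score cleaned of non-specific signal, and each participant's
epicentres are the top-k regions by that score.

The EM fitter is deliberately small and fully deterministic: quantile-based
initialization (component means at the 25th and 90th percentiles), a variance
floor with bounded jittered restarts, and an explicit log-likelihood trace
whose monotonicity is asserted in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: sentinel score for excluded parcels; can never win top-k selection
EXCLUDED_SCORE = -np.inf


@dataclass
class RegionGMM:
    """Two-component univariate Gaussian mixture, mu1 <= mu2.

    ``pi_abn`` is the mixing weight of the higher-mean ("abnormal")
    component.  ``unimodal`` is set when a single Gaussian explains the
    region better by BIC, i.e. the region carries no detectable abnormal
    signal; scoring treats such regions as entirely non-specific.
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    pi_abn: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = False
    n_restarts: int = 0
    unimodal: bool = False
    bic_1: float = float("nan")
    bic_2: float = float("nan")

    def p_abn(self, x) -> np.ndarray:
        """Posterior probability that x arises from the abnormal component."""
        x = np.asarray(x, dtype=float)
        f1 = (1.0 - self.pi_abn) * sps.norm.pdf(x, self.mu1, self.sigma1)
        f2 = self.pi_abn * sps.norm.pdf(x, self.mu2, self.sigma2)
        tot = f1 + f2
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(tot > 0, f2 / tot, np.where(x >= (self.mu1 + self.mu2) / 2, 1.0, 0.0))
        return post


def _em_once(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, w: np.ndarray,
             tol: float, max_iter: int, sigma_floor: float):
    """One EM run from the given start; returns params + trace or None on collapse."""
    n = x.size
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        comp = w[:, None] * sps.norm.pdf(x[None, :], mu[:, None], sigma[:, None])
        tot = comp.sum(axis=0)
        if np.any(tot <= 0) or not np.all(np.isfinite(tot)):
            return None
        ll = float(np.log(tot).sum())
        trace.append(ll)
        resp = comp / tot
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            return None
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
        sigma = np.sqrt(var)
        if np.any(sigma < sigma_floor):
            return None
        w = nk / n
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return mu, sigma, w, np.array(trace), converged


def fit_two_component_gmm(
    values: Sequence[float],
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    sigma_floor_frac: float = 1e-3,
    max_restarts: int = 5,
) -> RegionGMM:
    """Fit a two-component Gaussian mixture to one region's SUVR values.

    Initialization places the component means at the 25th and 90th
    percentiles with equal weights.  If a component's SD collapses below
    ``sigma_floor_frac`` times the data SD, the fit restarts from a jittered
    initialization (at most ``max_restarts`` times) and is flagged
    non-converged if all restarts collapse.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need at least 10 finite values, got {x.size}")
    sd = float(x.std(ddof=0))
    if sd == 0:
        raise ValueError("zero variance: cannot fit a mixture")
    sigma_floor = sigma_floor_frac * sd
    rng = np.random.default_rng(seed)

    mu0 = np.percentile(x, [25.0, 90.0]).astype(float)
    sigma0 = np.array([sd / 2.0, sd / 2.0])
    w0 = np.array([0.5, 0.5])

    result = None
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            mu, sigma, w = mu0.copy(), sigma0.copy(), w0.copy()
        else:
            n_restarts = attempt
            mu = mu0 + rng.normal(0.0, 0.25 * sd, 2)
            sigma = sigma0 * rng.uniform(0.5, 1.5, 2)
            w = np.array([0.5, 0.5])
        result = _em_once(x, mu, sigma, w, tol, max_iter, sigma_floor)
        if result is not None:
            break
    if result is None:
        # all restarts collapsed: report a degenerate, clearly flagged fit
        return RegionGMM(float(x.mean()), float(x.mean()), sd, sd, 0.5,
                         np.array([]), converged=False, n_restarts=n_restarts)
    mu, sigma, w, trace, converged = result
    order = np.argsort(mu)  # relabel so mu2 is the right-most component
    mu, sigma, w = mu[order], sigma[order], w[order]
    # one- vs two-component model selection: without this, regions carrying
    # only non-specific signal get a spurious bulk/tail split
    n = x.size
    ll1 = float(sps.norm.logpdf(x, x.mean(), max(x.std(ddof=0), sigma_floor)).sum())
    ll2 = float(trace[-1]) if trace.size else -np.inf
    bic1 = 2 * np.log(n) - 2 * ll1
    bic2 = 5 * np.log(n) - 2 * ll2
    return RegionGMM(float(mu[0]), float(mu[1]), float(sigma[0]), float(sigma[1]),
                     float(w[1]), trace, converged=converged, n_restarts=n_restarts,
                     unimodal=bool(bic1 <= bic2), bic_1=float(bic1), bic_2=float(bic2))


def fit_region_gmms(
    baseline_suvr: pd.DataFrame,
    exclusion_mask: Optional[Sequence[int]] = None,
    **kwargs,
) -> dict[int, RegionGMM]:
    """Fit the mixture for every non-excluded parcel of a participants x
    parcels baseline SUVR table."""
    excluded = set(int(e) for e in exclusion_mask) if exclusion_mask is not None else set()
    gmms = {}
    for parcel in baseline_suvr.columns:
        if int(parcel) in excluded:
            continue
        gmms[int(parcel)] = fit_two_component_gmm(baseline_suvr[parcel].to_numpy(), **kwargs)
    return gmms


def baseline_suvr_table(tau_scans: pd.DataFrame) -> pd.DataFrame:
    """Participants x parcels SUVR at each participant's first visit."""
    first = tau_scans.loc[tau_scans.groupby("id")["time"].transform("min")
                          == tau_scans["time"]]
    return first.pivot_table(index="id", columns="parcel", values="suvr")


def default_exclusion_mask(
    baseline_suvr: pd.DataFrame,
    networks: Sequence[str],
    network: str = "somatomotor",
    decile: float = 0.10,
) -> list[int]:
    """Parcels excluded from epicentre selection: parcels in the given
    network whose cohort-mean SUVR falls in the lowest decile."""
    means = baseline_suvr.mean(axis=0)
    cut = means.quantile(decile)
    return sorted(int(p) for p in baseline_suvr.columns
                  if networks[int(p)] == network and means[p] <= cut)


def epicentre_scores(
    baseline_suvr: pd.DataFrame,
    gmms: Mapping[int, RegionGMM],
    exclusion_mask: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Abnormality-weighted SUVR score per participant and parcel.

    score = p_abn(SUVR) x SUVR; excluded parcels carry ``-inf`` so they can
    never be selected as epicentres.
    """
    excluded = set(int(e) for e in exclusion_mask) if exclusion_mask is not None else set()
    scores = pd.DataFrame(index=baseline_suvr.index, columns=baseline_suvr.columns,
                          dtype=float)
    for parcel in baseline_suvr.columns:
        p = int(parcel)
        if p in excluded:
            scores[parcel] = EXCLUDED_SCORE
            continue
        if p not in gmms:
            raise KeyError(f"no fitted mixture for non-excluded parcel {p}")
        x = baseline_suvr[parcel].to_numpy(dtype=float)
        if gmms[p].unimodal:
            scores[parcel] = 0.0  # no abnormal component detected
        else:
            scores[parcel] = gmms[p].p_abn(x) * x
    return scores


def select_epicentres(scores: pd.DataFrame, k: int = 10) -> dict[str, tuple]:
    """Top-k parcels by score per participant, ties broken by lower index.

    Returns a mapping from participant id to a tuple of k parcels ordered by
    non-increasing score; selection equals a full sort's top-k.
    """
    cols = np.array([int(c) for c in scores.columns])
    if k > (scores.shape[1]):
        raise ValueError(f"k={k} exceeds the number of parcels {scores.shape[1]}")
    out = {}
    for pid, row in scores.iterrows():
        v = row.to_numpy(dtype=float)
        usable = np.isfinite(v)
        if usable.sum() < k:
            raise ValueError(f"participant {pid}: only {int(usable.sum())} "
                             f"selectable parcels for k={k}")
        order = np.lexsort((cols, -v))
        out[pid] = tuple(int(cols[i]) for i in order[:k])
    return out


def gmm_table(gmms: Mapping[int, RegionGMM]) -> pd.DataFrame:
    """Tidy per-region mixture parameters for on-disk export."""
    rows = [{
        "parcel": p, "mu1": g.mu1, "mu2": g.mu2, "sigma1": g.sigma1,
        "sigma2": g.sigma2, "pi_abn": g.pi_abn, "converged": g.converged,
        "unimodal": g.unimodal, "n_restarts": g.n_restarts,
        "n_iter": len(g.loglik_trace),
    } for p, g in sorted(gmms.items())]
    return pd.DataFrame(rows)
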