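"""Group functional-connectivity template and connectivity-based spreading statistic.

Builds the group template from parcel-wise rs-fMRI time series (motion
scrubbing, Pearson correlation, Fisher-z, subject averaging, density
thresholding, conversion to a bounded distance), then quantifies how strongly
each participant's regional tau accumulation rates track connectivity-based
distance to that participant's tau epicentres.  The per-participant statistic
is the standardized regression coefficient (equivalently the Pearson
correlation) of regional slope on distance across non-epicentre regions:
negative values mean regions more strongly connected to the epicentres
accumulate tau faster.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: correlations are capped at this magnitude before the Fisher transform so z stays finite
R_CAP = 1.0 - 1e-7


@dataclass
class SubjectFC:
    """One template subject's Fisher-z connectivity matrix after scrubbing."""

    z: np.ndarray
    censored_fraction: float
    retained: bool
    n_frames_used: int = 0


@dataclass
class ConnectivityTemplate:
    """Group-average connectome: mean Fisher-z, density mask and distance.

    ``distance`` lies in [0, 1]; the strongest retained edge has distance 0,
    the weakest retained edge distance 1, and every non-retained edge is
    assigned the maximal distance 1.  Self-distance is 0.
    """

    mean_z: np.ndarray
    mask: np.ndarray
    distance: np.ndarray
    density: float
    n_subjects: int = 0


@dataclass
class SpreadingStat:
    """Per-participant connectivity-based spreading statistic."""

    beta: float
    p_value: float
    n_regions: int
    epicentres: tuple = ()
    flagged: bool = False


def _round_half_away(x: float) -> int:
    # density * n_pairs edge count, bit-reproducible regardless of banker's rounding
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def scrub_and_fc(
    signals: np.ndarray,
    fd: np.ndarray,
    fd_threshold: float = 0.5,
    max_censored_fraction: float = 0.30,
    min_frames: int = 10,
) -> SubjectFC:
    """Censor high-motion frames and compute a Fisher-z connectivity matrix.

    Parameters
    ----------
    signals
        Parcel-by-timepoint signal matrix.
    fd
        Framewise displacement (mm) per timepoint.
    fd_threshold
        Frames with FD above this are dropped.
    max_censored_fraction
        Subjects needing this fraction (or more) of frames censored are
        flagged as not retained for template building.
    min_frames
        Minimum retained frames required to compute correlations.
    """
    signals = np.asarray(signals, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be a parcel x timepoint matrix")
    if fd.shape[0] != signals.shape[1]:
        raise ValueError("motion trace length must equal the number of timepoints")
    keep = fd <= fd_threshold
    censored = 1.0 - keep.mean()
    retained = censored < max_censored_fraction
    used = signals[:, keep]
    n_used = used.shape[1]
    n = signals.shape[0]
    if n_used < max(2, min_frames):
        return SubjectFC(np.full((n, n), np.nan), censored, False, n_used)
    sd = used.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(used)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    r = np.clip(r, -R_CAP, R_CAP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return SubjectFC(z, censored, retained, n_used)


def template_from_z(mean_z: np.ndarray, density: float = 0.30) -> ConnectivityTemplate:
    """Threshold an averaged Fisher-z matrix at a target edge density and
    convert it to a distance matrix.

    Exactly ``round(density * n_pairs)`` strongest edges (by mean z, ties
    broken by lower parcel indices) are retained.  Retained edges receive
    ``1 - minmax(z)``; all others distance 1.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    mean_z = np.asarray(mean_z, dtype=float)
    n = mean_z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    zvals = mean_z[iu, ju]
    n_pairs = zvals.size
    m = _round_half_away(density * n_pairs)
    m = max(1, min(m, n_pairs))
    order = np.lexsort((ju, iu, -zvals))  # strongest first, deterministic ties
    top = order[:m]

    mask = np.zeros((n, n), dtype=bool)
    mask[iu[top], ju[top]] = True
    mask |= mask.T

    distance = np.ones((n, n), dtype=float)
    zr = zvals[top]
    zmin, zmax = zr.min(), zr.max()
    if zmax > zmin:
        d_edges = 1.0 - (zr - zmin) / (zmax - zmin)
    else:
        d_edges = np.zeros_like(zr)
    distance[iu[top], ju[top]] = d_edges
    distance[ju[top], iu[top]] = d_edges
    np.fill_diagonal(distance, 0.0)
    return ConnectivityTemplate(mean_z, mask, distance, m / n_pairs)


def build_template(
    fcs: Iterable[SubjectFC],
    density: float = 0.30,
) -> ConnectivityTemplate:
    """Average retained subjects' z-matrices and build the group template."""
    kept = [fc.z for fc in fcs if fc.retained]
    if not kept:
        raise ValueError("no retained subjects: cannot build a template")
    stack = np.stack(kept)
    with np.errstate(invalid="ignore"):
        mean_z = np.nanmean(stack, axis=0)
    tpl = template_from_z(mean_z, density=density)
    tpl.n_subjects = len(kept)
    return tpl


def distance_to_epicentres(
    template: ConnectivityTemplate,
    epicentres: Sequence[int],
    agg: str = "mean",
) -> pd.Series:
    """Distance of every parcel to an epicentre set.

    ``agg`` chooses how the k per-epicentre distances collapse to one number
    per region ("mean" by default; "min" and "median" available).
    """
    epis = np.asarray(list(epicentres), dtype=int)
    n = template.distance.shape[0]
    if epis.size == 0:
        raise ValueError("epicentre set is empty")
    if epis.min() < 0 or epis.max() >= n:
        raise ValueError("epicentre index outside the atlas")
    sub = template.distance[:, epis]
    if agg == "mean":
        d = sub.mean(axis=1)
    elif agg == "min":
        d = sub.min(axis=1)
    elif agg == "median":
        d = np.median(sub, axis=1)
    else:
        raise ValueError(f"unknown aggregation '{agg}'")
    return pd.Series(d, index=np.arange(n), name="distance")


def spreading_beta(
    slopes: pd.Series,
    distances: pd.Series,
    epicentres: Sequence[int],
    min_regions: int = 10,
    exclude: Optional[Sequence[int]] = None,
) -> SpreadingStat:
    """Standardized regression of regional tau slope on distance to epicentres.

    Both variables are z-scored across non-epicentre regions, so the
    coefficient equals the Pearson correlation; a two-sided p-value is
    reported.  Epicentre parcels never enter the regression.
    """
    epis = set(int(e) for e in epicentres)
    excl = set(int(e) for e in exclude) if exclude is not None else set()
    idx = [i for i in slopes.index if i not in epis and i not in excl]
    s = slopes.loc[idx].to_numpy(dtype=float)
    d = distances.loc[idx].to_numpy(dtype=float)
    ok = np.isfinite(s) & np.isfinite(d)
    s, d = s[ok], d[ok]
    n = s.size
    if n < min_regions:
        raise ValueError(
            f"only {n} usable non-epicentre regions (minimum {min_regions})"
        )
    if s.std() == 0 or d.std() == 0:
        return SpreadingStat(np.nan, np.nan, n, tuple(sorted(epis)), flagged=True)
    r, p = sps.pearsonr(s, d)
    return SpreadingStat(float(r), float(p), n, tuple(sorted(epis)))


def participant_spreading(
    slope_values: pd.DataFrame,
    template: ConnectivityTemplate,
    epicentre_sets: Mapping[str, Sequence[int]],
    agg: str = "mean",
    exclude: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Individual-level spreading statistic for every participant.

    ``slope_values`` is a participants x parcels table of tau-PET rates of
    change; ``epicentre_sets`` maps participant id to that individual's
    epicentre parcels.
    """
    rows = []
    for pid, epis in epicentre_sets.items():
        d = distance_to_epicentres(template, epis, agg=agg)
        stat = spreading_beta(slope_values.loc[pid], d, epis, exclude=exclude)
        rows.append({
            "id": pid,
            "beta": stat.beta,
            "p_value": stat.p_value,
            "n_regions": stat.n_regions,
            "flagged": stat.flagged,
        })
    return pd.DataFrame(rows).set_index("id")


def group_level_spread(
    slope_values: pd.DataFrame,
    template: ConnectivityTemplate,
    scores: pd.DataFrame,
    k: int = 10,
    agg: str = "mean",
) -> tuple[SpreadingStat, pd.DataFrame]:
    """Group-level spreading analysis.

    Group epicentres are the top-k parcels by cohort-mean epicentre score;
    regional slopes are averaged across participants and regressed on the
    distance to the group epicentres.  Returns the statistic and the
    region-level scatter table behind it.
    """
    mean_scores = scores.mean(axis=0)
    order = np.lexsort((mean_scores.index.to_numpy(), -mean_scores.to_numpy()))
    group_epis = [int(mean_scores.index[i]) for i in order[:k]]
    d = distance_to_epicentres(template, group_epis, agg=agg)
    mean_slopes = slope_values.mean(axis=0)
    stat = spreading_beta(mean_slopes, d, group_epis)
    keep = [i for i in mean_slopes.index if i not in set(group_epis)]
    scatter = pd.DataFrame({
        "parcel": keep,
        "mean_slope": mean_slopes.loc[keep].to_numpy(),
        "distance": d.loc[keep].to_numpy(),
    })
    return stat, scatter
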