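"""Synthetic biomarker cohort and template time-series generator.

Emulates the statistical structure of an ADNI-like non-demented sample with
longitudinal tau-PET, baseline amyloid-PET, CSF sTREM2 and MMSE visits:

* four strata (CU/MCI x amyloid-negative/positive) with stratum-specific
  demographics;
* per-region baseline tau-PET SUVR drawn from a two-component signal model
  (non-specific everywhere, abnormal in the true epicentre regions of
  amyloid-positive subjects);
* epicentre-seeded accumulation whose rate decays with connectivity-based
  distance to the epicentres, attenuated multiplicatively by standardized
  log sTREM2 in amyloid-positive subjects only;
* MMSE decline linearly coupled to the global tau accumulation rate;
* parcel-wise rs-fMRI time series for template subjects drawn from a planted
  low-rank block (network) correlation structure, with motion spikes.

The distance that drives the planted accumulation is computed by the
connectome module from the planted correlation structure itself, so the
spreading signal is expressed in exactly the metric the analysis measures.
Every planted quantity is recorded in :class:`GroundTruth` for
parameter-recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import CohortConfig, NETWORK_NAMES
from .connectome import R_CAP, ConnectivityTemplate, template_from_z

_FLOAT_FMT = "%.17g"


@dataclass
class CohortTables:
    """The four delimited-text tables every downstream stage consumes."""

    participants: pd.DataFrame
    tau_scans: pd.DataFrame     # long: id, time (years), parcel, suvr
    ab_baseline: pd.DataFrame   # long: id, parcel, suvr, global_suvr, centiloid
    mmse_visits: pd.DataFrame   # long: id, time (years), mmse


@dataclass
class GroundTruth:
    """Planted quantities behind a generated cohort (recovery-test oracle)."""

    epicentres: dict
    true_slopes: pd.DataFrame            # participants x parcels, SUVR/year
    gamma: float
    mediation_coefficients: dict
    true_mmse_slopes: pd.Series
    strem2_z: pd.Series
    correlation: np.ndarray
    distance: np.ndarray
    networks: list
    vulnerable_parcels: list


@dataclass
class TemplateSubject:
    signals: np.ndarray   # parcels x timepoints
    fd: np.ndarray        # framewise displacement (mm) per timepoint


@dataclass
class TimeSeriesSet:
    """Template-subject time series plus the planted covariance structure."""

    subjects: list
    correlation: np.ndarray
    networks: list


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal mean and SD must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def parcel_networks(n_parcels: int, n_networks: int = 7) -> list[str]:
    """Assign parcels to contiguous network blocks of near-equal size."""
    sizes = np.full(n_networks, n_parcels // n_networks, dtype=int)
    sizes[: n_parcels % n_networks] += 1
    labels = []
    for b, s in enumerate(sizes):
        name = NETWORK_NAMES[b % len(NETWORK_NAMES)]
        if b >= len(NETWORK_NAMES):
            name = f"{name}_{b // len(NETWORK_NAMES) + 1}"
        labels.extend([name] * s)
    return labels


def planted_structure(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    """Low-rank block correlation model shared by cohort and template.

    Each parcel i loads lambda_i on its network factor and g_i on a weak
    global factor; r_ij = lambda_i lambda_j [same network] + g_i g_j.  With
    ``covariance_heterogeneity`` h the loadings are jittered in (1-h, 1+h)
    so edge strengths are distinct; h = 0 reduces to equal within-block and
    between-block correlations.  The loadings rng is derived from the config
    seed independently of the cohort draws.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    n = config.n_parcels
    networks = parcel_networks(n, config.n_networks)
    _, blocks = np.unique(networks, return_inverse=True)
    h = config.covariance_heterogeneity
    lam = np.sqrt(config.within_block_r) * rng.uniform(1.0 - h, 1.0 + h, n)
    g = np.sqrt(config.between_block_r) * rng.uniform(1.0 - h, 1.0 + h, n)
    same = blocks[:, None] == blocks[None, :]
    corr = np.outer(g, g) + np.where(same, np.outer(lam, lam), 0.0)
    np.fill_diagonal(corr, 1.0)
    uniq = 1.0 - lam**2 - g**2
    if np.any(uniq <= 0):
        raise ValueError("planted loadings exceed unit variance; lower within/between r")
    return corr, lam, g, blocks, networks


def planted_template(config: CohortConfig) -> ConnectivityTemplate:
    """The connectivity template implied by the planted correlation structure."""
    corr, _, _, _, _ = planted_structure(config)
    z = np.arctanh(np.clip(corr, -R_CAP, R_CAP))
    np.fill_diagonal(z, 0.0)
    return template_from_z(z, density=config.density)


def _pick(value, value_abpos, positive: bool):
    if positive and value_abpos is not None:
        return value_abpos
    return value


def generate_cohort(config: CohortConfig) -> tuple[CohortTables, GroundTruth]:
    """Simulate a full cohort and return its tables plus the ground truth.

    All randomness comes from ``config.seed``; identical configs produce
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 202])
    gamma = config.strem2_attenuation_gamma
    n_parcels = config.n_parcels
    noise = config.noise_sds

    corr, lam, g, blocks, networks = planted_structure(config)
    template = planted_template(config)
    distance = template.distance

    non_sm = [i for i in range(n_parcels) if networks[i] != "somatomotor"]
    pool = non_sm if len(non_sm) >= config.n_vulnerable_parcels else list(range(n_parcels))
    vulnerable = sorted(rng.choice(pool, size=config.n_vulnerable_parcels, replace=False).tolist())

    strata = [
        ("CU", "neg", config.stratum_sizes[0]),
        ("CU", "pos", config.stratum_sizes[1]),
        ("MCI", "neg", config.stratum_sizes[2]),
        ("MCI", "pos", config.stratum_sizes[3]),
    ]
    demo = {  # stratum-level demographics by amyloid status
        "neg": dict(age=(69.7, 5.7), female=0.47, edu=(16.7, 2.5), apoe4=0.29,
                    ptau=(22.0, 8.0)),
        "pos": dict(age=(72.4, 6.2), female=0.51, edu=(15.7, 2.9), apoe4=0.49,
                    ptau=(28.0, 11.0)),
    }

    part_rows, tau_rows, ab_rows, mmse_rows = [], [], [], []
    epicentres: dict[str, tuple] = {}
    slope_rows, mmse_true = {}, {}
    strem2_z = {}
    pid_counter = 0
    k = config.n_true_epicentres
    n_hi = int(round(config.vulnerable_weight * k))
    vuln_arr = np.array(vulnerable)
    other_arr = np.array([i for i in range(n_parcels) if i not in set(vulnerable)])

    for diagnosis, ab_status, n_sub in strata:
        positive = ab_status == "pos"
        d = demo[ab_status]
        s_mean, s_sd = _pick(config.strem2_lognormal_mean_sd,
                             config.strem2_lognormal_mean_sd_abpos, positive)
        mu_log, sd_log = _lognormal_params(s_mean, s_sd)
        f_mean, f_sd = _pick(config.followup_years_mean_sd,
                             config.followup_years_mean_sd_abpos, positive)
        pt_mu, pt_sd = _lognormal_params(*d["ptau"])

        for _ in range(n_sub):
            pid = f"sub-{pid_counter:04d}"
            pid_counter += 1
            age = rng.normal(*d["age"])
            sex = "F" if rng.random() < d["female"] else "M"
            edu = max(6.0, rng.normal(*d["edu"]))
            apoe4 = int(rng.random() < d["apoe4"])
            strem2 = float(np.exp(rng.normal(mu_log, sd_log)))
            z_trem = (np.log(strem2) - mu_log) / sd_log
            ptau = float(np.exp(rng.normal(pt_mu, pt_sd)))
            strem2_z[pid] = z_trem

            # epicentre set
            if positive:
                hi = rng.choice(vuln_arr, size=min(n_hi, k), replace=False)
                lo = rng.choice(other_arr, size=k - hi.size, replace=False)
                epis = np.sort(np.concatenate([hi, lo]))
            else:
                epis = np.sort(rng.choice(n_parcels, size=k, replace=False))
            epicentres[pid] = tuple(int(e) for e in epis)

            # planted regional accumulation rates
            dbar = distance[:, epis].mean(axis=1)
            if positive:
                rate = config.spread_rate_base + config.spread_distance_coefficient * dbar
                rate = rate * (1.0 - gamma * z_trem)
            else:
                rate = (config.spread_rate_base_abneg
                        + config.spread_distance_coefficient_abneg * dbar)
            rate = rate + rng.normal(0.0, noise["slope"], n_parcels)
            slope_rows[pid] = rate

            # baseline tau-PET SUVR: two-signal model.  Every region starts
            # from the non-specific component; in amyloid-positive subjects a
            # region is already abnormal at baseline with a probability that
            # grows with its pre-baseline accumulation (so abnormality is
            # binary per region, graded in frequency with distance), and the
            # epicentres themselves are always abnormal.
            base = rng.normal(*config.suvr_nonspecific_mean_sd, size=n_parcels)
            if positive:
                gap = (config.suvr_abnormal_mean_sd[0]
                       - config.suvr_nonspecific_mean_sd[0])
                p_abn0 = np.clip(config.prebaseline_years * np.maximum(rate, 0.0)
                                 / max(gap, 1e-6), 0.0, 0.9)
                abn = rng.random(n_parcels) < p_abn0
                abn[epis] = True
                # abnormal intensity grades with maturity: secondary regions
                # turned abnormal later and sit below the epicentre level
                maturity = np.ones(n_parcels)
                maturity[abn] = p_abn0[abn]
                maturity[epis] = 1.0
                shift = -(1.0 - maturity) * 0.4 * gap
                base[abn] = (rng.normal(*config.suvr_abnormal_mean_sd,
                                        size=int(abn.sum())) + shift[abn])
            base = np.maximum(base, 0.2)

            # visit schedule: jittered around an even grid over the follow-up
            n_vis = int(rng.integers(config.visit_count_range[0],
                                     config.visit_count_range[1] + 1))
            total = max(0.5, rng.normal(f_mean, f_sd))
            times = np.linspace(0.0, total, n_vis)
            spacing = total / (n_vis - 1)
            times[1:] += rng.uniform(-0.1, 0.1, n_vis - 1) * spacing
            times = np.maximum.accumulate(np.maximum(times, 0.0))

            suvr = (base[None, :] + np.outer(times, rate)
                    + rng.normal(0.0, noise["suvr"], (n_vis, n_parcels)))
            suvr = np.maximum(suvr, 0.05)
            for vi, t in enumerate(times):
                tau_rows.append(pd.DataFrame({
                    "id": pid, "time": t,
                    "parcel": np.arange(n_parcels), "suvr": suvr[vi],
                }))

            # amyloid-PET: tracer-specific cut-off, global + smooth deviation
            tracer = "florbetapir" if rng.random() < 0.5 else "florbetaben"
            cutoff = config.ab_cutoff_fap if tracer == "florbetapir" else config.ab_cutoff_fbb
            if positive:
                ab_global = cutoff + 0.02 + abs(rng.normal(0.20, 0.12))
            else:
                ab_global = max(0.8, cutoff - 0.02 - abs(rng.normal(0.12, 0.06)))
            net_offset = rng.normal(0.0, noise["ab_network"], int(blocks.max()) + 1)
            ab_regional = (ab_global + net_offset[blocks]
                           + rng.normal(0.0, noise["ab"], n_parcels))
            ab_regional = np.maximum(ab_regional, 0.2)
            centiloid = config.centiloid_slope * ab_global + config.centiloid_intercept
            ab_rows.append(pd.DataFrame({
                "id": pid, "parcel": np.arange(n_parcels),
                "suvr": ab_regional, "global_suvr": ab_global,
                "centiloid": centiloid,
            }))

            # MMSE: slope coupled to the global (parcel-mean) tau rate
            global_rate = float(rate.mean())
            mmse_slope = (config.mmse_coupling * global_rate
                          + rng.normal(0.0, noise["mmse_slope"]))
            mmse_true[pid] = mmse_slope
            mmse0 = rng.normal(*config.mmse_baseline_mean_sd)
            mmse_vals = np.clip(
                mmse0 + mmse_slope * times + rng.normal(0.0, noise["mmse"], n_vis),
                0.0, 30.0)
            mmse_rows.append(pd.DataFrame({"id": pid, "time": times, "mmse": mmse_vals}))

            part_rows.append(dict(
                id=pid, age=age, sex=sex, diagnosis=diagnosis,
                ab_status=ab_status, strem2=strem2, csf_ptau=ptau,
                apoe4=apoe4, education=edu, tracer=tracer,
                ab_global=ab_global, centiloid=centiloid,
            ))

    participants = pd.DataFrame(part_rows)
    tables = CohortTables(
        participants=participants,
        tau_scans=pd.concat(tau_rows, ignore_index=True) if tau_rows else
        pd.DataFrame(columns=["id", "time", "parcel", "suvr"]),
        ab_baseline=pd.concat(ab_rows, ignore_index=True) if ab_rows else
        pd.DataFrame(columns=["id", "parcel", "suvr", "global_suvr", "centiloid"]),
        mmse_visits=pd.concat(mmse_rows, ignore_index=True) if mmse_rows else
        pd.DataFrame(columns=["id", "time", "mmse"]),
    )
    truth = GroundTruth(
        epicentres=epicentres,
        true_slopes=pd.DataFrame.from_dict(slope_rows, orient="index",
                                           columns=np.arange(n_parcels)),
        gamma=gamma,
        mediation_coefficients={
            "mmse_coupling": config.mmse_coupling,
            "mmse_slope_noise_sd": noise["mmse_slope"],
        },
        true_mmse_slopes=pd.Series(mmse_true, name="true_mmse_slope"),
        strem2_z=pd.Series(strem2_z, name="strem2_z"),
        correlation=corr,
        distance=distance,
        networks=networks,
        vulnerable_parcels=vulnerable,
    )
    return tables, truth


def generate_template_timeseries(n_subjects: int, config: CohortConfig) -> TimeSeriesSet:
    """Parcel-wise time series for template subjects with motion traces.

    Signals follow the planted low-rank block correlation model; motion
    spikes (framewise displacement drawn from ``fd_spike_mm`` and floored at
    0.55 mm, above the default scrubbing threshold) are inserted at a
    ``spike_fraction`` of frames.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    if config.n_timepoints < 2:
        raise ValueError("fewer than 2 timepoints cannot support correlations")
    corr, lam, g, blocks, networks = planted_structure(config)
    uniq = np.sqrt(1.0 - lam**2 - g**2)
    rng = np.random.default_rng([int(config.seed), 303])
    T = config.n_timepoints
    n_blocks = int(blocks.max()) + 1
    subjects = []
    n_spike = int(round(config.spike_fraction * T))
    for _ in range(n_subjects):
        f_block = rng.normal(size=(n_blocks, T))
        f_global = rng.normal(size=T)
        eps = rng.normal(size=(config.n_parcels, T))
        signals = (lam[:, None] * f_block[blocks]
                   + g[:, None] * f_global[None, :]
                   + uniq[:, None] * eps)
        fd = np.abs(rng.normal(*config.fd_baseline_mm, size=T))
        if n_spike > 0:
            idx = rng.choice(T, size=n_spike, replace=False)
            fd[idx] = np.maximum(np.abs(rng.normal(*config.fd_spike_mm, size=n_spike)), 0.55)
        subjects.append(TemplateSubject(signals=signals, fd=fd))
    return TimeSeriesSet(subjects=subjects, correlation=corr, networks=networks)


# ---------------------------------------------------------------------------
# delimited-text I/O (parcels written 1-based, read back 0-based)
# ---------------------------------------------------------------------------

def _to_1based(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["parcel"] = out["parcel"].astype(int) + 1
    return out.rename(columns={"parcel": "parcel_1based"})


def _to_0based(df: pd.DataFrame) -> pd.DataFrame:
    out = df.rename(columns={"parcel_1based": "parcel"}).copy()
    out["parcel"] = out["parcel"].astype(int) - 1
    return out


def write_cohort(tables: CohortTables, outdir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables as CSV (UTF-8, header row, 17 sig. digits)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    spec = {
        "participants": tables.participants,
        "tau_scans": _to_1based(tables.tau_scans),
        "ab_baseline": _to_1based(tables.ab_baseline),
        "mmse_visits": tables.mmse_visits,
    }
    for name, df in spec.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths[name] = p
    return paths


def read_cohort(outdir: str | Path) -> CohortTables:
    """Read cohort tables previously written by :func:`write_cohort`."""
    outdir = Path(outdir)
    return CohortTables(
        participants=pd.read_csv(outdir / "participants.csv"),
        tau_scans=_to_0based(pd.read_csv(outdir / "tau_scans.csv")),
        ab_baseline=_to_0based(pd.read_csv(outdir / "ab_baseline.csv")),
        mmse_visits=pd.read_csv(outdir / "mmse_visits.csv"),
    )


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Persist the planted quantities as delimited text + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    slopes = truth.true_slopes.copy()
    slopes.columns = [c + 1 for c in slopes.columns]
    slopes.to_csv(outdir / "ground_truth_slopes.csv", float_format=_FLOAT_FMT,
                  index_label="id")
    epi_long = pd.DataFrame(
        [(pid, e + 1) for pid, epis in truth.epicentres.items() for e in epis],
        columns=["id", "parcel_1based"])
    epi_long.to_csv(outdir / "ground_truth_epicentres.csv", index=False)
    pd.DataFrame(truth.distance).to_csv(outdir / "ground_truth_distance.csv",
                                        index=False, float_format=_FLOAT_FMT)
    meta = {
        "gamma": truth.gamma,
        "mediation_coefficients": truth.mediation_coefficients,
        "vulnerable_parcels_1based": [v + 1 for v in truth.vulnerable_parcels],
        "networks": truth.networks,
    }
    with open(outdir / "ground_truth_meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
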