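"""Configuration objects for cohort simulation and pipeline runs.

All randomness in the package flows from the single ``seed`` carried by these
objects; every generated table can be reproduced byte-for-byte from the same
configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

#: Yeo-style network names used to label parcels of the synthetic atlas.
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic biomarker cohort.

    Defaults emulate an ADNI-like non-demented sample: four strata
    (CU/MCI x amyloid-negative/positive), 200 cortical parcels, 2-4 tau-PET
    visits over roughly 2-3 years, a two-component (non-specific vs abnormal)
    SUVR signal, epicentre-seeded connectivity-dependent accumulation that is
    attenuated by CSF sTREM2 in amyloid-positive subjects only, lognormal
    sTREM2 concentrations and MMSE decline coupled to global tau accumulation.

    Fields ending in ``_abpos`` override the base field for amyloid-positive
    participants; set them to ``None`` to apply the base value to everyone.
    """

    # cohort composition: (CU Ab-, CU Ab+, MCI Ab-, MCI Ab+)
    stratum_sizes: tuple[int, int, int, int] = (47, 27, 60, 44)
    n_parcels: int = 200
    n_networks: int = 7

    # visit schedule
    visit_count_range: tuple[int, int] = (2, 4)
    followup_years_mean_sd: tuple[float, float] = (3.0, 1.6)
    followup_years_mean_sd_abpos: Optional[tuple[float, float]] = (2.3, 1.2)

    # tau-PET signal components (SUVR)
    suvr_nonspecific_mean_sd: tuple[float, float] = (1.10, 0.10)
    suvr_abnormal_mean_sd: tuple[float, float] = (1.90, 0.25)

    # epicentre / spreading structure
    n_true_epicentres: int = 10
    n_vulnerable_parcels: int = 30
    vulnerable_weight: float = 0.8
    spread_rate_base: float = 0.05            # SUVR/year at distance 0 (Ab+)
    spread_distance_coefficient: float = -0.04  # SUVR/year per unit distance
    spread_rate_base_abneg: float = 0.010
    spread_distance_coefficient_abneg: float = -0.010
    #: years of pre-baseline accumulation reflected in amyloid-positive
    #: baseline scans, so baseline SUVR already carries the graded,
    #: distance-dependent elevation the epicentre scoring relies on
    prebaseline_years: float = 8.0

    # CSF sTREM2 (pg/ml), lognormal moment-matched
    strem2_lognormal_mean_sd: tuple[float, float] = (3697.6, 2039.5)
    strem2_lognormal_mean_sd_abpos: Optional[tuple[float, float]] = (3916.9, 2301.3)
    #: multiplier (1 - gamma * z) on the spreading rate per SD of log-sTREM2,
    #: active in amyloid-positive participants only; must lie in [0, 1).
    strem2_attenuation_gamma: float = 0.3

    # amyloid-PET
    ab_cutoff_fap: float = 1.11   # florbetapir positivity cut-off (SUVR)
    ab_cutoff_fbb: float = 1.08   # florbetaben positivity cut-off (SUVR)
    centiloid_slope: float = 100.0
    centiloid_intercept: float = -100.0

    # cognition
    mmse_coupling: float = -20.0  # MMSE points/year per SUVR/year global slope
    mmse_baseline_mean_sd: tuple[float, float] = (28.6, 1.3)

    # noise scales per signal
    noise_sds: dict = field(default_factory=lambda: {
        "suvr": 0.05,      # per-scan tau-PET measurement noise (SUVR)
        "ab": 0.04,        # per-parcel amyloid measurement noise (SUVR)
        "ab_network": 0.04,  # spatially smooth (per-network) amyloid deviation
        "slope": 0.005,    # subject x region slope jitter (SUVR/year)
        "mmse": 0.5,       # per-visit MMSE noise (points)
        "mmse_slope": 0.2,  # subject-level MMSE slope noise (points/year)
    })

    # planted functional-connectivity structure (shared with the template)
    within_block_r: float = 0.6
    between_block_r: float = 0.05
    covariance_heterogeneity: float = 0.1
    density: float = 0.30

    # template time-series generation
    n_timepoints: int = 300
    spike_fraction: float = 0.10
    fd_baseline_mm: tuple[float, float] = (0.15, 0.05)
    fd_spike_mm: tuple[float, float] = (0.8, 0.2)

    seed: int = 0

    def validate(self) -> None:
        if any(s < 0 for s in self.stratum_sizes):
            raise ValueError("stratum sizes must be non-negative")
        if sum(self.stratum_sizes) <= 0:
            raise ValueError("total cohort size must be positive")
        if not (0.0 <= self.strem2_attenuation_gamma < 1.0):
            raise ValueError(
                "strem2_attenuation_gamma must lie in [0, 1) so that "
                "accumulation rates stay positive in expectation"
            )
        if self.ab_cutoff_fap <= 0 or self.ab_cutoff_fbb <= 0:
            raise ValueError("amyloid positivity cut-offs must be positive")
        if self.n_true_epicentres >= self.n_parcels:
            raise ValueError("n_true_epicentres must be smaller than n_parcels")
        lo, hi = self.visit_count_range
        if not (2 <= lo <= hi):
            raise ValueError("visit counts must be at least 2 and ordered")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``cohort`` describes a synthetic cohort to simulate, or the four
    ``*_path`` fields point at existing delimited-text tables with the same
    columns the simulator writes.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    participants_path: Optional[str] = None
    tau_scans_path: Optional[str] = None
    ab_baseline_path: Optional[str] = None
    mmse_visits_path: Optional[str] = None
    timeseries_dir: Optional[str] = None

    n_template_subjects: int = 69
    exclusion_mask_path: Optional[str] = None
    k_epicentres: int = 10
    density: float = 0.30
    fd_threshold_mm: float = 0.5
    slope_method: str = "mixed"     # "mixed" with OLS fallback, or "ols"
    model_specs: Sequence[int] = (1, 2, 3, 4)
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "tauspread_out"

    def validate(self) -> None:
        self.cohort.validate()
        if self.slope_method not in ("mixed", "ols"):
            raise ValueError("slope_method must be 'mixed' or 'ols'")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        bad = [s for s in self.model_specs if s not in (1, 2, 3, 4)]
        if bad:
            raise ValueError(f"unknown model specs: {bad}")


def _tupleize(obj):
    if isinstance(obj, list):
        return tuple(_tupleize(v) for v in obj)
    return obj


def load_run_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {}) or {}
    cohort = CohortConfig(**{k: _tupleize(v) for k, v in cohort_raw.items()})
    cfg = RunConfig(cohort=cohort, **{k: _tupleize(v) for k, v in raw.items()})
    cfg.validate()
    return cfg


def dump_run_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a :class:`RunConfig` to YAML (round-trips via load_run_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
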