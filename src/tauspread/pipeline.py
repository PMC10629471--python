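"""End-to-end orchestration: simulate -> slopes -> epicentres -> template ->
spreading -> associations -> mediations.

Each stage reads and writes only delimited-text contracts inside the output
directory, so stages are independently runnable and testable.  A manifest
records a content hash for every file plus a per-stage configuration hash;
rerunning with an unchanged configuration reuses cached stage outputs.
Parcel indices are 0-based in memory and 1-based in every written table
(column names state which).
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import connectome, epicentres, mediation, stats, synthetic, trajectories
from .config import CohortConfig, RunConfig

_FLOAT_FMT = "%.17g"
VERSION = "0.1.0"

logger = logging.getLogger("tauspread")
if not logger.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[tauspread] %(message)s"))
    logger.addHandler(h)
    logger.setLevel(logging.INFO)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _wide_to_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    out.columns = [f"parcel_{int(c) + 1:03d}" for c in out.columns]
    out.to_csv(path, float_format=_FLOAT_FMT, index_label="id")


def _wide_from_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="id")
    df.columns = [int(c.split("_")[1]) - 1 for c in df.columns]
    return df


def _matrix_to_csv(mat: np.ndarray, path: Path) -> None:
    cols = [f"parcel_{i + 1:03d}" for i in range(mat.shape[1])]
    pd.DataFrame(mat, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _matrix_from_csv(path: Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def _covariates(participants: pd.DataFrame) -> pd.DataFrame:
    cov = pd.DataFrame(index=participants["id"])
    cov["age"] = participants.set_index("id")["age"]
    cov["sex_female"] = (participants.set_index("id")["sex"] == "F").astype(float)
    return cov


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offenders."""


class Pipeline:
    """Stage runner with manifest-based caching over an output directory."""

    STAGES = ("simulate", "slopes", "epicentres", "template", "spread",
              "associate", "mediate")

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        else:
            self.manifest = {"version": VERSION, "seed": config.seed, "stages": {}}

    # -- manifest helpers ---------------------------------------------------
    def _record(self, stage: str, shash: str, files: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "hash": shash,
            "files": {p.name: _sha256(p) for p in files},
        }
        self.manifest["version"] = VERSION
        self.manifest["seed"] = self.cfg.seed
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    def _cached(self, stage: str, shash: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or entry["hash"] != shash:
            return False
        return all((self.outdir / f).exists() for f in entry["files"])

    def _run_stage(self, stage: str, shash: str, fn) -> None:
        if self._cached(stage, shash):
            logger.info(f"stage '{stage}': cached, reusing outputs")
            return
        t0 = time.time()
        try:
            files = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        self._record(stage, shash, files)
        logger.info(f"stage '{stage}': done in {time.time() - t0:.1f}s")

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.cfg
        external = cfg.participants_path is not None
        shash = _stage_hash({"cohort": asdict(cfg.cohort), "external": external,
                             "paths": [cfg.participants_path, cfg.tau_scans_path,
                                       cfg.ab_baseline_path, cfg.mmse_visits_path]})

        def _run():
            if external:
                needed = {"participants": cfg.participants_path,
                          "tau_scans": cfg.tau_scans_path,
                          "ab_baseline": cfg.ab_baseline_path,
                          "mmse_visits": cfg.mmse_visits_path}
                missing = [k for k, v in needed.items() if v is None or not Path(v).exists()]
                if missing:
                    raise PipelineError(
                        f"stage 'simulate': input tables missing: {missing}; "
                        "provide all four *_path entries or a synthetic cohort block")
                files = []
                for name, src in needed.items():
                    df = pd.read_csv(src)
                    dst = self.outdir / f"{name}.csv"
                    df.to_csv(dst, index=False, float_format=_FLOAT_FMT)
                    files.append(dst)
                return files
            tables, truth = synthetic.generate_cohort(cfg.cohort)
            paths = synthetic.write_cohort(tables, self.outdir)
            synthetic.write_ground_truth(truth, self.outdir)
            gt = [self.outdir / n for n in (
                "ground_truth_slopes.csv", "ground_truth_epicentres.csv",
                "ground_truth_distance.csv", "ground_truth_meta.json")]
            return list(paths.values()) + gt

        self._run_stage("simulate", shash, _run)

    def slopes(self) -> None:
        cfg = self.cfg
        shash = _stage_hash({"method": cfg.slope_method,
                             "up": self.manifest["stages"].get("simulate", {}).get("files")})

        def _run():
            tau = synthetic._to_0based(pd.read_csv(self.outdir / "tau_scans.csv"))
            sm = trajectories.fit_slope_matrix(tau, method=cfg.slope_method)
            _wide_to_csv(sm.values, self.outdir / "slopes.csv")
            diag = sm.diagnostics.copy()
            diag["method"] = sm.method
            diag.index = [i + 1 for i in diag.index]
            diag.to_csv(self.outdir / "slope_diagnostics.csv",
                        index_label="parcel_1based", float_format=_FLOAT_FMT)
            mmse = pd.read_csv(self.outdir / "mmse_visits.csv")
            cs = trajectories.fit_cognitive_slope(mmse, method=cfg.slope_method)
            pd.DataFrame({"mmse_slope": cs.values, "n_visits": cs.n_visits}) \
                .to_csv(self.outdir / "mmse_slopes.csv", index_label="id",
                        float_format=_FLOAT_FMT)
            return [self.outdir / "slopes.csv", self.outdir / "slope_diagnostics.csv",
                    self.outdir / "mmse_slopes.csv"]

        self._run_stage("slopes", shash, _run)

    def epicentres(self) -> None:
        cfg = self.cfg
        shash = _stage_hash({"k": cfg.k_epicentres, "mask": cfg.exclusion_mask_path,
                             "up": self.manifest["stages"].get("simulate", {}).get("files")})

        def _run():
            tau = synthetic._to_0based(pd.read_csv(self.outdir / "tau_scans.csv"))
            baseline = epicentres.baseline_suvr_table(tau)
            mask: list[int] = []
            if cfg.exclusion_mask_path:
                mask = [int(l) - 1 for l in
                        Path(cfg.exclusion_mask_path).read_text().split() if l.strip()]
            else:
                meta = self.outdir / "ground_truth_meta.json"
                if meta.exists():
                    networks = json.load(open(meta))["networks"]
                    mask = epicentres.default_exclusion_mask(baseline, networks)
            gmms = epicentres.fit_region_gmms(baseline, exclusion_mask=mask,
                                              seed=cfg.seed)
            scores = epicentres.epicentre_scores(baseline, gmms, exclusion_mask=mask)
            sets = epicentres.select_epicentres(scores, k=cfg.k_epicentres)
            tab = epicentres.gmm_table(gmms)
            tab["parcel"] = tab["parcel"] + 1
            tab.rename(columns={"parcel": "parcel_1based"}).to_csv(
                self.outdir / "gmm_params.csv", index=False, float_format=_FLOAT_FMT)
            _wide_to_csv(scores.replace(-np.inf, np.nan),
                         self.outdir / "epicentre_scores.csv")
            epi_long = pd.DataFrame(
                [(pid, rank + 1, e + 1) for pid, epis in sets.items()
                 for rank, e in enumerate(epis)],
                columns=["id", "rank", "parcel_1based"])
            epi_long.to_csv(self.outdir / "epicentres.csv", index=False)
            pd.Series([m + 1 for m in mask], name="parcel_1based", dtype=int).to_csv(
                self.outdir / "exclusion_mask.csv", index=False)
            return [self.outdir / n for n in (
                "gmm_params.csv", "epicentre_scores.csv", "epicentres.csv",
                "exclusion_mask.csv")]

        self._run_stage("epicentres", shash, _run)

    def template(self) -> None:
        cfg = self.cfg
        synthetic_ts = cfg.participants_path is None
        shash = _stage_hash({"n": cfg.n_template_subjects, "density": cfg.density,
                             "fd": cfg.fd_threshold_mm, "dir": cfg.timeseries_dir,
                             "cohort": asdict(cfg.cohort) if synthetic_ts else None})

        def _run():
            if cfg.timeseries_dir:
                ts = read_timeseries(cfg.timeseries_dir)
            elif synthetic_ts:
                ts = synthetic.generate_template_timeseries(
                    cfg.n_template_subjects, cfg.cohort)
            else:
                raise PipelineError(
                    "stage 'template': no template time series available; "
                    "provide timeseries_dir or use a synthetic cohort block")
            fcs = [connectome.scrub_and_fc(s.signals, s.fd,
                                           fd_threshold=cfg.fd_threshold_mm)
                   for s in ts.subjects]
            tpl = connectome.build_template(fcs, density=cfg.density)
            _matrix_to_csv(tpl.mean_z, self.outdir / "template_z.csv")
            _matrix_to_csv(tpl.distance, self.outdir / "template_distance.csv")
            pd.DataFrame({
                "subject": np.arange(len(fcs)),
                "censored_fraction": [fc.censored_fraction for fc in fcs],
                "retained": [fc.retained for fc in fcs],
            }).to_csv(self.outdir / "template_retention.csv", index=False,
                      float_format=_FLOAT_FMT)
            with open(self.outdir / "template_meta.json", "w") as fh:
                json.dump({"density": tpl.density, "n_subjects": tpl.n_subjects},
                          fh, indent=2)
            return [self.outdir / n for n in (
                "template_z.csv", "template_distance.csv",
                "template_retention.csv", "template_meta.json")]

        self._run_stage("template", shash, _run)

    def spread(self) -> None:
        cfg = self.cfg
        shash = _stage_hash({
            "k": cfg.k_epicentres,
            "up": [self.manifest["stages"].get(s, {}).get("files")
                   for s in ("slopes", "epicentres", "template")]})

        def _run():
            slopes = _wide_from_csv(self.outdir / "slopes.csv")
            dist = _matrix_from_csv(self.outdir / "template_distance.csv")
            tpl = connectome.ConnectivityTemplate(
                mean_z=_matrix_from_csv(self.outdir / "template_z.csv"),
                mask=dist < 1.0, distance=dist, density=cfg.density)
            epi_long = pd.read_csv(self.outdir / "epicentres.csv")
            sets = {pid: tuple(grp["parcel_1based"].to_numpy() - 1)
                    for pid, grp in epi_long.groupby("id", sort=True)}
            spread = connectome.participant_spreading(slopes, tpl, sets)
            spread.to_csv(self.outdir / "spreading.csv", float_format=_FLOAT_FMT)
            scores = _wide_from_csv(self.outdir / "epicentre_scores.csv")
            participants = pd.read_csv(self.outdir / "participants.csv")
            rows = []
            for label, ids in _analysis_groups(participants).items():
                stat, scatter = connectome.group_level_spread(
                    slopes.loc[ids], tpl, scores.loc[ids], k=cfg.k_epicentres)
                rows.append({"group": label, "beta": stat.beta,
                             "p_value": stat.p_value, "n_regions": stat.n_regions})
                scatter["parcel"] = scatter["parcel"] + 1
                scatter.rename(columns={"parcel": "parcel_1based"}).to_csv(
                    self.outdir / f"group_spread_scatter_{label}.csv",
                    index=False, float_format=_FLOAT_FMT)
            pd.DataFrame(rows).to_csv(self.outdir / "group_spread.csv",
                                      index=False, float_format=_FLOAT_FMT)
            return [self.outdir / "spreading.csv", self.outdir / "group_spread.csv"] + \
                [self.outdir / f"group_spread_scatter_{g}.csv"
                 for g in _analysis_groups(participants)]

        self._run_stage("spread", shash, _run)

    def associate(self) -> None:
        cfg = self.cfg
        shash = _stage_hash({
            "specs": list(cfg.model_specs),
            "up": [self.manifest["stages"].get(s, {}).get("files")
                   for s in ("slopes", "spread")]})

        def _run():
            participants = pd.read_csv(self.outdir / "participants.csv")
            slopes = _wide_from_csv(self.outdir / "slopes.csv")
            tau = synthetic._to_0based(pd.read_csv(self.outdir / "tau_scans.csv"))
            baseline_tau = epicentres.baseline_suvr_table(tau)
            ab = synthetic._to_0based(pd.read_csv(self.outdir / "ab_baseline.csv"))
            ab_wide = ab.pivot_table(index="id", columns="parcel", values="suvr")
            spread = pd.read_csv(self.outdir / "spreading.csv", index_col="id")
            pinfo = participants.set_index("id")
            cov = _covariates(participants)

            groups = _analysis_groups(participants)
            pd.DataFrame([{"group": g, "n": len(ids)} for g, ids in groups.items()]) \
                .to_csv(self.outdir / "groups.csv", index=False)

            ids = groups["abpos"]
            strem2_raw = pinfo.loc[ids, "strem2"]
            strem2_vals, logged = stats.normality_gate(strem2_raw)
            strem2 = pd.Series(strem2_vals, index=ids)

            model_frames = []
            for spec in cfg.model_specs:
                model_frames.append(stats.regionwise_models(
                    slopes.loc[ids], ab_wide, strem2, baseline_tau,
                    cov.loc[ids], spec=spec))
            models = pd.concat(model_frames, ignore_index=True)
            models["parcel"] = models["parcel"] + 1
            models.rename(columns={"parcel": "parcel_1based"}).to_csv(
                self.outdir / "regionwise_models.csv", index=False,
                float_format=_FLOAT_FMT)

            vif = stats.collinearity_check(pd.DataFrame({
                "global_ab": pinfo.loc[ids, "ab_global"].to_numpy(),
                "log_strem2" if logged else "strem2": strem2.to_numpy()}))
            vif.to_csv(self.outdir / "vif.csv", index=False, float_format=_FLOAT_FMT)

            rows = []
            for label, g_ids in groups.items():
                cv = cov.loc[g_ids].copy()
                cv["global_ab"] = pinfo.loc[g_ids, "ab_global"]
                assoc = stats.beta_strem2_association(
                    spread.loc[g_ids, "beta"], pinfo.loc[g_ids, "strem2"], cv)
                rows.append({"group": label, "adjustment": "none",
                             "coefficient": assoc.coefficient,
                             "p_value": assoc.p_value, "n": assoc.n})
                extra = baseline_tau.loc[g_ids].mean(axis=1).rename("baseline_tau_global")
                assoc_bt = stats.beta_strem2_association(
                    spread.loc[g_ids, "beta"], pinfo.loc[g_ids, "strem2"], cv,
                    extra_adjust=extra.to_frame())
                rows.append({"group": label, "adjustment": "baseline_tau",
                             "coefficient": assoc_bt.coefficient,
                             "p_value": assoc_bt.p_value, "n": assoc_bt.n})
            pd.DataFrame(rows).to_csv(self.outdir / "strem2_beta_association.csv",
                                      index=False, float_format=_FLOAT_FMT)

            power_rows = [{"group": g, "n": len(g_ids),
                           "power": stats.power_check(len(g_ids)),
                           "passes_80pct_gate": stats.power_check(len(g_ids)) > 0.8}
                          for g, g_ids in groups.items()]
            power_rows.append({"group": "all", "n": len(participants),
                               "power": stats.power_check(len(participants)),
                               "passes_80pct_gate":
                               stats.power_check(len(participants)) > 0.8})
            pd.DataFrame(power_rows).to_csv(self.outdir / "power.csv", index=False,
                                            float_format=_FLOAT_FMT)
            return [self.outdir / n for n in (
                "groups.csv", "regionwise_models.csv", "vif.csv",
                "strem2_beta_association.csv", "power.csv")]

        self._run_stage("associate", shash, _run)

    def mediate(self) -> None:
        cfg = self.cfg
        shash = _stage_hash({
            "n_boot": cfg.n_boot, "seed": cfg.seed,
            "up": [self.manifest["stages"].get(s, {}).get("files")
                   for s in ("slopes", "spread")]})

        def _run():
            participants = pd.read_csv(self.outdir / "participants.csv")
            pinfo = participants.set_index("id")
            slopes = _wide_from_csv(self.outdir / "slopes.csv")
            spread = pd.read_csv(self.outdir / "spreading.csv", index_col="id")
            mmse = pd.read_csv(self.outdir / "mmse_slopes.csv", index_col="id")
            ab = synthetic._to_0based(pd.read_csv(self.outdir / "ab_baseline.csv"))
            ab_wide = ab.pivot_table(index="id", columns="parcel", values="suvr")
            cov = _covariates(participants)
            ids = _analysis_groups(participants)["abpos"]

            log_strem2 = pd.Series(np.log(pinfo.loc[ids, "strem2"].to_numpy()),
                                   index=ids)
            region_med = mediation.regionwise_mediation(
                ab_wide.loc[ids], log_strem2, slopes.loc[ids],
                covariates=cov.loc[ids], n_boot=cfg.n_boot, seed=cfg.seed)
            region_med["parcel"] = region_med["parcel"] + 1
            region_med.rename(columns={"parcel": "parcel_1based"}).to_csv(
                self.outdir / "mediation_regionwise.csv", index=False,
                float_format=_FLOAT_FMT)

            gslope = trajectories.global_slope(slopes.loc[ids])
            rows = []
            mediators = {
                "spreading_beta": spread.loc[ids, "beta"],
                "global_tau_slope": gslope,
            }
            for name, med in mediators.items():
                res = mediation.cognition_mediation(
                    pinfo.loc[ids, "strem2"], med, mmse.loc[ids, "mmse_slope"],
                    covariates=cov.loc[ids], n_boot=cfg.n_boot, seed=cfg.seed)
                rows.append(mediation.result_row(res, mediator=name,
                                                 adjustment="none"))
            res_pt = mediation.cognition_mediation(
                pinfo.loc[ids, "strem2"], mediators["spreading_beta"],
                mmse.loc[ids, "mmse_slope"], covariates=cov.loc[ids],
                extra_covariate=pinfo.loc[ids, "csf_ptau"],
                n_boot=cfg.n_boot, seed=cfg.seed)
            rows.append(mediation.result_row(res_pt, mediator="spreading_beta",
                                             adjustment="csf_ptau"))
            pd.DataFrame(rows).to_csv(self.outdir / "mediation_cognition.csv",
                                      index=False, float_format=_FLOAT_FMT)
            return [self.outdir / "mediation_regionwise.csv",
                    self.outdir / "mediation_cognition.csv"]

        self._run_stage("mediate", shash, _run)

    def run_all(self) -> dict:
        for stage in self.STAGES:
            getattr(self, stage)()
        return self.manifest


def _analysis_groups(participants: pd.DataFrame) -> dict[str, list]:
    """Analysis groups: amyloid-positive CU+MCI combined, and the negatives."""
    pos = participants.loc[participants["ab_status"] == "pos", "id"].tolist()
    neg = participants.loc[participants["ab_status"] == "neg", "id"].tolist()
    groups = {}
    if pos:
        groups["abpos"] = pos
    if neg:
        groups["abneg"] = neg
    return groups


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the output manifest."""
    return Pipeline(config).run_all()


# -- time-series I/O --------------------------------------------------------

def write_timeseries(ts: synthetic.TimeSeriesSet, outdir: str | Path) -> None:
    """Per-subject signals (parcels x timepoints) and motion traces as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sub in enumerate(ts.subjects):
        pd.DataFrame(sub.signals).to_csv(outdir / f"sub-{i:03d}_timeseries.csv",
                                         index=False, float_format=_FLOAT_FMT)
        pd.DataFrame({"fd_mm": sub.fd}).to_csv(outdir / f"sub-{i:03d}_fd.csv",
                                               index=False, float_format=_FLOAT_FMT)


def read_timeseries(indir: str | Path) -> synthetic.TimeSeriesSet:
    indir = Path(indir)
    subjects = []
    for ts_path in sorted(indir.glob("sub-*_timeseries.csv")):
        fd_path = indir / ts_path.name.replace("_timeseries", "_fd")
        signals = pd.read_csv(ts_path).to_numpy(dtype=float)
        fd = pd.read_csv(fd_path)["fd_mm"].to_numpy(dtype=float)
        subjects.append(synthetic.TemplateSubject(signals=signals, fd=fd))
    if not subjects:
        raise FileNotFoundError(f"no sub-*_timeseries.csv files under {indir}")
    return synthetic.TimeSeriesSet(subjects=subjects, correlation=np.array([]),
                                   networks=[])
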