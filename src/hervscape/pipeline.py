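"""End-to-end orchestration: simulate -> quantify -> deconvolve -> score.

``run_pipeline`` drives the stages in a fixed order over a bundle
directory (as written by :func:`hervscape.synthetic.write_bundle` or
assembled from real inputs in the same formats), writes one output file
per stage plus an aggregated ``report.json``, and is byte-reproducible
given the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hervscape import friction, genomics, herv, io, msi, survival

log = logging.getLogger("hervscape.pipeline")

ALL_STAGES = ("herv", "deconv", "msi", "genomics", "survival")


@dataclass
class RunConfig:
    """All paths and constants of one pipeline run.

    Defaults reproduce the published analysis constants: 0.5 CPM noise
    floor, 0.1 median-CPM expression filter, top-30% dichotomisation, MSI
    thresholds 0.30 (paired WES) / 0.20 (baseline panel), 20% arm-event
    rule, and the nu-SVR grid {0.25, 0.5, 0.75}.
    """

    input_dir: str = "."
    out_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # hERV stage
    noise_floor: float = 0.5
    median_floor: float = 0.1
    top_fraction: float = 0.30
    # deconvolution stage
    fold_min: float = 5.0
    expr_min: float = 50.0
    max_genes_per_type: int = 50
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    # MSI stage
    msi_mode: str = "paired_wes"
    msi_threshold: float | None = None
    msi_min_reads: int = 20
    msi_k_sd: float = 3.0
    # genomics stage
    exonic_mb: float = 30.0
    arm_event_fraction: float = 0.20
    lynch_vaf_window: tuple[float, float] = (0.3, 0.7)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "nu_grid", "lynch_vaf_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("stages", "nu_grid", "lynch_vaf_window"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in fixed order and aggregate a report."""
    inp = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": 1, "seed": config.seed,
                    "parameters": dataclasses.asdict(config),
                    "stages": {}, "outputs": {}}
    report["parameters"]["stages"] = list(config.stages)
    report["parameters"]["nu_grid"] = list(config.nu_grid)
    report["parameters"]["lynch_vaf_window"] = list(config.lynch_vaf_window)

    herv_scores: pd.DataFrame | None = None
    fractions: pd.DataFrame | None = None
    msi_results: pd.DataFrame | None = None
    features: pd.DataFrame | None = None

    def _record(stage: str, path: Path, info: dict) -> None:
        info["output"] = str(path)
        info["sha256"] = _digest(path)
        report["stages"][stage] = info
        report["outputs"][path.name] = info["sha256"]
        log.info("stage %s -> %s (%s)", stage, path, info["sha256"])

    if "herv" in config.stages:
        try:
            counts = io.read_counts(inp / "counts.tsv")
            libs = io.read_library_sizes(inp / "library_sizes.tsv")
            panel_ids = io.read_panel(inp / "herv_panel.txt")
            matrix = herv.compute_cpm(counts, libs)
            floored = herv.apply_noise_floor(matrix, config.noise_floor)
            panel = herv.filter_expressed(floored, panel_ids,
                                          config.median_floor)
            score = herv.median_herv(floored, panel)
            cluster = herv.cluster_two(floored, panel)
            high = herv.dichotomize_top_fraction(score,
                                                 config.top_fraction)
            herv_scores = pd.DataFrame({
                "median_herv": score,
                "herv_label": np.where(high, "high", "low"),
                "cluster_label": cluster})
            herv_scores.index.name = "sample_id"
            path = out / "herv_scores.csv"
            herv_scores.to_csv(path, float_format="%.6g")
            _record("herv", path, {
                "n_reference": panel.n_reference,
                "n_retained": panel.n_retained})
        except Exception as exc:  # noqa: BLE001
            raise StageError("herv", exc) from exc

    if "deconv" in config.stages:
        try:
            purified = io.read_profiles(inp / "purified.tsv")
            background = io.read_profiles(inp / "background.tsv")
            counts = io.read_counts(inp / "counts.tsv")
            libs = io.read_library_sizes(inp / "library_sizes.tsv")
            matrix = herv.compute_cpm(counts, libs)
            gene_sets = friction.select_signature_genes(
                purified, background, fold_min=config.fold_min,
                expr_min=config.expr_min,
                max_genes_per_type=config.max_genes_per_type)
            signatures = friction.normalize_signatures(purified, gene_sets)
            shared = matrix.values.index.intersection(purified.index)
            mixtures = matrix.values.loc[shared]
            fractions = friction.deconvolve_matrix(
                mixtures, signatures, nu_grid=config.nu_grid)
            path = out / "fractions.csv"
            fractions.to_csv(path, float_format="%.6g")
            sig_path = out / "signatures.tsv"
            signatures.signature.to_csv(sig_path, sep="\t",
                                        float_format="%.6g")
            _record("deconv", path, {
                "n_signature_genes": len(signatures.gene_ids),
                "cell_types": signatures.cell_types})
        except Exception as exc:  # noqa: BLE001
            raise StageError("deconv", exc) from exc

    if "msi" in config.stages:
        try:
            sites = io.read_msi_sites(inp / "msi_sites.bed")
            hist = io.read_msi_histograms(inp / "msi_hist.tsv")
            catalog = msi.filter_site_catalog(sites)
            sample_names = set(hist["sample_id"])
            tumors = sorted(s for s in sample_names
                            if not s.endswith(".N")
                            and not s.startswith("BASE"))
            baselines = sorted(s for s in sample_names
                               if s.startswith("BASE"))
            rows = []
            for s in tumors:
                res = msi.score_sample(
                    catalog, hist, s, pipeline_mode=config.msi_mode,
                    baseline_samples=baselines,
                    min_reads=config.msi_min_reads, k_sd=config.msi_k_sd,
                    threshold=config.msi_threshold)
                rows.append(dataclasses.asdict(res))
            msi_results = pd.DataFrame(rows).set_index("sample_id")
            path = out / "msi_results.csv"
            msi_results.to_csv(path, float_format="%.6g")
            _record("msi", path, {"n_sites": len(catalog),
                                  "mode": config.msi_mode})
        except Exception as exc:  # noqa: BLE001
            raise StageError("msi", exc) from exc

    if "genomics" in config.stages:
        try:
            variants = io.read_variants_vcf(inp / "variants.vcf")
            cn_calls, gene_arms = io.read_cn_calls(inp / "cn_calls.tsv")
            features = genomics.extract_features(
                variants, cn_calls, gene_arms, exonic_mb=config.exonic_mb,
                event_fraction=config.arm_event_fraction,
                vaf_window=config.lynch_vaf_window)
            path = out / "features.csv"
            features.to_csv(path, float_format="%.6g")
            _record("genomics", path,
                    {"n_variants": int(len(variants))})
        except Exception as exc:  # noqa: BLE001
            raise StageError("genomics", exc) from exc

    if "survival" in config.stages:
        try:
            clinical = io.read_clinical(inp / "clinical.csv")
            times = survival.compute_survival_times(clinical)
            if herv_scores is None:
                raise ValueError("survival stage requires the herv stage")
            score = herv_scores["median_herv"].reindex(clinical.index)
            if fractions is not None:
                cd8 = fractions["CD8"].reindex(clinical.index)
            else:
                warnings.warn("deconvolution disabled: survival strata "
                              "fall back to hERV-only grouping",
                              stacklevel=2)
                cd8 = None
            if cd8 is not None:
                groups = survival.assign_wts_group(
                    cd8, score, fraction=config.top_fraction)
                strata = groups["wts_group"]
                strata_name = "wts"
            else:
                high = herv.dichotomize_top_fraction(
                    score, config.top_fraction)
                strata = pd.Series(np.where(high, "hERV+", "hERV-"),
                                   index=clinical.index)
                strata_name = "herv_only"
                groups = pd.DataFrame({"herv_high": high,
                                       "wts_group": pd.NA},
                                      index=clinical.index)
            cp = survival.assign_cp_group(clinical["age"],
                                          clinical["stage"],
                                          clinical["sidedness"],
                                          fraction=config.top_fraction)
            surv_report: dict = {"strata": strata_name, "endpoints": {}}
            for endpoint in ("os", "rfs"):
                t = times[f"{endpoint}_months"]
                e = times[f"{endpoint}_event"]
                entry: dict = {}
                for name, labels in [(strata_name, strata),
                                     ("cp", cp.dropna())]:
                    idx = labels.index
                    if labels.nunique() < 2:
                        entry[name] = {"note": "single group; no test"}
                        continue
                    fit = survival.km_logrank(t.loc[idx], e.loc[idx],
                                              labels)
                    entry[name] = {
                        "groups": [dataclasses.asdict(g)
                                   for g in fit.groups],
                        "logrank_stat": fit.logrank_stat,
                        "logrank_p": fit.logrank_p}
                cov = pd.DataFrame({
                    "age": clinical["age"].astype(float),
                    "stage_iii": (clinical["stage"] == "III").astype(int),
                    "right_sided": (clinical["sidedness"] == "right")
                    .astype(int),
                    "adjuvant": clinical["adjuvant"].astype(int),
                    "median_herv": score.astype(float),
                })
                if cd8 is not None:
                    cov["cd8_fraction"] = cd8.astype(float)
                if msi_results is not None:
                    cov["msi_h"] = (msi_results["classification"]
                                    .reindex(clinical.index) == "MSI-H") \
                        .astype(int)
                cov = cov.loc[:, cov.nunique() > 1]
                cox = survival.cox_fit(t, e, cov, mode="multivariate")
                entry["cox_multivariate"] = {
                    "converged": cox.converged,
                    "hazard_ratios": cox.hazard_ratios.round(6)
                    .to_dict(orient="index")}
                surv_report["endpoints"][endpoint] = entry
            path = out / "survival_report.json"
            path.write_text(json.dumps(surv_report, indent=2,
                                       default=float, sort_keys=True))
            _record("survival", path, {"n_patients": int(len(clinical))})
            # per-patient label table
            labels_out = pd.DataFrame({
                "os_months": times["os_months"].round(3),
                "os_event": times["os_event"],
                "rfs_months": times["rfs_months"].round(3),
                "rfs_event": times["rfs_event"],
                "strata": strata,
                "cp_group": cp})
            labels_out.index.name = "patient_id"
            labels_out.to_csv(out / "cohort_labels.csv")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("survival", exc) from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=float))
    return report
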