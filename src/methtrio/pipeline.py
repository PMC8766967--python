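"""End-to-end orchestration: simulate/load → QC → deconvolve → discordance →
DMP (before/after discordant-probe removal) → characterization → report.

Every stage output is a pure function of (inputs, config, seed); the JSON
report contains no timestamps or hardware-dependent values, so the same
configuration and seed reproduce it byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import characterize, discordance, dmp, qc
from .deconvolution import MixtureModel
from .errors import ConfigError, MethtrioError
from .io import (
    align,
    read_beta_matrix,
    read_probe_annotation,
    read_trio_design,
    write_beta_matrix,
    write_probe_annotation,
    write_trio_design,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds plus either input paths or simulation settings."""

    alpha: float = 0.05
    delta_beta_threshold: float = 0.1
    peak_threshold: float = -0.6
    q_threshold: float = 0.05
    qc_p_threshold: float = 0.01
    qc_fail_fraction: float = 0.05
    seed: int = 0
    output_dir: str | None = None
    # input paths (all three required together) ...
    beta_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    detection_path: str | None = None
    # ... or simulation settings
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "q_threshold", "qc_p_threshold", "qc_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} outside (0, 1)")
        if not 0.0 < self.delta_beta_threshold < 1.0:
            raise ConfigError("delta_beta_threshold outside (0, 1)")
        have_paths = self.beta_path is not None and self.design_path is not None
        if not have_paths and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if have_paths and self.simulation is not None:
            raise ConfigError("give input paths or simulation settings, not both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("delta_range", "lymph_weight_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        try:
            return cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        return cohort.beta, cohort.design, cohort.annotation, cohort
    beta = read_beta_matrix(config.beta_path, detection_path=config.detection_path)
    design = read_trio_design(config.design_path)
    annotation = (
        read_probe_annotation(config.annotation_path)
        if config.annotation_path
        else None
    )
    return beta, design, annotation, None


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute all stages; returns the consolidated report dictionary.

    A stage failure marks the report and skips downstream stages; the CLI
    converts that into a nonzero exit.
    """
    outdir = Path(output_dir or config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        "alpha": config.alpha,
        "delta_beta_threshold": config.delta_beta_threshold,
        "peak_threshold": config.peak_threshold,
        "q_threshold": config.q_threshold,
        "seed": config.seed,
        "simulated": config.simulation is not None,
    }, "stages": {}}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
                report["stages"][name] = "ok"
                logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
                return out
            except MethtrioError as exc:
                report["stages"][name] = f"failed: {exc}"
                logger.error("stage %s failed: %s", name, exc)
                raise
        return wrap

    try:
        beta, design, annotation, cohort = stage("load")(lambda: _load_inputs(config))
        if cohort is not None:
            write_beta_matrix(beta, outdir / "beta_matrix.tsv.gz")
            write_trio_design(design, outdir / "trio_design.csv")
            write_probe_annotation(annotation, outdir / "probe_annotation.tsv")

        n_input = beta.n_probes

        def qc_stage():
            filtered, rep = qc.filter_by_call_rate(
                beta, config.qc_p_threshold, config.qc_fail_fraction
            )
            return filtered, rep

        beta_qc, qc_report = stage("qc")(qc_stage)
        report["qc"] = qc_report.to_dict()
        beta_qc, design, annotation = align(beta_qc, design, annotation)

        results = stage("deconvolution")(lambda: MixtureModel(beta_qc, design).fit())
        weights = results.weights
        report["mixture"] = {
            "weights": weights.round(6).to_dict(orient="index"),
            "min_coefficient_sum": float(weights["coefficient_sum"].min()),
            "max_coefficient_sum": float(weights["coefficient_sum"].max()),
            "n_failed": len(results.failures),
        }
        weights.to_csv(outdir / "mixture_fits.csv", float_format="%.6f")

        def discordance_stage():
            residuals = results.residuals()
            part = discordance.standardize_and_flag(
                residuals, alpha=config.alpha, peak_threshold=config.peak_threshold
            )
            return residuals, part

        residuals, partition = stage("discordance")(discordance_stage)
        report["discordance"] = partition.counts()
        report["residual_histogram"] = discordance.residual_histogram(residuals)
        _write_partition(partition, residuals, outdir / "partition.tsv")

        def dmp_stage():
            return dmp.rerun_without_discordant(
                beta_qc, design, partition,
                delta_beta_threshold=config.delta_beta_threshold,
                q_threshold=config.q_threshold,
            )

        dmp_out = stage("dmp")(dmp_stage)
        report["dmp"] = {
            "original": dmp_out["original"].counts().to_dict(orient="index"),
            "filtered": dmp_out["filtered"].counts().to_dict(orient="index"),
            "relative_change": dmp_out["relative_change"],
        }

        if annotation is not None:
            def characterize_stage():
                all_probes = beta_qc.probe_ids
                enrich = {
                    "discordant": characterize.region_proportion_tests(
                        partition.discordant_probes, all_probes, annotation
                    ) if len(partition.discordant_probes) else None,
                    "peak": characterize.region_proportion_tests(
                        partition.peak_probes, all_probes, annotation
                    ) if len(partition.peak_probes) else None,
                }
                uniq = None
                if "unique_mapping" in annotation.columns and len(partition.discordant_probes):
                    uniq = characterize.uniqueness_report(
                        {
                            "discordant": partition.discordant_probes,
                            "concordant": partition.concordant_probes,
                        },
                        annotation,
                    )
                gc = None
                if len(partition.discordant_probes) and len(partition.concordant_probes):
                    gc = characterize.gc_comparison(
                        partition.discordant_probes, partition.concordant_probes,
                        annotation,
                    )
                return enrich, uniq, gc

            enrich, uniq, gc = stage("characterization")(characterize_stage)
            report["enrichment"] = {
                name: (res.table.round(6).to_dict(orient="index") if res else None)
                for name, res in enrich.items()
            }
            if uniq is not None:
                report["uniqueness"] = uniq.to_dict(orient="index")
            if gc is not None:
                report["gc_comparison"] = gc
            if enrich["discordant"] is not None:
                enrich["discordant"].table.to_csv(
                    outdir / "region_enrichment.tsv", sep="\t", float_format="%.6g"
                )

        report["counts"] = {
            "n_probes_input": int(n_input),
            "n_probes_failed_qc": int(n_input - beta_qc.n_probes),
            "n_probes_analyzed": int(beta_qc.n_probes),
            "n_discordant_probes": int(len(partition.discordant_probes)),
            "n_concordant_probes": int(len(partition.concordant_probes)),
        }
        c = report["counts"]
        assert c["n_probes_input"] == (
            c["n_probes_failed_qc"] + c["n_discordant_probes"] + c["n_concordant_probes"]
        )
    finally:
        _write_report(report, outdir)
    return report


def _write_partition(partition, residuals, path: Path) -> None:
    min_res = residuals.residuals.min(axis=1)
    n_disc_trios = pd.Series(0, index=residuals.probe_ids)
    for probe, _ in partition.discordant_trios:
        n_disc_trios[probe] += 1
    status = pd.Series("concordant", index=residuals.probe_ids)
    status[status.index.isin(partition.discordant_probes)] = "discordant"
    pd.DataFrame(
        {
            "status": status,
            "min_residual": min_res,
            "n_discordant_trios": n_disc_trios,
            "peak": status.index.isin(partition.peak_probes),
        }
    ).to_csv(path, sep="\t", float_format="%.6f", index_label="probe_id")


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonify, sort_keys=True)
    with open(outdir / "report.md", "w") as fh:
        fh.write(_markdown_report(report))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _markdown_report(report: dict) -> str:
    lines = ["# methtrio pipeline report", ""]
    lines.append("## Stages")
    for name, status in report.get("stages", {}).items():
        lines.append(f"- {name}: {status}")
    if "counts" in report:
        lines += ["", "## Probe accounting"]
        for k, v in report["counts"].items():
            lines.append(f"- {k}: {v}")
    if "mixture" in report:
        lines += ["", "## Mixture fits",
                  f"- min coefficient sum: {report['mixture']['min_coefficient_sum']:.4f}",
                  f"- max coefficient sum: {report['mixture']['max_coefficient_sum']:.4f}"]
    if "discordance" in report:
        lines += ["", "## Discordance"]
        for k, v in report["discordance"].items():
            lines.append(f"- {k}: {v}")
    if "dmp" in report:
        lines += ["", "## Differential methylation (counts)"]
        for block in ("original", "filtered"):
            lines.append(f"### {block}")
            for label, row in report["dmp"][block].items():
                lines.append(f"- {label}: {row}")
    return "\n".join(lines) + "\n"
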