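"""End-to-end runners with a reproducibility manifest.

``run_pipeline`` executes the molecular chain (simulate counts/reads ->
read cascade -> per-pair screen -> qPCR/ROC validation) and, when
screening records are supplied or simulated, the epidemiology report.
Every run writes a manifest (seed, thresholds, package versions, sha256
of inputs, per-stage record counts) next to its outputs, and a stage
failure aborts with an error naming the stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .epi_screen import prevalence_table, curve_profile_table
from .paired_screen import (pair_differential, select_reference_mirna,
                            shared_candidates)
from .qpcr_roc import compare_groups, delta_delta_ct, evaluate_marker
from .smallrna_quant import CountMatrix, normalize_cpm, process_sample
from .synthetic_data import (default_mirna_spec, default_population_spec,
                             default_qpcr_spec, random_catalog,
                             simulate_pair_counts, simulate_qpcr, simulate_reads,
                             simulate_screening_population)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated thresholds and sizes for one pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "quant", "screen", "roc")
    # molecular design (scaled-down read-level defaults)
    n_mirna: int = 60
    n_pairs: int = 6
    library_size: int = 20_000
    nb_dispersion: float = 0.05
    contaminant_fraction: float = 0.1
    # thresholds
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    pseudocount: float = 0.5
    min_len: int = 18
    max_len: int = 26
    adapter_min_overlap: int = 8
    adapter_max_mismatch_rate: float = 0.1
    assign_mismatches: int = 0
    caliper: float = 1.0
    ci_level: float = 0.95
    # optional epidemiology arm
    records_csv: str | None = None
    simulate_population_scale: float = 0.0  # 0 disables

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha {self.alpha} outside (0,1)")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level {self.ci_level} outside (0,1)")
        if self.min_abs_log2fc < 0 or self.pseudocount < 0:
            raise ValueError("min_abs_log2fc and pseudocount must be >= 0")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if self.caliper < 0:
            raise ValueError("caliper cannot be negative")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction outside [0,1)")
        if not 0 <= self.adapter_max_mismatch_rate < 1:
            raise ValueError("adapter mismatch rate outside [0,1)")
        if self.n_mirna <= 0 or self.n_pairs <= 0 or self.library_size <= 0:
            raise ValueError("design sizes must be positive")
        unknown = set(self.stages) - {"simulate", "epi", "quant", "screen", "roc"}
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest (also written)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": {"scoliomir": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "python": platform.python_version()},
        "stages": {},
        "inputs": {},
    }

    state: dict = {}
    for stage in config.stages:
        try:
            counts = _run_stage(stage, config, state, out, manifest)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = counts

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["inputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path,
               manifest: dict) -> dict:
    if stage == "simulate":
        spec = default_mirna_spec(seed=config.seed, n_mirna=config.n_mirna,
                                  n_pairs=config.n_pairs,
                                  library_size=config.library_size,
                                  nb_dispersion=config.nb_dispersion,
                                  contaminant_fraction=config.contaminant_fraction)
        counts, truth = simulate_pair_counts(spec)
        catalog = random_catalog(spec)
        reads = simulate_reads(spec, counts, catalog)
        io.write_catalog(catalog, out / "catalog")
        for sample, rlist in reads.items():
            io.write_fastq(rlist, out / f"{sample}.fastq")
        truth.to_csv(out / "truth.tsv", sep="\t")
        counts.to_tsv(out / "true_counts.tsv", out / "true_library_sizes.tsv")
        state.update(spec=spec, catalog=catalog, reads=reads, truth=truth,
                     true_counts=counts)
        return {"n_mirna": spec.n_mirna, "n_pairs": spec.n_pairs,
                "n_reads": {s: len(r) for s, r in reads.items()}}

    if stage == "epi":
        if config.records_csv:
            records = io.read_records_csv(config.records_csv)
        elif config.simulate_population_scale > 0:
            pop = default_population_spec(seed=config.seed,
                                          scale=config.simulate_population_scale)
            records = simulate_screening_population(pop)
            io.write_records_csv(records, out / "screening_records.csv")
        else:
            raise ValueError("epi stage needs records_csv or simulate_population_scale")
        table = prevalence_table(records)
        table.to_csv(out / "prevalence_table.tsv", sep="\t", index=False)
        positives = [r for r in records if r.is_positive]
        profile = curve_profile_table(positives)
        profile["severity_by_pattern"].to_csv(out / "severity_by_pattern.tsv", sep="\t")
        profile["severity_by_region"].to_csv(out / "severity_by_region.tsv", sep="\t")
        profile["severity_by_convexity"].to_csv(out / "severity_by_convexity.tsv", sep="\t")
        state["records"] = records
        return {"n_records": len(records), "n_positive": len(positives)}

    if stage == "quant":
        if "reads" not in state:
            raise ValueError("quant stage needs the simulate stage first")
        spec, catalog = state["spec"], state["catalog"]
        columns, stats_by_sample, libs = {}, {}, {}
        for sample, rlist in state["reads"].items():
            counts, cstats = process_sample(
                rlist, catalog, spec.adapter,
                min_overlap=config.adapter_min_overlap,
                max_mismatch_rate=config.adapter_max_mismatch_rate,
                min_len=config.min_len, max_len=config.max_len,
                assign_mismatches=config.assign_mismatches)
            if not cstats.balanced():
                raise ValueError(f"read accounting does not balance for {sample}")
            columns[sample] = counts
            libs[sample] = cstats.n_valid
            stats_by_sample[sample] = dataclasses.asdict(cstats)
        matrix = normalize_cpm(CountMatrix(pd.DataFrame(columns), pd.Series(libs)))
        matrix.to_tsv(out / "counts.tsv", out / "library_sizes.tsv")
        (out / "cascade_stats.json").write_text(json.dumps(stats_by_sample, indent=2))
        state["matrix"] = matrix
        return {"n_samples": len(columns),
                "n_valid_reads": {s: int(v) for s, v in libs.items()}}

    if stage == "screen":
        matrix = state.get("matrix")
        if matrix is None:
            raise ValueError("screen stage needs the quant stage first")
        n_pairs = config.n_pairs
        results = [pair_differential(matrix, (f"AIS_{k}", f"CTRL_{k}"),
                                     alpha=config.alpha,
                                     min_abs_log2fc=config.min_abs_log2fc,
                                     pseudocount=config.pseudocount)
                   for k in range(1, n_pairs + 1)]
        for res in results:
            res.table.to_csv(out / f"pair_{res.case_sample}.tsv", sep="\t")
        candidates = shared_candidates(results)
        candidates.upset_counts.to_csv(out / "upset_counts.tsv", sep="\t", index=False)
        case_ids = [f"AIS_{k}" for k in range(1, n_pairs + 1)]
        control_ids = [f"CTRL_{k}" for k in range(1, n_pairs + 1)]
        ref_id, ref_report = select_reference_mirna(matrix, case_ids, control_ids)
        summary = {
            "shared_ids": candidates.shared_ids,
            "consistent_ids": candidates.consistent_ids,
            "consistent_directions": candidates.consistent_directions,
            "reference_mirna": ref_id,
        }
        (out / "candidates.json").write_text(json.dumps(summary, indent=2))
        ref_report.to_csv(out / "reference_report.tsv", sep="\t")
        state["candidates"] = candidates
        return {"n_shared": len(candidates.shared_ids),
                "n_consistent": len(candidates.consistent_ids),
                "reference_mirna": ref_id}

    if stage == "roc":
        qspec = default_qpcr_spec(seed=config.seed)
        samples = simulate_qpcr(qspec)
        io.write_ct_csv(samples, out / "ct_table.csv")
        rel = delta_delta_ct(samples)
        rel.to_csv(out / "relative_expression.tsv", sep="\t", index=False)
        report = {}
        for target, grp in rel.groupby("target"):
            case = grp.loc[grp["group"] == "case", "rq"].to_numpy()
            control = grp.loc[grp["group"] == "control", "rq"].to_numpy()
            stat, p = compare_groups(case, control, test="welch_t")
            roc = evaluate_marker(grp["rq"].to_numpy(), grp["group"].to_numpy(),
                                  level=config.ci_level)
            report[target] = {"welch_t": stat, "p_value": p,
                              **dataclasses.asdict(roc)}
        (out / "roc_report.json").write_text(json.dumps(report, indent=2))
        state["roc_report"] = report
        return {"n_subjects": len(samples), "n_targets": len(report)}

    raise ValueError(f"unknown stage {stage!r}")
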