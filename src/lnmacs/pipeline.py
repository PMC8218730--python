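"""End-to-end orchestration with a run configuration and manifest.

``run_pipeline`` executes filter -> differential expression (C1, C2) ->
harmonize -> contamination on a counts/metadata pair plus a probe-level
matrix, logging record counts per stage and emitting a machine-readable
manifest. Threshold defaults are the analysis' canonical values
(total count >= 10, detected in >= 2 samples, p_holm < 0.01,
base mean > 100).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .diffexpr import filter_genes, run_comparison, select_deg
from .harmonize import harmonize_pair
from .io import (
    log_stage,
    read_expression_matrix,
    read_probe_matrix,
    read_sample_metadata,
    write_expression_matrix,
    write_run_config,
)
from .signatures import contamination_report


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    counts_path: str
    metadata_path: str
    probes_path: str | None = None
    probe_map_path: str | None = None
    out_dir: str = "lnmacs_run"
    total_count_min: int = 10
    min_detected_samples: int = 2
    padj_max: float = 0.01
    base_mean_min: float = 100.0
    normalization: str = "log2cpm1"
    shift: str = "minzero"
    mwu_mode: str = "auto"
    dispersion_method: str = "map"
    comparisons: tuple[str, ...] = ("C1", "C2")
    seed: int = 0

    @classmethod
    def from_mapping(cls, cfg: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = list(self.comparisons)
        return d


@dataclass
class Manifest:
    stages: list = field(default_factory=list)

    def record(self, stage: str, inputs: dict, outputs: dict,
               parameters: dict, counts: dict) -> None:
        self.stages.append({"stage": stage, "inputs": inputs,
                            "outputs": outputs, "parameters": parameters,
                            "counts": counts})
        log_stage(stage, **counts)

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages}, indent=2)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest as a dict.

    Every stage's input record count equals the upstream stage's output
    count; the resolved configuration is written next to the outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_run_config(config.to_mapping(), out / "config.resolved.yaml")
    manifest = Manifest()

    meta = read_sample_metadata(config.metadata_path)
    counts = read_expression_matrix(config.counts_path, "counts", metadata=meta)

    # ---- filter ----------------------------------------------------------
    filtered = filter_genes(counts, config.total_count_min,
                            config.min_detected_samples)
    write_expression_matrix(filtered, out / "counts.filtered.tsv")
    manifest.record(
        "filter",
        {"counts": str(config.counts_path)},
        {"filtered": str(out / "counts.filtered.tsv")},
        {"total_count_min": config.total_count_min,
         "min_detected_samples": config.min_detected_samples},
        {"genes_in": counts.shape[0], "genes_out": filtered.shape[0]},
    )

    # ---- differential expression ----------------------------------------
    de_counts = {}
    for which in config.comparisons:
        res = run_comparison(filtered, None, which,
                             dispersion_method=config.dispersion_method)
        res.table.to_csv(out / f"results.{which}.tsv", sep="\t", index=False)
        up, down = select_deg(res, config.padj_max, config.base_mean_min)
        up.to_csv(out / f"deg_up.{which}.tsv", sep="\t", index=False)
        down.to_csv(out / f"deg_down.{which}.tsv", sep="\t", index=False)
        de_counts[which] = {"tested": len(res.table), "up": len(up),
                            "down": len(down)}
        manifest.record(
            f"de_{which}",
            {"filtered": str(out / "counts.filtered.tsv")},
            {"results": str(out / f"results.{which}.tsv"),
             "deg_up": str(out / f"deg_up.{which}.tsv"),
             "deg_down": str(out / f"deg_down.{which}.tsv")},
            {"padj_max": config.padj_max,
             "base_mean_min": config.base_mean_min,
             "dispersion_method": config.dispersion_method},
            {"genes_in": filtered.shape[0], "genes_tested": len(res.table),
             "deg_up": len(up), "deg_down": len(down),
             "failed": len(res.failures)},
        )

    # ---- harmonize + contamination (needs the probe-level dataset) ------
    if config.probes_path and config.probe_map_path:
        probes = read_probe_matrix(config.probes_path, config.probe_map_path)
        harm = harmonize_pair(filtered, probes,
                              log_method=config.normalization)
        write_expression_matrix(harm["rnaseq"], out / "standardized.rnaseq.tsv")
        write_expression_matrix(harm["microarray"],
                                out / "standardized.microarray.tsv")
        manifest.record(
            "harmonize",
            {"filtered": str(out / "counts.filtered.tsv"),
             "probes": str(config.probes_path)},
            {"rnaseq": str(out / "standardized.rnaseq.tsv"),
             "microarray": str(out / "standardized.microarray.tsv")},
            {"normalization": config.normalization},
            {"genes_in": filtered.shape[0],
             "shared_genes": harm["rnaseq"].shape[0],
             "pearson_r": round(harm["pearson_r"], 6)},
        )

        report = contamination_report(harm["rnaseq"], harm["microarray"],
                                      shift=config.shift, mode=config.mwu_mode)
        with open(out / "contamination.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        manifest.record(
            "contamination",
            {"rnaseq": str(out / "standardized.rnaseq.tsv"),
             "microarray": str(out / "standardized.microarray.tsv")},
            {"report": str(out / "contamination.json")},
            {"shift": config.shift, "mwu_mode": config.mwu_mode},
            {"genes_in": harm["rnaseq"].shape[0],
             "panels": len(report["panels"])},
        )

    manifest_dict = {"stages": manifest.stages, "de": de_counts}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest_dict, fh, indent=2)
    return manifest_dict
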