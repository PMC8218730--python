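"""Tab-separated readers/writers and run configuration.

File dialect: TSV, UTF-8, '.' decimal separator, no quoting of identifiers —
the layout of typical GEO supplementary matrix exports. Gene/probe ids live
in the first column, sample ids in the header row. Floats are written with
Python's shortest round-tripping repr so that write -> read is bitwise exact.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ExpressionMatrix,
    ProbeMatrix,
    ValidationError,
    _duplicates,
    validate_metadata,
)

logger = logging.getLogger("lnmacs")


def setup_logging(level: int = logging.INFO) -> None:
    """Structured stage logs on stderr (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("lnmacs %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def log_stage(stage: str, **counts) -> None:
    fields = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, fields)


def _check_header_duplicates(path: Path) -> None:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ValidationError(f"{path}: empty file")
    cols = header.split("\t")[1:]
    dups = _duplicates(cols)
    if dups:
        raise ValidationError(f"{path}: duplicate sample ids in header: {dups}")


def read_expression_matrix(path, value_kind: str,
                           metadata: pd.DataFrame | None = None
                           ) -> ExpressionMatrix:
    """Read a gene x sample TSV matrix with a declared value kind."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_header_duplicates(path)
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    try:
        values = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric cell in matrix body: {exc}")
    if value_kind == "counts":
        arr = values.to_numpy()
        if np.isnan(arr).any():
            raise ValidationError(f"{path}: missing values not permitted in counts")
        if (arr < 0).any():
            raise ValidationError(f"{path}: negative value in counts matrix")
        values = values.astype(np.int64)
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    em = ExpressionMatrix(values, value_kind, metadata)
    log_stage("read_expression_matrix", path=path.name,
              genes=em.shape[0], samples=em.shape[1], kind=value_kind)
    return em


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    em.values.to_csv(path, sep="\t", index_label="gene_id")
    log_stage("write_expression_matrix", path=path.name,
              genes=em.shape[0], samples=em.shape[1])


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate the per-sample factor table.

    Required columns: sample_id, pool, td, phenotype, platform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: metadata file has no rows")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    meta = validate_metadata(df)
    log_stage("read_sample_metadata", path=path.name, samples=meta.shape[0])
    return meta


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_matrix(values_path, map_path) -> ProbeMatrix:
    """Read a probe x sample intensity TSV plus a probe->gene map TSV.

    The map file has columns ``probe_id`` and ``gene_id``. Probes absent
    from the map are kept but flagged unmapped (they are dropped, with a
    logged count, at aggregation time). Missing intensity cells are allowed
    and treated as "not detected".
    """
    values_path, map_path = Path(values_path), Path(map_path)
    for p in (values_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)
    _check_header_duplicates(values_path)
    values = pd.read_csv(values_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    try:
        values = values.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{values_path}: non-numeric probe intensity: {exc}")
    values.index = values.index.astype(str)
    pmap = pd.read_csv(map_path, sep="\t", dtype=str)
    for col in ("probe_id", "gene_id"):
        if col not in pmap.columns:
            raise ValidationError(f"{map_path}: missing column '{col}'")
    probe_to_gene = pd.Series(pmap["gene_id"].values,
                              index=pmap["probe_id"].values)
    pm = ProbeMatrix(values, probe_to_gene)
    log_stage("read_probe_matrix", path=values_path.name,
              probes=values.shape[0], samples=values.shape[1],
              unmapped=len(pm.unmapped_probes))
    return pm


def write_probe_matrix(pm: ProbeMatrix, values_path, map_path) -> None:
    values_path, map_path = Path(values_path), Path(map_path)
    values_path.parent.mkdir(parents=True, exist_ok=True)
    pm.values.to_csv(values_path, sep="\t", index_label="probe_id")
    pd.DataFrame({"probe_id": pm.probe_to_gene.index,
                  "gene_id": pm.probe_to_gene.values}
                 ).to_csv(map_path, sep="\t", index=False)


def read_run_config(path) -> dict:
    """YAML run configuration (paths, thresholds, seeds)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def write_run_config(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
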