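"""In-memory containers for expression data.

The central object is :class:`ExpressionMatrix`, a genes x samples numeric
matrix tagged with what kind of values it holds (raw counts, log2
intensities, or per-sample standardized scores) plus an optional per-sample
metadata table describing the sorted-macrophage factorial design
(Pool x tumor-draining status x CD11c phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_KINDS = ("counts", "log2_intensity", "standardized")
PLATFORMS = ("rnaseq", "microarray")
PHENOTYPES = ("+", "-")

#: tolerance for the standardized-column invariant (mean 0, sd 1)
STANDARDIZED_TOL = 1e-9

METADATA_COLUMNS = ("pool", "td", "phenotype", "platform")


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


def _duplicates(index) -> list:
    seen, dups = set(), []
    for x in index:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a per-sample metadata table.

    Expects a DataFrame indexed by sample_id (or with a ``sample_id``
    column) carrying ``pool``, ``td`` (0/1, 1 = tumor-draining),
    ``phenotype`` ('+' = CD11c+ MSM, '-' = CD11c- SSM) and ``platform``
    ('rnaseq' or 'microarray'). Returns a normalized copy.
    """
    if not isinstance(meta, pd.DataFrame):
        raise ValidationError("metadata must be a pandas DataFrame")
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if meta.shape[0] == 0:
        raise ValidationError("metadata table is empty")
    dups = _duplicates(meta.index)
    if dups:
        raise ValidationError(f"duplicate sample_id in metadata: {dups}")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata is missing required columns: {missing}")

    # td -> {0, 1}
    td = pd.to_numeric(meta["td"], errors="coerce")
    if td.isna().any() or not td.isin([0, 1]).all():
        bad = meta.loc[~td.isin([0, 1]) | td.isna(), "td"].tolist()
        raise ValidationError(f"td must be 0 or 1, got {bad}")
    meta["td"] = td.astype(int)

    # phenotype -> {'+', '-'}
    phen = meta["phenotype"].astype(str).str.strip()
    # tolerate unicode minus / 'neg'/'pos' style exports
    phen = phen.replace({"−": "-", "–": "-", "pos": "+", "neg": "-"})
    bad = sorted(set(phen) - set(PHENOTYPES))
    if bad:
        raise ValidationError(f"phenotype must be '+' or '-', got {bad}")
    meta["phenotype"] = phen

    plat = meta["platform"].astype(str).str.strip().str.lower()
    bad = sorted(set(plat) - set(PLATFORMS))
    if bad:
        raise ValidationError(f"platform must be one of {PLATFORMS}, got {bad}")
    meta["platform"] = plat

    meta["pool"] = meta["pool"].astype(str)
    return meta


def canonical_metadata(pools: int = 4, platform: str = "rnaseq",
                       prefix: str = "") -> pd.DataFrame:
    """The study's factorial design: ``pools`` x {TD=0,1} x {phenotype +,-}.

    With the default 4 pools this is the canonical 16-sample layout. Sample
    ids read e.g. ``P1_TD0_MSM`` (phenotype '+' = MSM, '-' = SSM).
    """
    rows = []
    for p in range(1, pools + 1):
        for td in (0, 1):
            for phen in ("+", "-"):
                label = "MSM" if phen == "+" else "SSM"
                rows.append({
                    "sample_id": f"{prefix}P{p}_TD{td}_{label}",
                    "pool": f"P{p}",
                    "td": td,
                    "phenotype": phen,
                    "platform": platform,
                })
    return validate_metadata(pd.DataFrame(rows))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a value-kind tag.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    value_kind
        One of ``counts`` (non-negative integers), ``log2_intensity``
        (may contain missing cells, e.g. unannotated microarray values) or
        ``standardized`` (each column mean 0, sd 1 to 1e-9).
    metadata
        Optional per-sample table (see :func:`validate_metadata`); its
        sample set must match the matrix columns.
    """

    values: pd.DataFrame
    value_kind: str
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self):
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        dg = _duplicates(self.values.index)
        if dg:
            raise ValidationError(f"duplicate gene ids: {dg}")
        ds = _duplicates(self.values.columns)
        if ds:
            raise ValidationError(f"duplicate sample ids: {ds}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("matrix body must be numeric")

        if self.value_kind == "counts":
            if np.isnan(arr).any():
                raise ValidationError("counts may not contain missing values")
            if (arr < 0).any():
                raise ValidationError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
                raise ValidationError("counts must be integers")
        elif self.value_kind == "standardized":
            if self.values.shape[0] > 1:
                col = self.values.to_numpy(dtype=float)
                means = np.nanmean(col, axis=0)
                sds = np.nanstd(col, axis=0, ddof=1)
                if (np.abs(means) > STANDARDIZED_TOL).any() or \
                        (np.abs(sds - 1.0) > max(STANDARDIZED_TOL, 1e-9)).any():
                    raise ValidationError(
                        "standardized matrix columns must have mean 0 and sd 1")

        if self.metadata is not None:
            meta = validate_metadata(self.metadata)
            if set(meta.index) != set(self.values.columns):
                only_m = sorted(set(meta.index) - set(self.values.columns))
                only_v = sorted(set(self.values.columns) - set(meta.index))
                raise ValidationError(
                    "metadata/matrix sample sets differ "
                    f"(metadata only: {only_m}, matrix only: {only_v})")
            # align metadata rows to column order
            object.__setattr__(self, "metadata", meta.loc[list(self.values.columns)])

    # -- manipulation ----------------------------------------------------
    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.value_kind,
                                self.metadata)

    def with_values(self, values: pd.DataFrame, value_kind: str | None = None
                    ) -> "ExpressionMatrix":
        return ExpressionMatrix(values, value_kind or self.value_kind,
                                self.metadata)


@dataclass
class ProbeMatrix:
    """Probe-level log2 intensities plus a probe -> gene annotation map."""

    values: pd.DataFrame                 # probes x samples
    probe_to_gene: pd.Series             # index: probe_id, value: gene_id

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("probe values must be a pandas DataFrame")
        dp = _duplicates(self.values.index)
        if dp:
            raise ValidationError(f"duplicate probe ids: {dp}")
        if not isinstance(self.probe_to_gene, pd.Series):
            self.probe_to_gene = pd.Series(self.probe_to_gene)
        dm = _duplicates(self.probe_to_gene.index)
        if dm:
            raise ValidationError(f"duplicate probe ids in annotation: {dm}")

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def unmapped_probes(self) -> list:
        mapped = set(self.probe_to_gene.index)
        return [p for p in self.values.index if p not in mapped]
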