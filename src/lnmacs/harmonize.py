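"""Cross-platform (RNA-seq vs microarray) harmonization.

The workflow makes two very different measurement platforms comparable:
probe-level array intensities are averaged per gene; RNA-seq counts are
put on a log2 scale (log2-CPM with pseudocount 1, removing depth
differences before any per-sample operation); the gene universe is
restricted to genes detected on both platforms; each sample column is
z-scored; platform-wise gene means are compared by Pearson correlation as
the comparability check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ProbeMatrix, ValidationError
from .io import log_stage


def aggregate_probes(probes: ProbeMatrix) -> ExpressionMatrix:
    """Average probe log2 intensities per gene (arithmetic mean, log2 scale).

    Unmapped probes are dropped with a logged count. Missing cells are
    ignored by the mean; a gene whose probes are all missing in a sample
    stays missing there.
    """
    mapped = [p for p in probes.values.index if p in probes.probe_to_gene.index]
    n_unmapped = probes.values.shape[0] - len(mapped)
    if not mapped:
        raise ValidationError("all probes are unmapped; nothing to aggregate")
    sub = probes.values.loc[mapped]
    gene_of = probes.probe_to_gene.loc[mapped]
    agg = sub.groupby(gene_of.values, sort=False).mean()
    agg.index.name = "gene_id"
    log_stage("aggregate_probes", probes=len(mapped), unmapped=n_unmapped,
              genes=agg.shape[0])
    return ExpressionMatrix(agg, "log2_intensity")


def log_transform_counts(counts: ExpressionMatrix,
                         method: str = "log2cpm1") -> ExpressionMatrix:
    """Counts -> log2 scale.

    ``log2cpm1`` (default): ``log2(1e6 * count / column_sum + 1)`` — depth
    is removed before the per-sample z-score, and the z-score later absorbs
    any multiplicative constant. ``log2count1``: ``log2(count + 1)``.
    """
    if counts.value_kind != "counts":
        raise ValidationError("log_transform_counts expects value_kind=counts")
    arr = counts.values.to_numpy(dtype=float)
    if method == "log2cpm1":
        colsum = arr.sum(axis=0)
        if (colsum == 0).any():
            bad = [counts.sample_ids[i] for i in np.where(colsum == 0)[0]]
            raise ValidationError(f"zero column sum for samples {bad}")
        out = np.log2(1e6 * arr / colsum + 1.0)
    elif method == "log2count1":
        out = np.log2(arr + 1.0)
    else:
        raise ValueError(f"unknown log transform {method!r}")
    return ExpressionMatrix(
        pd.DataFrame(out, index=counts.values.index,
                     columns=counts.values.columns),
        "log2_intensity", counts.metadata)


def _detected(em: ExpressionMatrix) -> pd.Index:
    """Genes 'detected' on a platform: >0 in >=1 sample for counts,
    non-missing in >=1 sample for intensities."""
    if em.value_kind == "counts":
        mask = (em.values > 0).any(axis=1)
    else:
        mask = em.values.notna().any(axis=1)
    return em.values.index[mask]


def intersect_platform_genes(a: ExpressionMatrix, b: ExpressionMatrix
                             ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to genes detected on both platforms.

    Gene order follows matrix ``a``. Raises on an empty intersection.
    """
    det_a, det_b = set(_detected(a)), set(_detected(b))
    shared = [g for g in a.values.index if g in det_a and g in det_b]
    if not shared:
        raise ValidationError("no genes detected on both platforms")
    out_a = ExpressionMatrix(a.values.loc[shared], a.value_kind, a.metadata)
    out_b = ExpressionMatrix(b.values.loc[shared], b.value_kind, b.metadata)
    log_stage("intersect_platform_genes", a_genes=a.shape[0],
              b_genes=b.shape[0], shared=len(shared))
    return out_a, out_b


def standardize_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per sample column: subtract the mean, divide by the sd (n-1).

    Missing cells are ignored in the moments and stay missing. A constant
    column is an error naming the sample.
    """
    arr = m.values.to_numpy(dtype=float)
    means = np.nanmean(arr, axis=0)
    sds = np.nanstd(arr, axis=0, ddof=1)
    zero = np.where(~(sds > 0))[0]
    if zero.size:
        bad = [m.sample_ids[i] for i in zero]
        raise ValidationError(f"constant column(s), cannot standardize: {bad}")
    out = (arr - means) / sds
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        "standardized", m.metadata)


def platform_means(m: ExpressionMatrix) -> pd.Series:
    """Per-gene mean over all of one platform's samples."""
    return m.values.mean(axis=1, skipna=True)


def cross_platform_correlation(mean_a: pd.Series, mean_b: pd.Series) -> float:
    """Pearson correlation between matched per-gene platform means."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("platform mean vectors must be matched, length >= 3")
    if isinstance(mean_a, pd.Series) and isinstance(mean_b, pd.Series):
        if list(mean_a.index) != list(mean_b.index):
            raise ValidationError("platform mean vectors have mismatched genes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("zero variance in a platform mean vector")
    return float(stats.pearsonr(a, b).statistic)


def harmonize_pair(counts: ExpressionMatrix, probes: ProbeMatrix,
                   log_method: str = "log2cpm1") -> dict:
    """Run the full chain on an RNA-seq counts matrix and a probe matrix.

    Returns a dict with the standardized per-platform matrices
    (``rnaseq``, ``microarray``), the per-gene platform means, and the
    cross-platform Pearson ``r``.
    """
    array_genes = aggregate_probes(probes)
    seq_log = log_transform_counts(counts, method=log_method)
    seq_shared, array_shared = intersect_platform_genes(seq_log, array_genes)
    seq_std = standardize_samples(seq_shared)
    array_std = standardize_samples(array_shared)
    mean_seq = platform_means(seq_std)
    mean_array = platform_means(array_std)
    r = cross_platform_correlation(mean_seq, mean_array)
    log_stage("harmonize_pair", shared_genes=seq_std.shape[0],
              pearson_r=round(r, 4))
    return {
        "rnaseq": seq_std,
        "microarray": array_std,
        "mean_rnaseq": mean_seq,
        "mean_microarray": mean_array,
        "pearson_r": r,
    }
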