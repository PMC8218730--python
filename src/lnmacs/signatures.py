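"""Lineage-signature scoring and contamination comparison.

A lineage signature for a sample is the sum of that sample's (standardized)
expression values over a fixed marker panel. The housekeeping panel, being
stable across samples and platforms, serves as the reference denominator:
``ratio = lineage signature / housekeeping signature``. Because z-scored
values can be negative, the default ``shift="minzero"`` subtracts the global
matrix minimum before summing, guaranteeing positive signatures while
preserving sample ordering. Ratio distributions between two datasets are
compared with the Mann-Whitney U test (exact enumeration for small groups).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .io import log_stage
from .panels import CANONICAL_PANELS, MarkerPanel

#: exact enumeration is used when min(n1, n2) <= this (C(16,8)=12870 tables)
EXACT_MAX_MIN_N = 8


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------

def score_signature(m: ExpressionMatrix, panel: MarkerPanel,
                    shift: str = "minzero",
                    shift_value: float | None = None) -> pd.DataFrame:
    """Per-sample signature values for one marker panel.

    Parameters
    ----------
    m
        Expression matrix (normally standardized / harmonized).
    panel
        Marker panel; genes absent from the matrix are skipped with a
        warning and reported through ``n_markers_found``.
    shift
        ``minzero`` (default) subtracts the global matrix minimum from every
        value before summing so signatures are non-negative; ``none`` sums
        raw values.
    shift_value
        Override for the minzero shift origin — pass the joint minimum of
        two matrices when signatures from both must share one shift.

    Returns a DataFrame indexed by sample_id with columns ``panel``,
    ``signature_value`` and ``n_markers_found``.
    """
    found = [g for g in panel.genes if g in m.values.index]
    if not found:
        raise ValueError(f"no gene of panel {panel.name!r} present in matrix")
    missing = [g for g in panel.genes if g not in m.values.index]
    if missing:
        warnings.warn(
            f"panel {panel.name}: {len(missing)} marker(s) absent from "
            f"matrix and skipped: {missing}", stacklevel=2)
    if shift == "minzero":
        origin = float(np.nanmin(m.values.to_numpy())) if shift_value is None \
            else float(shift_value)
    elif shift == "none":
        origin = 0.0
    else:
        raise ValueError(f"unknown shift mode {shift!r}")
    sub = m.values.loc[found] - origin
    sig = sub.sum(axis=0, skipna=True)
    out = pd.DataFrame({
        "panel": panel.name,
        "signature_value": sig,
        "n_markers_found": len(found),
    })
    out.index.name = "sample_id"
    return out


def contamination_ratio(lineage: pd.DataFrame, housekeeping: pd.DataFrame
                        ) -> pd.Series:
    """Per-sample ratio of a lineage signature to the housekeeping signature."""
    hk = housekeeping["signature_value"]
    if (hk <= 0).any():
        bad = list(hk.index[hk <= 0])
        raise ValueError(
            f"non-positive housekeeping signature for samples {bad}; "
            "score signatures with shift='minzero' to guarantee positivity")
    ratio = lineage["signature_value"] / hk.loc[lineage.index]
    ratio.name = f"{lineage['panel'].iloc[0]}_over_housekeeping"
    return ratio


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(ranks_a: np.ndarray, n1: int, n2: int) -> float:
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2.0)


def _exact_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n1) group assignments of
    the observed (mid)ranks: twice the smaller tail, capped at 1."""
    n = pooled_ranks.size
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp).reshape(-1, n1)
    rank_sums = pooled_ranks[combos].sum(axis=1)
    u_all = rank_sums - n1 * (n1 + 1) / 2.0
    tol = 1e-9
    p_low = np.mean(u_all <= u_obs + tol)
    p_high = np.mean(u_all >= u_obs - tol)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _normal_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    mean_u = n1 * n2 / 2.0
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    ``mode='exact'`` enumerates the permutation null of the observed
    midranks (feasible for ``min(n1, n2) <= 8``); ``'normal'`` uses the
    tie-corrected normal approximation; ``'auto'`` picks exact when
    feasible. Returns ``(U of group a, two-sided p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)          # midranks for ties
    u_obs = _u_statistic(ranks[:n1], n1, n2)

    if mode == "auto":
        mode = "exact" if min(n1, n2) <= EXACT_MAX_MIN_N else "normal"
    if mode == "exact":
        if min(n1, n2) > EXACT_MAX_MIN_N:
            raise ValueError(
                f"exact enumeration limited to min(n1, n2) <= {EXACT_MAX_MIN_N}")
        p = _exact_p(ranks, n1, u_obs)
    elif mode == "normal":
        p = _normal_p(ranks, n1, n2, u_obs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return u_obs, p


# ---------------------------------------------------------------------------
# dataset comparison
# ---------------------------------------------------------------------------

def signature_ratios(m: ExpressionMatrix,
                     panels: dict[str, MarkerPanel] | None = None,
                     shift: str = "minzero",
                     shift_value: float | None = None) -> pd.DataFrame:
    """Housekeeping-referenced ratios for every non-housekeeping panel.

    Returns a samples x panels DataFrame of ratios (housekeeping included
    as its own column, identically 1 by construction).
    """
    panels = dict(panels or CANONICAL_PANELS)
    if "housekeeping" not in panels:
        raise ValueError("panels must include a 'housekeeping' reference")
    scores = {name: score_signature(m, panel, shift=shift,
                                    shift_value=shift_value)
              for name, panel in panels.items()}
    hk = scores["housekeeping"]
    out = {name: contamination_ratio(df, hk) for name, df in scores.items()}
    return pd.DataFrame(out)


def compare_contamination(ratios_a: pd.DataFrame, ratios_b: pd.DataFrame,
                          panels: list[str] | None = None,
                          mode: str = "auto") -> dict:
    """Compare per-sample contamination ratios between two datasets.

    ``ratios_a``/``ratios_b`` are samples x panels tables (from
    :func:`signature_ratios`). Returns a JSON-ready report with, per panel,
    the group medians, U statistic and two-sided Mann-Whitney p, plus a
    boxplot-ready long table under ``"table"``.
    """
    panels = list(panels or ratios_a.columns)
    report: dict = {"panels": {}, "mwu_mode": mode}
    rows = []
    for panel in panels:
        va = ratios_a[panel].to_numpy(dtype=float)
        vb = ratios_b[panel].to_numpy(dtype=float)
        u, p = mann_whitney(va, vb, mode=mode)
        report["panels"][panel] = {
            "median_a": float(np.median(va)),
            "median_b": float(np.median(vb)),
            "n_a": int(va.size),
            "n_b": int(vb.size),
            "U": u,
            "p_value": p,
        }
        for ds, series in (("a", ratios_a[panel]), ("b", ratios_b[panel])):
            for sample, val in series.items():
                rows.append({"dataset": ds, "sample_id": sample,
                             "panel": panel, "ratio": float(val)})
    report["table"] = rows
    log_stage("compare_contamination",
              panels=len(panels),
              significant=sum(1 for v in report["panels"].values()
                              if v["p_value"] < 0.05))
    return report


def contamination_report(a: ExpressionMatrix, b: ExpressionMatrix,
                         panels: dict[str, MarkerPanel] | None = None,
                         shift: str = "minzero", mode: str = "auto") -> dict:
    """High-level comparison of two harmonized, standardized datasets.

    Uses one joint minzero shift (the global minimum over both matrices) so
    signatures from the two datasets live on a common positive scale; the
    choice is recorded in the report.
    """
    shift_value = None
    if shift == "minzero":
        shift_value = float(min(np.nanmin(a.values.to_numpy()),
                                np.nanmin(b.values.to_numpy())))
    ra = signature_ratios(a, panels, shift=shift, shift_value=shift_value)
    rb = signature_ratios(b, panels, shift=shift, shift_value=shift_value)
    report = compare_contamination(ra, rb, mode=mode)
    report["shift"] = shift
    report["shift_value"] = shift_value
    return report
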