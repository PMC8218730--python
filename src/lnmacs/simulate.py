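"""Synthetic data emulating the sorted lymph-node macrophage study design.

Counts are generated for a ``pools x {TD=0,1} x {phenotype +,-}`` factorial
design (4 pools = the canonical 16 samples). Each gene has a
macrophage-compartment mean and a lymphocyte-compartment mean; per-sample
lymphocyte contamination ``f`` (membrane blebs sticking to sorted events)
acts as a convex mixture of the two compartment profiles *before* negative
binomial sampling:

    mu[g, s] = L_s * ((1 - f_s) * m_g * 2**(effects) + f_s * l_g)

where ``L_s`` is a log-uniform library-size factor, ``m_g`` the macrophage
mean, ``l_g`` the lymphocyte mean (high for B/T marker genes, equal to the
macrophage level for broadly hematopoietic genes), and the log2 effects
cover the phenotype contrast, the tumor-draining contrast and small
pool-shared perturbations. Counts are NB with variance ``mu + alpha*mu**2``.

A microarray-like twin re-measures a counts matrix at probe level:
``generate_microarray`` assigns each gene k probes and emits
``log2-CPM(gene) + probe offset + Gaussian noise``, together with the
probe -> gene map. All draws consume a single generator seeded once, in the
documented order, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMatrix, canonical_metadata
from .harmonize import log_transform_counts
from .io import log_stage
from .panels import CANONICAL_PANELS, LINEAGE_OF_PANEL

_MU_OVERFLOW = 1e12


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults are the package's canonical scenario: 2000 genes, the 16-sample
    design, NB dispersion ``alpha = 0.05`` (variance ``mu + 0.05 mu^2``),
    2% lymphocyte contamination (a well-sorted preparation), and baseline
    log2 means uniform on (1, 9).
    """

    n_genes: int = 2000
    pools: int = 4
    baseline_log2_mean_range: tuple[float, float] = (1.0, 9.0)
    dispersion_alpha: float | np.ndarray = 0.05
    #: gene index -> log2 effect; positive = higher in SSM (CD11c-)
    phenotype_effects: dict[int, float] = field(default_factory=dict)
    #: gene index -> log2 effect; positive = higher in tumor-draining samples
    td_effects: dict[int, float] = field(default_factory=dict)
    #: per-sample mixture fraction f in [0, 1), scalar broadcasts
    contamination_fractions: float | np.ndarray = 0.02
    library_size_range: tuple[float, float] = (0.7, 1.4)
    #: sd (log2) of gene-wise perturbations shared within a pool
    pool_effect_sd: float = 0.05
    #: B/T marker level in the macrophage compartment (log2, near-silent)
    marker_macrophage_log2: float = 2.0
    #: B/T marker level in the lymphocyte compartment (log2, abundant)
    lymph_marker_log2: float = 8.0
    #: housekeeping genes: fixed high level in both compartments
    housekeeping_log2: float = 8.0
    #: lymphocyte/macrophage level ratio for macrophage-panel genes; the
    #: default 1.0 reflects that this panel is broadly hematopoietic
    macrophage_lymph_ratio: float = 1.0
    #: inclusive integer range of probes per gene for the microarray twin
    probes_per_gene: tuple[int, int] = (1, 4)
    probe_offset_sd: float = 0.3
    noise_sd_array: float = 0.25
    allow_marker_effects: bool = False
    seed: int = 0
    #: optional separate seed for gene-level draws (baselines, pool effects);
    #: pin it to share one "biology" across datasets that differ in
    #: contamination or sampling seed
    gene_seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.pools * 4

    def marker_gene_count(self) -> int:
        return sum(len(p) for p in CANONICAL_PANELS.values())

    def validate(self) -> None:
        n_markers = self.marker_gene_count()
        if self.n_genes < n_markers:
            raise ValueError(
                f"n_genes must be >= {n_markers} to host the marker panels")
        if self.pools < 1:
            raise ValueError("pools must be >= 1")
        lo, hi = self.baseline_log2_mean_range
        if not lo <= hi:
            raise ValueError("baseline_log2_mean_range must be (lo, hi)")
        alpha = np.atleast_1d(np.asarray(self.dispersion_alpha, dtype=float))
        if (alpha <= 0).any():
            raise ValueError("dispersion_alpha must be > 0")
        if alpha.size not in (1, self.n_genes):
            raise ValueError("dispersion_alpha must be scalar or per-gene")
        f = np.atleast_1d(np.asarray(self.contamination_fractions, dtype=float))
        if ((f < 0) | (f >= 1)).any():
            raise ValueError("contamination fractions must lie in [0, 1)")
        if f.size not in (1, self.n_samples):
            raise ValueError("contamination_fractions must be scalar or per-sample")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive (lo, hi)")
        klo, khi = self.probes_per_gene
        if not (1 <= klo <= khi):
            raise ValueError("probes_per_gene must be an integer range >= 1")
        for name, eff in (("phenotype_effects", self.phenotype_effects),
                          ("td_effects", self.td_effects)):
            for idx in eff:
                if not 0 <= idx < self.n_genes:
                    raise ValueError(f"{name}: gene index {idx} out of range")
                if idx < n_markers and not self.allow_marker_effects:
                    raise ValueError(
                        f"{name}: index {idx} targets a marker gene; set "
                        "allow_marker_effects=True to do this on purpose")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    genes: pd.DataFrame      # lineage, baseline_log2, lymph_log2, effects
    samples: pd.DataFrame    # design factors + contamination + library factor
    expected: pd.DataFrame   # noise-free expected expression mu[g, s]


def _gene_table(config: SimConfig, rng: np.random.Generator
                ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gene ids, lineage labels and the two compartment mean vectors.

    Marker genes come first (carrying their canonical symbols so signature
    scoring works on synthetic data out of the box), then background genes.
    """
    gene_ids, lineages = [], []
    for name, panel in CANONICAL_PANELS.items():
        gene_ids.extend(panel.genes)
        lineages.extend([LINEAGE_OF_PANEL[name]] * len(panel))
    n_bg = config.n_genes - len(gene_ids)
    gene_ids.extend(f"G{i:05d}" for i in range(n_bg))
    lineages.extend(["background"] * n_bg)
    lineages = np.array(lineages)

    lo, hi = config.baseline_log2_mean_range
    baseline_log2 = rng.uniform(lo, hi, config.n_genes)
    is_bt = np.isin(lineages, ("B", "T"))
    baseline_log2[is_bt] = config.marker_macrophage_log2
    baseline_log2[lineages == "housekeeping"] = config.housekeeping_log2

    lymph_log2 = baseline_log2.copy()
    lymph_log2[is_bt] = config.lymph_marker_log2
    is_mac = lineages == "macrophage"
    lymph_log2[is_mac] = baseline_log2[is_mac] + np.log2(
        config.macrophage_lymph_ratio) if config.macrophage_lymph_ratio > 0 \
        else -np.inf

    genes = pd.DataFrame({
        "lineage": lineages,
        "baseline_log2": baseline_log2,
        "lymph_log2": lymph_log2,
        "phenotype_log2fc": 0.0,
        "td_log2fc": 0.0,
    }, index=pd.Index(gene_ids, name="gene_id"))
    for idx, eff in config.phenotype_effects.items():
        genes.iloc[idx, genes.columns.get_loc("phenotype_log2fc")] = eff
    for idx, eff in config.td_effects.items():
        genes.iloc[idx, genes.columns.get_loc("td_log2fc")] = eff
    m = np.power(2.0, baseline_log2)
    l = np.where(np.isneginf(lymph_log2), 0.0, np.power(2.0, lymph_log2))
    return genes, m, l


def expected_means(config: SimConfig, genes: pd.DataFrame,
                   samples: pd.DataFrame, pool_effects: np.ndarray
                   ) -> np.ndarray:
    """Noise-free expected expression mu[g, s] under the mixture model."""
    m = np.power(2.0, genes["baseline_log2"].to_numpy())
    l = np.where(np.isneginf(genes["lymph_log2"].to_numpy()), 0.0,
                 np.power(2.0, genes["lymph_log2"].to_numpy()))
    phen_eff = genes["phenotype_log2fc"].to_numpy()
    td_eff = genes["td_log2fc"].to_numpy()

    pool_index = {p: i for i, p in enumerate(sorted(samples["pool"].unique()))}
    n_genes, n_samples = len(genes), len(samples)
    mu = np.empty((n_genes, n_samples))
    f = samples["contamination"].to_numpy()
    L = samples["library_factor"].to_numpy()
    is_ssm = (samples["phenotype"] == "-").to_numpy()
    td = samples["td"].to_numpy()
    for s in range(n_samples):
        log2_effect = (pool_effects[:, pool_index[samples["pool"].iloc[s]]]
                       + phen_eff * is_ssm[s] + td_eff * td[s])
        mac = m * np.power(2.0, log2_effect)
        mu[:, s] = L[s] * ((1.0 - f[s]) * mac + f[s] * l)
    if (mu > _MU_OVERFLOW).any():
        raise OverflowError("expected expression exceeds overflow guard 1e12")
    return mu


def generate_counts(config: SimConfig, seed: int | None = None
                    ) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate the factorial-design NB count matrix plus ground truth.

    Draw order (one generator, seeded once): gene baselines, pool-shared
    perturbations, library factors, NB counts. Fully reproducible from
    ``seed`` (defaults to ``config.seed``). If ``config.gene_seed`` is set,
    the gene-level draws (baselines, pool perturbations) come from their own
    generator so two datasets can share one biology while being sampled
    independently.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_rng = rng if config.gene_seed is None \
        else np.random.default_rng(config.gene_seed)

    meta = canonical_metadata(pools=config.pools, platform="rnaseq")
    n_samples = config.n_samples

    genes, _, _ = _gene_table(config, gene_rng)
    pool_effects = gene_rng.normal(0.0, config.pool_effect_sd,
                                   size=(config.n_genes, config.pools)) \
        if config.pool_effect_sd > 0 else np.zeros((config.n_genes, config.pools))
    lo, hi = config.library_size_range
    library = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples))

    f = np.broadcast_to(
        np.atleast_1d(np.asarray(config.contamination_fractions, dtype=float)),
        (n_samples,)).copy()

    samples = meta.copy()
    samples["contamination"] = f
    samples["library_factor"] = library

    mu = expected_means(config, genes, samples, pool_effects)

    alpha = np.broadcast_to(
        np.atleast_1d(np.asarray(config.dispersion_alpha, dtype=float)),
        (config.n_genes,)).copy()
    r = 1.0 / alpha
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p).astype(np.int64)

    values = pd.DataFrame(counts, index=genes.index, columns=meta.index)
    em = ExpressionMatrix(values, "counts", meta)
    truth = SimTruth(
        genes=genes,
        samples=samples,
        expected=pd.DataFrame(mu, index=genes.index, columns=meta.index),
    )
    log_stage("generate_counts", genes=config.n_genes, samples=n_samples,
              seed=config.seed if seed is None else seed)
    return em, truth


def generate_microarray(counts: ExpressionMatrix, config: SimConfig,
                        seed: int | None = None) -> ProbeMatrix:
    """Probe-level microarray twin of a synthetic counts dataset.

    Each gene gets k probes (k uniform on the configured inclusive range);
    probe value = gene log2-CPM abundance + a fixed probe offset
    (N(0, probe_offset_sd)) + cell-wise Gaussian noise (N(0, noise_sd_array)).
    Draw order: probe counts, probe offsets, noise. Reproducible from
    ``seed`` (defaults to ``config.seed + 1`` so the counts and the twin can
    share one config).
    """
    config.validate()
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    abundance = log_transform_counts(counts).values  # genes x samples, log2

    klo, khi = config.probes_per_gene
    n_genes = abundance.shape[0]
    k = rng.integers(klo, khi + 1, n_genes) if khi > klo \
        else np.full(n_genes, klo)
    total = int(k.sum())
    offsets = rng.normal(0.0, config.probe_offset_sd, total) \
        if config.probe_offset_sd > 0 else np.zeros(total)
    noise = rng.normal(0.0, config.noise_sd_array,
                       (total, abundance.shape[1])) \
        if config.noise_sd_array > 0 else np.zeros((total, abundance.shape[1]))

    probe_ids, gene_of_probe, rows = [], [], []
    pos = 0
    gene_values = abundance.to_numpy()
    for gi, gene in enumerate(abundance.index):
        for j in range(k[gi]):
            probe_ids.append(f"{gene}_p{j + 1}")
            gene_of_probe.append(gene)
            rows.append(gene_values[gi] + offsets[pos] + noise[pos])
            pos += 1
    values = pd.DataFrame(np.vstack(rows),
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=abundance.columns)
    pm = ProbeMatrix(values, pd.Series(gene_of_probe, index=probe_ids))
    log_stage("generate_microarray", genes=n_genes, probes=total,
              samples=abundance.shape[1])
    return pm
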