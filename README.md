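# lnmacs

Transcriptomic analysis of sorted lymph-node macrophage subsets: count
filtering, negative-binomial likelihood-ratio differential expression,
cross-platform (RNA-seq vs microarray) harmonization, and lineage-signature
contamination QC, plus a synthetic-data generator that emulates the
factorial study design.

## The problem

Sub-capsular sinus macrophages (SSMs) line the lymph-node sub-capsular
sinus and act as gatekeepers for particulate antigens. They are fragile:
during tissue dissociation they shed membrane blebs that stick to
lymphocytes, so sorted "macrophage" events are easily contaminated with
B-/T-cell material. This package implements the computational side of
profiling such sorted populations:

1. **Design.** 16 samples = 4 biological pools x {tumor-draining TD=1,
   non-draining TD=0} x {CD11c+ MSM ("+"), CD11c- SSM ("-")}.
2. **Differential expression.** Per gene *i*, counts are modeled as
   negative binomial with log link and median-of-ratios size factors
   `s_j` as offset:

   `log mu_ij = log s_j + b0 + b1*Pool + b2*TD + b3*Phenotype`,
   `Var = mu + alpha*mu^2`.

   Two nested comparisons are tested by likelihood ratio (chi-square,
   df = 1): **C1** drops Phenotype (SSM vs MSM contrast, adjusted for Pool
   and TD) and **C2** drops TD (tumor-draining contrast, adjusted for Pool
   and Phenotype). P-values are Holm step-down adjusted; genes are called
   differentially expressed when `p_holm < 0.01` and base mean > 100
   normalized reads. Positive log2 fold changes mean "up in SSM" (C1) or
   "up in tumor-draining" (C2). The dispersion is estimated per gene by
   Cox-Reid adjusted profile likelihood and moderated across genes
   (mean-dispersion trend + empirical-Bayes MAP), which keeps the
   chi-square reference calibrated at n = 16.
3. **Cross-platform harmonization.** Probe-level microarray intensities
   are averaged per gene; RNA-seq counts become log2-CPM(+1); genes
   detected on only one platform are dropped; each sample is z-scored; and
   per-gene platform means are compared by Pearson correlation as the
   comparability check.
4. **Contamination QC.** Lineage signatures (sum of marker expression over
   fixed B-cell, T-cell, macrophage and housekeeping panels) are
   referenced to the housekeeping signature; ratio distributions between
   datasets are compared with an exact Mann-Whitney U test.

## Worked example

```python
import lnmacs as L

# a synthetic dataset with the canonical design and 100 planted
# phenotype effects (log2 fold change 2, positive = up in SSM)
eff = {i: 2.0 for i in range(37, 137)}
cfg = L.SimConfig(n_genes=2000, phenotype_effects=eff, seed=1)
counts, truth = L.generate_counts(cfg)

filtered = L.filter_genes(counts)                 # total >= 10, detected >= 2
model = L.NBDifferentialExpression(filtered, comparison="C1")
res = model.fit()
print(res.summary())
```

prints

```
NB GLM likelihood-ratio differential expression
  comparison:        C1 (tested factor: phenotype)
  genes tested:      2000
  genes failed:      0
  dispersion:        trend-moderated MAP (Cox-Reid)
  DEG (p_holm<0.01, base_mean>100): 50 (50 up, 0 down)
  top genes by p_holm:
    G00077       base_mean=    267.4 log2_fc= +2.13 p_holm=8.05e-43
    G00025       base_mean=    200.1 log2_fc= +2.39 p_holm=3.11e-41
    ...
```

i.e. the planted SSM-high genes are recovered with the right sign and
magnitude, and only genes above the base-mean threshold are listed as DEGs.
Contamination QC against a heavily contaminated "legacy" dataset:

```python
from lnmacs.harmonize import log_transform_counts, standardize_samples

dirty_cfg = L.SimConfig(n_genes=2000, contamination_fractions=0.25,
                        seed=2, gene_seed=1)
dirty, _ = L.generate_counts(dirty_cfg)
za = standardize_samples(log_transform_counts(counts))
zb = standardize_samples(log_transform_counts(dirty))
report = L.contamination_report(za, zb)
for panel, row in report["panels"].items():
    print(panel, round(row["median_a"], 3), round(row["median_b"], 3),
          "p=%.2g" % row["p_value"])
```

prints

```
bcell 0.608 0.918 p=1.5e-06
tcell 0.75 1.126 p=1.5e-06
housekeeping 1.0 1.0 p=1
macrophage 0.824 0.816 p=0.75
```

— the B/T-cell signature ratios are significantly lower in the clean
dataset while housekeeping and macrophage signatures stay flat, which is
exactly the read-out used to certify a well-sorted preparation.

The same stages are available from the shell:

```bash
lnmacs simulate --seed 1 --out sim/
lnmacs filter sim/counts.tsv --out sim/filtered.tsv
lnmacs de sim/filtered.tsv sim/metadata.tsv --comparison C1 --out de/
lnmacs harmonize --counts sim/counts.tsv --probes sim/probes.tsv \
       --probe-map sim/probe_map.tsv --out harmonized/
lnmacs contamination --counts sim/counts.tsv --probes sim/probes.tsv \
       --probe-map sim/probe_map.tsv --out contamination/
lnmacs pipeline --config config.yaml --out run/
```

## Docs

`docs/methods.md` describes the statistical model, the synthetic-data
generator and all numerical choices in detail.
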