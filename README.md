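# sepstrat

Transcriptomic stratification of sepsis patients, with genetics.

Sepsis is a clinically heterogeneous syndrome: patients with the same
diagnosis mount very different immune responses, which is a major reason
immunomodulatory trials fail. `sepstrat` implements, as a reusable and
tested pipeline, the analysis chain that resolves this heterogeneity
from blood leucocyte expression profiles and relates it to outcome and
genetic variation:

1. **SRS discovery** — unsupervised stratification of patients into
   sepsis response signature (SRS) groups: Ward hierarchical clustering
   (Euclidean distance) on the most variable 10% of probes, consolidated
   by k-means from the hierarchical centroids, with the number of groups
   fixed by a permutation-calibrated within-group sum-of-squares elbow.
   SRS1 — the group with a majority-downregulated expression program —
   is the immunosuppressed, higher-mortality phenotype.
2. **Differential expression** — per-probe linear models with
   empirical-Bayes variance moderation: the moderated t shrinks each
   gene's variance toward a scaled-inverse-chi-square prior
   `(d0, s0²)` estimated from all genes, and calls are made at
   |FC| > 1.5, Benjamini-Hochberg FDR < 0.05.
3. **Sparse gene classifier** — L1-penalised logistic regression over a
   penalty path (extended-BIC model choice), with leakage-free
   leave-one-out cross-validation and exact model serialization for
   assigning SRS labels to new cohorts.
4. **Directional gene-set rotation test** — signed mean moderated t of a
   signature (e.g. an endotoxin-tolerance program), with the null
   generated by random rotation of the design's effect space, preserving
   gene-gene correlation.
5. **eQTL mapping** — additive-model associations between SNP dosage and
   expression with expression principal components as covariates,
   cis (< 1 Mb from the probe start) and trans (> 2.5 Mb or
   cross-chromosome, autosomes only) streams with separate FDR, lead-SNP
   reporting, SRS-group-specific calling (FDR < 0.01 in one group,
   > 0.05 in the other) and context comparison.
6. **Epigenetic-mark enrichment** — Fisher overlap and
   distance-to-nearest-mark Mann-Whitney tests of lead eSNPs against all
   SNPs within 1 Mb of a probe.
7. **Survival** — Kaplan-Meier curves, log-rank, Cox proportional
   hazards (Efron ties), fixed-horizon mortality and group covariate
   comparison tables.

Patient-level data of this kind cannot be redistributed, so the package
includes a first-class **synthetic cohort generator**
(`sepstrat.simulate`) that emulates the statistical structure these
stages assume — two unequal latent groups, a majority-downregulated DE
program, inverse-chi-square gene variances, planted cis/trans and
group-specific eQTL, a cell-proportion confounder, group-dependent
hazard, and mark intervals enriched at true regulatory SNPs — and
returns the ground truth against which recovery is scored. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
import pandas as pd
from sepstrat import SimConfig, simulate_cohort, SrsDiscovery, DifferentialExpression
from sepstrat.survival import cox_fit, mortality_at

cfg = SimConfig(seed=1, n_probes=3000, n_snps=1200, n_de_probes=350,
                n_cis_eqtl=80, n_trans_eqtl=10, n_group_specific=10)
cohort = simulate_cohort(cfg)

assignment = SrsDiscovery(cohort.expression).fit()
print(assignment.summary())

de = DifferentialExpression.from_expression(cohort.expression, assignment.labels).fit()
print(de.summary())

meta = cohort.metadata.table
cox = cox_fit(meta["time"], meta["event"],
              pd.DataFrame({"srs1": (assignment.labels.loc[meta.index] == "SRS1").astype(float)}))
print(cox.summary())
```

prints

```
SRS group discovery
  probes clustered: 300
  chosen k:         2
  SRS1: 109 (41%)
  SRS2: 156 (59%)
  WSS by k: 2:31907.7, 3:31534.9, 4:31213.1
  orientation: SRS1 = group with majority of DE probes (p<0.01) downregulated
Differential expression (moderated t)
  probes tested:        3000
  prior df (d0):        3.61
  prior variance (s0^2): 0.05186
  called (FC>1.5, FDR<0.05): 344
  downregulated in SRS1: 253 (73.5% of called)
Cox PH (srs1): HR 2.49, 95% CI 1.90-3.25, Wald p=3.23e-11, score p=7.81e-12, 225/265 events
```

Reading this: the clusterer recovers the two planted response groups at
their 41/59 split and chooses k = 2 because further splits reduce the
within-group sum of squares no more than permuted (structure-free) data
would; 344 probes pass the fold-change and FDR calls with 73.5%
downregulated in SRS1 (the planted immunosuppressed program); and SRS1
membership carries a hazard ratio near the planted 2.4 for survival.

The same stages run from the shell via the `sepstrat` CLI
(`simulate`, `discover`, `de`, `classify train|apply`,
`geneset derive|test`, `eqtl`, `epimarks`, `survive`), and

```bash
sepstrat pipeline run --seed 1 --scale 0.12 --out demo/
```

executes everything end to end, writing per-stage TSV/VCF/BED outputs, a
SHA-256 manifest (reruns are bit-identical) and `demo/report.md` with a
recovery-vs-truth section.

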