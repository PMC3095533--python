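# nbsubtype

Unsupervised discovery of four molecular subgroups in neuroblastoma (NB)
expression cohorts, and a 6-gene signature classifier that reproduces the
subgrouping from just **ALK, BIRC5, CCND1, MYCN, NTRK1** and **PHOX2B**.

Neuroblastoma tumours fall into genomically defined subtypes (Type 1:
favourable/triploid; Type 2A: 11q-deleted without *MYCN* amplification;
Type 2B: *MYCN*-amplified), but expression profiling suggests a finer,
four-group structure — including a fourth group of mostly 11q-deleted,
non-amplified, high-stage tumours with globally low expression of all six
signature genes. This package implements the complete discovery and
verification workflow as a tested, reusable pipeline for users with their
own log2 expression matrices (genes × samples, TSV), plus a synthetic
cohort generator that stands in for the original microarray data.

## The workflow

1. **Preprocess** — drop probes/genes with max log2 expression < 6,
   collapse probes to gene symbols by mean, variance-filter at ≈ 0.4.
2. **Discover** — PCA (3 components) of each cohort; samples are joined to
   their nearest Euclidean neighbour in score space and connected groups
   form the PCA clusters p1–p4; leave-one-out reruns quantify per-sample
   stability.
3. **Classify** — each sample's 6-gene profile in SD units is matched
   against per-group interval rules (UP: ≥ +t, DOWN: ≤ −t, NEUTRAL: |·| < t,
   default t = 0.5 SD); a sample joins r-group *g* if ≥ 5 of 6 genes agree
   with *g*'s rules and no other group also qualifies, otherwise it stays
   unassigned (ND).
4. **Gene set** — per cohort, SAM-style one-vs-rest moderated statistics
   d = (x̄_g − x̄_rest)/(s + s0) with pooled permutation p-values; the top
   4000 significant genes with fold change > 2 are intersected across
   cohorts, and the 30 genes with the highest combined (mean) log2 fold
   change per contrast form the discriminative union set.
5. **Verify** — average-linkage hierarchical clustering (Euclidean on
   per-gene standardized values) of an independent cohort on the union set,
   cut into 4 groups (h1–h4); samples falling between branches are rescued
   by their nearest assigned neighbour in PCA score space.
6. **Validate** — PCA loadings fitted on one cohort project the others onto
   the same components; per-dataset p-values are combined as
   Σ √(nᵢ/N)·zᵢ (weights square-sum to 1).
7. **Associate** — Fisher exact enrichment of clinical factors per cluster,
   ANOVA/Tukey and Welch tests for the signature genes, Kaplan–Meier /
   log-rank survival, five-year Fisher tests, and the genomic-subtype
   (Type 1 / 2A / 2B / Other) cross-tabulation.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from nbsubtype import (CohortSpec, generate_dataset_pair,
                       filter_low_expression, discover_subgroups,
                       classify_cohort)

spec = CohortSpec(n_samples=(24, 36), seed=7)      # two-platform study
(expr1, clin1, truth1), (expr2, clin2, truth2) = generate_dataset_pair(spec)

for name, expr, truth in [("ds1", expr1, truth1), ("ds2", expr2, truth2)]:
    filtered = filter_low_expression(expr, 6.0)
    assign, pca = discover_subgroups(filtered)
    ari = adjusted_rand_score(truth.labels, assign.labels)
    rules = classify_cohort(filtered)
    agree = (rules.labels[rules.labels != 0]
             == truth.labels[rules.labels != 0]).mean()
    print(f"{name}: {filtered.n_genes} genes after floor filter, "
          f"{assign.k} PCA clusters (ARI vs truth {ari:.2f}); "
          f"rule classifier: {len(rules.assigned())} assigned / "
          f"{rules.n_unassigned} ND, accuracy among assigned {agree:.2f}")
```

prints

```
ds1: 1900 genes after floor filter, 4 PCA clusters (ARI vs truth 1.00); rule classifier: 16 assigned / 8 ND, accuracy among assigned 1.00
ds2: 1901 genes after floor filter, 4 PCA clusters (ARI vs truth 1.00); rule classifier: 25 assigned / 11 ND, accuracy among assigned 1.00
```

Both synthetic cohorts yield exactly four PCA clusters that match the
planted subgroups perfectly (adjusted Rand index 1.0). The 6-gene rule
classifier assigns about two thirds of the samples — the rest are ND, the
deliberate reject option of a 5-of-6 agreement rule under noise — and every
assigned sample lands in its true subgroup.

The same chain is available from the shell:

```bash
nbsubtype run-all --seed 7 --out results/run
```

which generates a three-dataset synthetic study (two discovery cohorts plus
a verification cohort), runs discover → classify → geneset → verify →
project → associate, and writes every stage's TSV outputs together with a
JSON run manifest (config snapshot, input digests, per-stage outputs) that
is byte-identical across reruns with the same seed.

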