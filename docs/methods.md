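# Methods

This note documents the modelling choices, conventions and numerical
details behind `nbsubtype`, and what the synthetic-data tests do and do not
establish about real cohorts.

## Discovery: PCA and nearest-neighbour joining

Each cohort is variance-filtered (sample variance on log2 values, n−1
denominator, inclusive cutoff, default 0.4), per-gene standardized, and
decomposed by SVD of the sample-centered matrix. Components follow a
deterministic sign convention (the largest-magnitude loading entry of each
component is positive) so repeated fits and cross-dataset comparisons are
stable. Clustering operates on the first three score dimensions.

Subgroups come from nearest-neighbour joining: every sample contributes an
undirected edge to its single nearest Euclidean neighbour (ties broken by
smallest sample index) and connected samples form a group. A mathematical
caveat drives one design decision here: the 1-NN graph of even a perfectly
separated Gaussian point cloud fragments into mutual-NN islands — the
fragmentation is scale-free, so tightening the cloud does not heal it. The
raw graph therefore subdivides true subgroups. `discover_subgroups` runs
the joining in a *consolidating* mode: raw components are merged by single
linkage (minimum inter-group distance, i.e. the same joining rule applied
at the group level), and the agglomeration stops at the largest relative
jump in the join-distance sequence, seeded with the largest within-group
join distance already accepted. A jump must exceed `gap_factor` (default
2.0) to stop the merging; otherwise everything coalesces into one group.
This keeps the procedure purely distance-driven — no preset cluster count —
while recovering well-separated groups exactly. `nn_join_clusters` with
default arguments still returns the raw graph components.

Leave-one-out stability reruns the whole chain without each sample in
turn. Reduced-run clusters are matched to full-run clusters by greedy
maximum member overlap (ties by label order); unmatched reduced clusters
receive fresh labels, so every member of a cluster that did not exist in
the full run counts as shifted. The per-sample shift fraction aggregates
over all reruns in which the sample participated. Degenerate reruns (e.g.
the variance filter empties the matrix) are skipped with a warning.

## The 6-gene rule classifier

Profiles are per-gene standardized expression (mean 0, SD 1, n−1) of ALK,
BIRC5, CCND1, MYCN, NTRK1 and PHOX2B across the cohort. Each subgroup
r1–r4 states a direction per gene — UP (value ≥ +t), DOWN (≤ −t) or
NEUTRAL (|value| < t) — with a single symmetric threshold t (default
0.5 SD). A sample is assigned to the unique group whose intervals at least
`min_agree` = 5 of the 6 genes satisfy; zero or multiple qualifying groups
leave it unassigned (ND). Ambiguity deliberately maps to ND rather than a
tie-break: the classifier is conservative by construction.

The default directions are the per-group fold-change *sign pattern* of the
six genes: r1 {ALK−, BIRC5−, CCND1+, MYCN−, NTRK1+, PHOX2B+}, r2 {ALK+,
BIRC5+, CCND1+, MYCN·, NTRK1+, PHOX2B+}, r3 {ALK+, BIRC5+, CCND1·, MYCN+,
NTRK1−, PHOX2B·}, r4 all −, where · is NEUTRAL. Using one consistent
sign map for both the rules and the generator's canonical effect table
guarantees the self-consistency property that every canonical profile
classifies into its own group; the original interval table is not public,
so users can load replacement rules from YAML (`classify --rules`).

Classifier accuracy in tests is reported **among assigned samples**: the
rule set has an explicit reject option, and the reject rate (not the
error rate) is the quantity that grows with noise. ND fractions are
reported separately and are checked to be non-decreasing in profile noise.

## SAM-style differential expression and meta-combination

For each one-vs-rest contrast the statistic is the moderated t
d = (x̄_g − x̄_rest)/(s + s0), with s the pooled two-group standard error
and the fudge factor s0 defaulting to the median of all gene-wise standard
errors — the classic SAM heuristic that tempers near-constant genes. At
s0 = 0 the statistic reduces exactly to the pooled-variance two-sample t.

Significance comes from group-size-preserving label permutations with the
permuted |d*| pooled across genes:
p = (1 + #{|d*| ≥ |d|}/n_genes)/(n_perm + 1). The add-one convention keeps
p in (0, 1]; the ≥ comparison uses a relative tolerance of 1e−9 so that
the observed split, when it reappears among permutations, counts as a tie
regardless of floating-point evaluation order. An `exhaustive` mode
enumerates all distinct splits instead of sampling. No FDR machinery is
attached: selection is by rank (top 4000 by p, ties by |d| then symbol)
followed by a strict fold-change filter (|log2 FC| > 1, i.e. fold > 2).

Per-contrast lists from ≥ 2 cohorts are intersected; a gene's combined
log2 fold change is the arithmetic mean of its per-dataset values, and the
30 genes with the largest |combined FC| per contrast (ties by symbol) are
unioned without duplicates.

Cross-dataset evidence is combined as combined_z = Σ √(nᵢ/N)·zᵢ, where
zᵢ is the signed standard-normal quantile of the two-sided p (sign from
the fold-change direction). The weights square-sum to 1, so the combined
statistic is standard normal under the null — verified by simulation at
10,000 genes. p-values of exactly 0 or 1 are clamped to machine-safe
bounds with a warning.

## Hierarchical verification

Verification clusters an independent cohort on the discriminative union
set: UPGMA (average linkage) on Euclidean distances over per-gene
standardized values. Standardization makes Euclidean distance a monotone
function of (1 − Pearson correlation) across samples, which is how the
"Euclidean metric (Pearson correlation)" ambiguity is resolved; a
`metric="correlation"` option remains available. The dendrogram is cut at
the standard k = 4 level; branches smaller than `min_cluster_size`
(default 3) are marked unassigned — the operational reading of samples
"falling between" dendrogram trees — and rescued by the label of their
nearest assigned neighbour in PCA score space. Rescue never alters an
assigned label and is idempotent. Gene-axis clustering (default k = 5)
uses the same linkage.

## Cross-projection

Loadings are fitted on one cohort after restriction to the common gene set
and per-gene standardization; rank-deficient inputs (explained variance of
the last requested component ≤ 1e−10 of the first) are rejected rather
than silently zero-padded. Targets are standardized with their *own*
per-gene statistics before projection, so the model carries no centering
constants and platform-level location differences cannot leak into the
scores. Self-projection reproduces the fitted scores to < 1e−8.

## Clinical statistics

Fisher exact tests are two-sided (probability-ordering definition);
enrichment tables are factor × cluster-vs-rest with unknowns excluded
pairwise and no multiple-testing correction by default (a Bonferroni flag
exists). "High stage" means INSS 3 or 4; stage 4S is its own stratum and
never counts as high. ANOVA is the classic one-way F with Tukey HSD
(Tukey–Kramer at unequal sizes); two-group comparisons use Welch's t with
Satterthwaite degrees of freedom. Kaplan–Meier follows the product-limit
convention (events before censorings at tied times); log-rank is
Mantel–Cox with df = groups − 1; the five-year comparison is a Fisher test
of dead-vs-alive at 60 months with subjects censored earlier excluded.

Genomic subtypes: MNA ⇒ Type 2B; del11q without MNA ⇒ Type 2A; INSS 1–3
with **all** of MNA, del11q, del1p, del3p absent and not dead of disease ⇒
Type 1 (the and/or chain is read as absence of all four — the only reading
that makes Type 1 favourable); anything else, including rule-relevant
unknown flags, ⇒ Other. The mapping is total over tri-state inputs.

## The synthetic cohort generator

`CohortSpec` plants four subgroups (default proportions 0.30/0.25/0.25/
0.20, allocated by largest remainder so cohort-level proportions are exact,
then shuffled) into log2 expression matrices with:

- per-gene baselines Uniform(6, 12) log2, with a small fraction (5%) of
  low-expressed genes at Uniform(3, 4.5) to exercise the floor filter;
- the canonical 4 × 6 signature-effect table (entries ±1 / ±2 SD units
  following the six genes' per-group fold-change signs; group 4 entirely
  non-positive), realised as mean shifts of `effect × signature_scale`
  log2 units. `signature_scale` defaults to 1.0 log2 per SD unit — a "+"
  is a 2-fold, a "++" a 4-fold change, in line with the large fold changes
  these genes show between NB subtypes. The scale is deliberately **not**
  tied to `noise_sd`: shifts that scale with the noise would make the
  standardized profile exactly noise-invariant, so lowering the noise
  would never sharpen the planted structure;
- per-group marker blocks (default 40 genes/group, +2.0 log2 in their own
  group only) that give the discovery and verification stages a
  discriminative gene set to find;
- a planted *MYC* gene anti-correlated with *MYCN* (high outside the
  MNA-like group 3, strongly down inside it) so the MYCN/c-MYC
  correlation check has signal;
- i.i.d. Gaussian noise (default SD 0.5 log2) — at this level the 0.4
  variance cutoff separates informative from background genes, mirroring
  the strong reduction the variance slider achieved on the real arrays;
- clinical factors drawn per group (MNA 0.90 in group 3 and 0.05
  elsewhere; del11q 0.70 in groups 2 and 4; stage-4 probability rising
  1 → 3 then easing for group 4), with 5% of tri-state entries blanked to
  exercise unknown handling;
- exponential survival per group (worst in group 3, then 4, 2, 1; rates
  per month chosen so 5-year survival spans ≈ 40–97%), independent
  exponential censoring capped at 120 months, and EFS times dominated by
  OS.

Two- and three-platform studies share exactly
round(`shared_gene_fraction` × `n_genes`) symbols, always including the
signature, MYC and all marker blocks; generation is bitwise-reproducible
from the seed.

What the generator does **not** emulate: probe-level array physics, batch
and amplification effects, heteroscedastic or heavy-tailed noise,
correlated gene modules beyond the planted blocks, and informative
censoring. Passing tests therefore demonstrate that the pipeline's logic
recovers structure of the planted kind at realistic effect sizes — not
that real cohorts contain that structure.

## Problem sizes and numerical conventions

Tests and the acceptance script use cohorts of 24–100 samples and
600–2000 genes, 60–200 permutations, and 10–20 seeds per property — sizes
at which every checked property is stable while the full suite stays
fast. Determinism throughout comes from explicit seeds (`numpy`
`default_rng`), symbol-based tie-breaks in every ranking, the PCA sign
convention, and smallest-index tie-breaks in nearest-neighbour searches.
Degenerate inputs fail loudly: empty matrices after filtering, constant
signature genes, rank-deficient projection sources, groups with fewer than
two members, and survival inputs without events all raise with the cause
named.

## Known limitations

- The original SD-interval table behind the r-group rules is not public;
  the sign-pattern surrogate with a single symmetric threshold is a
  documented stand-in, and rule files can be substituted.
- The consolidation gap rule has one free constant (`gap_factor` = 2.0);
  data with genuinely hierarchical cluster structure at multiple scales
  may cut at a different level than a human reading of a 3-D score plot.
- Permutation p-values are pooled across genes (SAM convention), which
  assumes roughly exchangeable null distributions across genes; strongly
  heteroscedastic genes would call for per-gene nulls.
- The pipeline assumes pre-normalized log2 expression; no cross-array
  normalization or batch correction is provided.
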