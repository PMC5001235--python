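# dcorstrat

Functional stratification of cancer patients from their somatic-mutation
gene lists, using the distance correlation between the lists' expression
profiles over a shared cohort.

## The problem

Cancer patients rarely share mutated genes: in a typical breast-cancer
cohort the overwhelming majority of patient pairs have zero overlap between
their lists of protein-disrupting mutations, so the mutation lists
themselves cannot stratify patients. But two different gene lists can play
the same functional role — they may perturb the same module of co-expressed
genes. `dcorstrat` compares patients by how similarly their mutated gene
sets *organize the cohort in expression space* rather than by which genes
they share.

## The statistic

For a patient *a* with SMG list g_a (SMG = significantly mutated gene: a
gene carrying a frame-shift indel, splice-site, non-stop or nonsense
mutation), the expression submatrix E^a ∈ ℝ^(n_a × N) restricts the cohort
expression matrix to those genes. Each patient then induces an N × N
Euclidean distance matrix over the cohort samples,

    d_jk^a = ‖e_j^a − e_k^a‖ ,

which is double-centered (row means, column means and grand mean removed).
The similarity of two patients is the distance correlation of their
centered distance matrices,

    dCov(E^a, E^b) = (1/N²) Σ_jk  d̄_jk^a · d̄_jk^b
    dCor(E^a, E^b) = dCov(E^a, E^b) / √( dCov(E^a,E^a) · dCov(E^b,E^b) ) ,

the biased V-statistic form, in [0, 1], sensitive to nonlinear as well as
linear dependence. The P × P matrix D_dCor over all patients is turned into
the dissimilarity 1 − D_dCor, embedded in 3-D with classical (Torgerson)
multidimensional scaling for visualization, and partitioned with replicated
squared-Euclidean K-means. Downstream stages test per-cluster enrichment of
hormone-receptor subtypes (ER/PR/HER2, triple-negative; cluster-vs-rest
chi-square, Bonferroni-adjusted), run three negative controls (Jaccard
overlap sparsity, size-matched pseudo-SMG profiles, a structure-free
background expression table), and validate cluster-specific gene sets as
survival signatures (K = 2 expression split, Kaplan-Meier curves, log-rank
test).

## Worked example

No external data is needed: the package ships a synthetic-cohort generator
that plants functional gene modules driving both expression covariance and
SMG membership, with one group enriched for marker-negative status and an
elevated event hazard.

```sh
dcorstrat simulate --seed 7 --outdir cohort
dcorstrat run-all --maf cohort/mutations.maf.tsv \
    --expression cohort/expression.tsv --clinical cohort/clinical.tsv \
    --transform none -k 3 --seed 7 --outdir run
```

prints

```
pipeline complete; manifest at run/manifest.json
{"cluster": {"K": 3, "within_ss": 25.618448730908497, "mean_silhouette": 0.9186468712051256, "seconds": 0.215}}
```

a mean silhouette of 0.92 at K = 3 — three well-separated functional
groups. `run/enrichment.tsv` holds the cluster-vs-rest subtype tests:

```
cluster  marker  n_known  cluster_pos  cluster_neg  rest_pos  rest_neg  statistic  raw_p        adj_p        method
1        ER      150      21           29           76        24        16.8644    4.01471e-05  0.000120441  chi-square+bonferroni
2        ER      150      37           13           60        40        2.85937    0.0908433    0.27253      chi-square+bonferroni
```

Cluster 1 is the distinguished group: 29/50 of its patients are ER-negative
against 24/100 of the rest (adjusted p ≈ 1.2 × 10⁻⁴). Its cluster-specific
SMGs then act as a survival signature on the same cohort:

```sh
dcorstrat survival --expression cohort/expression.tsv \
    --survival cohort/survival.tsv \
    --signature run/cluster1_specific_genes.txt \
    --transform none --seed 7 --outdir surv
# log-rank statistic=9.9664, p=0.001594, groups=(63, 87)
```

The signature splits the cohort into groups with clearly different survival
(the planted high-hazard group), while `run/jaccard_summary.json` confirms
that 66% of patient pairs share no SMG at all — the structure found by
distance correlation is largely invisible to direct gene overlap.

All stage outputs are plain TSV/JSON (dCor matrix, MDS coordinates, cluster
labels and silhouettes, per-cluster gene sets, KM curve points, run
manifest with input checksums and seed), so runs are auditable and
reproducible bit-for-bit given the same seed.

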