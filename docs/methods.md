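# Methods

## The analysis model

The package treats an ETP-ALL cohort as a genes × samples matrix of
normalized log2-scale intensities with a binary group annotation (ETP vs
non-ETP). Three statistical claims are operationalized:

1. **Differential structure.** Genes separating the groups are called by a
   two-tailed unpaired *t*-test with Benjamini–Hochberg step-up FDR
   adjustment and a fold-change gate. Welch's unequal-variance form is the
   default: it is self-contained, conservative, and at the cohort sizes
   this analysis targets (order 12 vs 40) practically indistinguishable
   from a moderated test; the pooled Student form is available via
   `equal_var=True` since the underlying test family is the classical
   unpaired *t*. All thresholds are strict inequalities as stated
   (|Δlog2| > 1 for fold change 2, q < 0.1, sd > 2). Genes constant in
   both groups are defined to have t = 0, p = 1 and are reported
   non-significant rather than erroring out a whole cohort.

2. **Hub structure.** The DE∩variable signature defines the node universe
   of a confidence-filtered interaction network (edges kept at combined
   confidence ≥ 0.4; confidences are never used as weights). Hubs are
   ranked by Maximal Clique Centrality, MCC(v) = Σ over maximal cliques C
   containing v of (|C|−1)!, with two explicit conventions: a node whose
   neighborhood contains no internal edge scores its degree (equivalent to
   the sum — every neighbor then forms a maximal 2-clique — but stated
   because the metric's origin documents it as a special case), and
   isolated nodes score 0. Enumeration is Bron–Kerbosch with pivoting via
   networkx, which handles both the ~100-node signature networks and
   thousand-node converged interactomes. Rank ties break by higher degree,
   then lexicographic gene symbol, making rankings total and reproducible.

3. **Lineage bias.** Per sample: normalized(g) = expr(g) / cohort-mean(g);
   TES(g) = normalized(g) / normalized(PROM1); lineage scores are geometric
   means of TES over the lineage's panel genes; all lineages within 10% of
   the sample maximum are assigned. Geometric means make the score
   scale-free in each gene and bounded by the panel's min and max TES;
   normalizing by the cohort mean removes per-gene platform effects, and
   referencing to PROM1 expresses each marker as a fold change relative to
   the sample's stem-like baseline.

## Interpretation choices the formulas leave open

* **Normalization population.** "Population mean" is read as the mean over
  the scored ETP cohort (the default), because scoring targets ETP samples
  and a cohort-internal mean nullifies cohort-level effects; a
  `population="all"` flag normalizes over every labelled sample instead.
* **The 10% window** is relative (score ≥ 0.9 × max). Scores are ratios,
  so a relative window is the natural reading; an absolute-difference mode
  (`mode="absolute"`) is provided.
* **Expression scale.** Scoring consumes the matrix as deposited. If a
  user believes ratios of linear intensities were intended for log2 data,
  `delog2=True` exponentiates first. Non-positive values abort with an
  error — geometric means are undefined at 0 and a silent pseudo-count
  would change the statistic.
* **Missing panel genes abort scoring**: a partial-panel geometric mean is
  a different statistic, not an approximation of the same one.
* **Probe collapse** keeps the probe with the maximal mean across samples —
  a deterministic, widely used rule; it is configurable because annotation
  pipelines differ, and signature sizes are sensitive to this choice.
* **ROC cutoffs** use Youden's J maximized over midpoints of adjacent
  distinct scores (ties take the lower cutoff); closest-to-(0,1) is
  available. Confusion matrices are reported as percentages of each truth
  class, with direction handling so that markers depressed in ETP (CDH2)
  are evaluated on negated scores and annotated with flipped semantics.
* **PCA gene maps** treat genes as observations (rows) so that proximity
  encodes co-expression; rows are centered, not variance-scaled, by
  default (`scale_rows=True` opts in). Axis signs are fixed by making each
  axis's largest-magnitude loading positive. Hand-drawn lineage boundary
  polygons are replaced by a reproducible surrogate: nearest-centroid
  labels using the marker panel's per-lineage centroids.
* **Enrichment** is an upper-tail hypergeometric test of a query list
  against each gene set intersected with the declared background, gated at
  p < 0.01 and overlap ≥ 6 ("more than 5 genes").

## Synthetic cohorts: what they emulate and what they do not

`generate_cohort` simulates directly on the log2 scale: per-gene baselines
uniform on [4, 12] (typical microarray intensity range), i.i.d. Gaussian
noise, and four planted effects — a ±`de_shift` group shift for up/down
genes, an inflated within-ETP noise sd for variable genes, and a
`lineage_boost` added to a sample's hub-panel genes according to its latent
lineage drawn from `lineage_probs`. PROM1 is never boosted, anchoring the
reference. One seeded generator draws everything in a fixed order
(baselines, noise, lineage labels), so runs are bit-reproducible and a
config change perturbs only downstream draws. Values are floored at 0.1
log2 units to keep the scoring domain strictly positive.

Defaults are the study conditions: 12 ETP vs 40 non-ETP samples, noise sd
0.5 log2 (an ordinary within-group spread for normalized arrays), DE shift
2 log2, inflation factor 5 (inflated sd 2.5, clearing the sd > 2 gate with
margin), lineage boost 2 log2, and lineage probabilities
0.40/0.30/0.15/0.15 for myeloid/B/T/unidentified, echoing a
myeloid-dominant cohort with a substantial B fraction. Mixed lineage truth
is available (`mixed_lineage_prob`) but off by default.

The generator does **not** emulate probe-level artifacts, batch effects,
gene–gene correlation beyond the planted panel structure, or any real
cohort's covariance. Passing recovery tests therefore demonstrates that
the pipeline's inference is correct when its distributional assumptions
hold — not that those assumptions hold in any particular public dataset.

`generate_network` plants each hub as the first member of a dedicated
clique and links consecutive hubs, so hub nodes are strictly the most
clique-central nodes of the planted structure (a clique of size k gives
every member (k−1)!; the hub chain adds the margin that breaks the tie);
background edges are independent Bernoulli draws. For top-k recovery
checks the planted cliques are kept to ≤ k total members so that clique
peers cannot crowd hubs out of the reported list.

## Problem sizes and numerical tolerances

Simulation-based checks run at desk scale, chosen so the full suite
completes in well under a minute while keeping Monte-Carlo error far from
the asserted bounds: null-calibration at 600 genes × 20 seeds (12,000 null
genes), correlation-null calibration at 200 seeds of 150 × 16 matrices,
lineage recovery at 30 ETP samples × 20 seeds, discovery recovery at 5
file-based pipeline runs, oracle equivalences at 200 random graphs (n ≤
12, against an all-subsets clique oracle), 500 AUC instances and 1000 BH
vectors at 1e-12, and 1000 random matrices for the exact TES identity.
The intra-group correlation comparison treats within-group correlation
coefficients as exchangeable observations; under the global null they are
asymptotically uncorrelated, so the nominal 5% level is accurate to
binomial noise, which is what the calibration test asserts.

Exactness claims are literal where floating point allows: TES(PROM1) = 1
by construction (the reference row is set, not recomputed), and scorecards
are bit-identical under per-gene rescaling by powers of two (general
rescaling agrees to 1e-12 relative). The BH implementation delegates to
statsmodels and is checked against a literal step-up oracle; AUC delegates
to scikit-learn's ROC machinery and is checked against the rank-sum form.

## Known limitations

* Welch *t* is not a moderated test; at very small cohorts its power is
  lower than empirical-Bayes alternatives, and signature sizes shift
  accordingly.
* MCC is recomputed from a full clique enumeration; graphs far denser than
  interactome-scale inputs could make enumeration expensive.
* The scoring algorithm presumes the nine-gene panel and PROM1 reference
  are measured and positive; it does not impute.
* Assignment confidence is not quantified: the 10% window is a convention,
  not a calibrated posterior.
* Cross-cohort score comparability depends on each cohort being normalized
  against its own mean; no explicit batch harmonization is provided.
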