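# etplineage

Hub-gene discovery and personalized lineage-bias scoring for early T-cell
precursor acute lymphoblastic leukemia (ETP-ALL) transcriptomes.

ETP-ALL arises from multipotent early thymic progenitors that retain
myeloid and B-lymphoid potential, so the leukemic blasts of different
patients lean towards different hematopoietic lineages. This package is for
computational biologists who want to (a) find the hub genes that organize
that heterogeneity from bulk expression cohorts and (b) quantify each
patient's net lineage bias from a small marker panel — entirely from local
files, with a synthetic-cohort generator providing ground truth for every
stage.

## What it computes

**Discovery.** Genes differential between ETP-ALL and non-ETP-ALL
(two-tailed unpaired Welch *t*, Benjamini–Hochberg FDR < 0.1, fold change
> 2 on log2 data) are intersected with genes variable within the ETP-ALL
cohort (sd > 2 log2 units). A STRING-style interaction network over this
signature (edge confidence ≥ 0.4) is ranked by **Maximal Clique
Centrality**:

    MCC(v) = Σ_{maximal cliques C ∋ v} (|C| − 1)!

(degree for nodes whose neighborhood has no internal edge), and the top-10
nodes are the hub genes.

**Validation.** Each hub gene is re-tested in an independent cohort
(Welch *t* with BH over the hub list) and evaluated as a single-gene
classifier: ROC curve, AUC (rank-sum form, ties half-credited), Youden-J
cutoff and confusion matrix in percent-of-truth-class form, with explicit
direction handling for markers depressed in ETP-ALL (the CDH2 case).

**Scoring** — the core algorithm. For each ETP sample, each panel gene's
expression is normalized to its cohort mean and divided by the sample's
normalized PROM1 (stemness reference), giving a Transformed Expression
Score (TES). Lineage scores are geometric means over the panel:

    myeloid      = (TES_KIT · TES_HGF · TES_ANPEP · TES_CXCL2)^(1/4)
    B            = (TES_NT5E · TES_CXCL2)^(1/2)
    T            = TES_CDH2
    unidentified = (TES_CD33 · TES_IL1B)^(1/2)

Every lineage scoring within 10% of the sample's maximum is assigned, so a
sample can carry a mixed (e.g. myeloid + B) skew.

Supporting modules cover sample-correlation structure comparison, PCA gene
maps of co-expression, cohort bisection with marker tests, hypergeometric
over-representation analysis against GMT collections, and readers/writers
for expression TSV, GEO Series Matrix text, STRING edge lists, GMT and
label files.

## Worked example

`examples/` holds one short script per capability. Scoring a synthetic
12-sample ETP cohort whose latent lineage labels are known
(`python examples/05_lineage_scoring.py`) prints, per sample, the four
lineage scores and the assigned set:

```
sample    myeloid     B       T    unident.  assigned (planted)
ETP001    1.048   0.947   0.770   0.815   myeloid+B            (myeloid)
ETP002    0.892   0.882   1.075   0.794   T                    (T)
ETP003    0.937   0.956   0.927   1.317   unidentified         (unidentified)
...
ETP012    0.919   0.892   0.869   1.223   unidentified         (unidentified)

recovery: 12/12 samples contain their planted lineage in the assigned set
summary: {'T': 5, 'myeloid+B': 3, 'unidentified': 3, 'B': 1}
```

A score of 1.0 means "no skew relative to the PROM1-referenced cohort
mean"; ETP003's unidentified score of 1.32 with the rest below 0.96 is an
unambiguous single-lineage call, while ETP001's B score (0.947) sits
within 10% of its myeloid maximum (1.048), so both lineages are assigned.
The recovery line is the point: with a 2-log2 lineage boost and 0.25-log2
noise, the assigned set contains the simulated truth for every sample.

The same workflow is scriptable from the shell (`etplineage simulate`,
`de`, `hubs`, `roc`, `score`, `pca`, `bisect`, `ora`, `all`), each
subcommand a thin wrapper over the library functions.

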