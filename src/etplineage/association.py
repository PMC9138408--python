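"""Lineage-association analyses around the hub genes.

Covers: normalization of gene expression to a reference group's mean, the
two-dimensional PCA gene map (genes as observations so proximity reflects
co-expression), cohort bisection by a single gene's mean expression with
marker comparisons, and hypergeometric over-representation analysis of gene
lists against GMT collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortLabels
from .diffexpr import bh_adjust, welch_t_test
from .errors import ConfigurationError, DataFormatError
from .io import GeneSetCollection


@dataclass(frozen=True)
class MarkerPanel:
    """Canonical hematopoietic lineage markers used as anchors on the PCA
    gene map; each gene belongs to exactly one lineage here."""

    stemness: tuple[str, ...] = ("CD34",)
    myelomonocytic: tuple[str, ...] = ("CEBPA", "CSF3R")
    b_lineage: tuple[str, ...] = ("EBF1", "PAX5", "CD19", "CD79A")
    t_lineage: tuple[str, ...] = ("CD7", "HES1", "BCL11B", "CD1A")
    dendritic: tuple[str, ...] = ("SPI1", "ITGAX", "IRF8", "TCF4")

    def __post_init__(self):
        seen: dict[str, str] = {}
        for lineage, genes in self.lineage_sets.items():
            if not genes:
                raise ConfigurationError(f"marker set {lineage!r} is empty")
            for g in genes:
                if g in seen:
                    raise ConfigurationError(
                        f"marker {g} in both {seen[g]!r} and {lineage!r}"
                    )
                seen[g] = lineage

    @property
    def lineage_sets(self) -> dict[str, tuple[str, ...]]:
        return {
            "stemness": self.stemness,
            "myelomonocytic": self.myelomonocytic,
            "B": self.b_lineage,
            "T": self.t_lineage,
            "dendritic": self.dendritic,
        }


DEFAULT_MARKERS = MarkerPanel()


def normalize_to_reference_group(
    expr: pd.DataFrame,
    genes: Sequence[str],
    reference_samples: Sequence[str],
) -> pd.DataFrame:
    """Divide each gene row by its mean over the reference samples.

    The reference group's normalized mean is 1 per gene, so cross-group
    comparisons read as fold changes relative to the reference population.
    """
    if len(reference_samples) == 0:
        raise DataFormatError("reference group is empty")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise DataFormatError(f"genes missing from matrix: {missing}")
    missing_s = [s for s in reference_samples if s not in expr.columns]
    if missing_s:
        raise DataFormatError(f"reference samples missing: {missing_s}")
    sub = expr.loc[list(genes)].astype(float)
    ref_mean = sub[list(reference_samples)].mean(axis=1)
    zero = ref_mean[ref_mean == 0]
    if len(zero):
        raise DataFormatError(
            f"zero reference-group mean for genes {list(zero.index)}"
        )
    return sub.div(ref_mean, axis=0)


@dataclass(frozen=True)
class PCAGeneMap:
    """Gene coordinates on the top two principal axes plus the full
    decomposition needed for reconstruction checks."""

    coordinates: pd.DataFrame  # genes x (PC1, PC2)
    explained_variance: np.ndarray  # fractions over all components
    scores: pd.DataFrame  # genes x all components
    loadings: pd.DataFrame  # samples x all components
    row_means: pd.Series  # per-gene centering offsets


def pca_gene_map(
    normalized: pd.DataFrame,
    scale_rows: bool = False,
) -> PCAGeneMap:
    """PCA of a genes x samples matrix with genes as observations.

    Rows (genes) are centered — optionally scaled to unit variance — and
    projected onto the principal axes of their covariance, so proximity on
    the (PC1, PC2) plane reflects co-expression across the cohort. Each
    axis's sign is fixed so that its largest-magnitude loading is positive.
    """
    if normalized.shape[0] < 3 or normalized.shape[1] < 3:
        raise DataFormatError(
            f"need >= 3 genes and >= 3 samples, got {normalized.shape}"
        )
    x = normalized.to_numpy(float)
    sds = x.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = list(normalized.index[sds == 0])
        raise DataFormatError(f"constant gene rows: {bad}")
    row_means = x.mean(axis=1)
    xc = x - row_means[:, None]
    if scale_rows:
        xc = xc / sds[:, None]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| coordinate of each axis positive
    for k in range(s.size):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    explained = s**2 / np.sum(s**2)
    comp_names = [f"PC{i + 1}" for i in range(s.size)]
    return PCAGeneMap(
        coordinates=pd.DataFrame(
            scores[:, :2], index=normalized.index, columns=["PC1", "PC2"]
        ),
        explained_variance=explained,
        scores=pd.DataFrame(
            scores, index=normalized.index, columns=comp_names
        ),
        loadings=pd.DataFrame(
            vt.T, index=normalized.columns, columns=comp_names
        ),
        row_means=pd.Series(row_means, index=normalized.index),
    )


def lineage_centroid_labels(
    coordinates: pd.DataFrame,
    markers: MarkerPanel = DEFAULT_MARKERS,
) -> pd.Series:
    """Nearest-lineage-centroid label for every mapped gene.

    A reproducible surrogate for hand-drawn lineage demarcation boundaries:
    each lineage's centroid is the mean (PC1, PC2) position of its marker
    genes present on the map, and every gene is labelled by its nearest
    centroid (Euclidean distance).
    """
    centroids = {}
    for lineage, genes in markers.lineage_sets.items():
        present = [g for g in genes if g in coordinates.index]
        if present:
            centroids[lineage] = coordinates.loc[present].mean(axis=0)
    if not centroids:
        raise DataFormatError("no marker genes present on the map")
    labels = {}
    for gene, row in coordinates.iterrows():
        dists = {
            lineage: float(np.hypot(*(row - c)))
            for lineage, c in centroids.items()
        }
        labels[gene] = min(sorted(dists), key=dists.get)
    return pd.Series(labels, name="nearest_lineage")


def bisect_cohort_by_gene(
    expr: pd.DataFrame,
    cohort: Sequence[str],
    gene: str,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split a cohort at the gene's cohort-mean expression.

    ``high`` holds samples with expression strictly above the cohort mean,
    ``low`` the complement; either side may be empty (all-equal expression
    puts everyone in ``low``).
    """
    gene = str(gene).upper()
    if gene not in expr.index:
        raise DataFormatError(f"gene {gene!r} not in matrix")
    cohort = list(cohort)
    if len(cohort) < 2:
        raise DataFormatError("cohort must have >= 2 samples")
    vals = expr.loc[gene, cohort].astype(float)
    mean = vals.mean()
    high = frozenset(vals.index[vals > mean])
    return high, frozenset(cohort) - high


def compare_markers(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    markers: Sequence[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-marker two-group comparison with BH adjustment over the list.

    Returns a marker-indexed DataFrame with columns ``mean_a, mean_b, t, p,
    q, quasi_significant`` (the latter flags the 0.05 < p < 0.1 band).
    BH spans only the supplied marker list, mirroring per-figure
    comparisons.
    """
    markers = [str(m).upper() for m in markers]
    missing = [m for m in markers if m not in expr.index]
    if missing:
        raise DataFormatError(f"markers missing from matrix: {missing}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataFormatError("both groups need >= 2 samples")
    rows = []
    for m in markers:
        a = expr.loc[m, list(group_a)].to_numpy(float)
        b = expr.loc[m, list(group_b)].to_numpy(float)
        t, _, p = welch_t_test(a, b, equal_var=equal_var)
        rows.append((m, a.mean(), b.mean(), t, p))
    df = pd.DataFrame(
        rows, columns=["marker", "mean_a", "mean_b", "t", "p"]
    ).set_index("marker")
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["quasi_significant"] = (df["p"] > 0.05) & (df["p"] < 0.1)
    return df


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation outcome."""

    name: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p: float
    overlap_genes: tuple[str, ...] = field(default_factory=tuple)


def ora_hypergeometric(
    query: Sequence[str] | frozenset[str],
    background: Sequence[str] | frozenset[str],
    sets: GeneSetCollection,
    p_thresh: float = 0.01,
    min_overlap: int = 6,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the background before testing; ``p`` is the
    upper-tail probability of at least the observed overlap when the query
    is drawn uniformly from the background. Defaults gate results at
    p < 0.01 and overlap >= 6 (the "more than 5 genes" rule); results are
    sorted by ascending p.
    """
    query = frozenset(str(g).upper() for g in query)
    background = frozenset(str(g).upper() for g in background)
    if not query <= background:
        raise DataFormatError(
            f"query genes outside background: {sorted(query - background)[:5]}"
        )
    if p_thresh <= 0:
        raise ConfigurationError("p_thresh must be positive")
    results = []
    m = len(background)
    n_query = len(query)
    for gs in sets:
        members = gs.genes & background
        if not members:
            continue
        overlap = query & members
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query))
        if k >= min_overlap and p < p_thresh:
            results.append(
                EnrichmentResult(
                    name=gs.name,
                    overlap=k,
                    set_size=len(members),
                    query_size=n_query,
                    background_size=m,
                    p=min(p, 1.0),
                    overlap_genes=tuple(sorted(overlap)),
                )
            )
    return sorted(results, key=lambda r: (r.p, r.name))


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "background_size": r.background_size,
                "p": r.p,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in results
        ]
    )
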