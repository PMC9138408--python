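"""Two-group differential expression and within-group variability.

Differential genes between ETP-ALL and non-ETP-ALL are called with a
two-tailed unpaired t-test (Welch's unequal-variance form by default, the
pooled Student form behind a flag), Benjamini-Hochberg FDR adjustment, and a
fold-change gate. Input matrices are log2-scale, so a fold-change threshold
of 2 is applied as |delta log2| > 1; thresholds are strict inequalities.
Variable genes within the ETP cohort are those with an (n-1)-denominator
standard deviation above a threshold (2 log2 units by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortLabels, ETP, NONETP
from .errors import ConfigurationError, DataFormatError

UP, DOWN, NS = "UP", "DOWN", "NS"


def welch_t_test(
    x: Sequence[float],
    y: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test; returns (t, df, p).

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled Student form. Two constant groups with equal means are defined to
    give t = 0, p = 1 (no evidence of difference) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataFormatError(
            f"need >= 2 observations per group, got {x.size} and {y.size}"
        )
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        # infinite evidence under the model: means differ with no variance
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), float(x.size + y.size - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataFormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_matrices(
    expr: pd.DataFrame, labels: CohortLabels
) -> tuple[np.ndarray, np.ndarray]:
    labels.require_two_groups(min_per_group=2)
    etp = [s for s in labels.etp_samples if s in expr.columns]
    non = [s for s in labels.nonetp_samples if s in expr.columns]
    if len(etp) < 2 or len(non) < 2:
        raise DataFormatError(
            f"matrix holds {len(etp)} ETP / {len(non)} non-ETP labelled "
            "samples; need >= 2 per group"
        )
    return expr[etp].to_numpy(float), expr[non].to_numpy(float)


def differential_expression(
    expr: pd.DataFrame,
    labels: CohortLabels,
    fc_thresh: float = 2.0,
    fdr_thresh: float = 0.1,
    equal_var: bool = False,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-gene ETP vs non-ETP differential expression table.

    Returns a DataFrame indexed by gene with columns
    ``mean_etp, mean_nonetp, log2fc, t, df, p, q, status`` where status is
    UP iff log2fc > log2(fc_thresh) and q < fdr_thresh (DOWN symmetric,
    otherwise NS). ``log_scale=False`` treats values as linear intensities
    and applies the fold-change threshold to their ratio instead.
    """
    if fc_thresh <= 0 or fdr_thresh <= 0:
        raise ConfigurationError("fc_thresh and fdr_thresh must be > 0")
    xe, xn = _group_matrices(expr, labels)
    mean_etp = xe.mean(axis=1)
    mean_non = xn.mean(axis=1)
    res = stats.ttest_ind(xe, xn, axis=1, equal_var=equal_var)
    t = np.array(res.statistic, dtype=float, copy=True)
    df = np.array(res.df, dtype=float, copy=True)
    p = np.array(res.pvalue, dtype=float, copy=True)

    var_e = xe.var(axis=1, ddof=1)
    var_n = xn.var(axis=1, ddof=1)
    flat = (var_e == 0) & (var_n == 0)
    both_equal = flat & (mean_etp == mean_non)
    both_diff = flat & (mean_etp != mean_non)
    t[both_equal], p[both_equal] = 0.0, 1.0
    t[both_diff] = np.where(mean_etp[both_diff] > mean_non[both_diff],
                            np.inf, -np.inf)
    p[both_diff] = 0.0
    df[flat] = float(xe.shape[1] + xn.shape[1] - 2)

    q = bh_adjust(p)
    if log_scale:
        log2fc = mean_etp - mean_non
        fc_gate = np.log2(fc_thresh)
    else:
        if np.any(mean_etp <= 0) or np.any(mean_non <= 0):
            raise DataFormatError(
                "linear-scale mode requires positive group means"
            )
        log2fc = np.log2(mean_etp / mean_non)
        fc_gate = np.log2(fc_thresh)
    status = np.full(expr.shape[0], NS, dtype=object)
    status[(log2fc > fc_gate) & (q < fdr_thresh)] = UP
    status[(log2fc < -fc_gate) & (q < fdr_thresh)] = DOWN
    return pd.DataFrame(
        {
            "mean_etp": mean_etp,
            "mean_nonetp": mean_non,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "status": status,
        },
        index=expr.index,
    )


@dataclass(frozen=True)
class VariableGeneSet:
    """Genes exceeding a within-group standard-deviation threshold."""

    sd: pd.Series  # gene -> within-group sd, only genes above threshold
    threshold: float
    group: str

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.sd.index)

    def __len__(self) -> int:
        return len(self.sd)


def select_variable_genes(
    expr: pd.DataFrame,
    labels: CohortLabels,
    group: str = ETP,
    sd_thresh: float = 2.0,
) -> VariableGeneSet:
    """Genes whose sd over the group's samples strictly exceeds the
    threshold (sample sd, n-1 denominator)."""
    members = [s for s in labels.samples(group) if s in expr.columns]
    if len(members) < 2:
        raise DataFormatError(
            f"group {group} has {len(members)} samples in matrix; need >= 2"
        )
    sd = expr[members].std(axis=1, ddof=1)
    return VariableGeneSet(
        sd=sd[sd > sd_thresh], threshold=sd_thresh, group=group
    )


def intersect_signatures(
    up: frozenset[str] | set[str],
    down: frozenset[str] | set[str],
    variable: frozenset[str] | set[str],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(up ∩ variable, down ∩ variable, their union); the variable genes that
    are also differential form the heterogeneity signature."""
    up, down, variable = frozenset(up), frozenset(down), frozenset(variable)
    overlap = up & down
    if overlap:
        raise DataFormatError(
            f"up and down sets overlap: {sorted(overlap)[:5]}"
        )
    upvar = up & variable
    downvar = down & variable
    return upvar, downvar, upvar | downvar


def pairwise_sample_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation matrix over all genes."""
    if expr.shape[0] < 2:
        raise DataFormatError("need >= 2 genes for sample correlations")
    sds = expr.std(axis=0, ddof=0)
    zero = sds[sds == 0]
    if len(zero):
        raise DataFormatError(
            f"zero-variance samples: {list(zero.index)[:10]}"
        )
    return expr.corr(method="pearson")


def intragroup_correlation_compare(
    corr: pd.DataFrame,
    labels: CohortLabels,
    equal_var: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Within-group correlation coefficients and a two-group t-test.

    Returns (etp_coefficients, nonetp_coefficients, t, p) where each
    coefficient list holds the k(k-1)/2 upper-triangle entries of the
    within-group correlation block.
    """
    out = []
    for group in (ETP, NONETP):
        members = [s for s in labels.samples(group) if s in corr.columns]
        if len(members) < 2:
            raise DataFormatError(
                f"group {group} has {len(members)} samples; need >= 2"
            )
        block = corr.loc[members, members].to_numpy(float)
        iu = np.triu_indices(len(members), k=1)
        out.append(block[iu])
    t, _, p = welch_t_test(out[0], out[1], equal_var=equal_var)
    return out[0], out[1], t, p
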