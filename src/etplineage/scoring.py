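"""Personalized lineage-bias scoring of ETP-ALL samples.

ETP-ALL blasts derive from multipotent early thymic progenitors and retain a
patient-specific skew towards myeloid, B- or T-lineage differentiation. This
module quantifies that skew per sample from the expression of a small hub-gene
panel:

1. each panel gene's expression is normalized to its mean over the scored
   cohort (so the statistic is invariant to per-gene scale);
2. each normalized value is divided by the sample's normalized expression of
   the stemness reference gene (PROM1 by default), giving a Transformed
   Expression Score (TES) — a fold change relative to the stem-like state;
3. each lineage's score is the geometric mean of the TES values of the genes
   skewed towards that lineage:

   myeloid      = (TES_KIT * TES_HGF * TES_ANPEP * TES_CXCL2) ** (1/4)
   B            = (TES_NT5E * TES_CXCL2) ** (1/2)
   T            = TES_CDH2
   unidentified = (TES_CD33 * TES_IL1B) ** (1/2)

4. every lineage whose score falls within 10% of the sample's maximum lineage
   score is assigned to the sample, so mixed skews are first-class outcomes.

All expression values must be strictly positive: geometric means are undefined
at zero and a silent pseudo-count would corrupt the statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortLabels, ETP
from .errors import ConfigurationError, DataFormatError

LINEAGES = ("myeloid", "B", "T", "unidentified")

Lineage = Literal["myeloid", "B", "T", "unidentified"]


@dataclass(frozen=True)
class HubPanel:
    """Hub genes tagged by hematopoietic lineage, plus the stemness reference.

    The default panel is the nine validated ETP-ALL biomarkers with PROM1 as
    reference. CXCL2 legitimately appears in both the myeloid and the B set
    (it co-expresses with both marker families).
    """

    myeloid: tuple[str, ...] = ("KIT", "HGF", "ANPEP", "CXCL2")
    b_lineage: tuple[str, ...] = ("NT5E", "CXCL2")
    t_lineage: tuple[str, ...] = ("CDH2",)
    unidentified: tuple[str, ...] = ("CD33", "IL1B")
    reference: str = "PROM1"

    def __post_init__(self):
        for name, genes in self.lineage_sets.items():
            if not genes:
                raise ConfigurationError(f"lineage {name!r} has no genes")
            if self.reference in genes:
                raise ConfigurationError(
                    f"reference gene {self.reference} may not appear in "
                    f"lineage set {name!r}"
                )

    @property
    def lineage_sets(self) -> dict[str, tuple[str, ...]]:
        return {
            "myeloid": self.myeloid,
            "B": self.b_lineage,
            "T": self.t_lineage,
            "unidentified": self.unidentified,
        }

    @property
    def genes(self) -> tuple[str, ...]:
        """All panel genes (lineage-tagged plus reference), deduplicated,
        in a stable order."""
        seen: dict[str, None] = {}
        for genes in self.lineage_sets.values():
            for g in genes:
                seen.setdefault(g, None)
        seen.setdefault(self.reference, None)
        return tuple(seen)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "HubPanel":
        return cls(
            myeloid=tuple(d["myeloid"]),
            b_lineage=tuple(d["b_lineage"]),
            t_lineage=tuple(d["t_lineage"]),
            unidentified=tuple(d["unidentified"]),
            reference=d["reference"],
        )


DEFAULT_PANEL = HubPanel()


@dataclass(frozen=True)
class LineageScoreCard:
    """Per-sample scoring record: normalized expression, TES, lineage scores
    and the assigned lineage set."""

    sample_id: str
    normalized: Mapping[str, float]
    tes: Mapping[str, float]
    scores: Mapping[str, float]
    assigned: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "normalized": dict(self.normalized),
            "tes": dict(self.tes),
            "scores": dict(self.scores),
            "assigned": list(self.assigned),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LineageScoreCard":
        return cls(
            sample_id=d["sample_id"],
            normalized=dict(d["normalized"]),
            tes=dict(d["tes"]),
            scores=dict(d["scores"]),
            assigned=tuple(d["assigned"]),
        )


def _require_panel_rows(expr: pd.DataFrame, genes: Iterable[str]) -> None:
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise DataFormatError(f"panel genes missing from matrix: {missing}")


def normalize_to_cohort_mean(
    expr: pd.DataFrame,
    genes: Sequence[str],
    cohort: Sequence[str],
) -> pd.DataFrame:
    """Divide each gene's expression by its mean over ``cohort``.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (strictly positive values).
    genes
        Panel genes to normalize (rows of ``expr``).
    cohort
        Sample ids defining the normalization population; also the returned
        columns.

    Returns
    -------
    DataFrame of shape (len(genes), len(cohort)) whose rows each average to 1
    over the cohort.
    """
    if len(cohort) == 0:
        raise DataFormatError("normalization cohort is empty")
    _require_panel_rows(expr, genes)
    missing = [s for s in cohort if s not in expr.columns]
    if missing:
        raise DataFormatError(f"cohort samples missing from matrix: {missing}")
    sub = expr.loc[list(genes), list(cohort)].astype(float)
    if not np.all(sub.to_numpy() > 0):
        bad = sub.le(0).any(axis=1)
        raise DataFormatError(
            "non-positive expression for genes "
            f"{list(sub.index[bad])}; lineage scoring requires strictly "
            "positive values (no silent offset is applied)"
        )
    return sub.div(sub.mean(axis=1), axis=0)


def transformed_expression_scores(
    normalized: pd.DataFrame,
    reference: str = DEFAULT_PANEL.reference,
) -> pd.DataFrame:
    """Divide each normalized gene row by the normalized reference row.

    TES(reference) is exactly 1 in every sample.
    """
    if reference not in normalized.index:
        raise DataFormatError(f"reference gene {reference!r} not in matrix")
    ref = normalized.loc[reference]
    if not np.all(ref.to_numpy() > 0):
        raise DataFormatError(
            f"normalized reference {reference} has non-positive values"
        )
    tes = normalized.div(ref, axis=1)
    # force exactness: x/x may round away from 1.0 only if values are not
    # shared, but the reference row itself is defined to be 1
    tes.loc[reference] = 1.0
    return tes


def lineage_scores(
    tes: Mapping[str, float],
    panel: HubPanel = DEFAULT_PANEL,
) -> dict[str, float]:
    """Geometric-mean lineage scores from one sample's TES values."""
    out: dict[str, float] = {}
    for lineage, genes in panel.lineage_sets.items():
        missing = [g for g in genes if g not in tes]
        if missing:
            raise DataFormatError(f"TES missing for genes {missing}")
        vals = [float(tes[g]) for g in genes]
        if any(v <= 0 for v in vals):
            raise DataFormatError(
                f"non-positive TES in lineage {lineage!r}: {vals}"
            )
        out[lineage] = math.exp(sum(math.log(v) for v in vals) / len(vals))
    return out


def assign_lineages(
    scores: Mapping[str, float],
    tolerance: float = 0.10,
    mode: Literal["relative", "absolute"] = "relative",
) -> tuple[str, ...]:
    """Assign every lineage whose score is within ``tolerance`` of the max.

    ``relative`` (default): lineage L is assigned iff
    ``score_L >= (1 - tolerance) * max(scores)``. ``absolute`` uses
    ``score_L >= max(scores) - tolerance``. The maximum-scoring lineage is
    always assigned; ties admit all tied lineages.
    """
    if not 0 <= tolerance < 1:
        raise ConfigurationError(f"tolerance must be in [0, 1): {tolerance}")
    if not scores:
        raise DataFormatError("empty score mapping")
    vals = {k: float(v) for k, v in scores.items()}
    if any(v <= 0 for v in vals.values()):
        raise DataFormatError(f"lineage scores must be positive: {vals}")
    smax = max(vals.values())
    if mode == "relative":
        cut = (1.0 - tolerance) * smax
    elif mode == "absolute":
        cut = smax - tolerance
    else:
        raise ConfigurationError(f"unknown assignment mode {mode!r}")
    order = [k for k in LINEAGES if k in vals] + [
        k for k in vals if k not in LINEAGES
    ]
    return tuple(k for k in order if vals[k] >= cut)


def score_cohort(
    expr: pd.DataFrame,
    labels: CohortLabels,
    panel: HubPanel = DEFAULT_PANEL,
    tolerance: float = 0.10,
    population: Literal["etp", "all"] = "etp",
    mode: Literal["relative", "absolute"] = "relative",
    delog2: bool = False,
) -> list[LineageScoreCard]:
    """Score every ETP sample of a cohort.

    Parameters
    ----------
    expr
        Genes x samples expression matrix, strictly positive.
    labels
        Group annotation; only ETP samples are scored.
    population
        ``"etp"`` (default) normalizes against the scored ETP cohort's mean;
        ``"all"`` uses every labelled sample as the normalization population.
    delog2
        If True, exponentiate (2**x) before scoring, for users who consider
        the deposited values log2 and want ratios of linear intensities.
    """
    etp = labels.etp_samples
    if not etp:
        raise DataFormatError("no ETP samples to score")
    missing = [s for s in etp if s not in expr.columns]
    if missing:
        raise DataFormatError(f"labelled samples missing from matrix: {missing}")
    if population == "etp":
        pop = etp
    elif population == "all":
        pop = [s for s in expr.columns if s in labels.assignment]
    else:
        raise ConfigurationError(f"unknown population {population!r}")

    _require_panel_rows(expr, panel.genes)
    cols = list(dict.fromkeys([*pop, *etp]))
    working = expr.loc[list(panel.genes), cols].astype(float)
    if delog2:
        working = np.power(2.0, working)
    if not np.all(working.to_numpy() > 0):
        raise DataFormatError(
            "non-positive expression among panel genes; scoring requires "
            "strictly positive values"
        )
    # normalization population may exceed the scored samples: divide the
    # scored (ETP) columns by the row means over `pop`
    means = working[list(pop)].mean(axis=1)
    normalized = working[etp].div(means, axis=0)
    tes = transformed_expression_scores(normalized, panel.reference)

    cards = []
    for sample in etp:
        tes_col = tes[sample].to_dict()
        scores = lineage_scores(tes_col, panel)
        assigned = assign_lineages(scores, tolerance=tolerance, mode=mode)
        cards.append(
            LineageScoreCard(
                sample_id=sample,
                normalized=normalized[sample].to_dict(),
                tes=tes_col,
                scores=scores,
                assigned=assigned,
            )
        )
    return cards


def summarize_assignments(cards: Sequence[LineageScoreCard]) -> dict[str, int]:
    """Count samples per assigned lineage combination (joined with '+')."""
    out: dict[str, int] = {}
    for card in cards:
        key = "+".join(card.assigned)
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))
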