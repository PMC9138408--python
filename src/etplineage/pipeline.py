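"""Discovery -> validation -> scoring orchestration over files.

Each runner reads its inputs from the paths in :class:`PipelineConfig`,
executes the corresponding library stages, persists every intermediate as
TSV/JSON under the output directory, and writes a machine-readable
provenance record (config echo, package version, thresholds). Outputs are
deterministic: rerunning an identical config reproduces byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortLabels
from .diffexpr import (
    VariableGeneSet,
    bh_adjust,
    differential_expression,
    intersect_signatures,
    select_variable_genes,
    welch_t_test,
)
from .errors import ConfigurationError, DataFormatError, PipelineStageError
from .io import (
    read_edge_list,
    read_expression_tsv,
    read_labels_tsv,
    write_edge_list,
    write_scorecards_json,
)
from .network import (
    HubRanking,
    build_network,
    mcc_scores,
    network_to_edges,
    top_hubs,
)
from .roc import ClassifierEval, evaluate_biomarker, evaluation_table
from .scoring import (
    DEFAULT_PANEL,
    HubPanel,
    LineageScoreCard,
    score_cohort,
    summarize_assignments,
)

logger = logging.getLogger("etplineage")


@dataclass(frozen=True)
class PipelineConfig:
    """File paths, thresholds and seed for one pipeline run.

    Thresholds default to the published analysis settings: fold change 2,
    FDR 0.1, within-ETP sd 2, STRING confidence 0.4, top 10 hubs, 10%
    lineage-assignment tolerance.
    """

    expression: str | None = None
    labels: str | None = None
    edges: str | None = None
    validation_expression: str | None = None
    validation_labels: str | None = None
    gene_sets: str | None = None
    panel_override: str | None = None
    out_dir: str = "etplineage_out"
    fc_thresh: float = 2.0
    fdr_thresh: float = 0.1
    sd_thresh: float = 2.0
    confidence_cutoff: float = 0.4
    top_k: int = 10
    tolerance: float = 0.10
    score_population: str = "etp"
    edge_dialect: str = "string"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "fc_thresh",
            "fdr_thresh",
            "sd_thresh",
            "confidence_cutoff",
            "tolerance",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _provenance(config: PipelineConfig, stage: str, outdir: Path) -> None:
    record = {
        "stage": stage,
        "package": "etplineage",
        "version": __version__,
        "config": asdict(config),
    }
    with open(outdir / f"provenance_{stage}.json", "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def load_panel(config: PipelineConfig) -> HubPanel:
    if config.panel_override is None:
        return DEFAULT_PANEL
    with open(config.panel_override) as fh:
        return HubPanel.from_dict(json.load(fh))


@dataclass(frozen=True)
class DiscoveryResult:
    de_table: pd.DataFrame
    variable: VariableGeneSet
    up_variable: frozenset[str]
    down_variable: frozenset[str]
    signature: frozenset[str]
    network: nx.Graph
    ranking: HubRanking
    hubs: tuple[str, ...]


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Differential + variable genes -> signature -> network -> MCC hubs.

    Persists the DE table, variable-gene list, signature, filtered network
    edges, MCC ranking and the top-hub list under ``config.out_dir``.
    """
    for name in ("expression", "labels", "edges"):
        if getattr(config, name) is None:
            raise ConfigurationError(f"discovery requires config.{name}")
    out = _outdir(config)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (DataFormatError, ConfigurationError, KeyError) as exc:
            raise PipelineStageError(name, exc) from exc

    expr = stage("read_expression", read_expression_tsv, config.expression)
    labels = stage("read_labels", read_labels_tsv, config.labels)
    edges = stage(
        "read_edges",
        read_edge_list,
        config.edges,
        score_dialect=config.edge_dialect,
    )
    de = stage(
        "differential_expression",
        differential_expression,
        expr,
        labels,
        fc_thresh=config.fc_thresh,
        fdr_thresh=config.fdr_thresh,
    )
    variable = stage(
        "select_variable_genes",
        select_variable_genes,
        expr,
        labels,
        sd_thresh=config.sd_thresh,
    )
    up = frozenset(de.index[de["status"] == "UP"])
    down = frozenset(de.index[de["status"] == "DOWN"])
    upvar, downvar, signature = stage(
        "intersect_signatures", intersect_signatures, up, down, variable.genes
    )
    if not signature:
        logger.warning(
            "empty DE∩variable signature; network and hubs will be empty"
        )
        net = nx.Graph()
        ranking = HubRanking(mcc={}, degree={})
        hubs: tuple[str, ...] = ()
    else:
        net = stage(
            "build_network",
            build_network,
            edges,
            signature,
            confidence_cutoff=config.confidence_cutoff,
        )
        ranking = stage("mcc_scores", mcc_scores, net)
        if ranking.mcc:
            hubs = tuple(stage("top_hubs", top_hubs, ranking, config.top_k))
        else:
            logger.warning("no network nodes survived filtering; no hubs")
            hubs = ()

    de.to_csv(out / "differential_expression.tsv", sep="\t",
              float_format="%.12g")
    variable.sd.rename("sd").to_csv(out / "variable_genes.tsv", sep="\t",
                                    float_format="%.12g")
    (out / "signature_genes.txt").write_text(
        "\n".join(sorted(signature)) + ("\n" if signature else "")
    )
    write_edge_list(network_to_edges(net), out / "network_edges.tsv")
    with open(out / "mcc_ranking.tsv", "w") as fh:
        fh.write("gene\tmcc\tdegree\trank\n")
        for gene, mcc, degree, rank in ranking.as_rows():
            fh.write(f"{gene}\t{mcc}\t{degree}\t{rank}\n")
    (out / "top_hubs.txt").write_text(
        "\n".join(hubs) + ("\n" if hubs else "")
    )
    _provenance(config, "discovery", out)
    return DiscoveryResult(
        de_table=de,
        variable=variable,
        up_variable=upvar,
        down_variable=downvar,
        signature=signature,
        network=net,
        ranking=ranking,
        hubs=hubs,
    )


def run_validation(
    config: PipelineConfig, hub_genes: Sequence[str]
) -> pd.DataFrame:
    """Re-test hub genes in an independent cohort and evaluate them as
    classifiers.

    Per hub: Welch t between groups (BH over the hub list) plus ROC/AUC and
    Youden-cutoff confusion percentages; ``validated`` flags q < 0.05.
    Missing genes are skipped with a warning.
    """
    if not hub_genes:
        raise DataFormatError("empty hub gene list")
    expr_path = config.validation_expression or config.expression
    labels_path = config.validation_labels or config.labels
    if expr_path is None or labels_path is None:
        raise ConfigurationError("validation requires expression and labels")
    out = _outdir(config)
    expr = read_expression_tsv(expr_path)
    labels = read_labels_tsv(labels_path)
    labels.require_two_groups(min_per_group=2)
    etp = [s for s in labels.etp_samples if s in expr.columns]
    non = [s for s in labels.nonetp_samples if s in expr.columns]

    present = []
    for gene in (str(g).upper() for g in hub_genes):
        if gene in expr.index:
            present.append(gene)
        else:
            logger.warning("hub gene %s missing from validation matrix", gene)
    if not present:
        raise DataFormatError("no hub genes present in validation matrix")

    stats_rows = []
    evals: list[ClassifierEval] = []
    for gene in present:
        a = expr.loc[gene, etp].to_numpy(float)
        b = expr.loc[gene, non].to_numpy(float)
        t, _, p = welch_t_test(a, b)
        stats_rows.append((gene, a.mean(), b.mean(), t, p))
        evals.append(evaluate_biomarker(expr, labels, gene))
    table = pd.DataFrame(
        stats_rows, columns=["gene", "mean_etp", "mean_nonetp", "t", "p"]
    ).set_index("gene")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["validated"] = table["q"] < 0.05
    table = table.join(evaluation_table(evals).drop(columns=["gene"],
                                                    errors="ignore"))
    table.to_csv(out / "validation.tsv", sep="\t", float_format="%.12g")
    _provenance(config, "validation", out)
    return table


@dataclass(frozen=True)
class ScoringResult:
    cards: tuple[LineageScoreCard, ...]
    summary: Mapping[str, int]


def run_scoring(
    config: PipelineConfig, panel: HubPanel | None = None
) -> ScoringResult:
    """Score every ETP sample's lineage bias; persist scorecards and the
    per-combination summary."""
    if config.expression is None or config.labels is None:
        raise ConfigurationError("scoring requires expression and labels")
    out = _outdir(config)
    expr = read_expression_tsv(config.expression)
    labels = read_labels_tsv(config.labels)
    panel = panel or load_panel(config)
    cards = score_cohort(
        expr,
        labels,
        panel=panel,
        tolerance=config.tolerance,
        population=config.score_population,  # type: ignore[arg-type]
    )
    write_scorecards_json(cards, out / "scorecards.json")
    with open(out / "assignments.tsv", "w") as fh:
        fh.write("sample\tmyeloid\tB\tT\tunidentified\tassigned\n")
        for card in cards:
            fh.write(
                "\t".join(
                    [
                        card.sample_id,
                        *("%.12g" % card.scores[l]
                          for l in ("myeloid", "B", "T", "unidentified")),
                        "+".join(card.assigned),
                    ]
                )
                + "\n"
            )
    summary = summarize_assignments(cards)
    with open(out / "assignment_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _provenance(config, "scoring", out)
    return ScoringResult(cards=tuple(cards), summary=summary)
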