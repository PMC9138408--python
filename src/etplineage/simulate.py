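"""Synthetic leukemia cohorts and interaction networks with known truth.

The generator emulates the statistical structure the downstream analysis
assumes in a normalized log2-intensity expression matrix:

* two sample groups (ETP vs non-ETP) with planted up-/down-regulated genes
  (a constant log2 shift of the ETP group mean),
* a disjoint subset of genes whose within-ETP standard deviation is inflated
  (the "variable gene" signal),
* hub-panel genes boosted in the ETP samples of their latent lineage, giving
  each ETP sample a recoverable myeloid / B / T / unidentified bias,
* an optional interaction-network generator planting hub nodes inside
  dedicated cliques on an Erdos-Renyi background.

Expression is simulated directly on the log2 scale: Gaussian noise around
per-gene baselines drawn uniformly from ``baseline_mean_range``, truncated at
a small positive floor because lineage scoring needs strictly positive
values. A single seeded generator drives all draws in a fixed order
(baselines, noise, lineage labels, network edges), so identical configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortLabels, ETP, NONETP
from .errors import ConfigurationError
from .scoring import DEFAULT_PANEL, HubPanel, LINEAGES

EXPRESSION_FLOOR = 0.1  # log2-intensity floor keeping values strictly positive

DEFAULT_LINEAGE_PROBS: dict[str, float] = {
    # myeloid-dominant with a substantial B fraction, echoing the reported
    # composition of ETP-ALL cohorts
    "myeloid": 0.40,
    "B": 0.30,
    "T": 0.15,
    "unidentified": 0.15,
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of the synthetic two-group expression cohort.

    Defaults mirror the discovery-cohort design: 12 ETP vs 40 non-ETP
    samples, log2 baselines in [4, 12], within-group noise of 0.5 log2 units,
    planted DE shifts of 2 log2 units, and a 5x within-ETP noise inflation so
    inflated genes clear the sd > 2 variable-gene gate.
    """

    n_etp: int = 12
    n_nonetp: int = 40
    n_genes: int = 2000
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.5
    n_up: int = 100
    n_down: int = 100
    de_shift: float = 2.0
    n_variance_inflated: int = 50
    inflation_factor: float = 5.0
    hub_panel: HubPanel = DEFAULT_PANEL
    lineage_boost: float = 2.0
    lineage_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINEAGE_PROBS)
    )
    mixed_lineage_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = dict(
            n_etp=self.n_etp,
            n_nonetp=self.n_nonetp,
            n_genes=self.n_genes,
            n_up=self.n_up,
            n_down=self.n_down,
            n_variance_inflated=self.n_variance_inflated,
        )
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        lo, hi = self.baseline_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_mean_range must be (lo, hi)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.de_shift < 0:
            raise ConfigurationError("de_shift must be >= 0")
        if self.inflation_factor < 1:
            raise ConfigurationError("inflation_factor must be >= 1")
        if not 0 <= self.mixed_lineage_prob <= 1:
            raise ConfigurationError("mixed_lineage_prob must be in [0, 1]")
        budget = (
            self.n_up
            + self.n_down
            + self.n_variance_inflated
            + len(self.hub_panel.genes)
        )
        if budget > self.n_genes:
            raise ConfigurationError(
                f"planted gene budget {budget} exceeds n_genes={self.n_genes}"
            )
        probs = dict(self.lineage_probs)
        if set(probs) != set(LINEAGES):
            raise ConfigurationError(
                f"lineage_probs keys must be {LINEAGES}, got {tuple(probs)}"
            )
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"lineage_probs sum to {total}, not 1")
        if any(p < 0 for p in probs.values()):
            raise ConfigurationError("lineage_probs must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort and/or network."""

    up_genes: frozenset[str] = frozenset()
    down_genes: frozenset[str] = frozenset()
    variance_genes: frozenset[str] = frozenset()
    sample_lineage: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    planted_hubs: frozenset[str] = frozenset()

    def __post_init__(self):
        sets = [self.up_genes, self.down_genes, self.variance_genes]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ConfigurationError(
                        f"truth gene sets overlap: {sorted(overlap)[:5]}"
                    )

    def to_dict(self) -> dict:
        return {
            "up_genes": sorted(self.up_genes),
            "down_genes": sorted(self.down_genes),
            "variance_genes": sorted(self.variance_genes),
            "sample_lineage": {
                s: list(l) for s, l in self.sample_lineage.items()
            },
            "planted_hubs": sorted(self.planted_hubs),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            up_genes=frozenset(d.get("up_genes", ())),
            down_genes=frozenset(d.get("down_genes", ())),
            variance_genes=frozenset(d.get("variance_genes", ())),
            sample_lineage={
                s: tuple(l) for s, l in d.get("sample_lineage", {}).items()
            },
            planted_hubs=frozenset(d.get("planted_hubs", ())),
        )


def _gene_names(config: CohortSimConfig) -> list[str]:
    panel = list(config.hub_panel.genes)
    n_bg = config.n_genes - len(panel)
    width = max(4, len(str(max(n_bg, 1))))
    return panel + [f"G{i:0{width}d}" for i in range(1, n_bg + 1)]


def generate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, CohortLabels, SyntheticTruth]:
    """Simulate a genes x samples log2 expression matrix with planted truth.

    Returns
    -------
    (expr, labels, truth)
        ``expr``: DataFrame (n_genes x (n_etp + n_nonetp)), strictly
        positive; ``labels``: ETP/NONETP assignment; ``truth``: the planted
        up/down/variance genes and per-ETP-sample latent lineages.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    panel = config.hub_panel
    n_panel = len(panel.genes)
    etp_ids = [f"ETP{i:03d}" for i in range(1, config.n_etp + 1)]
    non_ids = [f"NON{i:03d}" for i in range(1, config.n_nonetp + 1)]
    samples = etp_ids + non_ids
    n_samples = len(samples)

    # draw order is fixed: baselines, noise, lineage labels, mixed labels
    lo, hi = config.baseline_mean_range
    baselines = rng.uniform(lo, hi, size=config.n_genes)
    noise = rng.normal(0.0, 1.0, size=(config.n_genes, n_samples))

    probs = np.array([config.lineage_probs[l] for l in LINEAGES])
    primary = rng.choice(len(LINEAGES), size=config.n_etp, p=probs)
    mixed_draw = rng.random(config.n_etp)
    secondary = rng.choice(len(LINEAGES), size=config.n_etp, p=probs)

    # planted background genes come right after the panel block
    i0 = n_panel
    up = genes[i0 : i0 + config.n_up]
    i0 += config.n_up
    down = genes[i0 : i0 + config.n_down]
    i0 += config.n_down
    var = genes[i0 : i0 + config.n_variance_inflated]

    values = baselines[:, None] + noise * config.noise_sd
    gene_idx = {g: i for i, g in enumerate(genes)}
    etp_cols = np.arange(config.n_etp)

    up_idx = [gene_idx[g] for g in up]
    down_idx = [gene_idx[g] for g in down]
    var_idx = [gene_idx[g] for g in var]
    if up_idx:
        values[np.ix_(up_idx, etp_cols)] += config.de_shift
    if down_idx:
        values[np.ix_(down_idx, etp_cols)] -= config.de_shift
    if var_idx and config.inflation_factor > 1:
        # rescale the already-drawn ETP noise so within-ETP sd becomes
        # inflation_factor * noise_sd without consuming extra draws
        block = noise[np.ix_(var_idx, etp_cols)] * config.noise_sd
        values[np.ix_(var_idx, etp_cols)] += block * (
            config.inflation_factor - 1.0
        )

    sample_lineage: dict[str, tuple[str, ...]] = {}
    for j, sid in enumerate(etp_ids):
        lineages = [LINEAGES[primary[j]]]
        if mixed_draw[j] < config.mixed_lineage_prob:
            second = LINEAGES[secondary[j]]
            if second not in lineages:
                lineages.append(second)
        sample_lineage[sid] = tuple(lineages)
        for lin in lineages:
            for g in panel.lineage_sets[lin]:
                values[gene_idx[g], j] += config.lineage_boost

    values = np.maximum(values, EXPRESSION_FLOOR)
    expr = pd.DataFrame(values, index=genes, columns=samples)
    labels = CohortLabels(
        assignment={
            **{s: ETP for s in etp_ids},
            **{s: NONETP for s in non_ids},
        }
    )
    truth = SyntheticTruth(
        up_genes=frozenset(up),
        down_genes=frozenset(down),
        variance_genes=frozenset(var),
        sample_lineage=sample_lineage,
    )
    return expr, labels, truth


def generate_network(
    n_nodes: int,
    planted_hubs: int,
    clique_size: int,
    background_edge_prob: float,
    seed: int = 0,
    nodes: Sequence[str] | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Simple graph with ``planted_hubs`` dedicated cliques on an
    Erdos-Renyi background.

    Each planted hub is the first member of its own clique of
    ``clique_size`` nodes; consecutive hubs are additionally linked to each
    other, so hub nodes belong to one more maximal clique than their clique
    peers and are strictly the most clique-central nodes of the planted
    structure. Remaining node pairs get independent background edges. All
    edge confidences are 1.0. ``nodes`` optionally names the nodes (e.g.
    with gene symbols); its length must equal ``n_nodes``.
    """
    if not 0 <= background_edge_prob <= 1:
        raise ConfigurationError(
            f"background_edge_prob must be in [0, 1]: {background_edge_prob}"
        )
    if planted_hubs > 0 and clique_size < 3:
        raise ConfigurationError("clique_size must be >= 3")
    if planted_hubs * clique_size > n_nodes:
        raise ConfigurationError(
            f"{planted_hubs} cliques of size {clique_size} exceed "
            f"n_nodes={n_nodes}"
        )
    if nodes is not None:
        nodes = list(nodes)
        if len(nodes) != n_nodes:
            raise ConfigurationError(
                f"len(nodes)={len(nodes)} differs from n_nodes={n_nodes}"
            )
        if len(set(nodes)) != n_nodes:
            raise ConfigurationError("node names must be unique")
    else:
        width = max(4, len(str(max(n_nodes, 1))))
        nodes = [f"N{i:0{width}d}" for i in range(1, n_nodes + 1)]

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    hubs = []
    clique_members: set[str] = set()
    for h in range(planted_hubs):
        members = nodes[h * clique_size : (h + 1) * clique_size]
        hubs.append(members[0])
        clique_members.update(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                g.add_edge(members[i], members[j], confidence=1.0)
    for a, b in zip(hubs, hubs[1:]):  # hub chain: strict MCC dominance
        g.add_edge(a, b, confidence=1.0)
    if background_edge_prob > 0:
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if g.has_edge(nodes[i], nodes[j]):
                    continue
                if rng.random() < background_edge_prob:
                    g.add_edge(nodes[i], nodes[j], confidence=1.0)
    truth = SyntheticTruth(planted_hubs=frozenset(hubs))
    return g, truth


def with_seed(config: CohortSimConfig, seed: int) -> CohortSimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
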