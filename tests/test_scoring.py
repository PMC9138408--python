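"""Lineage-score algebra: exact identities, invariances, assignment rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import etplineage as el
from etplineage.errors import ConfigurationError, DataFormatError

PANEL = el.DEFAULT_PANEL


def random_panel_matrix(rng, n_samples=8):
    return pd.DataFrame(
        rng.uniform(0.5, 15.0, size=(len(PANEL.genes), n_samples)),
        index=PANEL.genes,
        columns=[f"S{i}" for i in range(n_samples)],
    )


class TestNormalize:
    def test_constant_gene_normalizes_to_one(self):
        expr = pd.DataFrame(
            [[3.0, 3.0, 3.0]], index=["G1"], columns=["A", "B", "C"]
        )
        out = el.normalize_to_cohort_mean(expr, ["G1"], ["A", "B", "C"])
        assert np.allclose(out, 1.0)

    def test_hand_division(self):
        expr = pd.DataFrame([[2.0, 4.0]], index=["G1"], columns=["A", "B"])
        out = el.normalize_to_cohort_mean(expr, ["G1"], ["A", "B"])
        assert np.allclose(out.loc["G1"], [2 / 3, 4 / 3])

    def test_row_means_exactly_one(self, rng):
        expr = random_panel_matrix(rng)
        out = el.normalize_to_cohort_mean(
            expr, PANEL.genes, list(expr.columns)
        )
        assert np.allclose(out.mean(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        expr = random_panel_matrix(rng)
        scaled = expr.copy()
        scaled.loc["KIT"] *= 37.5
        a = el.normalize_to_cohort_mean(expr, PANEL.genes, list(expr.columns))
        b = el.normalize_to_cohort_mean(
            scaled, PANEL.genes, list(expr.columns)
        )
        assert np.allclose(a, b)

    def test_non_positive_rejected(self):
        expr = pd.DataFrame([[1.0, -2.0]], index=["G1"], columns=["A", "B"])
        with pytest.raises(DataFormatError, match="positive"):
            el.normalize_to_cohort_mean(expr, ["G1"], ["A", "B"])

    def test_missing_gene_named(self, rng):
        expr = random_panel_matrix(rng).drop(index="HGF")
        with pytest.raises(DataFormatError, match="HGF"):
            el.normalize_to_cohort_mean(
                expr, PANEL.genes, list(expr.columns)
            )


class TestTes:
    def test_reference_is_exactly_one(self, rng):
        for _ in range(50):
            expr = random_panel_matrix(rng)
            norm = el.normalize_to_cohort_mean(
                expr, PANEL.genes, list(expr.columns)
            )
            tes = el.transformed_expression_scores(norm)
            assert (tes.loc["PROM1"] == 1.0).all()

    def test_hand_ratio(self):
        norm = pd.DataFrame(
            {"S1": [0.8, 0.4]}, index=["KIT", "PROM1"]
        )
        tes = el.transformed_expression_scores(norm)
        assert tes.loc["KIT", "S1"] == pytest.approx(2.0)

    def test_sample_at_cohort_mean_has_unit_tes(self):
        norm = pd.DataFrame(
            {"S1": [1.0] * len(PANEL.genes)}, index=PANEL.genes
        )
        tes = el.transformed_expression_scores(norm)
        assert np.allclose(tes, 1.0)


class TestLineageScores:
    def test_all_unit_tes_gives_unit_scores(self):
        tes = {g: 1.0 for g in PANEL.genes}
        assert el.lineage_scores(tes) == {
            lin: pytest.approx(1.0) for lin in el.LINEAGES
        }

    def test_fourth_root_of_single_boost(self):
        tes = {g: 1.0 for g in PANEL.genes}
        tes["KIT"] = 16.0
        assert el.lineage_scores(tes)["myeloid"] == pytest.approx(2.0)

    def test_shared_gene_cxcl2_feeds_both_sets(self):
        tes = {g: 1.0 for g in PANEL.genes}
        tes["NT5E"] = 4.0
        scores = el.lineage_scores(tes)
        assert scores["B"] == pytest.approx(2.0)
        assert scores["myeloid"] == pytest.approx(1.0)
        tes["CXCL2"] = 4.0
        scores = el.lineage_scores(tes)
        assert scores["B"] == pytest.approx(4.0)
        assert scores["myeloid"] == pytest.approx(4.0 ** 0.25)

    def test_geometric_mean_bounds(self, rng):
        for _ in range(100):
            tes = {g: float(rng.uniform(0.1, 8)) for g in PANEL.genes}
            scores = el.lineage_scores(tes)
            for lin, genes in PANEL.lineage_sets.items():
                vals = [tes[g] for g in genes]
                assert min(vals) - 1e-12 <= scores[lin] <= max(vals) + 1e-12

    def test_monotone_in_single_gene(self):
        tes = {g: 1.0 for g in PANEL.genes}
        before = el.lineage_scores(tes)
        tes["CXCL2"] = 1.5
        after = el.lineage_scores(tes)
        assert after["myeloid"] > before["myeloid"]
        assert after["B"] > before["B"]
        assert after["T"] == before["T"]
        assert after["unidentified"] == before["unidentified"]

    def test_missing_tes_rejected(self):
        with pytest.raises(DataFormatError, match="KIT"):
            el.lineage_scores({"HGF": 1.0})


class TestAssignLineages:
    def test_clear_winner(self):
        scores = {"myeloid": 2.0, "B": 1.0, "T": 1.0, "unidentified": 1.0}
        assert el.assign_lineages(scores) == ("myeloid",)

    def test_within_ten_percent_joins(self):
        scores = {"myeloid": 1.0, "B": 0.95, "T": 0.5, "unidentified": 0.5}
        assert el.assign_lineages(scores) == ("myeloid", "B")

    def test_boundary_equality_assigned(self):
        scores = {"myeloid": 1.0, "B": 0.9, "T": 0.5, "unidentified": 0.5}
        assert "B" in el.assign_lineages(scores)
        scores = {"myeloid": 2.0, "B": 1.8, "T": 0.5, "unidentified": 0.5}
        assert "B" in el.assign_lineages(scores)

    def test_all_equal_assigns_all_four(self):
        scores = {lin: 1.3 for lin in el.LINEAGES}
        assert el.assign_lineages(scores) == el.LINEAGES

    def test_absolute_mode(self):
        scores = {"myeloid": 1.0, "B": 0.95, "T": 0.5, "unidentified": 0.5}
        assert el.assign_lineages(scores, tolerance=0.04, mode="absolute") \
            == ("myeloid",)
        assert el.assign_lineages(scores, tolerance=0.05, mode="absolute") \
            == ("myeloid", "B")

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ConfigurationError):
            el.assign_lineages({"myeloid": 1.0}, tolerance=1.0)
        with pytest.raises(ConfigurationError):
            el.assign_lineages({"myeloid": 1.0}, tolerance=-0.1)

    @given(
        st.dictionaries(
            st.sampled_from(el.LINEAGES),
            st.floats(0.01, 100, allow_nan=False),
            min_size=4,
            max_size=4,
        )
    )
    def test_rule_matches_direct_enumeration(self, scores):
        assigned = set(el.assign_lineages(scores))
        smax = max(scores.values())
        expected = {l for l, v in scores.items() if v >= 0.9 * smax}
        assert assigned == expected
        assert any(scores[l] == smax for l in assigned)


class TestScoreCohort:
    def test_identical_samples_assign_all_lineages(self):
        col = np.linspace(5, 9, len(PANEL.genes))
        expr = pd.DataFrame(
            {f"E{i}": col for i in range(4)}, index=PANEL.genes
        )
        labels = el.CohortLabels(
            assignment={f"E{i}": "ETP" for i in range(4)}
        )
        cards = el.score_cohort(expr, labels)
        assert len(cards) == 4
        for card in cards:
            assert card.assigned == el.LINEAGES
            assert all(
                v == pytest.approx(1.0) for v in card.scores.values()
            )

    def test_per_gene_scale_invariance(self, rng):
        expr = random_panel_matrix(rng, n_samples=6)
        labels = el.CohortLabels(
            assignment={c: "ETP" for c in expr.columns}
        )
        base = el.score_cohort(expr, labels)
        scaled = expr.copy()
        scaled.loc["CD33"] *= 10.0
        rescored = el.score_cohort(scaled, labels)
        for a, b in zip(base, rescored):
            assert a.assigned == b.assigned
            for lin in el.LINEAGES:
                assert a.scores[lin] == pytest.approx(b.scores[lin])

    def test_sample_permutation_permutes_cards(self, rng):
        expr = random_panel_matrix(rng, n_samples=6)
        labels = el.CohortLabels(
            assignment={c: "ETP" for c in expr.columns}
        )
        base = {c.sample_id: c for c in el.score_cohort(expr, labels)}
        perm = list(rng.permutation(expr.columns))
        labels2 = el.CohortLabels(assignment={c: "ETP" for c in perm})
        for card in el.score_cohort(expr[perm], labels2):
            ref = base[card.sample_id]
            for lin in el.LINEAGES:
                assert card.scores[lin] == pytest.approx(ref.scores[lin])

    def test_planted_lineage_recovered(self):
        cfg = el.CohortSimConfig(
            n_etp=30, n_nonetp=10, n_genes=100, n_up=20, n_down=20,
            n_variance_inflated=10, lineage_boost=2.0, noise_sd=0.25,
            seed=40,
        )
        expr, labels, truth = el.generate_cohort(cfg)
        cards = el.score_cohort(expr, labels)
        hits = sum(
            truth.sample_lineage[c.sample_id][0] in c.assigned
            for c in cards
        )
        assert hits / len(cards) >= 0.9

    def test_population_all_flag_changes_normalization(self, small_cohort):
        _, expr, labels, _ = small_cohort
        etp_cards = el.score_cohort(expr, labels, population="etp")
        all_cards = el.score_cohort(expr, labels, population="all")
        assert len(etp_cards) == len(all_cards)
        assert any(
            a.scores != b.scores for a, b in zip(etp_cards, all_cards)
        )

    def test_missing_panel_gene_aborts(self, rng):
        expr = random_panel_matrix(rng).drop(index="IL1B")
        labels = el.CohortLabels(
            assignment={c: "ETP" for c in expr.columns}
        )
        with pytest.raises(DataFormatError, match="IL1B"):
            el.score_cohort(expr, labels)

    def test_summary_counts(self):
        cards = [
            el.LineageScoreCard(
                sample_id=f"S{i}",
                normalized={},
                tes={},
                scores={l: 1.0 for l in el.LINEAGES},
                assigned=a,
            )
            for i, a in enumerate(
                [("myeloid",), ("myeloid",), ("myeloid", "B")]
            )
        ]
        assert el.summarize_assignments(cards) == {
            "myeloid": 2,
            "myeloid+B": 1,
        }
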