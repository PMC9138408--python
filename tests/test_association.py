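"""Association analyses: reference normalization, PCA map, bisection, ORA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import etplineage as el
from etplineage.errors import DataFormatError
from etplineage.io import GeneSet, GeneSetCollection


def make_collection(*sets):
    return GeneSetCollection(
        [GeneSet(f"S{i}", "-", frozenset(s)) for i, s in enumerate(sets)]
    )


class TestReferenceNormalization:
    def test_reference_mean_sample_reads_one(self):
        expr = pd.DataFrame(
            [[2.0, 4.0, 3.0]], index=["G1"], columns=["R1", "R2", "E1"]
        )
        out = el.normalize_to_reference_group(expr, ["G1"], ["R1", "R2"])
        assert out.loc["G1", "E1"] == pytest.approx(1.0)

    def test_doubling_reads_two(self):
        expr = pd.DataFrame(
            [[2.0, 2.0, 4.0, 4.0]],
            index=["G1"],
            columns=["R1", "R2", "E1", "E2"],
        )
        out = el.normalize_to_reference_group(expr, ["G1"], ["R1", "R2"])
        assert np.allclose(out[["E1", "E2"]], 2.0)

    def test_hand_division_two_plus_two(self):
        expr = pd.DataFrame(
            [[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 2.0, 6.0]],
            index=["G1", "G2"],
            columns=["R1", "R2", "E1", "E2"],
        )
        out = el.normalize_to_reference_group(
            expr, ["G1", "G2"], ["R1", "R2"]
        )
        assert np.allclose(out.loc["G1"], [0.5, 1.5, 2.5, 3.5])
        assert np.allclose(out.loc["G2"], [1.0, 1.0, 1.0, 3.0])

    def test_zero_reference_mean_rejected(self):
        expr = pd.DataFrame(
            [[0.0, 0.0, 1.0]], index=["G1"], columns=["R1", "R2", "E1"]
        )
        with pytest.raises(DataFormatError, match="G1"):
            el.normalize_to_reference_group(expr, ["G1"], ["R1", "R2"])


class TestPcaGeneMap:
    def _matrix(self, rng, n_genes=6, n_samples=5):
        return pd.DataFrame(
            rng.uniform(0.5, 3.0, size=(n_genes, n_samples)),
            index=[f"G{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )

    def test_duplicated_gene_rows_coincide(self, rng):
        m = self._matrix(rng)
        m.loc["G5"] = m.loc["G0"]
        pmap = el.pca_gene_map(m)
        assert np.allclose(
            pmap.coordinates.loc["G0"], pmap.coordinates.loc["G5"]
        )

    def test_full_reconstruction(self, rng):
        m = self._matrix(rng)
        pmap = el.pca_gene_map(m)
        centered = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        rebuilt = pmap.scores.to_numpy() @ pmap.loadings.to_numpy().T
        assert np.allclose(rebuilt, centered, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        m = self._matrix(rng, n_genes=4, n_samples=3)
        pmap = el.pca_gene_map(m)
        x = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(2):
            expected = evecs[:, k] * np.sqrt(evals[k])
            got = pmap.coordinates.to_numpy()[:, k]
            assert np.allclose(np.abs(got), np.abs(expected), atol=1e-8)

    def test_explained_variance_sums_to_one(self, rng):
        pmap = el.pca_gene_map(self._matrix(rng))
        assert pmap.explained_variance.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(pmap.explained_variance) <= 1e-12)

    def test_sign_convention_largest_loading_positive(self, rng):
        pmap = el.pca_gene_map(self._matrix(rng))
        for k in ("PC1", "PC2"):
            col = pmap.loadings[k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_row_rejected(self, rng):
        m = self._matrix(rng)
        m.loc["G2"] = 1.5
        with pytest.raises(DataFormatError, match="G2"):
            el.pca_gene_map(m)

    def test_centroid_labels_pull_to_nearest_lineage(self):
        coords = pd.DataFrame(
            {
                "PC1": [0.0, 0.1, 5.0, 5.1, 0.05, 5.05],
                "PC2": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            },
            index=["CD19", "EBF1", "CD7", "HES1", "NT5E", "CDH2"],
        )
        labels = el.lineage_centroid_labels(coords)
        assert labels["NT5E"] == "B"
        assert labels["CDH2"] == "T"


class TestBisect:
    def test_hand_mean_split(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 10.0]],
            index=["G1"],
            columns=["A", "B", "C", "D"],
        )
        high, low = el.bisect_cohort_by_gene(
            expr, ["A", "B", "C", "D"], "G1"
        )
        assert high == {"D"}
        assert low == {"A", "B", "C"}

    def test_all_equal_goes_low(self):
        expr = pd.DataFrame(
            [[2.0, 2.0, 2.0]], index=["G1"], columns=["A", "B", "C"]
        )
        high, low = el.bisect_cohort_by_gene(expr, ["A", "B", "C"], "G1")
        assert high == frozenset()
        assert low == {"A", "B", "C"}

    def test_symmetric_two_samples(self):
        expr = pd.DataFrame(
            [[1.0, 3.0]], index=["G1"], columns=["A", "B"]
        )
        high, low = el.bisect_cohort_by_gene(expr, ["A", "B"], "G1")
        assert (high, low) == ({"B"}, {"A"})

    def test_bisect_then_compare_on_same_gene_positive_gap(self, rng):
        vals = rng.uniform(2, 10, size=12)
        expr = pd.DataFrame(
            [vals, rng.uniform(2, 10, size=12)],
            index=["G1", "G2"],
            columns=[f"S{j}" for j in range(12)],
        )
        high, low = el.bisect_cohort_by_gene(expr, list(expr.columns), "G1")
        table = el.compare_markers(expr, sorted(high), sorted(low), ["G1"])
        assert table.loc["G1", "mean_a"] > table.loc["G1", "mean_b"]

    def test_missing_gene_rejected(self, tiny_expr):
        with pytest.raises(DataFormatError):
            el.bisect_cohort_by_gene(tiny_expr, ["S1", "S2"], "NOPE")


class TestCompareMarkers:
    def test_identical_marker_p_one(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0]],
            index=["M1"],
            columns=["A1", "A2", "B1", "B2"],
        )
        table = el.compare_markers(expr, ["A1", "A2"], ["B1", "B2"], ["M1"])
        assert table.loc["M1", "p"] == 1.0

    def test_swap_groups_symmetry(self, rng):
        expr = pd.DataFrame(
            rng.normal(8, 1, size=(3, 8)),
            index=["M1", "M2", "M3"],
            columns=[f"S{j}" for j in range(8)],
        )
        a, b = ["S0", "S1", "S2", "S3"], ["S4", "S5", "S6", "S7"]
        t1 = el.compare_markers(expr, a, b, ["M1", "M2", "M3"])
        t2 = el.compare_markers(expr, b, a, ["M1", "M2", "M3"])
        assert np.allclose(t1["p"], t2["p"])
        assert np.allclose(t1["mean_a"], t2["mean_b"])

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(
                rng.normal(8, 0.3, size=(1, 16)),
                index=["M1"],
                columns=[f"S{j}" for j in range(16)],
            )
            expr.loc["M1", [f"S{j}" for j in range(8)]] += 3.0
            table = el.compare_markers(
                expr,
                [f"S{j}" for j in range(8)],
                [f"S{j}" for j in range(8, 16)],
                ["M1"],
            )
            hits += table.loc["M1", "q"] < 0.05
        assert hits >= 99

    def test_missing_markers_listed(self, tiny_expr):
        with pytest.raises(DataFormatError, match="ZZZ"):
            el.compare_markers(
                tiny_expr, ["S1", "S2"], ["S3", "S4"], ["G1", "ZZZ"]
            )

    def test_quasi_significant_band_flagged(self):
        # engineered p in (0.05, 0.1): weak separation
        rng = np.random.default_rng(3)
        for _ in range(50):
            expr = pd.DataFrame(
                rng.normal(0, 1, size=(1, 10)),
                index=["M1"],
                columns=[f"S{j}" for j in range(10)],
            )
            table = el.compare_markers(
                expr,
                [f"S{j}" for j in range(5)],
                [f"S{j}" for j in range(5, 10)],
                ["M1"],
            )
            p = table.loc["M1", "p"]
            assert table.loc["M1", "quasi_significant"] == (0.05 < p < 0.1)


def ora_bruteforce_p(k, m, n_set, n_query):
    """Upper-tail hypergeometric by explicit enumeration of overlaps."""
    total = comb(m, n_query, exact=True)
    hits = sum(
        comb(n_set, i, exact=True) * comb(m - n_set, n_query - i, exact=True)
        for i in range(k, min(n_set, n_query) + 1)
    )
    return hits / total


class TestOra:
    def test_closed_form_one_over_252(self):
        background = {f"G{i}" for i in range(10)}
        target = {f"G{i}" for i in range(5)}
        coll = make_collection(target)
        (res,) = el.ora_hypergeometric(
            target, background, coll, p_thresh=1.0, min_overlap=1
        )
        assert res.p == pytest.approx(1 / 252)
        assert res.overlap == 5

    def test_disjoint_query_filtered_out(self):
        background = {f"G{i}" for i in range(10)}
        coll = make_collection({"G0", "G1"})
        assert (
            el.ora_hypergeometric({"G8", "G9"}, background, coll) == []
        )

    def test_set_equal_to_background_p_one(self):
        background = {f"G{i}" for i in range(8)}
        coll = make_collection(background)
        (res,) = el.ora_hypergeometric(
            {"G0", "G1", "G2"},
            background,
            coll,
            p_thresh=1.5,
            min_overlap=1,
        )
        assert res.p == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        with pytest.raises(DataFormatError):
            el.ora_hypergeometric(
                {"X"}, {"G0"}, make_collection({"G0"})
            )

    def test_min_overlap_gate_is_at_least_six_by_default(self):
        background = {f"G{i}" for i in range(30)}
        five = {f"G{i}" for i in range(5)}
        coll = make_collection(five)
        assert el.ora_hypergeometric(five, background, coll) == []

    def test_matches_bruteforce_enumeration_small_backgrounds(self, rng):
        for trial in range(50):
            m = int(rng.integers(6, 21))
            background = {f"G{i}" for i in range(m)}
            set_genes = set(
                rng.choice(sorted(background), rng.integers(2, m), False)
            )
            query = set(
                rng.choice(sorted(background), rng.integers(2, m), False)
            )
            coll = make_collection(set_genes)
            res = el.ora_hypergeometric(
                query, background, coll, p_thresh=1.5, min_overlap=0
            )
            k = len(query & set_genes)
            expected = ora_bruteforce_p(k, m, len(set_genes), len(query))
            assert res[0].p == pytest.approx(expected, rel=1e-10)
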