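"""Autoscaled PCA of the descriptor matrix and score-plot grouping."""

import numpy as np
import pandas as pd
import pytest

from iamtox.dataset_io import DESCRIPTOR_COLUMNS, load_table1, records_to_frame
from iamtox.errors import DegenerateDesignError
from iamtox.pca_profile import (
    GROUP_ANIONIC,
    GROUP_LIPOPHILIC,
    UNGROUPED,
    autoscale,
    pca_decompose,
    score_groups,
)

LIPOPHILIC_CLUSTER = {
    "Avobenzone", "Homosalate", "Meradimate", "Octinoxate",
    "Octisalate", "Octocrylene", "Oxybenzone", "Padimate O",
}
ANIONIC_CLUSTER = {
    "4-Aminobenzoic Acid", "Dioxybenzone", "Ensulizole",
    "Sulisobenzone", "Trolamine salicylate (Salicylic acid)",
}


@pytest.fixture(scope="module")
def descriptor_matrix():
    records = load_table1()
    frame = records_to_frame(records).set_index("name")
    return records, frame[list(DESCRIPTOR_COLUMNS)]


class TestAutoscale:
    def test_drops_the_two_constant_charge_columns(self, descriptor_matrix):
        _, matrix = descriptor_matrix
        scaled, retained, dropped = autoscale(matrix)
        assert sorted(dropped) == ["f_plus", "f_zwit"]
        assert len(retained) == 9
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_already_standardized_column_unchanged(self, rng):
        col = rng.normal(0, 1, 50)
        col = (col - col.mean()) / col.std(ddof=1)
        df = pd.DataFrame({"a": col, "b": rng.uniform(0, 4, 50)})
        scaled, _, _ = autoscale(df)
        np.testing.assert_allclose(scaled["a"], col, atol=1e-12)

    def test_variance_four_halves_deviations(self):
        df = pd.DataFrame({"a": [0.0, 2.0, 4.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})
        scaled, _, _ = autoscale(df)
        sd = df["a"].std(ddof=1)
        np.testing.assert_allclose(scaled["a"], (df["a"] - 2.0) / sd, atol=1e-12)

    def test_all_constant_rejected(self):
        with pytest.raises(DegenerateDesignError):
            autoscale(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestDecompose:
    def test_rank_one_data_is_fully_explained_by_pc1(self):
        base = np.array([1.0, -2.0, 0.5])
        rows = np.outer([1.0, 2.0, 3.0, 4.0], base) + 5.0
        df = pd.DataFrame(rows, columns=list("abc"))
        scaled, _, _ = autoscale(df)
        result = pca_decompose(scaled)
        assert result.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_eigendecomposition(self, rng):
        X = rng.normal(0, 1, (13, 9))
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(9)])
        scaled, _, _ = autoscale(df)
        result = pca_decompose(scaled)

        # independent oracle: eigen-decomposition of the covariance matrix
        Z = np.asarray(scaled)
        cov = Z.T @ Z / (len(Z) - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        np.testing.assert_allclose(
            result.explained_fraction, eigvals / eigvals.sum(), atol=1e-9
        )
        r = result.loadings.shape[1]
        for j in range(r):
            v = eigvecs[:, j]
            w = result.loadings[:, j]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-9

    def test_reconstruction_with_all_components(self, descriptor_matrix):
        _, matrix = descriptor_matrix
        scaled, _, _ = autoscale(matrix)
        result = pca_decompose(scaled)
        np.testing.assert_allclose(
            result.scores @ result.loadings.T, np.asarray(scaled), atol=1e-9
        )

    def test_variance_fractions_sum_to_one_and_decrease(self, descriptor_matrix):
        _, matrix = descriptor_matrix
        scaled, _, _ = autoscale(matrix)
        result = pca_decompose(scaled)
        assert result.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(result.explained_fraction) <= 1e-12)

    def test_invariant_to_row_and_column_order(self, descriptor_matrix, rng):
        _, matrix = descriptor_matrix
        scaled, _, _ = autoscale(matrix)
        base = pca_decompose(scaled).explained_fraction
        shuffled = matrix.sample(frac=1.0, random_state=3)[
            list(rng.permutation(matrix.columns))
        ]
        scaled2, _, _ = autoscale(shuffled)
        np.testing.assert_allclose(
            pca_decompose(scaled2).explained_fraction, base, atol=1e-9
        )

    def test_component_count_validated(self, descriptor_matrix):
        _, matrix = descriptor_matrix
        scaled, _, _ = autoscale(matrix)
        with pytest.raises(ValueError):
            pca_decompose(scaled, n_components=10)


class TestScoreGroups:
    def test_published_cluster_membership_reproduced(self, descriptor_matrix):
        records, matrix = descriptor_matrix
        scaled, _, _ = autoscale(matrix)
        result = pca_decompose(scaled, n_components=2)
        labels = dict(zip([r.name for r in records], score_groups(result, records)))
        for name in LIPOPHILIC_CLUSTER:
            assert labels[name] == GROUP_LIPOPHILIC, name
        for name in ANIONIC_CLUSTER:
            assert labels[name] == GROUP_ANIONIC, name

    def test_octocrylene_and_sulisobenzone_by_strict_rule(self, descriptor_matrix):
        records, matrix = descriptor_matrix
        labels = dict(
            zip([r.name for r in records], score_groups(None, records, borderline="strict"))
        )
        assert labels["Octocrylene"] == GROUP_LIPOPHILIC
        assert labels["Sulisobenzone"] == GROUP_ANIONIC

    def test_strict_mode_leaves_borderline_neutral_ungrouped(self):
        from iamtox.dataset_io import CompoundRecord

        rec = CompoundRecord(name="hypothetical", mw=250, log_p=3.8, f_minus=0.0)
        assert score_groups(None, [rec], borderline="strict") == [UNGROUPED]
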