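"""Allele-frequency and allele-copy PCA plus discriminatory-marker ranking."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

import genedup as gd
from genedup.core import MISSING
from genedup.ordination import _pca

from conftest import build_dataset


def eig_oracle_scores(matrix: np.ndarray) -> np.ndarray:
    """Independent oracle: eigendecomposition of the covariance of the
    centered matrix, scores = centered @ eigenvectors."""
    centered = matrix - matrix.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return centered @ v[:, order]


def freq_table(p: np.ndarray, units=None) -> gd.FrequencyTable:
    units = units or [f"acc{i + 1}" for i in range(p.shape[0])]
    n = np.full(p.shape, 10, dtype=int)
    return gd.FrequencyTable(tuple(units), tuple(f"m{j + 1}" for j in range(p.shape[1])), p, n)


class TestAccessionPca:
    def test_identical_accessions_get_identical_scores(self):
        p = np.array([[0.2, 0.7, 0.5], [0.2, 0.7, 0.5], [0.9, 0.1, 0.3]])
        result = gd.accession_pca(freq_table(p))
        np.testing.assert_allclose(
            result.scores.iloc[0].to_numpy(), result.scores.iloc[1].to_numpy(), atol=1e-10
        )

    def test_variance_proportions_ordered_and_bounded(self):
        rng = np.random.default_rng(0)
        result = gd.accession_pca(freq_table(rng.uniform(0.1, 0.9, (6, 20))))
        assert (np.diff(result.explained) <= 1e-12).all()
        assert result.explained.sum() <= 1 + 1e-9
        assert (result.explained >= 0).all()

    def test_matches_eigendecomposition_oracle(self):
        p = np.array([[0.1, 0.8], [0.5, 0.5], [0.9, 0.2]])
        result = gd.accession_pca(freq_table(p))
        matrix = np.column_stack([p[:, 0], 1 - p[:, 0], p[:, 1], 1 - p[:, 1]])
        oracle = eig_oracle_scores(matrix)
        k = result.n_components
        np.testing.assert_allclose(
            np.abs(result.scores.to_numpy()), np.abs(oracle[:, :k]), atol=1e-8
        )

    def test_incomplete_loci_dropped(self):
        p = np.array([[0.2, np.nan], [0.8, 0.5], [0.5, 0.5]])
        n = np.array([[5, 0], [5, 5], [5, 5]])
        ft = gd.FrequencyTable(("a", "b", "c"), ("m1", "m2"), p, n)
        result = gd.accession_pca(ft)
        assert all(v.startswith("m1") for v in result.loadings.index)

    def test_needs_two_accessions(self):
        with pytest.raises(ValueError, match="at least 2"):
            gd.accession_pca(freq_table(np.array([[0.5, 0.4]])))


class TestIndividualPca:
    def test_duplicated_individuals_coincide(self):
        calls = [[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 0, 1]]
        ds = build_dataset({"X": calls})
        result = gd.individual_pca(ds)
        np.testing.assert_allclose(
            result.scores.iloc[0].to_numpy(), result.scores.iloc[1].to_numpy(), atol=1e-10
        )

    def test_matches_eigendecomposition_oracle(self):
        calls = np.array([[0, 2], [1, 1], [2, 0], [2, 2]])
        ds = build_dataset({"X": calls.tolist()})
        result = gd.individual_pca(ds)
        matrix = np.column_stack(
            [2 - calls[:, 0], calls[:, 0], 2 - calls[:, 1], calls[:, 1]]
        ).astype(float)
        oracle = eig_oracle_scores(matrix)
        k = result.n_components
        np.testing.assert_allclose(
            np.abs(result.scores.to_numpy()), np.abs(oracle[:, :k]), atol=1e-8
        )

    def test_all_missing_marker_dropped_and_mean_imputation(self):
        M = MISSING
        calls = [[0, M, M], [2, M, 0], [1, M, 2]]
        ds = build_dataset({"X": calls})
        result = gd.individual_pca(ds)
        markers = {v.rsplit("|", 1)[0] for v in result.loadings.index}
        assert markers == {"m1", "m3"}

    def test_panmictic_sample_has_no_dominant_axis(self):
        """A single HWE accession has no between-group variance: the first
        PC should capture only a small share of the total."""
        rng = np.random.default_rng(21)
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 300), size=(40, 300))
        ds = build_dataset({"X": calls.tolist()})
        result = gd.individual_pca(ds)
        assert result.explained[0] < 0.15

    def test_scores_orthogonal(self, clean_study):
        ds, _ = clean_study
        result = gd.individual_pca(ds)
        s = result.scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


class TestPcaProperties:
    def test_centering_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 8))
        shifted = x + rng.normal(size=8)[None, :]  # constant per column
        a = _pca(x, range(6), [f"v{j}" for j in range(8)])
        b = _pca(shifted, range(6), [f"v{j}" for j in range(8)])
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-8)

    def test_accession_and_individual_pca_concordant(self, clean_study):
        """Accession centroids of the individual-level PCA agree with the
        accession-level PCA on clustered synthetic data (Procrustes)."""
        ds, _ = clean_study
        acc_pca = gd.accession_pca(gd.allele_frequencies(ds))
        ind_pca = gd.individual_pca(ds)
        codes = ds.accessions.active_codes()
        centroids = np.array(
            [
                ind_pca.scores.loc[list(ds.accessions[c].individuals), ["PC1", "PC2"]]
                .mean(axis=0)
                .to_numpy()
                for c in codes
            ]
        )
        acc_scores = acc_pca.scores.loc[list(codes), ["PC1", "PC2"]].to_numpy()
        _, _, disparity = procrustes(acc_scores, centroids)
        assert 1 - disparity > 0.81  # squared Procrustes correlation


class TestTopDiscriminatoryMarkers:
    def _fake_pca(self, loadings: dict[str, tuple[float, float]]) -> gd.PcaResult:
        idx, rows = [], []
        for marker, (l1, l2) in loadings.items():
            idx += [f"{marker}|ref", f"{marker}|alt"]
            rows += [[l1, l2], [-l1, -l2]]
        frame = pd.DataFrame(rows, index=idx, columns=["PC1", "PC2"])
        scores = pd.DataFrame(np.zeros((2, 2)), columns=["PC1", "PC2"])
        return gd.PcaResult(scores, frame, np.array([0.6, 0.3]))

    def test_ranking_and_zero_loading_last(self):
        pca = self._fake_pca({"m1": (0.1, 0.9), "m2": (0.5, 0.2), "m3": (0.0, 0.0)})
        ranked = gd.top_discriminatory_markers(pca, k=3)
        assert list(ranked["marker"]) == ["m1", "m2", "m3"]

    def test_k_equal_total_is_permutation(self):
        pca = self._fake_pca({"m1": (0.3, 0.1), "m2": (0.2, 0.4), "m3": (0.5, 0.0)})
        ranked = gd.top_discriminatory_markers(pca, k=3)
        assert sorted(ranked["marker"]) == ["m1", "m2", "m3"]

    def test_separating_marker_ranked_first(self):
        # two clusters of accessions separated by m2 only
        p = np.array(
            [[0.5, 0.05, 0.5], [0.5, 0.1, 0.5], [0.5, 0.9, 0.5], [0.5, 0.95, 0.5]]
        )
        pca = gd.accession_pca(freq_table(p))
        ranked = gd.top_discriminatory_markers(pca, k=1)
        assert ranked["marker"].iloc[0] == "m2"

    def test_k_above_total_returns_all_with_warning(self, caplog):
        pca = self._fake_pca({"m1": (0.3, 0.1), "m2": (0.2, 0.4)})
        ranked = gd.top_discriminatory_markers(pca, k=10)
        assert len(ranked) == 2
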