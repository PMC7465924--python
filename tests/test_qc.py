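"""Marker/individual filtering, concordance, chromosome failure summaries
and the Hardy-Weinberg scan."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import genedup as gd
from genedup.core import MISSING

from conftest import build_dataset, simple_map

M = MISSING


def toy_five_marker_dataset():
    """m1 all-missing (failed), m2 monomorphic, m3 60% missing, m4/m5 clean."""
    calls = [
        [M, 0, M, 0, 1],
        [M, 0, M, 1, 2],
        [M, 0, M, 2, 0],
        [M, 0, 1, 0, 1],
        [M, 0, 2, 1, 2],
    ]
    return build_dataset({"X": calls})


class TestFilterMarkers:
    def test_categories_counted_once_in_order(self):
        ds, report = gd.filter_markers(toy_five_marker_dataset())
        assert ds.genotypes.markers == ("m4", "m5")
        assert (report.n_failed, report.n_invariant, report.n_over_missing) == (1, 1, 1)
        assert report.n_markers_out == 2

    def test_clean_dataset_unchanged(self):
        ds0 = build_dataset({"X": [[0, 1], [1, 2], [2, 0]]})
        ds, report = gd.filter_markers(ds0)
        assert ds.genotypes.markers == ds0.genotypes.markers
        assert report.n_markers_out == report.n_markers_in

    def test_exact_half_missing_retained(self):
        # "more than 50%" is strict: missing fraction exactly 0.5 stays
        calls = [[M, 0], [M, 1], [0, 2], [1, 0]]
        ds, _ = gd.filter_markers(build_dataset({"X": calls}))
        assert "m1" in ds.genotypes.markers

    def test_all_markers_removed_is_error(self):
        with pytest.raises(ValueError, match="inspect"):
            gd.filter_markers(build_dataset({"X": [[M], [M]]}))

    def test_idempotent(self, default_study):
        ds, _ = default_study
        once, r1 = gd.filter_markers(ds)
        twice, r2 = gd.filter_markers(once)
        assert once.genotypes.markers == twice.genotypes.markers
        assert r2.n_failed == r2.n_invariant == r2.n_over_missing == 0

    def test_accounting_identity_on_random_missingness(self, default_study):
        ds, _ = default_study
        noisy = gd.inject_missingness(ds, 0.3, seed=7)
        _, report = gd.filter_markers(noisy)
        assert report.n_markers_out == (
            report.n_markers_in
            - report.n_failed
            - report.n_invariant
            - report.n_over_missing
        )
        assert len(report.failed_markers) == report.n_failed


class TestFilterIndividuals:
    def test_strict_forty_percent_boundary(self):
        n = 100
        row_40 = [M] * 40 + [0, 1] * 30
        row_41 = [M] * 41 + [0, 1] * 29 + [2]
        clean = [0, 1] * 50
        ds = build_dataset({"X": [row_40, row_41, clean, clean[::-1]]})
        filtered, report = gd.filter_individuals(ds)
        assert "X-1" in filtered.genotypes.individuals   # exactly 40% kept
        assert report.removed_individuals == ("X-2",)    # 41% removed

    def test_identity_when_all_clean(self):
        ds = build_dataset({"X": [[0, 1], [2, 1]]})
        filtered, report = gd.filter_individuals(ds)
        assert report.n_individuals_removed == 0
        assert filtered.genotypes.individuals == ds.genotypes.individuals

    def test_emptied_accession_flagged_excluded(self):
        bad = [[M] * 10 for _ in range(3)]
        good = [[0, 1] * 5 for _ in range(3)]
        ds = build_dataset({"A": bad, "B": good})
        filtered, report = gd.filter_individuals(ds)
        assert report.excluded_accessions == ("A",)
        assert filtered.accessions["A"].excluded
        assert "A" not in filtered.accessions.active_codes()
        # downstream statistics skip the excluded accession
        div = gd.accession_diversity(filtered)
        assert list(div["accession"]) == ["B"]


class TestFailureByChromosome:
    def test_hand_counts(self):
        markers = [f"m{i}" for i in range(1, 7)]
        chrom = ["X", "X", "X", "X", "Y", "Y"]
        mm = simple_map(markers)
        mm.table["chromosome"] = chrom
        calls = [[M, M, 0, 1, 0, 1], [M, M, 1, 2, 1, 0]]
        ds = build_dataset({"A": calls}, marker_map=mm, marker_ids=markers)
        _, report = gd.filter_markers(ds)
        table = gd.failure_by_chromosome(ds, report).set_index("chromosome")
        assert table.loc["X", "proportion_failed"] == pytest.approx(0.5)
        assert table.loc["Y", "proportion_failed"] == 0.0

    def test_unmapped_only(self):
        calls = [[M, 0], [M, 1]]
        ds = build_dataset({"A": calls})  # no map at all
        _, report = gd.filter_markers(ds)
        table = gd.failure_by_chromosome(ds, report)
        assert list(table["chromosome"]) == ["unmapped"]
        assert table["proportion_failed"].iloc[0] == pytest.approx(0.5)


class TestReplicateConcordance:
    def test_counts_and_missing_exclusion(self):
        calls = [
            [0, 1, 2, 1],
            [0, 1, 2, 1],   # identical to X-1
            [0, 2, 2, 1],   # one discordant marker vs X-1
            [0, M, 2, 1],   # missing call excluded from both sides
        ]
        ds = build_dataset({"X": calls})
        table = gd.replicate_concordance(
            ds, [("X-1", "X-2"), ("X-1", "X-3"), ("X-1", "X-4")]
        ).set_index("individual_b")
        assert table.loc["X-2", "n_discordant"] == 0
        assert table.loc["X-3", "n_discordant"] == 1
        assert table.loc["X-4", "n_comparable"] == 3

    def test_zero_comparable_flagged(self):
        ds = build_dataset({"X": [[M, 0], [1, M]]})
        table = gd.replicate_concordance(ds, [("X-1", "X-2")])
        assert bool(table["undefined"].iloc[0])
        assert np.isnan(table["n_discordant"].iloc[0])


class TestHweScan:
    def _dataset_from_counts(self, n00, n01, n11, extra_markers=0):
        """One accession whose single tested marker has the given genotype
        counts, plus optional extra polymorphic markers."""
        col = [0] * n00 + [1] * n01 + [2] * n11
        rows = [[c] + [i % 3 for _ in range(extra_markers)] for i, c in enumerate(col)]
        return build_dataset({"X": rows})

    def test_exact_hwe_counts_not_flagged(self):
        ds = self._dataset_from_counts(1, 2, 1)
        table, flagged = gd.hwe_scan(ds)
        row = table[table.marker == "m1"].iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert not flagged

    def test_heterozygote_deficit_flagged(self):
        # counts (5, 0, 5): expected (2.5, 5, 2.5) at p = 0.5 -> chi2 = 10
        ds = self._dataset_from_counts(5, 0, 5)
        table, flagged = gd.hwe_scan(ds, alpha=0.05)
        row = table[table.marker == "m1"].iloc[0]
        assert row["chi2"] == pytest.approx(10.0)
        assert row["p"] == pytest.approx(stats.chi2.sf(10, 1), rel=1e-9)
        assert ("X", "m1") in flagged

    def test_bonferroni_threshold_uses_tests_performed(self):
        # p ~ 0.0016 clears alpha = 0.05 but not alpha / 1000
        p_value = stats.chi2.sf(10.0, 1)
        assert p_value < 0.05 and p_value > 0.05 / 1000
        ds = self._dataset_from_counts(5, 0, 5, extra_markers=2)
        table, flagged = gd.hwe_scan(ds, alpha=0.05, bonferroni=True)
        # monomorphic markers are skipped; denominator = tests performed
        n_tests = len(table[table.accession == "X"])
        np.testing.assert_allclose(table["threshold"], 0.05 / n_tests)

    def test_monomorphic_marker_skipped(self):
        ds = build_dataset({"X": [[0, 0], [0, 1], [0, 2]]})
        table, _ = gd.hwe_scan(ds)
        assert list(table["marker"]) == ["m2"]

    def test_type_one_error_calibrated_under_hwe(self):
        """Under HWE the uncorrected scan flags about alpha of the markers."""
        rng = np.random.default_rng(42)
        n_ind, n_loci = 300, 600
        calls = rng.binomial(2, 0.5, size=(n_ind, n_loci))
        ds = build_dataset({"X": calls.tolist()})
        table, flagged = gd.hwe_scan(ds, alpha=0.05)
        rate = len(flagged) / len(table)
        se = np.sqrt(0.05 * 0.95 / len(table))
        assert abs(rate - 0.05) < 3 * se + 0.01
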