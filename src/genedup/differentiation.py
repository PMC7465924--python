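"""Pairwise accession differentiation: multilocus F_ST with permutation
significance and shared-allele summaries.

The estimator is Nei's G_ST for two demes with equal deme weights and
ratio-of-sums multilocus combination: per locus,

    h_S = (h_A + h_B) / 2            with h = 1 - p^2 - q^2,
    p_bar = (p_A + p_B) / 2,
    h_T = 1 - p_bar^2 - q_bar^2,

and F_ST = 1 - sum_l h_S / sum_l h_T over loci with h_T > 0.  Sample
allele frequencies enter without a sample-size correction.  Significance
comes from a permutation test that reshuffles individuals (not alleles)
between the two accessions, preserving accession sizes and genotypic
associations within individuals.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, AccessionTable, StudyDataset, logger


@dataclass
class PairwiseStat:
    """F_ST (with permutation p) and shared-allele average for one pair."""

    acc_a: str
    acc_b: str
    fst: float
    p_value: float
    n_loci: int
    shared_alleles: float
    n_perm: int = 0
    error: str | None = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.acc_a, self.acc_b))


def _stable_hash(text: str) -> int:
    """Deterministic 32-bit hash for seed derivation (not Python's hash)."""
    return zlib.crc32(text.encode())


def _pair_matrices(dataset: StudyDataset, acc_a: str, acc_b: str):
    rows_a = dataset.accession_rows(acc_a)
    rows_b = dataset.accession_rows(acc_b)
    calls = dataset.genotypes.calls[np.concatenate([rows_a, rows_b])]
    called = (calls != MISSING).astype(float)
    dosage = np.where(calls != MISSING, calls, 0).astype(float)
    return dosage, called, len(rows_a), len(rows_b)


def _locus_h_components(
    alt_a: np.ndarray, n_a: np.ndarray, alt_b: np.ndarray, n_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (h_S, h_T); NaN where either deme has no called genotype."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = (2 * n_a - alt_a) / (2 * n_a)
        p_b = (2 * n_b - alt_b) / (2 * n_b)
    usable = (n_a > 0) & (n_b > 0)
    p_a = np.where(usable, p_a, np.nan)
    p_b = np.where(usable, p_b, np.nan)
    h_a = 2 * p_a * (1 - p_a)
    h_b = 2 * p_b * (1 - p_b)
    h_s = (h_a + h_b) / 2
    p_bar = (p_a + p_b) / 2
    h_t = 2 * p_bar * (1 - p_bar)
    return h_s, h_t


def multilocus_fst(h_s: np.ndarray, h_t: np.ndarray) -> float:
    """Ratio-of-sums F_ST over loci with h_T > 0 (NaN loci excluded)."""
    use = np.isfinite(h_t) & (h_t > 0)
    if not use.any():
        raise ValueError("all loci monomorphic in the pooled pair; F_ST undefined")
    return float(1 - h_s[use].sum() / h_t[use].sum())


def _fst_pair_arrays(dosage, called, n_a_ind):
    """(h_S, h_T) per locus from stacked pair matrices."""
    alt_a = dosage[:n_a_ind].sum(axis=0)
    n_a = called[:n_a_ind].sum(axis=0)
    alt_b = dosage[n_a_ind:].sum(axis=0)
    n_b = called[n_a_ind:].sum(axis=0)
    return _locus_h_components(alt_a, n_a, alt_b, n_b)


def pair_locus_components(
    dataset: StudyDataset, acc_a: str, acc_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (h_S, h_T) for a pair over all dataset markers.

    Shared with the marker-subsampling module, which recombines the same
    per-locus components over random marker subsets.
    """
    dosage, called, n_a_ind, _ = _pair_matrices(dataset, acc_a, acc_b)
    return _fst_pair_arrays(dosage, called, n_a_ind)


def shared_alleles(dataset: StudyDataset, acc_a: str, acc_b: str) -> float:
    """Average per-locus count of allele labels observed in both accessions."""
    dosage, called, n_a_ind, _ = _pair_matrices(dataset, acc_a, acc_b)
    alt_a = dosage[:n_a_ind].sum(axis=0)
    n_a = called[:n_a_ind].sum(axis=0)
    alt_b = dosage[n_a_ind:].sum(axis=0)
    n_b = called[n_a_ind:].sum(axis=0)
    usable = (n_a > 0) & (n_b > 0)
    if not usable.any():
        raise ValueError(f"no usable loci for pair ({acc_a}, {acc_b})")
    ref_shared = ((2 * n_a - alt_a) > 0) & ((2 * n_b - alt_b) > 0)
    alt_shared = (alt_a > 0) & (alt_b > 0)
    shared = ref_shared.astype(int) + alt_shared.astype(int)
    return float(shared[usable].mean())


def pairwise_fst(
    dataset: StudyDataset,
    acc_a: str,
    acc_b: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> PairwiseStat:
    """Multilocus F_ST between two accessions with a permutation p-value.

    The permutation null reshuffles individuals between the two accessions
    preserving sizes; p = (#{F_perm >= F_obs} + 1) / (n_perm + 1), so p is
    never 0.
    """
    for code in (acc_a, acc_b):
        sub = dataset.genotypes.calls[dataset.accession_rows(code)]
        if (np.any(sub != MISSING, axis=1)).sum() < 2:
            raise ValueError(f"accession {code} has fewer than 2 called individuals")
    # canonical order so the result is symmetric in the pair
    lo, hi = sorted((acc_a, acc_b))
    dosage, called, n_a_ind, n_b_ind = _pair_matrices(dataset, lo, hi)
    h_s, h_t = _fst_pair_arrays(dosage, called, n_a_ind)
    fst = multilocus_fst(h_s, h_t)
    n_loci = int((np.isfinite(h_t) & (h_t > 0)).sum())
    shared = shared_alleles(dataset, acc_a, acc_b)

    p_value = np.nan
    if n_perm > 0:
        # order-independent stream so stat(A, B) == stat(B, A)
        rng = np.random.default_rng(
            [seed, *sorted((_stable_hash(acc_a), _stable_hash(acc_b)))]
        )
        n_tot = n_a_ind + n_b_ind
        # one-hot selection of the permuted "A" group; BLAS does the counting
        perm = np.argsort(rng.random((n_perm, n_tot)), axis=1)[:, :n_a_ind]
        sel = np.zeros((n_perm, n_tot))
        np.put_along_axis(sel, perm, 1.0, axis=1)
        alt_a = sel @ dosage
        n_a = sel @ called
        alt_b = dosage.sum(axis=0) - alt_a
        n_b = called.sum(axis=0) - n_a
        h_s_p, h_t_p = _locus_h_components(alt_a, n_a, alt_b, n_b)
        valid = np.isfinite(h_t_p) & (h_t_p > 0)
        num = np.where(valid, h_s_p, 0.0).sum(axis=1)
        den = np.where(valid, h_t_p, 0.0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = 1 - num / den
        f_perm = f_perm[np.isfinite(f_perm)]
        p_value = float(((f_perm >= fst).sum() + 1) / (len(f_perm) + 1))

    return PairwiseStat(acc_a, acc_b, fst, p_value, n_loci, shared, n_perm)


def fst_matrix(
    dataset: StudyDataset, n_perm: int = 1000, seed: int = 0
) -> list[PairwiseStat]:
    """All unordered accession pairs; deterministic given the seed.

    Per-pair random streams are derived from the master seed and the pair's
    accession codes, so results for a pair do not depend on which other
    pairs are computed.  Pairwise failures become flagged entries rather
    than aborting the whole matrix.
    """
    codes = dataset.accessions.active_codes()
    if len(codes) < 2:
        raise ValueError("need at least 2 accessions for an F_ST matrix")
    out: list[PairwiseStat] = []
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            try:
                out.append(pairwise_fst(dataset, a, b, n_perm=n_perm, seed=seed))
            except ValueError as exc:
                logger.warning("pair (%s, %s) flagged: %s", a, b, exc)
                out.append(PairwiseStat(a, b, np.nan, np.nan, 0, np.nan, n_perm, str(exc)))
    return out


def stats_to_frame(pairs: list[PairwiseStat], accessions: AccessionTable) -> pd.DataFrame:
    rows = [
        (
            s.acc_a,
            s.acc_b,
            accessions[s.acc_a].name_group == accessions[s.acc_b].name_group,
            s.fst,
            s.p_value,
            s.shared_alleles,
            s.n_loci,
            s.error or "",
        )
        for s in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["acc_a", "acc_b", "same_group", "fst", "p_perm", "shared_alleles", "n_loci", "error"],
    )


@dataclass
class GroupFstSummary:
    within_mean: float
    between_mean: float
    t: float
    p: float
    n_within: int
    n_between: int


def group_fst_summary(
    pairs: list[PairwiseStat], accessions: AccessionTable
) -> GroupFstSummary:
    """Mean F_ST within vs between name groups, with a Welch t-test."""
    within, between = [], []
    for s in pairs:
        if s.error is not None or not np.isfinite(s.fst):
            continue
        same = accessions[s.acc_a].name_group == accessions[s.acc_b].name_group
        (within if same else between).append(s.fst)
    if not within:
        raise ValueError("no within-group pairs")
    if not between:
        raise ValueError("no between-group pairs")
    t, p = stats.ttest_ind(within, between, equal_var=False)
    return GroupFstSummary(
        float(np.mean(within)), float(np.mean(between)), float(t), float(p),
        len(within), len(between),
    )


def write_pairwise_table(
    pairs: list[PairwiseStat], accessions: AccessionTable, path: str | Path
) -> None:
    stats_to_frame(pairs, accessions).to_csv(path, sep="\t", index=False, float_format="%.6g")
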