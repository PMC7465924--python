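"""Synthetic genebank datasets with known truth.

The generator emulates the structure the analysis assumes: name groups of
accessions, 10 genotyped individuals per accession in Hardy-Weinberg
proportions, group-level and accession-level divergence, regeneration
drift that grows with accession age, duplicate accession pairs, missing
calls, and optional re-genotyped replicate individuals.

Divergence follows a hierarchical Balding-Nichols model: a subunit's
allele frequency is Beta-distributed around its parent's with divergence
parameter F.  Because the pipeline's pairwise estimator compares two demes
against their own pooled frequencies (expected value F/(2-F) for raw
Balding-Nichols F), the generator calibrates the Beta parameter as
F' = 2F/(1+F) so that a configured ``f_acc`` (or ``f_group``) equals the
expected pairwise F_ST between sibling units at large sample size.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    Accession,
    AccessionTable,
    GenotypeMatrix,
    MarkerMap,
    StudyDataset,
)
from .drift import wright_fisher_step

#: accession counts per name group in the default design (27 accessions in
#: 10 groups: pairs, triplets and larger groups, as in a genebank
#: duplicate-candidate screen)
DEFAULT_GROUP_SIZES: tuple[int, ...] = (5, 2, 2, 4, 2, 3, 3, 2, 2, 2)


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults are the study conditions."""

    n_groups: int = 10
    accessions_per_group: int | Sequence[int] = DEFAULT_GROUP_SIZES
    individuals_per_accession: int = 10
    n_markers: int = 2000
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    f_group: float = 0.12
    f_acc: float = 0.10
    duplicate_links: int | Sequence[tuple[int, int]] = 2
    duplicate_drift_cycles: int = 5
    regen_population_size: int = 50
    regeneration_interval_years: int = 6
    year_range: tuple[int, int] = (1930, 1997)
    reference_year: int = 2020
    age_drift: bool = True
    missing_rate: float = 0.05
    replicate_pairs: int = 0
    replicate_error_rate: float = 3e-4
    chrom_failure_probs: Mapping[str, float] | None = None
    n_chromosomes: int = 9
    seed: int = 0

    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.accessions_per_group, int):
            return (self.accessions_per_group,) * self.n_groups
        sizes = tuple(self.accessions_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("accessions_per_group length must equal n_groups")
        return sizes

    def __post_init__(self) -> None:
        for name, f in (("f_group", self.f_group), ("f_acc", self.f_acc)):
            if not (0 <= f < 1):
                raise ValueError(f"{name} must lie in [0, 1); got {f}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.founder_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("founder_freq_range must satisfy 0 < lo < hi < 1")
        if self.individuals_per_accession < 1 or self.n_markers < 1:
            raise ValueError("need at least 1 individual and 1 marker")


@dataclass
class SyntheticTruth:
    """Latent state of a generated dataset, for oracle-style tests."""

    founder_p: np.ndarray
    group_p: dict[str, np.ndarray]
    accession_p: dict[str, np.ndarray]
    duplicate_links: tuple[tuple[str, str], ...]
    drift_cycles: dict[str, int]
    replicate_pairs: tuple[tuple[str, str], ...]
    config: SyntheticConfig


def _calibrated(f: float) -> float:
    """Beta divergence giving expected pairwise two-deme G_ST equal to f."""
    return 2 * f / (1 + f)


def _beta_divergence(parent: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f <= 0:
        return parent.copy()
    ratio = (1 - f) / f
    child = parent.copy()
    # loci already fixed in the parent stay fixed; Beta is undefined there
    interior = (parent > 0) & (parent < 1)
    child[interior] = rng.beta(parent[interior] * ratio, (1 - parent[interior]) * ratio)
    return child


def _auto_links(group_sizes: tuple[int, ...], k: int) -> list[tuple[int, int]]:
    """Place k duplicate links, one per group with at least two accessions."""
    links: list[tuple[int, int]] = []
    offset = 0
    for size in group_sizes:
        if len(links) >= k:
            break
        if size >= 2:
            links.append((offset, offset + 1))
        offset += size
    if len(links) < k:
        raise ValueError(f"cannot place {k} duplicate links in the configured groups")
    return links


def generate_study(config: SyntheticConfig) -> tuple[StudyDataset, SyntheticTruth]:
    """Generate a :class:`StudyDataset` and the latent truth behind it."""
    rng = np.random.default_rng(config.seed)
    sizes = config.group_sizes()
    n_acc = sum(sizes)
    lo, hi = config.founder_freq_range
    founder = rng.uniform(lo, hi, config.n_markers)

    # hierarchical frequencies
    group_labels = [f"group{g + 1:02d}" for g in range(config.n_groups)]
    group_p = {
        lab: _beta_divergence(founder, _calibrated(config.f_group), rng)
        for lab in group_labels
    }
    codes: list[str] = []
    code_group: dict[str, str] = {}
    for g, size in enumerate(sizes):
        for a in range(size):
            code = f"G{g + 1:02d}A{a + 1}"
            codes.append(code)
            code_group[code] = group_labels[g]
    acc_p = {
        code: _beta_divergence(group_p[code_group[code]], _calibrated(config.f_acc), rng)
        for code in codes
    }

    # metadata: acquisition year drives the number of regeneration cycles
    years = {
        code: int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        for code in codes
    }
    cycles: dict[str, int] = {}
    for code in codes:
        if config.age_drift:
            cycles[code] = max(
                0,
                (config.reference_year - years[code]) // config.regeneration_interval_years,
            )
        else:
            cycles[code] = 0

    # duplicate links: the second accession restarts from its partner's
    # frequencies and then drifts a few extra regeneration cycles
    if isinstance(config.duplicate_links, int):
        links_idx = _auto_links(sizes, config.duplicate_links)
    else:
        links_idx = [tuple(pair) for pair in config.duplicate_links]
    for i, j in links_idx:
        if not (0 <= i < n_acc and 0 <= j < n_acc):
            raise ValueError(f"duplicate link ({i}, {j}) references a missing accession")
    links = tuple((codes[i], codes[j]) for i, j in links_idx)

    def drift(p: np.ndarray, n_cycles: int) -> np.ndarray:
        for _ in range(n_cycles):
            p = wright_fisher_step(p, config.regen_population_size, rng)
        return p

    for code in codes:
        acc_p[code] = drift(acc_p[code], cycles[code])
    for a, b in links:
        acc_p[b] = drift(acc_p[a].copy(), config.duplicate_drift_cycles)
        cycles[b] = cycles[a] + config.duplicate_drift_cycles
        years[b] = years[a]

    # genotypes: HWE within accession (binomial dosage of the alt allele)
    n_ind = config.individuals_per_accession
    individuals: list[str] = []
    rows: list[np.ndarray] = []
    accessions: dict[str, Accession] = {}
    genebanks = ("VIR", "NGB")
    for k, code in enumerate(codes):
        ids = tuple(f"{code}-{i + 1:02d}" for i in range(n_ind))
        individuals.extend(ids)
        alt_p = 1 - acc_p[code]
        rows.append(rng.binomial(2, alt_p[None, :].repeat(n_ind, axis=0)))
        accessions[code] = Accession(
            code=code,
            individuals=ids,
            name_group=code_group[code],
            genebank=genebanks[k % 2],
            acquisition_year=years[code],
            accession_name=f"synthetic {code}",
            accession_number=f"SYN{k:04d}",
        )
    calls = np.concatenate(rows, axis=0).astype(np.int8)

    # re-genotyped replicate individuals with a small per-call error rate
    replicate_pairs: list[tuple[str, str]] = []
    if config.replicate_pairs > 0:
        picks = rng.choice(len(individuals), size=config.replicate_pairs, replace=False)
        for idx in picks:
            original = individuals[idx]
            rep_id = f"{original}-rep"
            row = calls[idx].copy()
            flip = rng.random(config.n_markers) < config.replicate_error_rate
            if flip.any():
                shift = rng.integers(1, 3, size=int(flip.sum()))
                row[flip] = (row[flip] + shift) % 3
            calls = np.vstack([calls, row[None, :]]).astype(np.int8)
            individuals.append(rep_id)
            code = next(c for c in codes if original in accessions[c].individuals)
            acc = accessions[code]
            accessions[code] = replace(acc, individuals=acc.individuals + (rep_id,))
            replicate_pairs.append((original, rep_id))

    # marker map: round-robin chromosome assignment
    markers = tuple(f"M{j + 1:05d}" for j in range(config.n_markers))
    chroms = [f"C{(j % config.n_chromosomes) + 1:02d}" for j in range(config.n_markers)]
    positions = [10_000 * (j // config.n_chromosomes + 1) for j in range(config.n_markers)]
    marker_map = MarkerMap(
        pd.DataFrame(
            {"chromosome": chroms, "position": positions, "allele1": "A", "allele2": "B"},
            index=pd.Index(markers, name="marker"),
        )
    )

    # chromosome-dependent total marker failure (array-transfer regime)
    if config.chrom_failure_probs:
        fail_p = np.array([config.chrom_failure_probs.get(c, 0.0) for c in chroms])
        failed_cols = rng.random(config.n_markers) < fail_p
        calls[:, failed_cols] = MISSING

    genotypes = GenotypeMatrix(tuple(individuals), markers, calls)
    dataset = StudyDataset(genotypes, marker_map, AccessionTable(accessions))
    if config.missing_rate > 0:
        dataset = inject_missingness(
            dataset, config.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    truth = SyntheticTruth(
        founder_p=founder,
        group_p=group_p,
        accession_p=acc_p,
        duplicate_links=links,
        drift_cycles=cycles,
        replicate_pairs=tuple(replicate_pairs),
        config=config,
    )
    return dataset, truth


def inject_missingness(dataset: StudyDataset, rate: float, seed: int = 0) -> StudyDataset:
    """Set each call to MISSING independently with probability ``rate``."""
    if not (0 <= rate < 1):
        raise ValueError("missing-call rate must lie in [0, 1)")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    mask = rng.random(dataset.genotypes.calls.shape) < rate
    calls = np.where(mask, MISSING, dataset.genotypes.calls).astype(np.int8)
    return StudyDataset(
        GenotypeMatrix(dataset.genotypes.individuals, dataset.genotypes.markers, calls),
        dataset.marker_map,
        dataset.accessions,
    )
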