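"""Genotype quality control.

Marker filtering removes, in fixed order, markers that failed entirely,
markers with a single observed allele, and markers missing in more than a
threshold fraction of individuals (strict comparison).  Individual
filtering then drops individuals with too many missing calls over the
retained markers.  The module also provides per-chromosome failure
summaries, replicate-genotyping concordance, and a per-accession
Hardy-Weinberg chi-square scan.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, StudyDataset, logger


@dataclass
class QcReport:
    """Accounting of one filtering pass.

    Marker counts satisfy
    ``n_markers_out = n_markers_in - n_failed - n_invariant - n_over_missing``;
    a marker is counted once, in the first matching category
    (failed -> invariant -> over-missing).
    """

    n_markers_in: int = 0
    n_failed: int = 0
    n_invariant: int = 0
    n_over_missing: int = 0
    n_markers_out: int = 0
    n_individuals_removed: int = 0
    failed_markers: tuple[str, ...] = ()
    invariant_markers: tuple[str, ...] = ()
    over_missing_markers: tuple[str, ...] = ()
    removed_individuals: tuple[str, ...] = ()
    excluded_accessions: tuple[str, ...] = ()
    per_individual_missing: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_markers_out != (
            self.n_markers_in - self.n_failed - self.n_invariant - self.n_over_missing
        ):
            raise ValueError("QcReport marker accounting identity violated")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def filter_markers(
    dataset: StudyDataset, max_missing_frac: float = 0.5
) -> tuple[StudyDataset, QcReport]:
    """Remove failed, invariant and over-missing markers.

    'Over-missing' means a missing fraction *strictly* greater than
    ``max_missing_frac`` (a marker missing in exactly half the individuals
    is retained at the default 0.5).
    """
    if not (0 < max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in (0, 1]")
    calls = dataset.genotypes.calls
    n_ind = dataset.n_individuals
    called = calls != MISSING
    n_called = called.sum(axis=0)
    miss_frac = 1.0 - n_called / n_ind

    failed = n_called == 0
    alt = np.where(called, calls, 0).sum(axis=0)
    ref = 2 * n_called - alt
    invariant = ~failed & ((alt == 0) | (ref == 0))
    over = ~failed & ~invariant & (miss_frac > max_missing_frac)

    markers = np.asarray(dataset.genotypes.markers)
    keep = ~(failed | invariant | over)
    if not keep.any():
        raise ValueError(
            "all markers removed by QC; inspect genotyping quality before proceeding"
        )
    report = QcReport(
        n_markers_in=len(markers),
        n_failed=int(failed.sum()),
        n_invariant=int(invariant.sum()),
        n_over_missing=int(over.sum()),
        n_markers_out=int(keep.sum()),
        failed_markers=tuple(markers[failed]),
        invariant_markers=tuple(markers[invariant]),
        over_missing_markers=tuple(markers[over]),
    )
    return dataset.subset_markers(list(markers[keep])), report


def filter_individuals(
    dataset: StudyDataset, max_missing_frac: float = 0.4
) -> tuple[StudyDataset, QcReport]:
    """Drop individuals whose missing fraction strictly exceeds the threshold.

    Run after :func:`filter_markers`: the fractions are computed over the
    retained markers.  Accessions left without individuals are flagged
    excluded (with a warning), not deleted.
    """
    if not (0 < max_missing_frac <= 1):
        raise ValueError("max_missing_frac must be in (0, 1]")
    calls = dataset.genotypes.calls
    n_markers = dataset.n_markers
    miss_frac = (calls == MISSING).sum(axis=1) / n_markers
    individuals = np.asarray(dataset.genotypes.individuals)
    keep = miss_frac <= max_missing_frac
    removed = individuals[~keep]
    filtered = dataset.subset_individuals(list(individuals[keep]))
    excluded = tuple(
        a.code for a in filtered.accessions if a.excluded and not dataset.accessions[a.code].excluded
    )
    report = QcReport(
        n_markers_in=n_markers,
        n_markers_out=n_markers,
        n_individuals_removed=int((~keep).sum()),
        removed_individuals=tuple(removed),
        excluded_accessions=excluded,
        per_individual_missing={
            ind: float(f) for ind, f in zip(individuals, miss_frac)
        },
    )
    return filtered, report


def apply_qc(
    dataset: StudyDataset,
    max_marker_missing: float = 0.5,
    max_individual_missing: float = 0.4,
) -> tuple[StudyDataset, QcReport, QcReport]:
    """Marker filtering followed by individual filtering (order fixed)."""
    ds, marker_report = filter_markers(dataset, max_marker_missing)
    ds, ind_report = filter_individuals(ds, max_individual_missing)
    return ds, marker_report, ind_report


def failure_by_chromosome(dataset: StudyDataset, qc: QcReport) -> pd.DataFrame:
    """Proportion of failed markers per chromosome.

    ``dataset`` is the pre-QC dataset whose map covers the failed markers;
    markers without a map entry aggregate under ``unmapped``.
    """
    failed = set(qc.failed_markers)
    rows: dict[str, list[int]] = {}
    for m in dataset.genotypes.markers:
        if dataset.marker_map is not None and m in dataset.marker_map:
            chrom = dataset.marker_map.chromosome(m)
        else:
            chrom = "unmapped"
        n_tot, n_fail = rows.get(chrom, [0, 0])
        rows[chrom] = [n_tot + 1, n_fail + (1 if m in failed else 0)]
    df = pd.DataFrame(
        [(c, t, f, f / t) for c, (t, f) in sorted(rows.items())],
        columns=["chromosome", "n_markers", "n_failed", "proportion_failed"],
    )
    return df


def replicate_concordance(
    dataset: StudyDataset, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Discordant-marker counts for re-genotyped individual pairs.

    Markers with any missing call in a pair are excluded from both the
    numerator and the denominator.  A pair with zero comparable markers is
    flagged and its count left undefined (NaN).
    """
    calls = dataset.genotypes.calls
    records = []
    for a, b in pairs:
        ra, rb = dataset.genotypes.individual_rows([a, b])
        va, vb = calls[ra], calls[rb]
        comparable = (va != MISSING) & (vb != MISSING)
        n_comp = int(comparable.sum())
        if n_comp == 0:
            logger.warning("replicate pair (%s, %s) has no comparable markers", a, b)
            records.append((a, b, 0, np.nan, True))
        else:
            n_disc = int((va[comparable] != vb[comparable]).sum())
            records.append((a, b, n_comp, n_disc, False))
    return pd.DataFrame(
        records,
        columns=["individual_a", "individual_b", "n_comparable", "n_discordant", "undefined"],
    )


def hwe_scan(
    dataset: StudyDataset, alpha: float = 0.05, bonferroni: bool = False
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Per-(accession, marker) Hardy-Weinberg chi-square test.

    One-df goodness of fit of observed genotype counts against the HWE
    expectation from the accession's sample allele frequency, without
    continuity correction.  Markers monomorphic within an accession are
    skipped and do not enter the Bonferroni denominator, which is the
    number of tests actually performed within that accession.
    """
    calls = dataset.genotypes.calls
    markers = np.asarray(dataset.genotypes.markers)
    frames = []
    flagged: set[tuple[str, str]] = set()
    for code in dataset.accessions.active_codes():
        sub = calls[dataset.accession_rows(code)]
        called = sub != MISSING
        n = called.sum(axis=0)
        n0 = ((sub == 0) & called).sum(axis=0)
        n1 = (sub == 1).sum(axis=0)
        n2 = (sub == 2).sum(axis=0)
        alt = n1 + 2 * n2
        ref = 2 * n - alt
        testable = (n > 0) & (alt > 0) & (ref > 0)
        if not testable.any():
            continue
        nt = n[testable].astype(float)
        p = ref[testable] / (2 * nt)
        q = 1 - p
        exp = np.stack([p**2 * nt, 2 * p * q * nt, q**2 * nt])
        obs = np.stack([n0[testable], n1[testable], n2[testable]]).astype(float)
        chi2 = ((obs - exp) ** 2 / exp).sum(axis=0)
        pval = stats.chi2.sf(chi2, df=1)
        n_tests = int(testable.sum())
        threshold = alpha / n_tests if bonferroni else alpha
        flag = pval < threshold
        frames.append(
            pd.DataFrame(
                {
                    "accession": code,
                    "marker": markers[testable],
                    "chi2": chi2,
                    "p": pval,
                    "threshold": threshold,
                    "flagged": flag,
                }
            )
        )
        for m in markers[testable][flag]:
            flagged.add((code, str(m)))
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            columns=["accession", "marker", "chi2", "p", "threshold", "flagged"]
        )
    return table, flagged
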