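"""Within-accession diversity statistics and diversity-metadata associations.

Per accession and locus: the observed number of alleles (1 or 2), Nei's
gene diversity h = 1 - sum(p_a^2) (the expected heterozygosity under HWE,
computed from sample allele frequencies without small-sample correction),
and the observed heterozygosity.  Loci with no called genotype in an
accession are excluded from that accession's averages.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, AccessionTable, StudyDataset, logger


def accession_diversity(dataset: StudyDataset) -> pd.DataFrame:
    """Diversity table with one row per (non-excluded) accession.

    Columns: ``accession``, ``n_loci``, ``avg_alleles``, ``nei_h``,
    ``obs_het``.
    """
    calls = dataset.genotypes.calls
    rows = []
    for acc in dataset.accessions:
        if acc.excluded or not acc.individuals:
            logger.info("accession %s excluded; skipped in diversity table", acc.code)
            continue
        sub = calls[dataset.accession_rows(acc.code)]
        called = sub != MISSING
        n = called.sum(axis=0)
        use = n > 0
        if not use.any():
            logger.warning("accession %s has no called loci; skipped", acc.code)
            continue
        nt = n[use].astype(float)
        alt = np.where(called, sub, 0).sum(axis=0)[use]
        ref = 2 * nt - alt
        p = ref / (2 * nt)
        q = 1 - p
        n_alleles = (ref > 0).astype(int) + (alt > 0).astype(int)
        h = 1 - p**2 - q**2
        het = (sub == 1).sum(axis=0)[use] / nt
        rows.append(
            (
                acc.code,
                int(use.sum()),
                float(n_alleles.mean()),
                float(h.mean()),
                float(het.mean()),
            )
        )
    return pd.DataFrame(
        rows, columns=["accession", "n_loci", "avg_alleles", "nei_h", "obs_het"]
    )


def diversity_metadata_correlation(
    rows: pd.DataFrame,
    accessions: AccessionTable,
    filter_genebank: str | None = None,
) -> tuple[float, float, int]:
    """Pearson correlation between acquisition year and Nei's h.

    Optionally restricted to accessions held by one genebank.  Returns
    ``(c, p, n)`` with the two-sided p-value from the t transform.
    """
    years, hs = [], []
    for _, row in rows.iterrows():
        acc = accessions[row["accession"]]
        if acc.acquisition_year is None:
            continue
        if filter_genebank is not None and acc.genebank != filter_genebank:
            continue
        years.append(acc.acquisition_year)
        hs.append(row["nei_h"])
    if len(years) < 3:
        raise ValueError(
            f"need >= 3 accessions with both year and h, got {len(years)}"
        )
    if np.std(years) == 0 or np.std(hs) == 0:
        raise ValueError("zero variance in year or diversity; correlation undefined")
    c, p = stats.pearsonr(years, hs)
    return float(c), float(p), len(years)


def genebank_diversity_ttest(
    rows: pd.DataFrame,
    accessions: AccessionTable,
    group_a: str,
    group_b: str,
) -> tuple[float, float]:
    """Welch two-sample t-test on Nei's h between two holding genebanks."""
    a = [
        row["nei_h"]
        for _, row in rows.iterrows()
        if accessions[row["accession"]].genebank == group_a
    ]
    b = [
        row["nei_h"]
        for _, row in rows.iterrows()
        if accessions[row["accession"]].genebank == group_b
    ]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each genebank group needs >= 2 accessions for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def write_diversity_table(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
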