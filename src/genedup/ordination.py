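"""Principal component analysis of accession allele frequencies and of
individual allele-copy counts.

Both PCAs use two variables per locus — the frequency (or copy count) of
each of the two alleles — mean-centered but not scaled to unit variance,
decomposed by SVD.  The two columns of a locus are perfectly anticorrelated
after centering; keeping both doubles each eigenvalue but leaves the score
geometry unchanged.  Components are oriented so the largest-magnitude
loading is positive, making outputs reproducible up to that convention.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, FrequencyTable, StudyDataset, logger

#: suffixes naming the two allele variables of a locus
_REF_SUFFIX = "|ref"
_ALT_SUFFIX = "|alt"


@dataclass
class PcaResult:
    """Scores (unit x PC), loadings (variable x PC) and variance shares."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray

    def __post_init__(self) -> None:
        if (self.explained < -1e-12).any():
            raise ValueError("negative explained-variance proportion")
        if self.explained.sum() > 1 + 1e-9:
            raise ValueError("explained-variance proportions sum above 1")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for var in self.loadings.index:
            seen.setdefault(_marker_of(var), None)
        return list(seen)


def _marker_of(variable: str) -> str:
    for suffix in (_REF_SUFFIX, _ALT_SUFFIX):
        if variable.endswith(suffix):
            return variable[: -len(suffix)]
    return variable


def _pca(matrix: np.ndarray, unit_ids, variable_ids) -> PcaResult:
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 units and 2 variables")
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # null components carry arbitrary orthonormal vectors from the SVD;
    # zero them so they cannot fake segregation in downstream rankings
    null = s <= (s[0] * 1e-9 if s[0] > 0 else np.inf)
    s = np.where(null, 0.0, s)
    vt[null] = 0.0
    u[:, null] = 0.0
    # orient each component so its largest-|loading| is positive
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    total = (s**2).sum()
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=list(unit_ids), columns=pcs)
    loadings = pd.DataFrame(vt.T, index=list(variable_ids), columns=pcs)
    return PcaResult(scores, loadings, explained)


def accession_pca(freqs: FrequencyTable) -> PcaResult:
    """PCA of per-accession allele frequencies.

    Variables are the two allele frequencies (p and 1-p) per locus; loci
    with an absent frequency in any accession are dropped (complete-case
    columns).
    """
    if len(freqs.units) < 2:
        raise ValueError("accession PCA needs at least 2 accessions")
    complete = ~np.isnan(freqs.p).any(axis=0)
    if complete.sum() < 1:
        raise ValueError("no loci with complete accession frequencies")
    markers = np.asarray(freqs.markers)[complete]
    p = freqs.p[:, complete]
    matrix = np.empty((p.shape[0], 2 * p.shape[1]))
    matrix[:, 0::2] = p
    matrix[:, 1::2] = 1 - p
    variables = [
        name
        for m in markers
        for name in (f"{m}{_REF_SUFFIX}", f"{m}{_ALT_SUFFIX}")
    ]
    return _pca(matrix, freqs.units, variables)


def individual_pca(dataset: StudyDataset) -> PcaResult:
    """PCA of individual allele-copy counts (dosage and its complement).

    Missing dosages are imputed with the marker mean before centering;
    markers with all-missing dosage are dropped.
    """
    calls = dataset.genotypes.calls
    if calls.shape[0] < 2:
        raise ValueError("individual PCA needs at least 2 individuals")
    called = calls != MISSING
    keep = called.any(axis=0)
    if keep.sum() < 1:
        raise ValueError("no markers with any called dosage")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("individual PCA dropped %d all-missing markers", dropped)
    sub = calls[:, keep].astype(float)
    mask = called[:, keep]
    col_mean = np.where(mask, sub, 0).sum(axis=0) / mask.sum(axis=0)
    dosage = np.where(mask, sub, col_mean[None, :])
    markers = np.asarray(dataset.genotypes.markers)[keep]
    matrix = np.empty((dosage.shape[0], 2 * dosage.shape[1]))
    matrix[:, 0::2] = 2 - dosage  # reference-allele copies
    matrix[:, 1::2] = dosage
    variables = [
        name
        for m in markers
        for name in (f"{m}{_REF_SUFFIX}", f"{m}{_ALT_SUFFIX}")
    ]
    return _pca(matrix, dataset.genotypes.individuals, variables)


def top_discriminatory_markers(pca: PcaResult, k: int) -> pd.DataFrame:
    """Markers ranked by segregation along PC1/PC2.

    A marker's score is the maximum absolute loading over its two allele
    variables and the first two components.  Ties break on marker ID so
    the ranking is deterministic.
    """
    if pca.n_components < 2:
        raise ValueError("need at least 2 components to rank markers")
    sub = pca.loadings[["PC1", "PC2"]].abs()
    score = sub.max(axis=1)
    per_marker: dict[str, float] = {}
    for var, s in score.items():
        m = _marker_of(var)
        per_marker[m] = max(per_marker.get(m, 0.0), float(s))
    df = pd.DataFrame(
        sorted(per_marker.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["marker", "score"],
    )
    if k > len(df):
        logger.warning("requested top %d markers but only %d available", k, len(df))
        return df
    return df.head(k).reset_index(drop=True)


def write_pca(pca: PcaResult, prefix: str | Path) -> None:
    prefix = Path(prefix)
    pca.scores.to_csv(f"{prefix}_scores.tsv", sep="\t", index_label="unit")
    pca.loadings.to_csv(f"{prefix}_loadings.tsv", sep="\t", index_label="variable")
    Path(f"{prefix}_variance.json").write_text(
        json.dumps({"explained": [float(x) for x in pca.explained]}, indent=2)
    )
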