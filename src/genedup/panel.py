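"""Linkage disequilibrium (D') and reduced marker-panel selection.

Two-locus haplotype frequencies are estimated from unphased diploid
genotypes by expectation-maximization: only double heterozygotes are
phase-ambiguous and are apportioned between the coupling and repulsion
phases according to the current haplotype-frequency estimates.  D' is
|D| / D_max with the usual frequency-dependent bound.

Panel selection is greedy: markers are traversed in decreasing order of
their discriminatory score along PC1/PC2 of the accession-level PCA, and a
marker is accepted iff its pooled gene diversity exceeds ``h_min``
(strict) and its D' against every already-accepted marker stays below
``d_max`` (strict).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, StudyDataset, allele_frequencies, logger
from .ordination import PcaResult, top_discriminatory_markers

_EM_TOL = 1e-8
_EM_MAX_ITER = 200


@dataclass
class MarkerPanel:
    """Ordered selected markers with a per-marker audit trail.

    ``table`` columns: rank, marker, h, score, max_dprime (maximum D'
    against the markers accepted before it; 0 for the first marker).
    ``rejections`` records each rejected candidate and the reason.
    """

    table: pd.DataFrame
    rejections: pd.DataFrame
    h_min: float
    d_max: float

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.table["marker"])

    def __post_init__(self) -> None:
        if (self.table["h"] <= self.h_min).any():
            raise ValueError("panel member with pooled h at or below h_min")
        if (self.table["max_dprime"] >= self.d_max).any():
            raise ValueError("panel member with recorded D' at or above d_max")


def _genotype_indicators(calls: np.ndarray) -> np.ndarray:
    """(n_individuals, 3) one-hot over dosage classes; missing rows all zero."""
    out = np.zeros((calls.shape[0], 3))
    for d in (0, 1, 2):
        out[:, d] = calls == d
    return out


def _em_batch(counts: np.ndarray) -> np.ndarray:
    """EM haplotype frequencies for a batch of 3x3 genotype-count tables.

    ``counts[k, i, j]`` is the number of individuals with dosage i at the
    first marker and j at the second.  Returns ``(k, 4)`` frequencies in
    the order (ref-ref, ref-alt, alt-ref, alt-alt).
    """
    n = counts.sum(axis=(1, 2))
    if (n == 0).any():
        raise ValueError("pair of markers with no jointly called individuals")
    two_n = 2 * n
    # unambiguous haplotype contributions
    c_rr = 2 * counts[:, 0, 0] + counts[:, 0, 1] + counts[:, 1, 0]
    c_ra = 2 * counts[:, 0, 2] + counts[:, 0, 1] + counts[:, 1, 2]
    c_ar = 2 * counts[:, 2, 0] + counts[:, 1, 0] + counts[:, 2, 1]
    c_aa = 2 * counts[:, 2, 2] + counts[:, 1, 2] + counts[:, 2, 1]
    dh = counts[:, 1, 1].astype(float)  # double heterozygotes
    freq = np.stack([c_rr + dh / 2, c_ra + dh / 2, c_ar + dh / 2, c_aa + dh / 2], axis=1)
    freq = freq / two_n[:, None]
    for _ in range(_EM_MAX_ITER):
        coupling = freq[:, 0] * freq[:, 3]
        repulsion = freq[:, 1] * freq[:, 2]
        denom = coupling + repulsion
        w = np.where(denom > 0, coupling / np.where(denom > 0, denom, 1.0), 0.5)
        new = np.stack(
            [c_rr + dh * w, c_ra + dh * (1 - w), c_ar + dh * (1 - w), c_aa + dh * w],
            axis=1,
        ) / two_n[:, None]
        delta = np.abs(new - freq).max()
        freq = new
        if delta < _EM_TOL:
            break
    return freq


def _dprime_from_hap(freq: np.ndarray) -> np.ndarray:
    """D' per row of (ref-ref, ref-alt, alt-ref, alt-alt) frequencies."""
    p1 = freq[:, 0] + freq[:, 1]  # ref at first marker
    p2 = freq[:, 0] + freq[:, 2]  # ref at second marker
    d = freq[:, 0] - p1 * p2
    d_max = np.where(
        d > 0,
        np.minimum(p1 * (1 - p2), (1 - p1) * p2),
        np.minimum(p1 * p2, (1 - p1) * (1 - p2)),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(d) / d_max
    return np.where(d == 0, 0.0, out)


def _pooled_rows(dataset: StudyDataset) -> np.ndarray:
    return dataset.genotypes.individual_rows(
        [i for acc in dataset.accessions if not acc.excluded for i in acc.individuals]
    )


def dprime(dataset: StudyDataset, marker_a: str, marker_b: str) -> float:
    """D' between two markers in the pooled sample.

    Individuals with a missing call at either marker are excluded.  Either
    marker monomorphic (in the jointly called individuals) is an error:
    D' is undefined there.
    """
    calls = dataset.genotypes.calls[_pooled_rows(dataset)]
    ca = calls[:, dataset.genotypes.marker_cols([marker_a])[0]]
    cb = calls[:, dataset.genotypes.marker_cols([marker_b])[0]]
    keep = (ca != MISSING) & (cb != MISSING)
    ca, cb = ca[keep], cb[keep]
    counts = np.zeros((1, 3, 3))
    for i in range(3):
        for j in range(3):
            counts[0, i, j] = ((ca == i) & (cb == j)).sum()
    for name, vec in ((marker_a, ca), (marker_b, cb)):
        alt = vec.sum()
        if alt == 0 or alt == 2 * len(vec):
            raise ValueError(f"marker {name} is monomorphic; D' undefined")
    return float(_dprime_from_hap(_em_batch(counts))[0])


def _dprime_one_vs_many(
    ind_cand: np.ndarray, ind_panel: np.ndarray
) -> np.ndarray:
    """D' of one candidate marker against a stack of accepted markers.

    ``ind_cand`` is (n, 3); ``ind_panel`` is (n, 3, k).  Missing calls are
    all-zero indicator rows, so the joint counts automatically use only
    individuals called at both markers.
    """
    counts = np.einsum("ni,njk->kij", ind_cand, ind_panel)
    return _dprime_from_hap(_em_batch(counts))


def max_pairwise_dprime(dataset: StudyDataset, markers: Sequence[str]) -> float:
    """Largest D' over all pairs of the given markers (post-hoc audit)."""
    if len(markers) < 2:
        return 0.0
    calls = dataset.genotypes.calls[_pooled_rows(dataset)]
    cols = dataset.genotypes.marker_cols(markers)
    indicators = np.stack(
        [_genotype_indicators(calls[:, c]) for c in cols], axis=2
    )
    worst = 0.0
    for i in range(len(markers) - 1):
        dp = _dprime_one_vs_many(indicators[:, :, i], indicators[:, :, i + 1 :])
        worst = max(worst, float(dp.max()))
    return worst


def select_panel(
    dataset: StudyDataset,
    pca: PcaResult,
    n: int = 500,
    h_min: float = 0.3,
    d_max: float = 0.25,
) -> MarkerPanel:
    """Greedy reduced-panel selection.

    Traverses markers in decreasing discriminatory-score order and accepts
    a marker iff pooled h > ``h_min`` and D' < ``d_max`` against every
    marker accepted so far.  Stops at ``n`` accepted markers or when the
    candidates are exhausted (shorter panel with a warning).
    """
    pooled = allele_frequencies(dataset, by="pooled")
    p = pooled.p[0]
    with np.errstate(invalid="ignore"):
        h_pooled = 1 - p**2 - (1 - p) ** 2
    h_by_marker = dict(zip(pooled.markers, h_pooled))

    ranking = top_discriminatory_markers(pca, k=len(pca.markers()))
    calls = dataset.genotypes.calls[_pooled_rows(dataset)]
    cols = {m: c for m, c in zip(dataset.genotypes.markers, range(dataset.n_markers))}

    accepted: list[tuple[int, str, float, float, float]] = []
    panel_indicators: list[np.ndarray] = []
    rejections: list[tuple[str, str, str]] = []
    for _, row in ranking.iterrows():
        if len(accepted) >= n:
            break
        marker, score = row["marker"], float(row["score"])
        h = h_by_marker.get(marker, np.nan)
        if not np.isfinite(h) or h <= h_min:
            rejections.append((marker, "low_h", f"h={h:.4g}"))
            continue
        ind = _genotype_indicators(calls[:, cols[marker]])
        if panel_indicators:
            dp = _dprime_one_vs_many(ind, np.stack(panel_indicators, axis=2))
            worst = int(np.argmax(dp))
            if dp[worst] >= d_max:
                rejections.append(
                    (marker, "high_ld", f"D'={dp[worst]:.4g} with {accepted[worst][1]}")
                )
                continue
            max_dp = float(dp.max())
        else:
            max_dp = 0.0
        accepted.append((len(accepted) + 1, marker, h, score, max_dp))
        panel_indicators.append(ind)
    if len(accepted) < n:
        logger.warning(
            "panel selection found only %d of the %d requested markers", len(accepted), n
        )
    table = pd.DataFrame(
        accepted, columns=["rank", "marker", "h", "score", "max_dprime"]
    )
    rej = pd.DataFrame(rejections, columns=["marker", "reason", "detail"])
    return MarkerPanel(table, rej, h_min, d_max)


def write_panel(panel: MarkerPanel, dataset: StudyDataset, path: str | Path,
                rejections_path: str | Path | None = None) -> None:
    table = panel.table.copy()
    if dataset.marker_map is not None:
        chrom, pos = [], []
        for m in table["marker"]:
            if m in dataset.marker_map:
                chrom.append(dataset.marker_map.chromosome(m))
                pos.append(int(dataset.marker_map.table.loc[m, "position"]))
            else:
                chrom.append("unmapped")
                pos.append(-1)
        table["chromosome"] = chrom
        table["position"] = pos
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if rejections_path is not None:
        panel.rejections.to_csv(rejections_path, sep="\t", index=False)
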