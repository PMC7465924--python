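"""Marker-subsampling stability of pairwise F_ST.

For each accession pair and subset size, B replicates each draw ``size``
markers uniformly without replacement and recompute the multilocus F_ST.
The summary reports the replicate mean, SD, SE of the mean (SD/sqrt(B)),
and whether the +-1 SE band around the subsample mean contains the
full-data value.  Each (pair, size) combination gets its own random stream
derived from the master seed, so adding pairs or sizes never shifts
existing results.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import StudyDataset
from .differentiation import _stable_hash, multilocus_fst, pair_locus_components


@dataclass
class SubsampleSummary:
    acc_a: str
    acc_b: str
    size: int
    n_replicates: int
    mean_fst: float
    sd_fst: float
    se_fst: float
    full_fst: float
    within_1se: bool

    def __post_init__(self) -> None:
        if self.sd_fst < 0:
            raise ValueError("SD must be non-negative")
        if self.se_fst > self.sd_fst + 1e-12:
            raise ValueError("SE cannot exceed SD")


def subsample_fst_stability(
    dataset: StudyDataset,
    pairs: list[tuple[str, str]],
    sizes: tuple[int, ...] = (10, 50, 100, 500),
    n_replicates: int = 1000,
    seed: int = 0,
) -> list[SubsampleSummary]:
    """Replicate F_ST estimates over random marker subsets.

    Sampling is without replacement within a replicate and independent
    across replicates; no permutation test runs inside replicates.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    n_markers = dataset.n_markers
    for size in sizes:
        if size > n_markers:
            raise ValueError(
                f"subset size {size} exceeds the {n_markers} available markers"
            )
    out: list[SubsampleSummary] = []
    for acc_a, acc_b in pairs:
        h_s, h_t = pair_locus_components(dataset, acc_a, acc_b)
        full = multilocus_fst(h_s, h_t)
        valid = np.isfinite(h_t) & (h_t > 0)
        num = np.where(valid, h_s, 0.0)
        den = np.where(valid, h_t, 0.0)
        for size in sizes:
            rng = np.random.default_rng(
                [seed, *sorted((_stable_hash(acc_a), _stable_hash(acc_b))), size]
            )
            # vectorised draws without replacement: argsort of uniforms
            idx = np.argsort(rng.random((n_replicates, n_markers)), axis=1)[:, :size]
            with np.errstate(divide="ignore", invalid="ignore"):
                f_rep = 1 - num[idx].sum(axis=1) / den[idx].sum(axis=1)
            f_rep = f_rep[np.isfinite(f_rep)]
            mean = float(f_rep.mean())
            sd = float(f_rep.std(ddof=1))
            se = sd / np.sqrt(len(f_rep))
            out.append(
                SubsampleSummary(
                    acc_a,
                    acc_b,
                    size,
                    len(f_rep),
                    mean,
                    sd,
                    float(se),
                    full,
                    # tiny slack so exhaustive subsets are not tripped up
                    # by floating summation order
                    bool(mean - se - 1e-12 <= full <= mean + se + 1e-12),
                )
            )
    return out


def summaries_to_frame(summaries: list[SubsampleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.acc_a, s.acc_b, s.size, s.n_replicates, s.mean_fst,
                s.sd_fst, s.se_fst, s.full_fst, s.within_1se,
            )
            for s in summaries
        ],
        columns=[
            "acc_a", "acc_b", "size", "n_replicates", "mean_fst",
            "sd_fst", "se_fst", "full_fst", "within_1se",
        ],
    )


def write_subsample_table(summaries: list[SubsampleSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False, float_format="%.6g")
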