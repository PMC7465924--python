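"""Pipeline orchestration and the duplicate-evidence report.

A pair of same-name-group accessions is called a candidate duplicate when
several lines of evidence agree: its F_ST sits at or below a low percentile
of all pairwise values and its shared-allele average at or above a high
percentile.  Percentile thresholds — rather than absolute cutoffs — keep
the judgement relative to the dataset at hand, which is how similarity "
compared to the average" is assessed in practice.  An accession whose
nearest neighbour by F_ST lies outside its name group (while a group
partner exists) is flagged as an outlier for its name.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import diversity as _diversity
from . import ordination as _ordination
from . import panel as _panel
from . import qc as _qc
from . import resampling as _resampling
from .core import StudyDataset, allele_frequencies, logger, write_genotypes
from .differentiation import (
    PairwiseStat,
    fst_matrix,
    group_fst_summary,
    stats_to_frame,
    write_pairwise_table,
)
from .ordination import PcaResult
from .synthetic import SyntheticConfig, generate_study


@dataclass
class DuplicateVerdict:
    acc_a: str
    acc_b: str
    same_name_group: bool
    fst: float
    fst_percentile: float
    p_perm: float
    shared_alleles: float
    shared_percentile: float
    pca_dist_percentile: float
    verdict: str  # candidate-duplicate | distinct | outlier-name
    evidence: tuple[str, ...]


def _percentile_of(values: np.ndarray, x: float) -> float:
    """Fraction of values <= x, as a percentage."""
    return float(100.0 * np.mean(values <= x))


def duplicate_report(
    dataset: StudyDataset,
    stats: list[PairwiseStat],
    pca: PcaResult,
    fst_percentile: float = 10.0,
    shared_percentile: float = 90.0,
    morphology: Mapping[tuple[str, str], float] | None = None,
) -> tuple[list[DuplicateVerdict], dict[str, Any]]:
    """Multi-evidence duplicate verdicts over all accession pairs.

    ``morphology`` optionally supplies externally computed per-pair
    p-values; they are echoed into the evidence list, never used in the
    decision rule.
    """
    valid = [s for s in stats if s.error is None and np.isfinite(s.fst)]
    if not valid:
        raise ValueError("differentiation stage produced no valid pairs")
    fsts = np.array([s.fst for s in valid])
    shares = np.array([s.shared_alleles for s in valid])
    fst_thr = float(np.percentile(fsts, fst_percentile))
    shared_thr = float(np.percentile(shares, shared_percentile))

    # PCA centroid distances on PC1-PC2
    pc = pca.scores[["PC1", "PC2"]] if pca.n_components >= 2 else pca.scores
    dists = {
        frozenset((s.acc_a, s.acc_b)): float(
            np.linalg.norm(pc.loc[s.acc_a] - pc.loc[s.acc_b])
        )
        for s in valid
        if s.acc_a in pc.index and s.acc_b in pc.index
    }
    dist_values = np.array(list(dists.values())) if dists else np.array([np.nan])

    # nearest neighbour by F_ST per accession, for name-outlier detection
    neighbours: dict[str, tuple[str, float]] = {}
    for s in valid:
        for me, other in ((s.acc_a, s.acc_b), (s.acc_b, s.acc_a)):
            best = neighbours.get(me)
            if best is None or s.fst < best[1]:
                neighbours[me] = (other, s.fst)
    groups = {a.code: a.name_group for a in dataset.accessions}
    has_partner = {
        code: any(g == groups[code] and c != code for c, g in groups.items())
        for code in groups
    }
    outliers = sorted(
        code
        for code, (nn, _) in neighbours.items()
        if has_partner.get(code, False) and groups[nn] != groups[code]
    )

    verdicts: list[DuplicateVerdict] = []
    for s in valid:
        same = groups[s.acc_a] == groups[s.acc_b]
        evidence: list[str] = []
        low_fst = s.fst <= fst_thr
        high_shared = s.shared_alleles >= shared_thr
        if low_fst:
            evidence.append(f"fst={s.fst:.4g} <= P{fst_percentile:g}={fst_thr:.4g}")
        if high_shared:
            evidence.append(
                f"shared={s.shared_alleles:.4g} >= P{shared_percentile:g}={shared_thr:.4g}"
            )
        if same:
            evidence.append("same name group")
        if same and low_fst and high_shared:
            verdict = "candidate-duplicate"
        elif same and (s.acc_a in outliers or s.acc_b in outliers):
            verdict = "outlier-name"
            who = [c for c in (s.acc_a, s.acc_b) if c in outliers]
            evidence.append(
                "nearest neighbour outside the name group for " + ", ".join(who)
            )
        else:
            verdict = "distinct"
        if morphology:
            key = (s.acc_a, s.acc_b)
            p_m = morphology.get(key, morphology.get((s.acc_b, s.acc_a)))
            if p_m is not None:
                evidence.append(f"morphology p={p_m:.4g} (external)")
        d = dists.get(frozenset((s.acc_a, s.acc_b)), np.nan)
        verdicts.append(
            DuplicateVerdict(
                acc_a=s.acc_a,
                acc_b=s.acc_b,
                same_name_group=same,
                fst=s.fst,
                fst_percentile=_percentile_of(fsts, s.fst),
                p_perm=s.p_value,
                shared_alleles=s.shared_alleles,
                shared_percentile=_percentile_of(shares, s.shared_alleles),
                pca_dist_percentile=(
                    _percentile_of(dist_values, d) if np.isfinite(d) else float("nan")
                ),
                verdict=verdict,
                evidence=tuple(evidence),
            )
        )
    report = {
        "thresholds": {
            "fst_percentile": fst_percentile,
            "fst_value": fst_thr,
            "shared_percentile": shared_percentile,
            "shared_value": shared_thr,
        },
        "n_pairs": len(valid),
        "outlier_name_accessions": outliers,
        "candidate_duplicates": [
            [v.acc_a, v.acc_b] for v in verdicts if v.verdict == "candidate-duplicate"
        ],
        "verdicts": [asdict(v) for v in verdicts],
    }
    return verdicts, report


def run_pipeline(
    dataset: StudyDataset | None = None,
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_perm: int = 1000,
    fst_percentile: float = 10.0,
    shared_percentile: float = 90.0,
    do_resampling: bool = False,
    resampling_sizes: tuple[int, ...] = (10, 50, 100, 500),
    resampling_replicates: int = 1000,
    do_panel: bool = False,
    panel_size: int = 500,
) -> dict[str, Any]:
    """Run qc -> diversity -> differentiation -> ordination
    (-> resampling -> panel) -> report.

    With no ``dataset``, a synthetic study is generated from ``config``
    (defaults if None).  Identical inputs and seed reproduce identical
    outputs; a stage failure halts with the stage name and cause.
    """
    out: dict[str, Any] = {"seed": seed}
    outdir = Path(out_dir) if out_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage '{name}': {exc}") from exc
        logger.info("stage %-14s %.2fs", name, time.perf_counter() - t0)
        return result

    if dataset is None:
        cfg = config if config is not None else SyntheticConfig(seed=seed)
        dataset, truth = stage("simulate", lambda: generate_study(cfg))
        out["truth"] = truth
        if outdir is not None:
            write_genotypes(
                dataset,
                outdir / "genotypes.tsv",
                outdir / "accessions.csv",
                outdir / "markers.tsv",
            )

    ds, marker_report, ind_report = stage("qc", lambda: _qc.apply_qc(dataset))
    out["qc_markers"] = marker_report
    out["qc_individuals"] = ind_report
    out["dataset"] = ds
    if outdir is not None:
        marker_report.to_json(outdir / "qc_markers.json")
        ind_report.to_json(outdir / "qc_individuals.json")

    div = stage("diversity", lambda: _diversity.accession_diversity(ds))
    out["diversity"] = div
    if outdir is not None:
        _diversity.write_diversity_table(div, outdir / "diversity.tsv")

    stats = stage("fst", lambda: fst_matrix(ds, n_perm=n_perm, seed=seed))
    out["pairwise"] = stats
    out["group_summary"] = stage("fst", lambda: group_fst_summary(stats, ds.accessions))
    if outdir is not None:
        write_pairwise_table(stats, ds.accessions, outdir / "pairwise_fst.tsv")

    freqs = stage("freqs", lambda: allele_frequencies(ds, by="accession"))
    pca = stage("pca", lambda: _ordination.accession_pca(freqs))
    out["accession_pca"] = pca
    if outdir is not None:
        _ordination.write_pca(pca, outdir / "accession_pca")

    if do_resampling:
        same_group_pairs = [
            (s.acc_a, s.acc_b)
            for s in stats
            if s.error is None
            and ds.accessions[s.acc_a].name_group == ds.accessions[s.acc_b].name_group
        ]
        summaries = stage(
            "resampling",
            lambda: _resampling.subsample_fst_stability(
                ds,
                same_group_pairs,
                sizes=tuple(s for s in resampling_sizes if s <= ds.n_markers),
                n_replicates=resampling_replicates,
                seed=seed,
            ),
        )
        out["resampling"] = summaries
        if outdir is not None:
            _resampling.write_subsample_table(summaries, outdir / "subsample_fst.tsv")

    if do_panel:
        pnl = stage("panel", lambda: _panel.select_panel(ds, pca, n=panel_size))
        out["panel"] = pnl
        if outdir is not None:
            _panel.write_panel(
                pnl, ds, outdir / "panel.tsv", outdir / "panel_rejections.tsv"
            )

    verdicts, report = stage(
        "report",
        lambda: duplicate_report(
            ds, stats, pca,
            fst_percentile=fst_percentile,
            shared_percentile=shared_percentile,
        ),
    )
    out["verdicts"] = verdicts
    out["report"] = report
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return out
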