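"""Shared fixtures and dataset builders for the test suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genedup import (
    Accession,
    AccessionTable,
    GenotypeMatrix,
    MarkerMap,
    StudyDataset,
    SyntheticConfig,
    generate_study,
)


def build_dataset(
    acc_calls: dict[str, list[list[int]]],
    groups: dict[str, str] | None = None,
    genebanks: dict[str, str] | None = None,
    years: dict[str, int] | None = None,
    marker_ids: list[str] | None = None,
    marker_map: MarkerMap | None = None,
) -> StudyDataset:
    """Assemble a StudyDataset from per-accession genotype rows."""
    individuals: list[str] = []
    rows: list[list[int]] = []
    accessions: dict[str, Accession] = {}
    n_markers = len(next(iter(acc_calls.values()))[0])
    for code, calls in acc_calls.items():
        ids = tuple(f"{code}-{i + 1}" for i in range(len(calls)))
        individuals.extend(ids)
        rows.extend(calls)
        accessions[code] = Accession(
            code=code,
            individuals=ids,
            name_group=(groups or {}).get(code, code),
            genebank=(genebanks or {}).get(code, "GB1"),
            acquisition_year=(years or {}).get(code),
        )
    markers = marker_ids or [f"m{j + 1}" for j in range(n_markers)]
    geno = GenotypeMatrix(tuple(individuals), tuple(markers), np.array(rows, dtype=np.int8))
    return StudyDataset(geno, marker_map, AccessionTable(accessions))


def simple_map(markers: list[str], chromosome: str = "C01") -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "position": [100 * (j + 1) for j in range(len(markers))],
                "allele1": "A",
                "allele2": "B",
            },
            index=pd.Index(markers, name="marker"),
        )
    )


@pytest.fixture(scope="session")
def default_study():
    """A moderate synthetic study under the default design (paper-style
    group sizes, 10 individuals per accession), shared across tests."""
    cfg = SyntheticConfig(seed=1234, n_markers=600)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def clean_study():
    """Fully-called, drift-free study for exact-structure tests."""
    cfg = SyntheticConfig(
        seed=99,
        n_markers=500,
        missing_rate=0.0,
        age_drift=False,
        duplicate_links=0,
    )
    return generate_study(cfg)
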