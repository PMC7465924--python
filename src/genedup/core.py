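"""Data containers, file I/O and allele-frequency computation.

The pipeline operates on diploid biallelic SNP-array genotype calls for
individuals grouped into genebank accessions.  A genotype is stored as the
dosage of the *alternate* allele (0, 1 or 2); the "reference" allele is the
first allele listed in the marker map.  A single sentinel (:data:`MISSING`)
encodes failed calls, and every downstream statistic uses complete-case
deletion per locus.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("genedup")

#: sentinel for a missing genotype call
MISSING: int = -1

#: unit label used for pooled (all-individual) allele frequencies
POOLED: str = "pooled"

_VALID_CALLS = frozenset({0, 1, 2, MISSING})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Rectangular individuals x markers matrix of alternate-allele dosages."""

    individuals: tuple[str, ...]
    markers: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = tuple(str(i) for i in self.individuals)
        self.markers = tuple(str(m) for m in self.markers)
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs in genotype matrix")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker IDs in genotype matrix")
        bad = set(np.unique(calls)) - _VALID_CALLS
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}; expected 0/1/2/{MISSING}")
        self.calls = calls
        self._ind_index = {v: i for i, v in enumerate(self.individuals)}
        self._marker_index = {v: i for i, v in enumerate(self.markers)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def individual_rows(self, individuals: Iterable[str]) -> np.ndarray:
        return np.array([self._ind_index[i] for i in individuals], dtype=int)

    def marker_cols(self, markers: Iterable[str]) -> np.ndarray:
        return np.array([self._marker_index[m] for m in markers], dtype=int)

    def take_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        cols = self.marker_cols(markers)
        return GenotypeMatrix(self.individuals, tuple(markers), self.calls[:, cols])

    def take_individuals(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        rows = self.individual_rows(individuals)
        return GenotypeMatrix(tuple(individuals), self.markers, self.calls[rows, :])

    def called_mask(self) -> np.ndarray:
        """Boolean matrix, True where the call is non-missing."""
        return self.calls != MISSING


@dataclass
class MarkerMap:
    """Chromosome, position and allele labels per marker.

    Backed by a DataFrame indexed by marker ID with columns
    ``chromosome``, ``position``, ``allele1``, ``allele2``.  ``allele1`` is
    the reference allele (dosage 0 = homozygous allele1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "position", "allele1", "allele2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate marker IDs in map: {dups[:5]}")
        if (self.table["position"].astype(int) < 0).any():
            raise ValueError("negative marker positions in map")
        same = self.table["allele1"].astype(str) == self.table["allele2"].astype(str)
        if same.any():
            raise ValueError("marker map alleles must be distinct")

    def __contains__(self, marker: str) -> bool:
        return marker in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def alleles(self, marker: str) -> tuple[str, str]:
        row = self.table.loc[marker]
        return str(row["allele1"]), str(row["allele2"])

    def chromosome(self, marker: str) -> str:
        return str(self.table.loc[marker, "chromosome"])

    def subset(self, markers: Sequence[str]) -> "MarkerMap":
        keep = [m for m in markers if m in self.table.index]
        return MarkerMap(self.table.loc[keep].copy())


@dataclass
class Accession:
    code: str
    individuals: tuple[str, ...]
    name_group: str
    genebank: str
    acquisition_year: int | None = None
    accession_name: str = ""
    accession_number: str = ""
    excluded: bool = False


@dataclass
class AccessionTable:
    """Accession metadata plus the individual-to-accession assignment."""

    accessions: dict[str, Accession]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for code, acc in self.accessions.items():
            if code != acc.code:
                raise ValueError(f"accession key {code!r} != code {acc.code!r}")
            for ind in acc.individuals:
                if ind in seen:
                    raise ValueError(
                        f"individual {ind!r} assigned to both {seen[ind]!r} and {code!r}"
                    )
                seen[ind] = code
        self._assignment = seen

    def __iter__(self):
        return iter(self.accessions.values())

    def __getitem__(self, code: str) -> Accession:
        return self.accessions[code]

    def __contains__(self, code: str) -> bool:
        return code in self.accessions

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.accessions)

    @property
    def assignment(self) -> Mapping[str, str]:
        """individual ID -> accession code"""
        return self._assignment

    def active_codes(self) -> tuple[str, ...]:
        """Accessions that are not excluded and still hold individuals."""
        return tuple(
            a.code for a in self if not a.excluded and len(a.individuals) > 0
        )

    def accession_of(self, individual: str) -> str:
        return self._assignment[individual]


@dataclass
class StudyDataset:
    """The pipeline's single input bundle: genotypes + map + accessions."""

    genotypes: GenotypeMatrix
    marker_map: MarkerMap | None
    accessions: AccessionTable

    def __post_init__(self) -> None:
        geno_inds = set(self.genotypes.individuals)
        for acc in self.accessions:
            for ind in acc.individuals:
                if ind not in geno_inds:
                    raise ValueError(
                        f"individual {ind!r} of accession {acc.code!r} "
                        "is absent from the genotype matrix"
                    )
        if self.marker_map is not None:
            extra = set(self.marker_map.table.index) - set(self.genotypes.markers)
            if extra:
                # the map may cover only a subset of markers, never extras
                logger.warning(
                    "marker map lists %d markers absent from the genotype matrix",
                    len(extra),
                )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    @property
    def n_markers(self) -> int:
        return self.genotypes.n_markers

    def subset_markers(self, markers: Sequence[str]) -> "StudyDataset":
        new_map = self.marker_map.subset(markers) if self.marker_map is not None else None
        return StudyDataset(self.genotypes.take_markers(markers), new_map, self.accessions)

    def subset_individuals(self, individuals: Sequence[str]) -> "StudyDataset":
        keep = set(individuals)
        new_accs: dict[str, Accession] = {}
        for acc in self.accessions:
            inds = tuple(i for i in acc.individuals if i in keep)
            excluded = acc.excluded or len(inds) == 0
            if excluded and not acc.excluded:
                logger.warning("accession %s left with 0 individuals; flagged excluded", acc.code)
            new_accs[acc.code] = Accession(
                acc.code, inds, acc.name_group, acc.genebank,
                acc.acquisition_year, acc.accession_name, acc.accession_number,
                excluded,
            )
        return StudyDataset(
            self.genotypes.take_individuals(list(individuals)),
            self.marker_map,
            AccessionTable(new_accs),
        )

    def accession_rows(self, code: str) -> np.ndarray:
        """Genotype-matrix row indices of an accession's individuals."""
        return self.genotypes.individual_rows(self.accessions[code].individuals)


@dataclass
class FrequencyTable:
    """Reference-allele frequency per (unit, marker).

    ``p[u, m]`` is NaN (entry absent) where the unit has no called genotype
    at the marker; ``n_called`` holds the number of called individuals.
    """

    units: tuple[str, ...]
    markers: tuple[str, ...]
    p: np.ndarray
    n_called: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n_called = np.asarray(self.n_called, dtype=int)
        shape = (len(self.units), len(self.markers))
        if self.p.shape != shape or self.n_called.shape != shape:
            raise ValueError("frequency table arrays do not match units x markers")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.p, initial=0.0) < 0 or np.nanmax(self.p, initial=0.0) > 1:
                raise ValueError("allele frequencies outside [0, 1]")
        if ((self.n_called == 0) != np.isnan(self.p)).any():
            raise ValueError("entries with n_called = 0 must be flagged absent (NaN)")

    def unit_row(self, unit: str) -> np.ndarray:
        return self.p[self.units.index(unit)]

    def to_frame(self) -> pd.DataFrame:
        u, m = np.meshgrid(np.arange(len(self.units)), np.arange(len(self.markers)), indexing="ij")
        return pd.DataFrame(
            {
                "unit": np.asarray(self.units)[u.ravel()],
                "marker": np.asarray(self.markers)[m.ravel()],
                "p": self.p.ravel(),
                "n_called": self.n_called.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _freq_from_rows(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference-allele frequency and called count per column of ``calls``."""
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    ref = 2 * n_called - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, ref / np.maximum(2 * n_called, 1), np.nan)
    return p, n_called


def allele_frequencies(dataset: StudyDataset, by: str = "accession") -> FrequencyTable:
    """Per-accession or pooled reference-allele frequencies.

    Missing calls are excluded per locus; a unit with zero called
    individuals at a marker gets an absent (NaN) entry rather than a silent
    NaN propagating downstream.  Pooled frequencies weight by called allele
    copies, not by accession.
    """
    if by not in {"accession", "pooled"}:
        raise ValueError(f"by must be 'accession' or 'pooled', got {by!r}")
    calls = dataset.genotypes.calls
    if by == "pooled":
        rows = dataset.genotypes.individual_rows(
            [i for acc in dataset.accessions if not acc.excluded for i in acc.individuals]
        )
        p, n = _freq_from_rows(calls[rows])
        return FrequencyTable((POOLED,), dataset.genotypes.markers, p[None, :], n[None, :])

    units = dataset.accessions.active_codes()
    p = np.empty((len(units), dataset.n_markers))
    n = np.empty((len(units), dataset.n_markers), dtype=int)
    for k, code in enumerate(units):
        p[k], n[k] = _freq_from_rows(calls[dataset.accession_rows(code)])
    return FrequencyTable(units, dataset.genotypes.markers, p, n)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _default_alleles() -> tuple[str, str]:
    return ("A", "B")


def _encode_call(dosage: int, alleles: tuple[str, str]) -> str:
    a1, a2 = alleles
    if dosage == MISSING:
        return "--"
    return {0: a1 + a1, 1: a1 + a2, 2: a2 + a2}[int(dosage)]


def _decode_call(text: str, alleles: tuple[str, str]) -> int:
    a1, a2 = alleles
    if text == "--" or text == "":
        return MISSING
    if text == a1 + a1:
        return 0
    if text in (a1 + a2, a2 + a1):
        return 1
    if text == a2 + a2:
        return 2
    return MISSING  # unparseable; caller logs the count


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})
    df = df.set_index("marker")
    df["position"] = df["position"].astype(int)
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.table.to_csv(path, sep="\t", index_label="marker")


def read_accessions(path: str | Path) -> AccessionTable:
    """Accession CSV: code, accession_name, accession_number, genebank,
    acquisition_year, name_group, individuals (semicolon-separated IDs)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    accs: dict[str, Accession] = {}
    for _, row in df.iterrows():
        code = row["code"]
        if code in accs:
            raise ValueError(f"duplicate accession code {code!r}")
        year = row.get("acquisition_year", "")
        inds = tuple(i for i in str(row.get("individuals", "")).split(";") if i)
        accs[code] = Accession(
            code=code,
            individuals=inds,
            name_group=row.get("name_group", ""),
            genebank=row.get("genebank", ""),
            acquisition_year=int(float(year)) if year not in ("", "nan") else None,
            accession_name=row.get("accession_name", ""),
            accession_number=row.get("accession_number", ""),
        )
    return AccessionTable(accs)


def write_accessions(accessions: AccessionTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["code", "accession_name", "accession_number", "genebank",
             "acquisition_year", "name_group", "individuals"]
        )
        for acc in accessions:
            writer.writerow(
                [acc.code, acc.accession_name, acc.accession_number, acc.genebank,
                 "" if acc.acquisition_year is None else acc.acquisition_year,
                 acc.name_group, ";".join(acc.individuals)]
            )


def _read_tsv_genotypes(path: str | Path, marker_map: MarkerMap | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0).fillna("--")
    markers = tuple(str(m) for m in df.columns)
    individuals = tuple(str(i) for i in df.index)
    alleles = [
        marker_map.alleles(m) if marker_map is not None and m in marker_map else _default_alleles()
        for m in markers
    ]
    calls = np.empty((len(individuals), len(markers)), dtype=np.int8)
    n_unparseable = 0
    values = df.to_numpy(dtype=str)
    for j, al in enumerate(alleles):
        col = values[:, j]
        for i, text in enumerate(col):
            d = _decode_call(text.strip(), al)
            if d == MISSING and text.strip() not in ("--", ""):
                n_unparseable += 1
            calls[i, j] = d
    if n_unparseable:
        logger.warning("%d unparseable genotype calls set to MISSING", n_unparseable)
    return GenotypeMatrix(individuals, markers, calls)


def _read_vcf_genotypes(path: str | Path) -> tuple[GenotypeMatrix, MarkerMap]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = tuple(vcf.samples)
    markers: list[str] = []
    rows: list[np.ndarray] = []
    map_rows: list[tuple[str, str, int, str, str]] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        marker = variant.ID or f"{variant.CHROM}:{variant.POS}"
        dosages = np.empty(len(individuals), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a = gt[:-1]  # trailing element is phasing
            if any(x < 0 for x in a):
                dosages[i] = MISSING
            else:
                dosages[i] = int(sum(1 for x in a if x > 0))
        markers.append(marker)
        rows.append(dosages)
        map_rows.append((marker, variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    if n_multi:
        logger.warning("skipped %d multiallelic VCF records", n_multi)
    calls = np.stack(rows, axis=1) if rows else np.empty((len(individuals), 0), dtype=np.int8)
    map_df = pd.DataFrame(
        map_rows, columns=["marker", "chromosome", "position", "allele1", "allele2"]
    ).set_index("marker")
    return GenotypeMatrix(individuals, tuple(markers), calls), MarkerMap(map_df)


def read_genotypes(
    genotype_path: str | Path,
    accessions_path: str | Path,
    map_path: str | Path | None = None,
    fmt: str = "tsv",
) -> StudyDataset:
    """Read a :class:`StudyDataset` from disk.

    ``fmt='tsv'``: header row of marker IDs, first column individual ID,
    calls as two-letter allele pairs or ``--``.  ``fmt='vcf'``: biallelic
    SNPs, GT field only; multiallelic records are skipped with a warning.
    """
    accessions = read_accessions(accessions_path)
    marker_map = read_marker_map(map_path) if map_path is not None else None
    if fmt == "tsv":
        genotypes = _read_tsv_genotypes(genotype_path, marker_map)
    elif fmt == "vcf":
        genotypes, vcf_map = _read_vcf_genotypes(genotype_path)
        if marker_map is None:
            marker_map = vcf_map
    else:
        raise ValueError(f"unknown format {fmt!r}")
    assigned = accessions.assignment
    for ind in genotypes.individuals:
        if ind not in assigned:
            raise ValueError(f"individual {ind!r} is absent from the accession table")
    return StudyDataset(genotypes, marker_map, accessions)


def write_genotypes(
    dataset: StudyDataset,
    genotype_path: str | Path,
    accessions_path: str | Path | None = None,
    map_path: str | Path | None = None,
) -> None:
    """Write the TSV dialect (and optionally the accession CSV / map TSV)."""
    geno = dataset.genotypes
    alleles = [
        dataset.marker_map.alleles(m)
        if dataset.marker_map is not None and m in dataset.marker_map
        else _default_alleles()
        for m in geno.markers
    ]
    with open(genotype_path, "w") as fh:
        fh.write("individual\t" + "\t".join(geno.markers) + "\n")
        for i, ind in enumerate(geno.individuals):
            row = [_encode_call(geno.calls[i, j], alleles[j]) for j in range(geno.n_markers)]
            fh.write(ind + "\t" + "\t".join(row) + "\n")
    if accessions_path is not None:
        write_accessions(dataset.accessions, accessions_path)
    if map_path is not None and dataset.marker_map is not None:
        write_marker_map(dataset.marker_map, map_path)
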