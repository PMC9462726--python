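"""Genotype matrices and the text formats they travel in.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
loci, coded as the dosage of the SNP (non-reference) allele — 0 = reference
homozygote, 1 = heterozygote, 2 = SNP homozygote, with ``MISSING`` (-9) for
failed calls.  DArTseq scoring uses a different two-state convention
("0" = reference homozygote, "1" = SNP homozygote, "2" = heterozygote);
:func:`recode_dart_to_dosage` converts at the boundary so every estimator
downstream consumes plain allele dosages.

Supported text formats: STRUCTURE genotype files (one- and two-row
dialects), delimited locus-metadata tables and sampling-site tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -9

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "LocusMetadata",
    "read_structure_genotypes",
    "write_structure_genotypes",
    "read_locus_metadata",
    "write_locus_metadata",
    "read_site_table",
    "recode_dart_to_dosage",
    "recode_dosage_to_dart",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the declared format."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci SNP-allele dosage matrix with population labels.

    Parameters
    ----------
    individual_ids
        Unique label per row.
    populations
        Population label per individual (one each).
    loci
        Unique locus ID per column.
    calls
        Integer array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    individual_ids: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n, L = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls rows")
        if len(self.populations) != n:
            raise ValueError("populations length does not match calls rows")
        if len(self.loci) != L:
            raise ValueError("loci length does not match calls columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual IDs must be unique")
        if len(set(self.loci)) != L:
            raise ValueError("locus IDs must be unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at individual "
                f"{self.individual_ids[i]!r}, locus {self.loci[j]!r}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def pop_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.pop_labels}

    def typed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    # -- subsetting -----------------------------------------------------
    def subset_loci(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            populations=list(self.populations),
            loci=[self.loci[j] for j in keep],
            calls=self.calls[:, keep].copy(),
        )

    def subset_individuals(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            loci=list(self.loci),
            calls=self.calls[keep, :].copy(),
        )

    def for_population(self, pop: str) -> "GenotypeMatrix":
        idx = self.pop_indices().get(pop)
        if idx is None:
            raise KeyError(f"unknown population {pop!r}")
        return self.subset_individuals(idx)

    def missingness_by_individual(self) -> np.ndarray:
        """Fraction of missing calls per individual (typed fraction is 1 - this)."""
        return (self.calls == MISSING).mean(axis=1)


@dataclass
class LocusMetadata:
    """Per-locus QC table driving the filter cascade.

    Mandatory columns: ``locus_id``, ``clone_id``, ``call_rate``,
    ``mean_read_depth``, ``repeatability``.  Extra columns are carried
    through untouched.
    """

    table: pd.DataFrame = field(repr=False)

    MANDATORY = ("locus_id", "clone_id", "call_rate", "mean_read_depth", "repeatability")

    def __post_init__(self) -> None:
        missing = [c for c in self.MANDATORY if c not in self.table.columns]
        if missing:
            raise ValueError(f"locus metadata missing mandatory columns: {missing}")
        t = self.table
        if t["locus_id"].duplicated().any():
            dup = t.loc[t["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValueError(f"duplicate locus_id {dup!r} in metadata")
        for col in ("call_rate", "repeatability"):
            v = t[col].to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        if (t["mean_read_depth"].to_numpy(dtype=float) < 0).any():
            raise ValueError("mean_read_depth must be non-negative")
        self.table = t.set_index("locus_id", drop=False)

    def for_loci(self, loci: list[str]) -> pd.DataFrame:
        missing = [l for l in loci if l not in self.table.index]
        if missing:
            raise KeyError(f"metadata missing for loci: {missing[:5]}")
        return self.table.loc[loci]


# ---------------------------------------------------------------------------
# STRUCTURE format
# ---------------------------------------------------------------------------

def read_structure_genotypes(
    path: str | Path | io.StringIO,
    rows_per_individual: int | None = None,
    pop_map: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a STRUCTURE genotype file into a dosage-coded matrix.

    The file has a single header row of locus names, then either two rows
    per individual (one allele per row) or one row per individual with two
    adjacent columns per locus.  The first two columns of each data row are
    the individual label and a population label; missing alleles are -9.
    The dialect is auto-detected from the column count when
    ``rows_per_individual`` is not given.

    Per locus the two observed allele codes are ordered numerically (or
    lexicographically for non-numeric codes): the smaller is taken as the
    reference allele, the larger as the SNP allele, and the stored dosage is
    the count of SNP-allele copies.  A genotype with any missing allele is
    recorded as ``MISSING``.

    ``pop_map`` overrides the in-file population column (individual label ->
    population), covering files that rely on an external site order.
    """
    if isinstance(path, io.StringIO):
        lines = [ln for ln in path.getvalue().splitlines() if ln.strip()]
    else:
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise GenotypeParseError("file has no data rows")
    header = lines[0].split()
    loci = header
    L = len(loci)
    rows = [ln.split() for ln in lines[1:]]
    ncols = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != ncols:
            raise GenotypeParseError(
                f"ragged row at line {k + 2}: expected {ncols} fields, got {len(r)}"
            )
    if rows_per_individual is None:
        if ncols == 2 + L:
            rows_per_individual = 2
        elif ncols == 2 + 2 * L:
            rows_per_individual = 1
        else:
            raise GenotypeParseError(
                f"cannot match {ncols} columns to {L} loci in either dialect"
            )
    else:
        expected = 2 + L if rows_per_individual == 2 else 2 + 2 * L
        if ncols != expected:
            raise GenotypeParseError(
                f"expected {expected} columns for {rows_per_individual}-row dialect, got {ncols}"
            )

    ids: list[str] = []
    pops: list[str] = []
    # allele codes per (individual, locus, 2)
    if rows_per_individual == 2:
        if len(rows) % 2:
            raise GenotypeParseError("odd number of data rows in two-row dialect")
        n = len(rows) // 2
        alleles = np.empty((n, L, 2), dtype=object)
        for i in range(n):
            r1, r2 = rows[2 * i], rows[2 * i + 1]
            if r1[0] != r2[0]:
                raise GenotypeParseError(
                    f"row pair at line {2 * i + 2} has mismatched labels {r1[0]!r}/{r2[0]!r}"
                )
            ids.append(r1[0])
            pops.append(r1[1])
            alleles[i, :, 0] = r1[2:]
            alleles[i, :, 1] = r2[2:]
    else:
        n = len(rows)
        alleles = np.empty((n, L, 2), dtype=object)
        for i, r in enumerate(rows):
            ids.append(r[0])
            pops.append(r[1])
            alleles[i, :, 0] = r[2::2]
            alleles[i, :, 1] = r[3::2]

    if pop_map is not None:
        pops = [pop_map.get(i, p) for i, p in zip(ids, pops)]

    calls = np.full((n, L), MISSING, dtype=np.int16)
    miss = {"-9"}
    for j in range(L):
        col = alleles[:, j, :]
        codes = sorted({c for c in col.ravel() if c not in miss},
                       key=lambda c: (0, float(c)) if _is_number(c) else (1, c))
        if len(codes) > 2:
            raise GenotypeParseError(
                f"locus {loci[j]!r} has {len(codes)} allele codes {codes}; "
                "expected at most two plus missing"
            )
        snp = codes[-1] if len(codes) == 2 else None
        a, b = col[:, 0], col[:, 1]
        ok = ~(np.isin(a, list(miss)) | np.isin(b, list(miss)))
        if snp is None:
            calls[ok, j] = 0
        else:
            calls[ok, j] = (a[ok] == snp).astype(np.int16) + (b[ok] == snp).astype(np.int16)
    return GenotypeMatrix(ids, pops, list(loci), calls)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_structure_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the two-row STRUCTURE dialect (alleles 1 = reference, 2 = SNP)."""
    pop_index = {p: k + 1 for k, p in enumerate(matrix.pop_labels)}
    out = [" ".join(matrix.loci)]
    for i, ind in enumerate(matrix.individual_ids):
        row = matrix.calls[i]
        first, second = [], []
        for d in row:
            if d == MISSING:
                first.append("-9")
                second.append("-9")
            else:
                first.append("2" if d >= 1 else "1")
                second.append("2" if d == 2 else "1")
        p = str(pop_index[matrix.populations[i]])
        out.append(" ".join([ind, p] + first))
        out.append(" ".join([ind, p] + second))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Delimited metadata / site tables
# ---------------------------------------------------------------------------

def read_locus_metadata(path: str | Path | io.StringIO, sep: str = ",") -> LocusMetadata:
    return LocusMetadata(pd.read_csv(path, sep=sep))


def write_locus_metadata(metadata: LocusMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, index=False)


def read_site_table(path: str | Path | io.StringIO, sep: str = ",") -> pd.DataFrame:
    """Read a sampling-site table: population, latitude, longitude[, n]."""
    t = pd.read_csv(path, sep=sep)
    required = {"population", "latitude", "longitude"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if (t["latitude"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (t["longitude"].abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    return t


# ---------------------------------------------------------------------------
# DArT two-state recoding
# ---------------------------------------------------------------------------

_DART_TO_DOSAGE = {0: 0, 1: 2, 2: 1, MISSING: MISSING}


def recode_dart_to_dosage(raw: np.ndarray) -> np.ndarray:
    """Convert DArT scores (0 ref hom, 1 SNP hom, 2 het) to SNP dosages.

    The map 0->0, 1->2, 2->1 swaps the meaning of 1 and 2 and is its own
    inverse.
    """
    raw = np.asarray(raw)
    if not np.isin(raw, (0, 1, 2, MISSING)).all():
        bad = raw[~np.isin(raw, (0, 1, 2, MISSING))]
        raise ValueError(f"invalid DArT codes present: {np.unique(bad)}")
    out = raw.copy()
    out[raw == 1] = 2
    out[raw == 2] = 1
    return out


def recode_dosage_to_dart(dosage: np.ndarray) -> np.ndarray:
    """Inverse of :func:`recode_dart_to_dosage` (same swap)."""
    return recode_dart_to_dosage(dosage)
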