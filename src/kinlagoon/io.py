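"""Reading, validating, filtering and writing multilocus microsatellite genotype tables.

Genotypes are codominant allele-size pairs. A cell is either fully typed
(two positive integer fragment sizes, stored in canonical sorted order) or
fully missing. The on-disk formats are a GenAlEx-style wide CSV (two columns
per locus, missing code ``0``) and a long CSV (one row per individual/locus).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel allele value for a missing genotype (GenAlEx convention)
MISSING = 0

DIALECTS = ("genalex_csv", "long_csv")


class GenotypeParseError(ValueError):
    """Raised when a genotype file is malformed; message names row/column."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci table of unordered allele pairs.

    ``alleles`` has shape (n_individuals, n_loci, 2), dtype int. A missing
    genotype is (0, 0); typed genotypes are canonicalised so that
    ``alleles[..., 0] <= alleles[..., 1]``. Both alleles of a cell are
    missing together or present together.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != L:
            raise ValueError("duplicate locus names")
        half_missing = (self.alleles == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, j = np.argwhere(half_missing)[0]
            raise ValueError(
                f"half-missing genotype for individual {self.ids[i]!r} "
                f"at locus {self.loci[j]!r}"
            )
        self.alleles = np.sort(self.alleles, axis=2)

    # -- basic queries -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype is scored."""
        return self.alleles[:, :, 0] != MISSING

    def amplification_rate(self) -> np.ndarray:
        """Per-individual proportion of scored loci."""
        return self.typed_mask().mean(axis=1)

    def missing_loci_count(self) -> np.ndarray:
        """Per-individual number of unscored loci."""
        return (~self.typed_mask()).sum(axis=1)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), list(self.loci), self.alleles[rows].copy())

    def locus_alleles(self, j: int) -> np.ndarray:
        """Flat array of observed (non-missing) alleles at locus column j."""
        col = self.alleles[:, j, :]
        return col[col != MISSING]


@dataclass
class SampleMetadata:
    """Per-individual coordinates (decimal degrees), depth (m), shell width (cm).

    Stored as a DataFrame indexed by individual id with columns
    ``lat, lon, depth_m, width_cm``; optional columns may hold NaN.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("lat", "lon")
    COLUMNS = ("lat", "lon", "depth_m", "width_cm")

    def __post_init__(self) -> None:
        t = self.table
        for c in self.REQUIRED:
            if c not in t.columns:
                raise ValueError(f"metadata missing required column {c!r}")
        for c in self.COLUMNS:
            if c not in t.columns:
                t[c] = np.nan
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        lat, lon = t["lat"].to_numpy(float), t["lon"].to_numpy(float)
        if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
            raise ValueError("coordinates outside valid decimal-degree ranges")
        if np.any(t["depth_m"].dropna() < 0):
            raise ValueError("negative sampling depth")
        if np.any(t["width_cm"].dropna() <= 0):
            raise ValueError("non-positive shell width")

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(ids)].copy())

    def coords(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return self.table[["lat", "lon"]].to_numpy(float)


# -- parsing helpers -------------------------------------------------------


def _parse_allele(text: str, missing_code: str, where: str) -> int:
    text = text.strip()
    if text == missing_code or text == "":
        return MISSING
    try:
        value = int(text)
    except ValueError as exc:
        raise GenotypeParseError(f"non-integer allele {text!r} at {where}") from exc
    if value < 0:
        raise GenotypeParseError(f"negative allele size {value} at {where}")
    return value


def read_genotypes(
    path: str | Path, dialect: str = "genalex_csv", missing_code: str = "0"
) -> GenotypeMatrix:
    """Read a genotype table.

    ``genalex_csv``: one header row -- first cell an id label, then each locus
    name followed by one blank cell (loci span two columns); one row per
    individual: id, then two allele columns per locus. ``long_csv``: columns
    id, locus, allele_a, allele_b. The missing code (default "0") maps to a
    missing genotype; a cell with exactly one missing allele is rejected.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(c.strip() for c in row)]
    if not rows:
        raise GenotypeParseError(f"{path}: empty file")
    if dialect == "long_csv":
        return _read_long(rows, missing_code)
    return _read_genalex(rows, missing_code)


def _read_genalex(rows: list[list[str]], missing_code: str) -> GenotypeMatrix:
    header = rows[0]
    if (len(header) - 1) % 2 != 0:
        raise GenotypeParseError(
            f"header has {len(header) - 1} allele columns; loci need two each"
        )
    loci = [header[i].strip() for i in range(1, len(header), 2)]
    if any(not name for name in loci):
        raise GenotypeParseError("blank locus name in header")
    fillers = [header[i].strip() for i in range(2, len(header), 2)]
    if any(fillers):
        raise GenotypeParseError(
            "each locus name must span two columns (second cell blank)"
        )
    ids: list[str] = []
    cells = np.zeros((len(rows) - 1, len(loci), 2), dtype=np.int64)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise GenotypeParseError(
                f"row {r}: expected {len(header)} columns, found {len(row)}"
            )
        ident = row[0].strip()
        if not ident:
            raise GenotypeParseError(f"row {r}: blank individual id")
        if ident in ids:
            raise GenotypeParseError(f"row {r}: duplicate individual id {ident!r}")
        ids.append(ident)
        for j, locus in enumerate(loci):
            a = _parse_allele(row[1 + 2 * j], missing_code, f"row {r}, locus {locus}")
            b = _parse_allele(row[2 + 2 * j], missing_code, f"row {r}, locus {locus}")
            if (a == MISSING) != (b == MISSING):
                raise GenotypeParseError(
                    f"row {r}, locus {locus}: half-missing genotype ({a}, {b})"
                )
            cells[r - 2, j] = (a, b)
    return GenotypeMatrix(ids, loci, cells)


def _read_long(rows: list[list[str]], missing_code: str) -> GenotypeMatrix:
    header = [c.strip().lower() for c in rows[0]]
    expected = ["id", "locus", "allele_a", "allele_b"]
    if header != expected:
        raise GenotypeParseError(f"long_csv header must be {expected}, got {header}")
    ids: list[str] = []
    loci: list[str] = []
    values: dict[tuple[str, str], tuple[int, int]] = {}
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise GenotypeParseError(f"row {r}: expected 4 columns, found {len(row)}")
        ident, locus = row[0].strip(), row[1].strip()
        a = _parse_allele(row[2], missing_code, f"row {r}")
        b = _parse_allele(row[3], missing_code, f"row {r}")
        if (a == MISSING) != (b == MISSING):
            raise GenotypeParseError(f"row {r}: half-missing genotype")
        if (ident, locus) in values:
            raise GenotypeParseError(f"row {r}: duplicate entry for ({ident}, {locus})")
        if ident not in ids:
            ids.append(ident)
        if locus not in loci:
            loci.append(locus)
        values[(ident, locus)] = (a, b)
    cells = np.zeros((len(ids), len(loci), 2), dtype=np.int64)
    for (ident, locus), (a, b) in values.items():
        cells[ids.index(ident), loci.index(locus)] = (a, b)
    return GenotypeMatrix(ids, loci, cells)


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    dialect: str = "genalex_csv",
    missing_code: str = "0",
) -> None:
    """Write a genotype table; inverse of :func:`read_genotypes` for the dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)

    def fmt(a: int) -> str:
        return missing_code if a == MISSING else str(a)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "genalex_csv":
            header: list[str] = ["id"]
            for locus in gm.loci:
                header += [locus, ""]
            writer.writerow(header)
            for i, ident in enumerate(gm.ids):
                row = [ident]
                for j in range(gm.n_loci):
                    row += [fmt(gm.alleles[i, j, 0]), fmt(gm.alleles[i, j, 1])]
                writer.writerow(row)
        else:
            writer.writerow(["id", "locus", "allele_a", "allele_b"])
            for i, ident in enumerate(gm.ids):
                for j, locus in enumerate(gm.loci):
                    writer.writerow(
                        [ident, locus, fmt(gm.alleles[i, j, 0]), fmt(gm.alleles[i, j, 1])]
                    )


def filter_by_amplification(
    gm: GenotypeMatrix, min_success: float = 0.75
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals scored at fewer than ``min_success`` of the loci.

    The threshold is inclusive: an individual scored at exactly the minimal
    rate is retained. Removal is per-individual only; the locus set is
    unchanged. Returns the filtered matrix and the removed ids.
    """
    if not 0 < min_success <= 1:
        raise ValueError("min_success must be in (0, 1]")
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    keep = gm.amplification_rate() >= min_success
    retained = [s for s, k in zip(gm.ids, keep) if k]
    removed = [s for s, k in zip(gm.ids, keep) if not k]
    return GenotypeMatrix(retained, list(gm.loci), gm.alleles[keep].copy()), removed


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata CSV with columns id, lat, lon, depth_m, width_cm."""
    table = pd.read_csv(path, dtype={"id": str}).set_index("id")
    return SampleMetadata(table)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="id")
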