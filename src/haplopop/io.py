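"""Readers and writers for the canonical CSV formats.

Canonical formats (all plain CSV, written and read):

* ``genotypes.csv`` — header ``sample_id,population,<locus1>,...,<locusL>``;
  one row per individual; integer allele sizes; ``0`` or empty = missing.
* ``sites.csv`` — ``population,region,latitude,longitude`` (decimal degrees).
* ``mat.csv`` — ``sample_id,idiomorph`` with MAT1-1 | MAT1-2 | NONE | BOTH.

A GenAlEx-style haploid export (two numeric header rows, then
``sample,pop,<loci>``) is importable via ``dialect="genalex-haploid"`` but is
never written.
"""

from __future__ import annotations

import csv
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import (MISSING, ConsistencyError, FormatError, GenotypeDataset,
                   MatTable, SitesTable)


def _parse_call(raw: str, row: int, col: str) -> int:
    raw = raw.strip()
    if raw == "" or raw == "0":
        return MISSING
    try:
        val = int(raw)
    except ValueError:
        raise ValueError(
            f"non-integer allele call {raw!r} at row {row}, column {col!r}"
        ) from None
    if val < 0:
        raise ValueError(f"negative allele call {val} at row {row}, column {col!r}")
    return val if val != 0 else MISSING


def read_genotypes(path, dialect: str = "canonical",
                   sites: Optional[SitesTable] = None,
                   region_of: Optional[Dict[str, str]] = None) -> GenotypeDataset:
    """Read a haploid genotype table.

    Parameters
    ----------
    path : str or Path
    dialect : {"canonical", "genalex-haploid"}
    sites : SitesTable, optional
        If given, supplies population->region mapping and populations are
        cross-checked against it.
    region_of : dict, optional
        Explicit population->region mapping; overrides ``sites``.  If neither
        is given, every population is placed in a single region ``"all"``.
    """
    if dialect not in ("canonical", "genalex-haploid"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if dialect == "genalex-haploid":
        # two numeric metadata rows precede the header
        if len(rows) < 4:
            raise FormatError("GenAlEx haploid file too short")
        rows = rows[2:]
    if not rows:
        raise FormatError("empty genotype file")
    header = [h.strip() for h in rows[0]]
    if len(header) < 3:
        raise FormatError("genotype header needs sample id, population and >=1 locus column")
    if dialect == "canonical" and (header[0] != "sample_id" or header[1] != "population"):
        raise FormatError(
            f"malformed canonical header: expected 'sample_id,population,...', got {header[:2]}"
        )
    loci = header[2:]
    sample_ids, pops, calls = [], [], []
    for r, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != len(header):
            raise FormatError(f"row {r} has {len(row)} fields, expected {len(header)}")
        sample_ids.append(row[0].strip())
        pops.append(row[1].strip())
        calls.append([_parse_call(row[2 + j], r, loci[j]) for j in range(len(loci))])
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ConsistencyError(f"duplicate sample ids: {dupes}")
    pop_of = dict(zip(sample_ids, pops))
    if region_of is None:
        if sites is not None:
            region_of = sites.region_of()
        else:
            region_of = {p: "all" for p in set(pops)}
    data = GenotypeDataset(sample_ids, loci, np.array(calls, dtype=np.int64),
                           pop_of, region_of)
    if sites is not None:
        sites.check_against(data)
    return data


def write_genotypes(data: GenotypeDataset, path) -> None:
    """Write the canonical genotypes CSV (missing encoded as 0)."""
    data.to_frame().to_csv(path, index=False)


def read_sites(path) -> SitesTable:
    return SitesTable(pd.read_csv(path))


def write_sites(sites: SitesTable, path) -> None:
    sites.table.to_csv(path, index=False)


def read_mat(path) -> MatTable:
    return MatTable(pd.read_csv(path, dtype=str))


def write_mat(mat: MatTable, path) -> None:
    mat.table.to_csv(path, index=False)
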