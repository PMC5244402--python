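"""Core data model for haploid multilocus microsatellite (SSR) datasets.

A :class:`GenotypeDataset` holds one integer allele call (fragment length in
base pairs) per locus per haploid individual, together with a two-level
sampling hierarchy: each sample belongs to exactly one population and each
population to exactly one region.  Missing calls are represented by the
module-level sentinel :data:`MISSING` in memory (``0`` or an empty cell on
disk, following fragment-analysis conventions).

All downstream statistics consume either the dataset itself or an
:class:`AlleleFrequencyTable` of per-stratum allele counts built from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: In-memory sentinel for a missing allele call.
MISSING: int = -1

VALID_IDIOMORPHS = ("MAT1-1", "MAT1-2", "NONE", "BOTH")


class FormatError(ValueError):
    """A file does not parse under the declared dialect."""


class ConsistencyError(ValueError):
    """Cross-table references (samples, populations, regions) do not line up."""


def _ordered_unique(values: Iterable[str]) -> List[str]:
    seen: Dict[str, None] = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


@dataclass
class GenotypeDataset:
    """Haploid multilocus genotypes with population/region strata.

    Parameters
    ----------
    sample_ids : list of str
        Unique identifiers, one per row of ``calls``.
    loci : list of str
        Ordered locus names (columns of ``calls``).  Locus order is stable
        across every derived table.
    calls : ndarray of shape (N, L), int
        Allele calls as positive integer fragment lengths; ``MISSING`` (-1)
        marks a failed call.
    pop_of : dict
        sample id -> population name.
    region_of : dict
        population name -> region name.
    """

    sample_ids: List[str]
    loci: List[str]
    calls: np.ndarray
    pop_of: Dict[str, str]
    region_of: Dict[str, str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.loci = [str(l).strip() for l in self.loci]
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array of shape (N, L)")
        n, l = self.calls.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample ids but {n} call rows")
        if l != len(self.loci):
            raise ValueError(f"{len(self.loci)} locus names but {l} call columns")
        if n < 1 or l < 1:
            raise ValueError("need at least one sample and one locus")
        if len(set(self.sample_ids)) != n:
            dupes = [s for s in self.sample_ids if self.sample_ids.count(s) > 1]
            raise ConsistencyError(f"duplicate sample ids: {sorted(set(dupes))}")
        if len(set(self.loci)) != l:
            raise ConsistencyError("duplicate locus names")
        bad = (self.calls <= 0) & (self.calls != MISSING)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"allele call must be a positive integer or MISSING; got "
                f"{self.calls[i, j]} at sample {self.sample_ids[i]!r}, locus {self.loci[j]!r}"
            )
        self.pop_of = {str(k).strip(): str(v).strip() for k, v in self.pop_of.items()}
        self.region_of = {str(k).strip(): str(v).strip() for k, v in self.region_of.items()}
        missing_pop = [s for s in self.sample_ids if s not in self.pop_of]
        if missing_pop:
            raise ConsistencyError(f"samples without population: {missing_pop[:5]}")
        missing_region = [p for p in self.populations if p not in self.region_of]
        if missing_region:
            raise ConsistencyError(f"populations without region: {missing_region}")

    # ---- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> List[str]:
        """Population names in order of first appearance."""
        return _ordered_unique(self.pop_of[s] for s in self.sample_ids)

    @property
    def regions(self) -> List[str]:
        return _ordered_unique(self.region_of[p] for p in self.populations)

    def pop_labels(self) -> np.ndarray:
        """Per-sample population name array (length N)."""
        return np.array([self.pop_of[s] for s in self.sample_ids])

    def region_labels(self) -> np.ndarray:
        """Per-sample region name array (length N)."""
        return np.array([self.region_of[self.pop_of[s]] for s in self.sample_ids])

    def samples_in(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to *population*."""
        labels = self.pop_labels()
        return np.flatnonzero(labels == population)

    def population_sizes(self) -> Dict[str, int]:
        labels = self.pop_labels()
        return {p: int((labels == p).sum()) for p in self.populations}

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing calls per locus."""
        frac = (self.calls == MISSING).mean(axis=0)
        return pd.Series(frac, index=self.loci, name="missing_fraction")

    def subset(self, rows: Sequence[int]) -> "GenotypeDataset":
        rows = np.asarray(rows, dtype=int)
        ids = [self.sample_ids[i] for i in rows]
        pops = {s: self.pop_of[s] for s in ids}
        return GenotypeDataset(ids, list(self.loci), self.calls[rows],
                               pops, dict(self.region_of))

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view (missing encoded as 0, as on disk)."""
        out = pd.DataFrame(self.calls, columns=self.loci)
        out.insert(0, "population", self.pop_labels())
        out.insert(0, "sample_id", self.sample_ids)
        out[self.loci] = out[self.loci].replace(MISSING, 0)
        return out


@dataclass
class SitesTable:
    """Population -> region assignment plus WGS84 decimal-degree coordinates."""

    table: pd.DataFrame  # columns: population, region, latitude, longitude

    def __post_init__(self) -> None:
        required = ["population", "region", "latitude", "longitude"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"sites table missing columns: {missing}")
        t = self.table.copy()
        t["population"] = t["population"].astype(str).str.strip()
        t["region"] = t["region"].astype(str).str.strip()
        t["latitude"] = t["latitude"].astype(float)
        t["longitude"] = t["longitude"].astype(float)
        if t["population"].duplicated().any():
            raise ConsistencyError("duplicate population in sites table")
        if not ((t["latitude"].abs() <= 90).all() and (t["longitude"].abs() <= 180).all()):
            raise ValueError("coordinates outside WGS84 bounds")
        self.table = t.reset_index(drop=True)

    @property
    def populations(self) -> List[str]:
        return list(self.table["population"])

    def coords_of(self, population: str) -> Tuple[float, float]:
        row = self.table[self.table["population"] == population]
        if row.empty:
            raise ConsistencyError(f"population {population!r} not in sites table")
        return float(row["latitude"].iloc[0]), float(row["longitude"].iloc[0])

    def region_of(self) -> Dict[str, str]:
        return dict(zip(self.table["population"], self.table["region"]))

    def check_against(self, data: GenotypeDataset) -> None:
        unknown = set(data.populations) - set(self.populations)
        if unknown:
            raise ConsistencyError(f"populations absent from sites table: {sorted(unknown)}")


@dataclass
class MatTable:
    """Per-sample mating-type idiomorph calls.

    ``BOTH`` is representable (two bands amplified) but flags a violation of
    heterothallism downstream; ``NONE`` records amplification failure.
    """

    table: pd.DataFrame  # columns: sample_id, idiomorph

    def __post_init__(self) -> None:
        required = ["sample_id", "idiomorph"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"MAT table missing columns: {missing}")
        t = self.table.copy()
        t["sample_id"] = t["sample_id"].astype(str).str.strip()
        t["idiomorph"] = t["idiomorph"].astype(str).str.strip()
        bad = ~t["idiomorph"].isin(VALID_IDIOMORPHS)
        if bad.any():
            raise ValueError(f"invalid idiomorph values: {sorted(t.loc[bad, 'idiomorph'].unique())}")
        if t["sample_id"].duplicated().any():
            raise ConsistencyError("duplicate sample_id in MAT table")
        self.table = t.reset_index(drop=True)

    def idiomorph_of(self) -> Dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["idiomorph"]))

    def check_against(self, data: GenotypeDataset) -> None:
        unknown = set(self.table["sample_id"]) - set(data.sample_ids)
        if unknown:
            raise ConsistencyError(f"MAT sample ids absent from genotypes: {sorted(unknown)[:5]}")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per-stratum, per-locus allele counts over non-missing calls.

    ``strata`` are population names (default) or region names when built with
    ``by="region"``.  Cells with no non-missing call are flagged empty rather
    than treated as errors.
    """

    loci: List[str]
    strata: List[str]
    counts: Dict[Tuple[str, str], Dict[int, int]]  # (stratum, locus) -> allele -> count

    def n(self, stratum: str, locus: str) -> int:
        """Non-missing sample size N_j for the cell."""
        return sum(self.counts.get((stratum, locus), {}).values())

    def is_empty(self, stratum: str, locus: str) -> bool:
        return self.n(stratum, locus) == 0

    def freqs(self, stratum: str, locus: str) -> Dict[int, float]:
        c = self.counts.get((stratum, locus), {})
        n = sum(c.values())
        if n == 0:
            return {}
        return {a: k / n for a, k in c.items()}

    def pooled_counts(self, locus: str) -> Dict[int, int]:
        """Counts summed over all strata (the global inventory at a locus)."""
        out: Dict[int, int] = {}
        for s in self.strata:
            for a, k in self.counts.get((s, locus), {}).items():
                out[a] = out.get(a, 0) + k
        return out

    def pooled_freqs(self, locus: str) -> Dict[int, float]:
        c = self.pooled_counts(locus)
        n = sum(c.values())
        return {a: k / n for a, k in c.items()} if n else {}

    def alleles(self, locus: str) -> List[int]:
        """Sorted distinct alleles observed at a locus across all strata."""
        return sorted(self.pooled_counts(locus))

    def total_distinct_alleles(self) -> int:
        return sum(len(self.pooled_counts(l)) for l in self.loci)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (s, l), c in self.counts.items():
            n = sum(c.values())
            for a, k in sorted(c.items()):
                rows.append({"stratum": s, "locus": l, "allele": a,
                             "count": k, "freq": k / n})
        return pd.DataFrame(rows, columns=["stratum", "locus", "allele", "count", "freq"])


def allele_frequencies(data: GenotypeDataset, by: str = "population") -> AlleleFrequencyTable:
    """Tabulate allele counts and frequencies over non-missing calls.

    Parameters
    ----------
    data : GenotypeDataset
    by : {"population", "region"}
        Stratification level; ``"region"`` pools population counts within
        each region (additive pooling, used for regional rarefaction).
    """
    if by == "population":
        labels = data.pop_labels()
        strata = data.populations
    elif by == "region":
        labels = data.region_labels()
        strata = data.regions
    else:
        raise ValueError("by must be 'population' or 'region'")
    counts: Dict[Tuple[str, str], Dict[int, int]] = {}
    for j, locus in enumerate(data.loci):
        col = data.calls[:, j]
        for s in strata:
            vals = col[(labels == s) & (col != MISSING)]
            cell: Dict[int, int] = {}
            if vals.size:
                alleles, ks = np.unique(vals, return_counts=True)
                cell = {int(a): int(k) for a, k in zip(alleles, ks)}
            counts[(s, locus)] = cell
    return AlleleFrequencyTable(list(data.loci), strata, counts)
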