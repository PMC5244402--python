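"""Spatial structure: isolation by distance, shared-allele and
geographically-restricted-allele analyses.

* Edwards' chord distance between population allele-frequency vectors,
  D_E = sqrt(1 - (1/L) sum_l sum_a sqrt(p_1la * p_2la)).
* Mantel test of genetic vs geographic distance (lower triangles, row/column
  permutation null), plus a 2-D kernel density of the distance pairs to
  distinguish a continuous cline from a patchy one.
* SAShA: the observed distribution of great-circle distances between pairs
  of individuals sharing an allele (one contribution per shared allele per
  pair) against the panmictic expectation, i.e. the distances between all
  pairs of individuals scored at the locus; significance by permuting the
  allele column among scored individuals within each locus.
* GRA: per-allele carrier centroids on an azimuthal-equidistant projection,
  with bootstrap null centroids from subsampling N_a coordinates without
  replacement; an allele is geographically restricted when its observed
  centroid falls outside the 95% bootstrap CI on at least one axis.

Geographic distances are great-circle (haversine, mean Earth radius
6371.0088 km); sites here span thousands of km, so planar Euclidean
distances on raw degrees would be badly distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencyTable, GenotypeDataset, SitesTable

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between decimal-degree coordinates."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geo_distance_matrix(sites: SitesTable,
                        populations: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Symmetric population-by-population great-circle distance matrix (km)."""
    pops = list(populations) if populations is not None else sites.populations
    lat = np.array([sites.coords_of(p)[0] for p in pops])
    lon = np.array([sites.coords_of(p)[1] for p in pops])
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pops, columns=pops)


def aeqd_project(lat, lon, lat0: float, lon0: float) -> Tuple[np.ndarray, np.ndarray]:
    """Azimuthal equidistant projection about (lat0, lon0), planar x/y in km."""
    phi = np.radians(np.asarray(lat, float))
    lam = np.radians(np.asarray(lon, float))
    phi0, lam0 = np.radians(lat0), np.radians(lon0)
    c = haversine_km(lat, lon, lat0, lon0) / EARTH_RADIUS_KM
    az = np.arctan2(np.sin(lam - lam0) * np.cos(phi),
                    np.cos(phi0) * np.sin(phi)
                    - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
    return EARTH_RADIUS_KM * c * np.sin(az), EARTH_RADIUS_KM * c * np.cos(az)


def _individual_coords(data: GenotypeDataset, sites: SitesTable
                       ) -> Tuple[np.ndarray, np.ndarray]:
    sites.check_against(data)
    coords = {p: sites.coords_of(p) for p in data.populations}
    pops = data.pop_labels()
    lat = np.array([coords[p][0] for p in pops])
    lon = np.array([coords[p][1] for p in pops])
    return lat, lon


# ---------------------------------------------------------------------------
# Edwards' chord distance
# ---------------------------------------------------------------------------

def edwards_distance(freqs: AlleleFrequencyTable) -> pd.DataFrame:
    """Edwards' chord distance between every pair of strata.

    Loci where either stratum has no non-missing call are excluded with L
    reduced accordingly; pairs with no shared scored locus get NaN.
    """
    strata = freqs.strata
    k = len(strata)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sims = []
            for l in freqs.loci:
                p1 = freqs.freqs(strata[i], l)
                p2 = freqs.freqs(strata[j], l)
                if not p1 or not p2:
                    continue
                s = sum(np.sqrt(p1[a] * p2[a]) for a in set(p1) & set(p2))
                sims.append(s)
            if not sims:
                out[i, j] = out[j, i] = np.nan
                continue
            d = np.sqrt(max(0.0, 1.0 - float(np.mean(sims))))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=strata, columns=strata)


# ---------------------------------------------------------------------------
# Mantel test and distance-pair KDE
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_perm: Optional[float]
    n_perm: int


def _lower(mat: np.ndarray) -> np.ndarray:
    il = np.tril_indices(mat.shape[0], k=-1)
    return mat[il]


def mantel_ibd(gen, geo, n_perm: int = 999, seed: Optional[int] = None) -> MantelResult:
    """Mantel correlation of two symmetric distance matrices.

    One-sided p-value for positive association, from simultaneous
    row/column permutation of the genetic matrix.
    """
    g = np.asarray(gen, dtype=float) if not isinstance(gen, pd.DataFrame) else gen.values.astype(float)
    e = np.asarray(geo, dtype=float) if not isinstance(geo, pd.DataFrame) else geo.values.astype(float)
    if g.shape != e.shape or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square and of matching shape")
    if not (np.allclose(g, g.T, equal_nan=True) and np.allclose(e, e.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    x, y = _lower(g), _lower(e)
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        return MantelResult(np.nan, None, n_perm)
    r = float(np.corrcoef(x, y)[0, 1])
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = g.shape[0]
        count = 0
        for _ in range(n_perm):
            pi = rng.permutation(n)
            rp = np.corrcoef(_lower(g[np.ix_(pi, pi)]), y)[0, 1]
            if rp >= r - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return MantelResult(r, p, n_perm)


@dataclass
class KdeGrid:
    x: np.ndarray          # grid over geographic distance
    y: np.ndarray          # grid over genetic distance
    density: np.ndarray    # (len(y), len(x))
    bandwidth_x: float
    bandwidth_y: float

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.x, axis=1), self.y))


def distance_pair_kde(gen, geo, grid: int = 100) -> KdeGrid:
    """Gaussian product-kernel density of (geographic, genetic) distance pairs.

    Per-axis bandwidths follow the 2-D normal reference rule
    h = sigma * n^(-1/6), with a small floor for degenerate axes.
    """
    g = gen.values if isinstance(gen, pd.DataFrame) else np.asarray(gen, float)
    e = geo.values if isinstance(geo, pd.DataFrame) else np.asarray(geo, float)
    y, x = _lower(g), _lower(e)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 distance pairs")
    n = x.size

    def bw(v: np.ndarray) -> float:
        s = float(np.std(v))
        if s <= 0:
            s = max(1e-8, 0.01 * (abs(float(np.mean(v))) + 1.0))
        return s * n ** (-1 / 6)

    hx, hy = bw(x), bw(y)
    gx = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, grid)
    gy = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, grid)
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = ky @ kx.T / n
    return KdeGrid(gx, gy, density, hx, hy)


# ---------------------------------------------------------------------------
# SAShA
# ---------------------------------------------------------------------------

@dataclass
class SashaResult:
    observed_mean_km: float
    expected_mean_km: float
    observed: np.ndarray           # per-shared-allele pair distances
    expected: np.ndarray           # all-pairs distances, aggregated over loci
    p_perm: Optional[float]
    n_perm: int
    perm_means: Optional[np.ndarray] = None


def sasha(data: GenotypeDataset, sites: SitesTable, n_perm: int = 1000,
          seed: Optional[int] = None,
          subset: Optional[Set[Tuple[str, int]]] = None,
          alternative: str = "less") -> SashaResult:
    """Spatial analysis of shared alleles.

    ``subset`` optionally restricts the observed aggregation to specific
    (locus, allele) pairs (used for the geographically-restricted subset);
    the expected distribution then aggregates the all-pairs distances of the
    loci represented in the subset.  ``alternative``: "less" tests for
    observed mean smaller than under panmixia (under-dispersion),
    "two-sided" doubles the smaller tail.
    """
    lat, lon = _individual_coords(data, sites)
    D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    rng = np.random.default_rng(seed)

    observed: List[np.ndarray] = []
    expected: List[np.ndarray] = []
    # per locus: (D submatrix, one-hot Z restricted to counted alleles, pair counts)
    per_locus = []
    for j, locus in enumerate(data.loci):
        col = data.calls[:, j]
        scored = np.flatnonzero(col != MISSING)
        if scored.size < 2:
            continue
        Dsub = D[np.ix_(scored, scored)]
        il = np.tril_indices(scored.size, k=-1)
        alleles = np.unique(col[scored])
        use = alleles if subset is None else np.array(
            [a for a in alleles if (locus, int(a)) in subset], dtype=alleles.dtype)
        if use.size == 0:
            continue
        Z = (col[scored][:, None] == use[None, :]).astype(float)
        counts = Z.sum(axis=0)
        n_pairs = counts * (counts - 1) / 2
        for a_i, a in enumerate(use):
            if counts[a_i] >= 2:
                carriers = np.flatnonzero(Z[:, a_i] > 0)
                sub = Dsub[np.ix_(carriers, carriers)]
                observed.append(sub[np.tril_indices(carriers.size, k=-1)])
        expected.append(Dsub[il])
        per_locus.append((Dsub, Z, float(n_pairs.sum())))

    obs = np.concatenate(observed) if observed else np.array([])
    exp = np.concatenate(expected) if expected else np.array([])
    obs_mean = float(obs.mean()) if obs.size else np.nan
    exp_mean = float(exp.mean()) if exp.size else np.nan

    p = None
    perm_means = None
    if n_perm > 0 and obs.size:
        total_pairs = sum(npair for _, _, npair in per_locus)
        perm_means = np.empty(n_perm)
        for b in range(n_perm):
            total = 0.0
            for Dsub, Z, _ in per_locus:
                Zp = Z[rng.permutation(Z.shape[0])]
                total += float(np.einsum("na,na->", Zp, Dsub @ Zp)) / 2.0
            perm_means[b] = total / total_pairs
        lo = (np.sum(perm_means <= obs_mean + 1e-9) + 1) / (n_perm + 1)
        hi = (np.sum(perm_means >= obs_mean - 1e-9) + 1) / (n_perm + 1)
        if alternative == "less":
            p = float(lo)
        elif alternative == "two-sided":
            p = float(min(1.0, 2 * min(lo, hi)))
        else:
            raise ValueError("alternative must be 'less' or 'two-sided'")
    return SashaResult(obs_mean, exp_mean, obs, exp, p, n_perm, perm_means)


# ---------------------------------------------------------------------------
# geographically restricted alleles
# ---------------------------------------------------------------------------

@dataclass
class GraResult:
    table: pd.DataFrame            # locus, allele, n_carriers, cx, cy, CIs, restricted
    n_boot: int
    restricted_sasha: Optional[SashaResult] = None

    @property
    def n_alleles(self) -> int:
        return len(self.table)

    @property
    def n_restricted(self) -> int:
        return int(self.table["restricted"].sum())

    @property
    def pct_restricted(self) -> float:
        return 100.0 * self.n_restricted / self.n_alleles if self.n_alleles else np.nan

    def restricted_subset(self) -> Set[Tuple[str, int]]:
        t = self.table[self.table["restricted"]]
        return {(row.locus, int(row.allele)) for row in t.itertuples()}


def detect_gra(data: GenotypeDataset, sites: SitesTable, n_boot: int = 1000,
               seed: Optional[int] = None, ci: float = 0.95,
               replace: bool = False) -> GraResult:
    """Detect geographically restricted alleles by centroid bootstrap.

    For every allele, the observed carrier centroid (planar km, azimuthal
    equidistant projection about the mean coordinate) is compared with
    centroids of ``n_boot`` random draws of N_a individuals from all
    individuals scored at the locus (without replacement by default).  An
    allele carried by every scored individual can never be restricted (its
    null is degenerate at its own centroid).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    lat, lon = _individual_coords(data, sites)
    x, y = aeqd_project(lat, lon, float(lat.mean()), float(lon.mean()))
    rng = np.random.default_rng(seed)
    qlo, qhi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for j, locus in enumerate(data.loci):
        col = data.calls[:, j]
        scored = np.flatnonzero(col != MISSING)
        xs, ys = x[scored], y[scored]
        n_s = scored.size
        for a in np.unique(col[scored]):
            carriers = np.flatnonzero(col[scored] == a)
            k = carriers.size
            cx, cy = float(xs[carriers].mean()), float(ys[carriers].mean())
            if k >= n_s:
                rows.append({"locus": locus, "allele": int(a), "n_carriers": k,
                             "cx": cx, "cy": cy, "ci_x_lo": cx, "ci_x_hi": cx,
                             "ci_y_lo": cy, "ci_y_hi": cy, "restricted": False})
                continue
            if replace:
                idx = rng.integers(0, n_s, size=(n_boot, k))
            else:
                idx = np.argsort(rng.random((n_boot, n_s)), axis=1)[:, :k]
            bx = xs[idx].mean(axis=1)
            by = ys[idx].mean(axis=1)
            xlo, xhi = np.percentile(bx, [qlo, qhi])
            ylo, yhi = np.percentile(by, [qlo, qhi])
            restricted = bool(cx < xlo or cx > xhi or cy < ylo or cy > yhi)
            rows.append({"locus": locus, "allele": int(a), "n_carriers": k,
                         "cx": cx, "cy": cy, "ci_x_lo": float(xlo),
                         "ci_x_hi": float(xhi), "ci_y_lo": float(ylo),
                         "ci_y_hi": float(yhi), "restricted": restricted})
    table = pd.DataFrame(rows)
    return GraResult(table, n_boot)


def sasha_gra(data: GenotypeDataset, sites: SitesTable, n_perm: int = 1000,
              n_boot: int = 1000, seed: Optional[int] = None) -> Tuple[SashaResult, GraResult]:
    """Full spatial shared-allele analysis: overall O/E plus GRA subset O/E."""
    rng = np.random.default_rng(seed)
    overall = sasha(data, sites, n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
    gra = detect_gra(data, sites, n_boot=n_boot, seed=int(rng.integers(2 ** 31)))
    subset = gra.restricted_subset()
    if subset:
        gra.restricted_sasha = sasha(data, sites, n_perm=n_perm,
                                     seed=int(rng.integers(2 ** 31)), subset=subset)
    return overall, gra
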