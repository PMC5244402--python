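"""Multilocus genotype accounting and the unbiased index of association.

rBarD measures multilocus linkage disequilibrium in haploid data and is the
classic signature of clonal reproduction: under free recombination alleles at
different loci associate at random and rBarD ~ 0.  For each pair of
individuals and each locus, d_l is the 0/1 mismatch indicator (pairs missing
at a locus are dropped from that locus); D is the sum of d_l over scored
loci.  With V_O the variance of D over pairs and var_l the per-locus
mismatch variances (V_E = sum var_l):

    I_A   = V_O / V_E - 1
    rBarD = (V_O - V_E) / (2 * sum_{l<m} sqrt(var_l * var_m))

Significance comes from independently permuting each locus column within the
population (breaking between-locus association while preserving allele
frequencies), with the +1-corrected p-value.

Variances use the number-of-pairs denominator (the convention of the
original index-of-association estimator), so small-sample toy examples can
be checked by direct enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset


def find_mlgs(data: GenotypeDataset, missing_wildcard: bool = False) -> np.ndarray:
    """Assign multilocus genotype (MLG) ids by exact allele-vector equality.

    Returns an integer array (length N) of MLG ids numbered in order of first
    appearance.  By default two rows differing only in which calls are
    MISSING are distinct MLGs (missing is not a wildcard); with
    ``missing_wildcard=True`` a row is merged into the first earlier row it
    is compatible with (equal wherever both are scored).
    """
    n = data.n_samples
    ids = np.empty(n, dtype=int)
    if not missing_wildcard:
        seen: Dict[tuple, int] = {}
        for i in range(n):
            key = tuple(data.calls[i])
            ids[i] = seen.setdefault(key, len(seen))
        return ids
    reps: List[np.ndarray] = []
    for i in range(n):
        row = data.calls[i]
        for k, rep in enumerate(reps):
            both = (row != MISSING) & (rep != MISSING)
            if np.array_equal(row[both], rep[both]):
                ids[i] = k
                break
        else:
            ids[i] = len(reps)
            reps.append(row)
    return ids


@dataclass
class LinkageResult:
    population: str
    n: int
    n_mlg: int
    ia: float
    rbar_d: float
    v_o: float
    v_e: float
    p_perm: Optional[float]
    n_perm: int


def _pair_variance(values: np.ndarray) -> float:
    """Variance with number-of-observations denominator, NaN-aware."""
    v = values[~np.isnan(values)]
    m = v.size
    if m == 0:
        return np.nan
    return float((np.sum(v * v) - np.sum(v) ** 2 / m) / m)


def _rbar_from_pairs(d: np.ndarray) -> Dict[str, float]:
    """Statistics from an (n_pairs, L) mismatch array with NaN for missing."""
    D = np.nansum(d, axis=1)
    scored = (~np.isnan(d)).sum(axis=1)
    D = D[scored > 0].astype(float)
    v_o = _pair_variance(D)
    var_l = np.array([_pair_variance(d[:, l]) for l in range(d.shape[1])])
    var_l = var_l[~np.isnan(var_l)]
    v_e = float(np.sum(var_l))
    s = float(np.sum(np.sqrt(var_l)))
    denom = s * s - v_e  # = 2 * sum_{l<m} sqrt(var_l var_m)
    if v_e == 0 or denom <= 0:
        return {"v_o": v_o, "v_e": v_e, "ia": np.nan, "rbar_d": np.nan}
    return {"v_o": v_o, "v_e": v_e, "ia": v_o / v_e - 1.0,
            "rbar_d": (v_o - v_e) / denom}


def _mismatch_matrices(calls: np.ndarray) -> np.ndarray:
    """(L, n, n) per-locus pairwise mismatch with NaN where either is missing."""
    n, L = calls.shape
    out = np.empty((L, n, n))
    for l in range(L):
        col = calls[:, l]
        m = (col[:, None] != col[None, :]).astype(float)
        miss = col == MISSING
        m[miss, :] = np.nan
        m[:, miss] = np.nan
        out[l] = m
    return out


def rbar_d(data: GenotypeDataset, population: str, n_perm: int = 999,
           seed: Optional[int] = None, clone_corrected: bool = False) -> LinkageResult:
    """Index of association rBarD for one population with a permutation test.

    Parameters
    ----------
    n_perm : int
        Number of within-population per-locus column permutations (0 skips
        the test).
    clone_corrected : bool
        If True, collapse repeated MLGs to a single representative before
        computing the statistic (off by default; relevant only for clonal
        data).
    """
    rows = data.samples_in(population)
    if rows.size == 0:
        raise ValueError(f"unknown population {population!r}")
    sub = data.subset(rows)
    if clone_corrected:
        mlg = find_mlgs(sub)
        _, first = np.unique(mlg, return_index=True)
        sub = sub.subset(np.sort(first))
    calls = sub.calls
    n, L = calls.shape
    n_mlg = int(np.unique(find_mlgs(sub)).size)
    if n < 3 or L < 2:
        raise ValueError("rBarD needs >=3 individuals and >=2 loci")
    M = _mismatch_matrices(calls)
    iu = np.triu_indices(n, k=1)
    d_obs = np.stack([M[l][iu] for l in range(L)], axis=1)
    obs = _rbar_from_pairs(d_obs)
    p = None
    if n_perm > 0 and np.isfinite(obs["rbar_d"]):
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            d_perm = np.empty_like(d_obs)
            for l in range(L):
                pi = rng.permutation(n)
                d_perm[:, l] = M[l][pi[iu[0]], pi[iu[1]]]
            r = _rbar_from_pairs(d_perm)["rbar_d"]
            if np.isfinite(r) and r >= obs["rbar_d"]:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return LinkageResult(population, n, n_mlg, obs["ia"], obs["rbar_d"],
                         obs["v_o"], obs["v_e"], p, n_perm)


def linkage_table(data: GenotypeDataset, n_perm: int = 999,
                  seed: Optional[int] = None) -> pd.DataFrame:
    """rBarD for every population; one row per population."""
    rows = []
    rng = np.random.default_rng(seed)
    for p in data.populations:
        sub_seed = int(rng.integers(2 ** 31))
        try:
            r = rbar_d(data, p, n_perm=n_perm, seed=sub_seed)
            rows.append({"population": p, "n": r.n, "n_MLG": r.n_mlg,
                         "Ia": r.ia, "rBarD": r.rbar_d, "p": r.p_perm,
                         "n_perm": r.n_perm, "seed": sub_seed})
        except ValueError:
            rows.append({"population": p, "n": int(data.samples_in(p).size),
                         "n_MLG": np.nan, "Ia": np.nan, "rBarD": np.nan,
                         "p": np.nan, "n_perm": n_perm, "seed": sub_seed})
    return pd.DataFrame(rows)
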