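"""Hierarchical distance-based AMOVA and pairwise population F_ST.

The molecular variance of haploid multilocus genotypes is partitioned over a
three-level hierarchy (regions / populations within regions / individuals
within populations) from pairwise genetic distances.  The default distance
between two individuals is the number of loci at which their alleles differ
(per-locus 0/1 mismatch, the infinite-allele convention behind F_ST-style
statistics); a stepwise squared repeat-length difference (R_ST-like) is
available via ``metric="stepwise"``.

"Weighted average over loci" means the per-locus sums of squares are
computed with per-locus pairwise deletion of missing calls and then summed
over loci.  Sums of squares follow the standard quadratic forms
(SS_total = (1/N) sum_{i<j} d^2 and the within-group analogues); variance
components come from the expected mean squares of the unbalanced three-level
design with the usual n', n'' coefficients.  Phi statistics:

    Phi_CT = s2_a / s2_tot                (among regions)
    Phi_SC = s2_b / (s2_b + s2_c)         (among populations within regions)
    Phi_ST = (s2_a + s2_b) / s2_tot       (overall)

Permutation schemes: Phi_ST permutes individuals across all populations,
Phi_SC permutes individuals among populations within regions, Phi_CT
permutes whole populations among regions; p = (count >= observed + 1) /
(n_perm + 1).  Negative variance components are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# sums of squares from per-group sufficient statistics
# ---------------------------------------------------------------------------

def _locus_info(calls: np.ndarray) -> List[Tuple[np.ndarray, int, np.ndarray]]:
    """Per locus: (allele codes with -1 for missing, n alleles, raw column)."""
    info = []
    for j in range(calls.shape[1]):
        col = calls[:, j]
        vals = np.unique(col[col != MISSING])
        code = np.searchsorted(vals, col)
        code[col == MISSING] = -1
        info.append((code, max(len(vals), 1), col))
    return info


def _ss_grouping(info, grp: np.ndarray, n_groups: int, metric: str) -> float:
    """Sum over loci of sum_g (1/n_gl) * sum_{i<j in g, scored} d^2_ij."""
    total = 0.0
    for code, n_alleles, col in info:
        scored = code >= 0
        g = grp[scored]
        if metric == "mismatch":
            c = code[scored]
            counts = np.bincount(g * n_alleles + c,
                                 minlength=n_groups * n_alleles
                                 ).reshape(n_groups, n_alleles)
            n_gl = counts.sum(axis=1)
            same = (counts * (counts - 1) // 2).sum(axis=1)
            sum_d = n_gl * (n_gl - 1) // 2 - same
        elif metric == "stepwise":
            x = col[scored].astype(float)
            n_gl = np.bincount(g, minlength=n_groups)
            sx = np.bincount(g, weights=x, minlength=n_groups)
            sx2 = np.bincount(g, weights=x * x, minlength=n_groups)
            sum_d = n_gl * sx2 - sx ** 2
        else:
            raise ValueError(f"unknown metric {metric!r}")
        ok = n_gl > 0
        total += float(np.sum(sum_d[ok] / n_gl[ok]))
    return total


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def _two_level_sigmas(ss_t: float, ss_w: float, pop_sizes: np.ndarray
                      ) -> Tuple[float, float, Tuple[int, int]]:
    """(s2_among, s2_within, (df_among, df_within)) for pops/individuals."""
    N = int(pop_sizes.sum())
    P = pop_sizes.size
    df_a, df_w = P - 1, N - P
    ms_w = ss_w / df_w if df_w else np.nan
    ms_a = (ss_t - ss_w) / df_a if df_a else np.nan
    n0 = (N - np.sum(pop_sizes ** 2) / N) / (P - 1)
    s2_c = ms_w
    s2_a = (ms_a - s2_c) / n0
    return s2_a, s2_c, (df_a, df_w)


def _three_level_coeffs(pop_sizes: np.ndarray, pop_region: np.ndarray,
                        n_regions: int) -> Tuple[float, float, float]:
    N = float(pop_sizes.sum())
    P = pop_sizes.size
    G = n_regions
    region_tot = np.bincount(pop_region, weights=pop_sizes, minlength=G)
    sum_np2 = float(np.sum(pop_sizes.astype(float) ** 2))
    term_g = float(np.sum(
        np.bincount(pop_region, weights=pop_sizes.astype(float) ** 2, minlength=G)
        / region_tot))
    n1 = (N - term_g) / (P - G)
    n2 = (term_g - sum_np2 / N) / (G - 1)
    n3 = (N - float(np.sum(region_tot ** 2)) / N) / (G - 1)
    return n1, n2, n3


def _three_level_sigmas(ss_t, ss_wr, ss_wp, pop_sizes, pop_region, n_regions):
    N = int(pop_sizes.sum())
    P = pop_sizes.size
    G = n_regions
    df_a, df_b, df_c = G - 1, P - G, N - P
    ss_ar = ss_t - ss_wr
    ss_ap = ss_wr - ss_wp
    ms_c = ss_wp / df_c if df_c else np.nan
    ms_b = ss_ap / df_b if df_b else np.nan
    ms_a = ss_ar / df_a if df_a else np.nan
    n1, n2, n3 = _three_level_coeffs(pop_sizes, pop_region, n_regions)
    s2_c = ms_c
    s2_b = (ms_b - s2_c) / n1 if df_b else np.nan
    s2_a = (ms_a - s2_c - n2 * (s2_b if df_b else 0.0)) / n3
    return (s2_a, s2_b, s2_c), (df_a, df_b, df_c), (ss_ar, ss_ap, ss_wp)


def _phis(s2_a: float, s2_b: float, s2_c: float) -> Dict[str, float]:
    tot = s2_a + (0.0 if np.isnan(s2_b) else s2_b) + s2_c
    phi_ct = s2_a / tot if tot else np.nan
    phi_sc = s2_b / (s2_b + s2_c) if not np.isnan(s2_b) and (s2_b + s2_c) else np.nan
    phi_st = (s2_a + (0.0 if np.isnan(s2_b) else s2_b)) / tot if tot else np.nan
    return {"phi_ct": phi_ct, "phi_sc": phi_sc, "phi_st": phi_st}


# ---------------------------------------------------------------------------
# public results
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    table: pd.DataFrame          # stratum, df, SS, sigma2, pct
    phi: Dict[str, float]
    p: Dict[str, Optional[float]]
    n_perm: int

    @property
    def phi_st(self) -> float:
        return self.phi["phi_st"]


@dataclass
class PairwiseFstMatrix:
    fst: pd.DataFrame
    pvalues: pd.DataFrame
    n_perm: int


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova(data: GenotypeDataset, n_perm: int = 20000,
          seed: Optional[int] = None, metric: str = "mismatch") -> AmovaResult:
    """Hierarchical AMOVA with Phi statistics and stratified permutations.

    With a single region the design collapses to the two-level AMOVA
    (among / within populations) and only Phi_ST is reported.
    """
    pops = data.populations
    pop_idx = {p: i for i, p in enumerate(pops)}
    grp = np.array([pop_idx[p] for p in data.pop_labels()])
    pop_sizes = np.bincount(grp, minlength=len(pops))
    regions = data.regions
    reg_idx = {r: i for i, r in enumerate(regions)}
    pop_region = np.array([reg_idx[data.region_of[p]] for p in pops])
    info = _locus_info(data.calls)
    N, P, G = data.n_samples, len(pops), len(regions)
    one = np.zeros(N, dtype=int)
    ss_t = _ss_grouping(info, one, 1, metric)
    ss_wp = _ss_grouping(info, grp, P, metric)
    rng = np.random.default_rng(seed)

    if G < 2:
        s2_a, s2_c, (df_a, df_w) = _two_level_sigmas(ss_t, ss_wp, pop_sizes)
        tot = s2_a + s2_c
        phi = {"phi_st": s2_a / tot if tot else np.nan}
        p: Dict[str, Optional[float]] = {"phi_st": None}
        if n_perm > 0 and np.isfinite(phi["phi_st"]):
            count = 0
            for _ in range(n_perm):
                gp = grp[rng.permutation(N)]
                ssw = _ss_grouping(info, gp, P, metric)
                sa, sc, _ = _two_level_sigmas(ss_t, ssw, pop_sizes)
                t = sa + sc
                if t and sa / t >= phi["phi_st"]:
                    count += 1
            p["phi_st"] = (count + 1) / (n_perm + 1)
        table = pd.DataFrame({
            "stratum": ["Among populations", "Within populations", "Total"],
            "df": [df_a, df_w, N - 1],
            "SS": [ss_t - ss_wp, ss_wp, ss_t],
            "sigma2": [s2_a, s2_c, tot],
            "pct": [100 * s2_a / tot if tot else np.nan,
                    100 * s2_c / tot if tot else np.nan, 100.0],
        })
        return AmovaResult(table, phi, p, n_perm)

    reg_of_ind = pop_region[grp]
    ss_wr = _ss_grouping(info, reg_of_ind, G, metric)
    sigmas, dfs, sss = _three_level_sigmas(ss_t, ss_wr, ss_wp,
                                           pop_sizes, pop_region, G)
    s2_a, s2_b, s2_c = sigmas
    phi = _phis(s2_a, s2_b, s2_c)
    p = {k: None for k in phi}

    if n_perm > 0:
        # Phi_ST: individuals permuted across all populations
        c_st = c_sc = c_ct = 0
        region_blocks = [np.flatnonzero(reg_of_ind == r) for r in range(G)]
        for _ in range(n_perm):
            # across-everything permutation
            gp = grp[rng.permutation(N)]
            sw_p = _ss_grouping(info, gp, P, metric)
            sw_r = _ss_grouping(info, pop_region[gp], G, metric)
            (sa, sb, sc), _, _ = _three_level_sigmas(ss_t, sw_r, sw_p,
                                                     pop_sizes, pop_region, G)
            if _phis(sa, sb, sc)["phi_st"] >= phi["phi_st"] - 1e-12:
                c_st += 1
            # within-region permutation of individuals (regions fixed)
            gp2 = grp.copy()
            for block in region_blocks:
                gp2[block] = gp2[block][rng.permutation(block.size)]
            sw_p2 = _ss_grouping(info, gp2, P, metric)
            (sa, sb, sc), _, _ = _three_level_sigmas(ss_t, ss_wr, sw_p2,
                                                     pop_sizes, pop_region, G)
            ph = _phis(sa, sb, sc)["phi_sc"]
            if np.isfinite(phi["phi_sc"]) and ph >= phi["phi_sc"] - 1e-12:
                c_sc += 1
            # whole populations permuted among regions
            pr = pop_region[rng.permutation(P)]
            sw_r3 = _ss_grouping(info, pr[grp], G, metric)
            (sa, sb, sc), _, _ = _three_level_sigmas(ss_t, sw_r3, ss_wp,
                                                     pop_sizes, pr, G)
            if _phis(sa, sb, sc)["phi_ct"] >= phi["phi_ct"] - 1e-12:
                c_ct += 1
        p["phi_st"] = (c_st + 1) / (n_perm + 1)
        p["phi_sc"] = (c_sc + 1) / (n_perm + 1) if np.isfinite(phi["phi_sc"]) else None
        p["phi_ct"] = (c_ct + 1) / (n_perm + 1)

    df_a, df_b, df_c = dfs
    ss_ar, ss_ap, ss_wp_ = sss
    tot = s2_a + (0.0 if np.isnan(s2_b) else s2_b) + s2_c
    table = pd.DataFrame({
        "stratum": ["Among regions", "Among populations within regions",
                    "Within populations", "Total"],
        "df": [df_a, df_b, df_c, N - 1],
        "SS": [ss_ar, ss_ap, ss_wp_, ss_t],
        "sigma2": [s2_a, s2_b, s2_c, tot],
        "pct": [100 * s2_a / tot, 100 * s2_b / tot if not np.isnan(s2_b) else np.nan,
                100 * s2_c / tot, 100.0],
    })
    return AmovaResult(table, phi, p, n_perm)


# ---------------------------------------------------------------------------
# pairwise F_ST
# ---------------------------------------------------------------------------

def _pair_fst(info, grp: np.ndarray, sizes: np.ndarray, metric: str,
              ss_t: float) -> float:
    ss_w = _ss_grouping(info, grp, 2, metric)
    s2_a, s2_c, _ = _two_level_sigmas(ss_t, ss_w, sizes)
    tot = s2_a + s2_c
    return s2_a / tot if tot else np.nan


def pairwise_fst(data: GenotypeDataset, n_perm: int = 999,
                 seed: Optional[int] = None, metric: str = "mismatch",
                 bh_adjust: bool = False) -> PairwiseFstMatrix:
    """Pairwise Phi_ST between all population pairs with permutation p-values.

    Each pair is a two-population one-level AMOVA; significance permutes
    individuals between the two populations.  Small negative estimates are
    reported as computed.  ``bh_adjust=True`` applies Benjamini-Hochberg
    across pairs (off by default).
    """
    pops = data.populations
    k = len(pops)
    fst = pd.DataFrame(np.zeros((k, k)), index=pops, columns=pops)
    pv = pd.DataFrame(np.full((k, k), np.nan), index=pops, columns=pops)
    np.fill_diagonal(pv.values, 0.0)
    rng = np.random.default_rng(seed)
    labels = data.pop_labels()
    raw_p = []
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            rows = np.flatnonzero((labels == pops[i]) | (labels == pops[j]))
            sizes = np.array([(labels[rows] == pops[i]).sum(),
                              (labels[rows] == pops[j]).sum()])
            if sizes.min() < 2:
                fst.iloc[i, j] = fst.iloc[j, i] = np.nan
                continue
            sub = data.calls[rows]
            info = _locus_info(sub)
            grp = (labels[rows] == pops[j]).astype(int)
            ss_t = _ss_grouping(info, np.zeros(grp.size, dtype=int), 1, metric)
            obs = _pair_fst(info, grp, sizes, metric, ss_t)
            fst.iloc[i, j] = fst.iloc[j, i] = obs
            if n_perm > 0 and np.isfinite(obs):
                count = 0
                for _ in range(n_perm):
                    gp = grp[rng.permutation(grp.size)]
                    f = _pair_fst(info, gp, sizes, metric, ss_t)
                    if np.isfinite(f) and f >= obs - 1e-12:
                        count += 1
                pval = (count + 1) / (n_perm + 1)
                pv.iloc[i, j] = pv.iloc[j, i] = pval
                raw_p.append(pval)
                pairs.append((i, j))
    if bh_adjust and raw_p:
        order = np.argsort(raw_p)
        m = len(raw_p)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(order[::-1]):
            q = raw_p[idx] * m / (m - rank)
            prev = min(prev, q)
            adj[idx] = prev
        for (i, j), q in zip(pairs, adj):
            pv.iloc[i, j] = pv.iloc[j, i] = q
    return PairwiseFstMatrix(fst, pv, n_perm)
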