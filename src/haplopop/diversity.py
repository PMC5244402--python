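"""Within-population and regional genetic diversity.

Implements Nei's unbiased haploid diversity

    uh = n/(n-1) * (1 - sum_a p_a^2)

and rarefaction-standardised allelic richness alpha_g and private allelic
richness pi_g at a common subsample size g.  For a stratum j with N_j
non-missing calls at a locus and N_ja copies of allele a, the probability
that allele a appears in a random subsample of g calls drawn without
replacement is

    Q_ja(g) = 1 - C(N_j - N_ja, g) / C(N_j, g)

so alpha_g = sum_a Q_ja(g), and the expected number of alleles private to
stratum j among size-g samples of every stratum is

    pi_g = sum_a Q_ja(g) * prod_{k != j} (1 - Q_ka(g)).

Binomial ratios are evaluated in log space (gammaln) so sample sizes in the
hundreds are exact to double precision.  Strata whose N_j < g at a locus are
excluded from that locus (for pi_g they are excluded both as focal and as
comparison strata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import AlleleFrequencyTable, GenotypeDataset, allele_frequencies


@dataclass
class DiversityResult:
    """Per-stratum unbiased haploid diversity (per locus + mean/SE over loci)."""

    per_locus: pd.DataFrame     # strata x loci, uh (NaN where undefined)
    mean: pd.Series             # mean over defined loci
    se: pd.Series               # sd over loci / sqrt(L_defined)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"uh_mean": self.mean, "uh_se": self.se})


@dataclass
class RarefactionResult:
    """Rarefied allelic (alpha_g) and private allelic (pi_g) richness."""

    g: int
    alpha: pd.DataFrame         # strata x loci (NaN where N_j < g)
    pi: pd.DataFrame
    alpha_mean: pd.Series
    alpha_se: pd.Series
    pi_mean: pd.Series
    pi_se: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "AR_mean": self.alpha_mean, "AR_se": self.alpha_se,
            "PAR_mean": self.pi_mean, "PAR_se": self.pi_se,
        })
        out["g"] = self.g
        return out


def _mean_se(df: pd.DataFrame) -> Tuple[pd.Series, pd.Series]:
    mean = df.mean(axis=1, skipna=True)
    ncol = df.notna().sum(axis=1)
    sd = df.std(axis=1, ddof=1, skipna=True)
    se = sd / np.sqrt(ncol.where(ncol > 0))
    return mean, se


def unbiased_haploid_diversity(freqs: AlleleFrequencyTable) -> DiversityResult:
    """Nei's unbiased haploid diversity per stratum.

    Cells with fewer than two non-missing calls are undefined (NaN) and are
    excluded from the over-loci mean with a warning.
    """
    table = pd.DataFrame(index=freqs.strata, columns=freqs.loci, dtype=float)
    undefined = []
    for s in freqs.strata:
        for l in freqs.loci:
            n = freqs.n(s, l)
            if n < 2:
                undefined.append((s, l))
                continue
            p = np.array(list(freqs.freqs(s, l).values()))
            h = 1.0 - float(np.sum(p * p))
            table.loc[s, l] = n / (n - 1) * h
    if undefined:
        warnings.warn(
            f"uh undefined (n < 2) for {len(undefined)} (stratum, locus) cells; "
            "excluded from means", stacklevel=2)
    mean, se = _mean_se(table)
    return DiversityResult(table, mean, se)


def _log_binom(n: np.ndarray, k: int) -> np.ndarray:
    """log C(n, k) for integer arrays with n >= k."""
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1) - gammaln(k + 1)


def presence_probability(n_j: int, n_ja: np.ndarray, g: int) -> np.ndarray:
    """Q_ja(g): probability each allele appears in a size-g subsample.

    Stable in log space; alleles with n_ja > n_j - g are certain to appear.
    """
    n_ja = np.asarray(n_ja, dtype=int)
    q = np.ones(n_ja.shape, dtype=float)
    rest = n_j - n_ja
    ok = rest >= g  # otherwise C(rest, g) = 0 and Q = 1
    if np.any(ok):
        logratio = _log_binom(rest[ok], g) - _log_binom(np.array([n_j]), g)
        q[ok] = -np.expm1(logratio)
    return q


def rarefied_allelic_richness(freqs: AlleleFrequencyTable, g: int) -> RarefactionResult:
    """Closed-form rarefaction of allelic and private allelic richness.

    Parameters
    ----------
    freqs : AlleleFrequencyTable
        Population- or region-level counts (regional counts are population
        counts pooled additively).
    g : int
        Standardised subsample size (>= 1).
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    strata, loci = freqs.strata, freqs.loci
    alpha = pd.DataFrame(index=strata, columns=loci, dtype=float)
    pi = pd.DataFrame(index=strata, columns=loci, dtype=float)
    dropped = []
    for l in loci:
        alleles = freqs.alleles(l)
        if not alleles:
            dropped.append(l)
            continue
        a_index = {a: i for i, a in enumerate(alleles)}
        included = [s for s in strata if freqs.n(s, l) >= g]
        if not included:
            dropped.append(l)
            continue
        # Q matrix: strata x alleles
        Q = np.zeros((len(included), len(alleles)))
        for r, s in enumerate(included):
            counts = freqs.counts.get((s, l), {})
            n_ja = np.zeros(len(alleles), dtype=int)
            for a, k in counts.items():
                n_ja[a_index[a]] = k
            Q[r] = presence_probability(freqs.n(s, l), n_ja, g)
        for r, s in enumerate(included):
            alpha.loc[s, l] = float(Q[r].sum())
            others = np.delete(Q, r, axis=0)
            absent_elsewhere = np.prod(1.0 - others, axis=0) if others.size else np.ones(len(alleles))
            pi.loc[s, l] = float(np.sum(Q[r] * absent_elsewhere))
    if dropped:
        warnings.warn(f"loci dropped at g={g} (no stratum with N_j >= g): {dropped}",
                      stacklevel=2)
    a_mean, a_se = _mean_se(alpha)
    p_mean, p_se = _mean_se(pi)
    return RarefactionResult(g, alpha, pi, a_mean, a_se, p_mean, p_se)


def default_g(freqs: AlleleFrequencyTable) -> int:
    """Largest g usable by every stratum at every non-empty locus."""
    mins = []
    for s in freqs.strata:
        ns = [freqs.n(s, l) for l in freqs.loci if not freqs.is_empty(s, l)]
        if ns:
            mins.append(min(ns))
    if not mins:
        raise ValueError("no non-empty cells")
    return max(1, min(mins))


def regional_pooling(data: GenotypeDataset) -> AlleleFrequencyTable:
    """Allele counts pooled additively over populations within each region."""
    return allele_frequencies(data, by="region")


def diversity_table(data: GenotypeDataset, g_population: Optional[int] = None,
                    g_region: Optional[int] = None) -> pd.DataFrame:
    """One row per population then per region: uh, AR and PAR with SEs.

    ``g`` defaults to the largest subsample size available to every stratum
    (per :func:`default_g`).
    """
    pop_freqs = allele_frequencies(data, by="population")
    reg_freqs = regional_pooling(data)
    gp = g_population if g_population is not None else default_g(pop_freqs)
    gr = g_region if g_region is not None else default_g(reg_freqs)
    uh_pop = unbiased_haploid_diversity(pop_freqs)
    uh_reg = unbiased_haploid_diversity(reg_freqs)
    rar_pop = rarefied_allelic_richness(pop_freqs, gp)
    rar_reg = rarefied_allelic_richness(reg_freqs, gr)
    pop = uh_pop.to_frame().join(rar_pop.to_frame())
    pop.insert(0, "level", "population")
    reg = uh_reg.to_frame().join(rar_reg.to_frame())
    reg.insert(0, "level", "region")
    out = pd.concat([pop, reg])
    out.index.name = "stratum"
    return out.reset_index()
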