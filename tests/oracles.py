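"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: rarefaction by exhaustive
subset enumeration, the index of association by explicit pair loops, and
AMOVA sums of squares by explicit pairwise distances.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence

import numpy as np

MISSING = -1


def rarefaction_enumerate(counts: Dict[int, int], g: int) -> float:
    """Expected distinct alleles in a size-g subsample, by full enumeration."""
    pool: List[int] = []
    for allele, k in counts.items():
        pool.extend([allele] * k)
    if g > len(pool):
        raise ValueError("g exceeds sample size")
    total = 0
    n_subsets = 0
    for subset in itertools.combinations(range(len(pool)), g):
        total += len({pool[i] for i in subset})
        n_subsets += 1
    return total / n_subsets


def rarefaction_monte_carlo(counts: Dict[int, int], g: int, n_rep: int,
                            rng: np.random.Generator) -> tuple[float, float]:
    """(mean, standard error) of distinct alleles over random subsamples."""
    pool = np.array([a for a, k in counts.items() for _ in range(k)])
    vals = np.empty(n_rep)
    for i in range(n_rep):
        vals[i] = len(np.unique(rng.choice(pool, size=g, replace=False)))
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_rep))


def _var_pairs(values: Sequence[float]) -> float:
    v = [x for x in values if x is not None]
    m = len(v)
    if m == 0:
        return float("nan")
    mean = sum(v) / m
    return sum((x - mean) ** 2 for x in v) / m


def rbar_brute(calls: np.ndarray) -> float:
    """rBarD by explicit pair loops (per-locus pairwise deletion)."""
    n, L = calls.shape
    per_locus: List[List[float]] = [[] for _ in range(L)]
    D: List[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            any_locus = False
            for l in range(L):
                a, b = calls[i, l], calls[j, l]
                if a == MISSING or b == MISSING:
                    per_locus[l].append(None)
                    continue
                d = 1.0 if a != b else 0.0
                per_locus[l].append(d)
                total += d
                any_locus = True
            D.append(total if any_locus else None)
    v_o = _var_pairs(D)
    var_l = [_var_pairs(col) for col in per_locus]
    var_l = [v for v in var_l if v == v]  # drop NaN
    v_e = sum(var_l)
    cov_terms = 0.0
    for a in range(len(var_l)):
        for b in range(a + 1, len(var_l)):
            cov_terms += (var_l[a] * var_l[b]) ** 0.5
    denom = 2 * cov_terms
    if denom == 0:
        return float("nan")
    return (v_o - v_e) / denom


def amova_ss_brute(calls: np.ndarray, groups: Sequence) -> tuple[float, float]:
    """(SS_total, SS_within_groups) via explicit pairwise mismatch distances.

    Distances are per-locus 0/1 mismatches with pairwise deletion; the
    quadratic forms divide by the per-locus number of scored individuals.
    """
    groups = np.asarray(groups)
    n, L = calls.shape

    def ss_of(indices: np.ndarray) -> float:
        total = 0.0
        for l in range(L):
            scored = [i for i in indices if calls[i, l] != MISSING]
            if not scored:
                continue
            s = 0.0
            for ai in range(len(scored)):
                for bi in range(ai + 1, len(scored)):
                    if calls[scored[ai], l] != calls[scored[bi], l]:
                        s += 1.0
            total += s / len(scored)
        return total

    ss_t = ss_of(np.arange(n))
    ss_w = sum(ss_of(np.flatnonzero(groups == g)) for g in np.unique(groups))
    return ss_t, ss_w
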