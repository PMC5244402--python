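"""Mating-type idiomorph ratio tests and heterothallism checks.

Heterothallic (self-incompatible) fungi carry exactly one idiomorph (MAT1-1
or MAT1-2) per haploid individual, and sexual populations are expected to
hold both near 1:1.  The per-population and pooled goodness-of-fit test
against 1:1 is the textbook chi-square

    chi2 = (n1 - n2)^2 / (n1 + n2),   df = 1,

with NONE (amplification failure) and BOTH (heterothallism violation)
counted but excluded from the test.  A two-sided exact binomial p-value is
reported alongside, preferable when n1 + n2 < 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeDataset, MatTable


def _test_counts(n1: int, n2: int) -> Dict[str, float]:
    n = n1 + n2
    if n == 0:
        return {"chi2": np.nan, "p_chi2": np.nan, "p_exact": np.nan}
    chi2 = (n1 - n2) ** 2 / n
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    p_exact = float(stats.binomtest(n1, n, 0.5).pvalue)
    return {"chi2": chi2, "p_chi2": p_chi2, "p_exact": p_exact}


def mat_ratio_tests(mat: MatTable, data: GenotypeDataset,
                    bonferroni: bool = False) -> pd.DataFrame:
    """Test 1:1 idiomorph balance per population and pooled over all samples.

    Returns one row per population plus an ``overall`` row with counts,
    chi-square and exact binomial p-values.  With ``bonferroni=True`` the
    per-population p-values are multiplied by the number of populations
    (capped at 1); no correction is applied by default.
    """
    mat.check_against(data)
    idio = mat.idiomorph_of()
    rows: List[dict] = []
    pops = data.populations
    pop_labels = data.pop_labels()
    groups = [(p, [s for s, lbl in zip(data.sample_ids, pop_labels) if lbl == p])
              for p in pops]
    groups.append(("overall", list(data.sample_ids)))
    for name, samples in groups:
        calls = [idio.get(s, "NONE") for s in samples]
        n1 = calls.count("MAT1-1")
        n2 = calls.count("MAT1-2")
        n_none = calls.count("NONE")
        n_both = calls.count("BOTH")
        row = {"population": name, "n1": n1, "n2": n2,
               "n_none": n_none, "n_both": n_both}
        row.update(_test_counts(n1, n2))
        rows.append(row)
    out = pd.DataFrame(rows)
    if bonferroni:
        k = len(pops)
        mask = out["population"] != "overall"
        for col in ("p_chi2", "p_exact"):
            out.loc[mask, col] = np.minimum(out.loc[mask, col] * k, 1.0)
    return out


@dataclass
class HeterothallismReport:
    """Consistency of idiomorph calls with strict heterothallism."""

    violations: List[str]        # samples with BOTH idiomorphs
    failures: List[str]          # samples with no amplification (NONE)
    n_samples: int
    success_fraction: float      # fraction with exactly one idiomorph

    @property
    def consistent(self) -> bool:
        return not self.violations


def heterothallism_check(mat: MatTable) -> HeterothallismReport:
    """List BOTH (violation) and NONE (failure) samples; amplification rate."""
    t = mat.table
    violations = list(t.loc[t["idiomorph"] == "BOTH", "sample_id"])
    failures = list(t.loc[t["idiomorph"] == "NONE", "sample_id"])
    n = len(t)
    called = int(t["idiomorph"].isin(["MAT1-1", "MAT1-2"]).sum())
    return HeterothallismReport(violations, failures, n, called / n if n else np.nan)
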