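"""Model-free population structure by DAPC.

Discriminant Analysis of Principal Components proceeds in three steps:

1. encode each haploid individual as a 0/1 allele-indicator vector, with
   missing calls replaced by the mean frequency of the corresponding allele
   over the whole set of individuals (so imputation adds no artefactual
   between-group differentiation);
2. discover clusters by k-means on the leading principal components for
   K = 1..k_max, choosing K by the Bayesian information criterion
   BIC(K) = n*ln(WSS_K/n) + K*ln(n) (ties broken toward smaller K);
3. fit a linear discriminant analysis on the retained PCs with the cluster
   labels, keeping K-1 discriminant functions, and report Gaussian posterior
   membership probabilities per individual.

Columns are centred but not scaled: allele indicators share a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import MISSING, GenotypeDataset


@dataclass
class OneHotMatrix:
    """Individuals x allele-indicator matrix with mean-frequency imputation."""

    X: np.ndarray                       # (N, total alleles), float
    columns: List[Tuple[str, int]]      # (locus, allele), allele ascending within locus
    sample_ids: List[str]

    def column_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.columns, names=["locus", "allele"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.column_index())


def one_hot_impute(data: GenotypeDataset) -> OneHotMatrix:
    """Deterministic allele one-hot encoding with mean-frequency imputation.

    For a fully observed individual the row sums to L exactly; for an
    individual missing at a locus the locus block is filled with the global
    allele frequencies there, so the row still sums to L and every column
    mean equals the global frequency of its allele.
    """
    blocks = []
    columns: List[Tuple[str, int]] = []
    for j, locus in enumerate(data.loci):
        col = data.calls[:, j]
        scored = col != MISSING
        alleles = np.unique(col[scored])
        if alleles.size == 0:
            continue
        block = (col[:, None] == alleles[None, :]).astype(float)
        freqs = block[scored].mean(axis=0)
        block[~scored] = freqs
        blocks.append(block)
        columns.extend((locus, int(a)) for a in alleles)
    X = np.hstack(blocks)
    return OneHotMatrix(X, columns, list(data.sample_ids))


@dataclass
class ClusterResult:
    bic_by_k: Dict[int, float]
    k_opt: int
    labels: np.ndarray            # cluster assignment for k_opt
    pcs: np.ndarray               # retained principal component scores
    n_pca: int
    explained: np.ndarray         # variance fraction per retained PC


@dataclass
class DapcResult:
    bic_by_k: Dict[int, float]
    k_opt: int
    n_pca_retained: int
    cluster_of: np.ndarray
    discriminant_coords: Optional[np.ndarray]   # (N, k_opt-1) or None when k_opt=1
    memberships: Optional[np.ndarray]           # (N, k_opt) posteriors or None
    cluster_by_population: Optional[pd.DataFrame] = None


def _pca_scores(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Centered-PCA scores and variance fractions, full rank."""
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = S > S[0] * 1e-9 if S.size and S[0] > 0 else S > 0
    S = S[keep]
    scores = U[:, keep] * S
    var = S ** 2
    return scores, var / var.sum()


def _default_n_pca(explained: np.ndarray, n: int) -> int:
    """Smallest PC count explaining >= 99% of variance (no hard cap).

    Cluster discovery by k-means does not overfit with many components, and
    truncating the PC space too aggressively concentrates the within-group
    variance onto few axes, which biases the BIC toward spurious extra
    clusters on unstructured data; only the numerically negligible tail is
    dropped.
    """
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, 0.99) + 1)
    return max(1, min(k, explained.size))


def find_clusters(X: OneHotMatrix, k_max: int = 8, n_pca: Optional[int] = None,
                  n_starts: int = 50, seed: Optional[int] = None) -> ClusterResult:
    """k-means cluster discovery on principal components with BIC selection."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    scores, explained = _pca_scores(X.X)
    n = scores.shape[0]
    if n_pca is None:
        n_pca = _default_n_pca(explained, n)
    elif n_pca > scores.shape[1]:
        import warnings
        warnings.warn(f"n_pca={n_pca} exceeds rank {scores.shape[1]}; reduced",
                      stacklevel=2)
        n_pca = scores.shape[1]
    pcs = scores[:, :n_pca]
    rng = np.random.default_rng(seed)
    bic: Dict[int, float] = {}
    labels_by_k: Dict[int, np.ndarray] = {}
    total_ss = float(np.sum((pcs - pcs.mean(axis=0)) ** 2))
    # scale-aware floor: once clusters are exactly recovered the residual
    # WSS is numerical dust, and without a floor the log would rank dust
    # values arbitrarily instead of letting the K-penalty decide
    wss_floor = max(total_ss * 1e-12, 1e-300)
    for k in range(1, min(k_max, n) + 1):
        if k == 1:
            wss = total_ss
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts,
                        random_state=int(rng.integers(2 ** 31)))
            labels_by_k[k] = km.fit_predict(pcs)
            wss = float(km.inertia_)
        bic[k] = n * np.log(max(wss, wss_floor) / n) + k * np.log(n)
    k_opt = min(bic, key=lambda k: (round(bic[k], 10), k))
    return ClusterResult(bic, k_opt, labels_by_k[k_opt], pcs, n_pca,
                         explained[:n_pca])


def cluster_composition(labels: np.ndarray, data: GenotypeDataset) -> pd.DataFrame:
    """Populations x clusters contingency table (rows sum to population sizes)."""
    pops = data.pop_labels()
    k = int(labels.max()) + 1
    out = pd.DataFrame(0, index=data.populations,
                       columns=[f"cluster_{c + 1}" for c in range(k)])
    for p, c in zip(pops, labels):
        out.loc[p, f"cluster_{c + 1}"] += 1
    out.index.name = "population"
    return out


def dapc(X: OneHotMatrix, cluster_of: Optional[np.ndarray] = None,
         n_pca: Optional[int] = None, k_max: int = 8, n_starts: int = 50,
         seed: Optional[int] = None,
         data: Optional[GenotypeDataset] = None) -> DapcResult:
    """Full DAPC: cluster discovery (if labels not given) then discriminants.

    With ``k_opt == 1`` the result carries the clustering only.  A singular
    within-class scatter is handled by the SVD solver with a small
    tolerance.  If ``data`` is given, the per-population cluster composition
    table is attached.
    """
    clus = find_clusters(X, k_max=k_max, n_pca=n_pca, n_starts=n_starts, seed=seed)
    labels = cluster_of if cluster_of is not None else clus.labels
    k = int(np.unique(labels).size)
    comp = cluster_composition(labels, data) if data is not None else None
    if k < 2:
        return DapcResult(clus.bic_by_k, clus.k_opt, clus.n_pca, labels,
                          None, None, comp)
    lda = LinearDiscriminantAnalysis(solver="svd", tol=1e-8)
    lda.fit(clus.pcs, labels)
    coords = lda.transform(clus.pcs)[:, : k - 1]
    memberships = lda.predict_proba(clus.pcs)
    return DapcResult(clus.bic_by_k, clus.k_opt, clus.n_pca, labels,
                      coords, memberships, comp)
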