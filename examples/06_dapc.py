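"""Model-free structure discovery by DAPC.

One-hot allele encoding with mean-frequency imputation of missing calls,
k-means on principal components with BIC selection of K, then linear
discriminants with posterior membership probabilities.
"""

from haplopop import dapc, one_hot_impute, paper_scale_config, simulate

data, *_ = simulate(paper_scale_config(seed=1))

X = one_hot_impute(data)
res = dapc(X, k_max=8, seed=1, data=data)

print("BIC by K:", {k: round(v, 1) for k, v in res.bic_by_k.items()})
print(f"optimal K = {res.k_opt} ({res.n_pca_retained} PCs retained)")
if res.memberships is not None:
    print(f"lowest maximum membership: {res.memberships.max(axis=1).min():.3f}")
    print("\ncluster composition by population:")
    print(res.cluster_by_population.to_string())
# Clusters spread across all populations (rather than one cluster per site)
# indicate admixed gene pools without geographic structure.
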