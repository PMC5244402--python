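"""Multilocus genotype accounting and linkage disequilibrium (rBarD).

Repeated multilocus genotypes and positive rBarD are the two signatures of
clonal reproduction; a freely recombining sexual population shows all
distinct genotypes and rBarD near zero.
"""

import numpy as np

from haplopop import find_mlgs, linkage_table, paper_scale_config, simulate

data, *_ = simulate(paper_scale_config(seed=1))

n_mlg = int(np.unique(find_mlgs(data)).size)
print(f"distinct multilocus genotypes: {n_mlg} of {data.n_samples} "
      f"({'no' if n_mlg == data.n_samples else 'some'} clonality)")

table = linkage_table(data, n_perm=199, seed=1)
print("\npopulation      n   n_MLG   rBarD      p")
for _, row in table.iterrows():
    print(f"{row['population']:14s} {row['n']:3d}   {row['n_MLG']:3.0f}   "
          f"{row['rBarD']:+.3f}  {row['p']:.3f}")
# rBarD near 0 with non-significant p: alleles at different loci associate
# at random, i.e. recombination is free and reproduction sexual.
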